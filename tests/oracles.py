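"""Independent brute-force oracles used to freeze expected values.

Each oracle computes the same quantity as the implementation by a
different, exhaustive route (path enumeration, grid search, direct
likelihood maximisation, or a from-scratch re-derivation) and must stay
independent of the code paths it checks.
"""

import itertools

import numpy as np
from scipy import optimize


def hmm_posterior_enumeration(panel, genotypes, M, T):
    """Dosage posteriors by summing over all 4^m joint chain paths."""
    pos = panel.genetic_pos
    p1, p2 = panel.freq_pop1, panel.freq_pop2
    m = panel.n_markers
    slices = panel.chromosome_slices()

    def chain_trans(d):
        r = np.exp(-T * d)
        return np.array([[r + (1 - r) * (1 - M), (1 - r) * M],
                         [(1 - r) * (1 - M), r + (1 - r) * M]])

    def emit(gj, c1, c2, j):
        if gj < 0:
            return 1.0
        f1 = p1[j] if c1 else p2[j]
        f2 = p1[j] if c2 else p2[j]
        return [(1 - f1) * (1 - f2),
                f1 * (1 - f2) + (1 - f1) * f2,
                f1 * f2][gj]

    post = np.zeros((m, 3))
    total = 1.0
    for sl in slices:
        idx = range(sl.start, sl.stop)
        L = sl.stop - sl.start
        sub_post = np.zeros((L, 3))
        sub_tot = 0.0
        for c1 in itertools.product([0, 1], repeat=L):
            for c2 in itertools.product([0, 1], repeat=L):
                pr = (M if c1[0] else 1 - M) * (M if c2[0] else 1 - M)
                for k in range(1, L):
                    P = chain_trans(pos[sl.start + k] - pos[sl.start + k - 1])
                    pr *= P[c1[k - 1], c1[k]] * P[c2[k - 1], c2[k]]
                for k, j in enumerate(idx):
                    pr *= emit(genotypes[j], c1[k], c2[k], j)
                sub_tot += pr
                for k in range(L):
                    sub_post[k, c1[k] + c2[k]] += pr
        post[sl.start:sl.stop] = sub_post / sub_tot
        total *= sub_tot
    return post, np.log(total)


def admixture_grid_search(panel, genotypes, n_grid=100_001):
    """Global-admixture MLE by exhaustive grid search of the likelihood."""
    grid = np.linspace(0.0, 1.0, n_grid)
    g = np.asarray(genotypes, float)
    obs = g >= 0
    f = grid[:, None] * panel.freq_pop1 + (1 - grid[:, None]) * panel.freq_pop2
    f = np.clip(f, 1e-12, 1 - 1e-12)
    ll = np.where(obs, g * np.log(f) + (2 - g) * np.log1p(-f), 0.0).sum(axis=1)
    return grid[np.argmax(ll)]


def haplotype_loglik_direct(genotypes, freqs):
    """Log-likelihood of unphased 2-SNP genotypes given haplotype freqs."""
    haps = list(itertools.product((0, 1), repeat=2))
    ll = 0.0
    for row in np.atleast_2d(genotypes):
        tot = 0.0
        for i, h1 in enumerate(haps):
            for j, h2 in enumerate(haps):
                if all(g < 0 or a + b == g for g, a, b in zip(row, h1, h2)):
                    tot += freqs[i] * freqs[j]
        ll += np.log(tot)
    return ll


def haplotype_ml_direct(genotypes):
    """Directly maximised 2-SNP haplotype likelihood (softmax simplex)."""
    best = -np.inf
    for start in range(5):
        rng = np.random.default_rng(start)
        x0 = rng.normal(size=4)

        def neg(x):
            f = np.exp(x - x.max())
            f = f / f.sum()
            return -haplotype_loglik_direct(genotypes, f)

        res = optimize.minimize(neg, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000})
        best = max(best, -res.fun)
    return best


def fst_weir_cockerham_reference(p1, n1, p2, n2, h1=None, h2=None):
    """From-scratch Weir-Cockerham theta, general-r formulas at r=2.

    Written directly from the variance-components (a, b, c) definitions,
    summing over both alleles of the biallelic locus, as an independent
    cross-check.
    """
    if h1 is None:
        h1 = 2 * p1 * (1 - p1)
    if h2 is None:
        h2 = 2 * p2 * (1 - p2)
    ns = np.array([n1, n2], float)
    r = len(ns)
    nbar = ns.mean()
    nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
    # multi-allelic route: sum the variance components over both alleles
    a_tot = b_tot = c_tot = 0.0
    for allele_freqs, het in ((np.array([p1, p2]), np.array([h1, h2])),
                              (1 - np.array([p1, p2]), np.array([h1, h2]))):
        pbar = (ns * allele_freqs).sum() / (r * nbar)
        s2 = (ns * (allele_freqs - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * het).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_tot += a
        b_tot += b
        c_tot += c
    return a_tot / (a_tot + b_tot + c_tot)
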