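"""Local-ancestry inference from unphased AIM genotypes.

The hidden state at each marker is the ordered pair of ancestries of an
individual's two haploid chains.  Each chain is an independent two-state
Markov process along the genetic map with switch intensity ``T`` per Morgan
and stationary distribution ``(M, 1 - M)`` over (European, African); the
joint transition kernel is the product of the per-chain kernels.  The
emission of an unphased dosage sums the Bernoulli allele probabilities over
the two orderings of allele assignment; missing genotypes emit probability
one.  Exact forward-backward recursions (scaled per marker) give per-marker
posteriors over European dosage ``a = 0, 1, 2``, run independently per
chromosome.

Global admixture ``M`` is estimated by supervised maximum likelihood under
marker independence: each allele carries the mixture frequency
``M p1 + (1 - M) p2``, and the per-individual likelihood is maximised on
[0, 1] by golden-section search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panel import AimPanel

__all__ = [
    "AncestryPosterior",
    "forward_backward",
    "estimate_global_admixture",
    "mean_local_ancestry",
    "dosage_prior",
]

class DataError(ValueError):
    pass


@dataclass
class AncestryPosterior:
    """Per-marker posteriors over European dosage for a set of individuals.

    gamma: (n, m, 3) posterior P(a | genotypes); rows sum to 1.
    prior: (n, 3) Binomial(2, M_i) dosage prior.
    M: (n,) global proportions the priors derive from.
    loglik: (n,) total observed-data log-likelihood under the null HMM.
    """

    gamma: np.ndarray
    prior: np.ndarray
    M: np.ndarray
    loglik: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_markers(self) -> int:
        return self.gamma.shape[1]

    def local_dosage(self) -> np.ndarray:
        """(n, m) posterior-mean European dosage."""
        return self.gamma @ np.array([0.0, 1.0, 2.0])

    def subset(self, idx) -> "AncestryPosterior":
        return AncestryPosterior(
            self.gamma[idx], self.prior[idx], self.M[idx], self.loglik[idx]
        )


def dosage_prior(M: np.ndarray) -> np.ndarray:
    """Binomial(2, M) prior over European dosage; shape (n, 3)."""
    M = np.atleast_1d(np.asarray(M, float))
    return np.stack([(1 - M) ** 2, 2 * M * (1 - M), M ** 2], axis=1)


def _emission_probs(panel: AimPanel, genotypes: np.ndarray) -> np.ndarray:
    """P(genotype | state) for the 4 ordered chain-pair states.

    Returns (n, m, 4) with state order [AfrAfr, AfrEur, EurAfr, EurEur];
    missing genotypes (-1) emit 1 in every state.
    """
    g = np.asarray(genotypes)
    if g.ndim == 1:
        g = g[None, :]
    if not np.all(np.isin(g, [-1, 0, 1, 2])):
        raise DataError("genotypes must be 0, 1, 2 or -1 (missing)")
    p1, p2 = panel.freq_pop1, panel.freq_pop2  # European, African
    n, m = g.shape
    # per-state allele frequencies of the two chains
    fa = np.stack([p2, p2, p1, p1])  # chain 1 freq per state, (4, m)
    fb = np.stack([p2, p1, p2, p1])  # chain 2 freq per state
    e = np.empty((n, m, 4))
    for s in range(4):
        probs = np.stack([
            (1 - fa[s]) * (1 - fb[s]),
            fa[s] * (1 - fb[s]) + (1 - fa[s]) * fb[s],
            fa[s] * fb[s],
        ])  # (3, m)
        e[:, :, s] = np.where(g >= 0, probs[np.clip(g, 0, 2), np.arange(m)], 1.0)
    return e


def _chain_transition(d: float, T: float, M: np.ndarray):
    """Single-chain 2x2 transition over distance d: entries as (n,) arrays.

    Returns (to_afr | from_afr, to_eur | from_afr, to_afr | from_eur,
    to_eur | from_eur).
    """
    r = np.exp(-T * d)
    to_eur_from_afr = (1 - r) * M
    to_eur_from_eur = r + (1 - r) * M
    return (1 - to_eur_from_afr, to_eur_from_afr,
            1 - to_eur_from_eur, to_eur_from_eur)


def _pair_transition(d: float, T: float, M: np.ndarray) -> np.ndarray:
    """(n, 4, 4) joint kernel: product of two independent chain kernels."""
    aa, ae, ea, ee = _chain_transition(d, T, M)
    single = np.empty((len(M), 2, 2))
    single[:, 0, 0], single[:, 0, 1] = aa, ae
    single[:, 1, 0], single[:, 1, 1] = ea, ee
    return np.einsum("nij,nkl->nikjl", single, single).reshape(len(M), 4, 4)


def forward_backward(
    panel: AimPanel,
    genotypes: np.ndarray,
    M: float | np.ndarray,
    T: float = 6.0,
) -> AncestryPosterior:
    """Exact dosage posteriors for one or many individuals.

    ``genotypes`` is (m,) or (n, m) with -1 for missing; ``M`` a scalar or
    (n,) vector of global European proportions.  Individuals with degenerate
    ``M`` (0 or 1) get the corresponding point-mass posterior directly.
    """
    g = np.asarray(genotypes)
    squeeze = g.ndim == 1
    if squeeze:
        g = g[None, :]
    n, m = g.shape
    M = np.broadcast_to(np.atleast_1d(np.asarray(M, float)), (n,)).copy()
    if np.any((M < 0) | (M > 1)):
        raise DataError("M must lie in [0, 1]")

    gamma = np.empty((n, m, 3))
    loglik = np.zeros(n)
    interior = (M > 0) & (M < 1)
    gamma[M == 0] = [1.0, 0.0, 0.0]
    gamma[M == 1] = [0.0, 0.0, 1.0]
    if np.any(M == 0) or np.any(M == 1):
        # likelihood of the fixed-ancestry genotypes, for completeness
        for val, col in ((0.0, None), (1.0, None)):
            idx = np.flatnonzero(M == val)
            if len(idx) == 0:
                continue
            f = panel.freq_pop1 if val == 1.0 else panel.freq_pop2
            probs = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
            gi = g[idx]
            with np.errstate(divide="ignore"):
                lp = np.where(gi >= 0,
                              np.log(probs[np.clip(gi, 0, 2), np.arange(m)]),
                              0.0)
            loglik[idx] = lp.sum(axis=1)

    idx = np.flatnonzero(interior)
    if len(idx):
        gi, Mi = g[idx], M[idx]
        e = _emission_probs(panel, gi)  # (k, m, 4)
        k = len(idx)
        pi_state = np.stack([
            (1 - Mi) ** 2, (1 - Mi) * Mi, Mi * (1 - Mi), Mi ** 2
        ], axis=1)  # (k, 4)
        post_state = np.empty((k, m, 4))
        ll = np.zeros(k)
        pos = panel.genetic_pos
        for sl in panel.chromosome_slices():
            j0, j1 = sl.start, sl.stop
            L = j1 - j0
            alpha = np.empty((k, L, 4))
            scale = np.empty((k, L))
            a = pi_state * e[:, j0]
            scale[:, 0] = a.sum(axis=1)
            alpha[:, 0] = a / scale[:, 0:1]
            kernels = []
            for t in range(1, L):
                P = _pair_transition(pos[j0 + t] - pos[j0 + t - 1], T, Mi)
                kernels.append(P)
                a = np.einsum("ns,nst->nt", alpha[:, t - 1], P) * e[:, j0 + t]
                scale[:, t] = a.sum(axis=1)
                alpha[:, t] = a / scale[:, t:t + 1]
            beta = np.ones((k, 4))
            post_state[:, j1 - 1] = alpha[:, L - 1]
            for t in range(L - 2, -1, -1):
                P = kernels[t]
                b = np.einsum("nst,nt->ns", P, e[:, j0 + t + 1] * beta)
                b /= scale[:, t + 1:t + 2]
                post_state[:, j0 + t] = alpha[:, t] * b
                beta = b
            # normalise for numerical safety
            post_state[:, j0:j1] /= post_state[:, j0:j1].sum(axis=2, keepdims=True)
            ll += np.log(scale).sum(axis=1)
        # marginalise ordered pairs to dosage
        gsub = np.empty((k, m, 3))
        gsub[:, :, 0] = post_state[:, :, 0]
        gsub[:, :, 1] = post_state[:, :, 1] + post_state[:, :, 2]
        gsub[:, :, 2] = post_state[:, :, 3]
        gamma[idx] = gsub
        loglik[idx] = ll

    out = AncestryPosterior(
        gamma=gamma, prior=dosage_prior(M), M=M, loglik=loglik
    )
    return out


def estimate_global_admixture(
    panel: AimPanel,
    genotypes: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Supervised maximum-likelihood global European proportion.

    Vectorised golden-section search of the marker-independence likelihood
    ``prod_j Binom(2, M p1_j + (1-M) p2_j)(g_j)`` on [0, 1].  Returns a
    scalar for a single genotype vector, else an (n,) array.  If the panel
    is entirely uninformative (p1 = p2 everywhere) a flat-likelihood warning
    is issued and 0.5 returned.
    """
    g = np.asarray(genotypes)
    squeeze = g.ndim == 1
    if squeeze:
        g = g[None, :]
    if not np.all(np.isin(g, [-1, 0, 1, 2])):
        raise DataError("genotypes must be 0, 1, 2 or -1 (missing)")
    if np.any(~np.any(g >= 0, axis=1)):
        raise DataError("need at least one non-missing genotype per individual")
    p1, p2 = panel.freq_pop1, panel.freq_pop2
    if panel.n_markers == 0 or np.allclose(p1, p2):
        warnings.warn("panel uninformative for admixture; returning 0.5")
        res = np.full(g.shape[0], 0.5)
        return res[0] if squeeze else res

    obs = g >= 0
    gg = np.clip(g, 0, 2).astype(float)

    def negll(M: np.ndarray) -> np.ndarray:
        f = np.clip(M[:, None] * p1 + (1 - M[:, None]) * p2, 1e-12, 1 - 1e-12)
        lp = gg * np.log(f) + (2 - gg) * np.log1p(-f)
        return -(np.where(obs, lp, 0.0)).sum(axis=1)

    invphi = (np.sqrt(5) - 1) / 2
    a = np.zeros(g.shape[0])
    b = np.ones(g.shape[0])
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = negll(c), negll(d)
    while np.max(b - a) > tol:
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = negll(c), negll(d)
    M = (a + b) / 2
    # snap to boundary when the optimum sits there
    M = np.where(negll(np.zeros_like(M)) <= negll(M), 0.0, M)
    M = np.where(negll(np.ones_like(M)) <= negll(M), 1.0, M)
    return M[0] if squeeze else M


def mean_local_ancestry(
    posterior: AncestryPosterior, group: np.ndarray | None = None
) -> np.ndarray:
    """Per-marker mean European proportion (posterior dosage / 2) in a group."""
    sub = posterior if group is None else posterior.subset(np.asarray(group))
    if sub.n_individuals == 0:
        raise DataError("empty group")
    return sub.local_dosage().mean(axis=0) / 2.0
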