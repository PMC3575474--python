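"""Single-SNP and haplotype case-control association.

Covers the fine-mapping statistical layer: allelic odds-ratio tests,
genetic-model fits compared by AIC, ancestry-adjusted logistic regression,
EM haplotype-frequency estimation from unphased genotypes, conditional
likelihood-ratio tests, pairwise LD, inverse-variance fixed-effects
meta-analysis, and the standard QC filters (missingness, MAF, control HWE).

Conventions: every allelic result is labelled with the counted allele; the
1-df allelic chi-square is computed without continuity correction; Wald
confidence intervals use z = 1.96; a Haldane-Anscombe 0.5 is added to all
four allele-count cells only when one is zero.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SnpCounts",
    "AssocResult",
    "allelic_test",
    "genotype_model_fit",
    "logistic_adjusted",
    "haplotype_em",
    "HaplotypeResult",
    "conditional_test",
    "ld_pairwise",
    "meta_fixed_effects",
    "qc_filter",
]

_Z95 = 1.959963984540054


class AssocError(ValueError):
    pass


@dataclass
class SnpCounts:
    """Genotype counts of a counted allele in cases and controls.

    ``case`` and ``control`` are (n0, n1, n2): individuals carrying 0, 1, 2
    copies of the counted allele.
    """

    case: tuple[int, int, int]
    control: tuple[int, int, int]
    counted_allele: str = "G"

    def __post_init__(self) -> None:
        if min(*self.case, *self.control) < 0:
            raise AssocError("genotype counts must be nonnegative")

    @classmethod
    def from_dosage(cls, dosage: np.ndarray, phenotype: np.ndarray,
                    counted_allele: str = "G") -> "SnpCounts":
        dosage = np.asarray(dosage)
        phenotype = np.asarray(phenotype, bool)
        ok = dosage >= 0
        def tally(mask):
            return tuple(int(np.sum(dosage[mask & ok] == k)) for k in (0, 1, 2))
        return cls(tally(phenotype), tally(~phenotype), counted_allele)

    def allele_counts(self, group: str) -> tuple[int, int]:
        """(counted, other) allele counts in 'case' or 'control'."""
        n0, n1, n2 = getattr(self, group)
        return n1 + 2 * n2, n1 + 2 * n0

    def allele_freq(self, group: str) -> float:
        a, b = self.allele_counts(group)
        return a / (a + b)


@dataclass
class AssocResult:
    counted_allele: str
    freq_case: float
    freq_control: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    flags: list[str] = field(default_factory=list)


def _or_ci_from_cells(a: float, b: float, c: float, d: float):
    """OR and Wald 95% CI for the 2x2 table [[a, b], [c, d]]."""
    flags = []
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags.append("haldane_correction")
    or_ = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - _Z95 * se), np.exp(np.log(or_) + _Z95 * se)
    return or_, lo, hi, flags


def allelic_test(counts: SnpCounts) -> AssocResult:
    """Allelic 2x2 chi-square test with odds ratio for the counted allele."""
    a, b = counts.allele_counts("case")
    c, d = counts.allele_counts("control")
    if a + b == 0 or c + d == 0:
        raise AssocError("both groups must be non-empty")
    flags = []
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        flags.append("monomorphic")
        return AssocResult(counts.counted_allele, counts.allele_freq("case"),
                           counts.allele_freq("control"), np.nan, np.nan,
                           np.nan, 0.0, 1.0, flags)
    or_, lo, hi, f = _or_ci_from_cells(a, b, c, d)
    flags += f
    table = np.array([[a, b], [c, d]], float)
    exp = table.sum(1, keepdims=True) * table.sum(0) / table.sum()
    chi2 = float(((table - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return AssocResult(counts.counted_allele, counts.allele_freq("case"),
                       counts.allele_freq("control"), or_, lo, hi, chi2, p, flags)


def or_from_freqs(freq_case: float, freq_control: float) -> float:
    """Allelic odds ratio recomputed from two allele frequencies."""
    return (freq_case / (1 - freq_case)) / (freq_control / (1 - freq_control))


# --- genetic-model fits ---------------------------------------------------

def _binom_loglik_2x2(case_exposed, case_ref, ctrl_exposed, ctrl_ref) -> float:
    """Saturated log-likelihood of case status given a binary exposure."""
    ll = 0.0
    for cs, ct in ((case_exposed, ctrl_exposed), (case_ref, ctrl_ref)):
        n = cs + ct
        if n == 0 or cs == 0 or ct == 0:
            continue
        p = cs / n
        ll += cs * np.log(p) + ct * np.log1p(-p)
    return ll


def _logit_from_counts(dosage_levels, case_counts, ctrl_counts, penalized=False):
    """Weighted logistic fit of phenotype on dosage from genotype counts."""
    x, y, w = [], [], []
    for lev, cs, ct in zip(dosage_levels, case_counts, ctrl_counts):
        adj = 0.5 if penalized else 0.0
        for val, n in ((1, cs + adj), (0, ct + adj)):
            if n > 0:
                x.append(lev)
                y.append(val)
                w.append(n)
    X = sm.add_constant(np.asarray(x, float))
    fit = sm.GLM(np.asarray(y, float), X, family=sm.families.Binomial(),
                 freq_weights=np.asarray(w, float)).fit()
    return fit


def genotype_model_fit(counts: SnpCounts) -> pd.DataFrame:
    """Fit allelic/additive, dominant, recessive and genotypic models.

    Returns a DataFrame indexed by model with columns
    ``logL, k, aic, odds_ratio, best, flags``; the best model minimises
    AIC = 2k - 2 logL, ties resolved toward fewer parameters.  Perfect
    separation is flagged and handled with a 0.5-count penalised fit.
    """
    ca, co = counts.case, counts.control
    rows = {}

    # dominant: carriers (n1+n2) vs non-carriers; recessive: n2 vs rest
    for name, split in (("dominant", 1), ("recessive", 2)):
        ce = sum(ca[split:])
        cr = sum(ca[:split])
        te = sum(co[split:])
        tr = sum(co[:split])
        flags = []
        if min(ce, cr, te, tr) == 0:
            flags.append("separation")
        or_, lo, hi, f = _or_ci_from_cells(ce, cr, te, tr)
        ll = _binom_loglik_2x2(ce, cr, te, tr)
        rows[name] = dict(logL=ll, k=2, aic=4 - 2 * ll, odds_ratio=or_,
                          flags=flags + f)

    # additive (allelic trend): logistic on dosage
    flags = []
    try:
        fit = _logit_from_counts((0, 1, 2), ca, co)
        beta = fit.params[1]
        if not np.isfinite(beta) or abs(beta) > 15:
            raise ValueError("separation")
        ll = fit.llf
    except Exception:
        flags.append("separation")
        fit = _logit_from_counts((0, 1, 2), ca, co, penalized=True)
        beta, ll = fit.params[1], fit.llf
    rows["additive"] = dict(logL=ll, k=2, aic=4 - 2 * ll,
                            odds_ratio=float(np.exp(beta)), flags=flags)

    # genotypic: saturated over three genotype classes
    ll = 0.0
    flags = []
    for cs, ct in zip(ca, co):
        n = cs + ct
        if n == 0:
            continue
        if cs == 0 or ct == 0:
            flags.append("separation")
            continue
        p = cs / n
        ll += cs * np.log(p) + ct * np.log1p(-p)
    or_het, *_ = _or_ci_from_cells(ca[1], ca[0], co[1], co[0])
    or_hom, *_ = _or_ci_from_cells(ca[2], ca[0], co[2], co[0])
    rows["genotypic"] = dict(logL=ll, k=3, aic=6 - 2 * ll,
                             odds_ratio=or_hom, flags=flags,
                             odds_ratio_het=or_het)

    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.sort_values(["aic", "k"], kind="stable")
    df["best"] = False
    df.iloc[0, df.columns.get_loc("best")] = True
    return df


def logistic_adjusted(dosage, phenotype, covariate=None, maxiter: int = 100):
    """Logistic regression of phenotype on dosage, optionally adjusted.

    Returns dict with beta, OR, SE, Wald p for the dosage term.  Constant
    covariates are dropped (the fit then equals the unadjusted additive
    model).
    """
    dosage = np.asarray(dosage, float)
    phenotype = np.asarray(phenotype, float)
    ok = dosage >= 0
    cols = [np.ones(ok.sum()), dosage[ok]]
    if covariate is not None:
        cov = np.atleast_2d(np.asarray(covariate, float))
        if cov.shape[0] != len(dosage):
            cov = cov.T
        for c in cov[ok].T:
            if np.ptp(c) > 0:
                cols.append(c)
    X = np.column_stack(cols)
    model = sm.Logit(phenotype[ok], X)
    try:
        fit = model.fit(disp=0, maxiter=maxiter)
        if not fit.mle_retvals.get("converged", True):
            raise AssocError(
                f"logistic fit failed to converge in {maxiter} iterations"
            )
    except np.linalg.LinAlgError as err:
        raise AssocError(f"logistic fit failed: {err}") from err
    beta = fit.params[1]
    se = fit.bse[1]
    return {
        "beta": float(beta),
        "odds_ratio": float(np.exp(beta)),
        "se": float(se),
        "p_value": float(fit.pvalues[1]),
        "loglik": float(fit.llf),
        "fit": fit,
    }


# --- haplotypes -----------------------------------------------------------

@dataclass
class HaplotypeResult:
    """EM haplotype frequencies over ``2**n_snps`` haplotypes.

    ``haplotypes[h]`` is a tuple of per-SNP alleles (1 = counted allele);
    ``frequencies`` aligns with it.  ``diplotype_posterior`` maps each kept
    individual to a list of ((h1, h2), probability).
    """

    haplotypes: list[tuple[int, ...]]
    frequencies: np.ndarray
    loglik: float
    loglik_trace: np.ndarray
    diplotype_posterior: list[list[tuple[tuple[int, int], float]]]
    kept: np.ndarray

    def frequency_of(self, hap: tuple[int, ...]) -> float:
        return float(self.frequencies[self.haplotypes.index(tuple(hap))])

    def expected_dosage(self) -> np.ndarray:
        """(n_kept, n_hap) posterior-expected haplotype counts."""
        out = np.zeros((len(self.diplotype_posterior), len(self.haplotypes)))
        for i, pairs in enumerate(self.diplotype_posterior):
            for (h1, h2), pr in pairs:
                out[i, h1] += pr
                out[i, h2] += pr
        return out


def _compatible_diplotypes(geno_row, haplotypes):
    """Index pairs (h1, h2), h1 <= h2, consistent with an unphased genotype.

    Missing genotypes (negative) are compatible with anything.
    """
    pairs = []
    for i, h1 in enumerate(haplotypes):
        for j in range(i, len(haplotypes)):
            h2 = haplotypes[j]
            if all(g < 0 or a + b == g for g, a, b in zip(geno_row, h1, h2)):
                pairs.append((i, j))
    return pairs


def haplotype_em(
    genotypes: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> HaplotypeResult:
    """Multinomial EM haplotype frequencies from unphased genotypes.

    ``genotypes`` is (n, s) counted-allele dosage with s <= 4 SNPs;
    individuals missing at every SNP are dropped.  Assumes random pairing
    of haplotypes (HWE at the haplotype level); the log-likelihood is
    asserted non-decreasing each iteration and iteration stops when the
    gain drops below ``tol``.
    """
    g = np.atleast_2d(np.asarray(genotypes))
    n, s = g.shape
    if s > 4:
        raise AssocError("haplotype EM supports at most 4 SNPs")
    kept = np.flatnonzero(np.any(g >= 0, axis=1))
    g = g[kept]
    haplotypes = list(itertools.product((0, 1), repeat=s))
    H = len(haplotypes)
    compat = [_compatible_diplotypes(row, haplotypes) for row in g]
    if any(len(c) == 0 for c in compat):
        raise AssocError("genotype incompatible with biallelic haplotypes")

    freq = np.full(H, 1.0 / H)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        ll = 0.0
        expected = np.zeros(H)
        for pairs in compat:
            probs = np.array([
                (2 - (i == j)) * freq[i] * freq[j] for i, j in pairs
            ])
            tot = probs.sum()
            ll += np.log(tot)
            w = probs / tot
            for (i, j), wk in zip(pairs, w):
                expected[i] += wk
                expected[j] += wk
        assert ll >= prev - 1e-9, "EM log-likelihood decreased"
        trace.append(ll)
        if ll - prev < tol:
            prev = ll
            break
        prev = ll
        freq = expected / expected.sum()

    posterior = []
    for pairs in compat:
        probs = np.array([(2 - (i == j)) * freq[i] * freq[j] for i, j in pairs])
        probs = probs / probs.sum()
        posterior.append([(pair, float(pr)) for pair, pr in zip(pairs, probs)])
    return HaplotypeResult(haplotypes, freq, prev, np.array(trace),
                           posterior, kept)


def conditional_test(
    phenotype: np.ndarray,
    target,
    conditioning: np.ndarray,
    mode: str = "snp",
):
    """Likelihood-ratio test of a target beyond conditioning dosages.

    ``mode='snp'``: target is a dosage vector tested in a logistic model
    already containing the conditioning dosages.  ``mode='haplotype'``:
    target is a HaplotypeResult; its expected haplotype dosages (all but a
    reference haplotype) are tested jointly.  Returns dict with lr, df, p.
    """
    phenotype = np.asarray(phenotype, float)
    cond = np.atleast_2d(np.asarray(conditioning, float))
    if cond.shape[0] == len(phenotype) and cond.shape[1] != len(phenotype):
        cond = cond.T
    if mode == "snp":
        tgt = np.atleast_2d(np.asarray(target, float))
        if tgt.shape[0] == len(phenotype) and tgt.shape[1] != len(phenotype):
            tgt = tgt.T
        for c in cond:
            for t in tgt:
                if np.allclose(c, t):
                    raise AssocError("target SNP is in the conditioning set")
    elif mode == "haplotype":
        dos = target.expected_dosage()
        keep = target.kept
        phenotype = phenotype[keep]
        cond = cond[:, keep]
        tgt = dos[:, 1:].T  # drop one reference haplotype
    else:
        raise AssocError(f"unknown mode {mode!r}")

    def fit(X):
        Xc = sm.add_constant(X)
        keep_cols = [0]
        for j in range(1, Xc.shape[1]):
            sub = Xc[:, keep_cols + [j]]
            if np.linalg.matrix_rank(sub) == len(keep_cols) + 1:
                keep_cols.append(j)
            else:
                warnings.warn("aliased predictor dropped from conditional model")
        Xc = Xc[:, keep_cols]
        return sm.Logit(phenotype, Xc).fit(disp=0), Xc.shape[1]

    null_fit, k0 = fit(cond.T)
    full_fit, k1 = fit(np.vstack([cond, tgt]).T)
    df = k1 - k0
    lr = 2 * (full_fit.llf - null_fit.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df=max(df, 1)))
    return {"lr": float(max(lr, 0.0)), "df": int(df), "p_value": p}


def ld_pairwise(g1: np.ndarray, g2: np.ndarray):
    """r^2 and D' between two SNPs from EM haplotype frequencies."""
    g1, g2 = np.asarray(g1), np.asarray(g2)
    for g in (g1, g2):
        gg = g[g >= 0]
        if gg.sum() == 0 or gg.sum() == 2 * len(gg):
            raise AssocError("monomorphic SNP; LD undefined")
    res = haplotype_em(np.column_stack([g1, g2]))
    f = {h: res.frequencies[i] for i, h in enumerate(res.haplotypes)}
    p_a = f[(1, 0)] + f[(1, 1)]
    p_b = f[(0, 1)] + f[(1, 1)]
    D = f[(1, 1)] - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = D ** 2 / denom if denom > 0 else np.nan
    if D >= 0:
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        dmax = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    dprime = abs(D) / dmax if dmax > 0 else np.nan
    return {"r2": float(r2), "d_prime": float(dprime), "D": float(D)}


def meta_fixed_effects(studies: list[tuple[float, float, float]]):
    """Inverse-variance fixed-effects meta-analysis of odds ratios.

    ``studies`` is a list of (OR, ci_low, ci_high); the log-OR standard
    error is recovered as (log hi - log lo) / 3.92.  Returns dict with the
    combined OR, its 95% CI and two-sided p.
    """
    if len(studies) == 0:
        raise AssocError("no studies")
    logs, ws = [], []
    for or_, lo, hi in studies:
        if not (0 < lo <= or_ <= hi):
            raise AssocError(f"invalid OR/CI triple ({or_}, {lo}, {hi})")
        se = (np.log(hi) - np.log(lo)) / (2 * _Z95)
        logs.append(np.log(or_))
        ws.append(1.0 / se ** 2)
    logs, ws = np.asarray(logs), np.asarray(ws)
    combined = float(np.sum(ws * logs) / ws.sum())
    se = float(1.0 / np.sqrt(ws.sum()))
    z = combined / se
    return {
        "odds_ratio": float(np.exp(combined)),
        "ci_low": float(np.exp(combined - _Z95 * se)),
        "ci_high": float(np.exp(combined + _Z95 * se)),
        "p_value": float(2 * stats.norm.sf(abs(z))),
        "n_studies": len(studies),
    }


# --- QC -------------------------------------------------------------------

def hwe_chi2_p(n0: int, n1: int, n2: int) -> float:
    """1-df chi-square Hardy-Weinberg test from genotype counts."""
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    p = (n1 + 2 * n2) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p ** 2])
    obs = np.array([n0, n1, n2], float)
    mask = exp > 0
    chi2 = float((((obs - exp) ** 2)[mask] / exp[mask]).sum())
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    miss_snp: float = 0.10,
    miss_ind: float = 0.05,
    hwe_p: float = 0.001,
    maf: float = 0.01,
    marker_ids=None,
):
    """Standard association QC in fixed order.

    Order: individual missingness (> ``miss_ind``) -> SNP missingness
    (> ``miss_snp``) -> MAF (< ``maf``) -> HWE in controls
    (p < ``hwe_p``).  Returns (filtered genotypes, kept individual index,
    kept SNP index, report DataFrame).
    """
    g = np.asarray(genotypes)
    phenotype = np.asarray(phenotype, bool)
    n, m = g.shape
    ids = np.asarray(marker_ids) if marker_ids is not None else np.arange(m)
    report = []

    miss_i = (g < 0).mean(axis=1)
    keep_ind = miss_i <= miss_ind
    for i in np.flatnonzero(~keep_ind):
        report.append(("individual", i, "missingness", miss_i[i]))
    g = g[keep_ind]
    phe = phenotype[keep_ind]

    keep_snp = np.ones(m, bool)
    miss_j = (g < 0).mean(axis=0) if len(g) else np.zeros(m)
    for j in np.flatnonzero(miss_j > miss_snp):
        keep_snp[j] = False
        report.append(("snp", ids[j], "missingness", miss_j[j]))

    for j in np.flatnonzero(keep_snp):
        col = g[:, j]
        obs = col[col >= 0]
        if len(obs) == 0:
            continue
        f = obs.mean() / 2
        mafj = min(f, 1 - f)
        if mafj < maf:
            keep_snp[j] = False
            report.append(("snp", ids[j], "maf", mafj))

    for j in np.flatnonzero(keep_snp):
        col = g[~phe, j]
        obs = col[col >= 0]
        counts = [int((obs == k).sum()) for k in (0, 1, 2)]
        p = hwe_chi2_p(*counts)
        if p < hwe_p:
            keep_snp[j] = False
            report.append(("snp", ids[j], "hwe", p))

    rep = pd.DataFrame(report, columns=["item_type", "item", "reason", "value"])
    if keep_snp.sum() == 0 or keep_ind.sum() == 0:
        warnings.warn("QC removed everything")
    return g[:, keep_snp], np.flatnonzero(keep_ind), np.flatnonzero(keep_snp), rep
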