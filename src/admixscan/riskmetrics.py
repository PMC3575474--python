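"""Ancestry-aware risk accounting for admixture-mapped loci.

Population attributable risk (PAR) per SNP and jointly across SNPs; the
locus-specific ancestry risk ratio lambda — the disease-risk ratio for
carrying one versus zero European-derived alleles at a locus, computed from
a per-allele odds ratio and the protective-allele frequencies in the two
ancestral populations under a multiplicative genotype model and within-
ancestry HWE; the Weir-Cockerham two-population F_ST estimator; Rosenberg's
informativeness for assignment; and the AIM frequency differential sigma.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "par_single",
    "par_joint",
    "lambda_locus",
    "lambda_combined",
    "fst_wc",
    "informativeness",
    "sigma_diff",
    "percent1",
    "round2",
]


class MetricError(ValueError):
    pass


def par_single(p: float, or_: float, allow_negative: bool = False) -> float:
    """Population attributable risk: p(OR-1) / (p(OR-1) + 1).

    ``p`` is the control frequency of the risk allele and ``or_`` its
    per-allele odds ratio.  By convention the caller orients to the allele
    with OR > 1 (for a protective allele with frequency f and odds ratio r,
    pass ``p = 1 - f`` and ``or_ = 1 / r``); an OR below 1 triggers a
    warning and, unless ``allow_negative``, an error.
    """
    if not (0 <= p <= 1):
        raise MetricError("p must lie in [0, 1]")
    if or_ <= 0:
        raise MetricError("OR must be positive")
    if or_ < 1:
        warnings.warn(
            "OR < 1: orient to the risk allele (p -> 1-p, OR -> 1/OR) "
            "or pass allow_negative=True"
        )
        if not allow_negative:
            raise MetricError("OR < 1 without allow_negative")
    x = p * (or_ - 1.0)
    return x / (x + 1.0)


def reorient_to_risk(freq: float, or_: float) -> tuple[float, float]:
    """Flip a (frequency, OR) pair to the allele with OR >= 1."""
    if or_ >= 1:
        return freq, or_
    return 1.0 - freq, 1.0 / or_


def par_joint(pars) -> float:
    """Joint PAR over independent loci: 1 - prod(1 - PAR_i)."""
    pars = np.asarray(list(pars), float)
    if np.any((pars < 0) | (pars >= 1)):
        raise MetricError("each PAR must lie in [0, 1)")
    return float(1.0 - np.prod(1.0 - pars))


def lambda_locus(p_eur: float, q_afr: float, or_a: float) -> float:
    """Locus-specific ancestry risk ratio for one vs zero European alleles.

    ``p_eur`` and ``q_afr`` are the protective ('a') allele frequencies in
    the European and African ancestral populations and ``or_a`` its
    per-allele odds ratio.  Under within-ancestry HWE, genotype
    probabilities with one European / one African allele are
    (p q, p(1-q) + q(1-p), (1-p)(1-q)) for (aa, Aa, AA) and with two
    African alleles (q^2, 2q(1-q), (1-q)^2); with OR(aa) = OR^2 and
    OR(Aa) = OR (multiplicative model, odds ratios approximating relative
    risks for a rare disease),

        lambda = [pq OR^2 + (p(1-q)+q(1-p)) OR + (1-p)(1-q)]
                 / [q^2 OR^2 + 2q(1-q) OR + (1-q)^2].
    """
    p, q = p_eur, q_afr
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise MetricError("frequencies must lie in [0, 1]")
    if or_a <= 0:
        raise MetricError("OR must be positive")
    num = p * q * or_a ** 2 + (p * (1 - q) + q * (1 - p)) * or_a \
        + (1 - p) * (1 - q)
    den = q ** 2 * or_a ** 2 + 2 * q * (1 - q) * or_a + (1 - q) ** 2
    return num / den


def lambda_combined(lambdas) -> tuple[float, float]:
    """Combined ancestry risk ratio and percent increase.

    Assumes loci contribute independently: the combined ratio is the
    product and the increase is (product - 1) * 100.
    """
    lambdas = np.asarray(list(lambdas), float)
    if np.any(lambdas <= 0):
        raise MetricError("each lambda must be positive")
    prod = float(np.prod(lambdas))
    return prod, (prod - 1.0) * 100.0


def fst_wc(
    p1: float, n1: int, p2: float, n2: int,
    h1: float | None = None, h2: float | None = None,
    clamp: bool = False,
) -> float:
    """Weir-Cockerham theta for two populations at a biallelic locus.

    ``p1, p2`` are allele frequencies, ``n1, n2`` diploid sample sizes and
    ``h1, h2`` observed heterozygote frequencies (HWE proportions
    ``2p(1-p)`` when omitted).  The finite-sample variance-components
    estimator is returned raw — slightly negative values are legitimate —
    unless ``clamp`` is set.  A locus monomorphic in both samples is
    undefined and raises.
    """
    if n1 < 2 or n2 < 2:
        raise MetricError("need at least 2 diploid individuals per sample")
    if h1 is None:
        h1 = 2 * p1 * (1 - p1)
    if h2 is None:
        h2 = 2 * p2 * (1 - p2)
    r = 2
    n = np.array([n1, n2], float)
    p = np.array([p1, p2], float)
    h = np.array([h1, h2], float)
    nbar = n.mean()
    nc = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / (r * nbar)
    if pbar in (0.0, 1.0):
        raise MetricError("locus monomorphic in both samples; theta undefined")
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    theta = a / (a + b + c)
    return float(max(theta, 0.0)) if clamp else float(theta)


def informativeness(p1: float, p2: float) -> float:
    """Rosenberg informativeness for assignment, two populations, biallelic.

    In = -sum_alleles pbar ln pbar + (1/2) sum_pops sum_alleles p ln p,
    with 0 ln 0 = 0.  Ranges from 0 (p1 = p2) to ln 2 (fixed difference).
    """
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise MetricError("frequencies must lie in [0, 1]")

    def xlogx(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0)), 0.0)

    pops = np.array([[p1, 1 - p1], [p2, 1 - p2]])
    pbar = pops.mean(axis=0)
    return float(-xlogx(pbar).sum() + 0.5 * xlogx(pops).sum())


def sigma_diff(p1: float, p2: float) -> float:
    """AIM informativeness sigma: absolute ancestral frequency difference."""
    return float(abs(p1 - p2))


def percent1(x: float) -> float:
    """Fraction to one-decimal percent (printing convention for PAR)."""
    return round(100.0 * x, 1)


def round2(x: float) -> float:
    """Two-decimal rounding (printing convention for odds ratios)."""
    return round(x, 2)
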