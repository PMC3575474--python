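"""Admixture-scan statistics.

Case-only scan: at marker ``j`` and risk model ``psi`` (multiplicative
disease risk per European allele), each case contributes

    log10 [ sum_a gamma_{ija} psi^a  /  sum_a pi_{ia} psi^a ]

where ``gamma`` is the posterior over European dosage under the null HMM
and ``pi`` the Binomial(2, M_i) prior from the case's global admixture.
The per-marker sum over cases is the LOD score for that risk model.  A
weighted score averages over a grid of risk models under a gamma prior on
psi (default: 27 models, 0.4-3.0, weights from a gamma density with mean
1.6 and SD 0.3); a genome score averages per-marker scores.  Both averages
default to Bayes-factor averaging (log10 of the mean of 10^LOD) with a
``literal`` arithmetic-mean alternative.

Case-control scan: Z statistic on the local deviation from global ancestry,
``D_ij = (posterior dosage)/2 - M_i``, compared between cases and controls
with a pooled two-sample standard error.

Score interpretation follows the conventional admixture-mapping thresholds:
LOD > 2 suggestive, LOD > 5 genome-wide significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .hmm import AncestryPosterior, forward_backward
from .panel import AimPanel
from .simulate import DiseaseModel, ParameterError, ascertain_cases

__all__ = [
    "RiskModel",
    "ScanResult",
    "case_only_lod",
    "weighted_lod",
    "genome_score",
    "case_control_z",
    "run_case_only_scan",
    "simulate_null_maxima",
    "empirical_peak_pvalue",
    "stratified_scan",
    "estimate_risk",
]

LOD_SUGGESTIVE = 2.0
LOD_SIGNIFICANT = 5.0

_LN10 = np.log(10.0)


@dataclass
class RiskModel:
    """Grid of multiplicative ancestry risk models with prior weights."""

    psi_grid: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.psi_grid = np.asarray(self.psi_grid, float)
        self.weights = np.asarray(self.weights, float)
        if self.psi_grid.size == 0:
            raise ParameterError("empty risk-model grid")
        if np.any(self.psi_grid <= 0):
            raise ParameterError("psi must be positive")
        if np.any(self.weights < 0):
            raise ParameterError("weights must be nonnegative")
        self.weights = self.weights / self.weights.sum()

    @classmethod
    def default(cls, mean: float = 1.6, sd: float = 0.3,
                lo: float = 0.4, hi: float = 3.0, n: int = 27) -> "RiskModel":
        """27 risk models on [0.4, 3.0] weighted by a gamma(mean 1.6, SD 0.3)."""
        grid = np.linspace(lo, hi, n)
        shape = (mean / sd) ** 2
        scale = sd ** 2 / mean
        w = stats.gamma.pdf(grid, a=shape, scale=scale)
        return cls(grid, w)

    @classmethod
    def fixed(cls, psi: float) -> "RiskModel":
        return cls(np.array([psi]), np.array([1.0]))

    @classmethod
    def fine(cls, lo: float = 1.3, hi: float = 1.6, step: float = 0.01,
             mean: float = 1.6, sd: float = 0.3) -> "RiskModel":
        """Fine weighted grid used to localise the risk estimate."""
        n = int(round((hi - lo) / step)) + 1
        grid = lo + step * np.arange(n)
        shape = (mean / sd) ** 2
        scale = sd ** 2 / mean
        return cls(grid, stats.gamma.pdf(grid, a=shape, scale=scale))


@dataclass
class ScanResult:
    """Output of a case-only (and optionally case-control) scan."""

    marker_ids: np.ndarray
    model: RiskModel
    lod: np.ndarray = field(repr=False)  # (n_psi, m)
    weighted: np.ndarray = field(repr=False)  # (m,)
    genome: float = 0.0
    z: np.ndarray | None = field(default=None, repr=False)
    z_pvalue: np.ndarray | None = field(default=None, repr=False)
    n_cases: int = 0
    n_controls: int = 0

    @property
    def best_index(self) -> int:
        return int(np.argmax(self.weighted))

    @property
    def best_marker(self) -> str:
        return str(self.marker_ids[self.best_index])

    @property
    def best_lod(self) -> float:
        return float(self.weighted[self.best_index])


def case_only_lod(
    posterior: AncestryPosterior, psi: float | np.ndarray
) -> np.ndarray:
    """Per-marker case-only LOD for one risk model or a grid.

    Returns (m,) for scalar ``psi``, else (n_psi, m).
    """
    psi_arr = np.atleast_1d(np.asarray(psi, float))
    if np.any(psi_arr <= 0):
        raise ParameterError("psi must be positive")
    n, m, _ = posterior.gamma.shape
    lod = np.empty((len(psi_arr), m))
    for p, ps in enumerate(psi_arr):  # one grid point at a time: O(n m) memory
        w = np.array([1.0, ps, ps * ps])
        num = posterior.gamma @ w  # (n, m)
        den = posterior.prior @ w  # (n,)
        lod[p] = np.log10(num).sum(axis=0) - np.log10(den).sum()
    return lod[0] if np.isscalar(psi) or np.ndim(psi) == 0 else lod


def weighted_lod(
    lod_matrix: np.ndarray, model: RiskModel, mode: str = "bayes_average"
) -> np.ndarray:
    """Combine per-model LODs into one per-marker score.

    ``bayes_average``: log10 of the weighted mean Bayes factor,
    ``log10(sum_m w_m 10^LOD_m)``; ``literal``: weighted arithmetic mean of
    the LODs.
    """
    lod = np.atleast_2d(np.asarray(lod_matrix, float))
    if lod.shape[0] != len(model.psi_grid):
        raise ParameterError("LOD matrix rows must match the psi grid")
    if mode == "literal":
        return model.weights @ lod
    if mode == "bayes_average":
        return logsumexp(
            lod * _LN10, axis=0, b=model.weights[:, None]
        ) / _LN10
    raise ParameterError(f"unknown mode {mode!r}")


def genome_score(scores: np.ndarray, mode: str = "bayes_average") -> float:
    """Genome-wide score: average of per-marker scores.

    ``bayes_average``: log10 of the mean of 10^score; ``literal``: plain
    mean.
    """
    scores = np.asarray(scores, float)
    if scores.size == 0:
        raise ParameterError("no markers")
    if mode == "literal":
        return float(scores.mean())
    if mode == "bayes_average":
        return float(logsumexp(scores * _LN10) / _LN10 - np.log10(scores.size))
    raise ParameterError(f"unknown mode {mode!r}")


def case_control_z(
    case_posterior: AncestryPosterior, control_posterior: AncestryPosterior
):
    """Per-marker case-control Z on local-vs-global ancestry deviation.

    Returns (z, two_sided_p); markers with zero variance in both groups
    yield NaN with a warning.
    """
    if case_posterior.n_individuals == 0 or control_posterior.n_individuals == 0:
        raise ParameterError("both groups must be non-empty")
    d_case = case_posterior.local_dosage() / 2 - case_posterior.M[:, None]
    d_ctrl = control_posterior.local_dosage() / 2 - control_posterior.M[:, None]
    n1, n2 = d_case.shape[0], d_ctrl.shape[0]
    v1 = d_case.var(axis=0, ddof=1) if n1 > 1 else np.zeros(d_case.shape[1])
    v2 = d_ctrl.var(axis=0, ddof=1) if n2 > 1 else np.zeros(d_ctrl.shape[1])
    se = np.sqrt(v1 / n1 + v2 / n2)
    diff = d_case.mean(axis=0) - d_ctrl.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.nan))
    if np.any(se == 0):
        warnings.warn("zero-variance markers in case-control Z; NaN returned")
    p = 2 * stats.norm.sf(np.abs(z))
    return z, p


def run_case_only_scan(
    panel: AimPanel,
    case_genotypes: np.ndarray,
    case_M: np.ndarray,
    model: RiskModel | None = None,
    T: float = 6.0,
    mode: str = "bayes_average",
    control_genotypes: np.ndarray | None = None,
    control_M: np.ndarray | None = None,
) -> ScanResult:
    """Full scan: HMM posteriors, LOD grid, weighted score, genome score.

    Optionally adds the case-control Z when control genotypes are given.
    """
    model = model or RiskModel.default()
    post = forward_backward(panel, case_genotypes, case_M, T)
    lod = case_only_lod(post, model.psi_grid)
    wl = weighted_lod(lod, model, mode)
    z = pz = None
    n_controls = 0
    if control_genotypes is not None:
        ctrl_post = forward_backward(panel, control_genotypes, control_M, T)
        z, pz = case_control_z(post, ctrl_post)
        n_controls = ctrl_post.n_individuals
    return ScanResult(
        marker_ids=panel.table["marker_id"].to_numpy(),
        model=model,
        lod=lod,
        weighted=wl,
        genome=genome_score(wl, mode),
        z=z,
        z_pvalue=pz,
        n_cases=post.n_individuals,
        n_controls=n_controls,
    )


def simulate_null_maxima(
    panel: AimPanel,
    n_cases: int,
    n_replicates: int,
    T: float = 6.0,
    admixture_mean: float = 0.175,
    admixture_sd: float = 0.09,
    model: RiskModel | None = None,
    mode: str = "bayes_average",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Best genome-wide weighted LOD from replicate null cohorts (psi=1).

    Scans use the cohorts' true global proportions; replicate seeds are
    split deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    model = model or RiskModel.default()
    null = DiseaseModel(causal_marker=None, psi=1.0)
    maxima = np.empty(n_replicates)
    for r in range(n_replicates):
        cohort = ascertain_cases(
            panel, null, n_cases, 0, T=T,
            admixture_mean=admixture_mean, admixture_sd=admixture_sd,
            seed=rng.integers(2 ** 31),
        )
        res = run_case_only_scan(
            panel, cohort.genotypes, cohort.M, model=model, T=T, mode=mode
        )
        maxima[r] = res.weighted.max()
    return maxima


def empirical_peak_pvalue(observed_best: float, null_maxima: np.ndarray) -> float:
    """Upper-tail normal probability of the observed best score.

    A normal distribution is fitted to the null replicate maxima and the
    one-sided (European-excess) tail probability of ``observed_best``
    returned.
    """
    null_maxima = np.asarray(null_maxima, float)
    if null_maxima.size < 2:
        raise ParameterError("need at least 2 null replicates")
    mu, sd = null_maxima.mean(), null_maxima.std(ddof=1)
    if sd == 0:
        raise ParameterError("degenerate null distribution (zero SD)")
    return float(stats.norm.sf(observed_best, loc=mu, scale=sd))


def stratified_scan(
    panel: AimPanel,
    case_genotypes: np.ndarray,
    case_M: np.ndarray,
    stratifier: str,
    model: RiskModel | None = None,
    T: float = 6.0,
    mode: str = "bayes_average",
) -> dict[int, ScanResult]:
    """Repeat the case-only scan within each genotype class at one SNP.

    Returns {genotype dosage: ScanResult}; individuals missing at the
    stratifier are excluded from every stratum, and empty strata are
    skipped with a warning.
    """
    j = panel.marker_index(stratifier)
    g = np.atleast_2d(case_genotypes)
    strat = g[:, j]
    out: dict[int, ScanResult] = {}
    for dose in (0, 1, 2):
        idx = np.flatnonzero(strat == dose)
        if len(idx) == 0:
            warnings.warn(f"stratum dosage={dose} is empty; skipped")
            continue
        out[dose] = run_case_only_scan(
            panel, g[idx], np.asarray(case_M)[idx], model=model, T=T, mode=mode
        )
    return out


def estimate_risk(
    posterior: AncestryPosterior,
    model: RiskModel | None = None,
    marker: int | None = None,
    mode: str = "bayes_average",
):
    """Best-supported psi on a fine grid, with its score profile.

    Maximises the genome score (default) or a single marker's LOD over the
    grid; ties break toward the smaller psi.  A flat profile triggers a
    warning and returns the grid midpoint.
    """
    model = model or RiskModel.fine()
    lod = case_only_lod(posterior, model.psi_grid)
    if marker is None:
        profile = np.array([genome_score(lod[i], mode) for i in range(lod.shape[0])])
    else:
        profile = lod[:, marker]
    if len(model.psi_grid) > 1 and np.ptp(profile) < 1e-12:
        warnings.warn("flat risk profile; returning grid midpoint")
        return float(model.psi_grid[len(model.psi_grid) // 2]), profile
    return float(model.psi_grid[int(np.argmax(profile))]), profile
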