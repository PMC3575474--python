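"""Synthetic two-way admixed cohorts.

Each haploid genome is a continuous two-state Markov chain along the genetic
map: ancestry switches occur at intensity ``T`` per Morgan (``T`` generations
since admixture under the Poisson-crossover approximation) and the stationary
distribution is ``(M, 1 - M)`` over (European, African).  Over a genetic
distance ``d`` the chain stays in the same state with probability
``exp(-T d) + (1 - exp(-T d)) * stationary(state)``.  Alleles at each AIM are
drawn independently given the chain's ancestry (linkage equilibrium within
each ancestral population), and the unphased genotype is the sum over the
two chains.

Case ascertainment follows a single-locus multiplicative model: an
individual with ``a`` European alleles at the causal marker is a case with
probability ``baseline * psi**a``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import AimPanel, PanelError

EUROPEAN, AFRICAN = 1, 0  # chain-state coding in truth tracts


class ParameterError(ValueError):
    pass


@dataclass
class DiseaseModel:
    """Single-locus multiplicative ancestry risk model.

    ``psi`` is the disease-risk multiplier per European allele at
    ``causal_marker``; ``baseline`` is the case probability for carriers of
    zero European alleles.  ``psi=1`` is the null (no causal locus).
    """

    causal_marker: str | None = None
    psi: float = 1.0
    baseline: float = 0.05

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ParameterError("psi must be >= 0")
        if not (0 < self.baseline < 1):
            raise ParameterError("baseline must be in (0, 1)")
        if self.baseline * max(1.0, self.psi) ** 2 > 1:
            raise ParameterError(
                f"baseline * psi^2 = {self.baseline * self.psi ** 2:.3g} exceeds 1"
            )

    def case_probability(self, a: np.ndarray) -> np.ndarray:
        return np.minimum(self.baseline * self.psi ** np.asarray(a, float), 1.0)


@dataclass
class Cohort:
    """Genotyped case-control sample with simulation truth.

    genotypes: (n, m) int8 reference-allele dosage, -1 = missing.
    phenotype: (n,) bool, True = case.
    M: (n,) true global European proportion.
    tracts: (n, 2, m) uint8 chain ancestry (1 = European), or None.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    M: np.ndarray
    tracts: np.ndarray | None = None
    panel: AimPanel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        g = self.genotypes
        if not np.all(np.isin(g, [-1, 0, 1, 2])):
            raise ParameterError("dosages must be in {0,1,2} or -1 (missing)")
        if np.any((self.M < 0) | (self.M > 1)):
            raise ParameterError("M must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return len(self.phenotype)

    @property
    def cases(self) -> np.ndarray:
        return np.flatnonzero(self.phenotype)

    @property
    def controls(self) -> np.ndarray:
        return np.flatnonzero(~self.phenotype)


def _stay_prob(d: np.ndarray, T: float) -> np.ndarray:
    """P(no net switch memory) over distance d: weight on copying the state."""
    return np.exp(-T * np.asarray(d, float))


def _simulate_chains(
    panel: AimPanel, M: np.ndarray, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Ancestry states (n, 2, m) for n individuals, 2 chains, m markers."""
    M = np.atleast_1d(np.asarray(M, float))
    n, m = len(M), panel.n_markers
    states = np.empty((n, 2, m), dtype=np.uint8)
    Mcol = M[:, None]
    for sl in panel.chromosome_slices():
        pos = panel.genetic_pos[sl]
        j0 = sl.start
        states[:, :, j0] = rng.random((n, 2)) < Mcol
        for k in range(1, len(pos)):
            stay = _stay_prob(pos[k] - pos[k - 1], T)
            copy = rng.random((n, 2)) < stay
            fresh = rng.random((n, 2)) < Mcol
            states[:, :, j0 + k] = np.where(copy, states[:, :, j0 + k - 1], fresh)
    return states


def _simulate_chains_conditional(
    panel: AimPanel,
    M: np.ndarray,
    T: float,
    anchor: int,
    anchor_states: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Chains conditioned on their states at marker index ``anchor``.

    The stationary two-state chain is reversible, so conditioning on the
    anchor and propagating outward in both directions with the forward
    kernel reproduces the unconditional law restricted to the anchor states.
    """
    M = np.atleast_1d(np.asarray(M, float))
    n, m = len(M), panel.n_markers
    states = np.empty((n, 2, m), dtype=np.uint8)
    Mcol = M[:, None]
    chroms = panel.chrom
    anchor_chrom = chroms[anchor]
    for sl in panel.chromosome_slices():
        pos = panel.genetic_pos[sl]
        j0 = sl.start
        if chroms[j0] != anchor_chrom:
            # other chromosomes are independent of the anchor
            states[:, :, sl] = _simulate_chains(
                AimPanel(panel.table.iloc[sl]), M, T, rng
            )
            continue
        states[:, :, anchor] = anchor_states
        for k in range(anchor + 1, sl.stop):  # rightward
            stay = _stay_prob(pos[k - j0] - pos[k - 1 - j0], T)
            copy = rng.random((n, 2)) < stay
            fresh = rng.random((n, 2)) < Mcol
            states[:, :, k] = np.where(copy, states[:, :, k - 1], fresh)
        for k in range(anchor - 1, j0 - 1, -1):  # leftward, by reversibility
            stay = _stay_prob(pos[k + 1 - j0] - pos[k - j0], T)
            copy = rng.random((n, 2)) < stay
            fresh = rng.random((n, 2)) < Mcol
            states[:, :, k] = np.where(copy, states[:, :, k + 1], fresh)
    return states


def _genotypes_from_chains(
    panel: AimPanel, states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reference-allele dosages given chain ancestries."""
    f1, f2 = panel.freq_pop1, panel.freq_pop2
    freqs = np.where(states == EUROPEAN, f1[None, None, :], f2[None, None, :])
    alleles = rng.random(states.shape) < freqs
    return alleles.sum(axis=1).astype(np.int8)


def simulate_individual(
    panel: AimPanel, M: float, T: float = 6.0, seed: int | np.random.Generator = 0
):
    """Simulate one admixed individual: (tracts (2, m), genotypes (m,)).

    ``M`` is the individual's European proportion; ``T`` the number of
    generations since admixture (switch intensity per Morgan).
    """
    if not (0 <= M <= 1):
        raise ParameterError("M must lie in [0, 1]")
    if T <= 0:
        raise ParameterError("T must be positive")
    rng = np.random.default_rng(seed)
    states = _simulate_chains(panel, np.array([M]), T, rng)
    geno = _genotypes_from_chains(panel, states, rng)
    return states[0], geno[0]


def draw_admixture_proportions(
    n: int,
    mean: float = 0.175,
    sd: float = 0.09,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Global European proportions from a normal truncated to [0, 1].

    Defaults emulate the African-American admixture distribution
    (mean 17.5%, SD 9%).
    """
    rng = np.random.default_rng(rng)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled) + 16)
        draw = draw[(draw >= 0) & (draw <= 1)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def ascertain_cases(
    panel: AimPanel,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    T: float = 6.0,
    admixture_mean: float = 0.175,
    admixture_sd: float = 0.09,
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Sample a case-control cohort under single-locus ascertainment.

    Individuals are drawn from the admixed population; each is retained as a
    case with probability ``baseline * psi**a`` (``a`` = true European
    dosage at the causal marker) and as a control with the complementary
    probability, until the requested numbers accrue.  Truth tracts and true
    ``M`` are kept for validation.

    Ascertainment only depends on the causal-locus ancestry, so the sampler
    draws ``(M, causal chain states)`` first, assigns disease status, and
    fills in the rest of the genome conditionally for retained individuals;
    this is distributionally identical to rejecting whole genomes.
    """
    rng = np.random.default_rng(seed)
    if model.causal_marker is None:
        anchor = panel.n_markers // 2 if panel.n_markers else 0
        if model.psi != 1.0:
            raise ParameterError("a non-null DiseaseModel needs a causal_marker")
    else:
        anchor = panel.marker_index(model.causal_marker)

    kept_M: list[np.ndarray] = []
    kept_states: list[np.ndarray] = []
    kept_pheno: list[np.ndarray] = []
    got_cases = got_controls = 0
    p_case_floor = model.baseline  # rough batch sizing
    while got_cases < n_cases or got_controls < n_controls:
        need_cases = max(n_cases - got_cases, 0)
        need_controls = max(n_controls - got_controls, 0)
        batch = int(min(max(need_cases / max(p_case_floor, 1e-3), need_controls,
                            1024) * 1.3, 500_000))
        M = draw_admixture_proportions(batch, admixture_mean, admixture_sd, rng)
        anchor_states = (rng.random((batch, 2)) < M[:, None]).astype(np.uint8)
        a = anchor_states.sum(axis=1)
        is_case = rng.random(batch) < model.case_probability(a)
        case_idx = np.flatnonzero(is_case)[:need_cases]
        ctrl_idx = np.flatnonzero(~is_case)[:need_controls]
        keep = np.concatenate([case_idx, ctrl_idx])
        if len(keep):
            kept_M.append(M[keep])
            kept_states.append(anchor_states[keep])
            kept_pheno.append(np.concatenate(
                [np.ones(len(case_idx), bool), np.zeros(len(ctrl_idx), bool)]
            ))
        got_cases += len(case_idx)
        got_controls += len(ctrl_idx)

    M = np.concatenate(kept_M)
    anchor_states = np.concatenate(kept_states)
    phenotype = np.concatenate(kept_pheno)
    # cases first, then controls, in draw order
    order = np.argsort(~phenotype, kind="stable")
    M, anchor_states, phenotype = M[order], anchor_states[order], phenotype[order]

    tracts = _simulate_chains_conditional(panel, M, T, anchor, anchor_states, rng)
    genotypes = _genotypes_from_chains(panel, tracts, rng)
    return Cohort(genotypes=genotypes, phenotype=phenotype, M=M,
                  tracts=tracts, panel=panel)
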