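"""Ancestry-informative-marker (AIM) panels.

An AIM panel is an ordered set of biallelic markers with the frequency of a
designated reference allele in each of the two ancestral populations
(population 1 = European, population 2 = African by convention) and a
genetic-map position in Morgans.  The per-marker ancestry informativeness is
summarised by ``sigma = |freq_pop1 - freq_pop2|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

PANEL_COLUMNS = [
    "marker_id",
    "chrom",
    "genetic_pos_M",
    "phys_pos_bp",
    "freq_pop1",
    "freq_pop2",
]

# Approximate sex-averaged genetic lengths of the human autosomes, in Morgans.
HUMAN_AUTOSOME_MORGANS: dict[int, float] = {
    1: 2.86, 2: 2.69, 3: 2.23, 4: 2.14, 5: 2.04, 6: 1.92, 7: 1.87,
    8: 1.68, 9: 1.66, 10: 1.81, 11: 1.58, 12: 1.75, 13: 1.26, 14: 1.19,
    15: 1.41, 16: 1.34, 17: 1.29, 18: 1.18, 19: 1.08, 20: 1.08,
    21: 0.62, 22: 0.74,
}

# bp per Morgan used to synthesise physical positions (1 cM/Mb average rate).
_BP_PER_MORGAN = 100_000_000


class PanelError(ValueError):
    """Raised for malformed or infeasible panel specifications."""


@dataclass
class AimPanel:
    """Ordered marker table with ancestral allele frequencies.

    Parameters
    ----------
    table
        DataFrame with columns ``marker_id, chrom, genetic_pos_M,
        phys_pos_bp, freq_pop1, freq_pop2``; markers must be sorted by
        (chrom, genetic_pos_M) with strictly increasing genetic positions
        within each chromosome.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise PanelError(f"panel table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        f1 = self.table["freq_pop1"].to_numpy(float)
        f2 = self.table["freq_pop2"].to_numpy(float)
        # NaN frequencies are allowed (panels read from map files lack them)
        if np.any((f1 < 0) | (f1 > 1)) or np.any((f2 < 0) | (f2 > 1)):
            raise PanelError("allele frequencies must lie in [0, 1]")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["genetic_pos_M"].to_numpy(float)
            if np.any(np.diff(pos) <= 0):
                raise PanelError(
                    f"genetic positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def freq_pop1(self) -> np.ndarray:
        return self.table["freq_pop1"].to_numpy(float)

    @property
    def freq_pop2(self) -> np.ndarray:
        return self.table["freq_pop2"].to_numpy(float)

    @property
    def sigma(self) -> np.ndarray:
        """Per-marker absolute ancestral frequency difference."""
        return np.abs(self.freq_pop1 - self.freq_pop2)

    @property
    def genetic_pos(self) -> np.ndarray:
        return self.table["genetic_pos_M"].to_numpy(float)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def chromosome_slices(self) -> list[slice]:
        """Contiguous index slices, one per chromosome, in table order."""
        out: list[slice] = []
        chroms = self.table["chrom"].to_numpy()
        if len(chroms) == 0:
            return out
        start = 0
        for j in range(1, len(chroms) + 1):
            if j == len(chroms) or chroms[j] != chroms[start]:
                out.append(slice(start, j))
                start = j
        return out

    def marker_index(self, marker_id: str) -> int:
        idx = self.table.index[self.table["marker_id"] == marker_id]
        if len(idx) == 0:
            raise KeyError(f"marker {marker_id!r} not in panel")
        return int(idx[0])

    def swap_populations(self) -> "AimPanel":
        """Panel with the two ancestral populations relabelled."""
        t = self.table.copy()
        t[["freq_pop1", "freq_pop2"]] = t[["freq_pop2", "freq_pop1"]].to_numpy()
        return AimPanel(t)

    # --- I/O -------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "AimPanel":
        return cls(pd.read_csv(path, sep="\t"))


def _beta_conditional_mean_diff(a: float, min_sigma: float) -> float:
    """E[|p1-p2|] for independent Beta(a, a) draws given |p1-p2| >= min_sigma.

    Evaluated by quadrature on the density of d = p1 - p2.
    """
    n = 800
    step = 1.0 / n
    grid = (np.arange(n) + 0.5) * step  # cell midpoints avoid endpoint poles
    pdf = stats.beta.pdf(grid, a, a)
    # density of |d| at lag k*step via discrete correlation of the marginal pdf
    corr = np.correlate(pdf, pdf, mode="full")[n - 1:] * step
    d = np.arange(n) * step
    mask = d >= min_sigma - 1e-12
    w = corr[mask] * step
    if w.sum() <= 0:
        return min_sigma
    return float(np.sum(d[mask] * w) / w.sum())


def build_aim_panel(
    n_markers: int = 1440,
    chrom_lengths: dict[int, float] | None = None,
    sigma_target: float = 0.56,
    min_sigma: float = 0.30,
    seed: int | np.random.Generator = 0,
) -> AimPanel:
    """Simulate an AIM panel with a target mean frequency differential.

    Ancestral frequencies are drawn as independent Beta(a, a) pairs and
    rejection-sampled until ``|freq_pop1 - freq_pop2| >= min_sigma``; the
    shape ``a`` is solved numerically so the post-rejection mean of sigma
    equals ``sigma_target``.  Marker positions are spread evenly along the
    supplied chromosome map (human autosomal lengths by default), allocated
    proportionally to genetic length.

    Raises
    ------
    PanelError
        If ``sigma_target`` is not attainable given ``min_sigma``.
    """
    if not (0 < min_sigma <= sigma_target <= 1):
        raise PanelError(
            f"require 0 < min_sigma <= sigma_target <= 1, "
            f"got min_sigma={min_sigma}, sigma_target={sigma_target}"
        )
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = HUMAN_AUTOSOME_MORGANS

    if n_markers == 0:
        return AimPanel(pd.DataFrame(columns=PANEL_COLUMNS))

    # frequencies
    if min_sigma >= 1.0 - 1e-12:
        # sigma = 1 forces fixed differences; orientation randomised
        flip = rng.random(n_markers) < 0.5
        f1 = np.where(flip, 0.0, 1.0)
        f2 = 1.0 - f1
    else:
        lo, hi = 0.02, 60.0
        m_lo = _beta_conditional_mean_diff(lo, min_sigma)
        m_hi = _beta_conditional_mean_diff(hi, min_sigma)
        if not (m_hi - 1e-3 <= sigma_target <= m_lo + 1e-3):
            raise PanelError(
                f"sigma_target={sigma_target} unattainable with min_sigma={min_sigma}"
            )
        shape = optimize.brentq(
            lambda a: _beta_conditional_mean_diff(a, min_sigma) - sigma_target,
            lo,
            hi,
            xtol=1e-4,
        )
        f1 = np.empty(n_markers)
        f2 = np.empty(n_markers)
        filled = 0
        while filled < n_markers:
            batch = max(4 * (n_markers - filled), 256)
            c1 = rng.beta(shape, shape, size=batch)
            c2 = rng.beta(shape, shape, size=batch)
            keep = np.abs(c1 - c2) >= min_sigma
            take = min(int(keep.sum()), n_markers - filled)
            f1[filled:filled + take] = c1[keep][:take]
            f2[filled:filled + take] = c2[keep][:take]
            filled += take

    # positions: allocate markers to chromosomes proportionally to length
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], float)
    alloc = np.floor(n_markers * lengths / lengths.sum()).astype(int)
    for k in np.argsort(-(n_markers * lengths / lengths.sum() - alloc)):
        if alloc.sum() >= n_markers:
            break
        alloc[k] += 1
    rows = []
    j = 0
    for c, L, n_c in zip(chroms, lengths, alloc):
        if n_c == 0:
            continue
        pos = (np.arange(n_c) + 0.5) / n_c * L
        for p in pos:
            rows.append(
                (f"aim{j:05d}", c, p, int(round(p * _BP_PER_MORGAN)) + 1,
                 f1[j], f2[j])
            )
            j += 1
    table = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    return AimPanel(table)
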