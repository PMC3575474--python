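import numpy as np
import pandas as pd
import pytest

from admixscan.panel import AimPanel


def make_panel(n_markers, seed=0, chrom_split=None, freqs=None):
    """Small random panel for unit tests; optionally fixed frequencies."""
    rng = np.random.default_rng(seed)
    if chrom_split is None:
        chrom_split = {1: n_markers}
    rows = []
    j = 0
    for chrom, count in chrom_split.items():
        pos = np.sort(rng.uniform(0, 1.0, size=count))
        pos += np.arange(count) * 1e-6  # guard against ties
        for p in pos:
            if freqs is None:
                f1, f2 = rng.random(), rng.random()
            else:
                f1, f2 = freqs[j]
            rows.append((f"m{j}", chrom, p, int(p * 1e8) + 1, f1, f2))
            j += 1
    return AimPanel(pd.DataFrame(
        rows, columns=["marker_id", "chrom", "genetic_pos_M", "phys_pos_bp",
                       "freq_pop1", "freq_pop2"]))


@pytest.fixture
def tiny_panel():
    return make_panel(5, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
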