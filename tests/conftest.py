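import numpy as np
import pandas as pd
import pytest

from cobitools import simulate
from cobitools.simulate import DepthTrack, GenomePlan


@pytest.fixture
def small_plan() -> GenomePlan:
    """100 kb two-chromosome genome with one planted Y and one X interval."""
    return GenomePlan(
        chromosomes=[("chr1", 60_000), ("chr2", 40_000)],
        y_intervals=[("chr1", 10_000, 20_000)],
        x_intervals=[("chr1", 30_000, 50_000)],
        seed=42,
    )


@pytest.fixture
def sex_tracks(small_plan) -> tuple[DepthTrack, DepthTrack]:
    male = simulate.simulate_pool_depth(small_plan, "male")
    female = simulate.simulate_pool_depth(small_plan, "female")
    return male, female


def constant_track(depth: int, lengths: dict[str, int], sex: str = "male") -> DepthTrack:
    return DepthTrack(
        depths={c: np.full(n, depth, dtype=np.int64) for c, n in lengths.items()},
        sex=sex,
    )


@pytest.fixture
def pairing_table() -> pd.DataFrame:
    """Balanced 4-chromosome, 2-individual grid with contrasting rates."""
    rows = []
    rates = {"Ch01A": 0.02, "Ch01B": 0.65, "Ch05": 0.12, "Ch20": 0.15}
    for chrom, p in rates.items():
        for ind in ("et1c4", "et1c5"):
            n = 120
            rows.append((chrom, ind, round(p * n), n - round(p * n)))
    return pd.DataFrame(rows, columns=["chromosome", "individual", "n_paired", "n_unpaired"])
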