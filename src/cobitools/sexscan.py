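"""Pool-Seq sex-chromosome discovery from male/female depth and SNP tables.

Two complementary signals locate sex-linked sequence in a male-
heterogametic (XY) system:

* **Depth ratio** — in sliding windows, the log2 ratio of summed female
  to summed male depth is ~0 on autosomes, ~+1 over X-differentiated
  regions (females carry two X copies, males one) and strongly negative
  over Y-hemizygous regions (females carry none).
* **Sex-specific SNPs** — variants whose alternate allele is present in
  every pool of one sex and absent from every pool of the other mark
  X/Y-differentiated sequence; their per-window count is normalised by
  the total SNPs in the window.

Candidate Y regions are maximal runs of bases with (near-)zero pooled
female depth and male depth at least a fraction of the male genome-wide
average; candidate X regions are runs of kilobase bins where female
depth is about twice male depth and close to the female genome average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DepthTrack


@dataclass
class ScanParams:
    window: int = 200_000
    step: int = 50_000
    ratio_pseudocount: float = 0.5
    y_male_min_frac: float = 0.30
    x_avg_tol: float = 0.20
    x_ratio_tol: float = 0.20
    min_region_len: int = 1_000
    female_max_depth: float = 0.0
    merge_gap: int = 100
    x_bin: int = 1_000

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError("require 0 < step <= window")
        for name in ("y_male_min_frac", "x_avg_tol", "x_ratio_tol"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# depth utilities


def genome_average_depth(track: DepthTrack) -> float:
    """Arithmetic mean depth over every assembled base (zeros included)."""
    total = track.total_length()
    if total == 0:
        raise ValueError("empty depth track")
    return sum(float(a.sum()) for a in track.depths.values()) / total


def aggregate_same_sex(tracks: list[DepthTrack]) -> DepthTrack:
    """Position-wise sum of same-sex pools into one combined track."""
    if not tracks:
        raise ValueError("no tracks to aggregate")
    sexes = {t.sex for t in tracks}
    if len(sexes) != 1:
        raise ValueError(f"tracks mix sexes: {sorted(sexes)}")
    first = tracks[0]
    out = {c: a.copy() for c, a in first.depths.items()}
    for t in tracks[1:]:
        if set(t.depths) != set(out):
            raise ValueError("tracks cover different chromosome sets")
        for c, a in t.depths.items():
            if len(a) != len(out[c]):
                raise ValueError(f"chromosome {c}: mismatched lengths")
            out[c] = out[c] + a
    return DepthTrack(depths=out, sex=first.sex, label="combined")


def tile_windows(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Window tiling: starts 0, step, 2*step, ... while start+window <= length,
    plus one terminal window ending at the chromosome end if bases remain
    uncovered.  A chromosome shorter than the window yields a single
    whole-chromosome window (with a warning)."""
    if window > length:
        warnings.warn(f"window {window} exceeds chromosome length {length}; using one window")
        return [(0, length)]
    starts = list(range(0, length - window + 1, step))
    wins = [(s, s + window) for s in starts]
    if wins[-1][1] < length:
        wins.append((length - window, length))
    return wins


def window_depth_ratio(
    male: DepthTrack, female: DepthTrack, params: ScanParams | None = None
) -> pd.DataFrame:
    """Per-window log2((sum female + c) / (sum male + c)) depth ratio."""
    params = params or ScanParams()
    if set(male.depths) != set(female.depths):
        raise ValueError("male and female tracks cover different chromosomes")
    rows = []
    for chrom in male.depths:
        m, f = male.depths[chrom], female.depths[chrom]
        if len(m) != len(f):
            raise ValueError(f"chromosome {chrom}: mismatched track lengths")
        cm = np.concatenate([[0], np.cumsum(m, dtype=np.float64)])
        cf = np.concatenate([[0], np.cumsum(f, dtype=np.float64)])
        for s, e in tile_windows(len(m), params.window, params.step):
            msum = cm[e] - cm[s]
            fsum = cf[e] - cf[s]
            c = params.ratio_pseudocount
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "male_sum": msum,
                    "female_sum": fsum,
                    "log2_fm": np.log2((fsum + c) / (msum + c)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sex-specific SNPs


def call_sexspecific_snps(
    snps: pd.DataFrame,
    presence_min_freq: float = 0.2,
    absence_max_alt: int = 0,
    min_pool_depth: int = 10,
) -> pd.DataFrame:
    """Flag SNPs whose alt allele segregates strictly by sex.

    A SNP is sex-specific iff in *every* pool of one sex the alt
    frequency is at least ``presence_min_freq`` and in *every* pool of
    the other sex the alt read count is at most ``absence_max_alt``,
    with all pools at depth >= ``min_pool_depth``.  Returns the input
    with added boolean columns ``male_linked``/``female_linked`` and
    ``sexspec_call``.
    """
    from .io import pool_columns

    pools = pool_columns(snps)
    male_pools = [p for p in pools if p.startswith("male")]
    female_pools = [p for p in pools if p.startswith("female")]
    if not male_pools or not female_pools:
        raise ValueError("need at least one pool per sex")

    def depth(p):
        return snps[f"{p}:ref"].to_numpy() + snps[f"{p}:alt"].to_numpy()

    def freq(p):
        d = depth(p).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(d > 0, snps[f"{p}:alt"].to_numpy() / d, 0.0)

    deep_enough = np.logical_and.reduce([depth(p) >= min_pool_depth for p in pools])
    present_m = np.logical_and.reduce([freq(p) >= presence_min_freq for p in male_pools])
    present_f = np.logical_and.reduce([freq(p) >= presence_min_freq for p in female_pools])
    absent_m = np.logical_and.reduce(
        [snps[f"{p}:alt"].to_numpy() <= absence_max_alt for p in male_pools]
    )
    absent_f = np.logical_and.reduce(
        [snps[f"{p}:alt"].to_numpy() <= absence_max_alt for p in female_pools]
    )
    out = snps.copy()
    out["male_linked"] = deep_enough & present_m & absent_f
    out["female_linked"] = deep_enough & present_f & absent_m
    out["sexspec_call"] = out["male_linked"] | out["female_linked"]
    return out


def window_snp_concentration(
    flagged: pd.DataFrame, params: ScanParams | None = None, chrom_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Per-window total and sex-specific SNP counts, normalised.

    Uses the same window tiling as the depth-ratio scan.  Windows with no
    SNPs get ``sexspec_norm`` 0 and an ``empty`` flag.
    """
    params = params or ScanParams()
    rows = []
    for chrom, sub in flagged.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        order = np.argsort(pos0)
        pos0 = pos0[order]
        spec = sub["sexspec_call"].to_numpy()[order]
        cum_spec = np.concatenate([[0], np.cumsum(spec)])
        length = chrom_lengths[chrom] if chrom_lengths else int(pos0.max()) + 1
        for s, e in tile_windows(length, params.window, params.step):
            i = int(np.searchsorted(pos0, s, side="left"))
            j = int(np.searchsorted(pos0, e, side="left"))
            n = j - i
            n_spec = int(cum_spec[j] - cum_spec[i])
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "n_snps": n,
                    "n_sexspec": n_spec,
                    "sexspec_norm": (n_spec / n) if n else 0.0,
                    "empty": n == 0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# candidate regions


def _runs_from_mask(mask: np.ndarray, merge_gap: int, min_len: int) -> list[tuple[int, int]]:
    """Maximal True runs; runs separated by < merge_gap False bases are
    joined; runs shorter than min_len discarded."""
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > merge_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    runs = [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]
    return [(s, e) for s, e in runs if e - s >= min_len]


def detect_y_regions(
    male: DepthTrack, female: DepthTrack, params: ScanParams | None = None
) -> pd.DataFrame:
    """Candidate Y-hemizygous regions.

    Maximal runs of bases where pooled female depth is at most
    ``female_max_depth`` (default: exactly zero) and pooled male depth
    is at least ``y_male_min_frac`` of the male genome-wide average.
    Runs separated by fewer than ``merge_gap`` failing bases are joined;
    runs shorter than ``min_region_len`` are discarded.
    """
    params = params or ScanParams()
    male_avg = genome_average_depth(male)
    thr = params.y_male_min_frac * male_avg
    rows = []
    for chrom in male.depths:
        m, f = male.depths[chrom], female.depths[chrom]
        mask = (f <= params.female_max_depth) & (m >= thr)
        for s, e in _runs_from_mask(mask, params.merge_gap, params.min_region_len):
            rows.append(
                {
                    "kind": "Y_specific",
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "mean_male_depth": float(m[s:e].mean()),
                    "mean_female_depth": float(f[s:e].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["kind", "chrom", "start", "end", "mean_male_depth", "mean_female_depth"])


def detect_x_regions(
    male: DepthTrack, female: DepthTrack, params: ScanParams | None = None
) -> pd.DataFrame:
    """Candidate X-differentiated regions.

    Evaluated on ``x_bin``-sized bins (per-base exact-ratio tests almost
    never fire under count noise): bins qualify when mean female depth is
    within ``x_ratio_tol`` of twice the male depth and within
    ``x_avg_tol`` of the female genome-wide average.  Qualifying bin
    runs are merged; ``min_region_len`` applies to the merged span.
    """
    params = params or ScanParams()
    female_avg = genome_average_depth(female)
    c = params.ratio_pseudocount
    rows = []
    for chrom in male.depths:
        m, f = male.depths[chrom], female.depths[chrom]
        nbin = len(m) // params.x_bin
        if nbin == 0:
            continue
        mb = m[: nbin * params.x_bin].reshape(nbin, params.x_bin).mean(axis=1)
        fb = f[: nbin * params.x_bin].reshape(nbin, params.x_bin).mean(axis=1)
        ratio = fb / (mb + c / params.x_bin)
        ok_ratio = (ratio >= 2 * (1 - params.x_ratio_tol)) & (ratio <= 2 * (1 + params.x_ratio_tol))
        ok_avg = (fb >= (1 - params.x_avg_tol) * female_avg) & (fb <= (1 + params.x_avg_tol) * female_avg)
        mask = ok_ratio & ok_avg
        for bs, be in _runs_from_mask(mask, merge_gap=1, min_len=1):
            s, e = bs * params.x_bin, be * params.x_bin
            if e - s < params.min_region_len:
                continue
            rows.append(
                {
                    "kind": "X_specific",
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "mean_male_depth": float(m[s:e].mean()),
                    "mean_female_depth": float(f[s:e].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["kind", "chrom", "start", "end", "mean_male_depth", "mean_female_depth"])


def rank_candidate_chromosomes(
    regions: pd.DataFrame, windowstats: pd.DataFrame, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Per-chromosome report ranking Y-candidate density.

    Reports total Y-region bases, region count, density (bases/Mb), mean
    |log2 depth ratio| and mean normalised sex-specific SNP
    concentration; sorted by density then SNP concentration.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = regions[(regions["chrom"] == chrom) & (regions["kind"] == "Y_specific")] if len(regions) else regions
        total = int((sub["end"] - sub["start"]).sum()) if len(sub) else 0
        ws = windowstats[windowstats["chrom"] == chrom] if len(windowstats) else windowstats
        rows.append(
            {
                "chrom": chrom,
                "y_bases": total,
                "n_regions": int(len(sub)) if len(regions) else 0,
                "density_per_mb": total / (length / 1e6),
                "mean_abs_log2_fm": float(np.abs(ws["log2_fm"]).mean()) if "log2_fm" in ws and len(ws) else 0.0,
                "mean_sexspec_norm": float(ws["sexspec_norm"].mean()) if "sexspec_norm" in ws and len(ws) else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["density_per_mb", "mean_sexspec_norm"], ascending=False, kind="stable"
    ).reset_index(drop=True)


def primer_strategy(region_start: int, region_end: int, product_len: int = 500) -> str:
    """PCR strategy for a candidate region: place both primers inside when
    the region can hold a full product, otherwise anchor one primer inside
    and one in flanking sequence."""
    if region_end <= region_start:
        raise ValueError("empty region")
    return "both_inside" if region_end - region_start >= product_len else "one_inside_one_flanking"
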