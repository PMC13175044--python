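"""Synthetic-data generators with planted ground truth.

Everything the downstream modules consume can be generated here: a
diploid genome with planted Y-hemizygous and X-differentiated intervals,
negative-binomial pooled depth tracks per sex, pooled SNP tables with a
Y-gametolog allele model, fragmented structural-variant records in the
whole-genome-alignment dialect, redundant repeat-consensus libraries
tiled over known family consensi, and binomial pairing-count tables.

All generators are deterministic given a seed: identical plan + seed
produce byte-identical output files.  Coordinates in generated truth are
0-based half-open; 1-based dialects are produced only at I/O boundaries.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .svmerge import SV_NEGATIVE_TYPES, SvRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")

# stream ids keep per-purpose RNGs independent under one root seed
_STREAM_GENOME = 1
_STREAM_DEPTH = 2
_STREAM_SNPS = 3
_STREAM_SV = 4
_STREAM_REPEATS = 5
_STREAM_PAIRING = 6


def _rng(seed: int, stream: int, *labels: str) -> np.random.Generator:
    keys = [seed, stream] + [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# genome plan


@dataclass
class GenomePlan:
    """Blueprint of a simulated genome with planted sex-linked architecture.

    ``y_intervals`` are male-hemizygous (copy number 1 in males, 0 in
    females); ``x_intervals`` are X-differentiated (1 in males, 2 in
    females) and enriched for sex-specific SNPs by ``sexsnp_enrichment``.
    Intervals are 0-based half-open and must be non-overlapping.
    """

    chromosomes: list[tuple[str, int]]
    y_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    x_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    snp_density: float = 0.001
    sexsnp_enrichment: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        claimed: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in list(self.y_intervals) + list(self.x_intervals):
            if chrom not in lengths:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(
                    f"interval ({chrom}, {start}, {end}) outside chromosome bounds"
                )
            for s, e in claimed.setdefault(chrom, []):
                if start < e and s < end:
                    raise ValueError(
                        f"overlapping planted intervals on {chrom}: "
                        f"({s}, {e}) and ({start}, {end})"
                    )
            claimed[chrom].append((start, end))

    def chrom_length(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def copy_number(self, sex: str) -> dict[str, np.ndarray]:
        """Per-base copy-number array for one sex (autosomal baseline 2)."""
        if sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
        cn = {name: np.full(length, 2, dtype=np.int8) for name, length in self.chromosomes}
        for chrom, start, end in self.x_intervals:
            cn[chrom][start:end] = 1 if sex == "male" else 2
        for chrom, start, end in self.y_intervals:
            cn[chrom][start:end] = 1 if sex == "male" else 0
        return cn

    def truth_bed(self) -> pd.DataFrame:
        rows = [(c, s, e, "Y_specific") for c, s, e in self.y_intervals]
        rows += [(c, s, e, "X_specific") for c, s, e in self.x_intervals]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "kind"])


def simulate_genome(plan: GenomePlan) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate chromosome sequences (uniform i.i.d. A/C/G/T) and truth BED."""
    rng = _rng(plan.seed, _STREAM_GENOME)
    seqs = {}
    for name, length in plan.chromosomes:
        idx = rng.integers(0, 4, size=length)
        seqs[name] = BASES[idx].tobytes().decode()
    return seqs, plan.truth_bed()


# ---------------------------------------------------------------------------
# pooled depth


@dataclass
class DepthTrack:
    """Per-base read depth of one sequencing pool over named chromosomes."""

    depths: dict[str, np.ndarray]
    sex: str
    label: str = "pool"

    def total_length(self) -> int:
        return sum(len(a) for a in self.depths.values())


def simulate_pool_depth(
    plan: GenomePlan,
    sex: str,
    mean_depth: float = 40.0,
    dispersion: float = 5.0,
    label: str = "pool",
    contamination: float = 0.0,
) -> DepthTrack:
    """Negative-binomial per-base depth with copy-number-scaled mean.

    Mean depth at a base is ``mean_depth * copy_number / 2`` (autosomes 2,
    X-differentiated male 1 / female 2, Y-hemizygous male 1 / female 0).
    ``dispersion`` is the NB size parameter (Poisson as it grows large);
    ``contamination`` adds Poisson(contamination * mean_depth) stray reads
    where copy number is zero, to probe the strictness of the zero-depth
    rule.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _rng(plan.seed, _STREAM_DEPTH, sex, label)
    cn = plan.copy_number(sex)
    depths: dict[str, np.ndarray] = {}
    for chrom, cn_arr in cn.items():
        out = np.zeros(len(cn_arr), dtype=np.int64)
        for copies in (1, 2):
            mask = cn_arr == copies
            n = int(mask.sum())
            if n == 0:
                continue
            m = mean_depth * copies / 2.0
            if np.isfinite(dispersion):
                p = dispersion / (dispersion + m)
                out[mask] = rng.negative_binomial(dispersion, p, size=n)
            else:
                out[mask] = rng.poisson(m, size=n)
        if contamination > 0:
            zero = cn_arr == 0
            if zero.any():
                out[zero] = rng.poisson(contamination * mean_depth, size=int(zero.sum()))
        depths[chrom] = out
    return DepthTrack(depths=depths, sex=sex, label=label)


# ---------------------------------------------------------------------------
# pooled SNPs


def simulate_pool_snps(
    plan: GenomePlan,
    pools: list[tuple[str, str]],
    mean_depth: float = 40.0,
    base_sexspec_frac: float = 0.005,
) -> pd.DataFrame:
    """Pooled SNP table with planted male-linked sex-specific SNPs.

    SNPs are placed uniformly at ``plan.snp_density``.  A background
    fraction ``base_sexspec_frac`` of SNPs is sex-specific everywhere;
    inside X-differentiated intervals that fraction is multiplied by
    ``plan.sexsnp_enrichment`` (capped at 1).  Sex-specific SNPs follow
    the Y-gametolog model: alt allele at frequency 0.5 in every male
    pool and absent from every female pool.  Per-pool read depth at a
    SNP is Poisson with the copy-number-scaled pool mean.

    Returns a DataFrame with columns ``chrom, pos (1-based), ref, alt,
    sexspec`` plus ``<sex>_<label>:ref`` / ``:alt`` integer columns.
    """
    if not pools:
        raise ValueError("at least one pool is required")
    sexes = {s for s, _ in pools}
    if sexes - {"male", "female"}:
        raise ValueError("pool sex must be 'male' or 'female'")
    rng = _rng(plan.seed, _STREAM_SNPS)
    cn = {s: plan.copy_number(s) for s in ("male", "female")}

    frames = []
    for chrom, length in plan.chromosomes:
        n_snps = rng.binomial(length, plan.snp_density)
        pos0 = np.sort(rng.choice(length, size=n_snps, replace=False))
        # per-SNP sex-specific probability, enriched inside x_intervals
        p_spec = np.full(n_snps, base_sexspec_frac)
        for c, s, e in plan.x_intervals:
            if c == chrom:
                inside = (pos0 >= s) & (pos0 < e)
                p_spec[inside] = min(1.0, base_sexspec_frac * plan.sexsnp_enrichment)
        sexspec = rng.random(n_snps) < p_spec
        ref_idx = rng.integers(0, 4, size=n_snps)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
        shared_freq = rng.uniform(0.05, 0.95, size=n_snps)

        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": BASES[ref_idx].astype(str),
                "alt": BASES[alt_idx].astype(str),
                "sexspec": sexspec,
            }
        )
        for sex, label in pools:
            copies = cn[sex][chrom][pos0]
            depth = rng.poisson(mean_depth * copies / 2.0)
            if sex == "male":
                freq = np.where(sexspec, 0.5, shared_freq)
            else:
                freq = np.where(sexspec, 0.0, shared_freq)
            alt_reads = rng.binomial(depth, freq)
            name = f"{sex}_{label}"
            frame[f"{name}:ref"] = depth - alt_reads
            frame[f"{name}:alt"] = alt_reads
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# structural variants


@dataclass
class PlantedSv:
    """One true rearrangement event (0-based half-open intervals)."""

    sv_type: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int

    def __post_init__(self) -> None:
        if self.ref_end <= self.ref_start or self.qry_end <= self.qry_start:
            raise ValueError("planted SV intervals must have positive length")
        if self.sv_type not in {"INV", "TRANS", "INVTR", "DUP", "INVDP"}:
            raise ValueError(f"unknown SV type {self.sv_type!r}")

    @property
    def orientation(self) -> str:
        return "-" if self.sv_type in SV_NEGATIVE_TYPES else "+"

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start


def plan_random_svs(
    n_events: int,
    seed: int,
    types: tuple[str, ...] = ("INV", "TRANS", "DUP"),
    length_range: tuple[int, int] = (60_000, 400_000),
    n_large: int = 0,
    large_length: int = 1_200_000,
    n_chroms: int = 5,
    margin: int = 50_000,
) -> list[PlantedSv]:
    """Place ``n_events`` non-overlapping events on a virtual genome.

    The last ``n_large`` events get reference spans of ``large_length``
    bases.  Within each (ref chrom, qry chrom, type, orientation) group
    the query intervals of consecutive (reference-ordered) events are
    assigned anti-monotonically: distinct events are separated by breaks
    in query continuity, which is precisely what distinguishes two
    events from one under the parsimonious-merge rule.
    """
    rng = _rng(seed, _STREAM_SV)
    lengths = []
    for i in range(n_events):
        if i >= n_events - n_large:
            lengths.append(large_length)
        else:
            lengths.append(int(rng.integers(length_range[0], length_range[1])))
    ev_types = [types[int(rng.integers(0, len(types)))] for _ in range(n_events)]
    chroms = [f"refChr{(i % n_chroms) + 1:02d}" for i in range(n_events)]

    # lay events left-to-right per ref chromosome with a safety margin
    cursor = {c: margin for c in set(chroms)}
    events = []
    for i in range(n_events):
        c = chroms[i]
        s = cursor[c]
        e = s + lengths[i]
        cursor[c] = e + margin
        qc = f"qryChr{(i % n_chroms) + 1:02d}"
        events.append((ev_types[i], c, s, e, qc, lengths[i]))

    # assign query intervals; reverse order within each merge group so the
    # merge rule's query-monotonicity check cleanly separates events
    groups: dict[tuple, list[int]] = {}
    for idx, (t, c, s, e, qc, ln) in enumerate(events):
        orient = "-" if t in SV_NEGATIVE_TYPES else "+"
        groups.setdefault((c, qc, t, orient), []).append(idx)
    qry_cursor: dict[str, int] = {}
    qry_assign: dict[int, tuple[int, int]] = {}
    for key, idxs in groups.items():
        idxs_sorted = sorted(idxs, key=lambda i: events[i][2])
        orient = key[3]
        order = list(reversed(idxs_sorted)) if orient == "+" else idxs_sorted
        for i in order:
            qc, ln = events[i][4], events[i][5]
            qs = qry_cursor.get(qc, margin)
            qry_cursor[qc] = qs + ln + margin
            qry_assign[i] = (qs, qs + ln)
    return [
        PlantedSv(t, c, s, e, qc, *qry_assign[i])
        for i, (t, c, s, e, qc, ln) in enumerate(events)
    ]


def fragment_svs(
    true_svs: list[PlantedSv],
    seed: int,
    k_range: tuple[int, int] = (3, 8),
    gap: int = 0,
    decoys: int = 0,
    min_block_len: int = 5_000,
) -> list[SvRecord]:
    """Emit each true event as adjacent same-type sub-blocks plus decoys.

    Each event is split into ``k`` (uniform in ``k_range``) reference-
    and query-consecutive sub-blocks, every one longer than
    ``min_block_len`` bases, separated by at most ``gap`` skipped bases.
    ``decoys`` extra single blocks of span <= ``min_block_len`` are
    scattered over the same chromosomes; they fall below the length
    filter and cannot merge or block a merge.  Output records use the
    1-based-inclusive 12-column dialect coordinates.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = _rng(seed, _STREAM_SV, "fragment")
    records: list[SvRecord] = []
    for n, ev in enumerate(true_svs):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        gaps = rng.integers(0, gap + 1, size=k - 1) if gap > 0 else np.zeros(k - 1, dtype=int)
        need = k * (min_block_len + 1) + int(gaps.sum())
        if ev.ref_len < need:
            raise ValueError(
                f"event {ev.sv_type} {ev.ref_chrom}:{ev.ref_start}-{ev.ref_end} "
                f"too short to fragment into {k} parts > {min_block_len} bases"
            )
        extra = rng.multinomial(ev.ref_len - need, [1.0 / k] * k)
        part_lens = min_block_len + 1 + extra
        rs = ev.ref_start
        qparts = []
        q = ev.qry_start
        for j in range(k):
            qparts.append((q, q + int(part_lens[j])))
            q += int(part_lens[j]) + (int(gaps[j]) if j < k - 1 else 0)
        if ev.orientation == "-":
            qparts = qparts[::-1]
        for j in range(k):
            re_ = rs + int(part_lens[j])
            qs, qe = qparts[j]
            records.append(
                SvRecord(
                    ref_chrom=ev.ref_chrom,
                    ref_start=rs + 1,
                    ref_end=re_,
                    qry_chrom=ev.qry_chrom,
                    qry_start=qs + 1,
                    qry_end=qe,
                    sv_type=ev.sv_type,
                    id=f"{ev.sv_type}{n}_p{j}",
                )
            )
            rs = re_ + (int(gaps[j]) if j < k - 1 else 0)
    ref_chroms = sorted({ev.ref_chrom for ev in true_svs}) or ["refChr01"]
    qry_chroms = sorted({ev.qry_chrom for ev in true_svs}) or ["qryChr01"]
    for d in range(decoys):
        span = int(rng.integers(200, min_block_len + 1))
        c = ref_chroms[int(rng.integers(0, len(ref_chroms)))]
        qc = qry_chroms[int(rng.integers(0, len(qry_chroms)))]
        s = int(rng.integers(0, 5_000_000))
        qs = int(rng.integers(0, 5_000_000))
        t = ("TRANS", "DUP", "INV")[int(rng.integers(0, 3))]
        records.append(
            SvRecord(
                ref_chrom=c,
                ref_start=s + 1,
                ref_end=s + span,
                qry_chrom=qc,
                qry_start=qs + 1,
                qry_end=qs + span,
                sv_type=t,
                id=f"DECOY{d}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# repeat libraries


@dataclass
class RepeatFamilyTruth:
    """Ground truth for one repeat family: consensus plus planted copies."""

    family_id: str
    consensus: str
    copy_count: int = 2
    divergence: float = 0.02

    def __post_init__(self) -> None:
        if len(self.consensus) < 100:
            raise ValueError("consensus length must be >= 100")
        if self.copy_count < 0:
            raise ValueError("copy count must be >= 0")


def random_repeat_families(
    n_families: int,
    consensus_len: int = 1200,
    copy_count: int = 3,
    divergence: float = 0.02,
    seed: int = 0,
) -> list[RepeatFamilyTruth]:
    rng = _rng(seed, _STREAM_REPEATS, "families")
    fams = []
    for i in range(n_families):
        seq = BASES[rng.integers(0, 4, size=consensus_len)].tobytes().decode()
        fams.append(
            RepeatFamilyTruth(f"FAM{i:02d}", seq, copy_count=copy_count, divergence=divergence)
        )
    return fams


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit):
        shift = rng.integers(1, 4, size=len(hit))
        idx = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def make_redundant_library(
    families: list[RepeatFamilyTruth],
    fragments_per_family: int = 6,
    overlap: int = 200,
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Tile each consensus into overlapping fragments (a redundant library).

    ``fragments_per_family`` fragments cover the consensus with adjacent
    pairs sharing at least ``overlap`` bases; each fragment is mutated
    at ``mutation_rate`` substitutions per base.  With one fragment the
    library is simply the (mutated) consensus set.
    """
    rng = _rng(seed, _STREAM_REPEATS, "library")
    lib: dict[str, str] = {}
    for fam in families:
        L = len(fam.consensus)
        k = fragments_per_family
        if k == 1:
            lib[f"{fam.family_id}_f0"] = _mutate(fam.consensus, mutation_rate, rng)
            continue
        if overlap >= L:
            raise ValueError("overlap must be smaller than the consensus length")
        frag_len = -(-(L + (k - 1) * overlap) // k)  # ceil
        step = (L - frag_len) / (k - 1)
        for j in range(k):
            s = round(j * step)
            e = min(L, s + frag_len)
            if j == k - 1:
                s, e = L - frag_len, L
            lib[f"{fam.family_id}_f{j}"] = _mutate(fam.consensus[s:e], mutation_rate, rng)
    return lib


def plant_repeat_genome(
    families: list[RepeatFamilyTruth],
    seed: int = 0,
    background_len: int = 40_000,
    n_decoys: int = 0,
    decoy_len: int = 400,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Random genome with each family's copies (and single-copy decoys) planted.

    Returns ``(genome, decoy_library, placements)`` where the genome is a
    single chromosome built from random background with family copies
    (mutated at each family's divergence) and each decoy inserted exactly
    once; ``decoy_library`` holds the decoy sequences for appending to a
    repeat library; ``placements`` records 0-based insert coordinates.
    """
    rng = _rng(seed, _STREAM_REPEATS, "genome")
    inserts: list[tuple[str, str]] = []
    for fam in families:
        for c in range(fam.copy_count):
            inserts.append((fam.family_id, _mutate(fam.consensus, fam.divergence, rng)))
    decoy_lib = {}
    for d in range(n_decoys):
        seq = BASES[rng.integers(0, 4, size=decoy_len)].tobytes().decode()
        decoy_lib[f"DECOY{d:02d}"] = seq
        inserts.append((f"DECOY{d:02d}", seq))
    order = rng.permutation(len(inserts))
    spacer = background_len // (len(inserts) + 1) if inserts else background_len
    parts = []
    rows = []
    pos = 0
    for idx in order:
        name, seq = inserts[idx]
        bg = BASES[rng.integers(0, 4, size=spacer)].tobytes().decode()
        parts.append(bg)
        pos += spacer
        rows.append((name, pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)
    parts.append(BASES[rng.integers(0, 4, size=spacer)].tobytes().decode())
    genome = {"genome1": "".join(parts)}
    placements = pd.DataFrame(rows, columns=["family", "start", "end"])
    return genome, decoy_lib, placements


# ---------------------------------------------------------------------------
# pairing counts


@dataclass
class PairingTruth:
    """True bivalent-formation probability per chromosome x individual cell."""

    cells: pd.DataFrame  # columns: chromosome, individual, p, n

    def __post_init__(self) -> None:
        need = {"chromosome", "individual", "p", "n"}
        if set(self.cells.columns) < need:
            raise ValueError(f"cells must have columns {sorted(need)}")
        if ((self.cells["p"] < 0) | (self.cells["p"] > 1)).any():
            raise ValueError("pairing probabilities must lie in [0, 1]")
        if (self.cells["n"] < 0).any():
            raise ValueError("cell counts must be >= 0")

    @classmethod
    def from_grid(
        cls,
        chromosomes: list[str],
        individuals: list[str],
        p: float | dict | np.ndarray,
        n: int,
    ) -> "PairingTruth":
        rows = []
        arr = np.asarray(p, dtype=float) if not np.isscalar(p) and not isinstance(p, dict) else p
        for i, c in enumerate(chromosomes):
            for j, ind in enumerate(individuals):
                if isinstance(p, dict):
                    pp = p[(c, ind)]
                elif np.isscalar(p):
                    pp = float(p)
                else:
                    pp = float(arr[i, j])
                rows.append((c, ind, pp, n))
        return cls(pd.DataFrame(rows, columns=["chromosome", "individual", "p", "n"]))


def simulate_pairing_counts(truth: PairingTruth, seed: int) -> pd.DataFrame:
    """Binomial draw of paired/unpaired spermatocytes per grid cell."""
    rng = _rng(seed, _STREAM_PAIRING)
    out = truth.cells.copy()
    out["n_paired"] = rng.binomial(out["n"].to_numpy(), out["p"].to_numpy())
    out["n_unpaired"] = out["n"] - out["n_paired"]
    return out[["chromosome", "individual", "n_paired", "n_unpaired"]]
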