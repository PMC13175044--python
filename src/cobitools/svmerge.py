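"""Parsing, filtering and parsimonious merging of whole-genome-alignment SVs.

A whole-genome-alignment annotator reports rearrangements as runs of
short tandem blocks — particularly translocations and duplications —
rather than one long event.  The merge rule here collapses neighbouring
blocks of the same type and orientation into a single inferred
rearrangement, yielding a more parsimonious set of changes in
chromosomal structure.

Coordinates follow the annotator's 12-column tabular dialect: 1-based
inclusive on both reference and query.  Records whose query interval is
reported end-before-start are normalised to start <= end, with the
inverted orientation carried by the type code (INV/INVTR/INVDP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SV_TYPES = {"SYN", "INV", "TRANS", "INVTR", "DUP", "INVDP", "NOTAL", "INS", "DEL"}
SV_NEGATIVE_TYPES = {"INV", "INVTR", "INVDP"}
REARRANGEMENT_TYPES = {"INV", "TRANS", "INVTR", "DUP", "INVDP"}


@dataclass
class SvRecord:
    """One alignment/annotation block (1-based inclusive coordinates)."""

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    sv_type: str
    id: str = "-"
    parent_id: str = "-"

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.qry_start > self.qry_end:
            self.qry_start, self.qry_end = self.qry_end, self.qry_start
        if self.ref_start > self.ref_end:
            raise ValueError(f"record {self.id}: ref_start > ref_end")

    @property
    def orientation(self) -> str:
        return "-" if self.sv_type in SV_NEGATIVE_TYPES else "+"

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass
class MergeParams:
    min_block_len: int = 5_000  # strictly-greater-than reference span filter
    max_gap: int | None = None  # None = unlimited
    large_event_threshold: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_block_len < 0:
            raise ValueError("min_block_len must be >= 0")


@dataclass
class MergedEvent:
    """One parsimoniously merged rearrangement."""

    sv_type: str
    orientation: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    member_ids: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.member_ids)

    @property
    def span_len(self) -> int:
        return self.ref_end - self.ref_start + 1

    def as_record(self) -> SvRecord:
        return SvRecord(
            ref_chrom=self.ref_chrom,
            ref_start=self.ref_start,
            ref_end=self.ref_end,
            qry_chrom=self.qry_chrom,
            qry_start=self.qry_start,
            qry_end=self.qry_end,
            sv_type=self.sv_type,
            id=";".join(self.member_ids) or "-",
        )


# ---------------------------------------------------------------------------
# I/O


def read_syri_tsv(path: str | Path, keep_children: bool = False) -> list[SvRecord]:
    """Parse the 12-column dialect.

    Columns: ref chrom/start/end, two sequence placeholders, qry
    chrom/start/end, id, parent id, type code, copy status.  Unknown
    type codes are skipped with a warning; non-numeric coordinates raise
    with the offending line number.  By default only top-level
    annotation records (parent ``-``) are kept.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            sv_type = parts[10]
            if sv_type not in SV_TYPES:
                warnings.warn(f"line {lineno}: unknown type code {sv_type!r}; skipped")
                continue
            try:
                rs, re_ = int(parts[1]), int(parts[2])
                qs, qe = int(parts[6]), int(parts[7])
            except ValueError as err:
                raise ValueError(f"line {lineno}: non-numeric coordinate ({err})") from None
            rec = SvRecord(
                ref_chrom=parts[0],
                ref_start=rs,
                ref_end=re_,
                qry_chrom=parts[5],
                qry_start=qs,
                qry_end=qe,
                sv_type=sv_type,
                id=parts[8],
                parent_id=parts[9],
            )
            if not keep_children and rec.parent_id != "-":
                continue
            records.append(rec)
    return records


def write_syri_tsv(records: list[SvRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            qs, qe = r.qry_start, r.qry_end
            if r.orientation == "-":
                qs, qe = qe, qs  # the dialect encodes inversion by reversed qry coords
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            r.ref_chrom, r.ref_start, r.ref_end, "-", "-",
                            r.qry_chrom, qs, qe, r.id, r.parent_id, r.sv_type, "-",
                        ],
                    )
                )
                + "\n"
            )


def records_to_frame(records: list[SvRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_chrom": r.ref_chrom,
                "ref_start": r.ref_start,
                "ref_end": r.ref_end,
                "qry_chrom": r.qry_chrom,
                "qry_start": r.qry_start,
                "qry_end": r.qry_end,
                "sv_type": r.sv_type,
                "orientation": r.orientation,
                "id": r.id,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# spacer concatenation / lift-back


@dataclass
class SpacerMap:
    """Offsets of components concatenated with fixed-length spacers."""

    name: str
    components: list[tuple[str, int, int]]  # (name, offset, length)
    spacer_len: int = 1_000

    @property
    def total_length(self) -> int:
        n, off, ln = self.components[-1]
        return off + ln


def concat_with_spacer(
    components: list[tuple[str, int]], spacer_len: int = 1_000, name: str = "concat"
) -> SpacerMap:
    if len(components) < 2:
        raise ValueError("need at least two components to concatenate")
    names = [n for n, _ in components]
    if len(set(names)) != len(names):
        raise ValueError("duplicate component names")
    out = []
    offset = 0
    for i, (cname, length) in enumerate(components):
        out.append((cname, offset, length))
        offset += length + (spacer_len if i < len(components) - 1 else 0)
    return SpacerMap(name=name, components=out, spacer_len=spacer_len)


def liftback(record: SvRecord, spacer_map: SpacerMap) -> list[SvRecord]:
    """Transfer a record's reference coordinates from the concatenated
    chromosome back onto its components.

    A record spanning a spacer is split into per-component records; a
    record wholly inside spacer sequence is dropped with a warning.
    """
    if record.ref_chrom != spacer_map.name:
        raise ValueError(
            f"record chromosome {record.ref_chrom!r} is not the concatenated "
            f"chromosome {spacer_map.name!r}"
        )
    if record.ref_end > spacer_map.total_length:
        raise ValueError(
            f"record end {record.ref_end} beyond concatenated length "
            f"{spacer_map.total_length}"
        )
    pieces = []
    for cname, offset, length in spacer_map.components:
        lo = max(record.ref_start, offset + 1)  # 1-based on the concatenation
        hi = min(record.ref_end, offset + length)
        if lo > hi:
            continue
        pieces.append(
            SvRecord(
                ref_chrom=cname,
                ref_start=lo - offset,
                ref_end=hi - offset,
                qry_chrom=record.qry_chrom,
                qry_start=record.qry_start,
                qry_end=record.qry_end,
                sv_type=record.sv_type,
                id=record.id,
                parent_id=record.parent_id,
            )
        )
    if not pieces:
        warnings.warn(f"record {record.id} lies wholly within spacer sequence; dropped")
    return pieces


# ---------------------------------------------------------------------------
# filter + merge


def filter_min_length(records: list[SvRecord], params: MergeParams | None = None) -> list[SvRecord]:
    """Keep records with reference span strictly greater than the cutoff."""
    params = params or MergeParams()
    return [r for r in records if r.ref_span > params.min_block_len]


def merge_neighbours(records: list[SvRecord], params: MergeParams | None = None) -> list[MergedEvent]:
    """Collapse runs of neighbouring same-type, same-orientation blocks.

    Within each (ref chrom, qry chrom, type, orientation) group records
    are taken in reference order; a run extends to the next record while

    a) the reference gap does not exceed ``max_gap`` (default unlimited)
       and the reference intervals do not overlap,
    b) no record of a *different* rearrangement type (syntenic and
       not-aligned records do not block) starts between the two in
       global reference order, and
    c) the query intervals progress monotonically in the direction
       implied by the orientation.

    Singleton runs yield single-member events.
    """
    params = params or MergeParams()
    max_gap = np.inf if params.max_gap is None else params.max_gap

    # per ref-chromosome index of rearrangement records for the blocking rule
    block_idx: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {r.ref_chrom for r in records}:
        rear = sorted(
            (r for r in records if r.ref_chrom == chrom and r.sv_type in REARRANGEMENT_TYPES),
            key=lambda r: (r.ref_start, r.ref_end),
        )
        block_idx[chrom] = (np.array([r.ref_start for r in rear]), [r.sv_type for r in rear])

    def blocked(chrom: str, lo: int, hi: int, sv_type: str) -> bool:
        # any different-type rearrangement starting strictly inside (lo, hi)?
        starts, types = block_idx[chrom]
        i = int(np.searchsorted(starts, lo, side="right"))
        j = int(np.searchsorted(starts, hi, side="left"))
        return any(types[k] != sv_type for k in range(i, j))

    groups: dict[tuple, list[SvRecord]] = {}
    for r in records:
        if r.sv_type not in REARRANGEMENT_TYPES:
            continue
        groups.setdefault((r.ref_chrom, r.qry_chrom, r.sv_type, r.orientation), []).append(r)

    events: list[MergedEvent] = []
    for (rc, qc, t, orient), recs in sorted(groups.items()):
        recs = sorted(recs, key=lambda r: (r.ref_start, r.ref_end))
        run = [recs[0]]
        for nxt in recs[1:]:
            prev = run[-1]
            ok = (
                nxt.ref_start > prev.ref_end
                and (nxt.ref_start - prev.ref_end - 1) <= max_gap
                and not blocked(rc, prev.ref_end, nxt.ref_start, t)
            )
            if ok:
                if orient == "+":
                    ok = nxt.qry_start >= prev.qry_end
                else:
                    ok = nxt.qry_end <= prev.qry_start
            if ok:
                run.append(nxt)
            else:
                events.append(_close_run(run, rc, qc, t, orient))
                run = [nxt]
        events.append(_close_run(run, rc, qc, t, orient))
    return sorted(events, key=lambda e: (e.ref_chrom, e.ref_start, e.sv_type))


def _close_run(run: list[SvRecord], rc: str, qc: str, t: str, orient: str) -> MergedEvent:
    return MergedEvent(
        sv_type=t,
        orientation=orient,
        ref_chrom=rc,
        ref_start=min(r.ref_start for r in run),
        ref_end=max(r.ref_end for r in run),
        qry_chrom=qc,
        qry_start=min(r.qry_start for r in run),
        qry_end=max(r.qry_end for r in run),
        member_ids=[r.id for r in run],
    )


def count_large_events(
    merged: list[MergedEvent], params: MergeParams | None = None
) -> pd.Series:
    """Events with reference span above the large-event threshold, by type."""
    params = params or MergeParams()
    big = [e.sv_type for e in merged if e.span_len > params.large_event_threshold]
    counts = pd.Series(big, dtype=object).value_counts().sort_index()
    counts["total"] = len(big)
    return counts


def summarize_by_type_length(
    items: list[SvRecord] | list[MergedEvent], bin_edges: list[float]
) -> pd.DataFrame:
    """Contingency table of type x reference-span length bin."""
    if sorted(bin_edges) != list(bin_edges):
        raise ValueError("bin edges must be ascending")
    if not items:
        return pd.DataFrame()
    types = [getattr(x, "sv_type") for x in items]
    spans = [
        x.span_len if isinstance(x, MergedEvent) else x.ref_span for x in items
    ]
    cut = pd.cut(spans, bin_edges, right=False)
    return pd.crosstab(pd.Series(types, name="sv_type"), cut, dropna=False)


# ---------------------------------------------------------------------------
# annotation overlap


def genes_spanned(event: MergedEvent, genes: pd.DataFrame) -> int:
    """Number of gene features overlapping the event's reference span.

    ``genes`` is the frame returned by :func:`cobitools.io.read_gff3_genes`
    (1-based inclusive coordinates).
    """
    sub = genes[genes["chrom"] == event.ref_chrom]
    if sub.empty:
        return 0
    hit = (sub["start"] <= event.ref_end) & (sub["end"] >= event.ref_start)
    return int(hit.sum())


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [], []
    for s, e in zip(starts, ends):
        if out_e and s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.array(out_s), np.array(out_e)


def indel_repeat_fraction(indels: pd.DataFrame, repeats: pd.DataFrame) -> float:
    """Fraction of indel bases covered by repeat annotation.

    Both inputs are BED-style frames (``chrom, start, end``; 0-based
    half-open).  Raises on zero total indel bases.
    """
    total = int((indels["end"] - indels["start"]).sum())
    if total <= 0:
        raise ValueError("indel set covers zero bases")
    covered = 0
    for chrom, ind in indels.groupby("chrom"):
        rep = repeats[repeats["chrom"] == chrom]
        if rep.empty:
            continue
        rs, re_ = _merge_intervals(rep["start"].to_numpy(), rep["end"].to_numpy())
        for s, e in zip(ind["start"], ind["end"]):
            i = int(np.searchsorted(re_, s, side="right"))
            while i < len(rs) and rs[i] < e:
                covered += min(e, re_[i]) - max(s, rs[i])
                i += 1
    return covered / total


# ---------------------------------------------------------------------------
# rate arithmetic


def generations_per_sv(
    n_svs: float, divergence_years: float, generation_time_years: float = 1.0
) -> float:
    """Average number of generations elapsed per accumulated SV.

    Computed as total elapsed generations (divergence time divided by
    generation time) over the number of observed SVs between the two
    genomes.
    """
    if n_svs <= 0:
        raise ValueError("n_svs must be positive")
    return divergence_years / generation_time_years / n_svs
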