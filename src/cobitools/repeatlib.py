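"""Iterative redundancy removal for repeat-consensus libraries.

A combined repeat library (de novo consensi from several genomes plus
curated families) contains fragments of the same underlying family that
overlap one another.  The procedure here mirrors an all-vs-all
self-comparison at word size 20 and 95% identity: overlapping sequences
are either joined into a new consensus (dovetail overlaps, which
reconstruct a fragmented family) or one of them is shortened to remove
the overlap, iterating until no qualifying overlap remains.  A second
refinement excises the portions of each library sequence that align to
the genome fewer than a minimum number of times, since single-hit
segments are not repetitive.

The alignment primitive is a seeded, ungapped local aligner: exact
shared words seed extensions scored +1/-1 with an X-drop cutoff, on both
strands.  On small inputs its hits contain those of an exhaustive
dynamic-programming local aligner at the same thresholds.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class DedupParams:
    word_size: int = 20
    min_identity: float = 0.95
    min_overlap: int = 50
    min_seq_len: int = 50
    min_genome_hits: int = 2
    end_slack: int = 10  # tolerance when classifying dovetail overlaps
    x_drop: int = 20

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")


@dataclass
class LocalAlignment:
    """An ungapped local alignment between a query and a subject sequence.

    Intervals are 0-based half-open on the forward strand of each
    sequence; ``strand`` is the subject strand.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    matches: int

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0

    def mirrored(self) -> "LocalAlignment":
        return LocalAlignment(
            query_id=self.subject_id,
            subject_id=self.query_id,
            q_start=self.s_start,
            q_end=self.s_end,
            s_start=self.q_start,
            s_end=self.q_end,
            strand=self.strand,
            matches=self.matches,
        )


# ---------------------------------------------------------------------------
# seeded aligner


def _word_index(seq: str, w: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(seq) - w + 1):
        index[seq[j : j + w]].append(j)
    return index


def _extend_on_diagonal(
    a: str, b: str, i: int, j: int, w: int, x_drop: int
) -> tuple[int, int, int]:
    """X-drop extension of an exact w-mer seed at (i, j); returns the
    maximal-scoring segment as (a_start, a_end, matches)."""
    # right extension (seed included in the running score)
    score = best = w
    matches = best_matches = w
    p, q = i + w, j + w
    best_p = p
    while p < len(a) and q < len(b):
        if a[p] == b[q]:
            score += 1
            matches += 1
        else:
            score -= 1
        p += 1
        q += 1
        if score > best:
            best, best_p, best_matches = score, p, matches
        elif score < best - x_drop:
            break
    right_end = best_p
    right_matches = best_matches
    # left extension
    score = best = 0
    matches = best_matches = 0
    p, q = i - 1, j - 1
    best_p = i
    while p >= 0 and q >= 0:
        if a[p] == b[q]:
            score += 1
            matches += 1
        else:
            score -= 1
        if score > best:
            best, best_p, best_matches = score, p, matches
        elif score < best - x_drop:
            break
        p -= 1
        q -= 1
    return best_p, right_end, right_matches + best_matches


def _align_one_strand(
    a: str,
    b: str,
    index: dict[str, list[int]],
    params: DedupParams,
) -> list[tuple[int, int, int, int, int]]:
    """Seed-and-extend a against an indexed subject; one alignment per
    covered stretch of each diagonal.  Returns (qs, qe, ss, se, matches)."""
    w = params.word_size
    seen_until: dict[int, int] = {}
    out = []
    for i in range(len(a) - w + 1):
        for j in index.get(a[i : i + w], ()):
            d = i - j
            if i < seen_until.get(d, 0):
                continue
            qs, qe, matches = _extend_on_diagonal(a, b, i, j, w, params.x_drop)
            seen_until[d] = qe
            length = qe - qs
            if length >= params.min_overlap and matches / length >= params.min_identity:
                out.append((qs, qe, qs - d, qe - d, matches))
    return out


def seeded_local_align(
    a_id: str, a: str, b_id: str, b: str, params: DedupParams | None = None
) -> list[LocalAlignment]:
    """All qualifying seeded local alignments of ``a`` against ``b``.

    Both subject strands are searched.  Reported hits satisfy
    ``identity >= min_identity`` and ``length >= min_overlap``; the
    search is symmetric, so aligning (b, a) reports mirrored intervals.
    """
    params = params or DedupParams()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    hits: list[LocalAlignment] = []
    index = _word_index(b, params.word_size)
    for qs, qe, ss, se, m in _align_one_strand(a, b, index, params):
        hits.append(LocalAlignment(a_id, b_id, qs, qe, ss, se, "+", m))
    b_rc = revcomp(b)
    index_rc = _word_index(b_rc, params.word_size)
    for qs, qe, ss, se, m in _align_one_strand(a, b_rc, index_rc, params):
        hits.append(
            LocalAlignment(a_id, b_id, qs, qe, len(b) - se, len(b) - ss, "-", m)
        )
    return hits


# ---------------------------------------------------------------------------
# overlap resolution


def _consensus_columns(x: str, y: str) -> str:
    """Per-column majority of two equal-length segments (ties keep the
    first, i.e. the suffix donor's base)."""
    return "".join(cx if cx == cy else cx for cx, cy in zip(x, y))


def resolve_overlap(
    a_id: str,
    a: str,
    b_id: str,
    b: str,
    aln: LocalAlignment,
    params: DedupParams | None = None,
) -> tuple[str, dict[str, str]]:
    """Apply the join-or-shorten rule to one qualifying overlap.

    Dovetail overlaps (the alignment covers a suffix of one sequence and
    a prefix of the other, within ``end_slack`` bases of the ends) JOIN
    the two into a single consensus, retiring both inputs.  Containments
    and internal overlaps TRIM the shorter sequence: its aligned segment
    is removed and only the longest remaining piece kept (dropped
    entirely if below ``min_seq_len``).  Length ties are broken by
    lexicographic id.

    Returns ``(action, replacement)`` where ``replacement`` maps new or
    surviving ids to sequences; ids of ``a``/``b`` absent from the map
    were removed.
    """
    params = params or DedupParams()
    if aln.query_id != a_id or aln.subject_id != b_id:
        raise ValueError("alignment does not reference the given sequences")
    if aln.q_end > len(a) or aln.s_end > len(b):
        raise ValueError("alignment inconsistent with sequence lengths")
    slack = params.end_slack
    cov_a_pre = aln.q_start <= slack
    cov_a_suf = aln.q_end >= len(a) - slack
    cov_b_pre = aln.s_start <= slack
    cov_b_suf = aln.s_end >= len(b) - slack

    a_contained = cov_a_pre and cov_a_suf
    b_contained = cov_b_pre and cov_b_suf
    if a_contained or b_contained:
        if a_contained and b_contained:
            # near-identical sequences: keep the longer (tie: smaller id)
            victim = (a_id, a) if (len(a), a_id) > (len(b), b_id) else (b_id, b)
        else:
            victim = (a_id, a) if a_contained else (b_id, b)
        keep = (b_id, b) if victim[0] == a_id else (a_id, a)
        repl = {keep[0]: keep[1]}
        piece = _trim(victim[1], aln, victim[0] == a_id, params)
        if piece:
            repl[victim[0]] = piece
        return "TRIM", repl

    if aln.strand == "+" and cov_a_suf and cov_b_pre:
        joined = (
            a[: aln.q_start]
            + _consensus_columns(a[aln.q_start : aln.q_end], b[aln.s_start : aln.s_end])
            + b[aln.s_end :]
        )
        return "JOIN", {a_id: joined}
    if aln.strand == "+" and cov_b_suf and cov_a_pre:
        joined = (
            b[: aln.s_start]
            + _consensus_columns(b[aln.s_start : aln.s_end], a[aln.q_start : aln.q_end])
            + a[aln.q_end :]
        )
        return "JOIN", {b_id: joined}

    # internal overlap: shorten the shorter sequence
    victim_is_a = (len(a), a_id) < (len(b), b_id)
    victim_id, victim = (a_id, a) if victim_is_a else (b_id, b)
    keep_id, keep = (b_id, b) if victim_is_a else (a_id, a)
    repl = {keep_id: keep}
    piece = _trim(victim, aln, victim_is_a, params)
    if piece:
        repl[victim_id] = piece
    return "TRIM", repl


def _trim(seq: str, aln: LocalAlignment, is_query: bool, params: DedupParams) -> str | None:
    s, e = (aln.q_start, aln.q_end) if is_query else (aln.s_start, aln.s_end)
    left, right = seq[:s], seq[e:]
    piece = left if len(left) >= len(right) else right
    return piece if len(piece) >= params.min_seq_len else None


# ---------------------------------------------------------------------------
# fixpoint iteration


def _best_pair_alignment(
    library: dict[str, str],
    params: DedupParams,
    cache: dict[tuple[str, str], LocalAlignment | None],
) -> LocalAlignment | None:
    ids = sorted(library)
    best: LocalAlignment | None = None
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            key = (x, y)
            if key not in cache:
                hits = seeded_local_align(x, library[x], y, library[y], params)
                cache[key] = max(hits, key=lambda h: (h.length, h.matches)) if hits else None
            h = cache[key]
            if h is not None and (
                best is None
                or (h.length, h.matches, h.query_id, h.subject_id)
                > (best.length, best.matches, best.query_id, best.subject_id)
            ):
                best = h
    return best


def dedup_iterate(
    library: dict[str, str], params: DedupParams | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Resolve overlaps (longest first) until no qualifying pair remains.

    Returns the fixpoint library and a per-round log of library size and
    total bases.  Total bases must strictly decrease every round; if
    they fail to, the iteration aborts with a diagnostic (this guards
    against non-termination).
    """
    params = params or DedupParams()
    if len(set(library)) != len(library):
        raise ValueError("library ids must be unique")
    lib = dict(library)
    cache: dict[tuple[str, str], LocalAlignment | None] = {}
    log_rows = [{"round": 0, "n_seqs": len(lib), "total_bases": sum(map(len, lib.values()))}]
    rnd = 0
    while True:
        aln = _best_pair_alignment(lib, params, cache)
        if aln is None:
            break
        rnd += 1
        x, y = aln.query_id, aln.subject_id
        action, repl = resolve_overlap(x, lib[x], y, lib[y], aln, params)
        for dead in (x, y):
            lib.pop(dead)
        for rid, seq in repl.items():
            if len(seq) >= params.min_seq_len:
                lib[rid] = seq
        # every cached alignment touching a changed id is stale
        cache = {k: v for k, v in cache.items() if x not in k and y not in k}
        total = sum(map(len, lib.values()))
        if total >= log_rows[-1]["total_bases"]:
            raise RuntimeError(
                f"round {rnd}: total library bases did not decrease "
                f"({log_rows[-1]['total_bases']} -> {total}); aborting"
            )
        log_rows.append({"round": rnd, "n_seqs": len(lib), "total_bases": total})
    return lib, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# genome-hit refinement and masking


def _genome_hits(
    seq_id: str, seq: str, genome: dict[str, str], params: DedupParams
) -> list[LocalAlignment]:
    hits = []
    for chrom, gseq in genome.items():
        hits.extend(seeded_local_align(seq_id, seq, chrom, gseq, params))
    return hits


def genome_hit_refine(
    library: dict[str, str], genome: dict[str, str], params: DedupParams | None = None
) -> dict[str, str]:
    """Excise library segments that align to the genome fewer than
    ``min_genome_hits`` times.

    Per-base genomic hit counts come from the seeded aligner; maximal
    under-supported segments are removed and resulting pieces shorter
    than ``min_seq_len`` dropped.  Multi-piece survivors get ``_p<k>``
    id suffixes.
    """
    params = params or DedupParams()
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    refined: dict[str, str] = {}
    for sid in sorted(library):
        seq = library[sid]
        count = np.zeros(len(seq), dtype=np.int32)
        for h in _genome_hits(sid, seq, genome, params):
            count[h.q_start : h.q_end] += 1
        mask = count >= params.min_genome_hits
        pieces = []
        idx = np.flatnonzero(mask)
        if len(idx):
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks, [len(idx) - 1]])
            for s, e in zip(starts, ends):
                lo, hi = int(idx[s]), int(idx[e]) + 1
                if hi - lo >= params.min_seq_len:
                    pieces.append(seq[lo:hi])
        if len(pieces) == 1:
            refined[sid] = pieces[0]
        else:
            for k, p in enumerate(pieces):
                refined[f"{sid}_p{k}"] = p
    return refined


def mask_genome(
    genome: dict[str, str], library: dict[str, str], params: DedupParams | None = None
) -> tuple[dict[str, str], pd.DataFrame]:
    """Soft-mask genomic bases covered by qualifying library alignments.

    Returns the masked genome (covered bases lower-cased) and a coverage
    table with the masked fraction per library sequence and overall.
    """
    params = params or DedupParams()
    masks = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
    per_family: dict[str, int] = {}
    for sid in sorted(library):
        fam_mask = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
        for h in _genome_hits(sid, library[sid], genome, params):
            fam_mask[h.subject_id][h.s_start : h.s_end] = True
        per_family[sid] = int(sum(m.sum() for m in fam_mask.values()))
        for c, m in fam_mask.items():
            masks[c] |= m
    masked = {}
    for c, s in genome.items():
        arr = np.frombuffer(s.encode(), dtype="S1").copy()
        lower = np.frombuffer(s.lower().encode(), dtype="S1")
        arr[masks[c]] = lower[masks[c]]
        masked[c] = arr.tobytes().decode()
    total_len = sum(len(s) for s in genome.values())
    total_masked = int(sum(m.sum() for m in masks.values()))
    rows = [
        {"family": sid, "masked_bases": n, "masked_fraction": n / total_len}
        for sid, n in sorted(per_family.items())
    ]
    rows.append(
        {
            "family": "overall",
            "masked_bases": total_masked,
            "masked_fraction": total_masked / total_len,
        }
    )
    return masked, pd.DataFrame(rows)
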