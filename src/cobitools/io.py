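"""File-format helpers shared by all pipeline stages.

Conventions
-----------
* FASTA via Biopython, wrapped at 60 columns.
* BED: 0-based half-open, 4th column is a free-text kind/name label.
* Depth TSV: ``chrom  pos  depth`` with 1-based positions (the common
  per-base depth dialect produced by ``samtools depth``).
* Pooled SNP TSV: ``chrom  pos  ref  alt`` followed by one column per pool
  holding ``refDepth,altDepth``; the header names pools as ``sex_label``.
* Rearrangement TSV: the 12-column whole-genome-alignment dialect
  (see :mod:`cobitools.svmerge`), 1-based inclusive coordinates.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a BED table (columns: chrom, start, end, then extras)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path: str | Path, names: Iterable[str] = ("chrom", "start", "end", "name")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    names = list(names)[: df.shape[1]]
    df.columns = names + [f"col{i}" for i in range(len(names), df.shape[1])]
    return df


def write_depth_tsv(depths: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Per-base depth, 1-based positions, one row per assembled base."""
    with open(path, "w") as fh:
        for chrom, arr in depths.items():
            frame = pd.DataFrame(
                {"chrom": chrom, "pos": np.arange(1, len(arr) + 1), "depth": arr}
            )
            frame.to_csv(fh, sep="\t", header=False, index=False)


def read_depth_tsv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"])
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = np.zeros(int(sub["pos"].max()), dtype=np.int64)
        arr[sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
        out[str(chrom)] = arr
    return out


def pool_columns(snps: pd.DataFrame) -> list[str]:
    """Pool names present in an in-memory SNP table (``<name>:ref`` columns)."""
    return [c[:-4] for c in snps.columns if c.endswith(":ref")]


def write_pool_snp_tsv(snps: pd.DataFrame, path: str | Path) -> None:
    """Serialise the in-memory SNP table to the ``refDepth,altDepth`` dialect."""
    pools = pool_columns(snps)
    out = snps[["chrom", "pos", "ref", "alt"]].copy()
    for p in pools:
        out[p] = (
            snps[f"{p}:ref"].astype(str) + "," + snps[f"{p}:alt"].astype(str)
        )
    out.to_csv(path, sep="\t", index=False)


def read_pool_snp_tsv(path: str | Path) -> pd.DataFrame:
    """Parse the pooled SNP dialect back to numeric per-pool columns.

    Raises ``ValueError`` naming the offending line for malformed
    allele-depth fields.
    """
    df = pd.read_csv(path, sep="\t")
    pools = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    out = df[["chrom", "pos", "ref", "alt"]].copy()
    for p in pools:
        split = df[p].astype(str).str.split(",", expand=True)
        if split.shape[1] != 2:
            raise ValueError(f"malformed allele-depth field in pool column {p!r}")
        for part, key in ((0, "ref"), (1, "alt")):
            col = pd.to_numeric(split[part], errors="coerce")
            if col.isna().any():
                # +2: 1 for the header row, 1 for 1-based line numbering
                line = int(col.index[col.isna()][0]) + 2
                raise ValueError(
                    f"malformed allele-depth field for pool {p!r} at line {line}"
                )
            out[f"{p}:{key}"] = col.astype(int)
    return out


def write_pairing_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table[["chromosome", "individual", "n_paired", "n_unpaired"]].to_csv(
        path, sep="\t", index=False
    )


def read_pairing_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chromosome", "individual", "n_paired", "n_unpaired"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"pairing table missing columns: {sorted(missing)}")
    return df


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Gene features from a GFF3 file (1-based inclusive coordinates)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attrs"],
    )
    genes = df[df["type"] == "gene"].reset_index(drop=True)
    return genes[["chrom", "start", "end", "attrs"]]


def tsv_header_comment(fh, tool: str, seed: int | None, params: Mapping | None = None) -> None:
    """Provenance comment line written at the top of emitted tables."""
    from . import __version__

    bits = [f"tool=cobitools/{tool}", f"version={__version__}"]
    if seed is not None:
        bits.append(f"seed={seed}")
    if params:
        bits.extend(f"{k}={v}" for k, v in params.items())
    fh.write("# " + " ".join(bits) + "\n")
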