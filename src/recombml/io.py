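"""File I/O with explicit coordinate-dialect conversion.

Internal coordinates are always 0-based half-open. BED stays as-is on
read/write; GFF3 and methylation reports (1-based) are converted at this
boundary. Malformed records are rejected with their line number rather than
silently truncated.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinGrid
from .recmap import CO_COLUMNS, COSet

__all__ = [
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "read_fasta",
    "write_fasta",
    "read_cytosine_calls",
    "read_tpm_table",
    "write_bin_track",
    "read_bin_track",
    "read_co_set",
    "write_co_set",
    "read_snp_map",
    "write_snp_map",
]


class ParseError(ValueError):
    pass


def read_bed(path) -> pd.DataFrame:
    """BED3+ records (0-based half-open) -> DataFrame(chrom, start, end[, name])."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{ln}: start must be < end")
            rows.append((parts[0], start, end, parts[3] if len(parts) > 3 else "."))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(frame: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name"] if c in frame.columns]
    frame[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene records from GFF3 (1-based closed -> 0-based half-open).

    Returns DataFrame(gene, chrom, start, end); the gene id comes from the
    ID= attribute.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{ln}: GFF3 requires 9 fields")
            if parts[2] != feature_type:
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}:{ln}: invalid 1-based interval")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene = attrs.get("ID", f"{parts[0]}:{start1}-{end1}")
            rows.append((gene, parts[0], start1 - 1, end1))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_cytosine_calls(path) -> pd.DataFrame:
    """Per-cytosine methylation report: chrom, pos (1-based), context, tissue,
    replicate, meth, total."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "context", "tissue", "replicate", "meth", "total"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["meth"] > df["total"]).any() or (df["meth"] < 0).any():
        raise ParseError(f"{path}: methylated calls must satisfy 0 <= meth <= total")
    return df


def read_tpm_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "tissue", "replicate", "tpm"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_bin_track(grid: BinGrid, values, path, name: str = "value") -> None:
    """One per-bin track as BED-like TSV: chrom, start, end, value."""
    out = grid.frame[["chrom", "start", "end"]].copy()
    out[name] = np.asarray(values)
    out.to_csv(path, sep="\t", index=False)


def read_bin_track(path, grid: BinGrid | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if grid is not None and len(df) != grid.n_bins:
        raise ParseError(f"{path}: {len(df)} rows but grid has {grid.n_bins} bins")
    return df


def write_co_set(cos: COSet, path, meioses_path=None) -> None:
    """CO intervals as BED-like TSV plus a sidecar of per-population meioses."""
    cos.frame[CO_COLUMNS].to_csv(path, sep="\t", index=False)
    if meioses_path is None:
        meioses_path = Path(str(path)).with_suffix(".meioses.tsv")
    pd.Series(cos.meioses, name="meioses").rename_axis("population").to_csv(
        meioses_path, sep="\t"
    )


def read_co_set(path, meioses_path=None) -> COSet:
    frame = pd.read_csv(path, sep="\t")
    if meioses_path is None:
        meioses_path = Path(str(path)).with_suffix(".meioses.tsv")
    m = pd.read_csv(meioses_path, sep="\t").set_index("population")["meioses"]
    return COSet(frame=frame, meioses={str(k): int(v) for k, v in m.items()})


def write_snp_map(snp_map: pd.DataFrame, path) -> None:
    snp_map[["chrom", "pos"]].to_csv(path, sep="\t", index=False)


def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos"} <= set(df.columns):
        raise ParseError(f"{path}: SNP map needs chrom and pos columns")
    return df
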