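"""Readers and writers for the plain-text formats used by the pipeline.

Formats
-------
chrom.sizes   two columns: chrom, length.
BED           chrom, start, end[, name, score, strand]; 0-based half-open.
bedGraph      chrom, start, end, value.
block table   TSV with one row per synteny block and the coordinates of the
              block on both genomes of a comparison:
              block_id, chrom_a, start_a, end_a, strand_a,
              chrom_b, start_b, end_b, strand_b.
count triples TSV: bin_i, bin_j (global window indices, i <= j), count and
              optionally an ``sdr`` column (reads with >= 1 end in a
              segmental duplication), with a companion bin BED mapping
              indices to windows.

All coordinate conversions are centralized here; the rest of the package
works exclusively with 0-based half-open intervals.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

BLOCK_COLUMNS = [
    "block_id",
    "chrom_a", "start_a", "end_a", "strand_a",
    "chrom_b", "start_b", "end_b", "strand_b",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"],
                     dtype={"chrom": str, "size": int})
    return dict(zip(df["chrom"], df["size"]))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED file (3-6 columns) into a DataFrame with canonical columns.

    An empty file yields an empty frame with the three coordinate columns.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS[:3])
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = BED_COLUMNS[:ncol]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    """Read a bedGraph file; malformed lines raise with their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}: malformed bedGraph line {lineno}: "
                    f"expected 4 fields, got {len(parts)}"
                )
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed bedGraph line {lineno}: {exc}"
                ) from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, ["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_block_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: block table missing columns {missing}")
    for col in ("chrom_a", "chrom_b"):
        df[col] = df[col].astype(str)
    for col in ("start_a", "end_a", "start_b", "end_b"):
        df[col] = df[col].astype(int)
    for col in ("strand_a", "strand_b"):
        bad = ~df[col].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"{path}: invalid strand values in {col}")
    return df


def write_block_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.loc[:, BLOCK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_triples(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("bin_i", "bin_j", "count"):
        if col not in df.columns:
            raise ValueError(f"{path}: count triples missing column {col!r}")
        df[col] = df[col].astype(int)
    if "sdr" in df.columns:
        df["sdr"] = df["sdr"].astype(int)
    if (df["bin_i"] > df["bin_j"]).any():
        raise ValueError(f"{path}: count triples must satisfy bin_i <= bin_j")
    return df


def write_triples(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["bin_i", "bin_j", "count"] + (["sdr"] if "sdr" in df.columns else [])
    df.loc[:, cols].to_csv(path, sep="\t", index=False)


def read_bin_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Bin BED: name column holds the global window index."""
    df = read_bed(path)
    if "name" not in df.columns:
        raise ValueError(f"{path}: bin BED needs a 4th (index) column")
    df = df.rename(columns={"name": "index"})
    df["index"] = df["index"].astype(int)
    return df[["index", "chrom", "start", "end"]]


def write_bin_bed(windows: pd.DataFrame, path: str | os.PathLike) -> None:
    out = windows.loc[:, ["chrom", "start", "end"]].copy()
    out["name"] = windows["index"].astype(int)
    write_bed(out, path)
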