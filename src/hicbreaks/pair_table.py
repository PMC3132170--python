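"""Assembly of the analysis table: covariates, breakpoint flags, logs.

One record per locus pair.  Pair-level covariates are products of the
per-locus values (gene-density fraction and summed DNaseI signal), and
natural-log transforms are attached where the raw value is positive.
Rows failing a positivity requirement are not deleted; each model or
test selects the rows valid for its own terms.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hic import LocusGrid
from .intervals import covered_fraction

__all__ = [
    "compute_gene_density",
    "compute_dnase_signal",
    "gene_density_track",
    "dnase_track",
    "flag_breakpoint_locus_pairs",
    "assemble_pair_table",
]

log = logging.getLogger(__name__)


def compute_gene_density(window: tuple[int, int],
                         gene_intervals: list[tuple[int, int]]) -> float:
    """Fraction of the window covered by the union of genic intervals."""
    start, end = window
    return covered_fraction(gene_intervals, start, end)


def compute_dnase_signal(window: tuple[int, int],
                         bedgraph: pd.DataFrame) -> float:
    """Sum of cleavage densities falling inside one window.

    Each bedGraph record contributes value * (overlap / record length),
    so records straddling a window boundary are split proportionally.
    """
    start, end = window
    s = bedgraph["start"].to_numpy()
    e = bedgraph["end"].to_numpy()
    v = bedgraph["value"].to_numpy(dtype=float)
    ov = np.minimum(e, end) - np.maximum(s, start)
    length = e - s
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(length > 0, np.clip(ov, 0, None) / length, 0.0)
    return float(np.sum(v * frac))


def _track(grid: LocusGrid, per_chrom, func) -> pd.Series:
    vals = np.zeros(grid.n_windows)
    for k, row in grid.windows.iterrows():
        vals[int(row["index"])] = func(row, per_chrom.get(row["chrom"]))
    return pd.Series(vals, index=grid.windows["index"].to_numpy())


def gene_density_track(grid: LocusGrid, gene_bed: pd.DataFrame) -> pd.Series:
    """Per-window genic covered fraction, indexed by global window index."""
    per_chrom = {
        str(c): list(zip(sub["start"].astype(int), sub["end"].astype(int)))
        for c, sub in gene_bed.groupby("chrom")
    } if len(gene_bed) else {}
    return _track(grid, per_chrom,
                  lambda row, ivs: compute_gene_density(
                      (row["start"], row["end"]), ivs or []))


def dnase_track(grid: LocusGrid, bedgraph: pd.DataFrame) -> pd.Series:
    """Per-window summed DNaseI signal, indexed by global window index."""
    per_chrom = {str(c): sub for c, sub in bedgraph.groupby("chrom")} \
        if len(bedgraph) else {}
    empty = pd.DataFrame(columns=["start", "end", "value"])
    return _track(grid, per_chrom,
                  lambda row, sub: compute_dnase_signal(
                      (row["start"], row["end"]),
                      sub if sub is not None else empty))


def flag_breakpoint_locus_pairs(
    pairs: Iterable, grid: LocusGrid,
    retained: Sequence[int] | None = None,
    *, mode: str = "midpoint",
) -> set[tuple[int, int]]:
    """Locus pairs (i <= j) containing at least one breakpoint pair.

    Each breakpoint is assigned to the window containing its midpoint
    (``mode='midpoint'``) or to every overlapped window
    (``mode='overlap'``); a locus pair is flagged when one member of a
    breakpoint pair lands in each of its loci.  Breakpoint pairs with a
    member on a filtered-out or off-grid locus are dropped and logged.
    ``pairs`` is an iterable of objects with ``bp1`` / ``bp2`` members
    carrying chrom, start and end.
    """
    if mode not in ("midpoint", "overlap"):
        raise ValueError("mode must be 'midpoint' or 'overlap'")
    retained_set = None if retained is None else {int(r) for r in retained}

    def windows_for(bp) -> list[int]:
        if mode == "midpoint":
            mid = (bp.start + bp.end) // 2
            # right-telomere sentinels sit exactly at the chromosome end
            mid = min(mid, grid.chrom_sizes.get(bp.chrom, mid + 1) - 1)
            w = grid.window_of(bp.chrom, mid)
            ws = [] if w is None else [w]
        else:
            ws = []
            lo = grid.window_of(bp.chrom, max(bp.start, 0))
            hi = grid.window_of(bp.chrom, max(bp.end - 1, 0))
            if lo is not None and hi is not None:
                ws = list(range(lo, hi + 1))
        if retained_set is not None:
            ws = [w for w in ws if w in retained_set]
        return ws

    flagged: set[tuple[int, int]] = set()
    dropped = 0
    for p in pairs:
        w1s = windows_for(p.bp1)
        w2s = windows_for(p.bp2)
        if not w1s or not w2s:
            dropped += 1
            continue
        for w1 in w1s:
            for w2 in w2s:
                flagged.add((min(w1, w2), max(w1, w2)))
    if dropped:
        log.info("flag_breakpoint_locus_pairs: dropped %d breakpoint pair(s) "
                 "on filtered or off-grid loci", dropped)
    return flagged


def assemble_pair_table(pair_counts: pd.DataFrame,
                        tracks: pd.DataFrame,
                        bp_flags: set[tuple[int, int]]) -> pd.DataFrame:
    """Join counts, covariates and flags into the analysis table.

    ``tracks`` is indexed by global window index with columns
    ``gene_density`` and (optionally) ``dnase``.  Pair covariates are
    products of the per-locus values; natural-log columns are NaN where
    the raw value is not positive, which marks the row as excluded from
    analyses requiring that term (rows are never deleted here).
    """
    needed = set(pair_counts["i"]).union(pair_counts["j"])
    missing = needed - set(tracks.index)
    if missing:
        raise ValueError(
            f"locus sets disagree: {len(missing)} pair loci missing from "
            f"tracks (e.g. {sorted(missing)[:5]})")
    df = pair_counts.copy()
    i = df["i"].to_numpy()
    j = df["j"].to_numpy()
    gd_i = tracks.loc[i, "gene_density"].to_numpy(dtype=float)
    gd_j = tracks.loc[j, "gene_density"].to_numpy(dtype=float)
    df["Gcov"] = gd_i * gd_j
    if "dnase" in tracks.columns:
        dn_i = tracks.loc[i, "dnase"].to_numpy(dtype=float)
        dn_j = tracks.loc[j, "dnase"].to_numpy(dtype=float)
        df["DNase"] = dn_i * dn_j
    flags = {(min(a, b), max(a, b)) for a, b in bp_flags}
    df["BP"] = [
        (int(a), int(b)) in flags
        for a, b in zip(df["i"], df["j"])
    ]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["log_RC"] = _safe_log(df["NRCSD"].to_numpy(dtype=float))
        df["log_GD"] = _safe_log(df["GD"].to_numpy(dtype=float))
        df["log_Gcov"] = _safe_log(df["Gcov"].to_numpy(dtype=float))
        if "DNase" in df.columns:
            df["log_DNase"] = _safe_log(df["DNase"].to_numpy(dtype=float))
    return df


def _safe_log(x: np.ndarray) -> np.ndarray:
    out = np.full(x.shape, np.nan)
    pos = np.isfinite(x) & (x > 0)
    out[pos] = np.log(x[pos])
    return out
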