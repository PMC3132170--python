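"""Locus grid construction, read-pair binning and segmental-duplication
correction for binned contact counts.

The genome is tiled with fixed-length windows (default 1 Mb) on the
autosomes only; windows more than half covered by assembly gaps are
discarded.  The contact frequency of a locus pair is the number of read
pairs with one end in each window.  Reads falling in segmental
duplications (SDs) are unreliable when multi-mapping reads were placed
at random, so corrected counts discard SD-involved reads and rescale the
remainder to the full-window expectation:

    NRCSD = (NR - SDR) / ((1 - FSD1) * (1 - FSD2))

where NR is the raw pair count, SDR the count of reads with at least one
end inside an SD and FSD1/FSD2 the SD-covered fractions of the two
windows.  The rescaling assumes reads are as dense inside SDs as in the
surrounding sequence.  The exact algebraic form of the published
correction is not spelled out in its source; this estimator is the
simple one implied by that uniformity assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import covered_fraction

__all__ = [
    "LocusGrid",
    "build_locus_grid",
    "filter_loci",
    "bin_read_pairs",
    "compute_sd_fraction",
    "correct_pair_count",
    "compute_genomic_distance",
    "n_unordered_pairs",
    "pair_count_table",
]

DEFAULT_WINDOW = 1_000_000
_SEX_CHROMS = {"chrX", "chrY", "X", "Y", "chrM", "MT", "chrW", "chrZ"}


@dataclass
class LocusGrid:
    """Fixed-length windows tiling the autosomes of one genome.

    ``windows`` has one row per window with columns ``index`` (global,
    contiguous), ``chrom``, ``start``, ``end``, ``gap_fraction`` and
    ``sd_fraction``.  The last window of a chromosome may be short.
    """

    window_length: int
    chrom_sizes: dict[str, int]
    windows: pd.DataFrame
    _index_lookup: dict[str, tuple[int, int]] = field(default_factory=dict,
                                                      repr=False)

    def __post_init__(self):
        if not self._index_lookup:
            for chrom, sub in self.windows.groupby("chrom", sort=False):
                self._index_lookup[str(chrom)] = (
                    int(sub["index"].iloc[0]), int(sub["index"].iloc[-1]))

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_of(self, chrom: str, pos: int) -> int | None:
        """Global window index containing (chrom, pos), or None if off-grid."""
        if chrom not in self._index_lookup:
            return None
        if pos < 0 or pos >= self.chrom_sizes[chrom]:
            return None
        first, last = self._index_lookup[chrom]
        idx = first + pos // self.window_length
        return idx if idx <= last else None


def _autosomes(chrom_sizes: dict[str, int],
               autosome_list: list[str] | None) -> list[str]:
    if autosome_list is not None:
        if not autosome_list:
            raise ValueError("empty autosome list")
        missing = [c for c in autosome_list if c not in chrom_sizes]
        if missing:
            raise ValueError(f"autosomes absent from chrom sizes: {missing}")
        return list(autosome_list)
    return [c for c in chrom_sizes if c not in _SEX_CHROMS]


def build_locus_grid(chrom_sizes: dict[str, int],
                     window_length: int = DEFAULT_WINDOW,
                     gap_bed: pd.DataFrame | None = None,
                     autosome_list: list[str] | None = None,
                     sd_bed: pd.DataFrame | None = None) -> LocusGrid:
    """Tile the autosomes with windows and attach gap and SD fractions.

    ``gap_bed`` / ``sd_bed`` are BED DataFrames (chrom, start, end); per
    window the covered fraction of the merged intervals is stored.
    """
    if window_length <= 0:
        raise ValueError("window length must be positive")
    chroms = _autosomes(chrom_sizes, autosome_list)
    gap_ivs = _per_chrom(gap_bed)
    sd_ivs = _per_chrom(sd_bed)
    rows = []
    idx = 0
    sizes = {}
    for chrom in chroms:
        size = int(chrom_sizes[chrom])
        if size <= 0:
            raise ValueError(f"non-positive size for {chrom}")
        sizes[chrom] = size
        for start in range(0, size, window_length):
            end = min(start + window_length, size)
            rows.append({
                "index": idx, "chrom": chrom, "start": start, "end": end,
                "gap_fraction": covered_fraction(gap_ivs.get(chrom, ()), start, end),
                "sd_fraction": covered_fraction(sd_ivs.get(chrom, ()), start, end),
            })
            idx += 1
    windows = pd.DataFrame(rows, columns=["index", "chrom", "start", "end",
                                          "gap_fraction", "sd_fraction"])
    return LocusGrid(window_length, sizes, windows)


def _per_chrom(bed: pd.DataFrame | None) -> dict[str, list[tuple[int, int]]]:
    if bed is None or len(bed) == 0:
        return {}
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, sub in bed.groupby("chrom"):
        out[str(chrom)] = list(zip(sub["start"].astype(int),
                                   sub["end"].astype(int)))
    return out


def filter_loci(grid: LocusGrid, max_gap_fraction: float = 0.5) -> np.ndarray:
    """Indices of retained windows: gap fraction strictly above the
    threshold removes a window (a fraction exactly at 0.5 is retained)."""
    keep = grid.windows["gap_fraction"].to_numpy() <= max_gap_fraction
    return grid.windows.loc[keep, "index"].to_numpy()


def compute_sd_fraction(window: tuple[int, int],
                        sd_intervals: list[tuple[int, int]]) -> float:
    """Fraction of one window covered by the union of SD intervals."""
    start, end = window
    return covered_fraction(sd_intervals, start, end)


def bin_read_pairs(read_pairs: pd.DataFrame, grid: LocusGrid
                   ) -> tuple[pd.DataFrame, int]:
    """Aggregate read pairs (chrom1, pos1, chrom2, pos2) into window pairs.

    Returns a triples DataFrame (bin_i <= bin_j, count) and the number of
    read pairs discarded because an end fell outside the grid.  Total
    reads are conserved: sum(count) + discarded == len(read_pairs).
    """
    i_idx = np.empty(len(read_pairs), dtype=float)
    j_idx = np.empty(len(read_pairs), dtype=float)
    for k, (c1, p1, c2, p2) in enumerate(
            read_pairs[["chrom1", "pos1", "chrom2", "pos2"]].itertuples(index=False)):
        w1 = grid.window_of(str(c1), int(p1))
        w2 = grid.window_of(str(c2), int(p2))
        i_idx[k] = np.nan if w1 is None else w1
        j_idx[k] = np.nan if w2 is None else w2
    ok = ~(np.isnan(i_idx) | np.isnan(j_idx))
    discarded = int((~ok).sum())
    lo = np.minimum(i_idx[ok], j_idx[ok]).astype(int)
    hi = np.maximum(i_idx[ok], j_idx[ok]).astype(int)
    if len(lo) == 0:
        return pd.DataFrame(columns=["bin_i", "bin_j", "count"]), discarded
    key = lo * grid.n_windows + hi
    uniq, counts = np.unique(key, return_counts=True)
    triples = pd.DataFrame({
        "bin_i": uniq // grid.n_windows,
        "bin_j": uniq % grid.n_windows,
        "count": counts.astype(int),
    })
    return triples, discarded


def correct_pair_count(nr, sdr, fsd1, fsd2):
    """SD-corrected count NRCSD = (NR - SDR) / ((1-FSD1)(1-FSD2)).

    Vectorised over array inputs.  Pairs where either window is entirely
    SD (FSD >= 1) are undefined: NaN is returned with a warning.
    """
    nr = np.asarray(nr, dtype=float)
    sdr = np.asarray(sdr, dtype=float)
    fsd1 = np.asarray(fsd1, dtype=float)
    fsd2 = np.asarray(fsd2, dtype=float)
    if np.any(sdr > nr) or np.any(sdr < 0):
        raise ValueError("SDR must satisfy 0 <= SDR <= NR")
    denom = (1.0 - fsd1) * (1.0 - fsd2)
    bad = (fsd1 >= 1.0) | (fsd2 >= 1.0)
    if np.any(bad):
        warnings.warn("window(s) entirely covered by SDs: corrected count "
                      "undefined for some pairs (set to NaN)")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (nr - sdr) / denom
    out = np.where(bad, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def compute_genomic_distance(grid: LocusGrid, i: int, j: int) -> float:
    """Genomic distance in Mb between two windows (by start positions);
    NaN marks an inter-chromosomal pair."""
    wi = grid.windows.iloc[int(i)]
    wj = grid.windows.iloc[int(j)]
    if wi["chrom"] != wj["chrom"]:
        return float("nan")
    return abs(int(wi["start"]) - int(wj["start"])) / 1e6


def n_unordered_pairs(n: int) -> int:
    """Number of unordered pairs of n loci, self-pairs included: n(n+1)/2."""
    if n < 0:
        raise ValueError("n must be non-negative")
    return n * (n + 1) // 2


def pair_count_table(triples: pd.DataFrame, grid: LocusGrid,
                     retained: np.ndarray | None = None,
                     *, all_pairs: bool = False) -> pd.DataFrame:
    """Per-locus-pair table: i, j, chrom_i, chrom_j, GD, NR, SDR, NRCSD.

    ``triples`` must carry bin_i <= bin_j and count; an optional ``sdr``
    column gives read-level SD-involved counts.  Without it, SDR is
    estimated under the uniformity assumption as
    NR * (1 - (1-FSD1)(1-FSD2)), which makes the correction the identity
    (the estimated mode is flagged in the ``sdr_mode`` attribute of the
    returned frame).  With ``all_pairs`` every unordered pair of retained
    loci is enumerated (zero counts included); otherwise only observed
    pairs are listed.  Pairs touching non-retained loci are dropped.
    """
    win = grid.windows.set_index("index")
    if retained is None:
        retained = win.index.to_numpy()
    retained_set = set(int(r) for r in retained)

    if all_pairs:
        r = np.sort(np.asarray(list(retained_set)))
        ii, jj = np.triu_indices(len(r))
        base = pd.DataFrame({"bin_i": r[ii], "bin_j": r[jj]})
        obs = triples.groupby(["bin_i", "bin_j"], as_index=False).sum()
        df = base.merge(obs, on=["bin_i", "bin_j"], how="left")
        df["count"] = df["count"].fillna(0).astype(int)
        if "sdr" in triples.columns:
            df["sdr"] = df["sdr"].fillna(0).astype(int)
    else:
        df = triples.copy()
        keep = df["bin_i"].isin(retained_set) & df["bin_j"].isin(retained_set)
        df = df.loc[keep].reset_index(drop=True)

    keep = df["bin_i"].isin(retained_set) & df["bin_j"].isin(retained_set)
    df = df.loc[keep].reset_index(drop=True)
    i = df["bin_i"].to_numpy()
    j = df["bin_j"].to_numpy()
    chrom_i = win.loc[i, "chrom"].to_numpy()
    chrom_j = win.loc[j, "chrom"].to_numpy()
    start_i = win.loc[i, "start"].to_numpy(dtype=float)
    start_j = win.loc[j, "start"].to_numpy(dtype=float)
    intra = chrom_i == chrom_j
    gd = np.where(intra, np.abs(start_i - start_j) / 1e6, np.nan)
    fsd1 = win.loc[i, "sd_fraction"].to_numpy(dtype=float)
    fsd2 = win.loc[j, "sd_fraction"].to_numpy(dtype=float)
    nr = df["count"].to_numpy(dtype=float)
    if "sdr" in df.columns:
        sdr = df["sdr"].to_numpy(dtype=float)
        sdr_mode = "read-level"
    else:
        sdr = nr * (1.0 - (1.0 - fsd1) * (1.0 - fsd2))
        sdr_mode = "estimated-from-fractions"
    nrcsd = correct_pair_count(nr, sdr, fsd1, fsd2) if len(df) else np.array([])
    out = pd.DataFrame({
        "i": i, "j": j,
        "chrom_i": chrom_i, "chrom_j": chrom_j,
        "GD": gd, "NR": nr.astype(int), "SDR": sdr,
        "NRCSD": nrcsd,
        "FSD1": fsd1, "FSD2": fsd2,
    })
    out.attrs["sdr_mode"] = sdr_mode
    return out
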