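"""Association tests between breakpoint pairs and contact frequency.

Three complementary routes:

* nested ordinary-least-squares models of log contact count on log
  genomic distance, the breakpoint-pair indicator and covariates,
  compared by extra-sum-of-squares F tests (ANCOVA);
* a two-sided rank-sum test on raw corrected counts of
  inter-chromosomal pairs (no distance model applies there);
* a stratified resampling null: within strata of genomic distance (and
  optionally gene density or DNaseI class), unflagged pairs are drawn
  to match the flagged pairs, and the mean corrected count of the
  flagged set is compared to the resampled means.

Model fits use intra-chromosomal pairs at genomic distance >= 1 Mb with
a positive corrected count; logs are natural logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "MODELS",
    "FitResult",
    "StratumScheme",
    "ResamplingResult",
    "analysis_rows",
    "fit_model",
    "compare_nested_models",
    "ancova",
    "ranksum_test",
    "ranksum_inter",
    "assign_strata",
    "stratified_resampling_test",
]


@dataclass(frozen=True)
class ModelSpec:
    """A linear model: response regressed on an intercept plus terms.

    Interaction terms are written ``"a:b"`` and expand to the product of
    the two named columns.
    """

    name: str
    terms: tuple[str, ...]
    response: str = "log_RC"

    def base_columns(self) -> set[str]:
        cols = {self.response}
        for t in self.terms:
            cols.update(t.split(":"))
        return cols

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (set(self.terms) < set(other.terms)
                and self.response == other.response)


#: The model family: distance-only baseline through covariate-adjusted
#: breakpoint-effect models with interactions.
MODELS: dict[str, ModelSpec] = {
    "M0": ModelSpec("M0", ("log_GD",)),
    "M1": ModelSpec("M1", ("log_GD", "BP")),
    "M2": ModelSpec("M2", ("log_GD", "BP", "log_GD:BP")),
    "M3": ModelSpec("M3", ("log_GD", "log_Gcov")),
    "M4": ModelSpec("M4", ("log_GD", "log_Gcov", "BP")),
    "M5": ModelSpec("M5", ("log_GD", "log_Gcov", "BP", "log_Gcov:BP")),
    "M6": ModelSpec("M6", ("log_GD", "log_DNase")),
    "M7": ModelSpec("M7", ("log_GD", "log_DNase", "BP")),
    "M8": ModelSpec("M8", ("log_GD", "log_DNase", "BP", "log_DNase:BP")),
}


@dataclass
class FitResult:
    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    rss: float
    df_resid: int
    nobs: int
    row_index: pd.Index = field(repr=False, default=None)


def _column(table: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    col = np.ones(len(table))
    for p in parts:
        v = table[p].to_numpy(dtype=float)
        col = col * v
    return col


def analysis_rows(table: pd.DataFrame, spec: ModelSpec) -> pd.Index:
    """Rows eligible for a model fit: intra-chromosomal, GD >= 1 Mb, and
    finite values for the response and every term column."""
    ok = (table["chrom_i"] == table["chrom_j"]) \
        if "chrom_i" in table.columns else pd.Series(True, index=table.index)
    if "GD" in table.columns:
        ok &= table["GD"].to_numpy(dtype=float) >= 1.0
    for col in sorted(spec.base_columns()):
        ok &= np.isfinite(table[col].to_numpy(dtype=float))
    return table.index[ok]


def fit_model(table: pd.DataFrame, spec: ModelSpec | str,
              rows: pd.Index | None = None) -> FitResult:
    """Ordinary least squares fit of ``spec`` on ``table``.

    ``rows`` restricts the fit (used to align nested models on a common
    row set); by default the rows from :func:`analysis_rows`.  A
    rank-deficient design is rejected, naming the collinear terms.
    """
    if isinstance(spec, str):
        spec = MODELS[spec]
    if rows is None:
        rows = analysis_rows(table, spec)
    sub = table.loc[rows]
    if len(sub) == 0:
        raise ValueError(f"{spec.name}: no usable rows")
    names = ["const"] + list(spec.terms)
    X = np.column_stack([np.ones(len(sub))]
                        + [_column(sub, t) for t in spec.terms])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        degenerate = [t for k, t in enumerate(spec.terms)
                      if np.ptp(X[:, k + 1]) == 0]
        raise ValueError(
            f"{spec.name}: rank-deficient design "
            f"(rank {rank} < {X.shape[1]}; degenerate/collinear terms: "
            f"{degenerate or spec.terms})")
    y = sub[spec.response].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    return FitResult(
        spec=spec,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        rss=float(res.ssr),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        row_index=sub.index,
    )


def compare_nested_models(small: FitResult, big: FitResult
                          ) -> tuple[float, float, int, int]:
    """Extra-sum-of-squares F test of a nested model comparison.

    Returns ``(F, p, df_num, df_den)`` with
    F = ((RSS_small - RSS_big) / ddf) / (RSS_big / df_big).
    Both fits must use the same rows and the small model's terms must be
    a strict subset of the big model's.
    """
    if not small.spec.is_nested_in(big.spec):
        raise ValueError(
            f"{small.spec.name} is not strictly nested in {big.spec.name}")
    if small.row_index is not None and big.row_index is not None:
        if not small.row_index.equals(big.row_index):
            raise ValueError("nested comparison requires identical row sets")
    ddf = len(big.spec.terms) - len(small.spec.terms)
    f = ((small.rss - big.rss) / ddf) / (big.rss / big.df_resid)
    p = float(st.f.sf(f, ddf, big.df_resid))
    return float(f), p, ddf, big.df_resid


def ancova(table: pd.DataFrame, small: ModelSpec | str, big: ModelSpec | str
           ) -> dict:
    """Fit a nested model pair on the rows valid for the bigger model and
    compare them; returns a result dict with both fits and the F test."""
    small_spec = MODELS[small] if isinstance(small, str) else small
    big_spec = MODELS[big] if isinstance(big, str) else big
    rows = analysis_rows(table, big_spec)
    fit_small = fit_model(table, small_spec, rows=rows)
    fit_big = fit_model(table, big_spec, rows=rows)
    f, p, dfn, dfd = compare_nested_models(fit_small, fit_big)
    return {"small": fit_small, "big": fit_big,
            "F": f, "p": p, "df_num": dfn, "df_den": dfd, "n": fit_big.nobs}


def ranksum_test(values_flagged, values_unflagged) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney) test; exact when samples are
    small without ties, normal approximation otherwise."""
    x = np.asarray(values_flagged, dtype=float)
    y = np.asarray(values_unflagged, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank-sum test requires two non-empty samples")
    res = st.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def ranksum_inter(table: pd.DataFrame, value_col: str = "NRCSD"
                  ) -> tuple[float, float]:
    """Rank-sum test of flagged vs unflagged inter-chromosomal pairs."""
    inter = table["chrom_i"] != table["chrom_j"]
    vals = table.loc[inter, value_col].to_numpy(dtype=float)
    flags = table.loc[inter, "BP"].to_numpy(dtype=bool)
    ok = np.isfinite(vals)
    return ranksum_test(vals[ok & flags], vals[ok & ~flags])


@dataclass(frozen=True)
class StratumScheme:
    """Partition of locus pairs into matching classes for the resampling
    null: equal-width log-distance classes (plus one inter-chromosomal
    class), optional gene-density classes with fixed thresholds, and
    optional DNaseI pair classes from a per-locus median split."""

    n_distance_classes: int = 9
    use_gene_density: bool = False
    gene_thresholds: tuple[float, ...] = (0.0, 0.1, 0.25, 1.0)
    use_dnase: bool = False


def assign_strata(table: pd.DataFrame, scheme: StratumScheme) -> pd.Series:
    """Stratum label per pair (string; components joined with '|').

    Distance classes are equal-width in log GD between the observed min
    and max over intra pairs, left-open right-closed with the minimum
    assigned to the first class; inter-chromosomal pairs get class
    ``inter``.  Gene classes: {0}, then the threshold intervals (open
    left, closed right) on the pair gene-density product.  DNase classes
    label each locus rich/poor by the median of per-locus values implied
    by the pair products, combined unordered.
    """
    labels = []

    intra = (table["chrom_i"] == table["chrom_j"]).to_numpy()
    gd = table["GD"].to_numpy(dtype=float)
    dist = np.full(len(table), "inter", dtype=object)
    usable = intra & np.isfinite(gd) & (gd > 0)
    if usable.any():
        lg = np.log(gd[usable])
        lo, hi = lg.min(), lg.max()
        if hi > lo:
            edges = np.linspace(lo, hi, scheme.n_distance_classes + 1)
            cls = np.digitize(lg, edges[1:-1], right=True)
        else:
            cls = np.zeros(len(lg), dtype=int)
        dist[usable] = [f"d{c}" for c in cls]
    labels.append(pd.Series(dist, index=table.index))

    if scheme.use_gene_density:
        g = table["Gcov"].to_numpy(dtype=float)
        th = scheme.gene_thresholds
        gcls = np.full(len(table), "g?", dtype=object)
        gcls[g <= th[0]] = "g0"
        for k in range(1, len(th)):
            sel = (g > th[k - 1]) & (g <= th[k])
            gcls[sel] = f"g{k}"
        labels.append(pd.Series(gcls, index=table.index))

    if scheme.use_dnase:
        # per-locus DNase sums are carried via table.attrs when the table
        # was assembled; fall back to a pair-level median split
        track = table.attrs.get("dnase_per_locus")
        if track is not None:
            med = float(np.median(list(track.values())))
            rich = {k for k, v in track.items() if v > med}
            lab = []
            for a, b in zip(table["i"], table["j"]):
                r = int(int(a) in rich) + int(int(b) in rich)
                lab.append(("pp", "rp", "rr")[r])
            labels.append(pd.Series(lab, index=table.index))
        else:
            d = table["DNase"].to_numpy(dtype=float)
            med = np.nanmedian(d)
            lab = np.where(d > med, "hi", "lo")
            labels.append(pd.Series(lab, index=table.index))

    out = labels[0].astype(str)
    for extra in labels[1:]:
        out = out + "|" + extra.astype(str)
    return out


@dataclass
class ResamplingResult:
    observed: float
    null_means: np.ndarray
    p: float
    B: int
    n_flagged: int


def stratified_resampling_test(
    table: pd.DataFrame,
    strata: pd.Series,
    B: int = 500,
    seed: int | None = None,
    value_col: str = "NRCSD",
    *, per_stratum_mean: bool = False,
) -> ResamplingResult:
    """Compare the mean count of flagged pairs to stratum-matched nulls.

    Per replicate and per stratum, as many unflagged pairs are drawn
    without replacement as there are flagged pairs in that stratum; the
    mean count over the sampled union is recorded (or the mean of
    per-stratum means with ``per_stratum_mean``).  The one-sided
    empirical p-value is (1 + #{null >= observed}) / (B + 1).
    """
    rng = np.random.default_rng(seed)
    vals = table[value_col].to_numpy(dtype=float)
    flags = table["BP"].to_numpy(dtype=bool)
    ok = np.isfinite(vals)
    vals, flags = vals[ok], flags[ok]
    strat = strata.to_numpy()[ok]

    n_flagged = int(flags.sum())
    if n_flagged == 0:
        raise ValueError("no flagged pairs")
    observed = float(vals[flags].mean())

    null_sums = np.zeros(B)
    null_cnts = np.zeros(B)
    stratum_means = []
    for s in pd.unique(strat[flags]):
        m = int((flags & (strat == s)).sum())
        cand = vals[~flags & (strat == s)]
        k = len(cand)
        if k < m:
            raise ValueError(
                f"stratum {s!r}: {m} flagged pairs but only {k} unflagged "
                f"candidates")
        if m == k:
            picked_sum = np.full(B, cand.sum())
        elif B * k <= 20_000_000:
            r = rng.random((B, k))
            idx = np.argpartition(r, m, axis=1)[:, :m]
            picked_sum = cand[idx].sum(axis=1)
        else:
            picked_sum = np.array([
                cand[rng.choice(k, size=m, replace=False)].sum()
                for _ in range(B)
            ])
        null_sums += picked_sum
        null_cnts += m
        stratum_means.append(picked_sum / m)
    if per_stratum_mean:
        null_means = np.mean(stratum_means, axis=0)
        obs_parts = [vals[flags & (strat == s)].mean()
                     for s in pd.unique(strat[flags])]
        observed = float(np.mean(obs_parts))
    else:
        null_means = null_sums / null_cnts
    p = float((1 + np.sum(null_means >= observed)) / (B + 1))
    return ResamplingResult(observed, null_means, p, B, n_flagged)
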