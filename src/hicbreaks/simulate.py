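"""Ground-truthed synthetic fixtures for the whole pipeline.

Four generators:

* :func:`simulate_rearrangement_scenario` applies inversions and
  translocations to two lineages descending from a common ancestral
  block order (the outgroup keeps the ancestral order) and derives the
  true breakpoint pairs, reciprocal flags and lineage origins directly
  from the resulting signed orders and the ancestor.
* :func:`simulate_contact_counts` draws binned contact counts with a
  linear log-log distance decay plus an additive breakpoint effect:
  count = round(exp(mu + a*ln(GD) + b*BP + c*ln(GD)*BP + N(0, sigma))),
  with intra-chromosomal pairs only (GD in Mb, natural logs) and
  inter-chromosomal pairs drawn from a low-mean Poisson.
* :func:`simulate_covariate_tracks` draws per-window segmental
  duplication (SD) fractions, gene densities, DNaseI signal and assembly
  gaps, with configurable enrichment at breakpoint-containing windows.
* :func:`simulate_sd_mapping_bias` emulates random placement of
  multi-mapping reads: a read end landing inside an SD is, with a given
  probability, relocated to a random window sharing that SD, conserving
  the total read count and recording which reads are SD-involved.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as hio
from .hic import LocusGrid

__all__ = [
    "ScenarioConfig",
    "ContactConfig",
    "TrackConfig",
    "Event",
    "GroundTruth",
    "simulate_rearrangement_scenario",
    "simulate_contact_counts",
    "simulate_covariate_tracks",
    "simulate_sd_mapping_bias",
    "write_fixture_bundle",
]

GENOME_A, GENOME_B, OUTGROUP = "A", "B", "O"
CHROM = "chr1"


@dataclass(frozen=True)
class ScenarioConfig:
    """Rearrangement scenario: event counts per lineage on one chromosome."""

    n_blocks: int
    block_length: int = 400_000
    gap_length: int = 100_000
    n_inversions_A: int = 0
    n_translocations_A: int = 0
    n_inversions_B: int = 0
    n_translocations_B: int = 0
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_inversions_A, self.n_translocations_A,
                  self.n_inversions_B, self.n_translocations_B)
        if any(c < 0 for c in counts):
            raise ValueError("event counts must be non-negative")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be positive")
        total = sum(counts)
        if total > 0 and self.n_blocks < 3:
            raise ValueError(
                f"{total} event(s) requested but only {self.n_blocks} blocks; "
                f"at least 3 blocks are needed for any rearrangement")
        if total > 2 * self.n_blocks:
            raise ValueError(
                f"{total} events is too many for {self.n_blocks} blocks")


@dataclass(frozen=True)
class ContactConfig:
    """Log-scale contact-count model.  Defaults follow the printed
    distance+breakpoint interaction estimates (natural-log scale)."""

    mu: float = 6.0
    a: float = -0.8
    b: float = 0.728
    c: float = -0.254
    sigma: float = 0.5
    inter_mean: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.inter_mean < 0:
            raise ValueError("inter_mean must be non-negative")


@dataclass(frozen=True)
class TrackConfig:
    """Per-window covariate distributions with breakpoint-locus enrichment."""

    sd_mean: float = 0.05
    gene_mean: float = 0.3
    dnase_mean: float = 100.0
    concentration: float = 20.0
    dnase_log_sd: float = 0.5
    sd_enrichment: float = 1.0
    gene_enrichment: float = 1.0
    dnase_enrichment: float = 1.0
    gap_windows: tuple[int, ...] = ()
    gap_fraction: float = 0.6
    seed: int = 0


@dataclass(frozen=True)
class Event:
    """One rearrangement: lineage 'A'/'B', kind 'inversion' (reverse and
    flip the segment [i..j]) or 'translocation' (excise block at index i
    and reinsert it at index j)."""

    lineage: str
    kind: str
    i: int
    j: int


SignedOrder = list[tuple[str, int]]  # [(block_id, strand)]


@dataclass
class GroundTruth:
    config: ScenarioConfig
    events: list[Event]
    orders: dict[str, SignedOrder]
    chrom_sizes: dict[str, dict[str, int]]
    block_tables: dict[str, pd.DataFrame]     # 'AB', 'AO', 'BO'
    true_pairs: list[dict]
    true_breakpoints: list[dict]              # genome-A breakpoint regions

    @property
    def n_pairs(self) -> int:
        return len(self.true_pairs)


# --- scenario simulation -------------------------------------------------

def _apply_event(order: SignedOrder, ev: Event) -> SignedOrder:
    n = len(order)
    if ev.kind == "inversion":
        i, j = ev.i, ev.j
        if not (0 <= i <= j < n):
            raise ValueError(f"inversion segment [{i},{j}] out of range")
        seg = [(b, -s) for b, s in reversed(order[i:j + 1])]
        return order[:i] + seg + order[j + 1:]
    if ev.kind == "translocation":
        i, j = ev.i, ev.j
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"translocation indices ({i},{j}) out of range")
        rest = order[:i] + order[i + 1:]
        return rest[:j] + [order[i]] + rest[j:]
    raise ValueError(f"unknown event kind {ev.kind!r}")


def _random_events(cfg: ScenarioConfig, rng: np.random.Generator) -> list[Event]:
    events = []
    for lineage, n_inv, n_tr in (
        (GENOME_A, cfg.n_inversions_A, cfg.n_translocations_A),
        (GENOME_B, cfg.n_inversions_B, cfg.n_translocations_B),
    ):
        kinds = ["inversion"] * n_inv + ["translocation"] * n_tr
        for kind in kinds:
            if kind == "inversion":
                i = int(rng.integers(0, cfg.n_blocks))
                j = int(rng.integers(i, cfg.n_blocks))
                events.append(Event(lineage, "inversion", i, j))
            else:
                i = int(rng.integers(0, cfg.n_blocks))
                j = int(rng.integers(0, cfg.n_blocks - 1))
                events.append(Event(lineage, "translocation", i, j))
    return events


def _coordinates(order: SignedOrder, block_length: int, gap_length: int
                 ) -> tuple[dict[str, tuple[int, int, int]], int]:
    """Map block id -> (start, end, strand) plus the chromosome length."""
    coords = {}
    pos = gap_length
    for block_id, strand in order:
        coords[block_id] = (pos, pos + block_length, strand)
        pos += block_length + gap_length
    return coords, pos


def _block_table(order_x, order_y, block_length, gap_length) -> pd.DataFrame:
    cx, _ = _coordinates(order_x, block_length, gap_length)
    cy, _ = _coordinates(order_y, block_length, gap_length)
    rows = []
    for block_id in sorted(cx, key=lambda b: cx[b][0]):
        sx, ex, stx = cx[block_id]
        sy, ey, sty = cy[block_id]
        rows.append({
            "block_id": block_id,
            "chrom_a": CHROM, "start_a": sx, "end_a": ex,
            "strand_a": "+" if stx == 1 else "-",
            "chrom_b": CHROM, "start_b": sy, "end_b": ey,
            "strand_b": "+" if sty == 1 else "-",
        })
    return pd.DataFrame(rows, columns=hio.BLOCK_COLUMNS)


# Ground-truth derivation works on raw signed orders with canonical
# adjacency tuples -- deliberately a different code path from the
# extremity-map traversal in the breakpoints module, so the two can be
# checked against each other.

def _canon(x, sx, y, sy):
    return min(((x, sx), (y, sy)), ((y, -sy), (x, -sx)))


def _adjacencies(order: SignedOrder) -> set:
    return {_canon(a, sa, b, sb)
            for (a, sa), (b, sb) in zip(order, order[1:])}


def _gap_ids(order: SignedOrder, other_adjs: set) -> list:
    """Broken-adjacency gap indices of ``order`` (ints) plus telomeres."""
    gaps = ["telL", "telR"]
    for k, ((a, sa), (b, sb)) in enumerate(zip(order, order[1:])):
        if _canon(a, sa, b, sb) not in other_adjs:
            gaps.append(k)
    return gaps


def _gap_coords(gap, order: SignedOrder, block_length, gap_length):
    coords, size = _coordinates(order, block_length, gap_length)
    if gap == "telL":
        return (CHROM, 0, 0)
    if gap == "telR":
        return (CHROM, size, size)
    left_id = order[gap][0]
    right_id = order[gap + 1][0]
    return (CHROM, coords[left_id][1], coords[right_id][0])


def _derive_truth(cfg: ScenarioConfig, orders: dict[str, SignedOrder]
                  ) -> tuple[list[dict], list[dict]]:
    """True breakpoint pairs and genome-A breakpoints from signed orders."""
    h, m, o = orders[GENOME_A], orders[GENOME_B], orders[OUTGROUP]
    adj_h, adj_m, adj_o = _adjacencies(h), _adjacencies(m), _adjacencies(o)
    h_gaps = set(_gap_ids(h, adj_m))
    pos_h = {b: (k, s) for k, (b, s) in enumerate(h)}
    n = len(h)

    def human_gap_at(block_id, facing_right_in_m, strand_in_m):
        p, hs = pos_h[block_id]
        right = (hs * strand_in_m > 0) == facing_right_in_m
        if right:
            return "telR" if p == n - 1 else p
        return "telL" if p == 0 else p - 1

    merged: dict[frozenset, int] = {}
    for k, ((x, sx), (y, sy)) in enumerate(zip(m, m[1:])):
        if _canon(x, sx, y, sy) in adj_h:
            continue  # not a breakpoint on B
        g1 = human_gap_at(x, True, sx)
        g2 = human_gap_at(y, False, sy)
        assert g1 in h_gaps and g2 in h_gaps, "linked gap is not a breakpoint"
        assert g1 != g2
        key = frozenset((g1, g2))
        merged[key] = merged.get(key, 0) + 1

    degree: dict = {}
    for key in merged:
        for g in key:
            degree[g] = degree.get(g, 0) + 1

    def gap_origin(gap):
        if gap in ("telL", "telR"):
            return "unknown"
        a, sa = h[gap]
        b, sb = h[gap + 1]
        # adjacency still ancestral -> the break happened in lineage B
        return "B" if _canon(a, sa, b, sb) in adj_o else "A"

    pairs = []
    for key, n_links in merged.items():
        g1, g2 = sorted(key, key=lambda g: _gap_coords(
            g, h, cfg.block_length, cfg.gap_length)[1])
        o1, o2 = gap_origin(g1), gap_origin(g2)
        pairs.append({
            "bp1": _gap_coords(g1, h, cfg.block_length, cfg.gap_length),
            "bp2": _gap_coords(g2, h, cfg.block_length, cfg.gap_length),
            "reciprocal": degree[g1] == 1 and degree[g2] == 1,
            "origin": o1 if (o1 == o2 and o1 != "unknown") else "unknown",
            "n_links": n_links,
        })
    pairs.sort(key=lambda p: (p["bp1"], p["bp2"]))

    bps = []
    for gap in sorted((g for g in h_gaps if isinstance(g, int))):
        chrom, start, end = _gap_coords(gap, h, cfg.block_length,
                                        cfg.gap_length)
        bps.append({"chrom": chrom, "start": start, "end": end,
                    "origin": gap_origin(gap)})
    return pairs, bps


def simulate_rearrangement_scenario(cfg: ScenarioConfig,
                                    events: list[Event] | None = None
                                    ) -> GroundTruth:
    """Apply the configured events to two lineages and derive ground truth.

    Events are applied to an ancestral identity order of oriented blocks;
    the outgroup keeps the ancestral order.  An explicit ``events`` list
    overrides random event generation (its counts need not match the
    config counts, but lineages and indices are validated).
    """
    rng = np.random.default_rng(cfg.seed)
    if events is None:
        events = _random_events(cfg, rng)
    ancestral: SignedOrder = [(f"b{k:03d}", 1) for k in range(cfg.n_blocks)]
    orders = {GENOME_A: list(ancestral), GENOME_B: list(ancestral),
              OUTGROUP: list(ancestral)}
    for ev in events:
        if ev.lineage not in (GENOME_A, GENOME_B):
            raise ValueError(f"unknown lineage {ev.lineage!r}")
        orders[ev.lineage] = _apply_event(orders[ev.lineage], ev)

    sizes = {}
    for g, order in orders.items():
        _, size = _coordinates(order, cfg.block_length, cfg.gap_length)
        sizes[g] = {CHROM: size}
    tables = {
        "AB": _block_table(orders[GENOME_A], orders[GENOME_B],
                           cfg.block_length, cfg.gap_length),
        "AO": _block_table(orders[GENOME_A], orders[OUTGROUP],
                           cfg.block_length, cfg.gap_length),
        "BO": _block_table(orders[GENOME_B], orders[OUTGROUP],
                           cfg.block_length, cfg.gap_length),
    }
    true_pairs, true_bps = _derive_truth(cfg, orders)
    return GroundTruth(cfg, list(events), orders, sizes, tables,
                       true_pairs, true_bps)


# --- contact counts ------------------------------------------------------

def simulate_contact_counts(grid: LocusGrid,
                            bp_flags: set[tuple[int, int]],
                            cfg: ContactConfig,
                            retained: np.ndarray | None = None
                            ) -> pd.DataFrame:
    """Draw sparse count triples for every unordered pair of retained loci.

    Intra-chromosomal pairs follow the log-linear decay model (GD in Mb,
    natural logs, Gaussian noise on the log scale, counts rounded);
    inter-chromosomal pairs are Poisson with a low constant mean.
    Self-pairs are not generated (the distance model is undefined at
    GD = 0).  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    win = grid.windows.set_index("index")
    if retained is None:
        retained = win.index.to_numpy()
    r = np.sort(np.asarray(retained))
    ii, jj = np.triu_indices(len(r), k=1)
    bi, bj = r[ii], r[jj]
    chrom_i = win.loc[bi, "chrom"].to_numpy()
    chrom_j = win.loc[bj, "chrom"].to_numpy()
    start_i = win.loc[bi, "start"].to_numpy(dtype=float)
    start_j = win.loc[bj, "start"].to_numpy(dtype=float)
    intra = chrom_i == chrom_j
    gd = np.abs(start_i - start_j) / 1e6
    if np.any(intra & (gd <= 0)):
        raise ValueError("intra-chromosomal pair with non-positive distance")
    flags = np.array([
        (min(a, b), max(a, b)) in bp_flags for a, b in zip(bi, bj)
    ], dtype=float)

    counts = np.zeros(len(bi), dtype=int)
    if intra.any():
        lg = np.log(gd[intra])
        mean = (cfg.mu + cfg.a * lg + cfg.b * flags[intra]
                + cfg.c * lg * flags[intra])
        noise = rng.normal(0.0, cfg.sigma, size=mean.shape) if cfg.sigma > 0 \
            else 0.0
        counts[intra] = np.maximum(
            np.rint(np.exp(mean + noise)).astype(int), 0)
    if (~intra).any():
        counts[~intra] = rng.poisson(cfg.inter_mean, size=int((~intra).sum()))
    out = pd.DataFrame({"bin_i": bi, "bin_j": bj, "count": counts})
    return out[out["count"] > 0].reset_index(drop=True)


# --- covariate tracks ----------------------------------------------------

def _beta(rng, mean, concentration, size):
    mean = np.clip(mean, 1e-3, 0.999)
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=size)


def simulate_covariate_tracks(grid: LocusGrid,
                              bp_windows: set[int],
                              cfg: TrackConfig) -> pd.DataFrame:
    """Per-window SD fraction, gene density, DNaseI signal and gap fraction.

    Windows in ``bp_windows`` draw from distributions whose means are
    multiplied by the configured enrichment factors (enrichment 1 makes
    breakpoint and background windows exchangeable).  Fractions live in
    [0, 1]; the DNase signal is a non-negative log-normal.
    """
    rng = np.random.default_rng(cfg.seed)
    n = grid.n_windows
    idx = grid.windows["index"].to_numpy()
    is_bp = np.isin(idx, list(bp_windows))

    def means(base, enrich):
        return np.where(is_bp, np.clip(base * enrich, 0.0, 0.95), base)

    sd = _beta(rng, means(cfg.sd_mean, cfg.sd_enrichment),
               cfg.concentration, n)
    gene = _beta(rng, means(cfg.gene_mean, cfg.gene_enrichment),
                 cfg.concentration, n)
    dn_mean = np.where(is_bp, cfg.dnase_mean * cfg.dnase_enrichment,
                       cfg.dnase_mean)
    dnase = rng.lognormal(np.log(dn_mean), cfg.dnase_log_sd, size=n)
    gap = np.where(np.isin(idx, list(cfg.gap_windows)),
                   cfg.gap_fraction, 0.0)
    return pd.DataFrame({
        "sd_fraction": sd, "gene_density": gene,
        "dnase": dnase, "gap_fraction": gap,
    }, index=pd.Index(idx, name="index"))


# --- SD mapping bias -----------------------------------------------------

def simulate_sd_mapping_bias(triples: pd.DataFrame,
                             sd_partner_map: dict[int, tuple[int, ...]],
                             relocation_rate: float,
                             sd_fractions: pd.Series | dict[int, float],
                             seed: int = 0) -> pd.DataFrame:
    """Relocate SD-involved read ends between SD partner windows.

    Each read end falling in window ``w`` lies inside an SD with
    probability ``sd_fractions[w]``; an SD-mapping end of a window listed
    in ``sd_partner_map`` is, with probability ``relocation_rate``,
    reassigned to a uniformly chosen partner window (where it again lies
    within the shared SD copy).  The output triples carry the biased
    counts (``count``) and the number of reads with at least one
    SD-involved end (``sdr``).  Total reads are conserved.
    """
    if not 0.0 <= relocation_rate <= 1.0:
        raise ValueError("relocation rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fsd = pd.Series(sd_fractions, dtype=float)

    end1 = np.repeat(triples["bin_i"].to_numpy(), triples["count"].to_numpy())
    end2 = np.repeat(triples["bin_j"].to_numpy(), triples["count"].to_numpy())
    n_reads = len(end1)
    if n_reads == 0:
        return pd.DataFrame(columns=["bin_i", "bin_j", "count", "sdr"])

    def process(ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        f = fsd.reindex(ends).fillna(0.0).to_numpy()
        in_sd = rng.random(n_reads) < f
        moved = ends.copy()
        if relocation_rate > 0:
            reloc = in_sd & (rng.random(n_reads) < relocation_rate)
            for w, partners in sd_partner_map.items():
                sel = reloc & (ends == w)
                k = int(sel.sum())
                if k and len(partners):
                    moved[sel] = rng.choice(np.asarray(partners), size=k)
        return moved, in_sd

    new1, sd1 = process(end1)
    new2, sd2 = process(end2)
    lo = np.minimum(new1, new2)
    hi = np.maximum(new1, new2)
    sd_any = sd1 | sd2
    width = int(max(hi.max(), lo.max())) + 1
    key = lo.astype(np.int64) * width + hi
    uniq, inverse = np.unique(key, return_inverse=True)
    nr = np.bincount(inverse, minlength=len(uniq))
    sdr = np.bincount(inverse, weights=sd_any.astype(float),
                      minlength=len(uniq)).astype(int)
    out = pd.DataFrame({
        "bin_i": (uniq // width).astype(int),
        "bin_j": (uniq % width).astype(int),
        "count": nr.astype(int),
        "sdr": sdr,
    })
    assert out["count"].sum() == n_reads
    return out


# --- fixture bundle ------------------------------------------------------

def tracks_to_beds(grid: LocusGrid, tracks: pd.DataFrame
                   ) -> dict[str, pd.DataFrame]:
    """Render per-window track values as BED/bedGraph records.

    Fractional tracks become one interval per window at the window start
    with length fraction * window width; the DNase value becomes one
    bedGraph record spanning the window (so summing densities inside the
    window recovers the value exactly).
    """
    win = grid.windows.set_index("index")
    beds: dict[str, list] = {"sd": [], "genes": [], "gaps": [], "dnase": []}
    for idx, row in tracks.iterrows():
        chrom = win.loc[idx, "chrom"]
        start = int(win.loc[idx, "start"])
        end = int(win.loc[idx, "end"])
        width = end - start
        for name, col in (("sd", "sd_fraction"), ("genes", "gene_density"),
                          ("gaps", "gap_fraction")):
            frac = float(row[col])
            if frac > 0:
                beds[name].append((chrom, start,
                                   start + int(round(frac * width))))
        beds["dnase"].append((chrom, start, end, float(row["dnase"])))
    out = {
        name: pd.DataFrame(beds[name], columns=["chrom", "start", "end"])
        for name in ("sd", "genes", "gaps")
    }
    out["dnase"] = pd.DataFrame(beds["dnase"],
                                columns=["chrom", "start", "end", "value"])
    return out


def write_fixture_bundle(out_dir: str | os.PathLike,
                         gt: GroundTruth,
                         grid: LocusGrid,
                         tracks: pd.DataFrame,
                         triples: pd.DataFrame,
                         extra_manifest: dict | None = None) -> dict[str, str]:
    """Write a self-describing fixture bundle readable by the pipeline.

    Emits block tables (genome A vs B, A vs outgroup, B vs outgroup),
    covariate BED/bedGraph tracks, the bin BED plus count triples,
    chromosome sizes for both ingroup genomes, and a JSON manifest with
    the ground truth.  Returns the path of every file written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(out_dir, name)
        return paths[name]

    hio.write_block_table(gt.block_tables["AB"], p("blocks_ab.tsv"))
    hio.write_block_table(gt.block_tables["AO"], p("blocks_ao.tsv"))
    hio.write_block_table(gt.block_tables["BO"], p("blocks_bo.tsv"))
    hio.write_chrom_sizes(gt.chrom_sizes[GENOME_A], p("genome_a.chrom.sizes"))
    hio.write_chrom_sizes(gt.chrom_sizes[GENOME_B], p("genome_b.chrom.sizes"))

    beds = tracks_to_beds(grid, tracks)
    hio.write_bed(beds["sd"], p("sd.bed"))
    hio.write_bed(beds["genes"], p("genes.bed"))
    hio.write_bed(beds["gaps"], p("gaps.bed"))
    hio.write_bedgraph(beds["dnase"], p("dnase.bedgraph"))

    hio.write_bin_bed(grid.windows, p("bins.bed"))
    hio.write_triples(triples, p("triples.tsv"))

    manifest = {
        "scenario_config": dataclasses.asdict(gt.config),
        "events": [dataclasses.asdict(e) for e in gt.events],
        "n_true_pairs": gt.n_pairs,
        "true_pairs": gt.true_pairs,
        "true_breakpoints": gt.true_breakpoints,
        "window_length": grid.window_length,
        "files": {k: os.path.basename(v) for k, v in paths.items()},
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(p("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
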