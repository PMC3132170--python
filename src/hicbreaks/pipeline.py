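"""End-to-end orchestration: fixture generation, staged analysis, validation.

``run_pipeline`` wires the stages together: breakpoint detection and
pairing (with optional outgroup origin assignment), locus-grid
construction and filtering, count correction, analysis-table assembly,
and the association tests.  Every run writes a reproducibility manifest
with the configuration hash, seeds, library versions and record counts
after each filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from . import __version__, association as assoc, io as hio
from .breakpoints import (annotate_pair_origins, block_order_from_table,
                          find_breakpoints, pair_breakpoints, pairs_to_frame)
from .hic import build_locus_grid, filter_loci, pair_count_table
from .pair_table import (assemble_pair_table, dnase_track,
                         flag_breakpoint_locus_pairs, gene_density_track)
from .simulate import (GENOME_A, ContactConfig, GroundTruth, ScenarioConfig,
                       TrackConfig, simulate_contact_counts,
                       simulate_covariate_tracks, simulate_rearrangement_scenario,
                       write_fixture_bundle)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "generate_fixture",
           "validate_inputs", "true_flagged_pairs"]


@dataclass
class PipelineConfig:
    """All inputs and knobs of one analysis run.  Paths are resolved
    relative to the config file's directory when loaded from YAML."""

    blocks_ab: str
    chrom_sizes: str
    triples: str
    bins: str | None = None
    blocks_ao: str | None = None
    blocks_bo: str | None = None
    chrom_sizes_b: str | None = None
    sd_bed: str | None = None
    gene_bed: str | None = None
    gap_bed: str | None = None
    dnase_bedgraph: str | None = None
    autosomes: list[str] | None = None
    window_length: int = 1_000_000
    max_gap_fraction: float = 0.5
    n_distance_classes: int = 9
    B: int = 500
    seed: int = 0
    bp_assignment: str = "midpoint"
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = os.path.dirname(os.path.abspath(path))
        for f in dataclasses.fields(cls):
            v = getattr(cfg, f.name)
            if f.name.endswith(("_ab", "_ao", "_bo", "_bed", "_bedgraph")) \
                    or f.name in ("chrom_sizes", "chrom_sizes_b", "triples",
                                  "bins", "out_dir"):
                if isinstance(v, str) and not os.path.isabs(v):
                    setattr(cfg, f.name, os.path.join(base, v))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_optional_bed(path: str | None) -> pd.DataFrame | None:
    return hio.read_bed(path) if path else None


def true_flagged_pairs(gt: GroundTruth, grid, retained=None
                       ) -> set[tuple[int, int]]:
    """Ground-truth flagged locus pairs from simulated breakpoint pairs
    (midpoint assignment), for use as simulation input and test oracle."""
    shims = []
    for p in gt.true_pairs:
        bp1 = SimpleNamespace(chrom=p["bp1"][0], start=p["bp1"][1],
                              end=p["bp1"][2])
        bp2 = SimpleNamespace(chrom=p["bp2"][0], start=p["bp2"][1],
                              end=p["bp2"][2])
        shims.append(SimpleNamespace(bp1=bp1, bp2=bp2))
    return flag_breakpoint_locus_pairs(shims, grid, retained)


def generate_fixture(out_dir: str,
                     scenario: ScenarioConfig | None = None,
                     contact: ContactConfig | None = None,
                     tracks_cfg: TrackConfig | None = None,
                     window_length: int = 1_000_000,
                     decoy_chrom_length: int = 6_000_000,
                     ) -> dict[str, str]:
    """Simulate a full fixture bundle ready for :func:`run_pipeline`.

    A decoy chromosome without blocks is appended to the contact grid so
    inter-chromosomal pairs exist.  Ground truth (pairs, flagged locus
    pairs) goes into the bundle manifest.
    """
    scenario = scenario or ScenarioConfig(n_blocks=18, n_inversions_A=2,
                                          n_translocations_B=1, seed=1)
    contact = contact or ContactConfig(seed=scenario.seed + 1)
    tracks_cfg = tracks_cfg or TrackConfig(seed=scenario.seed + 2)

    gt = simulate_rearrangement_scenario(scenario)
    sizes = dict(gt.chrom_sizes[GENOME_A])
    if decoy_chrom_length > 0:
        sizes["chr2"] = decoy_chrom_length
    grid = build_locus_grid(sizes, window_length)
    flags = true_flagged_pairs(gt, grid)
    bp_windows = {w for pair in flags for w in pair}
    tracks = simulate_covariate_tracks(grid, bp_windows, tracks_cfg)
    grid.windows["gap_fraction"] = tracks["gap_fraction"].to_numpy()
    grid.windows["sd_fraction"] = tracks["sd_fraction"].to_numpy()
    triples = simulate_contact_counts(grid, flags, contact)
    paths = write_fixture_bundle(
        out_dir, gt, grid, tracks, triples,
        extra_manifest={
            "contact_config": dataclasses.asdict(contact),
            "track_config": dataclasses.asdict(tracks_cfg),
            "flagged_locus_pairs": sorted([list(x) for x in flags]),
            "decoy_chrom_length": decoy_chrom_length,
        })
    cfg = PipelineConfig(
        blocks_ab=paths["blocks_ab.tsv"],
        blocks_ao=paths["blocks_ao.tsv"],
        blocks_bo=paths["blocks_bo.tsv"],
        chrom_sizes=_write_sizes(out_dir, sizes),
        chrom_sizes_b=paths["genome_b.chrom.sizes"],
        triples=paths["triples.tsv"],
        bins=paths["bins.bed"],
        sd_bed=paths["sd.bed"],
        gene_bed=paths["genes.bed"],
        gap_bed=paths["gaps.bed"],
        dnase_bedgraph=paths["dnase.bedgraph"],
        window_length=window_length,
        seed=scenario.seed,
        out_dir=os.path.join(out_dir, "results"),
    )
    cfg_path = os.path.join(out_dir, "config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    paths["config.yaml"] = cfg_path
    return paths


def _write_sizes(out_dir, sizes):
    path = os.path.join(out_dir, "grid.chrom.sizes")
    hio.write_chrom_sizes(sizes, path)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the result bundle to ``cfg.out_dir``.

    Returns a dict with the in-memory products (pairs frame, analysis
    table, stats report rows, manifest).  Any stage failure raises with
    the stage name prepended.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    counts: dict[str, int] = {}
    report_rows: list[dict] = []
    notices: list[str] = []

    def stage(name):
        log.info("stage: %s", name)
        return name

    try:
        stage_name = stage("breakpoints")
        sizes_a = hio.read_chrom_sizes(cfg.chrom_sizes)
        blocks_ab = hio.read_block_table(cfg.blocks_ab)
        sizes_b = (hio.read_chrom_sizes(cfg.chrom_sizes_b)
                   if cfg.chrom_sizes_b else None)
        order_a = block_order_from_table(blocks_ab, "a", sizes_a)
        order_b = block_order_from_table(blocks_ab, "b", sizes_b)
        pairs = pair_breakpoints(order_a, order_b)
        counts["breakpoint_pairs"] = len(pairs)

        stage_name = stage("origins")
        if cfg.blocks_ao and cfg.blocks_bo:
            t_ao = hio.read_block_table(cfg.blocks_ao)
            t_bo = hio.read_block_table(cfg.blocks_bo)
            hd = find_breakpoints(block_order_from_table(t_ao, "a", sizes_a),
                                  block_order_from_table(t_ao, "b"),
                                  include_telomeres=False)
            md = find_breakpoints(block_order_from_table(t_bo, "a", sizes_b),
                                  block_order_from_table(t_bo, "b"),
                                  include_telomeres=False)
            hd_map = _bps_to_map(hd)
            md_map = _bps_to_map(md)
            annotate_pair_origins(pairs, order_a, order_b, hd_map, md_map)
        else:
            notices.append("origin assignment skipped: outgroup block "
                           "tables not provided")

        stage_name = stage("grid")
        gap_bed = _read_optional_bed(cfg.gap_bed)
        sd_bed = _read_optional_bed(cfg.sd_bed)
        grid = build_locus_grid(sizes_a, cfg.window_length, gap_bed,
                                cfg.autosomes, sd_bed)
        counts["windows"] = grid.n_windows
        retained = filter_loci(grid, cfg.max_gap_fraction)
        counts["windows_retained"] = len(retained)

        stage_name = stage("binning")
        triples = hio.read_triples(cfg.triples)
        if cfg.bins:
            bins = hio.read_bin_bed(cfg.bins)
            if len(bins) != grid.n_windows:
                raise ValueError(
                    f"bin BED has {len(bins)} windows, grid has "
                    f"{grid.n_windows}")
        counts["triples"] = len(triples)
        pair_counts = pair_count_table(triples, grid, retained)
        counts["pair_records"] = len(pair_counts)

        stage_name = stage("covariates")
        gene_bed = _read_optional_bed(cfg.gene_bed)
        tracks = pd.DataFrame(index=pd.Index(retained, name="index"))
        tracks["gene_density"] = (
            gene_density_track(grid, gene_bed).loc[retained]
            if gene_bed is not None else 0.0)
        dnase_per_locus = None
        if cfg.dnase_bedgraph:
            bg = hio.read_bedgraph(cfg.dnase_bedgraph)
            dn = dnase_track(grid, bg).loc[retained]
            tracks["dnase"] = dn
            dnase_per_locus = {int(k): float(v) for k, v in dn.items()}
        else:
            notices.append("DNase analyses skipped: no bedGraph provided")

        stage_name = stage("table")
        flags = flag_breakpoint_locus_pairs(pairs, grid, retained,
                                            mode=cfg.bp_assignment)
        counts["flagged_locus_pairs"] = len(flags)
        table = assemble_pair_table(pair_counts, tracks, flags)
        if dnase_per_locus is not None:
            table.attrs["dnase_per_locus"] = dnase_per_locus

        stage_name = stage("association")
        report_rows += _association_report(table, cfg, notices,
                                           has_dnase=dnase_per_locus is not None,
                                           has_genes=gene_bed is not None)

        stage_name = stage("write")
        pairs_frame = pairs_to_frame(pairs)
        pairs_frame["used"] = _used_flags(pairs, grid, retained,
                                          cfg.bp_assignment)
        pairs_frame.to_csv(os.path.join(cfg.out_dir, "breakpoint_pairs.tsv"),
                           sep="\t", index=False)
        table.to_csv(os.path.join(cfg.out_dir, "pair_table.tsv"),
                     sep="\t", index=False, float_format="%.6g")
        track_out = grid.windows.merge(
            tracks.reset_index(), on="index", how="left")
        track_out.to_csv(os.path.join(cfg.out_dir, "locus_tracks.tsv"),
                         sep="\t", index=False, float_format="%.6g")
        report = pd.DataFrame(report_rows)
        report.to_csv(os.path.join(cfg.out_dir, "report.tsv"),
                      sep="\t", index=False, float_format="%.6g")
        _write_summary(os.path.join(cfg.out_dir, "report.txt"),
                       report_rows, counts, notices)
        manifest = {
            "config": cfg.to_dict(),
            "config_digest": cfg.digest(),
            "package_version": __version__,
            "versions": _versions(),
            "counts": counts,
            "notices": notices,
        }
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {exc}") \
            from exc

    return {"pairs": pairs_frame, "table": table, "report": report_rows,
            "counts": counts, "manifest": manifest}


def _bps_to_map(bps):
    out: dict[str, list[tuple[int, int]]] = {}
    for bp in bps:
        out.setdefault(bp.chrom, []).append((bp.start, bp.end))
    return out


def _used_flags(pairs, grid, retained, mode):
    used = []
    retained_set = {int(r) for r in retained}
    for p in pairs:
        f = flag_breakpoint_locus_pairs([p], grid, retained, mode=mode)
        used.append("yes" if f and all(
            w in retained_set for pr in f for w in pr) else "no")
    return used


def _association_report(table, cfg, notices, *, has_dnase, has_genes):
    rows = []
    comparisons = [("M0", "M1"), ("M1", "M2")]
    if has_genes:
        comparisons += [("M3", "M4"), ("M4", "M5")]
    if has_dnase:
        comparisons += [("M6", "M7"), ("M7", "M8")]
    for small, big in comparisons:
        try:
            res = assoc.ancova(table, small, big)
        except ValueError as exc:
            notices.append(f"ANCOVA {big} vs {small} skipped: {exc}")
            continue
        row = {"analysis": f"{big}_vs_{small}", "kind": "ancova",
               "stat": res["F"], "p": res["p"], "n": res["n"],
               "df_num": res["df_num"], "df_den": res["df_den"]}
        for name, val in res["big"].params.items():
            row[f"coef_{name}"] = val
        rows.append(row)

    try:
        stat, p = assoc.ranksum_inter(table)
        n_inter = int((table["chrom_i"] != table["chrom_j"]).sum())
        rows.append({"analysis": "inter_ranksum", "kind": "ranksum",
                     "stat": stat, "p": p, "n": n_inter})
    except ValueError as exc:
        notices.append(f"inter-chromosomal rank-sum skipped: {exc}")

    schemes = [("resampling_distance", assoc.StratumScheme(
        n_distance_classes=cfg.n_distance_classes))]
    if has_genes:
        schemes.append(("resampling_distance_gene", assoc.StratumScheme(
            n_distance_classes=cfg.n_distance_classes,
            use_gene_density=True)))
    if has_dnase:
        schemes.append(("resampling_distance_dnase", assoc.StratumScheme(
            n_distance_classes=cfg.n_distance_classes, use_dnase=True)))
    for name, scheme in schemes:
        try:
            strata = assoc.assign_strata(table, scheme)
            res = assoc.stratified_resampling_test(
                table, strata, B=cfg.B, seed=cfg.seed)
        except ValueError as exc:
            notices.append(f"{name} skipped: {exc}")
            continue
        rows.append({"analysis": name, "kind": "resampling",
                     "stat": res.observed, "p": res.p, "n": res.n_flagged,
                     "B": res.B,
                     "null_mean": float(np.mean(res.null_means)),
                     "null_sd": float(np.std(res.null_means))})
    return rows


def _write_summary(path, rows, counts, notices):
    with open(path, "w") as fh:
        fh.write("Breakpoint-pair contact association: run summary\n")
        fh.write("=" * 48 + "\n\nRecord counts\n")
        for k, v in counts.items():
            fh.write(f"  {k}: {v}\n")
        fh.write("\nAnalyses\n")
        for r in rows:
            fh.write(f"  {r['analysis']}: stat={r['stat']:.4g} "
                     f"p={r['p']:.3g} (n={r.get('n', '?')})\n")
        if notices:
            fh.write("\nNotices\n")
            for n in notices:
                fh.write(f"  - {n}\n")


def _versions():
    import scipy
    import statsmodels
    return {"numpy": np.__version__, "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__}


def validate_inputs(cfg: PipelineConfig) -> list[str]:
    """Well-formedness diagnostics for every configured input file.

    Returns a list of human-readable problems (empty when all inputs
    check out); never raises for content problems.
    """
    diags: list[str] = []

    def check(path, what, reader):
        if path is None:
            return None
        if not os.path.exists(path):
            diags.append(f"{what}: file not found: {path}")
            return None
        try:
            return reader(path)
        except Exception as exc:
            diags.append(f"{what}: {exc}")
            return None

    sizes = check(cfg.chrom_sizes, "chrom sizes", hio.read_chrom_sizes)
    if sizes is not None and any(v <= 0 for v in sizes.values()):
        diags.append("chrom sizes: non-positive chromosome length")

    for name in ("blocks_ab", "blocks_ao", "blocks_bo"):
        table = check(getattr(cfg, name), name, hio.read_block_table)
        if table is not None:
            dups = table["block_id"][table["block_id"].duplicated()]
            for d in dups:
                diags.append(f"{name}: duplicated block id {d!r}")
            if (table["end_a"] <= table["start_a"]).any() or \
                    (table["end_b"] <= table["start_b"]).any():
                diags.append(f"{name}: block with non-positive length")

    for name in ("sd_bed", "gene_bed", "gap_bed"):
        bed = check(getattr(cfg, name), name, hio.read_bed)
        if bed is not None and (bed["end"] < bed["start"]).any():
            diags.append(f"{name}: interval with end < start")

    check(cfg.dnase_bedgraph, "dnase_bedgraph", hio.read_bedgraph)

    bins = check(cfg.bins, "bins", hio.read_bin_bed)
    triples = check(cfg.triples, "triples", hio.read_triples)
    if bins is not None:
        idx = bins["index"].to_numpy()
        if not np.array_equal(np.sort(idx), np.arange(len(idx))):
            diags.append("bins: indices are not contiguous from 0")
        if triples is not None:
            n = len(bins)
            bad = triples.index[(triples["bin_i"] >= n)
                                | (triples["bin_j"] >= n)]
            for line in bad[:5]:
                diags.append(
                    f"triples: data row {int(line) + 1} references a bin "
                    f"index beyond the bin BED ({n} bins)")
    return diags
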