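import json

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from hicbreaks import io as hio
from hicbreaks.hic import build_locus_grid, filter_loci
from hicbreaks.simulate import (ContactConfig, Event, ScenarioConfig,
                                TrackConfig, simulate_contact_counts,
                                simulate_covariate_tracks,
                                simulate_rearrangement_scenario,
                                simulate_sd_mapping_bias,
                                write_fixture_bundle)


class TestScenario:
    def test_zero_events_identity(self):
        gt = simulate_rearrangement_scenario(ScenarioConfig(n_blocks=5))
        assert gt.orders["A"] == gt.orders["B"] == gt.orders["O"]
        assert gt.true_pairs == []
        assert gt.true_breakpoints == []

    def test_single_inversion_reciprocal_pair_with_origin(self, fig7_truth):
        assert len(fig7_truth.true_pairs) == 1
        (p,) = fig7_truth.true_pairs
        assert p["reciprocal"] is True
        assert p["origin"] == "A"
        assert p["n_links"] == 2
        assert len(fig7_truth.true_breakpoints) == 2

    def test_reuse_scenario_nonreciprocal(self, fig8_truth):
        shared = {}
        for p in fig8_truth.true_pairs:
            for bp in (tuple(p["bp1"]), tuple(p["bp2"])):
                shared[bp] = shared.get(bp, 0) + 1
        assert max(shared.values()) >= 2
        reused = [p for p in fig8_truth.true_pairs
                  if shared[tuple(p["bp1"])] > 1 or shared[tuple(p["bp2"])] > 1]
        assert len(reused) >= 2
        assert all(p["reciprocal"] is False for p in reused)

    def test_event_counts_validated(self):
        with pytest.raises(ValueError, match="at least 3 blocks"):
            ScenarioConfig(n_blocks=2, n_inversions_A=1)
        with pytest.raises(ValueError, match="too many"):
            ScenarioConfig(n_blocks=3, n_inversions_A=7)
        with pytest.raises(ValueError):
            ScenarioConfig(n_blocks=0)

    def test_explicit_event_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            simulate_rearrangement_scenario(
                ScenarioConfig(n_blocks=3),
                events=[Event("A", "inversion", 1, 5)])

    def test_deterministic_given_seed(self):
        cfg = ScenarioConfig(n_blocks=8, n_inversions_A=2,
                             n_translocations_B=1, seed=42)
        g1 = simulate_rearrangement_scenario(cfg)
        g2 = simulate_rearrangement_scenario(cfg)
        assert g1.orders == g2.orders
        assert g1.true_pairs == g2.true_pairs


class TestContactCounts:
    def _grid(self, n, chroms=1):
        sizes = {f"chr{k+1}": n * 1_000_000 for k in range(chroms)}
        return build_locus_grid(sizes, 1_000_000)

    def test_noiseless_mean_at_unit_distance(self):
        grid = self._grid(2)
        cfg = ContactConfig(mu=6.0, a=-0.8, b=0.0, c=0.0, sigma=0.0)
        tri = simulate_contact_counts(grid, set(), cfg)
        assert len(tri) == 1
        assert tri["count"].iloc[0] == 403  # round(exp(6.0))

    def test_distance_halving_follows_slope(self):
        grid = self._grid(3)
        cfg = ContactConfig(mu=6.0, a=-0.8, b=0.0, c=0.0, sigma=0.0)
        tri = simulate_contact_counts(grid, set(), cfg).set_index(
            ["bin_i", "bin_j"])
        assert tri.loc[(0, 1), "count"] == 403
        assert tri.loc[(0, 2), "count"] == 232  # round(exp(6 - 0.8 ln 2))

    def test_breakpoint_effect_applied(self):
        grid = self._grid(2)
        cfg = ContactConfig(mu=6.0, a=-0.8, b=0.7, c=0.0, sigma=0.0)
        tri = simulate_contact_counts(grid, {(0, 1)}, cfg)
        assert tri["count"].iloc[0] == round(np.exp(6.7))

    def test_seed_determinism(self):
        grid = self._grid(10)
        cfg = ContactConfig(seed=7)
        t1 = simulate_contact_counts(grid, {(0, 5)}, cfg)
        t2 = simulate_contact_counts(grid, {(0, 5)}, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_inter_chromosomal_low_mean(self):
        grid = self._grid(12, chroms=2)
        cfg = ContactConfig(sigma=0.0, inter_mean=5.0, seed=0)
        tri = simulate_contact_counts(grid, set(), cfg)
        win = grid.windows.set_index("index")
        inter = tri[win.loc[tri["bin_i"], "chrom"].to_numpy()
                    != win.loc[tri["bin_j"], "chrom"].to_numpy()]
        assert len(inter) > 0
        assert abs(inter["count"].mean() - 5.0) < 1.0

    def test_slope_recovered_noiseless(self):
        # 142 windows -> 10011 intra pairs; regression of log count on
        # log distance for unflagged pairs recovers the slope to < 0.01
        grid = self._grid(142)
        cfg = ContactConfig(mu=6.0, a=-0.8, b=0.0, c=0.0, sigma=0.0)
        tri = simulate_contact_counts(grid, set(), cfg)
        gd = (tri["bin_j"] - tri["bin_i"]).to_numpy(dtype=float)
        slope = np.polyfit(np.log(gd), np.log(tri["count"]), 1)[0]
        assert abs(slope - (-0.8)) < 0.01

    def test_sigma_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            ContactConfig(sigma=-0.1)


class TestCovariateTracks:
    def _grid(self, n=500):
        return build_locus_grid({"chr1": n * 1_000_000}, 1_000_000)

    def test_values_in_valid_ranges(self):
        grid = self._grid(200)
        tracks = simulate_covariate_tracks(grid, {3, 4}, TrackConfig(seed=0))
        assert ((tracks["sd_fraction"] >= 0) & (tracks["sd_fraction"] <= 1)).all()
        assert ((tracks["gene_density"] >= 0) & (tracks["gene_density"] <= 1)).all()
        assert (tracks["dnase"] >= 0).all()

    def test_null_enrichment_indistinguishable(self):
        grid = self._grid(500)
        bp = set(range(0, 500, 2))
        tracks = simulate_covariate_tracks(grid, bp, TrackConfig(seed=3))
        is_bp = tracks.index.isin(bp)
        _, p = st.mannwhitneyu(tracks.loc[is_bp, "sd_fraction"],
                               tracks.loc[~is_bp, "sd_fraction"])
        assert p > 0.05

    def test_sd_enrichment_raises_mean(self):
        grid = self._grid(1000)
        bp = set(range(0, 1000, 2))
        cfg = TrackConfig(sd_enrichment=3.0, seed=5)
        tracks = simulate_covariate_tracks(grid, bp, cfg)
        is_bp = tracks.index.isin(bp)
        assert tracks.loc[is_bp, "sd_fraction"].mean() > \
            tracks.loc[~is_bp, "sd_fraction"].mean()

    def test_gap_window_removed_by_filtering(self):
        grid = self._grid(10)
        cfg = TrackConfig(gap_windows=(4,), gap_fraction=0.6, seed=0)
        tracks = simulate_covariate_tracks(grid, set(), cfg)
        grid.windows["gap_fraction"] = tracks["gap_fraction"].to_numpy()
        retained = filter_loci(grid)
        assert 4 not in retained
        assert len(retained) == 9

    def test_seed_determinism(self):
        grid = self._grid(50)
        t1 = simulate_covariate_tracks(grid, {1}, TrackConfig(seed=9))
        t2 = simulate_covariate_tracks(grid, {1}, TrackConfig(seed=9))
        pd.testing.assert_frame_equal(t1, t2)


class TestSdMappingBias:
    def _triples(self):
        return pd.DataFrame({
            "bin_i": [0, 0, 1, 2],
            "bin_j": [1, 2, 2, 5],
            "count": [100, 50, 80, 10],
        })

    def test_rate_zero_identity(self):
        tri = self._triples()
        out = simulate_sd_mapping_bias(tri, {0: (5,), 5: (0,)}, 0.0,
                                       {0: 0.5, 5: 0.5}, seed=0)
        merged = out.groupby(["bin_i", "bin_j"])["count"].sum()
        for _, row in tri.iterrows():
            assert merged[(row["bin_i"], row["bin_j"])] == row["count"]

    def test_total_count_conserved(self):
        tri = self._triples()
        out = simulate_sd_mapping_bias(tri, {0: (5,), 5: (0,)}, 0.7,
                                       {0: 0.5, 5: 0.4}, seed=1)
        assert out["count"].sum() == tri["count"].sum()

    def test_rate_validated(self):
        with pytest.raises(ValueError, match="rate"):
            simulate_sd_mapping_bias(self._triples(), {}, 1.5, {}, seed=0)

    def test_long_range_partner_count_inflated(self):
        # windows 0 and 9 share an SD; short-range reads incident to 0
        # leak toward 9, inflating long-range pairs (x, 9); 200 replicates
        grid = build_locus_grid({"chr1": 10_000_000}, 1_000_000)
        cfg = ContactConfig(mu=6.0, a=-0.8, b=0, c=0, sigma=0.0)
        tri = simulate_contact_counts(grid, set(), cfg)
        fsd = {0: 0.4, 9: 0.4}
        pmap = {0: (9,), 9: (0,)}
        gains = []
        for rep in range(200):
            out = simulate_sd_mapping_bias(tri, pmap, 0.5, fsd, seed=rep)
            biased = out.set_index(["bin_i", "bin_j"])["count"]
            truth = tri.set_index(["bin_i", "bin_j"])["count"]
            key = (1, 9)
            gains.append(biased.get(key, 0) - truth.get(key, 0))
        assert np.mean(gains) > 0

    def test_sdr_bounded_by_count(self):
        tri = self._triples()
        out = simulate_sd_mapping_bias(tri, {0: (5,)}, 0.3,
                                       {0: 0.8, 2: 0.2}, seed=2)
        assert (out["sdr"] <= out["count"]).all()
        assert (out["sdr"] >= 0).all()


class TestFixtureBundle:
    def _bundle(self, tmp_path, scenario=None):
        scenario = scenario or ScenarioConfig(n_blocks=10, n_inversions_A=1,
                                              seed=3)
        gt = simulate_rearrangement_scenario(scenario)
        grid = build_locus_grid(gt.chrom_sizes["A"], 1_000_000)
        tracks = simulate_covariate_tracks(grid, {1}, TrackConfig(seed=4))
        triples = simulate_contact_counts(grid, set(), ContactConfig(seed=5))
        paths = write_fixture_bundle(tmp_path / "fx", gt, grid, tracks,
                                     triples)
        return gt, grid, tracks, triples, paths

    def test_round_trip_block_tables_and_triples(self, tmp_path):
        gt, grid, tracks, triples, paths = self._bundle(tmp_path)
        back = hio.read_block_table(paths["blocks_ab.tsv"])
        pd.testing.assert_frame_equal(back, gt.block_tables["AB"])
        tri_back = hio.read_triples(paths["triples.tsv"])
        pd.testing.assert_frame_equal(tri_back, triples)
        sizes = hio.read_chrom_sizes(paths["genome_a.chrom.sizes"])
        assert sizes == gt.chrom_sizes["A"]

    def test_manifest_pair_count_matches_truth(self, tmp_path):
        gt, *_, paths = self._bundle(tmp_path)
        with open(paths["manifest.json"]) as fh:
            manifest = json.load(fh)
        assert manifest["n_true_pairs"] == len(gt.true_pairs)
        assert len(manifest["true_pairs"]) == len(gt.true_pairs)

    def test_empty_scenario_valid_bundle(self, tmp_path):
        gt, *_, paths = self._bundle(
            tmp_path, ScenarioConfig(n_blocks=4, seed=0))
        with open(paths["manifest.json"]) as fh:
            manifest = json.load(fh)
        assert manifest["n_true_pairs"] == 0
        assert hio.read_block_table(paths["blocks_ab.tsv"]).shape[0] == 4

    def test_track_beds_round_trip_fractions(self, tmp_path):
        gt, grid, tracks, _, paths = self._bundle(tmp_path)
        sd = hio.read_bed(paths["sd.bed"])
        regrid = build_locus_grid(gt.chrom_sizes["A"], 1_000_000,
                                  sd_bed=sd)
        got = regrid.windows["sd_fraction"].to_numpy()
        want = tracks["sd_fraction"].to_numpy()
        # one interval per window, rounded to whole bases
        assert np.allclose(got, want, atol=1e-5)
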