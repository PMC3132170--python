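import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hicbreaks.hic import build_locus_grid, pair_count_table
from hicbreaks.pair_table import assemble_pair_table
from hicbreaks.simulate import (ContactConfig, Event, ScenarioConfig,
                                simulate_contact_counts,
                                simulate_rearrangement_scenario)

from helpers import constant_tracks


@pytest.fixture
def fig7_truth():
    """Single interior-block inversion in lineage A on three blocks."""
    cfg = ScenarioConfig(n_blocks=3, seed=0)
    return simulate_rearrangement_scenario(
        cfg, events=[Event("A", "inversion", 1, 1)])


@pytest.fixture
def fig8_truth():
    """Inversion then translocation re-using a breakpoint in lineage A."""
    cfg = ScenarioConfig(n_blocks=5, seed=0)
    events = [Event("A", "inversion", 1, 1),
              Event("A", "translocation", 2, 4)]
    return simulate_rearrangement_scenario(cfg, events=events)


@pytest.fixture
def small_grid():
    return build_locus_grid({"chr1": 10_000_000, "chr2": 5_000_000},
                            1_000_000)


def make_assoc_table(n_windows=60, n_flagged=40, contact=None, seed=0,
                     n_chroms=1):
    """Analysis table over an n_windows-per-chromosome grid with randomly
    flagged pairs and simulated counts (constant covariates)."""
    contact = contact or ContactConfig(seed=seed)
    sizes = {f"chr{k + 1}": n_windows * 1_000_000 for k in range(n_chroms)}
    grid = build_locus_grid(sizes, 1_000_000)
    rng = np.random.default_rng(seed)
    win = grid.windows
    intra_pairs = [
        (int(a), int(b))
        for chrom, sub in win.groupby("chrom")
        for a, b in zip(*np.triu_indices(len(sub), k=1))
        for a, b in [(sub["index"].iloc[a], sub["index"].iloc[b])]
    ]
    chosen = rng.choice(len(intra_pairs), size=n_flagged, replace=False)
    flags = {intra_pairs[k] for k in chosen}
    triples = simulate_contact_counts(grid, flags, contact)
    counts = pair_count_table(triples, grid)
    table = assemble_pair_table(
        counts, constant_tracks(win["index"].to_numpy()), flags)
    return table, flags, grid


@pytest.fixture
def assoc_table():
    return make_assoc_table()[0]
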