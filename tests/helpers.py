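"""Shared test helpers and independent oracles.

The oracles here deliberately re-derive expectations by the most naive
route available (2-gram scans of signed words, itertools enumeration,
direct arithmetic) so they stay independent of the package internals
they are used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from hicbreaks.breakpoints import BlockOrder, OrientedBlock

BLOCK_LEN = 400_000
GAP_LEN = 100_000


def make_order(signed: list[tuple[str, int]], genome_len: int | None = None,
               chrom: str = "chr1", block_len: int = BLOCK_LEN,
               gap_len: int = GAP_LEN) -> BlockOrder:
    """Lay out a signed block sequence on one chromosome with uniform
    block and gap lengths."""
    blocks = []
    pos = gap_len
    for bid, strand in signed:
        blocks.append(OrientedBlock(bid, chrom, pos, pos + block_len, strand))
        pos += block_len + gap_len
    size = genome_len if genome_len is not None else pos
    return BlockOrder(blocks, {chrom: size})


def signed_word(order: list[tuple[str, int]]) -> list[tuple[str, int]]:
    return list(order)


def broken_adjacencies_oracle(seq_a: list[tuple[str, int]],
                              seq_b: list[tuple[str, int]]) -> list[int]:
    """Indices k such that the adjacency between seq_a[k] and seq_a[k+1]
    is broken on B: the signed 2-gram (and its reverse complement) is
    scanned for directly in B's signed word."""
    bigrams_b = set()
    for (x, sx), (y, sy) in zip(seq_b, seq_b[1:]):
        bigrams_b.add(((x, sx), (y, sy)))
        bigrams_b.add(((y, -sy), (x, -sx)))
    broken = []
    for k, ((x, sx), (y, sy)) in enumerate(zip(seq_a, seq_a[1:])):
        if ((x, sx), (y, sy)) not in bigrams_b:
            broken.append(k)
    return broken


def enumerate_pairs_oracle(n: int) -> int:
    """Unordered pairs including self-pairs, by brute enumeration."""
    return sum(1 for _ in itertools.combinations_with_replacement(range(n), 2))


def exact_ranksum_p(x: list[float], y: list[float]) -> float:
    """Two-sided rank-sum p-value by exhaustive enumeration of all
    assignments of the pooled values to the two groups (no ties)."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: r for r, v in enumerate(pooled, start=1)}
    obs = sum(ranks[v] for v in x)
    n = len(x)
    stats = [sum(combo) for combo in
             itertools.combinations(range(1, len(pooled) + 1), n)]
    mean = np.mean(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean))
    return extreme / len(stats)


def pair_coord_set(pairs) -> set:
    """Canonical, comparable representation of BreakpointPair objects."""
    out = set()
    for p in pairs:
        c1 = (p.bp1.chrom, p.bp1.start, p.bp1.end)
        c2 = (p.bp2.chrom, p.bp2.start, p.bp2.end)
        out.add((min(c1, c2), max(c1, c2)))
    return out


def truth_coord_set(true_pairs) -> set:
    out = set()
    for p in true_pairs:
        c1, c2 = tuple(p["bp1"]), tuple(p["bp2"])
        out.add((min(c1, c2), max(c1, c2)))
    return out


def constant_tracks(indices, gene_density=0.5, dnase=10.0) -> pd.DataFrame:
    return pd.DataFrame({"gene_density": gene_density, "dnase": dnase},
                        index=pd.Index(np.asarray(indices), name="index"))
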