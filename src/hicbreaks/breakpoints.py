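"""Breakpoint detection, pairing, reciprocal classification and origin calls.

A rearrangement breakpoint on genome A is the region between two blocks
that are consecutive on A but whose orthologs on genome B are not
consecutive, or not in the same relative orientation.  Chromosome
extremities (telomeres) may optionally be treated as breakpoints; they
are emitted as zero-length sentinels at position 0 and at the chromosome
length.

Each non-telomere breakpoint on genome B is flanked by two block
extremities; following those extremities back to genome A locates two
genome-A breakpoints (or telomeres), which are therefore distant on A
but adjacent on B.  Such linked A-breakpoints form a *breakpoint pair*.
A pair is *reciprocal* when neither of its members belongs to any other
pair, the signature of a single simple rearrangement; pairs sharing a
member are *non-reciprocal* and indicate breakpoint re-use or complex
event series.

Lineage of origin is assigned with an outgroup: a genome-A breakpoint is
of A-lineage origin iff it overlaps an A-vs-outgroup breakpoint while
neither of its two genome-B partner breakpoints overlaps a
B-vs-outgroup breakpoint, and symmetrically for B-lineage origin.
Overlap means intersection of at least one base pair; zero-length
telomere sentinels never overlap anything and never receive an origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import overlaps_any

__all__ = [
    "OrientedBlock",
    "BlockOrder",
    "Breakpoint",
    "BreakpointPair",
    "block_order_from_table",
    "find_breakpoints",
    "pair_breakpoints",
    "classify_reciprocal",
    "assign_breakpoint_origin",
    "assign_pair_origin",
    "annotate_pair_origins",
    "pairs_to_frame",
]

HUMAN, MOUSE, UNKNOWN = "human", "mouse", "unknown"


@dataclass(frozen=True)
class OrientedBlock:
    """One synteny block as placed on a single genome."""

    block_id: str
    chrom: str
    start: int
    end: int
    strand: int  # +1 / -1

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"block {self.block_id}: end < start")
        if self.strand not in (1, -1):
            raise ValueError(f"block {self.block_id}: strand must be +1/-1")


class BlockOrder:
    """Ordered, oriented synteny blocks of one genome, grouped by chromosome.

    Parameters
    ----------
    blocks:
        Iterable of :class:`OrientedBlock`.  Within each chromosome the
        blocks must be sortable by start without overlaps; each block id
        must occur exactly once.
    chrom_sizes:
        Optional chromosome lengths, used to place right-telomere
        sentinels.  Defaults to the end of the last block per chromosome.
    """

    def __init__(self, blocks: Iterable[OrientedBlock],
                 chrom_sizes: Mapping[str, int] | None = None):
        by_chrom: dict[str, list[OrientedBlock]] = {}
        seen: set[str] = set()
        for b in blocks:
            if b.block_id in seen:
                raise ValueError(f"duplicated block id {b.block_id!r}")
            seen.add(b.block_id)
            by_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bl in by_chrom.items():
            bl.sort(key=lambda b: b.start)
            for left, right in zip(bl, bl[1:]):
                if right.start < left.end:
                    raise ValueError(
                        f"overlapping blocks {left.block_id!r}/{right.block_id!r} "
                        f"on {chrom}"
                    )
        self.chrom_orders = by_chrom
        self.block_ids = seen
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else {
            chrom: bl[-1].end for chrom, bl in by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.block_ids)


def block_order_from_table(table: pd.DataFrame, side: str,
                           chrom_sizes: Mapping[str, int] | None = None
                           ) -> BlockOrder:
    """Build the :class:`BlockOrder` for one side ('a' or 'b') of a block table."""
    if side not in ("a", "b"):
        raise ValueError("side must be 'a' or 'b'")
    blocks = [
        OrientedBlock(
            block_id=str(row["block_id"] if "block_id" in table.columns else i),
            chrom=row[f"chrom_{side}"],
            start=int(row[f"start_{side}"]),
            end=int(row[f"end_{side}"]),
            strand=1 if row[f"strand_{side}"] == "+" else -1,
        )
        for i, row in table.iterrows()
    ]
    return BlockOrder(blocks, chrom_sizes)


@dataclass(frozen=True)
class Breakpoint:
    """A breakpoint region on one genome.

    Non-telomere breakpoints lie between two consecutive blocks
    (``left_block`` and ``right_block``); telomere sentinels have exactly
    one flanking block and zero length.
    """

    genome: str
    chrom: str
    start: int
    end: int
    left_block: str | None
    right_block: str | None

    @property
    def is_telomere(self) -> bool:
        return self.left_block is None or self.right_block is None

    @property
    def name(self) -> str:
        return f"{self.left_block or 'TEL'}|{self.right_block or 'TEL'}"

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.name)


@dataclass
class BreakpointPair:
    """Two genome-A breakpoints that are adjacent on genome B."""

    bp1: Breakpoint
    bp2: Breakpoint
    linkers: tuple[Breakpoint, ...] = ()
    reciprocal: bool | None = None
    origin: str = UNKNOWN

    def __post_init__(self):
        if self.bp1 == self.bp2:
            raise ValueError("a breakpoint pair needs two distinct breakpoints")
        if self.bp2.sort_key() < self.bp1.sort_key():
            self.bp1, self.bp2 = self.bp2, self.bp1

    @property
    def key(self) -> frozenset:
        return frozenset((self.bp1, self.bp2))

    @property
    def multiplicity(self) -> int:
        return len(self.linkers)


# --- adjacency machinery -------------------------------------------------
#
# Each block has two abstract extremities, head 'h' and tail 't', fixed in
# the block's own frame.  On a genome where the block lies with strand s,
# the head is at the physical right end iff s == +1.  An adjacency between
# consecutive blocks is the unordered pair of the extremities that face
# each other; an adjacency is conserved iff the same extremity pair is
# adjacent on both genomes.  This makes jointly reversed runs of blocks
# adjacency-conserved automatically.

def _right_ext(b: OrientedBlock) -> tuple[str, str]:
    return (b.block_id, "h" if b.strand == 1 else "t")


def _left_ext(b: OrientedBlock) -> tuple[str, str]:
    return (b.block_id, "t" if b.strand == 1 else "h")


def _adjacency_set(order: BlockOrder) -> set[frozenset]:
    adjs: set[frozenset] = set()
    for blocks in order.chrom_orders.values():
        for x, y in zip(blocks, blocks[1:]):
            adjs.add(frozenset((_right_ext(x), _left_ext(y))))
    return adjs


def _check_same_blocks(order_a: BlockOrder, order_b: BlockOrder) -> None:
    only_a = order_a.block_ids - order_b.block_ids
    only_b = order_b.block_ids - order_a.block_ids
    if only_a or only_b:
        missing = sorted(only_a | only_b)
        raise ValueError(f"block ids not shared by both genomes: {missing}")


def _breakpoints_and_extremity_map(
    order_a: BlockOrder, order_b: BlockOrder, genome: str,
    include_telomeres: bool,
) -> tuple[list[Breakpoint], dict[tuple[str, str], Breakpoint]]:
    """Breakpoints of genome A (vs B) plus a map extremity -> facing breakpoint."""
    adj_b = _adjacency_set(order_b)
    bps: list[Breakpoint] = []
    ext_map: dict[tuple[str, str], Breakpoint] = {}
    for chrom, blocks in order_a.chrom_orders.items():
        if include_telomeres:
            tel_l = Breakpoint(genome, chrom, 0, 0, None, blocks[0].block_id)
            bps.append(tel_l)
            ext_map[_left_ext(blocks[0])] = tel_l
            size = order_a.chrom_sizes.get(chrom, blocks[-1].end)
            tel_r = Breakpoint(genome, chrom, size, size, blocks[-1].block_id, None)
            bps.append(tel_r)
            ext_map[_right_ext(blocks[-1])] = tel_r
        for x, y in zip(blocks, blocks[1:]):
            if frozenset((_right_ext(x), _left_ext(y))) in adj_b:
                continue  # conserved adjacency
            bp = Breakpoint(genome, chrom, x.end, y.start,
                            x.block_id, y.block_id)
            bps.append(bp)
            ext_map[_right_ext(x)] = bp
            ext_map[_left_ext(y)] = bp
    bps.sort(key=Breakpoint.sort_key)
    return bps, ext_map


def find_breakpoints(order_a: BlockOrder, order_b: BlockOrder, *,
                     genome: str = "A",
                     include_telomeres: bool = True) -> list[Breakpoint]:
    """Breakpoints on genome A relative to genome B.

    One breakpoint is emitted per broken adjacency; relative orientation
    is handled through block extremities, so a jointly reversed run of
    blocks does not create breakpoints.  With ``include_telomeres``,
    chromosome extremities are emitted as zero-length telomere sentinels.
    """
    _check_same_blocks(order_a, order_b)
    bps, _ = _breakpoints_and_extremity_map(order_a, order_b, genome,
                                            include_telomeres)
    return bps


def pair_breakpoints(order_a: BlockOrder, order_b: BlockOrder, *,
                     genome_a: str = "A", genome_b: str = "B",
                     include_telomeres: bool = True) -> list[BreakpointPair]:
    """Group genome-A breakpoints into pairs via genome-B adjacency.

    Every non-telomere genome-B breakpoint links the two genome-A
    breakpoints found at the orthologous extremities of its flanking
    blocks.  Candidate pairs with the same unordered member set are
    merged; all linking B-breakpoints are retained as metadata.
    Pairs are returned with members ordered by (chrom, start) and with
    the reciprocal flag already set (see :func:`classify_reciprocal`).
    """
    _check_same_blocks(order_a, order_b)
    _, ext_map_a = _breakpoints_and_extremity_map(
        order_a, order_b, genome_a, include_telomeres=True)
    bps_b, _ = _breakpoints_and_extremity_map(
        order_b, order_a, genome_b, include_telomeres=True)

    merged: dict[frozenset, BreakpointPair] = {}
    for bp_b in bps_b:
        if bp_b.is_telomere:
            continue  # a telomere has one flank: it cannot link two regions
        left = _find_block(order_b, bp_b.left_block)
        right = _find_block(order_b, bp_b.right_block)
        a1 = ext_map_a[_right_ext(left)]
        a2 = ext_map_a[_left_ext(right)]
        if not include_telomeres and (a1.is_telomere or a2.is_telomere):
            continue
        key = frozenset((a1, a2))
        if key in merged:
            merged[key].linkers = merged[key].linkers + (bp_b,)
        else:
            merged[key] = BreakpointPair(a1, a2, linkers=(bp_b,))
    pairs = sorted(merged.values(),
                   key=lambda p: (p.bp1.sort_key(), p.bp2.sort_key()))
    return classify_reciprocal(pairs)


def _find_block(order: BlockOrder, block_id: str) -> OrientedBlock:
    for blocks in order.chrom_orders.values():
        for b in blocks:
            if b.block_id == block_id:
                return b
    raise KeyError(block_id)


def classify_reciprocal(pairs: Sequence[BreakpointPair]) -> list[BreakpointPair]:
    """Flag each pair reciprocal iff neither member occurs in any other pair."""
    degree: dict[Breakpoint, int] = {}
    for p in pairs:
        degree[p.bp1] = degree.get(p.bp1, 0) + 1
        degree[p.bp2] = degree.get(p.bp2, 0) + 1
    for p in pairs:
        p.reciprocal = degree[p.bp1] == 1 and degree[p.bp2] == 1
    return list(pairs)


# --- origin assignment ---------------------------------------------------

def _partner_breakpoints(bp: Breakpoint, order_a: BlockOrder,
                         ext_map_b: Mapping[tuple[str, str], Breakpoint]
                         ) -> tuple[Breakpoint, Breakpoint] | None:
    """The two genome-B breakpoints orthologous to a genome-A breakpoint."""
    if bp.is_telomere:
        return None
    left = _find_block(order_a, bp.left_block)
    right = _find_block(order_a, bp.right_block)
    return ext_map_b[_right_ext(left)], ext_map_b[_left_ext(right)]


def assign_breakpoint_origin(
    bp_a: Breakpoint,
    partners: tuple[Breakpoint, Breakpoint] | None,
    outgroup_bps_a: Mapping[str, Sequence[tuple[int, int]]],
    outgroup_bps_b: Mapping[str, Sequence[tuple[int, int]]],
    *, label_a: str = HUMAN, label_b: str = MOUSE,
) -> str:
    """Lineage of origin of one genome-A breakpoint, via the outgroup.

    ``outgroup_bps_a`` maps genome-A chromosomes to A-vs-outgroup
    breakpoint intervals, ``outgroup_bps_b`` likewise on genome B.
    A-lineage origin requires an A-outgroup overlap and no B-outgroup
    overlap for either partner; B-lineage origin requires the exact
    opposite; anything else is unknown.
    """
    if partners is None:
        return UNKNOWN
    a_hit = overlaps_any(bp_a.start, bp_a.end,
                         outgroup_bps_a.get(bp_a.chrom, ()))
    p_hits = [
        overlaps_any(p.start, p.end, outgroup_bps_b.get(p.chrom, ()))
        for p in partners
    ]
    if a_hit and not any(p_hits):
        return label_a
    if not a_hit and all(p_hits):
        return label_b
    return UNKNOWN


def assign_pair_origin(origin1: str, origin2: str) -> str:
    """Pair origin: the common member origin if equal and known, else unknown."""
    if origin1 == origin2 and origin1 != UNKNOWN:
        return origin1
    return UNKNOWN


def annotate_pair_origins(
    pairs: Sequence[BreakpointPair],
    order_a: BlockOrder, order_b: BlockOrder,
    outgroup_bps_a: Mapping[str, Sequence[tuple[int, int]]],
    outgroup_bps_b: Mapping[str, Sequence[tuple[int, int]]],
    *, label_a: str = HUMAN, label_b: str = MOUSE,
) -> list[BreakpointPair]:
    """Assign member and pair origins in place and return the pair list."""
    _, ext_map_b = _breakpoints_and_extremity_map(
        order_b, order_a, "B", include_telomeres=True)
    cache: dict[Breakpoint, str] = {}

    def member_origin(bp: Breakpoint) -> str:
        if bp not in cache:
            cache[bp] = assign_breakpoint_origin(
                bp, _partner_breakpoints(bp, order_a, ext_map_b),
                outgroup_bps_a, outgroup_bps_b,
                label_a=label_a, label_b=label_b)
        return cache[bp]

    for p in pairs:
        p.origin = assign_pair_origin(member_origin(p.bp1),
                                      member_origin(p.bp2))
    return list(pairs)


def bed_to_interval_map(bed: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Group a BED DataFrame into per-chromosome (start, end) interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, sub in bed.groupby("chrom"):
        out[str(chrom)] = list(zip(sub["start"].astype(int),
                                   sub["end"].astype(int)))
    return out


def pairs_to_frame(pairs: Sequence[BreakpointPair]) -> pd.DataFrame:
    """Tabulate pairs: member coordinates, origin, R/NR type, multiplicity."""
    rows = []
    for p in pairs:
        rows.append({
            "chrom1": p.bp1.chrom, "start1": p.bp1.start, "end1": p.bp1.end,
            "chrom2": p.bp2.chrom, "start2": p.bp2.start, "end2": p.bp2.end,
            "name1": p.bp1.name, "name2": p.bp2.name,
            "origin": p.origin,
            "type": "R" if p.reciprocal else "NR",
            "n_links": p.multiplicity,
            "telomeric": p.bp1.is_telomere or p.bp2.is_telomere,
        })
    return pd.DataFrame(rows, columns=[
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "name1", "name2", "origin", "type", "n_links", "telomeric",
    ])
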