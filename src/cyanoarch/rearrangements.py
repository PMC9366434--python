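"""Synteny blocks, breakpoint regions, and IS enrichment around breakpoints.

Two genomes are compared through shared anchor features. Runs of anchors
whose order and orientation are consistent between the genomes form
collinear synteny blocks; the junction between adjacent blocks is a
putative rearrangement breakpoint, localized at the midpoint between the
flanking anchors (its error is bounded by the anchor spacing). IS
nucleotide frequency is then profiled in windows of increasing size around
the breakpoints and compared with the chromosome-wide background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genome_core import Interval, Replicon, merge_intervals


@dataclass(frozen=True)
class Anchor:
    anchor_id: str
    pos_a: int
    strand_a: str
    pos_b: int
    strand_b: str


@dataclass
class SyntenyBlock:
    anchors: list[Anchor]
    orientation: str  # 'same' or 'inverted'
    wrapped: bool = False  # block crosses the circular origin of genome A

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def a_first(self) -> int:
        return self.anchors[0].pos_a

    @property
    def a_last(self) -> int:
        return self.anchors[-1].pos_a


@dataclass
class BreakRegion:
    center: int  # genome A coordinates
    left_block: int  # indices into the block list
    right_block: int


def build_anchor_map(genome_a: Replicon, genome_b: Replicon) -> list[Anchor]:
    """Match anchor features between two genomes by identical feature ID.

    Only one-to-one matches are kept; IDs occurring more than once in
    either genome are dropped with a warning. Fails if no anchor is shared.
    """
    def anchor_features(rep: Replicon) -> dict[str, list]:
        feats: dict[str, list] = {}
        for f in rep.features:
            if f.kind == "anchor":
                feats.setdefault(f.id, []).append(f)
        return feats

    fa = anchor_features(genome_a)
    fb = anchor_features(genome_b)
    dups = {k for k, v in fa.items() if len(v) > 1} | {
        k for k, v in fb.items() if len(v) > 1
    }
    if dups:
        warnings.warn(f"dropping ambiguous anchor ids: {sorted(dups)}")
    shared = (set(fa) & set(fb)) - dups
    if not shared:
        raise ValueError(
            f"no shared anchors between {genome_a.id!r} and {genome_b.id!r}"
        )
    anchors = [
        Anchor(
            anchor_id=aid,
            pos_a=fa[aid][0].interval.start,
            strand_a=fa[aid][0].interval.strand,
            pos_b=fb[aid][0].interval.start,
            strand_b=fb[aid][0].interval.strand,
        )
        for aid in shared
    ]
    anchors.sort(key=lambda a: a.pos_a)
    return anchors


def collinear_blocks(
    anchors: Sequence[Anchor],
    length_a: int,
    length_b: int,
    min_anchors: int = 3,
    max_anchor_gap: int = 50_000,
    max_diagonal_drift: int = 20_000,
    circular: bool = True,
) -> list[SyntenyBlock]:
    """Greedy left-to-right chaining of anchors into collinear blocks.

    A block extends while the next anchor (in genome A order) continues the
    same strictly monotone direction in genome B, both the A- and B-gaps
    stay within ``max_anchor_gap``, and the B-step tracks the A-step to
    within ``max_diagonal_drift`` (in a collinear segment the two genomes
    advance together; a step far off the diagonal marks a rearrangement
    boundary even when it is numerically small). Runs shorter than
    ``min_anchors`` are discarded as noise. On circular genomes a block may
    cross the A origin: if the last and first runs continue each other
    across the origin they are merged into one wrapped block.
    """
    if len(anchors) < min_anchors:
        return []
    ordered = sorted(anchors, key=lambda a: a.pos_a)

    runs: list[tuple[list[Anchor], int]] = []  # (anchors, direction)
    current = [ordered[0]]
    direction = 0  # 0 unknown, +1 same, -1 inverted
    for prev, nxt in zip(ordered, ordered[1:]):
        a_gap = nxt.pos_a - prev.pos_a
        b_step = nxt.pos_b - prev.pos_b
        step_dir = 1 if b_step > 0 else (-1 if b_step < 0 else 0)
        compatible = (
            a_gap <= max_anchor_gap
            and abs(b_step) <= max_anchor_gap
            and abs(abs(b_step) - a_gap) <= max_diagonal_drift
            and step_dir != 0
            and (direction == 0 or step_dir == direction)
        )
        if compatible:
            current.append(nxt)
            direction = step_dir
        else:
            runs.append((current, direction))
            current = [nxt]
            direction = 0
    runs.append((current, direction))

    blocks = [
        SyntenyBlock(anchors=r, orientation="same" if d >= 0 else "inverted")
        for r, d in runs
        if len(r) >= min_anchors
    ]
    if not blocks:
        return []

    if circular and len(blocks) >= 2:
        last, first = blocks[-1], blocks[0]
        if last.orientation == first.orientation:
            a_gap = (first.a_first - last.a_last) % length_a
            if last.orientation == "same":
                b_gap = (first.anchors[0].pos_b - last.anchors[-1].pos_b) % length_b
            else:
                b_gap = (last.anchors[-1].pos_b - first.anchors[0].pos_b) % length_b
            if (
                a_gap <= max_anchor_gap
                and b_gap <= max_anchor_gap
                and abs(b_gap - a_gap) <= max_diagonal_drift
            ):
                merged = SyntenyBlock(
                    anchors=last.anchors + first.anchors,
                    orientation=last.orientation,
                    wrapped=True,
                )
                blocks = [merged] + blocks[1:-1]
    return blocks


def breakpoint_regions(
    blocks: Sequence[SyntenyBlock],
    genome_a_length: int,
    circular: bool = True,
) -> list[BreakRegion]:
    """One breakpoint region per adjacent block pair (circular adjacency).

    The center is the midpoint between the last anchor of the left block
    and the first anchor of the right block, in genome A coordinates.
    """
    n = len(blocks)
    if n < 2:
        return []
    pairs = [(i, (i + 1) % n) for i in range(n)] if circular else [
        (i, i + 1) for i in range(n - 1)
    ]
    regions = []
    for i, j in pairs:
        left_last = blocks[i].a_last
        right_first = blocks[j].a_first
        gap = (right_first - left_last) % genome_a_length
        center = (left_last + gap // 2) % genome_a_length
        regions.append(BreakRegion(center=center, left_block=i, right_block=j))
    regions.sort(key=lambda r: r.center)
    return regions


# ---------------------------------------------------------------------------
# IS profile around breakpoints
# ---------------------------------------------------------------------------

@dataclass
class BreakpointProfile:
    window_fraction: dict[int, float]  # pooled over all regions
    per_region_fraction: dict[int, list[float]]
    per_region_counts: list[int]  # IS copies overlapping center +/- 10 kbp
    background: float


def _wrapped_segments(start: int, end: int, length: int) -> list[tuple[int, int]]:
    span = end - start
    start %= length
    end = start + span
    if end <= length:
        return [(start, end)]
    return [(start, length), (0, end - length)]


def breakpoint_is_profile(
    regions: Sequence[BreakRegion],
    is_intervals: Iterable[Interval],
    genome: Replicon,
    windows: Sequence[int] = (10_000, 20_000, 30_000),
    count_window: int = 10_000,
) -> BreakpointProfile:
    """IS nucleotide fraction in symmetric windows around breakpoint centers.

    For each window w the pooled fraction is IS nucleotides inside the
    union of [center - w, center + w) over all regions, divided by the
    union length (overlapping windows are counted once). The per-region
    copy count tallies IS copies overlapping center +/- ``count_window``.
    Background is the IS fraction of the whole chromosome.
    """
    if not regions:
        raise ValueError("breakpoint_is_profile requires at least one region")
    L = genome.length
    for w in windows:
        if w > L // 2:
            raise ValueError(f"window {w} exceeds half the chromosome length {L}")
    is_intervals = list(is_intervals)
    merged_is = merge_intervals(is_intervals)
    background = sum(e - s for s, e in merged_is) / L

    def union_segments(w: int) -> list[tuple[int, int]]:
        segs: list[tuple[int, int]] = []
        for r in regions:
            segs.extend(_wrapped_segments(r.center - w, r.center + w, L))
        segs.sort()
        out: list[tuple[int, int]] = []
        for s, e in segs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    def covered(segs: list[tuple[int, int]]) -> int:
        total = 0
        for ws, we in segs:
            for s, e in merged_is:
                lo, hi = max(s, ws), min(e, we)
                if hi > lo:
                    total += hi - lo
        return total

    window_fraction: dict[int, float] = {}
    per_region_fraction: dict[int, list[float]] = {}
    for w in windows:
        segs = union_segments(w)
        union_len = sum(e - s for s, e in segs)
        window_fraction[w] = covered(segs) / union_len
        fracs = []
        for r in regions:
            rsegs = _wrapped_segments(r.center - w, r.center + w, L)
            fracs.append(covered(rsegs) / (2 * w))
        per_region_fraction[w] = fracs

    per_region_counts = []
    for r in regions:
        rsegs = _wrapped_segments(
            r.center - count_window, r.center + count_window, L
        )
        count = 0
        for iv in is_intervals:
            if any(iv.start < e and s < iv.end for s, e in rsegs):
                count += 1
        per_region_counts.append(count)

    return BreakpointProfile(
        window_fraction=window_fraction,
        per_region_fraction=per_region_fraction,
        per_region_counts=per_region_counts,
        background=background,
    )


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block": i,
                "n_anchors": b.n_anchors,
                "orientation": b.orientation,
                "a_first": b.a_first,
                "a_last": b.a_last,
                "wrapped": b.wrapped,
            }
            for i, b in enumerate(blocks)
        ],
        columns=["block", "n_anchors", "orientation", "a_first", "a_last", "wrapped"],
    )
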