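"""Insertion-sequence (IS) element cataloging.

Detects IS copies in a genome against a library of element consensus
sequences, groups copies by nucleotide similarity (single linkage, the
transitive analogue of BLAST-similarity grouping), classifies each copy as
full-length or fragment from its span and transposase ORF integrity, and
summarizes per-replicon IS content.

E-value thresholds of BLAST-based workflows are replaced by explicit
identity/length thresholds: e-values depend on database size and scoring
system, while a minimum match length and identity are directly
interpretable and calibrated so random megabase genomes yield no hits.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy import stats

from .genome_core import Interval, Replicon, nucleotide_fraction

# Fixed local-alignment scoring: match +1, mismatch -1, gap open -2, extend -1.
_MATCH = 1.0
_MISMATCH = -1.0
_GAP_OPEN = -2.0
_GAP_EXTEND = -1.0


@dataclass
class CatalogParams:
    """Thresholds governing IS detection, grouping, and classification."""

    min_match_length: int = 100
    min_identity: float = 0.80
    grouping_identity: float = 0.80
    grouping_coverage: float = 0.60
    full_length_span: float = 0.95
    full_orf_fraction: float = 0.90
    seed_k: int = 12
    min_seed_hits: int = 3  # k-mer hits required before a window is aligned

    def __post_init__(self) -> None:
        for name in (
            "min_identity",
            "grouping_identity",
            "grouping_coverage",
            "full_length_span",
            "full_orf_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_match_length < self.seed_k:
            raise ValueError("min_match_length must be >= seed_k")


@dataclass
class ISCopy:
    """One detected (or planted) IS element occurrence."""

    replicon_id: str
    interval: Interval
    sequence: str  # genome-forward-strand nucleotides of the span
    group_id: str | None = None
    identity: float = 0.0
    state: str | None = None  # 'full' or 'fragment', set by classify_copy
    matched_span_on_consensus: tuple[int, int] | None = None

    @property
    def oriented_sequence(self) -> str:
        """Sequence in the orientation of the matched consensus."""
        if self.interval.strand == "-":
            return str(Seq(self.sequence).reverse_complement())
        return self.sequence


@dataclass
class AlignmentResult:
    identity: float
    coverage_of_shorter: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    score: float
    n_columns: int


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = _MATCH
    aligner.mismatch_score = _MISMATCH
    aligner.open_gap_score = _GAP_OPEN
    aligner.extend_gap_score = _GAP_EXTEND
    return aligner


_ALIGNER = _make_aligner()


def align_identity(a: str, b: str) -> AlignmentResult:
    """Best local alignment of two DNA strings under fixed scores.

    Identity is matches / alignment columns with gap columns counted.
    Coverage is the aligned span on the shorter sequence divided by its
    length. Ties between co-optimal alignments are broken by taking the
    first (leftmost in a, then in b) alignment.
    """
    if not a or not b:
        raise ValueError("align_identity requires non-empty sequences")
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    blocks_a, blocks_b = aln.aligned
    span_a = (int(blocks_a[0][0]), int(blocks_a[-1][1]))
    span_b = (int(blocks_b[0][0]), int(blocks_b[-1][1]))
    short_len = min(len(a), len(b))
    aligned_short = (
        sum(int(e) - int(s) for s, e in blocks_a)
        if len(a) <= len(b)
        else sum(int(e) - int(s) for s, e in blocks_b)
    )
    return AlignmentResult(
        identity=matches / columns if columns else 0.0,
        coverage_of_shorter=aligned_short / short_len,
        span_a=span_a,
        span_b=span_b,
        score=float(aln.score),
        n_columns=int(columns),
    )


def sequences_linked(
    a: str, b: str, min_identity: float, min_coverage: float
) -> bool:
    """Similarity linkage used for grouping: identity AND coverage thresholds.

    A short perfect local match between otherwise unrelated sequences has
    identity near 1 but negligible coverage; requiring both keeps linkage
    meaningful.
    """
    res = align_identity(a, b)
    return res.identity >= min_identity and res.coverage_of_shorter >= min_coverage


# ---------------------------------------------------------------------------
# Detection (seed and extend)
# ---------------------------------------------------------------------------

def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _window_matches(
    genome: str,
    w_start: int,
    w_end: int,
    cons: str,
    params: CatalogParams,
) -> list[tuple[int, int, float, tuple[int, int]]]:
    """All qualifying matches of a consensus within a genome window.

    The best local alignment is extracted, then each remaining flank is
    re-scanned recursively so that two nearby copies of the same element in
    one window are both reported. Returns (start, end, identity,
    consensus_span) tuples in genome coordinates.
    """
    out: list[tuple[int, int, float, tuple[int, int]]] = []
    stack = [(w_start, w_end)]
    while stack:
        s, e = stack.pop()
        if e - s < params.min_match_length:
            continue
        res = align_identity(genome[s:e], cons)
        g_s, g_e = s + res.span_a[0], s + res.span_a[1]
        if (g_e - g_s) < params.min_match_length or res.identity < params.min_identity:
            continue
        out.append((g_s, g_e, res.identity, res.span_b))
        stack.append((s, g_s))
        stack.append((g_e, e))
    return out


def find_is_copies(
    replicon: Replicon,
    library: Mapping[str, str],
    params: CatalogParams | None = None,
) -> list[ISCopy]:
    """Seed-and-extend search of the replicon against each library consensus.

    Shared k-mers between the genome and each consensus (both orientations)
    seed candidate windows; windows are refined by local alignment. Matches
    shorter than ``min_match_length`` or below ``min_identity`` are dropped;
    overlapping candidates are resolved by highest identity, then longest,
    then leftmost.
    """
    if not library:
        raise ValueError("IS library must be non-empty")
    params = params or CatalogParams()
    k = params.seed_k
    genome = replicon.sequence

    # One combined index over all oriented consensi.
    oriented: list[tuple[str, str, str]] = []  # (group_id, strand, sequence)
    for gid, cons in library.items():
        oriented.append((gid, "+", cons))
        oriented.append((gid, "-", str(Seq(cons).reverse_complement())))
    seed_index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for idx, (_, _, cons) in enumerate(oriented):
        for pos in range(len(cons) - k + 1):
            seed_index[cons[pos : pos + k]].append((idx, pos))

    # Scan the genome once, collecting (genome pos, consensus pos) seed hits.
    hits: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for gpos in range(len(genome) - k + 1):
        entry = seed_index.get(genome[gpos : gpos + k])
        if entry:
            for idx, cpos in entry:
                hits[idx].append((gpos, cpos))

    candidates: list[ISCopy] = []
    for idx, seed_hits in hits.items():
        gid, strand, cons = oriented[idx]
        clen = len(cons)
        seed_hits.sort()
        # Cluster seed hits separated by less than a consensus length.
        clusters: list[list[tuple[int, int]]] = [[seed_hits[0]]]
        for gp, cp in seed_hits[1:]:
            if gp - clusters[-1][-1][0] <= clen:
                clusters[-1].append((gp, cp))
            else:
                clusters.append([(gp, cp)])
        for cl in clusters:
            if len(cl) < params.min_seed_hits:
                continue
            # Window bounds implied by the seed diagonals, with slack for gaps.
            w_start = max(0, min(gp - cp for gp, cp in cl) - 50)
            w_end = min(len(genome), max(gp + (clen - cp) for gp, cp in cl) + 50)
            for g_s, g_e, identity, span_b in _window_matches(
                genome, w_start, w_end, cons, params
            ):
                span_on_cons = span_b
                if strand == "-":
                    span_on_cons = (clen - span_b[1], clen - span_b[0])
                candidates.append(
                    ISCopy(
                        replicon_id=replicon.id,
                        interval=Interval(g_s, g_e, strand),
                        sequence=genome[g_s:g_e],
                        group_id=gid,
                        identity=identity,
                        matched_span_on_consensus=span_on_cons,
                    )
                )

    # Resolve overlaps: highest identity, then longest, then leftmost wins.
    candidates.sort(
        key=lambda c: (-c.identity, -(len(c.interval)), c.interval.start)
    )
    chosen: list[ISCopy] = []
    for cand in candidates:
        if all(not cand.interval.overlaps(c.interval) for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c.interval.start)
    return chosen


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def group_is_copies(
    copies: Sequence[ISCopy],
    params: CatalogParams | None = None,
    library: Mapping[str, str] | None = None,
) -> list[ISCopy]:
    """Assign group labels by single-linkage similarity clustering.

    Two copies are linked iff alignment identity >= grouping_identity and
    coverage of the shorter >= grouping_coverage. Connected components form
    groups. Components containing a library consensus inherit its group id;
    the rest are labelled ``novel_<n>`` ordered by leftmost member position.
    The result is independent of input order.
    """
    params = params or CatalogParams()
    if not copies:
        return []
    order = sorted(
        range(len(copies)),
        key=lambda i: (copies[i].replicon_id, copies[i].interval.start),
    )
    n = len(copies)
    lib_items = sorted(library.items()) if library else []
    n_lib = len(lib_items)

    parent = list(range(n + n_lib))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    # Copy-to-consensus edges (cheap: n_copies x n_lib).
    linked_to_lib = [False] * n
    for i in order:
        seq_i = copies[i].oriented_sequence
        for j, (_, cons) in enumerate(lib_items):
            if sequences_linked(
                seq_i, cons, params.grouping_identity, params.grouping_coverage
            ):
                union(i, n + j)
                linked_to_lib[i] = True

    # Copy-to-copy edges only where needed to connect library-less copies.
    for ai, bi in itertools.combinations(order, 2):
        if linked_to_lib[ai] and linked_to_lib[bi]:
            continue
        if find(ai) == find(bi):
            continue
        if sequences_linked(
            copies[ai].oriented_sequence,
            copies[bi].oriented_sequence,
            params.grouping_identity,
            params.grouping_coverage,
        ):
            union(ai, bi)

    # Name components deterministically.
    comp_label: dict[int, str] = {}
    for j, (gid, _) in enumerate(lib_items):
        comp_label.setdefault(find(n + j), gid)
    novel = 0
    for i in order:
        root = find(i)
        if root not in comp_label:
            novel += 1
            comp_label[root] = f"novel_{novel}"

    return [replace(c, group_id=comp_label[find(i)]) for i, c in enumerate(copies)]


# ---------------------------------------------------------------------------
# Full-length vs fragment classification
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def longest_orf(seq: str) -> tuple[int, int]:
    """Longest ATG-initiated ORF on the forward strand (bacterial code).

    Returns the [start, end) nucleotide span including the stop codon, or
    (0, 0) if no ORF exists. Scans all three frames; an ORF running to the
    sequence end without a stop is accepted (consensus sequences generated
    here always terminate with a stop).
    """
    best = (0, 0)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                if (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
        if start is not None and (len(seq) - start) > (best[1] - best[0]):
            end = start + ((len(seq) - start) // 3) * 3
            best = (start, end)
    return best


def classify_copy(
    copy: ISCopy,
    group_consensus: str,
    params: CatalogParams | None = None,
) -> str:
    """Classify a copy as 'full' or 'fragment'.

    Full requires (1) the matched span to cover >= full_length_span of the
    consensus and (2) an uninterrupted transposase reading frame: the part
    of the copy overlapping the consensus ORF, translated in the consensus
    ORF frame, contains no internal stop and covers >= full_orf_fraction of
    the ORF.
    """
    params = params or CatalogParams()
    if copy.group_id is None:
        raise ValueError("cannot classify a copy without a group assignment")
    if copy.matched_span_on_consensus is None:
        res = align_identity(copy.oriented_sequence, group_consensus)
        m_s, m_e = res.span_b
    else:
        m_s, m_e = copy.matched_span_on_consensus
        if copy.interval.strand == "-":
            # stored span is already in consensus coordinates
            pass
    clen = len(group_consensus)
    if (m_e - m_s) < params.full_length_span * clen:
        return "fragment"

    o_s, o_e = longest_orf(group_consensus)
    orf_len = o_e - o_s
    if orf_len == 0:
        return "fragment"
    c_s, c_e = max(o_s, m_s), min(o_e, m_e)
    if (c_e - c_s) < params.full_orf_fraction * orf_len:
        return "fragment"
    # Align copy coordinates to consensus coordinates (substitution-dominated
    # copies: offset mapping through the matched span).
    oriented = copy.oriented_sequence
    start_in_copy = c_s - m_s + ((o_s - c_s) % 3)
    end_in_copy = start_in_copy + ((c_e - (c_s + (o_s - c_s) % 3)) // 3) * 3
    region = oriented[start_in_copy:end_in_copy]
    for i in range(0, len(region) - 5, 3):  # exclude the terminal (stop) codon
        if region[i : i + 3] in _STOPS:
            return "fragment"
    return "full"


def classify_copies(
    copies: Sequence[ISCopy],
    library: Mapping[str, str],
    params: CatalogParams | None = None,
) -> list[ISCopy]:
    """Classify every copy whose group has a library consensus."""
    out = []
    for c in copies:
        if c.group_id in library:
            out.append(replace(c, state=classify_copy(c, library[c.group_id], params)))
        else:
            out.append(replace(c, state="fragment"))
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class ISStats:
    per_replicon: pd.DataFrame  # replicon, n_full, n_fragment, n_total, is_percent
    group_matrix_full: pd.DataFrame  # rows: groups, cols: replicons
    group_matrix_fragment: pd.DataFrame


def is_stats(replicons: Sequence[Replicon], copies: Sequence[ISCopy]) -> ISStats:
    """Per-replicon IS summary and per-group copy-number matrices."""
    by_rep: dict[str, list[ISCopy]] = defaultdict(list)
    for c in copies:
        by_rep[c.replicon_id].append(c)

    rows = []
    for rep in replicons:
        mine = by_rep.get(rep.id, [])
        n_full = sum(1 for c in mine if c.state == "full")
        n_frag = sum(1 for c in mine if c.state == "fragment")
        frac = nucleotide_fraction([c.interval for c in mine], rep.length)
        rows.append(
            {
                "replicon": rep.id,
                "n_full": n_full,
                "n_fragment": n_frag,
                "n_total": len(mine),
                "is_percent": 100.0 * frac,
            }
        )
    per_replicon = pd.DataFrame(rows).set_index("replicon")

    groups = sorted({c.group_id for c in copies if c.group_id is not None})
    rep_ids = [r.id for r in replicons]
    full = pd.DataFrame(0, index=groups, columns=rep_ids, dtype=int)
    frag = pd.DataFrame(0, index=groups, columns=rep_ids, dtype=int)
    for c in copies:
        if c.group_id is None or c.replicon_id not in full.columns:
            continue
        target = full if c.state == "full" else frag
        target.loc[c.group_id, c.replicon_id] += 1
    return ISStats(per_replicon, full, frag)


def size_vs_is_regression(
    points: Iterable[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS of IS percentage on chromosome size: (slope, intercept, r_squared).

    r_squared is the squared Pearson correlation; a constant response gives
    r_squared = 0 by convention.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("regression requires at least 3 points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("regression requires variance in chromosome size")
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
        return slope, intercept, 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def copies_to_frame(copies: Sequence[ISCopy]) -> pd.DataFrame:
    """Tidy table of copies (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "replicon": c.replicon_id,
                "start": c.interval.start,
                "end": c.interval.end,
                "strand": c.interval.strand,
                "group": c.group_id,
                "identity": round(c.identity, 4),
                "state": c.state,
            }
            for c in copies
        ],
        columns=["replicon", "start", "end", "strand", "group", "identity", "state"],
    )
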