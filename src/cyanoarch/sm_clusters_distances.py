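"""Secondary-metabolite gene clusters and their distances to IS elements.

Locates cluster gene runs on a replicon, classifies each cluster as
complete / partial / remnant / absent, computes circular net distances
(minimum nucleotide gap along either arc) between IS copies and cluster
spans, tests those distance samples against normality with a Monte Carlo
Lilliefors-corrected Kolmogorov-Smirnov test, measures IS nucleotide
frequency in windows flanking each cluster, and detects meta-clusters
(several clusters colocalized within a maximum circular gap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_core import Interval, Replicon, circular_gap, merge_intervals
from .is_catalog import ISCopy


@dataclass
class ClusterModel:
    """A named cluster defined by its required genes."""

    name: str
    required_genes: list[str]
    max_intergene_gap: int = 5_000

    def __post_init__(self) -> None:
        if not self.required_genes:
            raise ValueError(f"cluster model {self.name!r} needs >= 1 gene")


@dataclass
class ClusterInstance:
    model_name: str
    replicon_id: str
    span: Interval | None
    present_genes: list[str]
    state: str  # complete | partial | remnant | absent
    n_is_within: int = 0


@dataclass
class DistanceRecord:
    is_feature_id: str
    is_interval: Interval
    cluster_name: str
    replicon_id: str
    net_distance: int


# Fraction of required genes below which a non-empty cluster is a remnant.
REMNANT_GENE_FRACTION = 0.25


def locate_clusters(
    replicon: Replicon,
    models: Sequence[ClusterModel],
    is_intervals: Iterable[Interval] = (),
) -> list[ClusterInstance]:
    """Locate each cluster model on the replicon and classify its state.

    Genes are matched by the ``gene`` attribute of CDS/cluster_gene
    features. A run is broken where two consecutive present genes are
    farther apart than the model's gap limit; the run containing the most
    genes represents the cluster (ties and duplicate gene names warn).
    State: complete if all required genes are in one run; remnant if fewer
    than 25% of required genes are present; partial otherwise; absent if no
    gene is present.
    """
    is_intervals = list(is_intervals)
    out: list[ClusterInstance] = []
    gene_features = [
        f
        for f in replicon.features
        if f.kind in ("cluster_gene", "CDS") and "gene" in f.attributes
    ]
    for model in models:
        wanted = set(model.required_genes)
        present = sorted(
            (f for f in gene_features if f.attributes["gene"] in wanted),
            key=lambda f: f.interval.start,
        )
        if not present:
            out.append(ClusterInstance(model.name, replicon.id, None, [], "absent"))
            continue
        names = [f.attributes["gene"] for f in present]
        if len(names) != len(set(names)):
            warnings.warn(
                f"duplicate gene names for cluster {model.name!r} on "
                f"{replicon.id!r}; using the densest run"
            )
        runs: list[list] = [[present[0]]]
        for prev, feat in zip(present, present[1:]):
            gap = feat.interval.start - prev.interval.end
            if gap > model.max_intergene_gap:
                runs.append([feat])
            else:
                runs[-1].append(feat)
        best = max(runs, key=len)
        run_genes = [f.attributes["gene"] for f in best]
        span = Interval(best[0].interval.start, best[-1].interval.end)
        frac = len(set(run_genes)) / len(model.required_genes)
        if set(run_genes) >= wanted:
            state = "complete"
        elif frac < REMNANT_GENE_FRACTION:
            state = "remnant"
        else:
            state = "partial"
        n_within = sum(1 for iv in is_intervals if iv.overlaps(span))
        out.append(
            ClusterInstance(model.name, replicon.id, span, run_genes, state, n_within)
        )
    return out


def net_distance_table(
    copies: Sequence[ISCopy],
    clusters: Sequence[ClusterInstance],
    replicon_lengths: dict[str, int],
    topology: str = "circular",
) -> list[DistanceRecord]:
    """Circular net distance for every same-replicon (IS copy, cluster) pair.

    Cross-replicon pairs and clusters without a span are skipped.
    """
    records: list[DistanceRecord] = []
    for cl in clusters:
        if cl.span is None:
            continue
        length = replicon_lengths[cl.replicon_id]
        for i, copy in enumerate(copies):
            if copy.replicon_id != cl.replicon_id:
                continue
            d = circular_gap(copy.interval, cl.span, length, topology)
            records.append(
                DistanceRecord(
                    is_feature_id=f"is#{i}",
                    is_interval=copy.interval,
                    cluster_name=cl.model_name,
                    replicon_id=cl.replicon_id,
                    net_distance=d,
                )
            )
    return records


def distances_to_frame(records: Sequence[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon": r.replicon_id,
                "cluster": r.cluster_name,
                "is_start": r.is_interval.start,
                "is_end": r.is_interval.end,
                "net_distance": r.net_distance,
            }
            for r in records
        ],
        columns=["replicon", "cluster", "is_start", "is_end", "net_distance"],
    )


# ---------------------------------------------------------------------------
# Normality testing
# ---------------------------------------------------------------------------

_null_cache: dict[tuple[int, int, int], np.ndarray] = {}


def _lilliefors_statistic(x: np.ndarray) -> float:
    """K-S distance of the sample to a normal with estimated mean/sd."""
    x = np.sort(x)
    n = x.size
    m = x.mean()
    s = x.std(ddof=1)
    u = stats.norm.cdf((x - m) / s)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _null_distribution(n: int, n_mc: int, null_seed: int) -> np.ndarray:
    key = (n, n_mc, null_seed)
    if key not in _null_cache:
        rng = np.random.default_rng(null_seed)
        # Vectorized over replicates; chunked to bound memory.
        chunks = []
        chunk = max(1, min(n_mc, 2_000_000 // max(n, 1)))
        done = 0
        i = np.arange(1, n + 1)
        while done < n_mc:
            m = min(chunk, n_mc - done)
            z = rng.standard_normal((m, n))
            z.sort(axis=1)
            mu = z.mean(axis=1, keepdims=True)
            sd = z.std(axis=1, ddof=1, keepdims=True)
            u = stats.norm.cdf((z - mu) / sd)
            d_plus = (i / n - u).max(axis=1)
            d_minus = (u - (i - 1) / n).max(axis=1)
            chunks.append(np.maximum(d_plus, d_minus))
            done += m
        _null_cache[key] = np.concatenate(chunks)
    return _null_cache[key]


def ks_normality(
    distances: Sequence[float],
    alpha: float = 0.05,
    n_mc: int = 10_000,
    null_seed: int = 0,
) -> tuple[float, float, bool]:
    """One-sample K-S test against a fitted normal (Lilliefors-corrected).

    Because mean and sd are estimated from the sample, the classical K-S
    null is anti-conservative; the p-value is therefore computed from a
    seeded Monte Carlo null distribution of the same statistic (cached per
    sample size). Returns (D, p_value, reject at alpha).
    """
    x = np.asarray(list(distances), dtype=float)
    if x.size < 5:
        raise ValueError(f"ks_normality requires n >= 5, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("ks_normality requires non-zero variance")
    d = _lilliefors_statistic(x)
    null = _null_distribution(x.size, n_mc, null_seed)
    p = (1 + int(np.count_nonzero(null >= d))) / (n_mc + 1)
    return d, p, p < alpha


# ---------------------------------------------------------------------------
# Vicinity windows
# ---------------------------------------------------------------------------

def _wrapped_segments(start: int, end: int, length: int) -> list[tuple[int, int]]:
    """Normalize a possibly origin-crossing [start, end) onto [0, length)."""
    span = end - start
    start %= length
    end = start + span
    if end <= length:
        return [(start, end)]
    return [(start, length), (0, end - length)]


def _coverage_in(
    segments: list[tuple[int, int]], intervals: Iterable[Interval]
) -> int:
    merged = merge_intervals(intervals)
    covered = 0
    for ws, we in segments:
        for s, e in merged:
            lo, hi = max(s, ws), min(e, we)
            if hi > lo:
                covered += hi - lo
    return covered


def vicinity_is_frequency(
    cluster: ClusterInstance,
    is_intervals: Iterable[Interval],
    replicon: Replicon,
    windows: Sequence[int] = (10_000, 20_000, 30_000),
) -> dict:
    """IS nucleotide fraction in windows flanking a cluster span.

    For each window w the two flanks [span.start - w, span.start) and
    [span.end, span.end + w) are pooled (with circular wrap); the fraction
    is IS nucleotides in the flanks divided by 2w. Background is the IS
    fraction over the whole replicon (span included).
    """
    if cluster.span is None:
        raise ValueError(f"cluster {cluster.model_name!r} has no span")
    L = replicon.length
    is_intervals = list(is_intervals)
    for w in windows:
        if w > L // 2:
            raise ValueError(f"window {w} exceeds half the replicon length {L}")
    merged_total = sum(e - s for s, e in merge_intervals(is_intervals))
    background = merged_total / L
    span = cluster.span
    per_window: dict[int, float] = {}
    per_flank: dict[int, tuple[float, float]] = {}
    for w in windows:
        left = _wrapped_segments(span.start - w, span.start, L)
        right = _wrapped_segments(span.end, span.end + w, L)
        cov_left = _coverage_in(left, is_intervals)
        cov_right = _coverage_in(right, is_intervals)
        per_window[w] = (cov_left + cov_right) / (2 * w)
        per_flank[w] = (cov_left / w, cov_right / w)
    return {
        "cluster": cluster.model_name,
        "window_fraction": per_window,
        "flank_fractions": per_flank,
        "background": background,
    }


# ---------------------------------------------------------------------------
# Meta-clusters
# ---------------------------------------------------------------------------

@dataclass
class MetaCluster:
    members: list[str]
    replicon_id: str
    total_span: int  # bp from first to last member along the shorter covering arc


def meta_cluster_detect(
    clusters: Sequence[ClusterInstance],
    replicon_lengths: dict[str, int],
    max_gap: int = 300_000,
    topology: str = "circular",
) -> list[MetaCluster]:
    """Single-linkage grouping of clusters with pairwise circular gap <= max_gap.

    Only groups of two or more clusters are reported. The grouping is
    independent of input order; members are listed by position.
    """
    with_span = [c for c in clusters if c.span is not None]
    by_rep: dict[str, list[ClusterInstance]] = {}
    for c in with_span:
        by_rep.setdefault(c.replicon_id, []).append(c)

    out: list[MetaCluster] = []
    for rep_id, group in sorted(by_rep.items()):
        group = sorted(group, key=lambda c: c.span.start)
        L = replicon_lengths[rep_id]
        n = len(group)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if circular_gap(group[i].span, group[j].span, L, topology) <= max_gap:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)
        for root in sorted(comps):
            idxs = comps[root]
            if len(idxs) < 2:
                continue
            members = [group[i] for i in idxs]
            spans = [m.span for m in members]
            # Shorter covering arc: complement of the largest inter-member gap.
            if topology == "circular":
                ordered = sorted(spans, key=lambda s: s.start)
                gaps = [
                    (ordered[(k + 1) % len(ordered)].start - ordered[k].end) % L
                    for k in range(len(ordered))
                ]
                total = L - max(gaps)
            else:
                total = max(s.end for s in spans) - min(s.start for s in spans)
            out.append(
                MetaCluster(
                    members=[m.model_name for m in members],
                    replicon_id=rep_id,
                    total_span=total,
                )
            )
    return out


def clusters_to_frame(clusters: Sequence[ClusterInstance]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon": c.replicon_id,
                "cluster": c.model_name,
                "start": c.span.start if c.span else pd.NA,
                "end": c.span.end if c.span else pd.NA,
                "state": c.state,
                "n_genes_present": len(c.present_genes),
                "n_is_within": c.n_is_within,
            }
            for c in clusters
        ],
        columns=[
            "replicon", "cluster", "start", "end", "state",
            "n_genes_present", "n_is_within",
        ],
    )
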