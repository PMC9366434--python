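"""Synthetic genomes with planted ground truth.

Generates circular chromosomes (and optional plasmids) that emulate the
statistical structure of complete cyanobacterial genomes: IS element copies
from several sequence groups (full-length and fragments, together a few
percent of nucleotides), secondary-metabolite gene clusters, evenly spaced
anchor genes for synteny analysis, inversions between genome pairs, and an
optional excess of IS copies whose distance from inversion breakpoints
follows an exponential law. Every planted feature is recorded in a truth
table so downstream detection, grouping, classification, and breakpoint
recovery can be scored exactly.

All randomness flows from a single seeded generator per call; identical
configuration and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_core import CIRCULAR, Feature, Interval, Replicon
from .is_catalog import CatalogParams, sequences_linked

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ISGroupSpec:
    group_id: str
    n_full: int
    n_fragment: int
    divergence: float = 0.02  # substitutions per site vs the group consensus

    def __post_init__(self) -> None:
        if not (0 <= self.divergence <= 0.3):
            raise ValueError("divergence must be in [0, 0.3]")
        if self.n_full < 0 or self.n_fragment < 0:
            raise ValueError("copy counts must be >= 0")


@dataclass
class ClusterSpec:
    name: str
    n_genes: int
    gene_length: int
    intergene_gap: int = 100
    placement: int | None = None  # explicit start, or None for random

    @property
    def total_length(self) -> int:
        return self.n_genes * self.gene_length + (self.n_genes - 1) * self.intergene_gap

    def gene_names(self) -> list[str]:
        return [f"{self.name}{chr(ord('A') + i)}" for i in range(self.n_genes)]


@dataclass
class PlasmidSpec:
    length: int
    is_groups: list[ISGroupSpec] = field(default_factory=list)


@dataclass
class EnrichmentSpec:
    """Extra IS copies planted near each breakpoint of a derived genome."""

    extra_copies_per_breakpoint: int
    decay_scale: int  # bp; exponential scale of the breakpoint-to-copy gap
    group_id: str
    divergence: float = 0.02


@dataclass
class SimulationConfig:
    seed: int
    chromosome_length: int = 1_000_000
    gc: float = 0.39  # GC content matching the 37-39.8% of the emulated genomes
    is_groups: list[ISGroupSpec] = field(default_factory=list)
    clusters: list[ClusterSpec] = field(default_factory=list)
    plasmids: list[PlasmidSpec] = field(default_factory=list)
    anchor_spacing: int = 10_000
    anchor_length: int = 200

    def __post_init__(self) -> None:
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")


# ---------------------------------------------------------------------------
# Truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthIS:
    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    group_id: str
    state: str  # 'full' or 'fragment'


@dataclass
class TruthCluster:
    name: str
    replicon_id: str
    start: int
    end: int
    gene_ids: list[str]


@dataclass
class TruthTable:
    is_copies: list[TruthIS] = field(default_factory=list)
    clusters: list[TruthCluster] = field(default_factory=list)
    breakpoints: list[int] = field(default_factory=list)
    enrichment_distances: list[int] = field(default_factory=list)

    def is_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(t) for t in self.is_copies],
            columns=["feature_id", "replicon_id", "start", "end", "strand", "group_id", "state"],
        )

    def cluster_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": c.name,
                "replicon_id": c.replicon_id,
                "start": c.start,
                "end": c.end,
                "n_genes": len(c.gene_ids),
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows, columns=["name", "replicon_id", "start", "end", "n_genes"])


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(alphabet, size=length, p=probs).tobytes().decode()


def random_orf_sequence(length: int, rng: np.random.Generator) -> str:
    """Random coding sequence: ATG, sense codons, one terminal stop.

    The returned sequence has length rounded down to a codon multiple and is
    a single uninterrupted ORF, mimicking a transposase-coding IS element.
    """
    n_codons = max(3, length // 3)
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + stop


def mutate_sequence(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    preserve_orf: bool = False,
) -> str:
    """Substitute bases i.i.d. at the given rate (no indels).

    With ``preserve_orf`` the whole sequence is treated as a reading frame
    and any substitution that would create an internal stop codon is
    redrawn, so planted full-length copies keep an uninterrupted ORF.
    """
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = [b for b in base_codes if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    out = arr.tobytes().decode()
    if preserve_orf:
        chars = list(out)
        for i in hit:
            ci = (i // 3) * 3
            if ci + 3 > len(chars) - 3:  # terminal codon may stay/become a stop
                continue
            if "".join(chars[ci : ci + 3]) in _STOPS:
                original = seq[i]
                safe = []
                for b in _BASES:
                    if b == original:
                        continue
                    trial = chars[ci : ci + 3]
                    trial[i - ci] = b
                    if "".join(trial) not in _STOPS:
                        safe.append(b)
                chars[i] = safe[rng.integers(len(safe))]
        out = "".join(chars)
    return out


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# IS library
# ---------------------------------------------------------------------------

def build_is_library(
    n_groups: int,
    length_range: tuple[int, int] = (900, 1650),
    max_intergroup_identity: float = 0.6,
    seed: int = 0,
    max_attempts_per_group: int = 50,
) -> dict[str, str]:
    """Random IS consensus library with mutually dissimilar groups.

    Each consensus is a single random ORF. Candidates are rejection-sampled
    until no pair would be linked under the grouping rule at
    ``max_intergroup_identity`` (with the default grouping coverage), i.e.
    the groups are guaranteed separable by downstream clustering.
    """
    if n_groups < 0:
        raise ValueError("n_groups must be >= 0")
    rng = np.random.default_rng(seed)
    cov = CatalogParams().grouping_coverage
    library: dict[str, str] = {}
    for g in range(n_groups):
        for attempt in range(max_attempts_per_group):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            cand = random_orf_sequence(length, rng)
            if all(
                not sequences_linked(cand, other, max_intergroup_identity, cov)
                for other in library.values()
            ):
                library[f"group_{g + 1}"] = cand
                break
        else:
            raise RuntimeError(
                f"could not sample group {g + 1} dissimilar from existing groups "
                f"after {max_attempts_per_group} attempts; "
                "loosen max_intergroup_identity"
            )
    return library


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def _place_span(
    length: int,
    occupied: list[tuple[int, int]],
    total: int,
    rng: np.random.Generator,
    margin: int = 50,
    max_attempts: int = 2000,
) -> int:
    """Uniformly place a span of the given length avoiding occupied spans."""
    for _ in range(max_attempts):
        start = int(rng.integers(0, total - length))
        ok = True
        for s, e in occupied:
            if start - margin < e and s - margin < start + length:
                ok = False
                break
        if ok:
            occupied.append((start, start + length))
            return start
    raise RuntimeError(
        f"could not place a {length} bp span in {total} bp without overlap"
    )


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _plant_is_copies(
    seq_chars: list[str],
    rep_id: str,
    groups: Sequence[ISGroupSpec],
    library: Mapping[str, str],
    occupied: list[tuple[int, int]],
    total: int,
    rng: np.random.Generator,
    features: list[Feature],
    truth: TruthTable,
    id_prefix: str = "is",
) -> None:
    counter = sum(1 for f in features if f.kind == "IS_copy")
    for spec in groups:
        if spec.group_id not in library:
            raise KeyError(f"group {spec.group_id!r} not in library")
        consensus = library[spec.group_id]
        clen = len(consensus)
        plan = [("full", None)] * spec.n_full + [("fragment", None)] * spec.n_fragment
        for state, _ in plan:
            if state == "full":
                copy_seq = mutate_sequence(consensus, spec.divergence, rng, preserve_orf=True)
            else:
                frac = rng.uniform(0.2, 0.7)
                sub_len = max(60, int(round(frac * clen)))
                sub_start = int(rng.integers(0, clen - sub_len + 1))
                copy_seq = mutate_sequence(
                    consensus[sub_start : sub_start + sub_len], spec.divergence, rng
                )
            strand = "+" if rng.random() < 0.5 else "-"
            planted = copy_seq if strand == "+" else reverse_complement(copy_seq)
            start = _place_span(len(planted), occupied, total, rng)
            seq_chars[start : start + len(planted)] = planted
            counter += 1
            fid = f"{id_prefix}_{counter:04d}"
            features.append(
                Feature(
                    id=fid,
                    kind="IS_copy",
                    interval=Interval(start, start + len(planted), strand),
                    attributes={"is_group": spec.group_id, "is_state": state},
                )
            )
            truth.is_copies.append(
                TruthIS(fid, rep_id, start, start + len(planted), strand, spec.group_id, state)
            )


def simulate_genome(
    config: SimulationConfig, library: Mapping[str, str]
) -> tuple[list[Replicon], TruthTable]:
    """Simulate a chromosome (and plasmids) with planted ground truth."""
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    total = config.chromosome_length
    seq_chars = list(random_dna(total, rng, config.gc))
    occupied: list[tuple[int, int]] = []
    features: list[Feature] = []

    # Clusters first (largest spans; explicit placements honoured).
    for spec in config.clusters:
        span_len = spec.total_length
        if spec.placement is not None:
            start = spec.placement
            for s, e in occupied:
                if start < e and s < start + span_len:
                    raise RuntimeError(
                        f"explicit placement of cluster {spec.name!r} overlaps"
                    )
            occupied.append((start, start + span_len))
        else:
            start = _place_span(span_len, occupied, total, rng, margin=200)
        gene_ids = []
        pos = start
        for gene in spec.gene_names():
            gene_seq = random_orf_sequence(spec.gene_length, rng)
            seq_chars[pos : pos + len(gene_seq)] = gene_seq
            gid = gene
            gene_ids.append(gid)
            features.append(
                Feature(
                    id=gid,
                    kind="cluster_gene",
                    interval=Interval(pos, pos + spec.gene_length, "+"),
                    attributes={"gene": gene, "cluster": spec.name},
                )
            )
            pos += spec.gene_length + spec.intergene_gap
        truth.clusters.append(
            TruthCluster(spec.name, "chr", start, start + span_len, gene_ids)
        )

    _plant_is_copies(
        seq_chars, "chr", config.is_groups, library, occupied, total, rng, features, truth
    )

    # Anchor genes on a regular grid, skipping occupied positions.
    for i, pos in enumerate(range(0, total - config.anchor_length, config.anchor_spacing)):
        clash = any(
            pos < e and s < pos + config.anchor_length for s, e in occupied
        )
        if clash:
            continue
        features.append(
            Feature(
                id=f"anchor_{i:05d}",
                kind="anchor",
                interval=Interval(pos, pos + config.anchor_length, "+"),
                attributes={},
            )
        )

    chromosome = Replicon(
        id="chr", topology=CIRCULAR, sequence="".join(seq_chars), features=features
    )
    replicons = [chromosome]

    for p_idx, pspec in enumerate(config.plasmids, start=1):
        pid = f"plasmid_{p_idx}"
        p_chars = list(random_dna(pspec.length, rng, config.gc))
        p_occupied: list[tuple[int, int]] = []
        p_features: list[Feature] = []
        _plant_is_copies(
            p_chars, pid, pspec.is_groups, library, p_occupied, pspec.length,
            rng, p_features, truth, id_prefix=f"{pid}_is",
        )
        replicons.append(
            Replicon(id=pid, topology=CIRCULAR, sequence="".join(p_chars), features=p_features)
        )

    return replicons, truth


# ---------------------------------------------------------------------------
# Rearranged genome derivation
# ---------------------------------------------------------------------------

def _flip_strand(strand: str) -> str:
    return {"+": "-", "-": "+", ".": "."}[strand]


def derive_rearranged_genome(
    genome: Replicon,
    inversions: Sequence[tuple[int, int]],
    seed: int,
    enrichment: EnrichmentSpec | None = None,
    library: Mapping[str, str] | None = None,
    derived_id: str | None = None,
) -> tuple[Replicon, TruthTable]:
    """Apply inversions (and optional breakpoint-proximal IS enrichment).

    Each inversion [s, e) reverse-complements the segment in place and
    re-coordinates the contained features with flipped strand; features
    straddling an inversion boundary are an error. True breakpoints {s, e}
    are recorded. With enrichment, extra IS copies are planted at gaps drawn
    from an exponential law with the configured decay scale on a random
    side of each breakpoint.
    """
    rng = np.random.default_rng(seed)
    spans = sorted((int(s), int(e)) for s, e in inversions)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping inversions [{s1},{e1}) and [{s2},{e2})")
    L = genome.length
    for s, e in spans:
        if not (0 <= s < e <= L):
            raise ValueError(f"inversion [{s},{e}) outside the chromosome")

    seq = genome.sequence
    for s, e in spans:
        seq = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]

    new_features: list[Feature] = []
    for f in genome.features:
        iv = f.interval
        placed = False
        for s, e in spans:
            if iv.start >= s and iv.end <= e:
                new_iv = Interval(s + e - iv.end, s + e - iv.start, _flip_strand(iv.strand))
                new_features.append(Feature(f.id, f.kind, new_iv, dict(f.attributes)))
                placed = True
                break
            if iv.start < e and s < iv.end and not (iv.start >= s and iv.end <= e):
                raise ValueError(
                    f"feature {f.id!r} straddles inversion boundary [{s},{e})"
                )
        if not placed:
            new_features.append(Feature(f.id, f.kind, iv, dict(f.attributes)))

    truth = TruthTable()
    for s, e in spans:
        truth.breakpoints.extend([s, e])
    truth.breakpoints.sort()

    seq_chars = list(seq)
    if enrichment is not None:
        if library is None or enrichment.group_id not in library:
            raise ValueError("enrichment requires a library containing the group")
        consensus = library[enrichment.group_id]
        occupied = [(f.interval.start, f.interval.end) for f in new_features]
        counter = 0
        for bp in truth.breakpoints:
            for _ in range(enrichment.extra_copies_per_breakpoint):
                copy_seq = mutate_sequence(
                    consensus, enrichment.divergence, rng, preserve_orf=True
                )
                clen = len(copy_seq)
                for _attempt in range(500):
                    gap = int(rng.exponential(enrichment.decay_scale))
                    side = 1 if rng.random() < 0.5 else -1
                    if side > 0:
                        start = bp + gap
                    else:
                        start = bp - gap - clen
                    if start < 0 or start + clen > L:
                        continue
                    if any(start < e and s < start + clen for s, e in occupied):
                        continue
                    break
                else:
                    raise RuntimeError("could not place enrichment copy near breakpoint")
                strand = "+" if rng.random() < 0.5 else "-"
                planted = copy_seq if strand == "+" else reverse_complement(copy_seq)
                seq_chars[start : start + clen] = planted
                occupied.append((start, start + clen))
                counter += 1
                fid = f"bp_is_{counter:04d}"
                new_features.append(
                    Feature(
                        id=fid,
                        kind="IS_copy",
                        interval=Interval(start, start + clen, strand),
                        attributes={"is_group": enrichment.group_id, "is_state": "full"},
                    )
                )
                rep_id = derived_id or f"{genome.id}_derived"
                truth.is_copies.append(
                    TruthIS(fid, rep_id, start, start + clen, strand,
                            enrichment.group_id, "full")
                )
                truth.enrichment_distances.append(gap)

    derived = Replicon(
        id=derived_id or f"{genome.id}_derived",
        topology=genome.topology,
        sequence="".join(seq_chars),
        features=new_features,
    )
    return derived, truth


def random_inversion_spans(
    replicon: Replicon,
    n: int,
    rng: np.random.Generator,
    size_range: tuple[int, int] = (50_000, 200_000),
    min_separation: int = 50_000,
    max_attempts: int = 5000,
) -> list[tuple[int, int]]:
    """Sample disjoint inversion spans whose endpoints avoid features.

    Spans are kept at least ``min_separation`` apart from each other and
    from the origin so that synteny blocks between them retain enough
    anchors to be detected.
    """
    feature_spans = [(f.interval.start, f.interval.end) for f in replicon.features]
    chosen: list[tuple[int, int]] = []

    def endpoint_ok(p: int) -> bool:
        return all(not (s < p < e) for s, e in feature_spans)

    for _ in range(max_attempts):
        if len(chosen) == n:
            break
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        start = int(rng.integers(min_separation, replicon.length - size - min_separation))
        end = start + size
        if not (endpoint_ok(start) and endpoint_ok(end)):
            continue
        if any(
            start - min_separation < e and s - min_separation < end
            for s, e in chosen
        ):
            continue
        chosen.append((start, end))
    if len(chosen) < n:
        raise RuntimeError(f"could only place {len(chosen)} of {n} inversions")
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Study-scale defaults
# ---------------------------------------------------------------------------

def default_library(seed: int = 0, n_groups: int = 5) -> dict[str, str]:
    """Library emulating distinct IS element groups (0.9-1.65 kb elements)."""
    return build_is_library(n_groups=n_groups, seed=seed)


def default_config(seed: int) -> SimulationConfig:
    """A 1 Mbp test-scale chromosome emulating the study genomes.

    IS content about 2-3% of nucleotides from five groups (the emulated
    chromosomes carry 0.8-3.7%), seven secondary-metabolite gene clusters,
    and anchors every 10 kbp.
    """
    groups = [
        ISGroupSpec("group_1", n_full=4, n_fragment=3),
        ISGroupSpec("group_2", n_full=3, n_fragment=3),
        ISGroupSpec("group_3", n_full=3, n_fragment=2),
        ISGroupSpec("group_4", n_full=2, n_fragment=2),
        ISGroupSpec("group_5", n_full=2, n_fragment=2),
    ]
    clusters = [
        ClusterSpec("mcy", n_genes=10, gene_length=2500),
        ClusterSpec("aer", n_genes=9, gene_length=1500),
        ClusterSpec("apn", n_genes=5, gene_length=2400),
        ClusterSpec("oci", n_genes=4, gene_length=3500),
        ClusterSpec("mic", n_genes=5, gene_length=2000),
        ClusterSpec("mvd", n_genes=6, gene_length=800),
        ClusterSpec("pag", n_genes=5, gene_length=1200),
    ]
    return SimulationConfig(seed=seed, is_groups=groups, clusters=clusters)
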