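"""Domain types, FASTA/GFF3 I/O, and circular-coordinate interval arithmetic.

All coordinates are 0-based half-open internally; GFF3 on disk is 1-based
inclusive. Replicons are circular or linear; features are not allowed to
span the circular origin, which keeps every interval operation total.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CIRCULAR = "circular"
LINEAR = "linear"

FEATURE_KINDS = frozenset({"CDS", "IS_copy", "cluster_gene", "anchor", "other"})

#: GFF3 feature types that carry replicon topology rather than annotation.
_REGION_TYPES = frozenset({"region"})


@dataclass(frozen=True)
class Interval:
    """A genomic span: 0-based inclusive start, exclusive end."""

    start: int
    end: int
    strand: str = "."  # '+', '-' or '.' (unstranded)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Feature:
    id: str
    kind: str
    interval: Interval
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.id!r}: unknown kind {self.kind!r}")


@dataclass
class Replicon:
    """A single DNA molecule (chromosome or plasmid) with its features."""

    id: str
    topology: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in (CIRCULAR, LINEAR):
            raise ValueError(f"replicon {self.id!r}: bad topology {self.topology!r}")
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        seen: set[str] = set()
        for f in self.features:
            if f.id in seen:
                raise ValueError(f"replicon {self.id!r}: duplicate feature id {f.id!r}")
            seen.add(f.id)
            if f.interval.end > self.length:
                raise ValueError(
                    f"feature {f.id!r} [{f.interval.start}, {f.interval.end}) "
                    f"exceeds replicon {self.id!r} length {self.length}"
                )

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def subsequence(self, interval: Interval) -> str:
        return self.sequence[interval.start : interval.end]


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def circular_gap(a: Interval, b: Interval, length: int, topology: str = CIRCULAR) -> int:
    """Minimum number of nucleotides strictly between two intervals.

    Returns 0 when the intervals overlap or abut. On a circular replicon
    both arcs are considered and the shorter gap is returned; the result is
    symmetric in (a, b).
    """
    for iv in (a, b):
        if iv.end > length:
            raise ValueError(f"interval [{iv.start}, {iv.end}) outside [0, {length})")
    if a.overlaps(b):
        return 0
    if topology == LINEAR:
        if b.start >= a.end:
            return b.start - a.end
        return a.start - b.end
    gap_ab = (b.start - a.end) % length
    gap_ba = (a.start - b.end) % length
    return min(gap_ab, gap_ba)


def merge_intervals(intervals: Iterable[Interval]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint (start, end) pairs."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def nucleotide_fraction(intervals: Iterable[Interval], length: int) -> float:
    """Fraction of the replicon covered by the union of intervals."""
    if length <= 0:
        raise ValueError("replicon length must be positive")
    intervals = list(intervals)
    for iv in intervals:
        if iv.end > length:
            raise ValueError(f"interval [{iv.start}, {iv.end}) outside [0, {length})")
    covered = sum(e - s for s, e in merge_intervals(intervals))
    return covered / length


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_genome(
    replicons: Sequence[Replicon], fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write replicons as multi-FASTA (60-column wrap) plus GFF3.

    Record order is deterministic: replicons by id, features by start then id.
    Topology is carried by a ``region`` feature with ``Is_circular=true``.
    """
    ordered = sorted(replicons, key=lambda r: r.id)
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in ordered
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")

    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in ordered:
            fh.write(f"##sequence-region {rep.id} 1 {rep.length}\n")
        for rep in ordered:
            attrs = [f"ID={rep.id}"]
            if rep.topology == CIRCULAR:
                attrs.append("Is_circular=true")
            fh.write(
                f"{rep.id}\tcyanoarch\tregion\t1\t{rep.length}\t.\t+\t.\t"
                + ";".join(attrs)
                + "\n"
            )
            for feat in sorted(rep.features, key=lambda f: (f.interval.start, f.id)):
                iv = feat.interval
                attrs = [f"ID={feat.id}"] + [
                    f"{k}={v}" for k, v in sorted(feat.attributes.items())
                ]
                fh.write(
                    f"{rep.id}\tcyanoarch\t{feat.kind}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand if iv.strand != '.' else '.'}\t.\t"
                    + ";".join(attrs)
                    + "\n"
                )


def read_genome(fasta_path: str | Path, gff3_path: str | Path) -> list[Replicon]:
    """Read a multi-FASTA + GFF3 pair into Replicon objects.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    Topology comes from a ``region`` record carrying ``Is_circular=true``;
    replicons without one are linear. Malformed records fail with a message
    naming the offending feature.
    """
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not sequences:
        raise ValueError(f"no FASTA records in {fasta_path}")

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        sort_attribute_values=True,
    )

    topology: dict[str, str] = {sid: LINEAR for sid in sequences}
    features: dict[str, list[Feature]] = {sid: [] for sid in sequences}

    for rec in db.all_features():
        seqid = rec.seqid
        if seqid not in sequences:
            raise ValueError(f"GFF3 record {rec.id!r}: unknown seqid {seqid!r}")
        if rec.featuretype in _REGION_TYPES:
            circ = rec.attributes.get("Is_circular", ["false"])[0].lower()
            topology[seqid] = CIRCULAR if circ == "true" else LINEAR
            continue
        fid = rec.attributes.get("ID", [rec.id or "?"])[0]
        if rec.end < rec.start:
            raise ValueError(f"feature {fid!r}: end {rec.end} < start {rec.start}")
        if rec.end > len(sequences[seqid]):
            raise ValueError(
                f"feature {fid!r}: end {rec.end} exceeds {seqid!r} length "
                f"{len(sequences[seqid])}"
            )
        kind = rec.featuretype if rec.featuretype in FEATURE_KINDS else "other"
        strand = rec.strand if rec.strand in ("+", "-") else "."
        attrs = {
            k: v[0] for k, v in rec.attributes.items() if k != "ID"
        }
        features[seqid].append(
            Feature(
                id=fid,
                kind=kind,
                interval=Interval(rec.start - 1, rec.end, strand),
                attributes=attrs,
            )
        )

    return [
        Replicon(id=sid, topology=topology[sid], sequence=seq, features=features[sid])
        for sid, seq in sorted(sequences.items())
    ]


def read_genome_string(fasta_text: str, gff3_text: str) -> list[Replicon]:
    """Convenience wrapper parsing in-memory FASTA/GFF3 text."""
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "g.fa"
        gff = Path(tmp) / "g.gff3"
        fa.write_text(fasta_text)
        gff.write_text(gff3_text)
        return read_genome(fa, gff)
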