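"""Degenerate back-translation search and paralog quantification.

The back-translation of a peptide is the set of all DNA sequences encoding
it under the degeneracy of the bacterial genetic code (translation table
11). Exact coding occurrences of a peptide in a genome are found by
translating all six reading frames and substring-matching the peptide,
which is equivalent to exact nucleotide matching against the full
enumeration (enforced by an oracle test, not assumed).

Paralogs are quantified by all-pairs alignment of CDS features at an
identity cutoff and a query-coverage cutoff; a gene is paralogous if at
least one partner passes in either query direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_core import Feature, Replicon
from .is_catalog import align_identity

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

#: residue -> sorted list of sense codons (bacterial code)
CODONS_BY_RESIDUE: dict[str, list[str]] = {}
for codon, aa in _TABLE11.forward_table.items():
    CODONS_BY_RESIDUE.setdefault(aa, []).append(codon)
for aa in CODONS_BY_RESIDUE:
    CODONS_BY_RESIDUE[aa].sort()

VALID_RESIDUES = frozenset(CODONS_BY_RESIDUE)


def _check_peptide(peptide: str) -> None:
    if not peptide:
        raise ValueError("peptide must be non-empty")
    bad = set(peptide) - VALID_RESIDUES
    if bad:
        raise ValueError(f"unknown residue letter(s): {sorted(bad)}")


def degenerate_count(peptide: str) -> int:
    """Number of distinct DNA sequences encoding the peptide."""
    _check_peptide(peptide)
    n = 1
    for aa in peptide:
        n *= len(CODONS_BY_RESIDUE[aa])
    return n


def enumerate_backtranslations(peptide: str, cap: int = 100_000) -> list[str]:
    """All coding sequences for the peptide, lexicographically ordered."""
    _check_peptide(peptide)
    n = degenerate_count(peptide)
    if n > cap:
        raise ValueError(
            f"back-translation of {peptide!r} has {n} sequences, above cap {cap}"
        )
    return [
        "".join(codons)
        for codons in itertools.product(*(CODONS_BY_RESIDUE[aa] for aa in peptide))
    ]


@dataclass(frozen=True)
class CodingHit:
    replicon_id: str
    start: int  # forward-strand 0-based half-open
    end: int
    strand: str
    frame: int  # 0-2 on the scanned strand


def scan_coding_matches(
    replicons: Iterable[Replicon], peptide: str
) -> list[CodingHit]:
    """All loci whose nucleotide window exactly encodes the peptide.

    Both strands are scanned by six-frame translation; hits are reported in
    forward coordinates. The circular origin is not crossed (no feature or
    hit may span it).
    """
    _check_peptide(peptide)
    m = len(peptide)
    hits: list[CodingHit] = []
    for rep in replicons:
        L = rep.length
        for strand, seq in (("+", rep.sequence), ("-", str(Seq(rep.sequence).reverse_complement()))):
            for frame in range(3):
                usable = (len(seq) - frame) // 3 * 3
                if usable < 3 * m:
                    continue
                protein = str(Seq(seq[frame : frame + usable]).translate(table=11))
                idx = protein.find(peptide)
                while idx != -1:
                    nt_start = frame + 3 * idx
                    nt_end = nt_start + 3 * m
                    if strand == "+":
                        hits.append(CodingHit(rep.id, nt_start, nt_end, "+", frame))
                    else:
                        hits.append(
                            CodingHit(rep.id, L - nt_end, L - nt_start, "-", frame)
                        )
                    idx = protein.find(peptide, idx + 1)
    hits.sort(key=lambda h: (h.replicon_id, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Paralogs
# ---------------------------------------------------------------------------

@dataclass
class ParalogParams:
    min_identity: float = 0.97
    min_coverage: float = 0.90  # of the query, strict inequality per the cutoff

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1) or not (0 < self.min_coverage <= 1):
            raise ValueError("paralog thresholds must be in (0, 1]")


@dataclass
class ParalogSummary:
    n_genes: int
    n_paralogous_genes: int
    percent_cds: float
    percent_transposase_of_paralogs: float
    pairs: list[tuple[str, str]]


def _is_transposase(feature: Feature) -> bool:
    if feature.attributes.get("is_transposase", "").lower() in ("1", "true", "yes"):
        return True
    return "transposase" in feature.attributes.get("product", "").lower()


def paralog_pairs(
    cds_features: Sequence[tuple[Feature, str]],
    params: ParalogParams | None = None,
) -> ParalogSummary:
    """All-pairs paralog detection among CDS of one replicon.

    ``cds_features`` pairs each Feature with its nucleotide sequence. A
    pair passes when alignment identity >= min_identity and the aligned
    span covers > min_coverage of the query in at least one query
    direction (the symmetric rule avoids order dependence). The summary
    counts genes, not pairs; the transposase share is computed over the
    paralogous genes flagged as transposases.
    """
    params = params or ParalogParams()
    if len(cds_features) < 2:
        raise ValueError("paralog analysis requires >= 2 CDS")
    order = sorted(range(len(cds_features)), key=lambda i: cds_features[i][0].id)

    # Seed prefilter: genes passing the identity/coverage cutoffs share many
    # exact k-mers, while unrelated pairs share almost none; skipping
    # near-disjoint pairs avoids quadratic full alignments.
    k = 12
    kmer_sets = [
        {s[p : p + k] for p in range(0, max(0, len(s) - k + 1))}
        for _, s in cds_features
    ]
    min_shared = 4

    passing: list[tuple[str, str]] = []
    flagged: set[str] = set()
    for i, j in itertools.combinations(order, 2):
        fa, sa = cds_features[i]
        fb, sb = cds_features[j]
        if len(kmer_sets[i] & kmer_sets[j]) < min_shared:
            continue
        res = align_identity(sa, sb)
        if res.identity < params.min_identity:
            continue
        cov_a = (res.span_a[1] - res.span_a[0]) / len(sa)
        cov_b = (res.span_b[1] - res.span_b[0]) / len(sb)
        if cov_a > params.min_coverage or cov_b > params.min_coverage:
            pair = tuple(sorted((fa.id, fb.id)))
            passing.append(pair)
            flagged.update(pair)
    n_genes = len(cds_features)
    by_id = {f.id: f for f, _ in cds_features}
    n_tpn = sum(1 for gid in flagged if _is_transposase(by_id[gid]))
    return ParalogSummary(
        n_genes=n_genes,
        n_paralogous_genes=len(flagged),
        percent_cds=100.0 * len(flagged) / n_genes,
        percent_transposase_of_paralogs=(
            100.0 * n_tpn / len(flagged) if flagged else 0.0
        ),
        pairs=sorted(set(passing)),
    )


def hits_to_frame(hits: Sequence[CodingHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "replicon": h.replicon_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "frame": h.frame,
            }
            for h in hits
        ],
        columns=["replicon", "start", "end", "strand", "frame"],
    )
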