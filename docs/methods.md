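# Methods

`cyanoarch` analyses the interplay between insertion-sequence (IS)
elements, secondary-metabolite (SM) biosynthesis gene clusters, and
chromosomal rearrangements on complete bacterial (cyanobacterial)
genomes. Because complete, consistently annotated genome sets are rarely
at hand, every stage is exercised against a seeded synthetic-genome
generator with planted ground truth; this note describes the models,
the parameters that matter, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Coordinates and topology

All coordinates are 0-based half-open internally; GFF3 on disk is 1-based
inclusive. Replicons are circular or linear. Features may not span the
circular origin: the generator rotates nothing across the origin and the
reader rejects features extending past the sequence end. This keeps all
interval arithmetic total; the cost is that a real genome whose
annotation crosses the origin must be rotated before import.

The distance primitive is the *circular gap*: the minimum number of
nucleotides strictly between two interval edges along either arc, zero
for overlap or abutment. Distances are edge-to-edge, not
midpoint-based, so an IS copy inside a cluster span has distance 0 —
consistent with counting in-cluster IS copies separately. Strand is
ignored in all distance and enrichment computations.

## Synthetic genomes

`synthetic_data.simulate_genome` draws a uniform-composition background
sequence (GC default 0.39, matching the ~37–40% GC of the emulated
genomes), then plants, without overlap:

- **IS copies** from a library of consensus "elements". Each consensus
  is a single uninterrupted ORF (ATG, sense codons, one stop),
  mimicking a transposase coding sequence of 0.9–1.65 kbp. Full-length
  copies are the consensus mutated at the configured divergence
  (substitutions only, no indels, so planted identity is analytically
  1 − divergence); fragments are contiguous sub-spans of 20–70% of the
  consensus (uniform), guaranteeing separation from the ≥ 95%
  full-length criterion. Substitutions in full-length copies that would
  create an in-frame stop codon are redrawn, because a planted "full"
  copy must remain a valid full-length element by construction.
- **SM gene clusters** as runs of consecutive `cluster_gene` CDS
  features with short intergenic gaps. The default test-scale
  configuration plants seven clusters named after the *Planktothrix*
  pathways (mcy, aer, apn, oci, mic, mvd, pag) with gene counts and
  spans loosely following the published cluster sizes (5–26 kbp).
- **Anchor genes** every `anchor_spacing` bp (default 10 kbp), the
  synthetic stand-in for conserved single-copy genes used in synteny
  analysis.

Default scale is a 1 Mbp chromosome (roughly a 1:5 scale model of the
4.7–6.6 Mbp chromosomes it emulates) carrying ~2–3% IS nucleotides from
five groups — inside the 0.8–3.7% chromosomal range reported for the
emulated genomes. A single seeded NumPy generator drives each
simulation; identical config + seed gives byte-identical output.

`derive_rearranged_genome` applies disjoint inversions
(reverse-complement in place, contained features re-coordinated with
flipped strand; a feature straddling a boundary is an error) and
records the true breakpoints. Optional breakpoint enrichment plants
extra IS copies whose gap from the breakpoint is exponential with a
configurable decay scale, truncated at the chromosome ends and
rejection-sampled against overlap.

What the generator does **not** emulate: transposition dynamics, indel
divergence, terminal inverted repeats/direct repeats, codon structure of
the background, gene content realism, HGT, or plasmid mobilization.
Recovery results on synthetic genomes therefore demonstrate algorithmic
correctness under the stated noise model, not performance on real
annotations (where diverged paralogous transposase families and indels
make detection harder).

## IS catalog

Detection replaces BLAST e-value thresholds with explicit,
interpretable thresholds: minimum match length 100 bp and minimum
identity 0.80 (both configurable). E-values depend on database size and
scoring system; a length/identity pair does not, and the defaults are
calibrated so that random megabase genomes yield zero false hits.

The search is seed-and-extend: exact k-mers (k = 12) shared between the
genome and each oriented consensus seed candidate windows; windows
supported by at least `min_seed_hits` (3) seeds are refined by local
alignment (match +1, mismatch −1, gap open −2, extend −1; ties broken
by the leftmost alignment). After a match is accepted, the window's
flanks are re-scanned recursively so two nearby copies of the same
element are both found. Overlapping candidates are resolved by highest
identity, then length, then leftmost position. The seed-support
threshold is what keeps the scan near-linear: a random 12-mer match on
a 1 Mbp genome is common, three co-located ones are not; a genuine
borderline match (100 bp at 80% identity) still carries ~6 expected
intact 12-mers.

Grouping is single-linkage clustering — the transitive closure matching
how BLAST-similarity grouping behaves — with linkage defined as
alignment identity ≥ 0.80 **and** coverage of the shorter sequence
≥ 0.60. Both conditions matter: local alignment of unrelated sequences
always contains short perfect matches of identity ≈ 1 at negligible
coverage. Components containing a library consensus inherit its group
id; the rest are numbered deterministically by leftmost member.

Classification calls a copy **full** iff its matched span covers ≥ 95%
of the group consensus and the copy's sequence, translated in the frame
of the consensus ORF (bacterial code, table 11), contains no internal
stop over ≥ 90% of that ORF; otherwise **fragment**. The published
workflow additionally used copy-number context ("shorter sequences
occurring in higher copy number") to call fragments; that rule is not
per-copy testable, so classification here is span + ORF only and
copy-number context is reported separately in the group matrices.

## Cluster location, distances, and statistics

Clusters are located by gene name; a run breaks where consecutive
present genes are > 5 kbp apart. States: **complete** (all required
genes in one run), **remnant** (< 25% of required genes present —
e.g. a single *mcyT* left from a lost *mcy* cluster), **partial**
(otherwise), **absent**. The 25% remnant threshold and 5 kbp gap are
package choices; the source data distinguish these states only
qualitatively.

Net distances (circular gap between each IS copy and each cluster span
on the same replicon) are tested against normality with a one-sample
Kolmogorov–Smirnov statistic whose reference normal has mean and sd
estimated from the sample. Estimated parameters make the classical K-S
null anti-conservative, so the p-value is Monte Carlo
(Lilliefors-style): the null distribution of the statistic is simulated
(default 10,000 seeded replicates, cached per sample size) and the
p-value is the usual (1 + #{D₀ ≥ D}) / (N + 1). Calibration is verified
by the acceptance suite: the rejection rate on normal samples at
α = 0.05 lies inside the central 99% binomial envelope over 200 trials.

Vicinity profiles report the IS nucleotide fraction in the two flanks
(± w for w = 10, 20, 30 kbp, circular wrap, pooled across both flanks,
per-flank values also emitted) against the whole-chromosome background
(cluster span included). Meta-clusters are single-linkage groups of
clusters with pairwise circular gap ≤ 300 kbp (the scale of the
inversion that colocalizes the mvd–apn–oci clusters); groups of ≥ 2 are
reported with the length of the shorter covering arc.

## Synteny blocks and breakpoints

Anchors are matched one-to-one by feature id (ambiguous ids dropped
with a warning). Blocks are built by a greedy left-to-right scan in
genome-A order: a run extends while the next anchor moves strictly
monotonically in B, both gaps are ≤ 50 kbp, and the B-step tracks the
A-step to within a 20 kbp diagonal drift. The drift bound is essential:
without it, the first anchor inside an inversion occasionally continues
the preceding run (its B-jump can be numerically small) and the
breakpoint shifts by one anchor spacing. Runs of < 3 anchors are
discarded as noise; this suppresses single-gene transpositions and
chance monotone runs. On circular genomes, the first and last runs are
merged into one origin-wrapping block when they continue each other, so
a single inversion yields two blocks and two breakpoint regions (with
`circular=False` the same data yield the three blocks of a linear
reading).

A breakpoint region is centered at the midpoint between the last anchor
of one block and the first anchor of the next (circular adjacency
included). The midpoint is the maximum-entropy localization; its error
is bounded by half the anchor spacing, which is why recovery is tested
at a ± 10 kbp tolerance with 10 kbp anchors. The IS profile around
breakpoints pools the window union across regions (overlaps counted
once) and also emits per-region fractions and ± 10 kbp copy counts.

This block finder is deliberately greedy rather than an optimal
chaining or common-intervals algorithm: the rearrangements of interest
are few and large (tens to hundreds of kbp). It will not resolve
micro-rearrangements below the anchor spacing.

## Back-translation and paralogs

Degenerate back-translation uses translation table 11 sense codons; the
count is the product of per-residue codon degeneracies (the 8-residue
planktocyclin core P-G-L-V-M-F-G-V gives 4·4·6·4·1·2·4·4 = 12,288
24-mers). Genome scanning translates all six frames and
substring-matches the peptide — linear time versus the size of the
enumeration — and a test enforces equivalence with exhaustive
enumeration + string search rather than assuming it. The expected
number of chance exact hits in a random genome is ≈ 2L·12288/4²⁴ ≪ 1
per Mbp, so a single hit is informative.

Paralogs: all CDS pairs are aligned; a pair passes at identity ≥ 0.97
and aligned coverage > 0.90 of the query, evaluated in both query
directions (a pair passes if either direction passes, making the result
order-independent). A shared-k-mer prefilter (≥ 4 shared 12-mers) skips
pairs that cannot approach the identity cutoff; pairs near the
threshold always share hundreds of exact 12-mers, and an edit-distance
brute-force oracle test checks end-to-end equality. Summaries count
genes, not pairs; the transposase share is computed over paralogous
genes flagged as transposases.

## Problem sizes and defaults used in the shipped benchmarks

Recovery suites run on 1 Mbp chromosomes: 10 seeds at 5% divergence for
catalog recovery, 20 seeded simulations with 1–5 inversions for
breakpoint recovery, 8–10 simulations for enrichment profiles, 200
trials of n = 500 for K-S calibration. These sizes give the reported
rates sampling errors well below the asserted margins while keeping a
full run in minutes on one core. `scripts/acceptance.py` recomputes the
same quantities from scratch at slightly reduced replication (4 catalog
seeds, 8 breakpoint simulations) and additionally reports the
chromosome-size vs %IS regression on the bundled 13-genome summary
(R² = 0.793 on the printed values; the published legend value 0.81 was
computed on unrounded data) and an enrichment profile on
study-emulating genomes (normal IS complement plus one short extra
copy per breakpoint), whose breaking-region vs background contrast
(~5–6% vs ~3%) mirrors the ~2× contrast reported for real chromosomes
(1.9–4.5% vs 0.9–2.6%).

## Known limitations

- No indel model in the generator; detection on real, indel-diverged
  copies will trim spans more aggressively than the ± 10 bp recovered
  here.
- Origin-spanning features are unsupported (rotate real genomes first).
- The block finder assumes a single circular chromosome pair and few,
  large rearrangements; it is not a general rearrangement-distance
  tool.
- `classify_copy` maps consensus ORF coordinates onto the copy by
  offset, exact for substitution-only divergence; large indels would
  shift the frame mapping.
- The K-S null cache is per (n, replicates, seed); extremely many
  distinct sample sizes would grow memory linearly.
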