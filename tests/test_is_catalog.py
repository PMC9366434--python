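"""IS detection, grouping, classification, and summaries."""

import numpy as np
import pytest

from cyanoarch.datasets import planktothrix_genome_summary
from cyanoarch.genome_core import CIRCULAR, Interval, Replicon
from cyanoarch.is_catalog import (
    ISCopy,
    align_identity,
    classify_copy,
    find_is_copies,
    group_is_copies,
    is_stats,
    longest_orf,
    size_vs_is_regression,
)
from cyanoarch.synthetic_data import (
    random_dna,
    random_orf_sequence,
    reverse_complement,
)


class TestAlignIdentity:
    def test_identical_sequences(self, rng):
        seq = random_dna(500, rng)
        res = align_identity(seq, seq)
        assert res.identity == 1.0
        assert res.coverage_of_shorter == 1.0
        assert res.span_a == (0, 500)

    def test_reverse_complement_requires_orientation(self, rng):
        """The caller must try both orientations: the RC orientation aligns
        perfectly while the forward orientation shows no full-length
        similarity (only short chance matches)."""
        seq = random_dna(400, rng)
        rc = reverse_complement(seq)
        rc_res = align_identity(reverse_complement(rc), seq)
        assert rc_res.identity == 1.0 and rc_res.coverage_of_shorter == 1.0
        fwd = align_identity(seq, rc)
        assert fwd.identity < 1.0 or fwd.coverage_of_shorter < 0.5

    def test_fifteen_substitutions_give_095(self, rng):
        """300-mer with 15 interior substitutions: identity exactly 0.95."""
        seq = random_dna(300, rng)
        positions = list(range(10, 300 - 10, 19))[:15]
        assert len(positions) == 15
        chars = list(seq)
        for p in positions:
            chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
        mutated = "".join(chars)
        res = align_identity(seq, mutated)
        assert res.identity == pytest.approx(285 / 300)
        assert res.coverage_of_shorter == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_identity("", "ACGT")


class TestFindISCopies:
    def test_recovers_all_planted_copies(self, library, small_sim, cataloged):
        replicons, truth = small_sim
        assert len(cataloged) == len(truth.is_copies)
        detected = sorted(cataloged, key=lambda c: c.interval.start)
        for t in sorted(truth.is_copies, key=lambda t: t.start):
            match = [
                c
                for c in detected
                if c.interval.start < t.end and t.start < c.interval.end
            ]
            assert len(match) == 1
            c = match[0]
            assert c.interval.strand == t.strand
            assert c.group_id == t.group_id
            if t.state == "full":
                # full copies recovered within +/- 10 bp of the planted span
                assert abs(c.interval.start - t.start) <= 10
                assert abs(c.interval.end - t.end) <= 10

    def test_random_genome_yields_no_hits(self, library):
        for seed in (101, 102):
            rng = np.random.default_rng(seed)
            rep = Replicon(
                id=f"rand{seed}", topology=CIRCULAR,
                sequence=random_dna(500_000, rng, 0.39),
            )
            assert find_is_copies(rep, library) == []

    def test_empty_library_rejected(self, small_sim):
        with pytest.raises(ValueError):
            find_is_copies(small_sim[0][0], {})


class TestGrouping:
    def test_recovery_with_library(self, small_sim, cataloged):
        _, truth = small_sim
        truth_by_pos = {t.start: t.group_id for t in truth.is_copies}
        for c in cataloged:
            # match by overlap with the planted record
            t_group = next(
                g for s, g in truth_by_pos.items()
                if abs(s - c.interval.start) < 2000
                and any(
                    t.start < c.interval.end and c.interval.start < t.end
                    for t in truth.is_copies if t.group_id == g and t.start == s
                )
            )
            assert c.group_id == t_group

    def test_order_invariance(self, library, cataloged, rng):
        perm = list(rng.permutation(len(cataloged)))
        shuffled = [cataloged[i] for i in perm]
        regrouped = group_is_copies(shuffled, library=library)
        original = group_is_copies(cataloged, library=library)
        by_pos_a = {c.interval.start: c.group_id for c in original}
        by_pos_b = {c.interval.start: c.group_id for c in regrouped}
        assert by_pos_a == by_pos_b

    def test_identical_copies_share_group_without_library(self, rng):
        seq = random_orf_sequence(600, rng)
        copies = [
            ISCopy("chr", Interval(0, 600, "+"), seq),
            ISCopy("chr", Interval(1000, 1600, "+"), seq),
        ]
        grouped = group_is_copies(copies)
        assert grouped[0].group_id == grouped[1].group_id

    def test_empty_input(self):
        assert group_is_copies([]) == []


class TestClassify:
    def make_copy(self, seq, consensus, span=None):
        return ISCopy(
            "chr",
            Interval(0, len(seq), "+"),
            seq,
            group_id="g",
            matched_span_on_consensus=span or (0, len(seq)),
        )

    def test_planted_full_copies_classified_full(self, small_sim, cataloged):
        _, truth = small_sim
        truth_states = {t.start: t.state for t in truth.is_copies}
        for c in cataloged:
            planted_state = next(
                st for s, st in truth_states.items()
                if abs(s - c.interval.start) <= 100
            )
            assert c.state == planted_state

    def test_truncated_copy_is_fragment(self, library):
        cons = library["group_1"]
        n = int(0.4 * len(cons))
        copy = self.make_copy(cons[:n], cons, span=(0, n))
        assert classify_copy(copy, cons) == "fragment"

    def test_engineered_internal_stop_is_fragment(self, library):
        cons = library["group_1"]
        mid = (len(cons) // 2 // 3) * 3  # in-frame interior codon start
        broken = cons[:mid] + "TAA" + cons[mid + 3 :]
        copy = self.make_copy(broken, cons)
        assert classify_copy(copy, cons) == "fragment"
        intact = self.make_copy(cons, cons)
        assert classify_copy(intact, cons) == "full"

    def test_span_extension_is_monotone(self, library):
        """Growing a prefix fragment toward the full consensus never flips
        full -> fragment."""
        cons = library["group_1"]
        states = []
        for frac in np.linspace(0.3, 1.0, 15):
            n = int(frac * len(cons))
            copy = self.make_copy(cons[:n], cons, span=(0, n))
            states.append(classify_copy(copy, cons))
        seen_full = False
        for s in states:
            if s == "full":
                seen_full = True
            assert not (seen_full and s == "fragment")
        assert states[-1] == "full"

    def test_unassigned_group_rejected(self, library):
        copy = ISCopy("chr", Interval(0, 100, "+"), "A" * 100)
        with pytest.raises(ValueError):
            classify_copy(copy, library["group_1"])

    def test_longest_orf_spans_generated_consensus(self, library):
        for cons in library.values():
            assert longest_orf(cons) == (0, len(cons))


class TestStats:
    def test_summary_matches_truth(self, small_sim, cataloged):
        replicons, truth = small_sim
        stats = is_stats(replicons, cataloged)
        row = stats.per_replicon.loc["chr"]
        assert row["n_full"] == sum(1 for t in truth.is_copies if t.state == "full")
        assert row["n_fragment"] == sum(
            1 for t in truth.is_copies if t.state == "fragment"
        )
        assert row["n_full"] + row["n_fragment"] == row["n_total"]
        expected_pct = (
            100.0
            * sum(t.end - t.start for t in truth.is_copies)
            / replicons[0].length
        )
        assert row["is_percent"] == pytest.approx(expected_pct, rel=0.02)
        # matrix column sums equal totals
        total = (
            stats.group_matrix_full["chr"].sum()
            + stats.group_matrix_fragment["chr"].sum()
        )
        assert total == row["n_total"]

    def test_no_copies_all_zero(self, small_sim):
        replicons, _ = small_sim
        stats = is_stats(replicons, [])
        assert (stats.per_replicon["n_total"] == 0).all()
        assert (stats.per_replicon["is_percent"] == 0.0).all()


class TestRegression:
    def test_collinear_r2_is_one(self):
        pts = [(1.0, 2.0), (2.0, 4.0), (3.0, 6.0), (4.0, 8.0)]
        slope, intercept, r2 = size_vs_is_regression(pts)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)

    def test_constant_response_r2_zero(self):
        assert size_vs_is_regression([(1, 5), (2, 5), (3, 5)])[2] == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            size_vs_is_regression([(1, 1), (2, 2)])

    def test_zero_x_variance(self):
        with pytest.raises(ValueError):
            size_vs_is_regression([(1, 1), (1, 2), (1, 3)])

    def test_published_genome_summary(self):
        """The 13 published (chromosome size, %IS) pairs give R^2 = 0.7933
        (closed-form OLS on the printed values; the figure-legend value 0.81
        was computed on unrounded data)."""
        df = planktothrix_genome_summary()
        pts = list(zip(df["chromosome_mb"], df["is_percent_chromosome"]))
        slope, intercept, r2 = size_vs_is_regression(pts)
        # independent closed form via the correlation coefficient
        expected = float(
            np.corrcoef(df["chromosome_mb"], df["is_percent_chromosome"])[0, 1] ** 2
        )
        assert r2 == pytest.approx(expected)
        assert r2 == pytest.approx(0.79327, abs=5e-4)
        assert slope > 0
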