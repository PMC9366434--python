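"""Cluster location/state, net distances, K-S normality, vicinity, meta-clusters."""

import numpy as np
import pytest

from cyanoarch.genome_core import CIRCULAR, Feature, Interval, Replicon
from cyanoarch.is_catalog import ISCopy
from cyanoarch.sm_clusters_distances import (
    ClusterInstance,
    ClusterModel,
    ks_normality,
    locate_clusters,
    meta_cluster_detect,
    net_distance_table,
    vicinity_is_frequency,
)
from cyanoarch.synthetic_data import derive_rearranged_genome, random_dna

from .helpers import walking_gap


def toy_replicon(gene_spans, length=60_000, seed=0, extra_features=()):
    """Replicon with cluster_gene features at the given (gene, start, end)."""
    rng = np.random.default_rng(seed)
    feats = [
        Feature(
            f"{gene}_{i}", "cluster_gene", Interval(s, e, "+"), {"gene": gene}
        )
        for i, (gene, s, e) in enumerate(gene_spans)
    ]
    feats.extend(extra_features)
    return Replicon(
        id="toy", topology=CIRCULAR, sequence=random_dna(length, rng), features=feats
    )


MODEL = ClusterModel("apn", ["apnA", "apnB", "apnC", "apnD", "apnE"])


class TestLocateClusters:
    def test_complete_cluster(self):
        spans = [(f"apn{c}", 1000 + i * 1200, 2000 + i * 1200) for i, c in enumerate("ABCDE")]
        rep = toy_replicon(spans)
        (inst,) = locate_clusters(rep, [MODEL])
        assert inst.state == "complete"
        assert inst.span == Interval(1000, 2000 + 4 * 1200)

    def test_remnant_single_gene_of_ten(self):
        model = ClusterModel("mcy", [f"mcy{c}" for c in "TABCDEFGHJ"])
        rep = toy_replicon([("mcyT", 5000, 6000)])
        (inst,) = locate_clusters(rep, [model])
        assert inst.state == "remnant"  # 1/10 < 25% of required genes

    def test_partial_cluster(self):
        spans = [(f"apn{c}", 1000 + i * 1200, 2000 + i * 1200) for i, c in enumerate("ABC")]
        rep = toy_replicon(spans)
        (inst,) = locate_clusters(rep, [MODEL])
        assert inst.state == "partial"  # 3/5 genes

    def test_absent_cluster(self):
        rep = toy_replicon([("other", 100, 200)])
        (inst,) = locate_clusters(rep, [MODEL])
        assert inst.state == "absent"
        assert inst.span is None

    def test_contiguity_gap_splits_runs(self):
        # apnA..apnD contiguous, apnE 20 kbp away: run of 4 wins -> partial
        spans = [(f"apn{c}", 1000 + i * 1200, 2000 + i * 1200) for i, c in enumerate("ABCD")]
        spans.append(("apnE", 30_000, 31_000))
        rep = toy_replicon(spans)
        (inst,) = locate_clusters(rep, [MODEL])
        assert inst.state == "partial"
        assert inst.span.end == 2000 + 3 * 1200

    def test_duplicate_gene_names_warn(self):
        spans = [("apnA", 1000, 2000), ("apnA", 10_000, 11_000),
                 ("apnB", 2500, 3500)]
        rep = toy_replicon(spans)
        with pytest.warns(UserWarning, match="duplicate"):
            (inst,) = locate_clusters(rep, [MODEL])
        assert inst.span.start == 1000  # densest run

    def test_is_within_counted(self):
        spans = [(f"apn{c}", 1000 + i * 1200, 2000 + i * 1200) for i, c in enumerate("ABCDE")]
        rep = toy_replicon(spans)
        inside = Interval(2100, 2400)
        outside = Interval(50_000, 50_300)
        (inst,) = locate_clusters(rep, [MODEL], [inside, outside])
        assert inst.n_is_within == 1


class TestNetDistance:
    def make_setup(self, seed=0):
        rng = np.random.default_rng(seed)
        L = 50_000
        clusters = [
            ClusterInstance("apn", "toy", Interval(10_000, 15_000), [], "complete"),
            ClusterInstance("mvd", "toy", Interval(40_000, 42_000), [], "complete"),
        ]
        copies = []
        for _ in range(30):
            s = int(rng.integers(0, L - 500))
            copies.append(ISCopy("toy", Interval(s, s + 500), "A"))
        return copies, clusters, L

    def test_copy_inside_cluster_distance_zero(self):
        copies = [ISCopy("toy", Interval(11_000, 11_500), "A")]
        clusters = [ClusterInstance("apn", "toy", Interval(10_000, 15_000), [], "complete")]
        (rec,) = net_distance_table(copies, clusters, {"toy": 50_000})
        assert rec.net_distance == 0

    def test_matches_walking_oracle(self):
        copies, clusters, L = self.make_setup()
        records = net_distance_table(copies, clusters, {"toy": L})
        assert len(records) == len(copies) * len(clusters)
        by_key = {
            (r.is_interval.start, r.cluster_name): r.net_distance for r in records
        }
        for c in copies:
            for cl in clusters:
                expected = walking_gap(c.interval, cl.span, L, "circular")
                assert by_key[(c.interval.start, cl.model_name)] == expected

    def test_rotation_invariance(self):
        copies, clusters, L = self.make_setup()
        k = 6_543
        rot_copies = [
            ISCopy("toy", Interval((c.interval.start + k) % L,
                                   (c.interval.start + k) % L + 500), "A")
            for c in copies
            if (c.interval.start + k) % L + 500 <= L  # skip origin-crossers
        ]
        kept = [c for c in copies if (c.interval.start + k) % L + 500 <= L]
        rot_clusters = [
            ClusterInstance(cl.model_name, "toy",
                            Interval(cl.span.start + k, cl.span.end + k), [], cl.state)
            for cl in clusters
        ]
        orig = net_distance_table(kept, clusters, {"toy": L})
        rot = net_distance_table(rot_copies, rot_clusters, {"toy": L})
        assert [r.net_distance for r in orig] == [r.net_distance for r in rot]

    def test_cross_replicon_pairs_skipped(self):
        copies = [ISCopy("plasmid", Interval(0, 100), "A")]
        clusters = [ClusterInstance("apn", "toy", Interval(10, 20), [], "complete")]
        assert net_distance_table(copies, clusters, {"toy": 1000}) == []


class TestKSNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([5.0] * 10)

    def test_uniform_sample_rejected_as_non_normal(self):
        rng = np.random.default_rng(1)
        sample = rng.uniform(0, 500_000, size=500)
        d, p, reject = ks_normality(sample, alpha=0.01, n_mc=2000)
        assert p < 0.01
        assert reject

    def test_normal_sample_usually_accepted(self):
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(30):
            sample = rng.normal(100_000, 20_000, size=500)
            _, _, reject = ks_normality(sample, alpha=0.05, n_mc=2000)
            rejections += reject
        assert rejections <= 6  # ~alpha * 30 expected; generous bound

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(0, 1, size=100)
        assert ks_normality(sample, n_mc=1000) == ks_normality(sample, n_mc=1000)


class TestVicinity:
    def cluster_at(self, start, end):
        return ClusterInstance("apn", "toy", Interval(start, end), [], "complete")

    def test_no_is_nearby_all_zero(self):
        rep = toy_replicon([], length=200_000)
        cl = self.cluster_at(100_000, 110_000)
        out = vicinity_is_frequency(cl, [Interval(0, 500)], rep)
        assert all(v == 0.0 for v in out["window_fraction"].values())
        assert out["background"] > 0

    def test_dilution_when_is_only_in_first_flank(self):
        rep = toy_replicon([], length=200_000)
        cl = self.cluster_at(100_000, 110_000)
        # 4 kbp of IS inside the 10 kbp right flank only
        ivs = [Interval(111_000, 113_000), Interval(114_000, 116_000)]
        out = vicinity_is_frequency(cl, ivs, rep)
        f = out["window_fraction"]
        assert f[10_000] > f[20_000] > f[30_000] > 0

    def test_circular_wrap(self):
        rep = toy_replicon([], length=200_000)
        cl = self.cluster_at(2_000, 8_000)  # left flank wraps the origin
        ivs = [Interval(195_000, 196_000)]  # sits in the wrapped flank
        out = vicinity_is_frequency(cl, ivs, rep)
        assert out["window_fraction"][10_000] == pytest.approx(1000 / 20_000)

    def test_window_exceeding_half_replicon_rejected(self):
        rep = toy_replicon([], length=40_000)
        cl = self.cluster_at(10_000, 12_000)
        with pytest.raises(ValueError):
            vicinity_is_frequency(cl, [], rep, windows=[30_000])

    def test_uniform_density_close_to_background(self):
        rng = np.random.default_rng(4)
        rep = toy_replicon([], length=500_000)
        ivs = []
        for s in range(0, 500_000 - 1000, 5_000):  # exactly uniform tiling
            ivs.append(Interval(s, s + 1000))
        cl = self.cluster_at(200_000, 220_000)
        out = vicinity_is_frequency(cl, ivs, rep)
        for v in out["window_fraction"].values():
            assert abs(v - out["background"]) < 0.05


class TestMetaClusters:
    def inst(self, name, start, end):
        return ClusterInstance(name, "toy", Interval(start, end), [], "complete")

    def test_three_close_clusters_form_meta(self):
        clusters = [
            self.inst("mvd", 100_000, 105_000),
            self.inst("apn", 130_000, 154_000),
            self.inst("oci", 180_000, 210_000),
        ]
        metas = meta_cluster_detect(clusters, {"toy": 1_000_000})
        assert len(metas) == 1
        assert metas[0].members == ["mvd", "apn", "oci"]
        assert metas[0].total_span == 110_000

    def test_distant_clusters_no_meta(self):
        clusters = [self.inst("mvd", 0, 5_000), self.inst("apn", 500_000, 505_000)]
        assert meta_cluster_detect(clusters, {"toy": 1_000_000}) == []

    def test_order_invariance(self):
        clusters = [
            self.inst("oci", 180_000, 210_000),
            self.inst("mvd", 100_000, 105_000),
            self.inst("apn", 130_000, 154_000),
        ]
        metas = meta_cluster_detect(clusters, {"toy": 1_000_000})
        assert metas[0].members == ["mvd", "apn", "oci"]

    def test_inversion_creates_meta_cluster(self):
        """An inversion moving two clusters next to a third creates the
        colocalized meta-cluster that was absent before."""
        gene_spans = (
            [("mvdA", 40_000, 44_000), ("mvdB", 44_100, 48_100)]
            + [("apnA", 300_000, 304_000), ("apnB", 304_100, 308_100)]
            + [("ociA", 330_000, 334_000), ("ociB", 334_100, 338_100)]
        )
        rep = toy_replicon(gene_spans, length=1_000_000)
        models = [
            ClusterModel("mvd", ["mvdA", "mvdB"]),
            ClusterModel("apn", ["apnA", "apnB"]),
            ClusterModel("oci", ["ociA", "ociB"]),
        ]
        lengths = {"toy": rep.length, "toy_derived": rep.length}

        before = locate_clusters(rep, models)
        metas_before = meta_cluster_detect(before, lengths, max_gap=100_000)
        assert not any("mvd" in m.members for m in metas_before)

        derived, _ = derive_rearranged_genome(rep, [(60_000, 350_000)], seed=0)
        after = locate_clusters(derived, models)
        metas_after = meta_cluster_detect(after, lengths, max_gap=100_000)
        assert len(metas_after) == 1
        assert set(metas_after[0].members) == {"mvd", "apn", "oci"}
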