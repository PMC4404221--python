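"""Depth filtering, clustering backends, class labeling, and summaries."""

import numpy as np
import pandas as pd
import pytest

import spikegbs as sg
from spikegbs.calling import MISSING, UNCLASSIFIED, ClusterAssignment

from .oracles import check_dbscan_against_oracle


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "locus_id",
                                       "count_a", "count_b", "count_unmatched"])


def freq_points(freqs, locus="locus1", depth=100):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(freqs))],
            "locus_id": locus,
            "depth": depth,
            "freq_a": list(freqs),
            "freq_b": [1 - f for f in freqs],
        }
    )


class TestDepthFilter:
    @pytest.mark.parametrize(
        "count_a,count_b,kept",
        [(4, 5, False),    # total 9: below the 10-read floor
         (10, 0, True),    # total 10: boundary is inclusive
         (0, 0, False)],
    )
    def test_ten_read_boundary(self, count_a, count_b, kept):
        table = counts_frame([("s1", "L", count_a, count_b, 0)])
        out = sg.depth_filter(table, min_depth=10)
        assert (len(out) == 1) == kept
        if kept:
            assert out.loc[0, "freq_a"] == count_a / (count_a + count_b)

    def test_unmatched_reads_do_not_count_toward_depth(self):
        table = counts_frame([("s1", "L", 4, 4, 50)])
        assert sg.depth_filter(table, min_depth=10).empty

    def test_freq_sums_to_one(self):
        table = counts_frame([("s1", "L", 7, 13, 0)])
        out = sg.depth_filter(table, min_depth=10)
        assert abs(out.loc[0, "freq_a"] + out.loc[0, "freq_b"] - 1) < 1e-12


class TestKmeans:
    def test_perfectly_separated_three_clusters(self):
        pts = freq_points([0.0] * 10 + [0.5] * 10 + [1.0] * 10)
        out = sg.call_kmeans(pts, k=3, seed=0)
        assert np.allclose(sorted(out.centroids), [0.0, 0.5, 1.0])
        # ids are ordered by ascending centroid
        assert list(out.cluster_ids) == [0] * 10 + [1] * 10 + [2] * 10

    def test_k_one_returns_mean(self):
        pts = freq_points([0.2, 0.4, 0.9])
        out = sg.call_kmeans(pts, k=1, seed=0)
        assert out.n_clusters == 1
        assert np.isclose(out.centroids[0], np.mean([0.2, 0.4, 0.9]))

    def test_k_exceeding_points_rejected(self):
        with pytest.raises(sg.ValidationError):
            sg.call_kmeans(freq_points([0.1, 0.9]), k=3, seed=0)

    def test_never_unclassified_and_deterministic(self):
        rng = np.random.default_rng(0)
        pts = freq_points(rng.random(40))
        a = sg.call_kmeans(pts, k=3, seed=7)
        b = sg.call_kmeans(pts, k=3, seed=7)
        assert (a.cluster_ids >= 0).all()
        assert np.array_equal(a.cluster_ids, b.cluster_ids)


class TestDbscan:
    def test_three_tight_groups(self):
        rng = np.random.default_rng(1)
        freqs = np.concatenate(
            [c + rng.uniform(-0.01, 0.01, 10) for c in (0.0, 0.5, 1.0)]
        ).clip(0, 1)
        out = sg.call_dbscan(freq_points(freqs), eps=0.1, min_pts=4)
        assert out.n_clusters == 3
        assert (out.cluster_ids != UNCLASSIFIED).all()
        check_dbscan_against_oracle(freqs, out.cluster_ids, 0.1, 4)

    def test_isolated_point_is_noise(self):
        freqs = [0.0] * 6 + [1.0] * 6 + [0.75]
        out = sg.call_dbscan(freq_points(freqs), eps=0.1, min_pts=4)
        assert out.cluster_ids[-1] == UNCLASSIFIED

    def test_large_eps_single_cluster(self):
        out = sg.call_dbscan(freq_points([0.0, 0.3, 0.6, 0.9]), eps=1.5, min_pts=2)
        assert out.n_clusters == 1
        assert (out.cluster_ids == 0).all()

    def test_matches_brute_force_oracle_on_random_sets(self):
        """Exhaustive density-reachability check on many small point sets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(5, 31))
            freqs = rng.random(n)
            eps = float(rng.uniform(0.02, 0.3))
            min_pts = int(rng.integers(2, 6))
            out = sg.call_dbscan(freq_points(freqs), eps=eps, min_pts=min_pts)
            check_dbscan_against_oracle(freqs, out.cluster_ids, eps, min_pts)


class TestLabelClusters:
    def _assignment(self, centroids, ids, method="kmeans", locus="locus1"):
        return ClusterAssignment(
            locus_id=locus, method=method,
            sample_ids=[f"s{i}" for i in range(len(ids))],
            cluster_ids=np.asarray(ids),
            centroids=np.asarray(centroids),
        )

    def test_biallelic_nearest_fraction(self, biallelic_marker):
        a = self._assignment([0.02, 0.51, 0.98], [0, 1, 2])
        out = sg.label_clusters(a, biallelic_marker)
        assert out["label"].tolist() == ["B", "Heterozygous", "A"]

    def test_hexaploid_dosage_labels(self, toy_markers):
        marker = toy_markers[1]  # dosage model (1, 2/3, 1/3, 0)
        a = self._assignment([0.34, 0.66, 0.99], [0, 1, 2], locus="locus2")
        out = sg.label_clusters(a, marker)
        assert out["label"].tolist() == ["AABBBB", "AAAABB", "AAAAAA"]

    def test_two_clusters_claiming_one_class_is_error(self, biallelic_marker):
        a = self._assignment([0.45, 0.55], [0, 1])
        with pytest.raises(sg.LabelingError):
            sg.label_clusters(a, biallelic_marker)

    def test_unclassified_becomes_missing(self, biallelic_marker):
        a = self._assignment([0.0, 1.0], [0, UNCLASSIFIED, 1], method="dbscan")
        out = sg.label_clusters(a, biallelic_marker)
        assert out["label"].tolist() == ["B", MISSING, "A"]

    def test_more_clusters_than_classes_is_error(self, biallelic_marker):
        a = self._assignment([0.0, 0.3, 0.6, 1.0], [0, 1, 2, 3])
        with pytest.raises(sg.LabelingError):
            sg.label_clusters(a, biallelic_marker)

    def test_point_order_does_not_change_labels(self, biallelic_marker):
        """Cluster ids are internal; labels depend only on the data."""
        rng = np.random.default_rng(3)
        freqs = np.concatenate(
            [c + rng.uniform(-0.02, 0.02, 8) for c in (0.0, 0.5, 1.0)]
        ).clip(0, 1)
        pts = freq_points(freqs)
        shuffled = pts.sample(frac=1, random_state=1).reset_index(drop=True)
        for make in (lambda p: sg.call_kmeans(p, 3, seed=0),
                     lambda p: sg.call_dbscan(p, 0.1, 4)):
            l1 = sg.label_clusters(make(pts), biallelic_marker)
            l2 = sg.label_clusters(make(shuffled), biallelic_marker)
            merged = l1.merge(l2, on="sample_id", suffixes=("_a", "_b"))
            assert (merged["label_a"] == merged["label_b"]).all()


class TestConcordance:
    def _gm(self, labels):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(labels))],
                "locus_id": "L",
                "label": labels,
                "method": "kmeans",
                "cluster_id": 0,
            }
        )

    def test_identical_matrices(self):
        g = self._gm(["A", "B", "Heterozygous", "A"])
        assert sg.concordance(g, g) == (1.0, 1.0, 4)

    def test_missing_cells_split_the_two_readings(self):
        g1 = self._gm(["A", "B", "A", "B"])
        g2 = self._gm(["A", "B", MISSING, MISSING])
        overall, co, n_co = sg.concordance(g1, g2)
        assert (overall, co, n_co) == (0.5, 1.0, 2)

    def test_mismatched_domains_rejected(self):
        g1 = self._gm(["A", "B"])
        g2 = self._gm(["A", "B", "A"])
        with pytest.raises(sg.InputError):
            sg.concordance(g1, g2)


class TestMarkerSummary:
    def test_call_rate_arithmetic(self):
        labels = ["A"] * 150 + [MISSING] * 3
        gm = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(153)],
                "locus_id": "L",
                "label": labels,
                "method": "kmeans",
                "cluster_id": 0,
            }
        )
        table = counts_frame([(f"s{i}", "L", 20, 0, 0) for i in range(153)])
        out = sg.marker_summary(gm, table, n_samples=153)
        assert out.loc[0, "call_rate"] == pytest.approx(150 / 153)
        assert f"{out.loc[0, 'call_rate'] * 100:.1f}" == "98.0"

    def test_no_passing_samples_reports_na(self):
        gm = pd.DataFrame(
            {"sample_id": ["s1"], "locus_id": ["L"], "label": [MISSING],
             "method": ["kmeans"], "cluster_id": [UNCLASSIFIED]}
        )
        table = counts_frame([("s1", "L", 2, 3, 0)])
        out = sg.marker_summary(gm, table)
        assert out.loc[0, "call_rate"] == 0.0
        assert np.isnan(out.loc[0, "avg_depth"])


class TestRecovery:
    def make_counts(self, seed, n=200, depth_mean=50, error=0.01):
        markers = [sg.MarkerDefinition(
            "L", "ACGGTACT", "TTGACCAT", "CAGTTAGCAT", "CAGTCAGCAT"
        )]
        samples = [f"s{i:03d}" for i in range(n)]
        truth = sg.simulate_truth(
            samples, markers,
            {"L": {"A": 0.4, "Heterozygous": 0.2, "B": 0.4}}, seed=seed,
        )
        counts = sg.simulate_allele_counts(
            truth, sg.DepthModel(mean=depth_mean), seed=seed + 1,
            error_rate=error,
        )
        return markers, truth, counts

    @pytest.mark.parametrize("method", ["kmeans", "dbscan"])
    def test_both_callers_recover_truth(self, method):
        """Called genotypes match simulated truth on a standard 3-class locus."""
        from spikegbs.pipeline import genotype_recovery

        for seed in (10, 20, 30):
            markers, truth, counts = self.make_counts(seed)
            gm = sg.call_genotypes(counts, markers, method=method, seed=0)
            assert genotype_recovery(gm, truth) >= 0.99

    def test_methods_agree_on_separated_clusters(self):
        for seed in (1, 2, 3, 4, 5):
            markers, truth, counts = self.make_counts(seed, depth_mean=100,
                                                      error=0.0)
            gk = sg.call_genotypes(counts, markers, method="kmeans", seed=0)
            gd = sg.call_genotypes(counts, markers, method="dbscan")
            _, co, n_co = sg.concordance(gk, gd)
            assert n_co > 0 and co == 1.0
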