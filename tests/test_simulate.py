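"""Simulator behaviour: truth draws, read generation, run assembly."""

import numpy as np
import pandas as pd
import pytest

import spikegbs as sg
from spikegbs.simulate import _rng


def binom_bound(n, p, z=4.0):
    return z * np.sqrt(n * p * (1 - p))


class TestSimulateTruth:
    def test_degenerate_frequencies(self, toy_markers):
        truth = sg.simulate_truth(
            ["s1", "s2", "s3"], toy_markers[:1], {"locus1": {"A": 1.0}}, seed=0
        )
        assert (truth["true_class"] == "A").all()
        assert (truth["expected_fraction"] == 1.0).all()

    def test_class_draws_are_binomial(self, toy_markers):
        n = 10_000
        truth = sg.simulate_truth(
            [f"s{i}" for i in range(n)], toy_markers[:1],
            {"locus1": {"A": 0.5, "B": 0.5}}, seed=3,
        )
        n_a = (truth["true_class"] == "A").sum()
        assert abs(n_a - n / 2) <= binom_bound(n, 0.5)

    def test_same_seed_identical(self, toy_markers):
        kwargs = dict(
            samples=["s1", "s2"], markers=toy_markers, class_frequencies=None
        )
        pd.testing.assert_frame_equal(
            sg.simulate_truth(seed=5, **kwargs), sg.simulate_truth(seed=5, **kwargs)
        )

    def test_bad_frequency_sum_rejected(self, toy_markers):
        with pytest.raises(sg.ConfigError):
            sg.simulate_truth(
                ["s1"], toy_markers[:1], {"locus1": {"A": 0.6, "B": 0.6}}, seed=0
            )


class TestAmpliconReads:
    def _truth_row(self, sample, locus, cls, frac):
        return pd.DataFrame(
            [{"sample_id": sample, "locus_id": locus,
              "true_class": cls, "expected_fraction": frac}]
        )

    def test_noise_free_homozygote_reads_are_exact(self, parts, toy_markers,
                                                   barcodes12):
        truth = self._truth_row(barcodes12.samples[0], "locus1", "A", 1.0)
        reads, audit = sg.simulate_amplicon_reads(
            truth, toy_markers, barcodes12, parts,
            sg.DepthModel("fixed", mean=20), error_rate=0.0, seed=1,
        )
        expected = sg.expected_amplicon(
            parts, barcodes12.barcodes[0], toy_markers[0], "A"
        )
        assert len(reads) == 20
        assert all(seq == expected for _, seq in reads)
        assert audit.loc[0, ["count_a", "count_b"]].tolist() == [20, 0]

    @pytest.mark.parametrize("frac,depth", [(0.5, 10_000), (2 / 3, 9_000)])
    def test_allele_split_is_binomial(self, parts, toy_markers, barcodes12,
                                      frac, depth):
        truth = self._truth_row(barcodes12.samples[0], "locus1", "x", frac)
        _, audit = sg.simulate_amplicon_reads(
            truth, toy_markers, barcodes12, parts,
            sg.DepthModel("fixed", mean=depth), error_rate=0.0, seed=2,
        )
        assert abs(audit.loc[0, "count_a"] - frac * depth) <= binom_bound(depth, frac)

    def test_sample_without_barcode_rejected(self, parts, toy_markers, barcodes12):
        truth = self._truth_row("not_a_sample", "locus1", "A", 1.0)
        with pytest.raises(sg.ConfigError):
            sg.simulate_amplicon_reads(
                truth, toy_markers, barcodes12, parts,
                sg.DepthModel("fixed", mean=5), 0.0, seed=0,
            )


class TestGbsBackground:
    def test_perfect_rates(self, parts, barcodes12):
        reads = sg.simulate_gbs_background(
            200, barcodes12, "TGCAG", 150, 20, 1.0, 1.0, seed=0,
            forbidden=parts.m13_tail,
        )
        for _, seq in reads:
            assert seq[:10] in set(barcodes12.barcodes)
            assert seq[10:15] == "TGCAG"

    def test_configured_rates_recovered(self, parts, barcodes12):
        n = 30_000
        reads = sg.simulate_gbs_background(
            n, barcodes12, "TGCAG", 145, 30, 0.836, 0.813, seed=1,
            forbidden=parts.m13_tail,
        )
        bc_frac, both_frac = sg.qc_gbs_rates(reads, barcodes12, "TGCAG")
        assert abs(bc_frac * n - 0.836 * n) <= binom_bound(n, 0.836)
        assert abs(both_frac * n - 0.813 * n) <= binom_bound(n, 0.813)
        assert both_frac < bc_frac

    def test_empty_stream(self, barcodes12):
        assert sg.simulate_gbs_background(
            0, barcodes12, "TGCAG", 145, 30, 1.0, 1.0, seed=0
        ) == []

    def test_no_m13_contamination(self, parts, barcodes12):
        reads = sg.simulate_gbs_background(
            2_000, barcodes12, "TGCAG", 60, 10, 0.8, 0.7, seed=2,
            forbidden=parts.m13_tail,
        )
        assert all(parts.m13_tail not in seq for _, seq in reads)

    def test_rate_ordering_enforced(self, barcodes12):
        with pytest.raises(sg.ConfigError):
            sg.simulate_gbs_background(
                10, barcodes12, "TGCAG", 145, 30, 0.5, 0.9, seed=0
            )


class TestSimulateRun:
    def test_spike_fraction_binomial_at_fixed_total(self, toy_markers):
        cfg = sg.SimConfig(n_samples=10, spike_fraction=0.02,
                           depth=sg.DepthModel(mean=50), error_rate=0.0, seed=9)
        result = sg.simulate_run(cfg, toy_markers, n_reads=100_000)
        assert result.n_amplicon + result.n_background == 100_000
        assert abs(result.n_amplicon - 2_000) <= binom_bound(100_000, 0.02)

    def test_same_seed_byte_identical_fastq(self, toy_markers, tmp_path):
        cfg = sg.SimConfig(n_samples=6, spike_fraction=0.1,
                           depth=sg.DepthModel(mean=20), error_rate=0.01, seed=4)
        paths = [tmp_path / "a.fastq", tmp_path / "b.fastq"]
        for p in paths:
            sg.simulate_run(cfg, toy_markers, fastq_path=p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_frequency_converges_at_high_depth(self, parts, toy_markers, barcodes12):
        """Per-cell allele-A fraction approaches the expected fraction."""
        truth = sg.simulate_truth(
            barcodes12.samples[:3], toy_markers[:1],
            {"locus1": {"Heterozygous": 1.0}}, seed=0,
        )
        _, audit = sg.simulate_amplicon_reads(
            truth, toy_markers, barcodes12, parts,
            sg.DepthModel("fixed", mean=2_000), error_rate=0.0, seed=5,
        )
        for row in audit.itertuples():
            assert abs(row.count_a - 1_000) <= binom_bound(2_000, 0.5)

    def test_truth_tsv_round_trip(self, toy_markers, tmp_path):
        truth = sg.simulate_truth(["s1", "s2"], toy_markers, None, seed=1)
        path = tmp_path / "truth.tsv"
        from spikegbs.simulate import truth_from_tsv, truth_to_tsv

        truth_to_tsv(truth, path)
        pd.testing.assert_frame_equal(truth_from_tsv(path), truth)


class TestCountsLevelSimulator:
    def test_matches_binomial_expectation(self, toy_markers):
        truth = sg.simulate_truth(
            [f"s{i}" for i in range(200)], toy_markers[:1],
            {"locus1": {"Heterozygous": 1.0}}, seed=1,
        )
        counts = sg.simulate_allele_counts(
            truth, sg.DepthModel("fixed", mean=1_000), seed=2
        )
        total_a = counts["count_a"].sum()
        n = 200 * 1_000
        assert abs(total_a - n / 2) <= binom_bound(n, 0.5)

    def test_error_rate_thins_counts(self, toy_markers):
        truth = sg.simulate_truth(
            [f"s{i}" for i in range(50)], toy_markers[:1], None, seed=3
        )
        clean = sg.simulate_allele_counts(
            truth, sg.DepthModel("fixed", mean=500), seed=4, error_rate=0.0
        )
        noisy = sg.simulate_allele_counts(
            truth, sg.DepthModel("fixed", mean=500), seed=4, error_rate=0.05
        )
        assert (noisy["count_a"] + noisy["count_b"]).sum() < (
            clean["count_a"] + clean["count_b"]
        ).sum()
        assert (noisy["count_unmatched"] > 0).any()


class TestRandomMarkers:
    def test_targets_resolve_uniquely(self, parts):
        markers = sg.random_markers(8, seed=11, parts=parts)
        for m in markers:
            payload_a = m.forward_flank + m.allele_a_target + m.reverse_flank
            payload_b = m.forward_flank + m.allele_b_target + m.reverse_flank
            assert sg.match_allele(payload_a, m) == "A"
            assert sg.match_allele(payload_b, m) == "B"
            for other in markers:
                if other.locus_id != m.locus_id:
                    assert sg.match_allele(payload_a, other) == "unmatched"
                    assert sg.match_allele(payload_b, other) == "unmatched"
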