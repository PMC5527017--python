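"""Smoothing, thresholding and consecutive-probe region calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from promtile import (
    ThresholdSpec,
    assign_genes,
    call_bound_genes,
    call_enriched_regions,
    compute_threshold,
    smooth_track,
)
from tests.conftest import make_probe_table


def oracle_regions(signals, threshold, min_run):
    """Brute force: every maximal contiguous run of strictly above-threshold
    probes, kept if its length reaches min_run."""
    n = len(signals)
    runs = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            if all(s > threshold for s in signals[i:j]):
                left_ok = i == 0 or signals[i - 1] <= threshold
                right_ok = j == n or signals[j] <= threshold
                if left_ok and right_ok and j - i >= min_run:
                    runs.append((i, j))
    return runs


class TestSmoothTrack:
    def test_single_probe_is_its_own_mean(self):
        np.testing.assert_allclose(smooth_track(np.array([100.0]), np.array([2.5])), [2.5])

    def test_constant_signal_invariant(self):
        centers = np.arange(0, 8000, 205.0)
        out = smooth_track(centers, np.full(len(centers), 1.7))
        np.testing.assert_allclose(out, 1.7)

    def test_three_probes_within_one_window_all_average(self):
        out = smooth_track(np.array([0.0, 205.0, 410.0]), np.array([0.0, 3.0, 0.0]), 1400)
        np.testing.assert_allclose(out, [1.0, 1.0, 1.0])

    def test_mass_conserved_when_window_covers_all_probes(self, rng):
        centers = np.arange(0, 10 * 50, 50.0)
        values = rng.normal(size=10)
        out = smooth_track(centers, values, window_bp=10_000)
        assert out.mean() == pytest.approx(values.mean())

    def test_matches_quadratic_oracle(self, rng):
        centers = np.sort(rng.uniform(0, 8000, 60))
        values = rng.normal(size=60)
        out = smooth_track(centers, values, 1400)
        expected = [
            values[np.abs(centers - c) <= 700].mean() for c in centers
        ]
        np.testing.assert_allclose(out, expected)

    def test_empty_track(self):
        assert len(smooth_track(np.array([]), np.array([]))) == 0

    def test_unsorted_centers_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            smooth_track(np.array([10.0, 0.0]), np.array([1.0, 2.0]))


class TestComputeThreshold:
    def test_standard_normal_monte_carlo(self, rng):
        values = rng.normal(0, 1, 200_000)
        t = compute_threshold(values, ThresholdSpec(center_statistic="mean"))
        assert t == pytest.approx(2.5, abs=0.05)

    def test_constant_values_warn_and_return_center(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert compute_threshold(np.full(10, 3.3)) == pytest.approx(3.3)

    def test_median_center_is_robust_to_enriched_tail(self, rng):
        values = np.r_[rng.normal(0, 0.1, 9000), np.full(1000, 3.0)]
        t_median = compute_threshold(values, ThresholdSpec(center_statistic="median"))
        t_mean = compute_threshold(values, ThresholdSpec(center_statistic="mean"))
        assert t_median < t_mean

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(sd_multiplier=-1)
        with pytest.raises(ValueError):
            ThresholdSpec(min_run=0)


class TestCallEnrichedRegions:
    @pytest.mark.parametrize(
        "signals,n_regions",
        [
            ((0, 0, 0, 0), 0),
            ((0, 2, 2, 2, 0), 1),
            ((2, 2, 0, 2, 2), 0),  # two runs of 2 do not qualify
        ],
    )
    def test_worked_examples(self, signals, n_regions):
        regions = call_enriched_regions(make_probe_table(signals), threshold=1.0, min_run=3)
        assert len(regions) == n_regions
        if n_regions:
            assert regions["n_probes"].iloc[0] == 3

    def test_region_spans_first_to_last_qualifying_probe(self):
        table = make_probe_table((0, 2, 2, 2, 0), spacing=205)
        region = call_enriched_regions(table, 1.0).iloc[0]
        assert region["start"] == table["start"].iloc[1]
        assert region["end"] == table["end"].iloc[3]

    def test_merge_gap_bridges_single_dropout(self):
        signals = (2, 2, 2, 0, 2, 2, 2)
        strict = call_enriched_regions(make_probe_table(signals), 1.0, merge_gap=0)
        merged = call_enriched_regions(make_probe_table(signals), 1.0, merge_gap=1)
        assert len(strict) == 2
        assert len(merged) == 1 and merged["n_probes"].iloc[0] == 7

    def test_multiple_genes_rejected(self):
        t1, t2 = make_probe_table((2, 2, 2), "gA"), make_probe_table((2, 2, 2), "gB")
        with pytest.raises(ValueError, match="single gene"):
            call_enriched_regions(pd.concat([t1, t2]), 1.0)

    @settings(max_examples=300, derandomize=True)
    @given(
        signals=st.lists(st.integers(0, 3), min_size=1, max_size=12),
        min_run=st.integers(1, 4),
    )
    def test_agrees_with_brute_force_on_short_tracks(self, signals, min_run):
        table = make_probe_table(signals)
        regions = call_enriched_regions(table, threshold=1.0, min_run=min_run)
        expected = oracle_regions(signals, 1.0, min_run)
        assert len(regions) == len(expected)
        for (_, region), (i, j) in zip(regions.iterrows(), expected):
            assert region["n_probes"] == j - i
            assert region["start"] == table["start"].iloc[i]
            assert region["end"] == table["end"].iloc[j - 1]

    @settings(max_examples=100, derandomize=True)
    @given(
        signals=st.lists(st.floats(-1, 4, allow_nan=False), min_size=1, max_size=20),
        threshold=st.floats(0, 3),
        min_run=st.integers(1, 4),
    )
    def test_gene_calls_monotone_in_threshold_and_min_run(self, signals, threshold, min_run):
        """Raising the threshold or the run length never enriches more genes
        (regions may split, but a called gene stays called at laxer settings)."""
        table = make_probe_table(signals)

        def called(thr, mr):
            return len(call_enriched_regions(table, thr, mr)) > 0

        base = called(threshold, min_run)
        assert called(threshold + 0.5, min_run) <= base
        assert called(threshold, min_run + 1) <= base


class TestAssignGenes:
    def test_gene_with_two_regions_appears_once_with_best_region(self):
        regions = pd.DataFrame(
            {
                "gene_id": ["g1", "g1"],
                "chrom": "chr1",
                "start": [0, 1000],
                "end": [500, 1500],
                "n_probes": [3, 4],
                "peak_signal": [1.0, 2.0],
                "mean_signal": [0.8, 1.5],
            }
        )
        bound, best = assign_genes(regions)
        assert bound == {"g1"}
        assert best["peak_signal"].iloc[0] == 2.0

    def test_no_regions_gives_empty_set(self):
        bound, best = assign_genes(pd.DataFrame(columns=["gene_id", "peak_signal"]))
        assert bound == set() and best.empty


def test_full_calling_recovers_spiked_genes(experiment):
    """Seeded run at study conditions: every treated-bound gene recovered,
    no false genes."""
    from promtile import normalize_condition

    averaged = normalize_condition(experiment["scans"]["t3"])
    result = call_bound_genes(averaged)
    truth = experiment["truth"]
    true_bound = set(truth.loc[truth["bound_in_t3"], "gene_id"])
    assert result["bound_genes"] == true_bound
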