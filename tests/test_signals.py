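"""Binned signal areas, tertile labels, TF Z-scores, 4C×ChIP integration."""

import numpy as np
import pytest

from conftest import dense_signal, random_intervals
from silencerscape.fourc import FourCComparison
from silencerscape.genome import GenomicInterval, SignalTrack
from silencerscape.signals import (
    integrate_fourc_chip,
    signal_area,
    tertile_labels,
    tf_zscore_matrix,
)


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestSignalArea:
    def test_two_bin_worked_example(self):
        track = SignalTrack({"chr1": ([0, 50], [50, 100], [2.0, 4.0])})
        binned = signal_area(track, _iv(0, 100), bin_size=50)
        assert binned.values.tolist() == [2.0, 4.0]
        assert binned.total_area == 300.0

    def test_zero_track(self):
        track = SignalTrack({})
        assert signal_area(track, _iv(0, 1000), 50).total_area == 0.0

    def test_bin_size_one_equals_region_signal(self, rng):
        starts = np.arange(0, 2000, 40)
        track = SignalTrack(
            {"chr1": (starts, starts + 40, rng.uniform(0, 3, starts.size))}
        )
        region = _iv(117, 1531)
        binned = signal_area(track, region, bin_size=1)
        assert binned.total_area == pytest.approx(
            track.region_signal(region), rel=1e-9
        )

    def test_bin_size_region_length_equals_region_signal(self, rng):
        starts = np.arange(0, 2000, 40)
        track = SignalTrack(
            {"chr1": (starts, starts + 40, rng.uniform(0, 3, starts.size))}
        )
        region = _iv(100, 1700)
        binned = signal_area(track, region, bin_size=len(region))
        assert binned.total_area == pytest.approx(
            track.region_signal(region), rel=1e-9
        )

    def test_truncated_final_bin_uses_true_width(self):
        track = SignalTrack({"chr1": ([0], [1000], [3.0])})
        binned = signal_area(track, _iv(0, 130), bin_size=50)
        assert binned.bin_widths.tolist() == [50.0, 50.0, 30.0]
        assert binned.total_area == pytest.approx(390.0)

    def test_additive_over_partition(self, rng):
        starts = np.arange(0, 5000, 25)
        track = SignalTrack(
            {"chr1": (starts, starts + 25, rng.uniform(0, 2, starts.size))}
        )
        whole = signal_area(track, _iv(0, 5000), 64).total_area
        parts = sum(
            signal_area(track, _iv(a, b), 64).total_area
            for a, b in [(0, 1234), (1234, 3456), (3456, 5000)]
        )
        assert parts == pytest.approx(whole, rel=1e-9)

    def test_bin_size_validation(self):
        with pytest.raises(ValueError):
            signal_area(SignalTrack({}), _iv(0, 100), 0)


class TestTertiles:
    def test_one_to_nine(self):
        labels = tertile_labels(list(range(1, 10)))
        assert labels == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3

    def test_all_equal_lands_low_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = tertile_labels([4.0, 4.0, 4.0, 4.0])
        assert labels == ["low"] * 4

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tertile_labels([1.0, 2.0])

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.uniform(0, 100, size=30)
        base = tertile_labels(values)
        assert tertile_labels(np.exp(values / 20)) == base
        assert tertile_labels(values * 7 + 3) == base


class TestTfZscores:
    def test_constant_counts_give_zero(self):
        regions = [_iv(0, 100), _iv(1000, 1100), _iv(2000, 2100)]
        peaks = {"TF1": [_iv(10, 20), _iv(1010, 1020), _iv(2010, 2020)]}
        z = tf_zscore_matrix(regions, peaks)
        assert np.allclose(z["TF1"], 0.0)

    def test_matches_direct_standardization(self):
        regions = [_iv(0, 100), _iv(1000, 1100), _iv(2000, 2100)]
        peaks = {"TF1": [_iv(2000, 2010), _iv(2020, 2030), _iv(2050, 2060)]}
        z = tf_zscore_matrix(regions, peaks)
        counts = np.array([0, 0, 3.0])
        expected = (counts - counts.mean()) / counts.std()
        assert np.allclose(z["TF1"].to_numpy(), expected)

    def test_no_overlaps_zero_matrix(self):
        regions = [_iv(0, 100), _iv(1000, 1100)]
        z = tf_zscore_matrix(regions, {"TF1": [_iv(500_000, 500_100)]})
        assert not z.to_numpy().any()

    def test_columns_standardized(self, rng):
        regions = random_intervals(rng, 20, chrom_len=100_000)
        peaks = {
            f"TF{j}": random_intervals(rng, 50, chrom_len=100_000) for j in range(4)
        }
        z = tf_zscore_matrix(regions, peaks)
        for col in z:
            if z[col].std() > 0:
                assert abs(z[col].mean()) < 1e-9
                assert abs(z[col].to_numpy().std() - 1) < 1e-9

    def test_needs_two_regions(self):
        with pytest.raises(ValueError):
            tf_zscore_matrix([_iv(0, 10)], {})


class TestIntegration:
    @staticmethod
    def _comparisons(statuses, spacing=10_000):
        return [
            FourCComparison(
                fragment=_iv(i * spacing, i * spacing + 4000),
                status=s,
                rpm_control={"rep1": 100.0},
                rpm_experiment={"rep1": 50.0},
            )
            for i, s in enumerate(statuses)
        ]

    def test_identical_tracks_zero_deltas(self, toy_genome):
        track = SignalTrack.constant(toy_genome, 2.0)
        records, tests = integrate_fourc_chip(
            self._comparisons(["gained", "lost", "unchanged"] * 2),
            k27me3_tracks={"c": track, "e": track},
            k27ac_tracks={"c": track, "e": track},
            control_condition="c",
            experiment_condition="e",
        )
        assert (records["k27me3_delta"] == 0).all()
        assert (records["k27ac_delta"] == 0).all()

    def test_log10_rpm(self, toy_genome):
        track = SignalTrack.constant(toy_genome, 1.0)
        records, _ = integrate_fourc_chip(
            self._comparisons(["unchanged"] * 3),
            k27me3_tracks={"c": track, "e": track},
            k27ac_tracks={"c": track, "e": track},
            control_condition="c",
            experiment_condition="e",
        )
        assert np.allclose(records["rpm_log10_control"], 2.0)

    def test_missing_condition_track_rejected(self, toy_genome):
        track = SignalTrack.constant(toy_genome, 1.0)
        with pytest.raises(ValueError, match="missing"):
            integrate_fourc_chip(
                self._comparisons(["unchanged"] * 3),
                k27me3_tracks={"c": track},
                k27ac_tracks={"c": track, "e": track},
                control_condition="c",
                experiment_condition="e",
            )

    def test_planted_decrease_flagged_only_in_unchanged_group(self, toy_genome, rng):
        # plant an H3K27me3 drop confined to the unchanged regions
        statuses = (["unchanged"] * 10 + ["gained"] * 10) * 2
        comparisons = self._comparisons(statuses)
        starts = np.array([c.fragment.start for c in comparisons])
        control_runs = ([], [], [])
        exp_runs = ([], [], [])
        for c in comparisons:
            control_runs[0].append(c.fragment.start)
            control_runs[1].append(c.fragment.end)
            control_runs[2].append(5.0)
            exp_runs[0].append(c.fragment.start)
            exp_runs[1].append(c.fragment.end)
            exp_runs[2].append(1.0 if c.status == "unchanged" else 5.0)
        control = SignalTrack({"chr1": tuple(np.array(x) for x in control_runs)})
        experiment = SignalTrack({"chr1": tuple(np.array(x) for x in exp_runs)})
        flat = SignalTrack.constant(toy_genome, 1.0)
        records, tests = integrate_fourc_chip(
            comparisons,
            k27me3_tracks={"c": control, "e": experiment},
            k27ac_tracks={"c": flat, "e": flat},
            control_condition="c",
            experiment_condition="e",
        )
        t = tests.set_index(["mark", "group"])
        assert t.loc[("k27me3", "unchanged"), "wilcoxon_paired_p"] < 0.01
        assert t.loc[("k27me3", "unchanged"), "median_delta"] < 0
        assert np.isnan(t.loc[("k27me3", "gained"), "wilcoxon_paired_p"])
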