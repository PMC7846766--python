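"""Peak stitching, region scoring, and the slope-1 rank cutoff."""

import numpy as np
import pytest

from conftest import dense_signal, random_intervals
from silencerscape.genome import GenomicInterval, SignalTrack
from silencerscape.mrr import (
    DEFAULT_WINDOWS,
    call_regions,
    presence_across_samples,
    score_regions,
    slope_cutoff,
    stitch_peaks,
)


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestStitchPeaks:
    def test_merges_within_window_only(self):
        peaks = [_iv(0, 100), _iv(3000, 3100), _iv(8000, 8100)]
        regions = stitch_peaks(peaks, 4000)  # gaps 2900 < 4000 < 4900
        assert [(r.interval.start, r.interval.end) for r in regions] == [
            (0, 3100),
            (8000, 8100),
        ]
        assert [r.n_constituents for r in regions] == [2, 1]

    def test_single_peak_identity(self):
        (region,) = stitch_peaks([_iv(5, 50)], 12500)
        assert (region.interval.start, region.interval.end) == (5, 50)

    def test_window_zero_merges_only_overlapping(self):
        peaks = [_iv(0, 100), _iv(50, 150), _iv(150, 200), _iv(300, 400)]
        regions = stitch_peaks(peaks, 0)
        # overlapping and abutting pairs merge; the separated peak stays
        assert [(r.interval.start, r.interval.end) for r in regions] == [
            (0, 200),
            (300, 400),
        ]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            stitch_peaks([], 4000)

    def test_fuzzed_invariants(self, rng):
        for _ in range(100):
            peaks = random_intervals(rng, int(rng.integers(1, 60)), chrom_len=50_000)
            window = int(rng.integers(0, 3000))
            regions = stitch_peaks(peaks, window)
            # constituents partition the input
            constituents = sorted(
                (c.chrom, c.start, c.end)
                for r in regions
                for c in r.constituents
            )
            assert constituents == sorted((p.chrom, p.start, p.end) for p in peaks)
            # pairwise separation ≥ window
            for a, b in zip(regions[:-1], regions[1:]):
                if a.interval.chrom == b.interval.chrom:
                    assert b.interval.start - a.interval.end >= max(window, 1)
            # idempotence on the merged intervals
            again = stitch_peaks([r.interval for r in regions], window)
            assert [(r.interval.start, r.interval.end) for r in again] == [
                (r.interval.start, r.interval.end) for r in regions
            ]

    def test_region_count_monotone_in_window(self, rng):
        peaks = random_intervals(rng, 80, chrom_len=100_000)
        counts = [len(stitch_peaks(peaks, w)) for w in (0, 100, 500, 2000, 10_000)]
        assert counts == sorted(counts, reverse=True)


class TestScoreRegions:
    def test_constant_tracks(self, toy_genome):
        treatment = SignalTrack.constant(toy_genome, 3.0)
        control = SignalTrack.constant(toy_genome, 1.0)
        (region,) = stitch_peaks([_iv(0, 1000)], 0)
        (scored,) = score_regions([region], treatment, control)
        assert scored.score == 2000.0

    def test_floor_at_zero_when_control_exceeds_treatment(self, toy_genome):
        treatment = SignalTrack.constant(toy_genome, 1.0)
        control = SignalTrack.constant(toy_genome, 5.0)
        (scored,) = score_regions(stitch_peaks([_iv(0, 1000)], 0), treatment, control)
        assert scored.score == 0.0

    def test_matches_per_bp_oracle(self, rng):
        starts = np.arange(0, 10_000, 100)
        treatment = SignalTrack(
            {"chr1": (starts, starts + 100, rng.uniform(0, 4, starts.size))}
        )
        control = SignalTrack(
            {"chr1": (starts, starts + 100, rng.uniform(0, 2, starts.size))}
        )
        t_dense = dense_signal(treatment, "chr1", 10_000)
        c_dense = dense_signal(control, "chr1", 10_000)
        regions = stitch_peaks(random_intervals(rng, 20, chrom_len=10_000), 200)
        for scored in score_regions(regions, treatment, control):
            s, e = scored.interval.start, scored.interval.end
            expected = max(0.0, t_dense[s:e].sum() - c_dense[s:e].sum())
            assert scored.score == pytest.approx(expected, rel=1e-9)

    def test_density_mode_divides_by_length(self, toy_genome):
        treatment = SignalTrack.constant(toy_genome, 3.0)
        (scored,) = score_regions(
            stitch_peaks([_iv(0, 1000)], 0), treatment, None, mode="density"
        )
        assert scored.score == pytest.approx(3.0)


class TestSlopeCutoff:
    def test_worked_example(self):
        curve = slope_cutoff([1, 1, 1, 10])
        # scaled differences are [0, -1/3, -2/3, 0]; argmin at the 3rd point
        assert curve.cutoff_index == 2
        assert curve.cutoff_value == 1
        assert (curve.scores > curve.cutoff_value).sum() == 1

    def test_linear_scores_tie_break_to_largest_index(self):
        curve = slope_cutoff([10, 20, 30, 40, 50])
        assert curve.cutoff_index == 4
        assert (curve.scores > curve.cutoff_value).sum() == 0

    def test_constant_scores_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            curve = slope_cutoff([5, 5, 5, 5])
        assert curve.degenerate

    def test_too_few_scores_degenerate(self):
        with pytest.warns(UserWarning):
            assert slope_cutoff([1, 2]).degenerate

    def test_cutoff_index_invariant_under_shift_and_scale(self, rng):
        for _ in range(50):
            scores = rng.lognormal(0, 1, size=int(rng.integers(3, 80)))
            if scores.max() == scores.min():
                continue
            base = slope_cutoff(scores).cutoff_index
            assert slope_cutoff(scores + 7.5).cutoff_index == base
            assert slope_cutoff(scores * 3.25).cutoff_index == base


class TestCallRegions:
    def test_default_windows(self):
        assert DEFAULT_WINDOWS["H3K27me3"] == 4000
        assert DEFAULT_WINDOWS["H3K27ac"] == 12500

    def test_planted_clusters_called_rich(self):
        from silencerscape.genome import overlaps_any
        from silencerscape.simulate import make_genome, make_peaks_and_signal

        genome = make_genome(1, 4_000_000)
        peaks, treatment, control, truth = make_peaks_and_signal(
            genome, n_clusters=5, n_isolated=50, seed=11
        )
        regions, _ = call_regions(peaks, treatment, control, mark="H3K27me3")
        rich = [r.interval for r in regions if r.is_rich]
        assert len(rich) == 5
        assert overlaps_any(truth.mrr_intervals, rich).all()

    def test_ranks_are_permutation(self, rng, toy_genome):
        treatment = SignalTrack(
            {"chr1": (np.arange(0, 5000, 100), np.arange(100, 5100, 100),
                      rng.uniform(0, 10, 50))}
        )
        regions, _ = call_regions(
            random_intervals(rng, 30, chrom_len=5000), treatment, None, window=50
        )
        assert sorted(r.rank for r in regions) == list(range(1, len(regions) + 1))


class TestPresenceAcrossSamples:
    @staticmethod
    def _rich(intervals):
        regions = stitch_peaks(intervals, 0)
        for r in regions:
            r.label = "rich"
        return regions

    def test_identical_sets_all_present(self):
        sets = {
            "s1": self._rich([_iv(0, 1000), _iv(5000, 6000)]),
            "s2": self._rich([_iv(0, 1000), _iv(5000, 6000)]),
        }
        assert presence_across_samples(sets, 0.5).to_numpy().all()

    def test_disjoint_sets_identity_pattern(self):
        sets = {
            "s1": self._rich([_iv(0, 1000)]),
            "s2": self._rich([_iv(50_000, 51_000)]),
        }
        matrix = presence_across_samples(sets, 0.5)
        for (sample, _), row in matrix.iterrows():
            assert row[sample]
            assert not row.drop(sample).any()

    def test_matches_quadratic_overlap_fraction_oracle(self, rng):
        base = random_intervals(rng, 15, chrom_len=50_000)
        shifted = []
        for iv in base:
            delta = int(rng.integers(-400, 400))
            start = max(0, iv.start + delta)
            shifted.append(GenomicInterval("chr1", start, start + len(iv)))
        frac = 0.5
        sets = {"a": self._rich(base), "b": self._rich(shifted)}
        matrix = presence_across_samples(sets, frac)
        rich_a = [r.interval for r in sets["a"]]
        rich_b = [r.interval for r in sets["b"]]
        for i, iv in enumerate(rich_a):
            expected = any(
                iv.overlap_bp(o) / min(len(iv), len(o)) >= frac for o in rich_b
            )
            assert matrix.loc[("a", f"a_rich_{i}"), "b"] == expected

    def test_fraction_bounds(self):
        sets = {"a": self._rich([_iv(0, 10)]), "b": self._rich([_iv(0, 10)])}
        with pytest.raises(ValueError):
            presence_across_samples(sets, 0.0)
        with pytest.raises(ValueError):
            presence_across_samples(sets, 1.5)
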