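"""Anchor grid construction, call projection and frequency profiles."""

import numpy as np
import pytest

from mdr21 import harmonization as hz
from mdr21.segmentation import Segment


def seg(start_bp, end_bp, state, start_index=0, n=10):
    return Segment(start_index=start_index, end_index=start_index + n,
                   start_bp=start_bp, end_bp=end_bp, mean_level=0.0,
                   n_probes=n, state=state)


class TestAnchorGrid:
    def test_midpoint_placement_formula(self):
        grid = hz.build_anchor_grid(10000, 5)
        assert grid.positions.tolist() == [1000, 3000, 5000, 7000, 9000]

    def test_single_anchor_sits_at_midpoint(self):
        assert hz.build_anchor_grid(10000, 1).positions.tolist() == [5000]

    def test_default_grid_has_5000_anchors(self):
        grid = hz.build_anchor_grid(48_129_895)
        assert grid.n_anchors == 5000
        assert np.all(np.diff(grid.positions) > 0)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            hz.build_anchor_grid(10, 10)


class TestProjection:
    def grid(self):
        return hz.build_anchor_grid(10000, 5)

    def test_whole_chromosome_neutral_covers_all_anchors(self):
        m = hz.project_calls_to_anchors(
            {"s": [seg(0, 10000, "neutral")]}, self.grid()
        )
        assert np.all(m.states == hz.NEUTRAL)

    def test_loss_segment_captures_contained_anchor_only(self):
        tracks = {"s": [seg(0, 2000, "neutral"), seg(2000, 4000, "loss", 10),
                        seg(4000, 10000, "neutral", 20)]}
        m = hz.project_calls_to_anchors(tracks, self.grid())
        assert m.states[0].tolist() == [
            hz.NEUTRAL, hz.LOSS, hz.NEUTRAL, hz.NEUTRAL, hz.NEUTRAL,
        ]

    def test_uncovered_anchor_goes_to_nearest_within_gap(self):
        # segments [0,2000) and [6000,10000): anchor 3000 lies 1001 bp from
        # the left segment and 3000 bp from the right one -> left state;
        # anchor 5000 lies 3001 bp left / 1000 bp right -> right state
        tracks = {"s": [seg(0, 2000, "loss"), seg(6000, 10000, "gain", 10)]}
        m = hz.project_calls_to_anchors(tracks, self.grid(), max_gap=1500)
        assert m.states[0].tolist() == [
            hz.LOSS, hz.LOSS, hz.GAIN, hz.GAIN, hz.GAIN,
        ]
        strict = hz.project_calls_to_anchors(tracks, self.grid(), max_gap=900)
        assert strict.states[0].tolist() == [
            hz.LOSS, hz.MISSING, hz.MISSING, hz.GAIN, hz.GAIN,
        ]

    def test_desert_beyond_max_gap_is_missing(self):
        tracks = {"s": [seg(0, 1200, "loss")]}
        m = hz.project_calls_to_anchors(tracks, self.grid(), max_gap=500)
        assert m.states[0].tolist() == [
            hz.LOSS, hz.MISSING, hz.MISSING, hz.MISSING, hz.MISSING,
        ]

    def test_equidistant_anchor_takes_left_segment(self):
        # anchor 5000: left segment last bp 3999 -> 1001; right starts 6001
        # -> 1001; tie goes left
        tracks = {"s": [seg(0, 4000, "loss"), seg(6001, 10000, "gain", 10)]}
        m = hz.project_calls_to_anchors(tracks, self.grid(), max_gap=None)
        assert m.states[0][2] == hz.LOSS

    def test_overlapping_segments_rejected(self):
        tracks = {"s": [seg(0, 5000, "loss"), seg(4000, 10000, "gain", 10)]}
        with pytest.raises(ValueError, match="partition"):
            hz.project_calls_to_anchors(tracks, self.grid())

    def test_enlarging_loss_segment_keeps_loss_anchors(self):
        grid = self.grid()
        small = hz.project_calls_to_anchors(
            {"s": [seg(2000, 4000, "loss")]}, grid, max_gap=0
        )
        large = hz.project_calls_to_anchors(
            {"s": [seg(1000, 8000, "loss")]}, grid, max_gap=0
        )
        was_loss = small.states[0] == hz.LOSS
        assert np.all(large.states[0][was_loss] == hz.LOSS)


class TestFrequencies:
    def matrix(self, states):
        grid = hz.build_anchor_grid(10000, len(states[0]))
        return hz.AnchorCallMatrix(
            grid=grid, sample_ids=[f"s{i}" for i in range(len(states))],
            states=np.array(states, dtype=np.int8), cohort="c",
        )

    def test_unanimous_loss_gives_frequency_one(self):
        prof = hz.compute_frequencies(self.matrix([[hz.LOSS]] * 4))
        assert prof.del_freq[0] == 1.0
        assert prof.amp_freq[0] == 0.0

    def test_three_of_thirtyfour(self):
        states = [[hz.LOSS]] * 3 + [[hz.NEUTRAL]] * 31
        prof = hz.compute_frequencies(self.matrix(states))
        assert prof.del_freq[0] == pytest.approx(3 / 34)

    def test_missing_samples_excluded_from_denominator(self):
        states = ([[hz.LOSS]] * 3 + [[hz.NEUTRAL]] * 3 + [[hz.MISSING]] * 4)
        prof = hz.compute_frequencies(self.matrix(states))
        assert prof.del_freq[0] == 0.5
        assert prof.n_informative[0] == 6

    def test_no_informative_samples_gives_nan(self):
        prof = hz.compute_frequencies(self.matrix([[hz.MISSING]] * 2))
        assert np.isnan(prof.del_freq[0])

    def test_del_plus_amp_never_exceeds_one(self):
        rng = np.random.default_rng(0)
        states = rng.choice(
            [hz.LOSS, hz.NEUTRAL, hz.GAIN, hz.MISSING], size=(30, 40)
        ).astype(np.int8)
        grid = hz.build_anchor_grid(100000, 40)
        prof = hz.compute_frequencies(
            hz.AnchorCallMatrix(grid=grid,
                                sample_ids=[f"s{i}" for i in range(30)],
                                states=states)
        )
        ok = ~np.isnan(prof.del_freq)
        assert np.all(prof.del_freq[ok] + prof.amp_freq[ok] <= 1 + 1e-12)


class TestMedianCombine:
    def profile(self, del_vals, cohort="c"):
        grid = hz.build_anchor_grid(10000, len(del_vals))
        d = np.asarray(del_vals, dtype=float)
        return hz.FrequencyProfile(
            grid=grid, cohort=cohort, del_freq=d, amp_freq=np.zeros_like(d),
            n_informative=np.full(len(d), 5),
        )

    def test_median_of_reported_region_frequencies(self):
        profiles = [self.profile([v]) for v in (0.269, 0.117, 0.617, 0.0)]
        combined = hz.combine_profiles_median(profiles)
        assert combined.del_freq[0] == pytest.approx(0.193)

    def test_identical_profiles_unchanged(self):
        profiles = [self.profile([0.2, 0.4])] * 3
        combined = hz.combine_profiles_median(profiles)
        assert combined.del_freq.tolist() == [0.2, 0.4]

    def test_single_profile_identity(self):
        combined = hz.combine_profiles_median([self.profile([0.3])])
        assert combined.del_freq.tolist() == [0.3]

    def test_nan_cohorts_excluded_from_median(self):
        profiles = [self.profile([0.4]), self.profile([np.nan]),
                    self.profile([0.2])]
        combined = hz.combine_profiles_median(profiles)
        assert combined.del_freq[0] == pytest.approx(0.3)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            hz.combine_profiles_median(
                [self.profile([0.1]), self.profile([0.1, 0.2])]
            )


def test_frequencies_invariant_under_sample_and_platform_partition():
    rng = np.random.default_rng(1)
    grid = hz.build_anchor_grid(50_000, 25)
    states = rng.choice([hz.LOSS, hz.NEUTRAL, hz.GAIN], size=(20, 25)).astype(np.int8)
    ids = [f"s{i}" for i in range(20)]
    full = hz.compute_frequencies(
        hz.AnchorCallMatrix(grid=grid, sample_ids=ids, states=states)
    )
    perm = rng.permutation(20)
    shuffled = hz.compute_frequencies(
        hz.AnchorCallMatrix(grid=grid, sample_ids=[ids[i] for i in perm],
                            states=states[perm])
    )
    np.testing.assert_array_equal(full.del_freq, shuffled.del_freq)
    # partition into two "platforms" and pool counts manually
    a = states[:8]
    b = states[8:]
    da = (a == hz.LOSS).sum(axis=0)
    db = (b == hz.LOSS).sum(axis=0)
    np.testing.assert_allclose((da + db) / 20, full.del_freq)
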