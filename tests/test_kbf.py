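"""Knowledge-based filter: modes, tail quantiles, intersection, cropping.

The end-to-end oracle here re-derives the filter from first principles with
plain Python sets and sorted lists — no shared code with the implementation.
"""

import math
import warnings
from collections import Counter

import numpy as np
import pytest

from kbfmgmt.kbf import (KBFParams, ROIOverflowError, apply_roi,
                         crop_and_normalize, intensity_mode, kbf_mask,
                         mode_split, quantile_select)
from kbfmgmt.volume import BrainMask, ROIMask, Volume


def _vol(grid, **kw):
    return Volume(grid=np.asarray(grid, float), spacing=(1, 1, 1), **kw)


# ------------------------------------------------------------------ oracle

def kbf_oracle(flair, t1, brain, fraction):
    """Sorted-list / set-intersection reference for the volume-scope filter."""
    def mode_of(vals):
        counts = Counter(vals)
        best = max(counts.values())
        return min(v for v, c in counts.items() if c == best)

    coords = [tuple(c) for c in np.argwhere(brain)]
    f_val = {c: float(flair[c]) for c in coords}
    t_val = {c: float(t1[c]) for c in coords}
    m_f = mode_of(list(f_val.values()))
    m_t = mode_of(list(t_val.values()))
    supra = [c for c in coords if f_val[c] > m_f]
    sub = [c for c in coords if t_val[c] < m_t]

    def flat(c):
        return (c[0] * brain.shape[1] + c[1]) * brain.shape[2] + c[2]

    def tail(cands, val, largest):
        k = math.ceil(fraction * len(cands))
        key = (lambda c: (-val[c], flat(c))) if largest else \
              (lambda c: (val[c], flat(c)))
        return set(sorted(cands, key=key)[:k])

    top = tail(supra, f_val, True) if supra else set()
    low = tail(sub, t_val, False) if sub else set()
    mask = np.zeros_like(brain)
    for c in top & low:
        mask[c] = True
    return mask


# ------------------------------------------------------------------ mode

class TestIntensityMode:
    @pytest.mark.parametrize("values,expected", [
        ([1, 1, 2, 3], 1),
        ([5, 5, 7, 7], 5),          # tie breaks toward the smallest
        ([3], 3),
        ([-2, -2, 0, 1], -2),
    ])
    def test_integer_modes(self, values, expected):
        assert intensity_mode(values) == expected

    def test_two_peak_mixture_mode_near_taller_peak(self, rng):
        sample = np.concatenate([
            rng.normal(100.0, 5.0, size=7000),
            rng.normal(40.0, 5.0, size=3000),
        ])
        bins = 64
        mode = intensity_mode(sample, bins=bins)
        # brute-force histogram count as the oracle
        counts, edges = np.histogram(sample, bins=bins)
        k = int(np.argmax(counts))
        assert edges[k] <= mode <= edges[k + 1]
        width = edges[1] - edges[0]
        assert abs(mode - 100.0) <= width

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            intensity_mode([])

    def test_continuous_without_bins_rejected(self):
        with pytest.raises(ValueError):
            intensity_mode([0.5, 1.2])


class TestModeSplit:
    def test_constant_flair_gives_empty_supra(self):
        brain = BrainMask(np.ones((2, 2, 2), bool))
        flair = _vol(np.full((2, 2, 2), 5.0), modality="FLAIR")
        t1 = _vol(np.arange(8).reshape(2, 2, 2), modality="T1w")
        supra, _sub = mode_split(flair, t1, brain)
        assert supra.n_voxels == 0  # strict inequality at the mode

    def test_enumerated_example(self):
        # in-brain FLAIR values {1,1,2,3}: mode 1, supra marks 2 and 3
        grid = np.array([1.0, 1.0, 2.0, 3.0]).reshape(1, 1, 4)
        brain = BrainMask(np.ones((1, 1, 4), bool))
        flair = _vol(grid, modality="FLAIR")
        t1 = _vol(np.zeros((1, 1, 4)), modality="T1w")
        supra, sub = mode_split(flair, t1, brain)
        assert list(supra.grid[0, 0]) == [False, False, True, True]
        assert sub.n_voxels == 0  # constant T1: nothing strictly below mode

    def test_mode_over_brain_voxels_only(self):
        # huge zero background must not drag the mode to 0
        grid = np.zeros((4, 4, 4))
        brain = np.zeros((4, 4, 4), bool)
        brain[1:3, 1:3, 1:3] = True
        grid[brain] = [5, 5, 6, 7, 5, 6, 7, 8]
        supra, _ = mode_split(_vol(grid, modality="FLAIR"),
                              _vol(grid, modality="T1w"), BrainMask(brain))
        assert supra.n_voxels == 5  # values 6,7,6,7,8 above mode 5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mode_split(_vol(np.zeros((2, 2, 2))), _vol(np.zeros((3, 3, 3))),
                       BrainMask(np.ones((2, 2, 2), bool)))


class TestQuantileSelect:
    def test_empty_mask_passes_through(self):
        mask = ROIMask(np.zeros((3, 3, 3), bool))
        out = quantile_select(mask, _vol(np.zeros((3, 3, 3))), 0.25, "highest")
        assert out.n_voxels == 0

    def test_exact_top_quarter_of_distinct_values(self, rng):
        vals = rng.permutation(1000).astype(float).reshape(10, 10, 10)
        mask = ROIMask(np.ones((10, 10, 10), bool))
        out = quantile_select(mask, _vol(vals), 0.25, "highest")
        assert out.n_voxels == 250
        assert set(vals[out.grid]) == set(np.sort(vals, axis=None)[-250:])

    def test_ceil_rounding_rule(self, rng):
        mask = np.zeros((1, 1, 20), bool)
        mask[0, 0, :10] = True
        out = quantile_select(ROIMask(mask), _vol(rng.normal(size=(1, 1, 20))),
                              0.25, "lowest")
        assert out.n_voxels == math.ceil(0.25 * 10) == 3

    def test_tie_break_is_lexicographic(self):
        vals = np.zeros((1, 1, 8))
        mask = ROIMask(np.ones((1, 1, 8), bool))
        out = quantile_select(mask, _vol(vals), 0.5, "highest")
        assert list(np.flatnonzero(out.grid.ravel())) == [0, 1, 2, 3]

    def test_bad_fraction_rejected(self):
        mask = ROIMask(np.ones((2, 2, 2), bool))
        with pytest.raises(ValueError):
            quantile_select(mask, _vol(np.zeros((2, 2, 2))), 0.0, "highest")


class TestKbfMask:
    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            shape = tuple(rng.integers(4, 17, size=3))
            flair = rng.integers(0, 12, size=shape).astype(float)
            t1 = rng.integers(0, 12, size=shape).astype(float)
            brain = rng.random(shape) < 0.8
            if not brain.any():
                continue
            expected = kbf_oracle(flair, t1, brain, 0.25)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = kbf_mask(_vol(flair, modality="FLAIR"),
                               _vol(t1, modality="T1w"), BrainMask(brain))
            assert np.array_equal(got.grid, expected)

    def test_disjoint_selections_warn_and_empty(self):
        # FLAIR top voxels and T1 low voxels at different locations
        flair = np.array([1, 1, 9, 1.0]).reshape(1, 1, 4)
        t1 = np.array([1, 5, 5, 5.0]).reshape(1, 1, 4)
        brain = BrainMask(np.ones((1, 1, 4), bool))
        with pytest.warns(UserWarning, match="empty"):
            roi = kbf_mask(_vol(flair, modality="FLAIR"),
                           _vol(t1, modality="T1w"), brain)
        assert roi.n_voxels == 0

    def test_monotone_in_tail_fraction(self, rng):
        shape = (12, 12, 12)
        flair = rng.integers(0, 30, size=shape).astype(float)
        t1 = rng.integers(0, 30, size=shape).astype(float)
        brain = BrainMask(rng.random(shape) < 0.9)
        prev = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for f in (0.1, 0.2, 0.3, 0.5):
                roi = kbf_mask(_vol(flair, modality="FLAIR"),
                               _vol(t1, modality="T1w"), brain,
                               KBFParams(tail_fraction=f))
                if prev is not None:
                    assert not (prev & ~roi.grid).any()  # nested selections
                prev = roi.grid

    def test_scale_invariance(self, rng):
        shape = (10, 10, 10)
        flair = rng.integers(0, 20, size=shape).astype(float)
        t1 = rng.integers(0, 20, size=shape).astype(float)
        brain = BrainMask(np.ones(shape, bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = kbf_mask(_vol(flair, modality="FLAIR"),
                         _vol(t1, modality="T1w"), brain)
            b = kbf_mask(_vol(flair * 3, modality="FLAIR"),
                         _vol(t1 * 3, modality="T1w"), brain)
        assert np.array_equal(a.grid, b.grid)

    def test_localizes_seeded_tumor_phantom(self, textured_phantom):
        """Tumor recovery on a seeded phantom: overlap and centroid."""
        ph = textured_phantom
        roi = kbf_mask(ph.flair, ph.t1, ph.brain_mask, KBFParams(crop_side=48))
        t, r = ph.tumor_mask, roi.grid
        dice = 2 * (t & r).sum() / (t.sum() + r.sum())
        assert dice >= 0.5
        cent = np.array(np.nonzero(r)).mean(axis=1)
        tn = np.nonzero(t)
        for ax in range(3):
            assert tn[ax].min() <= cent[ax] <= tn[ax].max()

    def test_roi_subset_of_brain(self, small_phantom):
        roi = kbf_mask(small_phantom.flair, small_phantom.t1,
                       small_phantom.brain_mask, KBFParams(crop_side=48))
        assert not (roi.grid & ~small_phantom.brain_mask.grid).any()

    def test_per_slice_scope_runs_independently(self, small_phantom):
        roi = kbf_mask(small_phantom.flair, small_phantom.t1,
                       small_phantom.brain_mask,
                       KBFParams(scope="per_slice", crop_side=48))
        # each nonempty brain slice is processed on its own; result is a
        # valid in-brain mask that still finds the tumor slicewise
        assert not (roi.grid & ~small_phantom.brain_mask.grid).any()
        assert roi.n_voxels > 0


class TestApplyRoi:
    def test_full_roi_is_identity(self, rng):
        grid = rng.integers(0, 9, size=(4, 4, 4)).astype(float)
        out = apply_roi(_vol(grid), ROIMask(np.ones((4, 4, 4), bool)))
        assert np.array_equal(out.grid, grid)

    def test_empty_roi_zeroes_volume(self, rng):
        grid = rng.integers(1, 9, size=(4, 4, 4)).astype(float)
        out = apply_roi(_vol(grid), ROIMask(np.zeros((4, 4, 4), bool)))
        assert not out.grid.any()

    def test_support_is_intersection(self, rng):
        grid = rng.integers(0, 3, size=(6, 6, 6)).astype(float)
        roi = ROIMask(rng.random((6, 6, 6)) < 0.5)
        out = apply_roi(_vol(grid), roi)
        assert np.array_equal(out.grid != 0, roi.grid & (grid != 0))


class TestCropAndNormalize:
    def _inputs(self, vol_side=60, brain_lo=10, brain_hi=50, roi_box=None):
        grid = np.zeros((vol_side,) * 3)
        brain = np.zeros((vol_side,) * 3, bool)
        brain[brain_lo:brain_hi, brain_lo:brain_hi, brain_lo:brain_hi] = True
        roi = np.zeros((vol_side,) * 3, bool)
        if roi_box is not None:
            lo, hi = roi_box
            roi[lo:hi, lo:hi, lo:hi] = True
            grid[roi] = np.arange(roi.sum()) + 1.0
        return _vol(grid), BrainMask(brain), ROIMask(roi)

    def test_output_is_requested_cube(self):
        vol, brain, roi = self._inputs(roi_box=(20, 25))
        out = crop_and_normalize(vol, brain, roi, KBFParams(crop_side=192))
        assert out.grid.shape == (192, 192, 192)

    def test_minmax_range(self):
        vol, brain, roi = self._inputs(roi_box=(20, 25))
        out = crop_and_normalize(vol, brain, roi, KBFParams(crop_side=64))
        assert out.grid.min() == 0.0 and out.grid.max() == 1.0

    def test_constant_window_maps_to_zeros(self):
        vol, brain, roi = self._inputs()
        out = crop_and_normalize(vol, brain, roi, KBFParams(crop_side=32))
        assert not out.grid.any()

    def test_window_shift_preserves_roi(self):
        # ROI hugging the edge of a brain larger than the crop window
        vol, brain, roi = self._inputs(vol_side=80, brain_lo=4, brain_hi=76,
                                       roi_box=(66, 74))
        params = KBFParams(crop_side=48)
        out = crop_and_normalize(vol, brain, roi, params)
        assert (out.grid > 0).sum() == roi.n_voxels

    def test_roi_larger_than_window_rejected(self):
        vol, brain, roi = self._inputs(vol_side=60, roi_box=(12, 48))
        with pytest.raises(ROIOverflowError):
            crop_and_normalize(vol, brain, roi, KBFParams(crop_side=16))
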