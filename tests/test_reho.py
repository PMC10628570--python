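"""Preprocessing and Kendall's-W regional homogeneity mapping."""

import numpy as np
import pytest
from scipy.stats import rankdata

from restbrain.reho import (MotionTrace, RehoConfig, bandpass_filter, kendalls_w,
                            motion_qc, reho_map, slice_timing_correct,
                            standardize_reho)
from restbrain.volgrid import BoldSeries, MaskVolume


def brute_force_w(matrix: np.ndarray) -> float:
    """Independent rank-sum implementation of Kendall's W."""
    k, n = matrix.shape
    ranks = np.array([rankdata(row) for row in matrix])
    R = ranks.sum(axis=0)
    return float(12.0 * ((R - R.mean()) ** 2).sum() / (k ** 2 * (n ** 3 - n)))


def make_series(data, tr=2.0, spacing=(3.0, 3.0, 3.0)):
    return BoldSeries(np.asarray(data, dtype=float), spacing, tr_seconds=tr)


class TestSliceTiming:
    def test_zero_offsets_identity(self, rng):
        series = make_series(rng.standard_normal((4, 4, 3, 20)))
        out = slice_timing_correct(series, [0, 1, 2], ref_slice=0)
        # reference slice itself is untouched
        np.testing.assert_allclose(out.data[:, :, 0], series.data[:, :, 0])

    def test_constant_series_unchanged(self):
        series = make_series(np.full((2, 2, 4, 15), 7.0))
        out = slice_timing_correct(series, [0, 2, 1, 3], ref_slice=0)
        np.testing.assert_allclose(out.data, 7.0)

    def test_sinusoid_half_tr_shift(self):
        # slice acquired half a TR later, shifted back to the reference time
        tr, f, n_t = 2.0, 0.05, 64
        t = np.arange(n_t) * tr
        data = np.zeros((1, 1, 2, n_t))
        data[0, 0, 0] = np.sin(2 * np.pi * f * t)
        data[0, 0, 1] = np.sin(2 * np.pi * f * (t + tr / 2))
        series = make_series(data, tr=tr)
        out = slice_timing_correct(series, [0, 1], ref_slice=0)
        expected = np.sin(2 * np.pi * f * t)
        err = np.abs(out.data[0, 0, 1, 1:-1] - expected[1:-1]).max()
        assert err < 0.5 * (np.pi * f * tr) ** 2

    def test_invalid_order(self, rng):
        series = make_series(rng.standard_normal((2, 2, 3, 12)))
        with pytest.raises(ValueError, match="permutation"):
            slice_timing_correct(series, [0, 0, 2])


class TestMotionQC:
    def test_exactly_at_limit_retained(self):
        trace = MotionTrace(np.array([[1.5, 0, 0, 0, 0, 0]]))
        assert not motion_qc(trace).excluded

    def test_rotation_over_limit_excluded_with_index(self):
        params = np.zeros((5, 6))
        params[3, 4] = 2.0  # 2 degrees at volume 3
        rec = motion_qc(MotionTrace(params))
        assert rec.excluded
        assert rec.offending_volumes == [3]

    def test_all_zero_retained(self):
        rec = motion_qc(MotionTrace(np.zeros((10, 6))))
        assert not rec.excluded and rec.offending_volumes == []

    def test_round_trip_text(self, tmp_path, rng):
        trace = MotionTrace(rng.standard_normal((7, 6)))
        trace.write(tmp_path / "motion.txt")
        back = MotionTrace.read(tmp_path / "motion.txt")
        np.testing.assert_allclose(back.params, trace.params, atol=1e-6)


class TestBandpass:
    def test_in_band_sinusoid_passes(self):
        tr, n_t = 2.0, 200
        t = np.arange(n_t) * tr
        sig = np.sin(2 * np.pi * 0.04 * t)
        series = make_series(np.tile(sig, (2, 2, 2, 1)), tr=tr)
        out = bandpass_filter(series, (0.01, 0.08))
        assert out.data[0, 0, 0].std() / sig.std() > 0.99

    def test_out_of_band_sinusoid_blocked(self):
        tr, n_t = 2.0, 200
        t = np.arange(n_t) * tr
        sig = np.sin(2 * np.pi * 0.2 * t)
        series = make_series(np.tile(sig, (1, 1, 1, 1)), tr=tr)
        out = bandpass_filter(series, (0.01, 0.08))
        assert out.data[0, 0, 0].std() / sig.std() < 0.01

    def test_constant_series_zeroed(self):
        series = make_series(np.full((2, 2, 1, 50), 5.0))
        out = bandpass_filter(series)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_band_above_nyquist_rejected(self, rng):
        series = make_series(rng.standard_normal((2, 2, 1, 50)), tr=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(series, (0.01, 0.3))


class TestKendallsW:
    def test_perfect_concordance(self):
        m = np.array([[1.0, 2, 3], [10, 20, 30], [0.1, 0.5, 0.9]])
        assert kendalls_w(m) == pytest.approx(1.0, abs=1e-15)

    def test_perfect_discordance_two_series(self):
        m = np.array([[1.0, 2, 3], [3.0, 2, 1]])
        assert kendalls_w(m) == pytest.approx(0.0, abs=1e-15)

    def test_matches_bruteforce_random(self, rng):
        m = rng.standard_normal((27, 30))
        assert kendalls_w(m) == pytest.approx(brute_force_w(m), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        m = rng.standard_normal((9, 25))
        transformed = m.copy()
        transformed[0] = np.exp(m[0])
        transformed[1] = m[1] ** 3
        transformed[2] = np.arctan(m[2])
        assert abs(kendalls_w(m) - kendalls_w(transformed)) < 1e-12

    def test_shared_time_permutation_invariance(self, rng):
        m = rng.standard_normal((8, 20))
        perm = rng.permutation(20)
        assert abs(kendalls_w(m) - kendalls_w(m[:, perm])) < 1e-12

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            kendalls_w(np.ones((1, 5)))


class TestRehoMap:
    def test_blob_phantom_contrast(self):
        from restbrain import phantoms
        b = phantoms.make_bold_phantom((24, 24, 10), n_t=80,
                                       blob_spec=[((8, 8, 5), 3.0, 0.9),
                                                  ((17, 17, 5), 3.0, 0.9)],
                                       seed=4, spacing=(3.0, 3.0, 3.0))
        series = bandpass_filter(b.volumes["bold"])
        mask = MaskVolume(np.ones((24, 24, 10), np.uint8), (3.0, 3.0, 3.0))
        rmap = reho_map(series, mask)
        blobs = np.zeros((24, 24, 10), bool)
        for bm in b.truth["blob_masks"]:
            blobs |= bm
        assert rmap.data[blobs].mean() - rmap.data[~blobs].mean() > 0.1

    def test_identical_series_gives_one(self):
        sig = np.sin(np.linspace(0, 8 * np.pi, 40))
        data = np.tile(sig, (6, 6, 4, 1))
        series = make_series(data)
        mask = MaskVolume(np.ones((6, 6, 4), np.uint8), (3.0, 3.0, 3.0))
        rmap = reho_map(series, mask)
        np.testing.assert_allclose(rmap.data, 1.0, atol=1e-10)

    def test_iid_noise_low_reho(self, rng):
        series = make_series(rng.standard_normal((10, 10, 6, 210)))
        mask = MaskVolume(np.ones((10, 10, 6), np.uint8), (3.0, 3.0, 3.0))
        rmap = reho_map(series, mask)
        assert rmap.data[mask.data].mean() < 0.2

    def test_matches_per_voxel_bruteforce(self, rng):
        """Vectorized map equals the direct neighborhood Kendall's W."""
        shape = (6, 6, 4)
        data = rng.standard_normal(shape + (30,))
        mask_arr = rng.random(shape) > 0.2
        mask_arr[3, 3, 2] = True
        series = make_series(data)
        mask = MaskVolume(mask_arr.astype(np.uint8), (3.0, 3.0, 3.0))
        rmap = reho_map(series, mask)
        for (i, j, k) in [(3, 3, 2), (0, 0, 0), (5, 5, 3), (2, 4, 1)]:
            if not mask_arr[i, j, k]:
                continue
            neigh = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for dk in (-1, 0, 1):
                        ii, jj, kk = i + di, j + dj, k + dk
                        if 0 <= ii < 6 and 0 <= jj < 6 and 0 <= kk < 4 and mask_arr[ii, jj, kk]:
                            neigh.append(data[ii, jj, kk])
            expected = brute_force_w(np.array(neigh)) if len(neigh) >= 2 else 0.0
            assert rmap.data[i, j, k] == pytest.approx(expected, abs=1e-10)

    def test_empty_mask_rejected(self, rng):
        series = make_series(rng.standard_normal((4, 4, 2, 12)))
        with pytest.raises(ValueError, match="empty"):
            reho_map(series, MaskVolume(np.zeros((4, 4, 2), np.uint8), (3.0, 3.0, 3.0)))


class TestStandardize:
    def test_mask_mean_is_one(self, rng):
        from restbrain.volgrid import Volume
        vals = np.abs(rng.standard_normal((8, 8, 4))) + 0.1
        mask = MaskVolume((rng.random((8, 8, 4)) > 0.3).astype(np.uint8), (3.0, 3.0, 3.0))
        out = standardize_reho(Volume(vals, (3.0, 3.0, 3.0)), mask)
        assert out.data[mask.data].mean() == pytest.approx(1.0, abs=1e-12)

    def test_constant_map_all_ones(self):
        from restbrain.volgrid import Volume
        mask = MaskVolume(np.ones((5, 5, 3), np.uint8), (3.0, 3.0, 3.0))
        out = standardize_reho(Volume(np.full((5, 5, 3), 0.4), (3.0, 3.0, 3.0)), mask)
        np.testing.assert_allclose(out.data, 1.0)

    def test_smoothing_after_standardization_near_conserves_mean(self, rng):
        from restbrain.volgrid import Volume, gaussian_smooth
        vals = np.abs(rng.standard_normal((16, 16, 8))) + 0.2
        mask = MaskVolume(np.ones((16, 16, 8), np.uint8), (3.0, 3.0, 4.0))
        out = standardize_reho(Volume(vals, (3.0, 3.0, 4.0)), mask)
        smoothed = gaussian_smooth(out, 6.0)
        assert smoothed.data[mask.data].mean() == pytest.approx(1.0, rel=0.02)
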