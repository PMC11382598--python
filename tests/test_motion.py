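"""Motion magnitude, outlier fractions, censoring, and summaries, each
checked against literal brute-force re-implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmriqc.motion import (CensorVector, MotionParams, build_censor,
                           censor_summary, compute_enorm,
                           compute_outlier_fraction, distribution_stats,
                           select_min_outlier_volume)
from tests.conftest import make_4d, make_mask


def enorm_loop_oracle(vals, run_lengths):
    """Literal per-element forward-difference norm."""
    e = np.zeros(vals.shape[0])
    start = 0
    for rl in run_lengths:
        for t in range(start + 1, start + rl):
            s = 0.0
            for k in range(6):
                s += (vals[t, k] - vals[t - 1, k]) ** 2
            e[t] = s ** 0.5
        start += rl
    return e


class TestEnorm:
    def test_zero_params_zero_series(self):
        mp = MotionParams(np.zeros((12, 6)))
        np.testing.assert_array_equal(compute_enorm(mp), np.zeros(12))

    def test_three_four_five_step(self):
        vals = np.zeros((4, 6))
        vals[2] = [0.3, 0.4, 0, 0, 0, 0]
        e = compute_enorm(MotionParams(vals))
        assert e[2] == pytest.approx(0.5)
        assert e[3] == pytest.approx(0.5)  # step back down

    def test_matches_loop_oracle_multirun(self, rng):
        vals = rng.standard_normal((20, 6))
        mp = MotionParams(vals, run_lengths=[8, 12])
        np.testing.assert_allclose(compute_enorm(mp),
                                   enorm_loop_oracle(vals, [8, 12]), atol=1e-12)

    @given(shift=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_constant_offset(self, shift):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((15, 6))
        shifted = vals.copy()
        shifted[:, 2] += shift
        np.testing.assert_allclose(compute_enorm(MotionParams(vals)),
                                   compute_enorm(MotionParams(shifted)),
                                   atol=1e-10)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="6 motion columns"):
            MotionParams(np.zeros((10, 5)))


def outlier_loop_oracle(dset, mask):
    """Per-voxel loop re-implementation of the outlier-fraction rule."""
    from scipy.stats import norm
    from fmriqc.timeseries import detrend_series, polort_for_run
    coords = np.argwhere(mask.values)
    frac = np.zeros(dset.n_volumes)
    start = 0
    for rl in dset.run_lengths:
        q = norm.ppf(1.0 - 0.001 / (2.0 * rl))
        order = polort_for_run(rl, dset.tr)
        counts = np.zeros(rl)
        for (i, j, k) in coords:
            series = dset.values[i, j, k, start:start + rl]
            resid = detrend_series(series[None, :], order)[0]
            med = np.median(resid)
            madn = 1.4826 * np.median(np.abs(resid - med))
            if madn == 0:
                continue
            counts += np.abs(resid - med) > q * madn
        frac[start:start + rl] = counts / len(coords)
        start += rl
    return frac


class TestOutlierFraction:
    def test_constant_dataset_all_zero(self):
        ds = make_4d(np.full((6, 6, 4, 30), 7.0))
        mask = make_mask(np.ones((6, 6, 4)))
        np.testing.assert_array_equal(compute_outlier_fraction(ds, mask),
                                      np.zeros(30))

    def test_injected_shift_recovers_fraction(self, rng):
        shape = (10, 10, 6)
        T = 60
        sd = 1.0
        data = rng.standard_normal(shape + (T,)) * sd + 100
        mask = make_mask(np.ones(shape))
        n_vox = int(np.prod(shape))
        n_shift = n_vox // 10
        flat = data.reshape(n_vox, T)
        flat[:n_shift, 30] += 20 * sd
        ds = make_4d(flat.reshape(shape + (T,)))
        frac = compute_outlier_fraction(ds, mask)
        assert frac[30] == pytest.approx(0.10, abs=0.02)

    def test_matches_per_voxel_loop(self, rng):
        data = rng.standard_normal((8, 8, 4, 30)) + 50
        data[2, 3, 1, 12] += 30  # one clear outlier
        ds = make_4d(data, run_lengths=[15, 15])
        mask = make_mask((rng.uniform(size=(8, 8, 4)) > 0.3).astype(int))
        np.testing.assert_allclose(compute_outlier_fraction(ds, mask),
                                   outlier_loop_oracle(ds, mask), atol=1e-12)

    def test_empty_mask_rejected(self):
        ds = make_4d(np.zeros((4, 4, 4, 12)))
        with pytest.raises(ValueError, match="mask"):
            compute_outlier_fraction(ds, make_mask(np.zeros((4, 4, 4))))


class TestMinOutlierVolume:
    @pytest.mark.parametrize("series,expected", [
        ([0.2, 0.0, 0.1], 1),
        ([0.1, 0.1], 0),            # tie -> earliest
        ([0.5, 0.5, 0.2, 0.2], 2),
    ])
    def test_examples(self, series, expected):
        assert select_min_outlier_volume(np.array(series)) == expected

    def test_clean_volume_among_perturbed_is_selected(self, rng):
        shape = (10, 10, 6)
        T = 30
        data = rng.standard_normal(shape + (T,)) + 100
        n_vox = int(np.prod(shape))
        flat = data.reshape(n_vox, T)
        clean = 17
        for t in range(T):
            if t == clean:
                continue
            hit = rng.choice(n_vox, n_vox // 10, replace=False)
            flat[hit, t] += 25.0  # a different 10% of voxels disturbed per volume
        epi = make_4d(flat.reshape(shape + (T,)))
        frac = compute_outlier_fraction(epi, make_mask(np.ones(shape)))
        assert select_min_outlier_volume(frac) == clean


def censor_loop_oracle(enorm, outfrac, limits, extend, run_lengths):
    T = len(enorm)
    cens = [False] * T
    start = 0
    for rl in run_lengths:
        for t in range(start, start + rl):
            if outfrac[t] > limits["outlier_limit"]:
                cens[t] = True
            if enorm[t] > limits["enorm_limit"]:
                cens[t] = True
                if extend and t - 1 >= start:
                    cens[t - 1] = True
        start += rl
    return np.array([0 if c else 1 for c in cens])


class TestBuildCensor:
    def test_all_below_limits_all_kept(self):
        cv = build_censor(np.full(10, 0.1), np.full(10, 0.01))
        assert cv.n_censored == 0

    def test_extend_previous_censors_both(self):
        enorm = np.zeros(10)
        enorm[7] = 0.5
        cv = build_censor(enorm, np.zeros(10), {"enorm_limit": 0.3,
                                                "outlier_limit": 0.05})
        assert sorted(cv.censored_indices) == [6, 7]

    def test_random_series_match_loop_oracle(self, rng):
        enorm = rng.uniform(0, 0.6, 40)
        outfrac = rng.uniform(0, 0.1, 40)
        limits = {"enorm_limit": 0.3, "outlier_limit": 0.05}
        for extend in (True, False):
            cv = build_censor(enorm, outfrac, limits, extend_previous=extend,
                              run_lengths=[25, 15])
            np.testing.assert_array_equal(
                cv.keep, censor_loop_oracle(enorm, outfrac, limits, extend,
                                            [25, 15]))

    def test_nonpositive_limits_rejected(self):
        with pytest.raises(ValueError):
            build_censor(np.zeros(5), np.zeros(5), {"enorm_limit": 0.0})


class TestCensorSummary:
    def test_printed_worked_example(self):
        keep = np.ones(242, dtype=int)
        keep[[10, 50, 90]] = 0
        rd = censor_summary(CensorVector(keep), [242])
        assert rd["censor fraction"] == 0.012397
        assert rd["num TRs per run (applied)"] == 239
        assert rd["TRs censored"] == 3
        assert rd["TRs total (uncensored)"] == 242

    def test_no_censoring(self):
        rd = censor_summary(CensorVector(np.ones(100, dtype=int)))
        assert rd["censor fraction"] == 0

    def test_everything_censored(self):
        rd = censor_summary(CensorVector(np.zeros(50, dtype=int)))
        assert rd["censor fraction"] == 1
        assert rd["TRs total"] == 0


class TestDistributionStats:
    def test_constant_series_degenerate(self):
        ds = distribution_stats(np.full(20, 3.0),
                                CensorVector(np.ones(20, dtype=int)))
        assert ds.bc == (3.0,) * 5

    def test_median_linear_interpolation(self):
        ds = distribution_stats(np.arange(1, 101, dtype=float),
                                CensorVector(np.ones(100, dtype=int)))
        assert ds.bc[2] == pytest.approx(50.5)

    def test_censoring_top_decile_caps_ac_max(self, rng):
        x = rng.standard_normal(100)
        order = np.argsort(x)
        keep = np.ones(100, dtype=int)
        keep[order[-10:]] = 0
        ds = distribution_stats(x, CensorVector(keep))
        assert ds.ac[4] == pytest.approx(np.sort(x)[89])

    def test_all_censored_flags_ac_none(self):
        ds = distribution_stats(np.arange(5.0),
                                CensorVector(np.zeros(5, dtype=int)))
        assert ds.ac is None
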