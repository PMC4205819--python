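import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalconn.preprocess import (
    PreprocessConfig,
    bandpass,
    censor,
    displacement,
    noise_pcs,
    preprocess_subject,
    regress_confounds,
    select_highvar_voxel_channels,
)


class TestDisplacement:
    def test_pure_translation(self):
        m = np.zeros((3, 6))
        m[1, 3] = 1.0  # 1 mm along x between frames 0 and 1
        d = displacement(m, radius_mm=50.0)
        assert d.values[0] == 0.0
        assert d.values[1] == pytest.approx(1.0)

    def test_pure_rotation_with_lever_arm(self):
        m = np.zeros((2, 6))
        m[1, 2] = 0.02  # rad
        d = displacement(m, radius_mm=50.0)
        assert d.values[1] == pytest.approx(1.0)

    def test_constant_trace_never_censored(self):
        m = np.tile(np.array([0.1, -0.2, 0.0, 3.0, 1.0, -2.0]), (20, 1))
        d = displacement(m)
        assert np.all(d.values == 0.0)
        assert censor(d).all()

    def test_malformed_motion_rejected(self):
        with pytest.raises(ValueError):
            displacement(np.zeros((5, 7)))
        with pytest.raises(ValueError):
            displacement(np.full((5, 6), np.nan))


class TestCensor:
    def test_direct_rule(self):
        mask = censor(np.array([0.1, 2.5, 0.3]), threshold_mm=2.0)
        assert np.array_equal(mask, [True, False, True])

    def test_all_below_threshold_keeps_everything(self):
        assert censor(np.full(50, 1.9)).all()

    def test_infinite_threshold_limit(self):
        assert censor(np.array([0.1, 99.0, 5.0]), threshold_mm=np.inf).all()

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=10), min_size=2, max_size=40),
        st.floats(min_value=0.1, max_value=5),
        st.floats(min_value=0.0, max_value=5),
    )
    def test_monotone_in_threshold(self, disp, thr, extra):
        disp = np.asarray(disp)
        low = censor(disp, thr)
        high = censor(disp, thr + extra)
        assert np.all(high | ~low)  # raising the threshold never censors more


class TestNoisePcs:
    def test_rank_one_input_dominated_by_first_component(self):
        t = np.arange(50)
        base = np.sin(2 * np.pi * 0.1 * t)
        x = np.tile(base[:, None], (1, 8)) + 1e-4 * np.random.default_rng(0).standard_normal(
            (50, 8)
        )
        pcs = noise_pcs(x, 3)
        var = pcs.var(axis=0, ddof=1)
        assert var[0] / var.sum() > 0.99

    def test_orthogonal_sinusoids_equal_power(self):
        t = np.arange(200)
        s1 = np.sin(2 * np.pi * 0.05 * t)
        s2 = np.cos(2 * np.pi * 0.05 * t)
        rng = np.random.default_rng(1)
        x = np.column_stack([s1, s2, s1, s2]) + 1e-6 * rng.standard_normal((200, 4))
        pcs = noise_pcs(x, 2)
        var = pcs.var(axis=0, ddof=1)
        assert var[0] == pytest.approx(var[1], rel=0.05)

    def test_shape_and_orthogonality_contract(self):
        x = np.random.default_rng(2).standard_normal((50, 20))
        pcs = noise_pcs(x, 5)
        assert pcs.shape == (50, 5)
        gram = pcs.T @ pcs
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_rank_deficit_warns_and_truncates(self):
        x = np.tile(np.arange(30.0)[:, None], (1, 6))
        with pytest.warns(UserWarning):
            pcs = noise_pcs(x, 4)
        assert pcs.shape[1] < 4


class TestHighVarianceChannelSelection:
    def test_highest_sd_column_selected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 10))
        x[:, 3] *= 10
        sub, idx = select_highvar_voxel_channels(x, fraction=0.1)
        assert list(idx) == [3]

    def test_fraction_one_is_identity(self):
        x = np.random.default_rng(1).standard_normal((20, 5))
        sub, idx = select_highvar_voxel_channels(x, fraction=1.0)
        assert np.array_equal(sub, x)
        assert list(idx) == list(range(5))

    def test_ties_break_to_lower_index(self):
        col = np.random.default_rng(2).standard_normal(30)
        x = np.column_stack([col, col, col])
        _, idx = select_highvar_voxel_channels(x, fraction=1 / 3)
        assert list(idx) == [0]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_highvar_voxel_channels(np.empty((10, 0)), 0.5)


class TestRegressConfounds:
    def test_self_regression_annihilates_region(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((60, 4))
        cleaned = regress_confounds(y, y[:, [2]])
        assert np.abs(cleaned.data[:, 2]).max() < 1e-10

    def test_orthogonal_confounds_leave_centered_input(self):
        t = np.arange(64)
        y = np.column_stack([np.sin(2 * np.pi * 4 * t / 64), np.cos(2 * np.pi * 6 * t / 64)])
        conf = np.sin(2 * np.pi * 10 * t / 64)[:, None]
        cleaned = regress_confounds(y, conf)
        assert np.allclose(cleaned.data, y - y.mean(0), atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((50, 6))
        conf = rng.standard_normal((50, 4))
        cleaned = regress_confounds(y, conf)
        assert np.abs(conf.T @ cleaned.data).max() < 1e-8

    def test_cardiac_sinusoid_removed_via_shared_component(self):
        # the aliased cardiac component appears in both data and noise PCs;
        # regression suppresses its band power by more than 90%
        rng = np.random.default_rng(4)
        t = np.arange(50.0)
        card = np.sin(2 * np.pi * 0.4 * t + 0.3)
        y = rng.standard_normal((50, 5)) * 0.3 + card[:, None]
        channels = card[:, None] * rng.uniform(0.5, 1.5, 8) + 0.2 * rng.standard_normal((50, 8))
        pcs = noise_pcs(channels, 5)
        cleaned = regress_confounds(y, pcs)

        def band_power(sig):
            spec = np.abs(np.fft.rfft(sig, axis=0)) ** 2
            freqs = np.fft.rfftfreq(50, 1.0)
            sel = (freqs > 0.35) & (freqs < 0.45)
            return spec[sel].sum()

        assert band_power(cleaned.data) < 0.1 * band_power(y - y.mean(0))

    def test_collinear_columns_dropped_and_recorded(self):
        rng = np.random.default_rng(5)
        c = rng.standard_normal((40, 2))
        conf = np.column_stack([c, c[:, 0] * 2.0])
        cleaned = regress_confounds(rng.standard_normal((40, 3)), conf)
        assert len(cleaned.dropped_confounds) == 1


class TestBandpass:
    def test_stopband_attenuation(self):
        t = np.arange(200.0)
        sig = np.sin(2 * np.pi * 0.25 * t)[:, None]
        out = bandpass(sig, 0.01, 0.1, 1.0)
        assert (out**2).sum() < 0.01 * (sig**2).sum()

    def test_passband_preservation(self):
        t = np.arange(200.0)
        sig = np.sin(2 * np.pi * 0.04 * t)[:, None]
        out = bandpass(sig, 0.01, 0.1, 1.0)
        assert (out**2).sum() > 0.9 * (sig**2).sum()

    def test_constant_series_zeroed(self):
        out = bandpass(np.full((64, 3), 7.5), 0.01, 0.1, 1.0)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((50, 2)), 0.01, 0.6, 1.0)
        with pytest.raises(ValueError):
            bandpass(np.zeros((50, 2)), 0.2, 0.1, 1.0)


class TestPreprocessSubject:
    def test_clean_subject_retains_most_frames(self, atlas16, truth16):
        from fetalconn.cohort import simulate_subject

        rec = simulate_subject(atlas16, truth16, 30.0, seed=8)
        clean = preprocess_subject(rec)
        assert clean.usable
        assert clean.n_frames >= 41

    def test_spike_frames_censored_exactly(self, small_cohort):
        rec = small_cohort[0]
        disp = displacement(rec.motion)
        expected = np.flatnonzero(disp.values <= 2.0)
        clean = preprocess_subject(rec)
        assert np.array_equal(clean.frame_indices, expected)

    def test_output_orthogonal_to_all_confounds(self, small_cohort):
        clean = preprocess_subject(small_cohort[1])
        norms = np.linalg.norm(clean.confounds, axis=0) * np.linalg.norm(clean.data, axis=0).max()
        inner = np.abs(clean.confounds.T @ clean.data)
        assert inner.max() < 1e-8 * max(norms.max(), 1.0)

    def test_too_few_frames_flagged_unusable(self, atlas16, truth16):
        from fetalconn.cohort import simulate_subject

        rec = simulate_subject(atlas16, truth16, 30.0, seed=8)
        rec.motion[1::2, 3] += np.arange(1, 26) * 10.0  # jumps censor half the scan
        clean = preprocess_subject(rec, PreprocessConfig(min_frames=30))
        assert not clean.usable
        assert clean.qc["n_retained"] < 30

    def test_censoring_reduces_temporal_variance(self, atlas16, truth16):
        # motion spikes inflate variance; removing them lowers the per-region SD
        from fetalconn.cohort import NoiseConfig, simulate_subject

        noisy = NoiseConfig(spike_prob=0.15, spike_amp=5.0)
        reduced = 0
        total = 0
        for seed in range(5):
            rec = simulate_subject(atlas16, truth16, 30.0, noise=noisy, seed=seed)
            mask = censor(displacement(rec.motion))
            if mask.all():
                continue
            sd_pre = rec.timeseries.std(0)
            sd_post = rec.timeseries[mask].std(0)
            reduced += int((sd_post <= sd_pre).sum())
            total += rec.timeseries.shape[1]
        assert total > 0
        assert reduced / total >= 0.95

    def test_motion_uncorrelated_with_age_across_cohorts(self, atlas16, truth16):
        from fetalconn.cohort import simulate_cohort

        not_significant = 0
        for seed in range(10):
            cohort = simulate_cohort(atlas16, truth16, n_subjects=32, seed=100 + seed)
            ga = [r.ga_weeks for r in cohort]
            mot = [displacement(r.motion).values.mean() for r in cohort]
            _, p = scipy.stats.pearsonr(ga, mot)
            not_significant += int(p > 0.05)
        assert not_significant >= 9
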