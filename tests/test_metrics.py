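"""Measurement stack: spectra, phases, PLV, circular statistics, lags, GLM,
ICA, connectivity, features and group comparison."""

import numpy as np
import pytest

from neurosync import (
    ALPHA_BAND,
    BETA_BAND,
    BandSpec,
    band_power,
    circular_stats,
    correlation_matrix,
    extract_features,
    glm_fit,
    group_compare,
    ica_decompose,
    instantaneous_phase,
    phase_lag,
    plv,
)
from neurosync.signals import DEFAULT_REGION_MIXTURES, simulate_region_bold, task_block_design


class TestBandPower:
    def test_pure_alpha_tone_dominates_beta(self):
        t = np.arange(0, 20, 0.01)
        x = np.sin(2 * np.pi * 10 * t)
        assert band_power(x, 100.0, ALPHA_BAND) / band_power(x, 100.0, BETA_BAND) > 20

    def test_zero_series_has_zero_power(self):
        assert band_power(np.zeros(1000), 100.0, ALPHA_BAND) == 0.0

    def test_white_noise_ratio_tracks_bandwidth_ratio(self, rng):
        ratios = []
        for _ in range(50):
            x = rng.standard_normal(2000)
            ratios.append(band_power(x, 100.0, ALPHA_BAND) / band_power(x, 100.0, BETA_BAND))
        expected = (12 - 8) / (30 - 13)
        assert abs(np.mean(ratios) - expected) < 0.3 * expected

    def test_power_is_quadratic_in_amplitude(self, rng):
        x = rng.standard_normal(2000)
        assert band_power(3 * x, 100.0, BETA_BAND) == pytest.approx(
            9 * band_power(x, 100.0, BETA_BAND)
        )

    def test_undersampled_band_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(1000), 50.0, BETA_BAND)


class TestInstantaneousPhase:
    def test_tone_phase_advances_at_carrier_rate(self):
        t = np.arange(0, 10, 0.01)
        ph = instantaneous_phase(np.sin(2 * np.pi * 10 * t), 100.0, ALPHA_BAND)
        slope = np.polyfit(t[100:-100], np.unwrap(ph)[100:-100], 1)[0]
        assert abs(slope - 2 * np.pi * 10) / (2 * np.pi * 10) < 0.01

    def test_values_lie_in_principal_interval(self):
        t = np.arange(0, 5, 0.01)
        ph = instantaneous_phase(np.sin(2 * np.pi * 9 * t), 100.0, ALPHA_BAND)
        assert np.all(ph > -np.pi) and np.all(ph <= np.pi)

    def test_quarter_period_shift_reads_half_pi(self):
        t = np.arange(0, 20, 0.01)
        a = np.sin(2 * np.pi * 10 * t)
        b = np.sin(2 * np.pi * 10 * (t - 0.025))
        dphi = instantaneous_phase(a, 100.0, ALPHA_BAND) - instantaneous_phase(b, 100.0, ALPHA_BAND)
        mean_diff = np.angle(np.mean(np.exp(1j * dphi[200:-200])))
        assert abs(mean_diff - np.pi / 2) < 0.05

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.ones(500), 100.0, ALPHA_BAND)


class TestPlv:
    def test_identical_series_fully_locked(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert plv(ph, ph) == pytest.approx(1.0)

    def test_constant_offset_invariance(self, rng):
        ph = rng.uniform(-np.pi, np.pi, 500)
        assert plv(ph, ph + 1.3) == pytest.approx(1.0)

    def test_independent_phases_near_null_level(self, rng):
        a = rng.uniform(-np.pi, np.pi, 10_000)
        b = rng.uniform(-np.pi, np.pi, 10_000)
        assert plv(a, b) < 0.05  # null expectation ≈ 1/√n ≈ 0.009

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            a = rng.uniform(-np.pi, np.pi, 100)
            b = a + rng.normal(0, 0.5, 100)
            assert 0.0 <= plv(a, b) <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(10), np.zeros(11))


class TestCircularStats:
    def test_point_mass_has_zero_spread(self):
        s = circular_stats(np.full(40, 0.5))
        assert s.mean_direction == pytest.approx(0.5)
        assert s.circular_std == pytest.approx(0.0, abs=1e-6)

    def test_wraparound_mean_near_pi_not_zero(self):
        s = circular_stats(np.array([3.1, -3.1]))
        assert abs(abs(s.mean_direction) - np.pi) < 0.05

    def test_uniform_angles_have_large_spread(self, rng):
        s = circular_stats(rng.uniform(-np.pi, np.pi, 10_000))
        assert s.circular_std > 2.0

    def test_rotation_invariance_of_spread(self, rng):
        angles = rng.normal(0.3, 0.4, 1000)
        a = circular_stats(angles)
        b = circular_stats(np.angle(np.exp(1j * (angles + 2.0))))
        assert a.circular_std == pytest.approx(b.circular_std, rel=1e-9)

    def test_zero_resultant_flagged(self):
        s = circular_stats(np.array([0.0, np.pi]))
        assert s.undefined_direction


class TestPhaseLag:
    def test_identical_series_have_zero_lag(self, rng):
        x = np.cumsum(rng.standard_normal(1000))
        assert phase_lag(x, x, fs=100.0, max_lag=1.0) == 0.0

    def test_delayed_copy_recovers_positive_lag(self, rng):
        x = np.cumsum(rng.standard_normal(3000))
        b = np.roll(x, 20)  # 0.2 s at 100 Hz; positive lag = b trails a
        assert phase_lag(x[100:-100], b[100:-100], fs=100.0, max_lag=1.0) == pytest.approx(0.2)

    def test_antisymmetry(self, rng):
        a = np.cumsum(rng.standard_normal(2000))
        b = np.roll(a, 13)
        lag_ab = phase_lag(a[50:-50], b[50:-50], fs=100.0, max_lag=1.0)
        lag_ba = phase_lag(b[50:-50], a[50:-50], fs=100.0, max_lag=1.0)
        assert lag_ab == pytest.approx(-lag_ba)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            phase_lag(np.ones(100), np.arange(100.0), fs=100.0, max_lag=0.1)


class TestGlmFit:
    def test_exact_linear_relation_recovered(self):
        x = np.arange(100.0)
        res = glm_fit(2.0 * x, [x])
        assert res.params[1] == pytest.approx(2.0)
        assert res.rsquared == pytest.approx(1.0)

    def test_noise_free_mixture_identified_exactly(self):
        task = task_block_design(300, dt=1.0)
        rng = np.random.default_rng(5)
        eeg = rng.standard_normal(300).cumsum()
        mix = tuple(
            type(m)(m.name, m.w_task, m.w_eeg, 0.0) for m in DEFAULT_REGION_MIXTURES[:2]
        )
        regions, _, conv_task, conv_eeg = simulate_region_bold(task, eeg, mix, dt=1.0, seed=0)
        res = glm_fit(regions[0], [conv_task, conv_eeg])
        assert res.params[1] == pytest.approx(0.6, abs=1e-8)
        assert res.params[2] == pytest.approx(0.3, abs=1e-8)
        assert res.rsquared == pytest.approx(1.0)

    def test_independent_noise_explains_nothing(self, rng):
        r2 = []
        for _ in range(50):
            y = rng.standard_normal(1000)
            x = rng.standard_normal(1000)
            r2.append(glm_fit(y, [x]).rsquared)
        assert np.mean(r2) < 0.01

    def test_collinear_design_rejected_with_names(self):
        x = np.arange(50.0)
        with pytest.raises(ValueError, match="x0"):
            glm_fit(x, [x, 2.0 * x], names=["x0", "x1"])

    def test_coefficient_recovery_within_confidence_intervals(self):
        # generative weights fall inside the 95% CI in ≥ 90% of replicates
        task = task_block_design(300, dt=1.0)
        covered = 0
        trials = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            eeg = rng.standard_normal(300).cumsum()
            mix = (type(DEFAULT_REGION_MIXTURES[0])("Prefrontal", 0.6, 0.3, 0.05),)
            regions, _, conv_task, conv_eeg = simulate_region_bold(task, eeg, mix, dt=1.0, seed=rng)
            res = glm_fit(regions[0], [conv_task, conv_eeg])
            for idx, true_w in ((1, 0.6), (2, 0.3)):
                lo = res.params[idx] - 1.96 * res.bse[idx]
                hi = res.params[idx] + 1.96 * res.bse[idx]
                covered += lo <= true_w <= hi
                trials += 1
        assert covered / trials >= 0.90


class TestIcaDecompose:
    def test_known_sources_recovered(self, rng):
        t = np.arange(0, 10, 0.01)
        sources = np.vstack([np.sin(2 * np.pi * 1.3 * t), rng.uniform(-1, 1, len(t))])
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        mixed = A @ sources
        comps, _, _ = ica_decompose(mixed, k=2, seed=0)
        corr = np.abs(np.corrcoef(np.vstack([comps, sources]))[:2, 2:])
        # each source matched by some component up to sign/permutation
        assert corr.max(axis=0).min() >= 0.95

    def test_component_count_and_unit_variance(self, rng):
        signals = rng.standard_normal((4, 500))
        comps, mixing, _ = ica_decompose(signals, k=3, seed=1)
        assert comps.shape == (3, 500)
        assert mixing.shape == (4, 3)
        assert np.allclose(comps.std(axis=1), 1.0, atol=0.05)

    def test_full_rank_reconstruction(self, rng):
        signals = rng.standard_normal((3, 800))
        comps, mixing, _ = ica_decompose(signals, k=3, seed=2)
        recon = mixing @ comps
        z = (signals - signals.mean(axis=1, keepdims=True)) / signals.std(axis=1, keepdims=True)
        assert np.allclose(recon, z, atol=1e-6)

    def test_k_larger_than_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            ica_decompose(rng.standard_normal((2, 100)), k=3)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal(self, rng):
        c = correlation_matrix(rng.standard_normal((5, 200)))
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T)
        assert np.all(np.abs(c) <= 1.0 + 1e-12)

    def test_negated_channel_perfectly_anticorrelated(self, rng):
        x = rng.standard_normal(300)
        c = correlation_matrix(np.vstack([x, -x]))
        assert c[0, 1] == pytest.approx(-1.0)

    def test_constant_channel_named_in_error(self, rng):
        sig = np.vstack([rng.standard_normal(100), np.ones(100)])
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(sig, names=["ok", "flat"])


class TestExtractFeatures:
    def test_constant_run_mean(self):
        R = np.full(500, 0.5)
        feats = extract_features(R, np.zeros(500), R, fs=100.0)
        assert feats["mean_R"] == 0.5
        assert feats["std_E"] == 0.0

    def test_self_reference_perfect_alignment(self, rng):
        R = np.cumsum(rng.standard_normal(1000)) * 0.001 + 0.5
        feats = extract_features(R, np.ones(1000), R, fs=100.0)
        assert feats["corr_R"] == pytest.approx(1.0)
        assert feats["phase_lag"] == 0.0

    def test_delayed_reference_recovers_lag(self, rng):
        R = np.cumsum(rng.standard_normal(3000)) * 0.01 + 0.5
        delayed = np.roll(R, 20)
        feats = extract_features(delayed[100:-100], np.ones(2800), R[100:-100], fs=100.0)
        assert feats["phase_lag"] == pytest.approx(0.2)


class TestGroupCompare:
    def test_identical_groups_show_no_effect(self, rng):
        g = rng.standard_normal(30)
        res = group_compare([g, g.copy(), g.copy()])
        assert res["F"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.standard_normal(25), rng.standard_normal(25) + 0.5
        res = group_compare([a, b])
        t = res["pairwise"].iloc[0]["t"]
        assert res["F"] == pytest.approx(t**2)

    def test_large_separation_is_significant(self, rng):
        a = rng.standard_normal(20)
        b = rng.standard_normal(20) + 5.0
        assert group_compare([a, b])["p"] < 0.001

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            group_compare([np.ones(5), np.full(5, 2.0)])
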