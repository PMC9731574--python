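"""Cross-frequency coupling: Tort MI against a direct-formula oracle,
shuffle z-normalization, peak-matched condition contrasts, waveshape
asymmetry index and the harmonic control."""

import numpy as np
import pytest
from scipy import stats

import spikefield as sf
from spikefield import cfc, spectral


def oracle_mi(phase, amp, n_bins=18):
    """Independent loop-based histogram-entropy implementation."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    means = []
    for j in range(n_bins):
        sel = (phase >= edges[j]) & (phase < edges[j + 1])
        means.append(amp[sel].mean() if sel.any() else 0.0)
    p = np.array(means) / np.sum(means)
    h = 0.0
    for pj in p:
        if pj > 0:
            h -= pj * np.log(pj)
    return (np.log(n_bins) - h) / np.log(n_bins)


class TestModulationIndex:
    def test_constant_amplitude_gives_zero(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 5000)
        mi, p = cfc.modulation_index(phase, np.full(5000, 2.0))
        assert mi == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(p, 1.0 / 18.0, atol=1e-12)

    def test_single_bin_mass_gives_one(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 2000)
        amp = np.where((phase >= 0) & (phase < 2 * np.pi / 18), 1.0, 0.0)
        mi, _ = cfc.modulation_index(phase, amp)
        assert mi == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        sig = sf.gen_pac_lfp(sf.PACSpec(coupling_depth=0.5), 20.0, 1000.0,
                             noise_sd=0.0, seed=7)
        mi, _ = cfc.modulation_index(sig.theta_phase, sig.gamma_env)
        assert mi == pytest.approx(
            oracle_mi(sig.theta_phase, sig.gamma_env), abs=1e-12)

    def test_amplitude_rescaling_invariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 3000)
        amp = rng.gamma(2.0, 1.0, 3000)
        assert cfc.modulation_index(phase, 7.3 * amp)[0] == pytest.approx(
            cfc.modulation_index(phase, amp)[0], abs=1e-14)

    def test_bin_rotation_equivariance(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 3000)
        amp = 1.0 + 0.4 * np.cos(phase)
        shift = 3 * (2 * np.pi / 18)  # whole bins
        mi0, _ = cfc.modulation_index(phase, amp)
        mi1, _ = cfc.modulation_index(
            np.mod(phase + shift + np.pi, 2 * np.pi) - np.pi, amp)
        assert mi1 == pytest.approx(mi0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cfc.modulation_index(np.zeros(5), np.zeros(6))


class TestShuffleZ:
    def _trials(self, rng, depth, n_trials=24, fs=1000.0, dur=1.0,
                f_theta=8.0, f_gamma=70.0):
        phases, amps = [], []
        for _ in range(n_trials):
            sig = sf.gen_pac_lfp(
                sf.PACSpec(theta_freq=f_theta, gamma_freq=f_gamma,
                           coupling_depth=depth),
                dur, fs, noise_sd=0.3, seed=rng.integers(2**31))
            analytic = spectral.hilbert_phase(sig.samples, fs, f_gamma, 16.0)
            phases.append(sig.theta_phase)
            amps.append(np.abs(analytic[0]))
        return phases, amps

    def test_planted_coupling_gives_large_z(self, rng):
        phases, amps = self._trials(rng, depth=0.8)
        out = cfc.mi_shuffle_z(phases, amps, n_shuffles=100, seed=1)
        assert out["z"] > 3.0

    def test_null_z_centered_under_trial_imbalance(self, rng):
        """No coupling, 80/20-style trial counts: mean shuffle-z over
        seeds stays near zero (bias-free contrast)."""
        zs = []
        for s in range(12):
            phases, amps = self._trials(rng, depth=0.0,
                                        n_trials=8 if s % 2 else 32)
            out = cfc.mi_shuffle_z(phases, amps, n_shuffles=60, seed=s)
            zs.append(out["z"])
        assert abs(np.mean(zs)) < 0.6

    def test_peak_matched_contrast_detects_hit_only_pac(self, rng):
        z_h, z_m = [], []
        for s in range(12):
            ph_h, am_h = self._trials(rng, depth=0.7, n_trials=16)
            ph_m, am_m = self._trials(rng, depth=0.0, n_trials=12)
            out = cfc.peak_matched_cfc(
                {sf.HIT: (ph_h, am_h), sf.MISS: (ph_m, am_m)},
                n_shuffles=60, seed=s)
            z_h.append(out[sf.HIT]["z"])
            z_m.append(out[sf.MISS]["z"])
        t, p = stats.ttest_rel(z_h, z_m)
        assert t > 0 and p < 0.05

    def test_equal_conditions_difference_centered(self, rng):
        diffs = []
        for s in range(10):
            ph_h, am_h = self._trials(rng, depth=0.4, n_trials=12)
            ph_m, am_m = self._trials(rng, depth=0.4, n_trials=12)
            out = cfc.peak_matched_cfc(
                {sf.HIT: (ph_h, am_h), sf.MISS: (ph_m, am_m)},
                n_shuffles=60, seed=s)
            diffs.append(out[sf.HIT]["z"] - out[sf.MISS]["z"])
        t, p = stats.ttest_1samp(diffs, 0.0)
        assert p > 0.05


class TestConditionTest:
    def test_planted_effect_detected(self, rng):
        z_hit = rng.normal(2.0, 1.0, 20)
        z_miss = rng.normal(0.0, 1.0, 20)
        out = cfc.cfc_condition_test(z_hit, z_miss)
        assert out["p"] < 0.05
        assert out["median_diff"] > 0

    def test_type_one_error_rate(self, rng):
        n_false = 0
        n_runs = 200
        for _ in range(n_runs):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            n_false += cfc.cfc_condition_test(a, b)["p"] < 0.05
        assert n_false / n_runs <= 0.09

    def test_single_channel_refused(self):
        with pytest.raises(ValueError):
            cfc.cfc_condition_test([1.0], [0.0])

    def test_small_sample_uses_exact_test(self, rng):
        out = cfc.cfc_condition_test(rng.normal(size=5), rng.normal(size=5))
        assert 0.0 < out["p"] <= 1.0


class TestHarmonic:
    def test_eighth_harmonic_arithmetic(self):
        assert cfc.harmonic_frequency(9.0) == 72.0
        assert cfc.harmonic_frequency(8.0) == 64.0

    def _sawtooth_theta(self, rng, n_trials=16, fs=1000.0, dur=1.0,
                        f=8.0, rise_frac=0.8):
        """Asymmetric (non-sinusoidal) theta with no genuine gamma PAC."""
        t = np.arange(int(dur * fs)) / fs
        trials = []
        for _ in range(n_trials):
            phi0 = rng.uniform(0, 1)
            saw = np.mod(f * t + phi0, 1.0)
            x = np.where(saw < rise_frac, saw / rise_frac,
                         (1.0 - saw) / (1.0 - rise_frac))
            trials.append(2.0 * x - 1.0 + 0.05 * rng.normal(size=t.size))
        return np.vstack(trials), f

    def test_sawtooth_flags_spurious_coupling(self, rng):
        """Asymmetric theta with no true PAC: the MI contrast at the 8th
        harmonic is at least as strong as at a nearby non-harmonic
        'gamma', so the control flags the waveshape."""
        data, f = self._sawtooth_theta(rng)
        fs = 1000.0
        phase = np.angle(spectral.hilbert_phase(data, fs, f, 4.0))
        amp_harm = np.abs(spectral.wavelet_transform(
            data, fs, freqs=[8 * f], n_cycles=12, derivative=True))[:, 0]
        amp_off = np.abs(spectral.wavelet_transform(
            data, fs, freqs=[8 * f + 9.0], n_cycles=12, derivative=True))[:, 0]
        mi_harm = cfc.modulation_index(phase.ravel(), amp_harm.ravel())[0]
        mi_off = cfc.modulation_index(phase.ravel(), amp_off.ravel())[0]
        assert mi_harm >= mi_off

    def test_genuine_pac_beats_harmonic_control(self, rng):
        """Sinusoidal theta with planted 70 Hz PAC (theta at 8 Hz, so the
        8th harmonic is 64 Hz... kept distinct at 7 Hz -> 56 Hz): the
        real-gamma contrast exceeds the harmonic contrast."""
        fs = 1000.0
        f_theta, f_gamma = 7.0, 70.0
        hit_z, miss_z, hit_zh, miss_zh = [], [], [], []
        for s, depth in ((0, 0.8), (1, 0.0)):
            phases, amps, amps_h = [], [], []
            r = np.random.default_rng(50 + s)
            for _ in range(14):
                sig = sf.gen_pac_lfp(
                    sf.PACSpec(theta_freq=f_theta, gamma_freq=f_gamma,
                               coupling_depth=depth),
                    1.0, fs, noise_sd=0.3, seed=r.integers(2**31))
                phases.append(sig.theta_phase)
                amps.append(np.abs(spectral.hilbert_phase(
                    sig.samples, fs, f_gamma, 16.0))[0])
                amps_h.append(np.abs(spectral.hilbert_phase(
                    sig.samples, fs, cfc.harmonic_frequency(f_theta),
                    16.0))[0])
            real = cfc.mi_shuffle_z(phases, amps, n_shuffles=60, seed=s)
            harm = cfc.mi_shuffle_z(phases, amps_h, n_shuffles=60, seed=s)
            if depth > 0:
                hit_z, hit_zh = real["z"], harm["z"]
            else:
                miss_z, miss_zh = real["z"], harm["z"]
        out = cfc.harmonic_control({sf.HIT: hit_z, sf.MISS: miss_z},
                                   {sf.HIT: hit_zh, sf.MISS: miss_zh})
        assert out["delta_real"] > out["delta_harmonic"]
        assert not out["suspect_waveshape"]


class TestAsymmetryIndex:
    def _sawtooth(self, rise_ms, fall_ms, n_cycles=30, fs=1000.0, reverse=False):
        period = rise_ms + fall_ms
        t_ms = np.arange(int(n_cycles * period * fs / 1e3)) / fs * 1e3
        ph = np.mod(t_ms, period)
        x = np.where(ph < rise_ms, -1.0 + 2.0 * ph / rise_ms,
                     1.0 - 2.0 * (ph - rise_ms) / fall_ms)
        return x[::-1].copy() if reverse else x

    def test_sinusoid_is_symmetric(self):
        t = np.arange(3000) / 1000.0
        x = np.cos(2 * np.pi * 10.0 * t)
        res = cfc.asymmetry_index(np.tile(x, (5, 1)), 1000.0, 10.0)
        assert abs(res.ai) < 0.02

    def test_sawtooth_closed_form(self):
        """75 ms rise / 25 ms fall at 10 Hz: AI = (75 - 25) / 100 = 0.5."""
        x = self._sawtooth(75.0, 25.0)
        res = cfc.asymmetry_index(np.tile(x, (3, 1)), 1000.0, 10.0)
        assert res.ai == pytest.approx(0.5, abs=0.02)
        assert res.t_asc_ms == pytest.approx(75.0, abs=2.0)
        assert res.t_desc_ms == pytest.approx(25.0, abs=2.0)

    def test_time_reversal_flips_sign(self):
        x = self._sawtooth(75.0, 25.0, reverse=True)
        res = cfc.asymmetry_index(np.tile(x, (3, 1)), 1000.0, 10.0)
        assert res.ai == pytest.approx(-0.5, abs=0.02)

    @pytest.mark.parametrize("noise", [0.1, 0.3, 0.5])
    def test_noise_robustness(self, rng, noise):
        """Planted asymmetry recovered within +-0.05 for noise SD up to
        50% of the signal amplitude (averaged over trials)."""
        x = self._sawtooth(70.0, 30.0, n_cycles=40)
        trials = np.tile(x, (40, 1)) + noise * rng.normal(size=(40, x.size))
        res = cfc.asymmetry_index(trials, 1000.0, 10.0)
        assert res.ai == pytest.approx(0.4, abs=0.05)

    def test_too_short_window_rejected(self):
        x = np.cos(2 * np.pi * 5.0 * np.arange(100) / 1000.0)
        with pytest.raises(ValueError):
            cfc.asymmetry_index(x[None, :], 1000.0, 5.0)
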