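"""Spike-field coupling: PPC against the O(n^2) oracle, Rayleigh test
against an independent implementation, screening behavior, pair-count
nulls, condition contrasts, peak detection and the selection-bias
control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikefield as sf
from spikefield import sfc
from spikefield._stats import fdr_bh, rayleigh_test
from spikefield.sfc import PairPhaseData


def brute_force_ppc(phases):
    n = len(phases)
    acc = 0.0
    for j in range(n):
        for k in range(j + 1, n):
            acc += np.cos(phases[j] - phases[k])
    return 2.0 * acc / (n * (n - 1))


class TestPPC:
    def test_equal_phases_give_one(self):
        assert sfc.ppc(np.full(17, 0.8)) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_pair_gives_minus_one(self):
        assert sfc.ppc(np.array([0.0, np.pi])) == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 50, 200])
    def test_matches_brute_force_oracle(self, rng, n):
        phases = rng.uniform(-np.pi, np.pi, n)
        assert sfc.ppc(phases) == pytest.approx(brute_force_ppc(phases),
                                                abs=1e-12)

    @given(st.floats(-np.pi, np.pi))
    @settings(max_examples=25, deadline=None, derandomize=True,
              database=None)
    def test_invariant_under_global_rotation(self, rotation):
        rng = np.random.default_rng(99)
        phases = rng.uniform(-np.pi, np.pi, 40)
        assert sfc.ppc(phases + rotation) == pytest.approx(
            sfc.ppc(phases), abs=1e-10)

    def test_uniform_phases_unbiased(self, rng):
        vals = [sfc.ppc(rng.uniform(-np.pi, np.pi, 20)) for _ in range(2000)]
        assert abs(np.mean(vals)) < 0.005

    def test_too_few_phases_rejected(self):
        with pytest.raises(ValueError):
            sfc.ppc(np.array([0.1]))


class TestRayleigh:
    @pytest.mark.parametrize("kappa,n", [(0.0, 50), (1.0, 30), (3.0, 100)])
    def test_matches_independent_implementation(self, rng, kappa, n):
        from pingouin import circ_rayleigh

        phases = rng.vonmises(0.0, kappa, n) if kappa > 0 else \
            rng.uniform(-np.pi, np.pi, n)
        z, p = rayleigh_test(phases)
        z_ref, p_ref = circ_rayleigh(phases)
        assert z == pytest.approx(z_ref, rel=1e-9)
        # the two standard small-sample approximations agree to ~1e-3
        assert p == pytest.approx(p_ref, rel=1e-2, abs=1e-4)


def _pair_from_arrays(trial_phases, spike_samples, labels, freqs=None,
                      **kwargs):
    freqs = freqs if freqs is not None else np.arange(trial_phases.shape[1],
                                                      dtype=float) + 2.0
    defaults = dict(unit_id="u0", channel=0, locality="distal")
    defaults.update(kwargs)
    return PairPhaseData(freqs=freqs, trial_phases=trial_phases,
                         spike_samples=spike_samples,
                         labels=np.asarray(labels), **defaults)


def _null_pair(rng, n_trials=20, n_freqs=8, n_samp=400, spikes_per_trial=10,
               n_hits=None):
    """Pair with uniform phases and random spikes: no coupling."""
    phases = rng.uniform(-np.pi, np.pi, (n_trials, n_freqs, n_samp))
    spikes = [np.sort(rng.integers(0, n_samp, spikes_per_trial))
              for _ in range(n_trials)]
    n_hits = n_trials // 2 if n_hits is None else n_hits
    labels = np.array([sf.HIT] * n_hits + [sf.MISS] * (n_trials - n_hits))
    return _pair_from_arrays(phases, spikes, labels)


class TestScreening:
    def test_planted_locking_detected_at_frequency(self):
        pair = sf.synth.gen_pair_phase_data(
            "low", {"hit": 8.0, "miss": 8.0}, kappa=2.0, rate=10.0, seed=2)
        scr = sfc.screen_pair(pair)
        assert scr.significant
        sig_freqs = pair.freqs[scr.p_fdr < 0.05]
        assert np.any(np.abs(sig_freqs - 8.0) <= 2.0)

    def test_too_few_spikes_excluded(self, rng):
        pair = _null_pair(rng, spikes_per_trial=1, n_trials=29)
        scr = sfc.screen_pair(pair)
        assert scr.excluded and not scr.significant

    def test_type_one_error_controlled(self, rng):
        """Uniform phases: the Rayleigh+FDR screen flags at most ~5% of
        pairs (smaller replica of the full acceptance simulation)."""
        n_sig = 0
        n_runs = 200
        for _ in range(n_runs):
            phases = rng.uniform(-np.pi, np.pi, (40, 10))
            scr = sfc.screen_phases(phases, np.arange(10.0) + 2.0)
            n_sig += scr.significant
        assert n_sig / n_runs <= 0.055 + 0.03


class TestPairCountNull:
    def test_null_session_count_inside_interval(self, rng):
        pairs = [_null_pair(rng) for _ in range(15)]
        res = sfc.pair_count_null(pairs, n_shuffles=30, n_draws=2000, seed=1)
        lo, hi = np.percentile(res["null_counts"], [2.5, 97.5])
        assert lo <= res["observed"] <= hi
        assert res["p"] > 0.01

    def test_planted_couplings_detected(self, rng):
        """Moderate locking with few spikes per trial: real pairs screen
        significant while trial-shuffled pairings (which break the
        spike-LFP phase relation but keep spike rhythmicity) do not."""
        pairs = [sf.synth.gen_pair_phase_data(
            "high", {"hit": 70.0, "miss": 70.0}, kappa=2.0, rate=6.0,
            n_hits=12, n_misses=8, freq_walk_sd=0.05, seed=s)
            for s in range(8)]
        res = sfc.pair_count_null(pairs, n_shuffles=30, n_draws=2000, seed=2)
        assert res["observed"] >= 7
        assert res["p"] < 0.01

    def test_zero_pairs_degenerate(self):
        res = sfc.pair_count_null([], seed=0)
        assert res["observed"] == 0
        assert np.all(res["null_counts"] == 0)


class TestConditionContrast:
    def test_insufficient_condition_spikes_dropped(self, rng):
        pair = _null_pair(rng, n_trials=20, spikes_per_trial=10, n_hits=1)
        good = _null_pair(rng, n_trials=20, spikes_per_trial=10)
        out = sfc.condition_contrast([pair, good])
        assert len(out.pair_ids) == 1
        assert len(out.dropped) == 1

    def test_identical_conditions_rarely_survive_fdr(self, rng):
        n_false = 0
        n_runs = 10
        for run in range(n_runs):
            pairs = [_null_pair(rng, n_trials=24, spikes_per_trial=15)
                     for _ in range(12)]
            out = sfc.condition_contrast(pairs)
            n_false += bool(out.significant.any())
        assert n_false <= 2


class TestPeakDetection:
    def test_peak_found_and_threshold_enforced(self):
        freqs = np.arange(40.0, 81.0, 2.0)
        spec = 0.001 + 0.05 * np.exp(-0.5 * ((freqs - 70.0) / 4.0) ** 2)
        got = sfc.detect_peak(freqs, spec, (45.0, 75.0))
        assert got[0] == 70.0
        flat = np.full(freqs.size, 0.004)  # below the 0.005 threshold
        assert sfc.detect_peak(freqs, flat, (45.0, 75.0)) is None

    def test_tie_breaks_toward_lower_frequency(self):
        freqs = np.arange(1.0, 14.0)
        spec = np.zeros(freqs.size)
        spec[[4, 8]] = 0.02  # equal peaks at 5 and 9 Hz
        got = sfc.detect_peak(freqs, spec, (3.0, 13.0))
        assert got[0] == 5.0

    def test_planted_frequency_shift_recovered(self):
        pairs = [sf.synth.gen_pair_phase_data(
            "low", {"hit": 8.0, "miss": 5.0}, kappa=4.0, rate=25.0,
            n_hits=16, n_misses=12, seed=100 + s) for s in range(10)]
        res = sfc.peak_frequency_shift(pairs, (3.0, 13.0))
        shift = (res["table"]["peak_hit"] - res["table"]["peak_miss"]).mean()
        assert res["n_pairs"] >= 8
        assert 2.0 <= shift <= 4.0
        assert res["p"] < 0.05
        assert res["t"] > 0

    def test_flat_spectra_excluded(self, rng):
        pairs = [_null_pair(rng, spikes_per_trial=3, n_trials=24)]
        res = sfc.peak_frequency_shift(pairs, (3.0, 13.0))
        assert res["n_pairs"] <= 1  # uniform phases rarely yield peaks > 0.005


class TestSelectionBias:
    def test_unbalanced_null_peak_shift_centered_at_zero(self):
        """80/20 hit/miss imbalance with identical locking frequency in
        both conditions: the peak frequencies of the bias-corrected
        condition spectra do not shift systematically.  (The corrected z
        spectra feed the same peak-frequency analysis as the raw PPC.)
        """
        diffs = []
        for s in range(6):
            pair = sf.synth.gen_pair_phase_data(
                "high", {"hit": 70.0, "miss": 70.0}, kappa=2.5, rate=15.0,
                n_hits=32, n_misses=8, seed=200 + s)
            out = sfc.selection_bias_control(pair, n_shuffles=150, seed=s)
            if out["z_hit"] is None:
                continue
            pk_h = sfc.detect_peak(pair.freqs, out["z_hit"], (45.0, 75.0),
                                   threshold=0.0)
            pk_m = sfc.detect_peak(pair.freqs, out["z_miss"], (45.0, 75.0),
                                   threshold=0.0)
            if pk_h is None or pk_m is None:
                continue
            diffs.append(pk_h[0] - pk_m[0])
        assert len(diffs) >= 4
        assert abs(np.mean(diffs)) <= 2.0  # one grid step

    def test_planted_shift_survives_correction(self):
        """Moderate locking in white noise gives peaked spectra; the
        corrected condition spectra keep the planted 70 vs 62 Hz order."""
        shifts = []
        for s in range(4):
            pair = sf.synth.gen_pair_phase_data(
                "high", {"hit": 70.0, "miss": 62.0}, kappa=2.0, rate=20.0,
                noise_sd=1.0, seed=300 + s)
            out = sfc.selection_bias_control(pair, n_shuffles=150, seed=s)
            pk_h = sfc.detect_peak(pair.freqs, out["z_hit"], (45.0, 75.0),
                                   threshold=0.0)
            pk_m = sfc.detect_peak(pair.freqs, out["z_miss"], (45.0, 75.0),
                                   threshold=0.0)
            if pk_h is None or pk_m is None:
                continue
            shifts.append(pk_h[0] - pk_m[0])
        assert len(shifts) >= 3
        assert np.mean(shifts) > 2.0

    def test_no_coupling_warns_about_kept_shuffles(self, rng):
        pair = _null_pair(rng, n_trials=30, spikes_per_trial=15)
        out = sfc.selection_bias_control(pair, n_shuffles=100, seed=2)
        assert out["warning"]


class TestFdr:
    def test_bh_reference_values(self):
        # worked example: m=5, q=0.05
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.20])
        reject, p_adj = fdr_bh(p, alpha=0.05)
        assert list(reject) == [True, True, False, False, False]
        assert p_adj[0] == pytest.approx(0.005)
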