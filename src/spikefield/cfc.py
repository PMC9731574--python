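"""Theta-gamma cross-frequency coupling: Tort modulation index at
condition-matched peak frequencies, trial-shuffle z-normalization,
waveshape-asymmetry and harmonic controls.

The modulation index (MI) quantifies how strongly the amplitude of a
fast oscillation depends on the phase of a slow one: gamma amplitude is
averaged in 18 theta-phase bins, the binned distribution P_j is compared
to uniform via its entropy H, and MI = (log N - H) / log N in [0, 1].
Because a non-sinusoidal (asymmetric) theta can fake such coupling at
its harmonics, two controls are provided: repeating the contrast with
gamma forced to the 8th theta harmonic, and the flank-asymmetry index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from ._stats import wrap_phase
from .session import HIT, MISS

N_BINS = 18
CFC_THETA_BAND = (5.0, 11.0)
CFC_GAMMA_BAND = (50.0, 80.0)
HARMONIC_ORDER = 8


def modulation_index(phase: np.ndarray, amp: np.ndarray,
                     n_bins: int = N_BINS):
    """Tort modulation index of phase-amplitude coupling.

    18 equal phase bins on [-pi, pi); P_j = mean amplitude in bin j
    normalized to sum 1; MI = (log N - H) / log N with the entropy
    H = -sum P_j log P_j (0 log 0 = 0).  Returns (mi, P_j).
    """
    phase = np.asarray(phase, dtype=float).ravel()
    amp = np.asarray(amp, dtype=float).ravel()
    if phase.size != amp.size:
        raise ValueError("phase and amplitude series differ in length")
    if phase.size == 0:
        raise ValueError("empty phase/amplitude series")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(wrap_phase(phase), edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=amp, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = means.sum()
    if total <= 0:
        return 0.0, np.full(n_bins, 1.0 / n_bins)
    p = means / total
    nz = p > 0
    h = -(p[nz] * np.log(p[nz])).sum()
    return float((np.log(n_bins) - h) / np.log(n_bins)), p


def mi_shuffle_z(phase_trials, amp_trials, n_shuffles: int = 200, seed=0,
                 n_bins: int = N_BINS) -> dict:
    """MI of trial-concatenated series, z-scored against trial shuffles.

    The null permutes which phase trial is paired with which amplitude
    trial (marginals preserved), re-concatenates and recomputes MI
    ``n_shuffles`` times; z = (MI - mean) / SD of the null.
    """
    phase_trials = [np.asarray(p, dtype=float) for p in phase_trials]
    amp_trials = [np.asarray(a, dtype=float) for a in amp_trials]
    if len(phase_trials) != len(amp_trials):
        raise ValueError("phase and amplitude trial counts differ")
    rng = np.random.default_rng(seed)
    amp_cat = np.concatenate(amp_trials)
    mi_real, _ = modulation_index(np.concatenate(phase_trials), amp_cat, n_bins)
    null = np.empty(n_shuffles)
    n_tr = len(phase_trials)
    for s in range(n_shuffles):
        perm = rng.permutation(n_tr)
        ph = np.concatenate([phase_trials[i] for i in perm])
        null[s], _ = modulation_index(ph, amp_cat, n_bins)
    sd = null.std()
    z = (mi_real - null.mean()) / sd if sd > 0 else np.nan
    return {"mi": mi_real, "z": float(z), "null_mean": float(null.mean()),
            "null_sd": float(sd)}


def peak_matched_cfc(cond_data: dict, n_shuffles: int = 200, seed=0) -> dict:
    """Condition-wise MI at each condition's own (theta, gamma) peaks.

    ``cond_data`` maps condition -> (phase_trials, amp_trials), where the
    phase is taken at that condition's theta PPC peak and the amplitude
    at its gamma PPC peak.  Returns {condition: {'mi', 'z', ...}}.
    """
    rng = np.random.default_rng(seed)
    return {cond: mi_shuffle_z(ph, am, n_shuffles, rng.integers(2**31))
            for cond, (ph, am) in cond_data.items()}


def harmonic_frequency(theta_peak: float, order: int = HARMONIC_ORDER) -> float:
    """Gamma frequency of the waveshape control: the 8th theta harmonic
    (e.g. 9 Hz theta -> 72 Hz)."""
    return order * theta_peak


def harmonic_control(real_z: dict, harmonic_z: dict) -> dict:
    """Compare the hit-miss MI contrast at the real gamma peak with the
    contrast at the 8th theta harmonic.

    If the real contrast merely reflects an asymmetric theta waveshape,
    the harmonic contrast should be at least as strong; a real-gamma
    contrast exceeding the harmonic one argues for genuine coupling.
    """
    d_real = real_z[HIT] - real_z[MISS]
    d_harm = harmonic_z[HIT] - harmonic_z[MISS]
    return {"delta_real": float(d_real), "delta_harmonic": float(d_harm),
            "suspect_waveshape": bool(d_harm >= d_real)}


def cfc_condition_test(z_hit, z_miss) -> dict:
    """Nonparametric paired test of z-MI across channels (Wilcoxon
    signed-rank; exact for small samples)."""
    z_hit = np.asarray(z_hit, dtype=float)
    z_miss = np.asarray(z_miss, dtype=float)
    if z_hit.size != z_miss.size:
        raise ValueError("condition vectors differ in length")
    if z_hit.size < 2:
        raise ValueError("need at least 2 channels for a paired test")
    method = "exact" if z_hit.size < 6 else "auto"
    res = stats.wilcoxon(z_hit, z_miss, method=method)
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n": int(z_hit.size),
            "median_diff": float(np.median(z_hit - z_miss))}


# ---------------------------------------------------------------------------
# waveshape asymmetry

@dataclass
class AsymmetryResult:
    """Flank-asymmetry of the theta waveshape.

    AI = (T_asc - T_desc) / omega per cycle, averaged; positive values
    mean longer ascending flanks.  omega is the nominal theta cycle
    length.
    """

    ai: float
    ai_per_trial: np.ndarray
    t_asc_ms: float
    t_desc_ms: float
    omega_ms: float


def _extremum_offset(raw_trials, anchors_per_trial, adjust: int,
                     sign: float) -> int:
    """Offset (samples) between filtered-trace anchors and the raw-trace
    extremum, from the cycle-averaged raw waveform around the anchors.

    Averaging across all cycles and trials before taking the argmax
    makes the adjustment noise-robust without smoothing (and hence
    distorting) the waveshape itself.
    """
    segs = []
    width = 2 * adjust + 1
    for raw, anchors in zip(raw_trials, anchors_per_trial):
        for k in anchors:
            lo, hi = k - adjust, k + adjust + 1
            if lo < 0 or hi > raw.size:
                continue
            segs.append(raw[lo:hi])
    if not segs:
        return 0
    mean_seg = np.mean(segs, axis=0)
    return int(np.argmax(sign * mean_seg)) - adjust


def asymmetry_index(lfp_trials: np.ndarray, fs: float, theta_freq: float,
                    halfwidth: float = 2.0, order: int = 3) -> AsymmetryResult:
    """Asymmetry index of theta cycles in the window of interest.

    Each trial is band-passed at theta_freq +- 2 Hz; peak/trough times
    from the filtered trace are adjusted to the unfiltered extrema
    within a quarter cycle (via the cycle-averaged raw waveform around
    the filtered anchors); ascending (trough->peak) and descending
    (peak->trough) flank durations are divided by the nominal cycle
    length.  Trials with fewer than two full cycles are skipped.
    """
    lfp_trials = np.atleast_2d(np.asarray(lfp_trials, dtype=float))
    lo = max(theta_freq - halfwidth, 0.5)
    hi = theta_freq + halfwidth
    sos = signal.butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    omega_s = 1.0 / theta_freq
    adjust = int(round(fs * omega_s / 4.0))
    filtered = [signal.sosfiltfilt(sos, raw) for raw in lfp_trials]
    peaks = [signal.find_peaks(f)[0] for f in filtered]
    troughs = [signal.find_peaks(-f)[0] for f in filtered]
    off_peak = _extremum_offset(lfp_trials, peaks, adjust, +1.0)
    off_trough = _extremum_offset(lfp_trials, troughs, adjust, -1.0)

    ai_trials, asc_all, desc_all = [], [], []
    for pk, tr in zip(peaks, troughs):
        events = sorted([(k + off_peak, +1) for k in pk]
                        + [(k + off_trough, -1) for k in tr])
        asc, desc = [], []
        for (k0, kind0), (k1, kind1) in zip(events[:-1], events[1:]):
            dt = (k1 - k0) / fs
            if dt <= 0:
                continue
            if kind0 < 0 and kind1 > 0:
                asc.append(dt)
            elif kind0 > 0 and kind1 < 0:
                desc.append(dt)
        if len(asc) < 2 or len(desc) < 2:
            continue
        ai_trials.append((np.mean(asc) - np.mean(desc)) / omega_s)
        asc_all.extend(asc)
        desc_all.extend(desc)
    if not ai_trials:
        raise ValueError("no trial contains two full theta cycles")
    return AsymmetryResult(
        ai=float(np.mean(ai_trials)),
        ai_per_trial=np.array(ai_trials),
        t_asc_ms=float(np.mean(asc_all) * 1e3),
        t_desc_ms=float(np.mean(desc_all) * 1e3),
        omega_ms=omega_s * 1e3,
    )
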