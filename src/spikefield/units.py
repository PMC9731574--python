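"""Unit quality metrics, single- vs multi-unit classification, and
normalized spike-density series.

A unit is called a single unit (SU) only if its waveform variability over
the rising flank is low (c2 < 3) and fewer than 1% of inter-spike
intervals violate the 3 ms refractory period; otherwise it is a
multi-unit (MU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session import HIT, MISS, UnitRecord

ISI_REFRACTORY_S = 0.003
SU_MAX_ISI_VIOLATION = 0.01
SU_MAX_C2 = 3.0


def isi_violation_rate(unit: UnitRecord,
                       refractory_s: float = ISI_REFRACTORY_S) -> float:
    """Fraction of inter-spike intervals shorter than the refractory period."""
    isis = unit.all_isis()
    if isis.size == 0:
        return 0.0
    return float((isis < refractory_s).mean())


def rise_window(mean_wave: np.ndarray) -> tuple[int, int]:
    """Locate the rising flank of the mean spike waveform.

    The end of the rise (t_j) is the waveform peak; the start (t_i) is
    the sample of maximum curvature (second derivative) in the region
    before the peak.
    """
    m = np.asarray(mean_wave, dtype=float)
    if m.size < 5:
        raise ValueError("waveform too short")
    t_j = int(np.argmax(m))
    if t_j < 2 or np.allclose(m, m[0]):
        raise ValueError("waveform has no detectable rising flank")
    curvature = np.gradient(np.gradient(m))
    t_i = int(np.argmax(curvature[:t_j]))
    return t_i, t_j


def waveform_variability_c2(waveforms: np.ndarray,
                            rise: tuple[int, int] | None = None) -> float:
    """Waveform-variability criterion c2.

    Summed across-spike standard deviation over the rise-time samples,
    divided by the spike height (mean voltage at peak minus at rise
    start).  Low c2 means a homogeneous waveshape, i.e. a putative
    single unit.
    """
    w = np.asarray(waveforms, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need at least 2 waveforms")
    m = w.mean(axis=0)
    if rise is None:
        rise = rise_window(m)
    t_i, t_j = rise
    height = m[t_j] - m[t_i]
    if height <= 0:
        raise ValueError("invalid rise window: peak not above rise start")
    s = w.std(axis=0, ddof=0)
    return float(s[t_i:t_j + 1].sum() / height)


def classify_unit(unit: UnitRecord) -> str:
    """'SU' iff c2 < 3 and ISI violation rate <= 1%, else 'MU'."""
    if unit.c2 is None or unit.isi_violation_rate is None:
        raise ValueError("compute c2 and isi_violation_rate first")
    if unit.isi_violation_rate > SU_MAX_ISI_VIOLATION or unit.c2 >= SU_MAX_C2:
        return "MU"
    return "SU"


def unit_inclusion(unit: UnitRecord, labels: np.ndarray,
                   encoding_window: tuple = (0.0, 4.0)) -> bool:
    """Keep units with >= 50 spikes in hits or misses, a mean spike count
    > 2, and a mean firing rate > 1 Hz in the encoding window (strict
    inequalities except the 50-spike floor)."""
    labels = np.asarray(labels)
    if labels.size != len(unit.spike_times):
        raise ValueError("labels do not match the unit's trial count")
    counts = np.array([len(t) for t in unit.spike_times])
    n_hit = counts[labels == HIT].sum()
    n_miss = counts[labels == MISS].sum()
    if max(n_hit, n_miss) < 50:
        return False
    if counts.mean() <= 2:
        return False
    lo, hi = encoding_window
    enc_counts = np.array([
        ((t >= lo) & (t < hi)).sum() for t in unit.spike_times])
    rate = enc_counts.mean() / (hi - lo)
    return bool(rate > 1.0)


# ---------------------------------------------------------------------------
# spike density

def gaussian_kernel(length_ms: float, fs: float,
                    sd_ms: float | None = None) -> np.ndarray:
    """Unit-area Gaussian kernel of the given support.

    By default sigma = length / 6 so >= 99.7% of the mass lies inside the
    stated support.
    """
    n = max(int(round(length_ms * fs / 1e3)), 1)
    sd = (length_ms / 6.0 if sd_ms is None else sd_ms) * fs / 1e3
    k = signal.windows.gaussian(n, std=max(sd, 1e-9))
    return k / k.sum()


def binary_spike_series(spike_times_s: np.ndarray, times: np.ndarray,
                        fs: float) -> np.ndarray:
    """0/1 series on the epoch time grid (1 kHz) from spike times."""
    out = np.zeros(times.size)
    idx = np.round((np.asarray(spike_times_s) - times[0]) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < times.size)]
    out[idx] = 1.0
    return out


@dataclass
class SpikeDensity:
    """Normalized spike-density series per condition.

    z(t) = (sd(t) - mu_bl) / (sigma_bl + lambda) with the baseline taken
    at -1000..-125 ms before the cue; the regularization lambda = 0.1
    keeps z finite for silent baselines.
    """

    times: np.ndarray
    z: dict            # condition -> z(t)
    sd: dict           # condition -> raw density (Hz)
    mu_bl: dict
    sigma_bl: dict
    lam: float


def spike_density(unit: UnitRecord, times: np.ndarray, labels: np.ndarray,
                  fs: float = 1000.0, kernel_len_ms: float = 250.0,
                  baseline: tuple = (-1.0, -0.125),
                  lam: float = 0.1) -> SpikeDensity:
    """Gaussian-smoothed firing density, baseline-normalized per condition."""
    bl_sel = (times >= baseline[0]) & (times <= baseline[1])
    if not bl_sel.any():
        raise ValueError("baseline window contains no samples")
    kernel = gaussian_kernel(kernel_len_ms, fs)
    dens = np.stack([
        signal.fftconvolve(binary_spike_series(t, times, fs), kernel,
                           mode="same") * fs
        for t in unit.spike_times
    ])
    labels = np.asarray(labels)
    z, sd, mu_bl, sigma_bl = {}, {}, {}, {}
    for cond in (HIT, MISS):
        mask = labels == cond
        if not mask.any():
            continue
        mean_dens = dens[mask].mean(axis=0)
        mu = mean_dens[bl_sel].mean()
        sig = mean_dens[bl_sel].std()
        sd[cond] = mean_dens
        mu_bl[cond], sigma_bl[cond] = float(mu), float(sig)
        z[cond] = (mean_dens - mu) / (sig + lam)
    return SpikeDensity(times=times, z=z, sd=sd, mu_bl=mu_bl,
                        sigma_bl=sigma_bl, lam=lam)


def spike_train_spectrum(unit: UnitRecord, times: np.ndarray,
                         fs: float = 1000.0, window: tuple = (2.0, 3.0),
                         kernel_len_ms: float = 25.0,
                         smoothing_hz: float = 2.0):
    """Multitaper power spectrum of the smoothed spike density in the
    window of interest (+-2 Hz frequency smoothing), averaged over trials.

    Returns (freqs, power).
    """
    if window[0] < times[0] or window[1] > times[-1] + 1.0 / fs:
        raise ValueError("window outside the epoch")
    sel = (times >= window[0]) & (times < window[1])
    n = int(sel.sum())
    kernel = gaussian_kernel(kernel_len_ms, fs)
    t_len = n / fs
    nw = max(t_len * smoothing_hz, 1.0)
    n_tapers = max(int(2 * nw - 1), 1)
    tapers = signal.windows.dpss(n, nw, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectra = []
    for t in unit.spike_times:
        x = signal.fftconvolve(binary_spike_series(t, times, fs), kernel,
                               mode="same")[sel] * fs
        if x.any():
            x = x - x.mean()
        tapered = tapers * x[None, :]
        p = (np.abs(np.fft.rfft(tapered, axis=1)) ** 2).mean(axis=0)
        spectra.append(p)
    power = np.mean(spectra, axis=0) if spectra else np.zeros(freqs.size)
    return freqs, power
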