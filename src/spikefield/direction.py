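"""Phase-slope-index directionality between spike-density and LFP signals.

The phase slope index (PSI) infers the direction of information flow
from the slope of the cross-spectral phase over frequency: a constant
conduction delay from A to B makes the phase difference grow linearly
with frequency.  Here A is a unit's Gaussian-smoothed spike density and
B a distally coupled LFP; positive PSI means the spike series leads.
Raw PSI values are z-normalized against trial shuffles of the
spike-providing signal so that spike-count differences between
conditions cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from ._stats import fdr_bh

MIN_SPIKES_PSI = 60
MIN_SPIKES_PSI_RELAXED = 30


@dataclass
class PSISpectrum:
    freqs: np.ndarray
    psi: np.ndarray
    z: np.ndarray | None
    n_shuffles: int
    n_spikes: int | None = None


def segment_ffts(trials: np.ndarray, fs: float, seg_len_s: float = 0.5,
                 overlap: float = 0.5):
    """Hann-tapered FFTs of overlapping segments of every trial.

    Returns (spectra (n_trials, n_segments, n_freqs) complex, freqs).
    """
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    nper = int(round(seg_len_s * fs))
    if trials.shape[1] < nper:
        raise ValueError("trials shorter than one segment")
    step = max(int(round(nper * (1.0 - overlap))), 1)
    starts = np.arange(0, trials.shape[1] - nper + 1, step)
    win = signal.windows.hann(nper, sym=False)
    segs = np.stack([trials[:, s:s + nper] for s in starts], axis=1)
    segs = (segs - segs.mean(axis=-1, keepdims=True)) * win
    return np.fft.rfft(segs, axis=-1), np.fft.rfftfreq(nper, d=1.0 / fs)


def _psi_from_coherency(coh: np.ndarray, freqs: np.ndarray,
                        band: tuple, bandwidth: float) -> tuple:
    df = freqs[1] - freqs[0]
    half = bandwidth / 2.0
    out_f, out_psi = [], []
    for f in freqs:
        if f < band[0] or f > band[1]:
            continue
        sel = np.nonzero((freqs >= f - half) & (freqs + df <= f + half)
                         & (freqs + df <= freqs[-1] + 1e-9))[0]
        sel = sel[sel + 1 < freqs.size]
        if sel.size == 0:
            continue
        out_f.append(f)
        out_psi.append(np.imag(np.sum(np.conj(coh[sel]) * coh[sel + 1])))
    return np.array(out_f), np.array(out_psi)


def psi(spike_density_trials: np.ndarray, lfp_trials: np.ndarray, fs: float,
        band: tuple = (2.0, 13.0), bandwidth: float = 5.0,
        seg_len_s: float = 0.5, overlap: float = 0.5,
        n_shuffles: int = 100, seed=0,
        n_spikes: int | None = None, relaxed: bool = False) -> PSISpectrum | None:
    """Shuffle-normalized PSI between a spike-density and an LFP signal.

    Cross-spectra are averaged over trials and 50%-overlapping 500 ms
    Hann segments within the window of interest, normalized to complex
    coherency, and the phase slope is summed over a 5 Hz window.  The z
    score comes from ``n_shuffles`` permutations of the spike-providing
    trials (spike counts preserved).  Pairs with fewer than 60 spikes
    (30 in relaxed mode) are excluded and return None.
    """
    min_spk = MIN_SPIKES_PSI_RELAXED if relaxed else MIN_SPIKES_PSI
    if n_spikes is not None and n_spikes < min_spk:
        return None
    rng = np.random.default_rng(seed)
    X, freqs = segment_ffts(spike_density_trials, fs, seg_len_s, overlap)
    Y, _ = segment_ffts(lfp_trials, fs, seg_len_s, overlap)
    if X.shape != Y.shape:
        raise ValueError("spike and LFP trials have mismatched shapes")
    s_xx = (np.abs(X) ** 2).mean(axis=(0, 1))
    s_yy = (np.abs(Y) ** 2).mean(axis=(0, 1))
    denom = np.sqrt(s_xx * s_yy)
    denom = np.where(denom > 0, denom, np.inf)

    def _psi_for(x):
        s_xy = (x * np.conj(Y)).mean(axis=(0, 1))
        coh = s_xy / denom
        return _psi_from_coherency(coh, freqs, band, bandwidth)

    out_f, psi_real = _psi_for(X)
    n_tr = X.shape[0]
    null = np.empty((n_shuffles, psi_real.size))
    for s in range(n_shuffles):
        perm = rng.permutation(n_tr)
        _, null[s] = _psi_for(X[perm])
    mu = null.mean(axis=0)
    sd = null.std(axis=0)
    z = np.where(sd > 0, (psi_real - mu) / np.where(sd > 0, sd, 1.0), np.nan)
    return PSISpectrum(out_f, psi_real, z, n_shuffles, n_spikes)


def psi_condition_contrast(z_hit: np.ndarray, z_miss: np.ndarray,
                           freqs: np.ndarray, alpha: float = 0.05,
                           min_pairs: int = 5) -> dict:
    """Across-pairs tests of z-PSI: hit vs miss per frequency (paired t,
    FDR) and each condition against zero."""
    z_hit = np.atleast_2d(z_hit)
    z_miss = np.atleast_2d(z_miss)
    n_pairs = z_hit.shape[0]
    warning = n_pairs < min_pairs
    out = {"freqs": freqs, "n_pairs": n_pairs, "warning": warning}
    if n_pairs >= 2:
        t, p = stats.ttest_rel(z_hit, z_miss, axis=0)
        reject, p_fdr = fdr_bh(p, alpha)
        t0h, p0h = stats.ttest_1samp(z_hit, 0.0, axis=0)
        t0m, p0m = stats.ttest_1samp(z_miss, 0.0, axis=0)
        out.update(t=t, p=p, p_fdr=p_fdr, significant=reject,
                   t_hit_vs_zero=t0h, p_hit_vs_zero=p0h,
                   t_miss_vs_zero=t0m, p_miss_vs_zero=p0m,
                   mean_diff=(z_hit - z_miss).mean(axis=0))
    return out
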