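"""LFP preprocessing: filtering, spike interpolation, line-noise template
subtraction, epoching/downsampling, artifact rejection, and local
Gram-Schmidt re-referencing.

The fixed stage order is: low-pass -> spike interpolation -> line-noise
removal -> epoching/downsampling -> artifact rejection -> re-referencing.
Spike interpolation and line-noise subtraction are idempotent on clean
data, so re-running the chain is safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class RawLFP:
    """Continuous multi-channel voltage record before epoching."""

    data: np.ndarray                 # (n_channels, n_samples), uV
    fs: float
    spike_markers: list | None = None  # per channel, sample indices
    bundle_of: np.ndarray | None = None


@dataclass
class LFPEpochs:
    """Epoched trials with rejection bookkeeping.

    ``trial_mask`` / ``channel_mask`` are True for surviving entries; the
    data array keeps its original shape so indices stay stable, and the
    rejection log records every rule that fired.
    """

    data: np.ndarray                 # (n_trials, n_times, n_channels)
    times: np.ndarray                # s relative to cue
    fs: float
    bundle_of: np.ndarray
    trial_mask: np.ndarray = None
    channel_mask: np.ndarray = None
    log: list = field(default_factory=list)

    def __post_init__(self):
        if self.trial_mask is None:
            self.trial_mask = np.ones(self.data.shape[0], dtype=bool)
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.data.shape[2], dtype=bool)

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log, columns=["kind", "index", "rule", "z"])


# ---------------------------------------------------------------------------
# continuous-record operations

def lowpass_filter(raw: RawLFP, cutoff: float = 300.0, order: int = 2) -> RawLFP:
    """Zero-phase Butterworth low-pass (default order 2, 300 Hz)."""
    if raw.fs <= 2.0 * cutoff:
        raise ValueError(
            f"sampling rate {raw.fs} Hz too low for a {cutoff} Hz low-pass")
    sos = signal.butter(order, cutoff, btype="low", fs=raw.fs, output="sos")
    return replace(raw, data=signal.sosfiltfilt(sos, raw.data, axis=-1))


def _merge_intervals(intervals):
    """Union of [lo, hi) integer intervals, sorted."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return merged


def interpolate_intervals(x: np.ndarray, intervals) -> np.ndarray:
    """Replace [lo, hi) spans of a 1-D series by linear interpolation
    between the samples flanking the span (clipped at record edges)."""
    out = x.copy()
    n = x.size
    for lo, hi in _merge_intervals([(max(int(a), 0), min(int(b), n)) for a, b in intervals]):
        if lo >= hi:
            continue
        left = lo - 1
        right = hi
        if left < 0 and right >= n:
            out[lo:hi] = 0.0
        elif left < 0:
            out[lo:hi] = out[right]
        elif right >= n:
            out[lo:hi] = out[left]
        else:
            out[lo:hi] = np.linspace(out[left], out[right], hi - lo + 2)[1:-1]
    return out


def interpolate_spikes(raw: RawLFP, pre_ms: float = 2.0,
                       post_ms: float = 6.0) -> RawLFP:
    """Excise spike transients: each marked spike's [t-2 ms, t+6 ms] span
    is replaced by a straight line; overlapping spans are merged."""
    if raw.spike_markers is None:
        raise ValueError("no spike markers on this record")
    pre = int(round(pre_ms * raw.fs / 1e3))
    post = int(round(post_ms * raw.fs / 1e3))
    data = raw.data.copy()
    for ch, markers in enumerate(raw.spike_markers):
        if markers is None or len(markers) == 0:
            continue
        iv = [(m - pre, m + post + 1) for m in np.asarray(markers, dtype=int)]
        data[ch] = interpolate_intervals(data[ch], iv)
    return replace(raw, data=data)


def fit_line_noise(x: np.ndarray, fs: float, line_freq: float) -> np.ndarray:
    """Least-squares sinusoid at the line frequency (template estimate)."""
    t = np.arange(x.size) / fs
    design = np.column_stack([
        np.sin(2 * np.pi * line_freq * t),
        np.cos(2 * np.pi * line_freq * t),
    ])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return design @ coef


def remove_line_noise(raw: RawLFP, line_freq: float = 50.0) -> RawLFP:
    """Template subtraction of mains noise.

    A stationary sinusoid at the line frequency is fit per channel by
    least squares and subtracted; unlike a band-stop filter this keeps
    physiological (non-stationary) activity at the line frequency.
    """
    data = np.stack([x - fit_line_noise(x, raw.fs, line_freq) for x in raw.data])
    return replace(raw, data=data)


def epoch_and_downsample(raw: RawLFP, cue_times, fs_target: float = 1000.0,
                         epoch: tuple = (-7.0, 7.0)) -> LFPEpochs:
    """Cut 14 s epochs around each cue and resample to 1 kHz.

    Anti-aliased polyphase resampling; cues whose epoch exceeds the
    record bounds are dropped with a log entry.
    """
    from fractions import Fraction

    frac = Fraction(fs_target / raw.fs).limit_denominator(10000)
    down = signal.resample_poly(raw.data, frac.numerator, frac.denominator, axis=-1)
    n_new = down.shape[-1]
    n_times = int(round((epoch[1] - epoch[0]) * fs_target)) + 1
    times = epoch[0] + np.arange(n_times) / fs_target
    epochs, log, kept = [], [], []
    for i, cue in enumerate(cue_times):
        start = int(round((cue + epoch[0]) * fs_target))
        stop = start + n_times
        if start < 0 or stop > n_new:
            log.append({"kind": "trial", "index": i,
                        "rule": "epoch_out_of_bounds", "z": np.nan})
            continue
        epochs.append(down[:, start:stop])
        kept.append(i)
    if not epochs:
        raise ValueError("no cue yields an in-bounds epoch")
    data = np.stack(epochs).transpose(0, 2, 1)  # trials x time x channels
    bundle_of = (raw.bundle_of if raw.bundle_of is not None
                 else np.zeros(raw.data.shape[0], dtype=int))
    return LFPEpochs(data=data, times=times, fs=fs_target,
                     bundle_of=np.asarray(bundle_of), log=log)


# ---------------------------------------------------------------------------
# epoch-level operations

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def reject_artifacts(epochs: LFPEpochs, window: tuple = (-0.5, 5.0),
                     channel_z: float = 3.0, trial_z: float = 4.0,
                     min_trials: int = 25) -> LFPEpochs:
    """Amplitude-based artifact rejection.

    1. channel RMS amplitude (RMSA) in the window, z-scored across
       channels; z > 3 rejects the channel;
    2. per-trial RMSA (averaged over surviving channels), z-scored across
       trials; z > 4 rejects the trial;
    3. per-trial maximum raw amplitude, z-scored across trials; z > 4
       rejects the trial;
    4. channels are kept only if >= 25 trials remain.
    """
    sel = (epochs.times >= window[0]) & (epochs.times <= window[1])
    data = epochs.data[:, sel, :]
    trial_mask = epochs.trial_mask.copy()
    channel_mask = epochs.channel_mask.copy()
    log = list(epochs.log)

    rmsa = np.sqrt((data**2).mean(axis=1))            # trials x channels
    ch_idx = np.nonzero(channel_mask)[0]
    z_ch = _zscore(rmsa[:, ch_idx][trial_mask].mean(axis=0))
    for j, z in zip(ch_idx, z_ch):
        if z > channel_z:
            channel_mask[j] = False
            log.append({"kind": "channel", "index": int(j),
                        "rule": "rmsa_channel_z", "z": float(z)})
    if not channel_mask.any():
        raise ValueError("all channels rejected by the RMSA rule")

    ch_idx = np.nonzero(channel_mask)[0]
    tr_idx = np.nonzero(trial_mask)[0]
    z_tr = _zscore(rmsa[tr_idx][:, ch_idx].mean(axis=1))
    maxamp = np.abs(data[tr_idx][:, :, ch_idx]).max(axis=(1, 2))
    z_max = _zscore(maxamp)
    for i, z1, z2 in zip(tr_idx, z_tr, z_max):
        if z1 > trial_z:
            trial_mask[i] = False
            log.append({"kind": "trial", "index": int(i),
                        "rule": "rmsa_trial_z", "z": float(z1)})
        elif z2 > trial_z:
            trial_mask[i] = False
            log.append({"kind": "trial", "index": int(i),
                        "rule": "max_amplitude_z", "z": float(z2)})

    if trial_mask.sum() < min_trials:
        for j in np.nonzero(channel_mask)[0]:
            channel_mask[j] = False
            log.append({"kind": "channel", "index": int(j),
                        "rule": "min_trials", "z": float(trial_mask.sum())})
    if not channel_mask.any():
        raise ValueError("no channel retains the minimum number of trials")
    return replace(epochs, trial_mask=trial_mask, channel_mask=channel_mask,
                   log=log)


def gram_schmidt_rereference(epochs: LFPEpochs) -> LFPEpochs:
    """Project out the same-bundle neighbor mean from each channel.

    For channel x with neighbor mean r (surviving channels of the same
    bundle, excluding x), per trial: x' = x - (<x, r> / <r, r>) r, so the
    output is orthogonal to the local reference.  Channels without any
    surviving neighbor are dropped with a log entry.
    """
    data = epochs.data.copy()
    channel_mask = epochs.channel_mask.copy()
    log = list(epochs.log)
    alive = np.nonzero(channel_mask)[0]
    for ch in alive:
        neigh = [j for j in alive
                 if j != ch and epochs.bundle_of[j] == epochs.bundle_of[ch]]
        if not neigh:
            channel_mask[ch] = False
            log.append({"kind": "channel", "index": int(ch),
                        "rule": "no_reference_neighbor", "z": np.nan})
            continue
        r = epochs.data[:, :, neigh].mean(axis=2)     # trials x time
        num = (epochs.data[:, :, ch] * r).sum(axis=1)
        den = (r * r).sum(axis=1)
        beta = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        data[:, :, ch] = epochs.data[:, :, ch] - beta[:, None] * r
    if not channel_mask.any():
        raise ValueError("no channel has a same-bundle reference neighbor")
    return replace(epochs, data=data, channel_mask=channel_mask, log=log)
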