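"""Shuffle-normalized cross-correlation of sender/receiver spike trains.

Putative 'sending' units are distally theta-coupled to the LFP of a
region whose locally gamma-coupled units serve as putative 'receivers'.
Co-firing at lag tau is the cross-correlation of the two units'
Gaussian-smoothed spike densities; raw values are z-scored against
receiver-trial shuffles (2000 by default) so that firing-rate and
trial-count differences cancel.  Positive lags mean the receiver fires
after the sender.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal, stats

from .session import HIT, MISS
from .units import gaussian_kernel

KERNEL_SUPPORT_MS = 25.0
KERNEL_SD_MS = 10.0 / 2.355        # ~10 ms FWHM
MAX_LAG_MS = 100.0
N_SHUFFLES = 2000
COINCIDENCE_Z = 1.0


@dataclass
class CrossCorrResult:
    lags_ms: np.ndarray
    raw: np.ndarray
    z: np.ndarray
    n_shuffles: int
    n_spikes_sender: int
    n_spikes_receiver: int


def density_trials(spike_trials, duration_s: float, fs: float = 1000.0,
                   kernel_support_ms: float = KERNEL_SUPPORT_MS,
                   kernel_sd_ms: float = KERNEL_SD_MS) -> np.ndarray:
    """Gaussian-smoothed spike density per trial.

    ``spike_trials`` holds spike times in seconds from the start of the
    analysis window.
    """
    n = int(round(duration_s * fs))
    kernel = gaussian_kernel(kernel_support_ms, fs, sd_ms=kernel_sd_ms)
    out = np.zeros((len(spike_trials), n))
    for i, times in enumerate(spike_trials):
        idx = np.round(np.asarray(times, dtype=float) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        series = np.zeros(n)
        series[idx] = 1.0
        out[i] = signal.fftconvolve(series, kernel, mode="same")
    return out


def _pairwise_xcorr_tensor(sender_dens: np.ndarray, receiver_dens: np.ndarray,
                           max_lag: int):
    """C[a, b, l] = sum_t sender_a(t) * receiver_b(t + lag_l) for every
    sender/receiver trial combination, lags -max_lag..max_lag."""
    n_tr, n_t = sender_dens.shape
    nfft = sfft.next_fast_len(2 * n_t)
    fs_ = sfft.rfft(sender_dens, nfft, axis=1)
    fr_ = sfft.rfft(receiver_dens, nfft, axis=1)
    cross = np.einsum("af,bf->abf", np.conj(fs_), fr_)
    full = sfft.irfft(cross, nfft, axis=2)
    lags = np.arange(-max_lag, max_lag + 1)
    return full[:, :, lags % nfft], lags


def cofiring_xcorr(sender_trials, receiver_trials, duration_s: float,
                   fs: float = 1000.0, max_lag_ms: float = MAX_LAG_MS,
                   n_shuffles: int = N_SHUFFLES, seed=0,
                   kernel_support_ms: float = KERNEL_SUPPORT_MS,
                   kernel_sd_ms: float = KERNEL_SD_MS) -> CrossCorrResult:
    """Trial-concatenated sender->receiver cross-correlation with a
    receiver-trial-shuffle z-transform.

    The correlation at each lag is the dot product of the smoothed
    densities summed over matched trials; the null re-pairs receiver
    trials with sender trials 2000 times (spike counts preserved).
    Empty trains are rejected.
    """
    n_spk_s = sum(len(t) for t in sender_trials)
    n_spk_r = sum(len(t) for t in receiver_trials)
    if n_spk_s == 0 or n_spk_r == 0:
        raise ValueError("empty spike train")
    if len(sender_trials) != len(receiver_trials):
        raise ValueError("sender and receiver trial counts differ")
    rng = np.random.default_rng(seed)
    dens_s = density_trials(sender_trials, duration_s, fs,
                            kernel_support_ms, kernel_sd_ms)
    dens_r = density_trials(receiver_trials, duration_s, fs,
                            kernel_support_ms, kernel_sd_ms)
    max_lag = int(round(max_lag_ms * fs / 1e3))
    tensor, lags = _pairwise_xcorr_tensor(dens_s, dens_r, max_lag)
    n_tr = dens_s.shape[0]
    diag = np.arange(n_tr)
    raw = tensor[diag, diag].sum(axis=0)
    null = np.empty((n_shuffles, lags.size))
    for s in range(n_shuffles):
        perm = rng.permutation(n_tr)
        null[s] = tensor[diag, perm].sum(axis=0)
    mu = null.mean(axis=0)
    sd = null.std(axis=0)
    z = (raw - mu) / np.where(sd > 0, sd, np.nan)
    return CrossCorrResult(lags * 1e3 / fs, raw, z, n_shuffles,
                           n_spk_s, n_spk_r)


def cofiring_by_condition(sender_trials, receiver_trials, labels,
                          duration_s: float, fs: float = 1000.0,
                          seed=0, **kwargs) -> dict:
    """CrossCorrResult per condition (hits / misses analyzed separately)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out = {}
    for cond in (HIT, MISS):
        sel = np.nonzero(labels == cond)[0]
        if sel.size == 0:
            continue
        out[cond] = cofiring_xcorr(
            [sender_trials[i] for i in sel],
            [receiver_trials[i] for i in sel],
            duration_s, fs, seed=rng.integers(2**31), **kwargs)
    return out


def coincidence_filter(results: dict, threshold: float = COINCIDENCE_Z) -> bool:
    """Keep a pair if the condition-mean z exceeds 1 at any lag (strict)."""
    zs = [r.z for r in results.values() if r is not None]
    if not zs:
        return False
    mean_z = np.mean(np.vstack(zs), axis=0)
    return bool(np.nanmax(mean_z) > threshold)


def peak_lag(result: CrossCorrResult, side: str = "positive") -> float | None:
    """Lag (ms) of the global z maximum over one side of the
    correlogram; ties break toward zero lag."""
    if side == "positive":
        sel = result.lags_ms >= 0
    elif side == "negative":
        sel = result.lags_ms <= 0
    else:
        raise ValueError("side must be 'positive' or 'negative'")
    lags = result.lags_ms[sel]
    z = result.z[sel]
    order = np.argsort(np.abs(lags), kind="stable")
    lags, z = lags[order], z[order]
    if np.all(np.isnan(z)):
        return None
    return float(lags[np.nanargmax(z)])


def peak_lag_contrast(pair_results: list, side: str = "positive") -> dict:
    """Per-pair peak co-firing lags for hits vs misses + paired t-test.

    ``pair_results`` holds per-pair {condition: CrossCorrResult} dicts;
    pairs missing a peak in either condition are dropped.
    """
    rows = []
    for k, res in enumerate(pair_results):
        if HIT not in res or MISS not in res:
            continue
        lag_h = peak_lag(res[HIT], side)
        lag_m = peak_lag(res[MISS], side)
        if lag_h is None or lag_m is None:
            continue
        rows.append({"pair": k, "lag_hit_ms": lag_h, "lag_miss_ms": lag_m})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        t, p = stats.ttest_rel(table["lag_hit_ms"], table["lag_miss_ms"])
    else:
        t, p = np.nan, np.nan
    return {"table": table, "t": float(t) if t == t else np.nan,
            "p": float(p) if p == p else np.nan, "n_pairs": len(table)}


def select_pairs(pair_table: pd.DataFrame) -> list:
    """Sender/receiver unit pairs from the SFC screening table.

    Expects columns unit_id, unit_bundle, lfp_bundle, band, locality,
    significant.  A sender shows significant distal low-frequency
    coupling to bundle B; every unit of B with significant local
    gamma coupling is a receiver.  Returns (sender, receiver, bundle)
    tuples.
    """
    required = {"unit_id", "unit_bundle", "lfp_bundle", "band", "locality",
                "significant"}
    missing = required - set(pair_table.columns)
    if missing:
        raise ValueError(f"pair table lacks columns: {sorted(missing)}")
    senders = pair_table[
        (pair_table["band"] == "low")
        & (pair_table["locality"] == "distal")
        & pair_table["significant"]
    ]
    receivers = pair_table[
        (pair_table["band"] == "high")
        & (pair_table["locality"] != "distal")
        & pair_table["significant"]
    ]
    pairs = []
    for _, srow in senders.iterrows():
        target = srow["lfp_bundle"]
        for _, rrow in receivers.iterrows():
            if rrow["unit_bundle"] != target:
                continue
            if rrow["unit_id"] == srow["unit_id"]:
                continue
            key = (srow["unit_id"], rrow["unit_id"], target)
            if key not in pairs:
                pairs.append(key)
    return pairs
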