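"""Spike-field coupling: Rayleigh+FDR screening, PPC spectra, shuffle
nulls for the number of coupled pairs, condition contrasts, peak-
frequency analysis, and the selection-bias control.

A spike-LFP pair couples a unit's spike times (in the 2-3 s window of
interest) to the phase of one LFP channel on a frequency grid.  Pairs
are 'local' when spikes and LFP come from the same microwire bundle
(including the same wire) and 'distal' otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import fdr_bh, ppc, ppc_along_axis, rayleigh_test
from .session import HIT, MISS

MIN_SPIKES_SCREEN = 30
PPC_PEAK_THRESHOLD = 0.005
THETA_PEAK_BAND = (3.0, 13.0)
GAMMA_PEAK_BAND = (45.0, 75.0)

__all__ = [
    "PairPhaseData", "SpikePhaseSet", "RayleighScreen", "screen_pair",
    "pair_count_null", "condition_contrast", "detect_peak",
    "peak_frequency_shift", "selection_bias_control", "ppc",
]


@dataclass
class PairPhaseData:
    """Per-trial substrate of one spike-LFP pair.

    ``trial_phases`` holds the LFP phase in the window of interest for
    every trial and frequency; ``spike_samples`` are per-trial sample
    indices (into the window) of the unit's spikes.  Keeping the trial
    structure allows trial-shuffled nulls that preserve spike counts and
    hit/miss trial numbers exactly.
    """

    unit_id: str
    channel: int
    locality: str                     # 'same_wire' | 'local_bundle' | 'distal'
    freqs: np.ndarray
    trial_phases: np.ndarray          # (n_trials, n_freqs, n_win) float
    spike_samples: list               # per trial, int arrays
    labels: np.ndarray                # per-trial condition

    @property
    def n_trials(self) -> int:
        return len(self.spike_samples)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spike_samples))

    def spike_labels(self) -> np.ndarray:
        return np.repeat(self.labels,
                         [len(s) for s in self.spike_samples])

    def gather(self, assignment: np.ndarray | None = None) -> np.ndarray:
        """Phases at spike times, (n_spikes, n_freqs).

        ``assignment[i]`` is the LFP trial paired with spike trial i
        (identity when None); shuffled assignments implement the
        trial-shuffle null with all counts preserved.
        """
        if assignment is None:
            assignment = np.arange(self.n_trials)
        chunks = []
        for i, s in enumerate(self.spike_samples):
            if len(s):
                chunks.append(self.trial_phases[assignment[i]][:, s].T)
        if not chunks:
            return np.empty((0, self.freqs.size))
        return np.concatenate(chunks, axis=0)

    def is_local(self) -> bool:
        return self.locality in ("same_wire", "local_bundle")


@dataclass
class SpikePhaseSet:
    """Gathered spike phases of one pair (spikes x freqs) with labels."""

    unit_id: str
    channel: int
    locality: str
    freqs: np.ndarray
    phases: np.ndarray
    conditions: np.ndarray

    @classmethod
    def from_pair(cls, pair: PairPhaseData) -> "SpikePhaseSet":
        return cls(pair.unit_id, pair.channel, pair.locality, pair.freqs,
                   pair.gather(), pair.spike_labels())


@dataclass
class RayleighScreen:
    freqs: np.ndarray
    z: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    significant: bool
    n_spikes: int
    excluded: bool = False


def screen_phases(phases: np.ndarray, freqs: np.ndarray, alpha: float = 0.05,
                  min_spikes: int = MIN_SPIKES_SCREEN) -> RayleighScreen:
    """Rayleigh test per frequency, Benjamini-Hochberg across the grid.

    A pair is significant if any FDR-corrected p < alpha.  Pairs with
    fewer than 30 spikes are excluded (flagged, not an error).
    """
    n = phases.shape[0]
    if n < min_spikes:
        nan = np.full(freqs.size, np.nan)
        return RayleighScreen(freqs, nan, nan, nan, False, n, excluded=True)
    z, p = rayleigh_test(phases, axis=0)
    reject, p_fdr = fdr_bh(p, alpha)
    return RayleighScreen(freqs, z, p, p_fdr, bool(reject.any()), n)


def screen_pair(pair: PairPhaseData, alpha: float = 0.05,
                min_spikes: int = MIN_SPIKES_SCREEN) -> RayleighScreen:
    return screen_phases(pair.gather(), pair.freqs, alpha, min_spikes)


def ppc_spectrum(phases: np.ndarray) -> np.ndarray:
    """PPC per frequency from (n_spikes, n_freqs) phases."""
    return ppc_along_axis(phases, axis=0)


def condition_ppc(pair: PairPhaseData, min_spikes: int = MIN_SPIKES_SCREEN):
    """PPC spectra for all trials, hits, and misses.

    Returns dict {'all'|'hit'|'miss': PPC(f)}; a condition with fewer
    than ``min_spikes`` spikes maps to None.
    """
    phases = pair.gather()
    labels = pair.spike_labels()
    out = {"all": ppc_spectrum(phases) if phases.shape[0] >= 2 else None}
    for cond in (HIT, MISS):
        sel = labels == cond
        out[cond] = ppc_spectrum(phases[sel]) if sel.sum() >= min_spikes else None
    return out


# ---------------------------------------------------------------------------
# pair-count randomization

def pair_count_null(pairs: list, alpha: float = 0.05,
                    min_spikes: int = MIN_SPIKES_SCREEN,
                    n_shuffles: int = 100, n_draws: int = 10000,
                    seed=0) -> dict:
    """Null distribution of the number of significantly coupled pairs.

    For every pair, spike/LFP trial pairings are shuffled ``n_shuffles``
    times (hit/miss trial counts and spike counts unchanged) and the
    Rayleigh+FDR screen re-run.  The null is then built by drawing
    ``n_draws`` samples, each picking one shuffle outcome per pair and
    counting how many came out significant.
    """
    rng = np.random.default_rng(seed)
    if not pairs:
        return {"observed": 0, "null_counts": np.zeros(n_draws, dtype=int),
                "p": 1.0}
    observed = sum(screen_pair(p, alpha, min_spikes).significant for p in pairs)
    sig = np.zeros((len(pairs), n_shuffles), dtype=bool)
    for i, pair in enumerate(pairs):
        n_tr = pair.n_trials
        for s in range(n_shuffles):
            assignment = rng.permutation(n_tr)
            phases = pair.gather(assignment)
            sig[i, s] = screen_phases(phases, pair.freqs, alpha,
                                      min_spikes).significant
    draws = rng.integers(0, n_shuffles, size=(n_draws, len(pairs)))
    null_counts = sig[np.arange(len(pairs))[None, :], draws].sum(axis=1)
    p = (1.0 + (null_counts >= observed).sum()) / (n_draws + 1.0)
    return {"observed": int(observed), "null_counts": null_counts, "p": float(p)}


# ---------------------------------------------------------------------------
# condition contrast and peak analysis

@dataclass
class ConditionContrast:
    freqs: np.ndarray
    pair_ids: list
    ppc_hit: np.ndarray    # (n_pairs, n_freqs)
    ppc_miss: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    dropped: list = field(default_factory=list)


def condition_contrast(pairs: list, min_spikes: int = MIN_SPIKES_SCREEN,
                       alpha: float = 0.05) -> ConditionContrast:
    """Across-pairs paired t-test of hit vs miss PPC per frequency (FDR).

    Pairs lacking 30 spikes in either condition are dropped with a note.
    """
    rows_h, rows_m, ids, dropped = [], [], [], []
    for pair in pairs:
        spectra = condition_ppc(pair, min_spikes)
        if spectra[HIT] is None or spectra[MISS] is None:
            dropped.append(pair.unit_id + f"->ch{pair.channel}")
            continue
        rows_h.append(spectra[HIT])
        rows_m.append(spectra[MISS])
        ids.append((pair.unit_id, pair.channel))
    if not ids:
        raise ValueError("no pair has enough spikes in both conditions")
    ppc_hit = np.vstack(rows_h)
    ppc_miss = np.vstack(rows_m)
    freqs = pairs[0].freqs
    if len(ids) >= 2:
        t, p = stats.ttest_rel(ppc_hit, ppc_miss, axis=0)
        reject, p_fdr = fdr_bh(p, alpha)
    else:
        t = np.full(freqs.size, np.nan)
        p = np.full(freqs.size, np.nan)
        p_fdr, reject = p.copy(), np.zeros(freqs.size, dtype=bool)
    return ConditionContrast(freqs, ids, ppc_hit, ppc_miss, t, p, p_fdr,
                             reject, dropped)


def detect_peak(freqs: np.ndarray, spectrum: np.ndarray, band: tuple,
                threshold: float = PPC_PEAK_THRESHOLD):
    """Highest local maximum of a spectrum inside a band.

    Interior local maxima only (strict neighbors); ties break toward the
    lower frequency; returns (freq, value) or None when no local maximum
    exceeds the threshold.
    """
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f = freqs[sel]
    s = np.asarray(spectrum)[sel]
    if f.size < 3:
        return None
    is_peak = (s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:])
    idx = np.nonzero(is_peak)[0] + 1
    idx = idx[s[idx] > threshold]
    if idx.size == 0:
        return None
    best = idx[np.argmax(s[idx])]  # argmax returns first (lowest freq) on ties
    return float(f[best]), float(s[best])


def peak_frequency_shift(pairs: list, band: tuple,
                         threshold: float = PPC_PEAK_THRESHOLD,
                         min_spikes: int = MIN_SPIKES_SCREEN,
                         spectra: list | None = None) -> dict:
    """Per-pair PPC peak frequencies for hits and misses + paired t-test.

    A pair contributes only if both conditions have a qualifying peak
    (above the 0.005 PPC threshold) inside the band.  ``spectra`` may
    supply precomputed {'hit':..., 'miss':...} spectra per pair (e.g.
    bias-corrected ones); otherwise they are computed from the pair data.
    """
    rows = []
    for k, pair in enumerate(pairs):
        sp = spectra[k] if spectra is not None else condition_ppc(pair, min_spikes)
        if sp[HIT] is None or sp[MISS] is None:
            continue
        peak_h = detect_peak(pair.freqs, sp[HIT], band, threshold)
        peak_m = detect_peak(pair.freqs, sp[MISS], band, threshold)
        if peak_h is None or peak_m is None:
            continue
        rows.append({"unit_id": pair.unit_id, "channel": pair.channel,
                     "peak_hit": peak_h[0], "peak_miss": peak_m[0],
                     "ppc_peak_hit": peak_h[1], "ppc_peak_miss": peak_m[1]})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        t, p = stats.ttest_rel(table["peak_hit"], table["peak_miss"])
    else:
        t, p = np.nan, np.nan
    return {"table": table, "t": float(t) if t == t else np.nan,
            "p": float(p) if p == p else np.nan,
            "n_pairs": len(table)}


# ---------------------------------------------------------------------------
# selection-bias control

def selection_bias_control(pair: PairPhaseData, n_shuffles: int = 5000,
                           alpha: float = 0.05,
                           min_spikes: int = MIN_SPIKES_SCREEN,
                           min_kept: int = 50, seed=0) -> dict:
    """Bias-corrected condition PPC via screened trial shuffles.

    Trial pairings between the spike- and LFP-providing data are
    shuffled (hit/miss counts unchanged); shuffles whose all-trials
    Rayleigh screen survives FDR are kept, and their pseudo-hit /
    pseudo-miss PPC spectra form the baseline.  The real condition PPC
    spectra are z-transformed by the mean/SD of that baseline, removing
    the bias the significance screening introduces under unequal trial
    or spike counts.
    """
    rng = np.random.default_rng(seed)
    n_tr = pair.n_trials
    labels = pair.spike_labels()
    kept_h, kept_m = [], []
    for _ in range(n_shuffles):
        assignment = rng.permutation(n_tr)
        phases = pair.gather(assignment)
        if not screen_phases(phases, pair.freqs, alpha, min_spikes).significant:
            continue
        sel_h = labels == HIT
        if sel_h.sum() >= min_spikes and (~sel_h).sum() >= min_spikes:
            kept_h.append(ppc_spectrum(phases[sel_h]))
            kept_m.append(ppc_spectrum(phases[~sel_h]))
    n_kept = len(kept_h)
    warning = n_kept < min_kept
    real = condition_ppc(pair, min_spikes)
    out = {"n_kept": n_kept, "warning": warning, "z_hit": None, "z_miss": None}
    if n_kept >= 2 and real[HIT] is not None and real[MISS] is not None:
        kept_h = np.vstack(kept_h)
        kept_m = np.vstack(kept_m)
        sd_h = kept_h.std(axis=0)
        sd_m = kept_m.std(axis=0)
        sd_h = np.where(sd_h > 0, sd_h, np.nan)
        sd_m = np.where(sd_m > 0, sd_m, np.nan)
        out["z_hit"] = (real[HIT] - kept_h.mean(axis=0)) / sd_h
        out["z_miss"] = (real[MISS] - kept_m.mean(axis=0)) / sd_m
    return out
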