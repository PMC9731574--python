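"""End-to-end orchestration: behavioral labeling, chance-level
arithmetic, configuration, and the full analysis chain

    preprocess -> units -> spectral -> sfc -> direction -> cfc -> cofire

run on one session, with per-stage failure capture and deterministic,
seeded outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import cfc as cfc_mod
from . import cofire as cofire_mod
from . import direction as dir_mod
from . import preprocess as pre
from . import sfc as sfc_mod
from . import spectral
from . import units as units_mod
from .session import HIT, MISS, SessionData


# ---------------------------------------------------------------------------
# behavior

@dataclass
class TrialLabels:
    outcome: np.ndarray     # 'both_correct' | 'one_correct' | 'none_correct'
    condition: np.ndarray   # 'hit' | 'miss'


def label_trials(recall_records) -> TrialLabels:
    """Hit iff both cued-recall selections were correct.

    Each record is either a pair of booleans (first/second selection
    correct) or the string 'none_remembered' when the patient reported
    remembering nothing.  One-correct and none-correct trials pool into
    the miss condition.
    """
    outcomes, conditions = [], []
    for rec in recall_records:
        if isinstance(rec, str):
            if rec != "none_remembered":
                raise ValueError(f"unknown recall record {rec!r}")
            outcomes.append("none_correct")
        else:
            a, b = rec
            n = int(bool(a)) + int(bool(b))
            outcomes.append(
                {2: "both_correct", 1: "one_correct", 0: "none_correct"}[n])
        conditions.append(HIT if outcomes[-1] == "both_correct" else MISS)
    return TrialLabels(np.array(outcomes), np.array(conditions))


def chance_probabilities() -> dict:
    """Chance levels of the cued-recall task.

    Two targets are selected sequentially among four candidates (two
    targets, two foils) without replacement: p(first correct) = 2/4,
    p(second also correct | first correct) = 1/3, so p_both = 1/6; by
    symmetry p_none = 1/6, p_one = 2/3, and p_miss = 1 - p_both = 5/6.
    """
    p_both = (2.0 / 4.0) * (1.0 / 3.0)
    p_none = (2.0 / 4.0) * (1.0 / 3.0)
    p_one = 1.0 - p_both - p_none
    return {"p_both": p_both, "p_one": p_one, "p_none": p_none,
            "p_miss": 1.0 - p_both}


def phase_lag_to_latency(phase_lag_rad: float, freq_hz: float) -> float:
    """Firing latency (s) implied by a constant phase lag at a coupling
    frequency: latency = lag / (2 pi f).

    A quarter-cycle lag (pi/2) at 8 Hz gives 31.25 ms; the same lag at
    4 Hz gives 62.5 ms — faster oscillations pack co-firing into
    shorter windows.
    """
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    return phase_lag_rad / (2.0 * np.pi * freq_hz)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """All analysis parameters; the defaults are the reference settings.

    Shuffle counts (100 / 200 / 2000 / 5000 / 10000), spike minimums
    (30 / 60), the 2-3 s window, the 0.005 PPC peak threshold, the z > 1
    coincidence threshold and FDR q = 0.05 are the pinned defaults;
    reduce shuffle counts only for quick exploratory runs.
    """

    window: tuple = (2.0, 3.0)
    power_window: tuple = (-0.5, 5.0)
    line_freq: float = 50.0
    min_spikes_screen: int = 30
    min_spikes_psi: int = 60
    psi_relaxed: bool = False
    fdr_alpha: float = 0.05
    ppc_peak_threshold: float = 0.005
    sfc_theta_band: tuple = (3.0, 13.0)
    sfc_gamma_band: tuple = (45.0, 75.0)
    cfc_theta_band: tuple = (5.0, 11.0)
    cfc_gamma_band: tuple = (50.0, 80.0)
    coincidence_z: float = 1.0
    psi_bandwidth: float = 5.0
    n_shuffles_pair_null: int = 100
    n_draws_pair_null: int = 10000
    n_shuffles_bias: int = 5000
    n_shuffles_mi: int = 200
    n_shuffles_psi: int = 100
    n_shuffles_cofire: int = 2000
    run_bias_control: bool = False
    max_lag_ms: float = 100.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# pipeline stages

def preprocess_session(session: SessionData, config: RunConfig) -> pre.LFPEpochs:
    """Clean the epoched LFP: low-pass, spike interpolation, line-noise
    template subtraction, artifact rejection, Gram-Schmidt
    re-referencing."""
    data = session.lfp.astype(float)
    n_trials, n_times, n_ch = data.shape
    fs = session.fs
    from scipy import signal as sig

    sos = sig.butter(2, 300.0, btype="low", fs=fs, output="sos") \
        if fs > 600.0 else None
    if sos is not None:
        data = sig.sosfiltfilt(sos, data, axis=1)

    pre_n = int(round(2e-3 * fs))
    post_n = int(round(6e-3 * fs))
    markers = {}  # channel -> list per trial of sample indices
    for u in session.units:
        per_trial = markers.setdefault(u.channel, [[] for _ in range(n_trials)])
        for tr, times in enumerate(u.spike_times):
            idx = np.round((np.asarray(times) - session.times[0]) * fs).astype(int)
            per_trial[tr].extend(idx[(idx >= 0) & (idx < n_times)].tolist())
    for ch, per_trial in markers.items():
        for tr, idx in enumerate(per_trial):
            if idx:
                iv = [(k - pre_n, k + post_n + 1) for k in idx]
                data[tr, :, ch] = pre.interpolate_intervals(data[tr, :, ch], iv)

    t = np.arange(n_times) / fs
    design = np.column_stack([
        np.sin(2 * np.pi * config.line_freq * t),
        np.cos(2 * np.pi * config.line_freq * t),
    ])
    flat = data.transpose(1, 0, 2).reshape(n_times, -1)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    flat = flat - design @ coef
    data = flat.reshape(n_times, n_trials, n_ch).transpose(1, 0, 2)

    epochs = pre.LFPEpochs(data=data, times=session.times, fs=fs,
                           bundle_of=np.asarray(session.bundle_of))
    epochs = pre.reject_artifacts(epochs, window=config.power_window)
    epochs = pre.gram_schmidt_rereference(epochs)
    return epochs


def unit_table(session: SessionData, config: RunConfig) -> pd.DataFrame:
    """Classify every unit and evaluate the inclusion rules."""
    rows = []
    for u in session.units:
        u.isi_violation_rate = units_mod.isi_violation_rate(u)
        try:
            u.c2 = units_mod.waveform_variability_c2(u.waveforms)
        except ValueError:
            u.c2 = np.inf
        u.label = units_mod.classify_unit(u)
        included = units_mod.unit_inclusion(u, session.labels)
        rows.append({
            "unit_id": u.unit_id, "channel": u.channel,
            "n_spikes": u.n_spikes,
            "isi_violation_rate": u.isi_violation_rate,
            "c2": u.c2, "label": u.label, "included": included,
        })
    return pd.DataFrame(rows)


def build_pair_data(session: SessionData, epochs: pre.LFPEpochs,
                    config: RunConfig, included_ids=None) -> dict:
    """PairPhaseData for every included unit x surviving channel x band."""
    fs = session.fs
    tr_idx = np.nonzero(epochs.trial_mask)[0]
    ch_idx = np.nonzero(epochs.channel_mask)[0]
    win = config.window
    w0 = int(np.searchsorted(epochs.times, win[0]))
    w1 = int(np.searchsorted(epochs.times, win[1]))
    labels = session.labels[tr_idx]
    units = [u for u in session.units
             if included_ids is None or u.unit_id in included_ids]
    spike_samples = {}
    for u in units:
        per_trial = []
        n_win = w1 - w0
        for tr in tr_idx:
            t = np.asarray(u.spike_times[tr])
            t = t[(t >= win[0]) & (t < win[1])]
            idx = np.floor((t - win[0]) * fs).astype(int)
            per_trial.append(np.clip(idx, 0, n_win - 1))
        spike_samples[u.unit_id] = per_trial

    pairs = {"low": [], "high": []}
    for ch in ch_idx:
        trials = epochs.data[tr_idx][:, :, ch]
        for band in ("low", "high"):
            grid = spectral.grid_for_band(band)
            coef = spectral.wavelet_transform(trials, fs, grid=grid)
            phases = np.angle(coef[:, :, w0:w1]).astype(np.float32)
            del coef
            for u in units:
                if u.channel == ch:
                    locality = "same_wire"
                elif session.bundle_of[u.channel] == session.bundle_of[ch]:
                    locality = "local_bundle"
                else:
                    locality = "distal"
                pairs[band].append(sfc_mod.PairPhaseData(
                    unit_id=u.unit_id, channel=int(ch), locality=locality,
                    freqs=grid.freqs, trial_phases=phases,
                    spike_samples=spike_samples[u.unit_id], labels=labels))
    return pairs


def run_pipeline(session: SessionData, config: RunConfig | None = None,
                 outdir=None) -> dict:
    """Run every analysis stage on one session.

    Returns a report dict of DataFrames and result objects; if a stage
    fails its error is recorded in the failure manifest and dependent
    stages are skipped.  With ``outdir`` all tables are written as CSV.
    """
    if config is None:
        config = RunConfig()
    session.validate()
    rng = np.random.default_rng(config.seed)
    report: dict = {"config": config.to_dict(), "failures": []}

    def _guard(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:  # noqa: BLE001 - failure manifest
            report["failures"].append({"stage": name, "error": repr(err)})
            return None

    epochs = _guard("preprocess", preprocess_session, session, config)
    if epochs is not None:
        report["rejection_log"] = epochs.log_frame()

    utable = _guard("units", unit_table, session, config)
    if utable is not None:
        report["unit_table"] = utable

    if epochs is None or utable is None:
        _write_report(report, outdir)
        return report
    included = set(utable.loc[utable["included"], "unit_id"])

    pairs = _guard("spectral", build_pair_data, session, epochs, config,
                   included)
    if pairs is None:
        _write_report(report, outdir)
        return report

    # --- SFC screening --------------------------------------------------
    def _sfc_stage():
        rows = []
        screened = {"low": [], "high": []}
        unit_channel = {u.unit_id: u.channel for u in session.units}
        for band in ("low", "high"):
            for pair in pairs[band]:
                scr = sfc_mod.screen_pair(pair, config.fdr_alpha,
                                          config.min_spikes_screen)
                rows.append({
                    "unit_id": pair.unit_id,
                    "unit_bundle": int(session.bundle_of[unit_channel[pair.unit_id]]),
                    "channel": pair.channel,
                    "lfp_bundle": int(session.bundle_of[pair.channel]),
                    "band": band, "locality": pair.locality,
                    "n_spikes": scr.n_spikes, "excluded": scr.excluded,
                    "significant": scr.significant,
                    "p_fdr_min": float(np.nanmin(scr.p_fdr))
                    if not scr.excluded else np.nan,
                })
                if scr.significant:
                    screened[band].append(pair)
        return pd.DataFrame(rows), screened

    sfc_out = _guard("sfc_screen", _sfc_stage)
    if sfc_out is None:
        _write_report(report, outdir)
        return report
    pair_table, screened = sfc_out
    report["sfc_pairs"] = pair_table

    def _null_stage():
        out = {}
        for band in ("low", "high"):
            for name, pred in (("local", lambda p: p.is_local()),
                               ("distal", lambda p: not p.is_local())):
                subset = [p for p in pairs[band] if pred(p)]
                res = sfc_mod.pair_count_null(
                    subset, config.fdr_alpha, config.min_spikes_screen,
                    config.n_shuffles_pair_null, config.n_draws_pair_null,
                    seed=rng.integers(2**31))
                out[f"{band}_{name}"] = {"observed": res["observed"],
                                         "p": res["p"]}
        return out

    null_res = _guard("sfc_pair_null", _null_stage)
    if null_res is not None:
        report["sfc_pair_counts"] = pd.DataFrame(null_res).T

    def _contrast_stage():
        out = {}
        for band, group, peak_band in (
                ("high", "local", config.sfc_gamma_band),
                ("low", "distal", config.sfc_theta_band)):
            pred = (lambda p: p.is_local()) if group == "local" \
                else (lambda p: not p.is_local())
            subset = [p for p in screened[band] if pred(p)]
            if not subset:
                continue
            try:
                contrast = sfc_mod.condition_contrast(
                    subset, config.min_spikes_screen, config.fdr_alpha)
            except ValueError:
                continue
            shift = sfc_mod.peak_frequency_shift(
                subset, peak_band, config.ppc_peak_threshold,
                config.min_spikes_screen)
            out[f"{band}_{group}"] = {"contrast": contrast, "shift": shift}
        return out

    contrasts = _guard("sfc_contrast", _contrast_stage)
    if contrasts:
        report["sfc_contrasts"] = contrasts
        for key, val in contrasts.items():
            report[f"sfc_peak_shift_{key}"] = val["shift"]["table"]

    if config.run_bias_control:
        def _bias_stage():
            out = {}
            for band, group in (("high", "local"), ("low", "distal")):
                pred = (lambda p: p.is_local()) if group == "local" \
                    else (lambda p: not p.is_local())
                subset = [p for p in screened[band] if pred(p)]
                out[f"{band}_{group}"] = [
                    sfc_mod.selection_bias_control(
                        p, config.n_shuffles_bias, config.fdr_alpha,
                        config.min_spikes_screen, seed=rng.integers(2**31))
                    for p in subset]
            return out
        bias = _guard("sfc_bias_control", _bias_stage)
        if bias is not None:
            report["sfc_bias_control"] = bias

    # --- PSI directionality ---------------------------------------------
    def _psi_stage():
        tr_idx = np.nonzero(epochs.trial_mask)[0]
        labels = session.labels[tr_idx]
        win = config.window
        w0 = int(np.searchsorted(epochs.times, win[0]))
        w1 = int(np.searchsorted(epochs.times, win[1]))
        dur = (w1 - w0) / session.fs
        unit_by_id = {u.unit_id: u for u in session.units}
        rows, z_h, z_m, freqs = [], [], [], None
        for pair in screened["low"]:
            if pair.is_local():
                continue
            unit = unit_by_id[pair.unit_id]
            spk = [np.asarray(unit.spike_times[tr]) for tr in tr_idx]
            spk = [t[(t >= win[0]) & (t < win[1])] - win[0] for t in spk]
            lfp = epochs.data[tr_idx][:, w0:w1, pair.channel]
            res_by_cond = {}
            for cond in (HIT, MISS):
                sel = labels == cond
                n_spk = int(sum(len(spk[i]) for i in np.nonzero(sel)[0]))
                dens = cofire_mod.density_trials(
                    [spk[i] for i in np.nonzero(sel)[0]], dur, session.fs)
                res = dir_mod.psi(
                    dens, lfp[sel], session.fs,
                    band=(config.sfc_theta_band[0], config.sfc_theta_band[1]),
                    bandwidth=config.psi_bandwidth,
                    n_shuffles=config.n_shuffles_psi,
                    seed=rng.integers(2**31), n_spikes=n_spk,
                    relaxed=config.psi_relaxed)
                res_by_cond[cond] = res
            if res_by_cond[HIT] is None or res_by_cond[MISS] is None:
                continue
            freqs = res_by_cond[HIT].freqs
            z_h.append(res_by_cond[HIT].z)
            z_m.append(res_by_cond[MISS].z)
            rows.append({"unit_id": pair.unit_id, "channel": pair.channel,
                         "mean_z_hit": float(np.nanmean(res_by_cond[HIT].z)),
                         "mean_z_miss": float(np.nanmean(res_by_cond[MISS].z))})
        out = {"table": pd.DataFrame(rows)}
        if len(z_h) >= 2:
            out["contrast"] = dir_mod.psi_condition_contrast(
                np.vstack(z_h), np.vstack(z_m), freqs, config.fdr_alpha)
        return out

    psi_res = _guard("direction", _psi_stage)
    if psi_res is not None:
        report["psi"] = psi_res

    # --- CFC --------------------------------------------------------------
    def _cfc_stage():
        tr_idx = np.nonzero(epochs.trial_mask)[0]
        labels = session.labels[tr_idx]
        win = config.window
        w0 = int(np.searchsorted(epochs.times, win[0]))
        w1 = int(np.searchsorted(epochs.times, win[1]))
        # bundles where a local gamma coupling and a distal theta coupling meet
        gamma_by_bundle, theta_by_bundle = {}, {}
        for pair in screened["high"]:
            if pair.is_local():
                gamma_by_bundle.setdefault(
                    int(session.bundle_of[pair.channel]), pair)
        for pair in screened["low"]:
            if not pair.is_local():
                theta_by_bundle.setdefault(
                    int(session.bundle_of[pair.channel]), pair)
        rows = []
        for bundle in sorted(set(gamma_by_bundle) & set(theta_by_bundle)):
            tpair = theta_by_bundle[bundle]
            gpair = gamma_by_bundle[bundle]
            tspec = sfc_mod.condition_ppc(tpair, config.min_spikes_screen)
            gspec = sfc_mod.condition_ppc(gpair, config.min_spikes_screen)
            row = {"bundle": bundle, "theta_channel": tpair.channel,
                   "gamma_channel": gpair.channel}
            ok = True
            peaks = {}
            for cond in (HIT, MISS):
                if tspec[cond] is None or gspec[cond] is None:
                    ok = False
                    break
                pk_t = sfc_mod.detect_peak(tpair.freqs, tspec[cond],
                                           config.cfc_theta_band,
                                           config.ppc_peak_threshold)
                pk_g = sfc_mod.detect_peak(gpair.freqs, gspec[cond],
                                           config.cfc_gamma_band,
                                           config.ppc_peak_threshold)
                if pk_t is None or pk_g is None:
                    ok = False
                    break
                peaks[cond] = (pk_t[0], pk_g[0])
                row[f"theta_peak_{cond}"] = pk_t[0]
                row[f"gamma_peak_{cond}"] = pk_g[0]
            if not ok:
                continue
            lfp_phase_tr = epochs.data[tr_idx][:, :, tpair.channel]
            lfp_amp_tr = epochs.data[tr_idx][:, :, gpair.channel]
            for cond in (HIT, MISS):
                sel = labels == cond
                th_f, ga_f = peaks[cond]
                coef_t = spectral.wavelet_transform(
                    lfp_phase_tr[sel], session.fs, freqs=[th_f],
                    n_cycles=spectral.LOW_CYCLES)
                coef_g = spectral.wavelet_transform(
                    lfp_amp_tr[sel], session.fs, freqs=[ga_f],
                    n_cycles=spectral.HIGH_CYCLES, derivative=True)
                phase = np.angle(coef_t[:, 0, w0:w1])
                amp = np.abs(coef_g[:, 0, w0:w1])
                res = cfc_mod.mi_shuffle_z(list(phase), list(amp),
                                           config.n_shuffles_mi,
                                           seed=rng.integers(2**31))
                row[f"mi_{cond}"] = res["mi"]
                row[f"mi_z_{cond}"] = res["z"]
                # harmonic control: amplitude at 8 x theta peak
                harm_f = cfc_mod.harmonic_frequency(th_f)
                if harm_f < session.fs / 2 - 1:
                    coef_h = spectral.wavelet_transform(
                        lfp_amp_tr[sel], session.fs, freqs=[harm_f],
                        n_cycles=spectral.HIGH_CYCLES, derivative=True)
                    amp_h = np.abs(coef_h[:, 0, w0:w1])
                    res_h = cfc_mod.mi_shuffle_z(list(phase), list(amp_h),
                                                 config.n_shuffles_mi,
                                                 seed=rng.integers(2**31))
                    row[f"mi_z_harm_{cond}"] = res_h["z"]
            rows.append(row)
        table = pd.DataFrame(rows)
        out = {"table": table}
        if len(table) >= 2:
            out["condition_test"] = cfc_mod.cfc_condition_test(
                table["mi_z_hit"].to_numpy(), table["mi_z_miss"].to_numpy())
        return out

    cfc_res = _guard("cfc", _cfc_stage)
    if cfc_res is not None:
        report["cfc"] = cfc_res
        if "table" in cfc_res:
            report["cfc_table"] = cfc_res["table"]

    # --- co-firing --------------------------------------------------------
    def _cofire_stage():
        selected = cofire_mod.select_pairs(pair_table)
        tr_idx = np.nonzero(epochs.trial_mask)[0]
        labels = session.labels[tr_idx]
        win = config.window
        dur = win[1] - win[0]
        unit_by_id = {u.unit_id: u for u in session.units}

        def _win_trials(uid):
            u = unit_by_id[uid]
            out = []
            for tr in tr_idx:
                t = np.asarray(u.spike_times[tr])
                out.append(t[(t >= win[0]) & (t < win[1])] - win[0])
            return out

        results, kept = [], []
        for sender, receiver, bundle in selected:
            res = cofire_mod.cofiring_by_condition(
                _win_trials(sender), _win_trials(receiver), labels, dur,
                session.fs, seed=rng.integers(2**31),
                n_shuffles=config.n_shuffles_cofire,
                max_lag_ms=config.max_lag_ms)
            retained = cofire_mod.coincidence_filter(res, config.coincidence_z)
            results.append({"sender": sender, "receiver": receiver,
                            "bundle": bundle, "retained": retained})
            if retained:
                kept.append(res)
        out = {"pairs": pd.DataFrame(results)}
        if kept:
            out["lag_contrast"] = cofire_mod.peak_lag_contrast(kept)
            out["lag_contrast_reverse"] = cofire_mod.peak_lag_contrast(
                kept, side="negative")
        return out

    cof = _guard("cofire", _cofire_stage)
    if cof is not None:
        report["cofire"] = cof
        if "pairs" in cof:
            report["cofire_pairs"] = cof["pairs"]
        if "lag_contrast" in cof:
            report["cofire_lags"] = cof["lag_contrast"]["table"]

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir) -> None:
    if outdir is None:
        return
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(outdir / f"{key}.csv", index=False,
                       float_format="%.10g")
    summary = {
        "failures": report.get("failures", []),
        "config": report.get("config", {}),
    }
    if "sfc_pair_counts" in report:
        summary["sfc_pair_counts"] = report["sfc_pair_counts"].to_dict()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
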