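"""Session containers and HDF5 persistence.

A session holds everything one recording contributes to the analysis:
epoched LFP trials (time-locked to the cue, 1 kHz), per-unit spike times
and waveforms, trial outcome labels, and channel/bundle metadata.  The
HDF5 layout mirrors the in-memory structure:

    /lfp                       trials x time x channels, float32
    /units/<id>/spike_times    ragged, stored as concatenated + offsets
    /units/<id>/waveforms      spikes x samples
    /trials/labels             per-trial condition label
    /meta                      fs, bundle map, JSON-encoded ground truth
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

HIT, MISS = "hit", "miss"


@dataclass
class UnitRecord:
    """One putative single-/multi-unit: spike times, waveforms, labels.

    ``spike_times`` is a list with one array per trial, in seconds
    relative to cue onset (so values lie inside the epoch, e.g. -7..7).
    Classification fields are filled in by :mod:`spikefield.units`.
    """

    unit_id: str
    channel: int
    spike_times: list
    waveforms: np.ndarray
    fs_wave: float = 32000.0
    isi_violation_rate: float | None = None
    c2: float | None = None
    label: str | None = None

    @property
    def n_spikes(self) -> int:
        return int(sum(len(t) for t in self.spike_times))

    def spikes_in_window(self, window) -> list:
        lo, hi = window
        return [t[(t >= lo) & (t < hi)] for t in self.spike_times]

    def all_isis(self) -> np.ndarray:
        isis = [np.diff(np.sort(t)) for t in self.spike_times if len(t) > 1]
        if not isis:
            return np.empty(0)
        return np.concatenate(isis)


@dataclass
class SessionData:
    """Epoched LFP + spikes + labels for one recording session."""

    lfp: np.ndarray              # (n_trials, n_times, n_channels) float32
    fs: float
    times: np.ndarray            # seconds relative to cue onset
    labels: np.ndarray           # per-trial 'hit' / 'miss'
    bundle_of: np.ndarray        # per-channel bundle id
    units: list = field(default_factory=list)
    ground_truth: dict | None = None

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[2]

    def condition_mask(self, condition: str) -> np.ndarray:
        return self.labels == condition

    def validate(self) -> None:
        if self.lfp.ndim != 3:
            raise ValueError("lfp must be trials x time x channels")
        if self.lfp.shape[0] == 0:
            raise ValueError("session has no trials")
        if len(self.labels) != self.n_trials:
            raise ValueError("labels length does not match trial count")
        if len(self.bundle_of) != self.n_channels:
            raise ValueError("bundle map length does not match channel count")
        if len(self.times) != self.lfp.shape[1]:
            raise ValueError("time axis does not match LFP samples")
        for u in self.units:
            if not 0 <= u.channel < self.n_channels:
                raise ValueError(f"unit {u.unit_id} references unknown channel")
            if len(u.spike_times) != self.n_trials:
                raise ValueError(f"unit {u.unit_id} trial count mismatch")


def save_session(session: SessionData, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp.astype(np.float32))
        trials = f.create_group("trials")
        trials.create_dataset(
            "labels", data=np.array([s.encode() for s in session.labels])
        )
        meta = f.create_group("meta")
        meta.attrs["fs"] = session.fs
        meta.create_dataset("times", data=session.times)
        meta.create_dataset("bundle_of", data=session.bundle_of)
        meta.attrs["ground_truth"] = json.dumps(
            session.ground_truth, default=_json_default
        )
        units = f.create_group("units")
        for u in session.units:
            g = units.create_group(u.unit_id)
            flat = (
                np.concatenate(u.spike_times)
                if any(len(t) for t in u.spike_times)
                else np.empty(0)
            )
            offsets = np.cumsum([0] + [len(t) for t in u.spike_times])
            g.create_dataset("spike_times", data=flat)
            g.create_dataset("offsets", data=offsets)
            g.create_dataset("waveforms", data=u.waveforms.astype(np.float32))
            g.attrs["channel"] = u.channel
            g.attrs["fs_wave"] = u.fs_wave


def load_session(path) -> SessionData:
    with h5py.File(path, "r") as f:
        lfp = f["lfp"][:]
        labels = np.array([s.decode() for s in f["trials/labels"][:]])
        fs = float(f["meta"].attrs["fs"])
        times = f["meta/times"][:]
        bundle_of = f["meta/bundle_of"][:]
        gt = json.loads(f["meta"].attrs["ground_truth"])
        units = []
        for uid in sorted(f["units"]):
            g = f["units"][uid]
            flat = g["spike_times"][:]
            offsets = g["offsets"][:]
            spike_times = [
                flat[offsets[i]:offsets[i + 1]] for i in range(len(offsets) - 1)
            ]
            units.append(
                UnitRecord(
                    unit_id=uid,
                    channel=int(g.attrs["channel"]),
                    spike_times=spike_times,
                    waveforms=g["waveforms"][:],
                    fs_wave=float(g.attrs["fs_wave"]),
                )
            )
    return SessionData(
        lfp=lfp, fs=fs, times=times, labels=labels,
        bundle_of=bundle_of, units=units, ground_truth=gt,
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
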