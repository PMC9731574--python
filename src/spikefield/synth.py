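"""Synthetic LFP/spike sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* non-stationary theta whose instantaneous frequency performs a reflected
  Gaussian random walk inside a band (mean ~6 Hz, range 3.5-9 Hz),
* gamma bursts whose envelope is modulated by theta phase (phase-amplitude
  coupling, maximal by default at the theta trough),
* units that fire as inhomogeneous Poisson processes with a von Mises gain
  on the phase of their target oscillation (theta or gamma), with the
  locking frequency depending on the trial condition (hit vs miss),
* pairs of units that co-fire at a controllable, condition-dependent lag.

Every generated quantity is reproducible bit-for-bit from (spec, seed),
and the hidden parameters are attached to the session for parameter-
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
from scipy.special import i0

from ._stats import TWO_PI, wrap_phase
from .session import HIT, MISS, SessionData, UnitRecord


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class OscillatorSpec:
    """A band-limited oscillator with randomly drifting frequency.

    ``freq_walk_sd`` is the standard deviation (Hz) of the per-sample
    Gaussian increment of the instantaneous frequency; the walk is kept
    inside ``freq_range`` by reflection.  The default 0.02 Hz/step at
    1 kHz lets the walk explore the full 3.5-9 Hz band within ~60 s.
    """

    mean_freq: float = 6.0
    freq_range: tuple = (3.5, 9.0)
    freq_walk_sd: float = 0.02
    mean_reversion: float = 2e-4
    amplitude: float = 1.0
    duration: float = 60.0
    fs: float = 1000.0

    def validate(self) -> None:
        lo, hi = self.freq_range
        if not lo <= self.mean_freq <= hi:
            raise ValueError("mean_freq outside freq_range")
        if self.fs <= 2.0 * hi:
            raise ValueError(
                f"sampling rate {self.fs} Hz too low for frequencies up to "
                f"{hi} Hz (need fs > {2 * hi} Hz)"
            )
        if self.freq_walk_sd < 0 or self.duration < 0:
            raise ValueError("freq_walk_sd and duration must be non-negative")


@dataclass(frozen=True)
class LockingSpec:
    """von Mises phase locking of a unit to an oscillation.

    kappa = 0 reproduces a homogeneous Poisson process independent of
    phase; larger kappa concentrates spikes around ``preferred_phase``.
    """

    target: str = "theta"            # 'theta' | 'gamma'
    preferred_phase: float = -np.pi  # trough of a cosine oscillator
    kappa: float = 4.0
    base_rate: float = 10.0          # Hz, time-averaged

    def validate(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.target not in ("theta", "gamma"):
            raise ValueError("target must be 'theta' or 'gamma'")


@dataclass(frozen=True)
class PACSpec:
    """Theta-phase to gamma-amplitude coupling of the generated LFP.

    The gamma envelope is 1 + coupling_depth * cos(theta_phase -
    gamma_phase_of_max); depth 0 yields a constant envelope.
    """

    theta_freq: float = 8.0
    gamma_freq: float = 70.0
    coupling_depth: float = 0.5
    gamma_phase_of_max: float = np.pi  # gamma largest near theta trough

    def validate(self) -> None:
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise ValueError("coupling_depth must lie in [0, 1]")
        if self.gamma_freq <= self.theta_freq:
            raise ValueError("gamma_freq must exceed theta_freq")


@dataclass(frozen=True)
class CofireSpec:
    """Sender -> receiver spike copying at a fixed (jittered) lag.

    ``lag_ms`` may be negative for the reverse-direction control
    (receiver leading).  The receiver also fires independent background
    spikes at ``background_rate``.
    """

    lag_ms: float = 20.0
    jitter_sd_ms: float = 2.0
    copy_prob: float = 0.5
    background_rate: float = 2.0

    def validate(self) -> None:
        if not 0.0 <= self.copy_prob <= 1.0:
            raise ValueError("copy_prob must lie in [0, 1]")
        if self.jitter_sd_ms < 0:
            raise ValueError("jitter_sd_ms must be >= 0")


class Oscillation(NamedTuple):
    samples: np.ndarray    # amplitude * cos(phase)
    phase: np.ndarray      # wrapped to [-pi, pi)
    inst_freq: np.ndarray  # Hz, per sample
    fs: float


# ---------------------------------------------------------------------------
# elementary generators

def gen_nonstationary_oscillator(spec: OscillatorSpec, seed) -> Oscillation:
    """Oscillator whose instantaneous frequency random-walks in a band.

    The frequency performs a reflected Gaussian walk inside
    ``spec.freq_range`` starting at ``spec.mean_freq``; the phase is the
    cumulative integral of the frequency.  Returns samples together with
    the true phase so locking generators and recovery tests can use it.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.fs))
    if n == 0:
        empty = np.empty(0)
        return Oscillation(empty, empty, empty, spec.fs)
    lo, hi = spec.freq_range
    if spec.freq_walk_sd > 0:
        # weakly mean-reverting Gaussian walk, reflected into [lo, hi]
        steps = rng.normal(0.0, spec.freq_walk_sd, n - 1)
        freq = np.empty(n)
        f = spec.mean_freq
        theta = spec.mean_reversion
        mu = spec.mean_freq
        freq[0] = f
        for i in range(1, n):
            f = f + theta * (mu - f) + steps[i - 1]
            if f > hi:
                f = 2.0 * hi - f
            elif f < lo:
                f = 2.0 * lo - f
            f = min(max(f, lo), hi)
            freq[i] = f
    else:
        freq = np.full(n, spec.mean_freq)
    phi0 = rng.uniform(-np.pi, np.pi)
    phase = phi0 + TWO_PI * np.cumsum(freq) / spec.fs
    samples = spec.amplitude * np.cos(phase)
    return Oscillation(samples, wrap_phase(phase), freq, spec.fs)


def gen_locked_spikes(phase: np.ndarray, fs: float, spec: LockingSpec,
                      seed) -> np.ndarray:
    """Spike times (s) from a phase-modulated inhomogeneous Poisson process.

    The instantaneous rate is base_rate * exp(kappa cos(phi - phi0)) / I0(kappa),
    whose time average is ~base_rate when the phase sweeps uniformly; the
    process is realized by per-sample Bernoulli thinning.
    """
    spec.validate()
    phase = np.asarray(phase, dtype=float)
    if phase.size == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    gain = np.exp(spec.kappa * np.cos(phase - spec.preferred_phase)) / i0(spec.kappa)
    p = np.clip(spec.base_rate * gain / fs, 0.0, 1.0)
    idx = np.nonzero(rng.random(phase.size) < p)[0]
    return idx / fs


class PACSignal(NamedTuple):
    samples: np.ndarray
    theta_phase: np.ndarray
    gamma_env: np.ndarray   # envelope of the gamma component (>= 0)
    fs: float


def gen_pac_lfp(spec: PACSpec, duration: float, fs: float, noise_sd: float,
                seed, theta_amp: float = 1.0, gamma_amp: float = 0.5,
                theta_phase: np.ndarray | None = None) -> PACSignal:
    """LFP with theta and theta-phase-modulated gamma plus white noise.

    If ``theta_phase`` is given (e.g. from a non-stationary oscillator)
    it is used directly; otherwise theta is a pure sinusoid at
    ``spec.theta_freq``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if theta_phase is None:
        phi0 = rng.uniform(-np.pi, np.pi)
        theta_phase = wrap_phase(phi0 + TWO_PI * spec.theta_freq * t)
    else:
        theta_phase = np.asarray(theta_phase, dtype=float)[:n]
        if theta_phase.size != n:
            raise ValueError("theta_phase shorter than requested duration")
    env = 1.0 + spec.coupling_depth * np.cos(theta_phase - spec.gamma_phase_of_max)
    gamma_phi0 = rng.uniform(-np.pi, np.pi)
    gamma = gamma_amp * env * np.cos(TWO_PI * spec.gamma_freq * t + gamma_phi0)
    samples = theta_amp * np.cos(theta_phase) + gamma
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, n)
    return PACSignal(samples, theta_phase, gamma_amp * env, fs)


def gen_cofiring_pair(sender_times: np.ndarray, spec: CofireSpec,
                      duration: float, seed) -> np.ndarray:
    """Receiver spike train echoing a fraction of sender spikes at a lag."""
    spec.validate()
    sender_times = np.asarray(sender_times, dtype=float)
    if sender_times.size == 0:
        raise ValueError("sender spike train is empty")
    rng = np.random.default_rng(seed)
    copied = sender_times[rng.random(sender_times.size) < spec.copy_prob]
    echoes = copied + spec.lag_ms / 1e3
    if spec.jitter_sd_ms > 0:
        echoes = echoes + rng.normal(0.0, spec.jitter_sd_ms / 1e3, copied.size)
    n_bg = rng.poisson(spec.background_rate * duration)
    background = rng.uniform(0.0, duration, n_bg)
    out = np.concatenate([echoes, background])
    out = out[(out >= 0.0) & (out < duration)]
    return np.sort(out)


# ---------------------------------------------------------------------------
# whole-session generation

@dataclass(frozen=True)
class ConditionParams:
    """Condition-dependent oscillation and co-firing parameters."""

    theta_freq: float
    gamma_freq: float
    cofire_lag_ms: float
    pac_depth: float = 0.8


@dataclass
class SessionDesign:
    """Full recipe for a synthetic session (the hidden ground truth).

    Defaults implement the headline scenario: hits lock at fast theta
    (8 Hz) and fast gamma (70 Hz) with short co-firing lags (20 ms),
    misses at slow theta (5 Hz) / slow gamma (62 Hz) with long lags
    (60 ms).  Two bundles of four microwires each; per bundle one unit
    distally theta-locked to the *other* bundle's LFP (the putative
    sender) and one unit locally gamma-locked (the putative receiver).
    """

    n_hits: int = 24
    n_misses: int = 16
    n_bundles: int = 2
    channels_per_bundle: int = 4
    fs: float = 1000.0
    epoch: tuple = (-7.0, 7.0)
    window: tuple = (2.0, 3.0)
    hit: ConditionParams = field(
        default_factory=lambda: ConditionParams(8.0, 70.0, 20.0, 0.8))
    miss: ConditionParams = field(
        default_factory=lambda: ConditionParams(5.0, 62.0, 60.0, 0.3))
    theta_kappa: float = 4.0
    gamma_kappa: float = 3.0
    locked_rate: float = 40.0        # Hz inside the window of interest
    background_rate: float = 3.0     # Hz outside the window
    cofire_copy_prob: float = 0.6
    cofire_jitter_sd_ms: float = 2.0
    theta_amp: float = 1.0
    gamma_amp: float = 0.5
    noise_sd: float = 0.4
    pink_noise_amp: float = 0.0      # optional 1/f noise amplitude
    freq_walk_sd: float = 0.01
    theta_halfrange: float = 1.0     # theta walks inside mean +/- this
    seed: int = 0

    def condition(self, label: str) -> ConditionParams:
        return self.hit if label == HIT else self.miss

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        if self.n_hits + self.n_misses == 0:
            raise ValueError("design has no trials")
        if self.n_bundles < 1 or self.channels_per_bundle < 1:
            raise ValueError("need at least one bundle and one channel")
        for cp in (self.hit, self.miss):
            if cp.gamma_freq <= cp.theta_freq:
                raise ValueError("gamma_freq must exceed theta_freq")


def _pink_noise(n: int, rng) -> np.ndarray:
    """1/f-amplitude Gaussian noise (exponent 1 in power is 2 in amplitude
    terms of 1/sqrt(f)), unit variance."""
    white = rng.normal(0.0, 1.0, n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    spec = spec / np.sqrt(f)
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _spike_template(n: int = 64, fs_wave: float = 32000.0) -> np.ndarray:
    """Canonical extracellular spike shape: fast positive peak, slow
    after-hyperpolarization."""
    t = np.arange(n) / fs_wave * 1e3  # ms
    peak = 100.0 * np.exp(-0.5 * ((t - 0.8) / 0.15) ** 2)
    ahp = -35.0 * np.exp(-0.5 * ((t - 1.4) / 0.35) ** 2)
    return peak + ahp


def gen_session(design: SessionDesign) -> SessionData:
    """Generate a full synthetic session from a design.

    The LFP of every channel is a gain-weighted mixture of its bundle's
    theta and PAC-modulated gamma plus independent noise (so local
    re-referencing attenuates, but does not annihilate, the shared
    oscillation).  Spikes are condition-locked inside the window of
    interest and homogeneous Poisson elsewhere.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    fs = design.fs
    t0, t1 = design.epoch
    n_times = int(round((t1 - t0) * fs)) + 1
    times = t0 + np.arange(n_times) / fs
    n_trials = design.n_hits + design.n_misses
    labels = np.array([HIT] * design.n_hits + [MISS] * design.n_misses)
    perm = rng.permutation(n_trials)
    labels = labels[perm]

    n_ch = design.n_bundles * design.channels_per_bundle
    bundle_of = np.repeat(np.arange(design.n_bundles), design.channels_per_bundle)
    # fixed per-channel mixing gains (differ across wires of a bundle)
    g_theta = rng.uniform(0.6, 1.4, n_ch)
    g_gamma = rng.uniform(0.6, 1.4, n_ch)

    win_lo = int(round((design.window[0] - t0) * fs))
    win_hi = int(round((design.window[1] - t0) * fs))
    epoch_dur = t1 - t0

    lfp = np.zeros((n_trials, n_times, n_ch), dtype=np.float32)
    theta_phase = np.zeros((n_trials, design.n_bundles, n_times))
    gamma_phase = np.zeros_like(theta_phase)

    for tr in range(n_trials):
        cp = design.condition(labels[tr])
        for b in range(design.n_bundles):
            osc_seed = rng.integers(2**31)
            osc = gen_nonstationary_oscillator(
                OscillatorSpec(
                    mean_freq=cp.theta_freq,
                    freq_range=(cp.theta_freq - design.theta_halfrange,
                                cp.theta_freq + design.theta_halfrange),
                    freq_walk_sd=design.freq_walk_sd,
                    amplitude=design.theta_amp,
                    duration=epoch_dur + 1.0 / fs,
                    fs=fs,
                ),
                osc_seed,
            )
            th_phase = osc.phase[:n_times]
            env = 1.0 + cp.pac_depth * np.cos(th_phase - np.pi)
            g_phi0 = rng.uniform(-np.pi, np.pi)
            g_phase = wrap_phase(
                g_phi0 + TWO_PI * cp.gamma_freq * np.arange(n_times) / fs)
            gamma = design.gamma_amp * env * np.cos(g_phase)
            theta_phase[tr, b] = th_phase
            gamma_phase[tr, b] = g_phase
            for ch in np.nonzero(bundle_of == b)[0]:
                noise = rng.normal(0.0, design.noise_sd, n_times)
                if design.pink_noise_amp > 0:
                    noise = noise + design.pink_noise_amp * _pink_noise(n_times, rng)
                lfp[tr, :, ch] = (
                    g_theta[ch] * design.theta_amp * np.cos(th_phase)
                    + g_gamma[ch] * gamma + noise
                )

    # --- units -------------------------------------------------------------
    # per bundle: a theta 'sender' locked to the OTHER bundle's theta, and a
    # gamma 'receiver' locked to its own bundle's gamma which additionally
    # echoes the sender's spikes at the condition lag.
    units = []
    template = _spike_template()
    sender_window_spikes = {}  # bundle -> list per trial of window spike times

    def _make_waveforms(n_spk: int, noise_uv: float) -> np.ndarray:
        return template[None, :] + rng.normal(0.0, noise_uv, (max(n_spk, 1), template.size))

    for b in range(design.n_bundles):
        other = (b + 1) % design.n_bundles
        # sender: distally locked to theta of bundle `other`
        sender_trials = []
        win_spikes = []
        for tr in range(n_trials):
            spk = _locked_trial_spikes(
                theta_phase[tr, other], fs, design, design.theta_kappa,
                win_lo, win_hi, t0, rng)
            sender_trials.append(spk)
            win = spk[(spk >= design.window[0]) & (spk < design.window[1])]
            win_spikes.append(win)
        sender_window_spikes[b] = win_spikes
        ch_sender = b * design.channels_per_bundle
        n_spk = sum(len(s) for s in sender_trials)
        units.append(UnitRecord(
            unit_id=f"u{2 * b:02d}_sender_b{b}", channel=ch_sender,
            spike_times=sender_trials,
            waveforms=_make_waveforms(n_spk, 2.0)))

    for b in range(design.n_bundles):
        other = (b + 1) % design.n_bundles
        receiver_trials = []
        for tr in range(n_trials):
            cp = design.condition(labels[tr])
            spk = _locked_trial_spikes(
                gamma_phase[tr, b], fs, design, design.gamma_kappa,
                win_lo, win_hi, t0, rng)
            # echo the sender (in the other bundle) that targets this bundle
            sender_win = sender_window_spikes[other][tr]
            if sender_win.size:
                echo = gen_cofiring_pair(
                    sender_win - design.window[0],
                    CofireSpec(lag_ms=cp.cofire_lag_ms,
                               jitter_sd_ms=design.cofire_jitter_sd_ms,
                               copy_prob=design.cofire_copy_prob,
                               background_rate=0.0),
                    design.window[1] - design.window[0],
                    rng.integers(2**31),
                ) + design.window[0]
                spk = np.sort(np.concatenate([spk, echo]))
            receiver_trials.append(spk)
        ch_receiver = b * design.channels_per_bundle + 1
        n_spk = sum(len(s) for s in receiver_trials)
        units.append(UnitRecord(
            unit_id=f"u{2 * b + 1:02d}_receiver_b{b}", channel=ch_receiver,
            spike_times=receiver_trials,
            waveforms=_make_waveforms(n_spk, 2.0)))

    units.sort(key=lambda u: u.unit_id)
    gt = {
        "design": design.to_dict(),
        "labels": labels.tolist(),
        "g_theta": g_theta.tolist(),
        "g_gamma": g_gamma.tolist(),
        "units": {
            u.unit_id: {"channel": int(u.channel)} for u in units
        },
    }
    session = SessionData(
        lfp=lfp, fs=fs, times=times, labels=labels, bundle_of=bundle_of,
        units=units, ground_truth=gt,
    )
    session.validate()
    return session


def gen_pair_phase_data(band: str, freq_by_cond: dict, kappa: float = 4.0,
                        n_hits: int = 24, n_misses: int = 16,
                        fs: float = 1000.0, rate: float = 40.0,
                        noise_sd: float = 0.5, seed=0,
                        locality: str = "distal", unit_id: str = "u00",
                        channel: int = 0, freq_halfrange: float = 0.75,
                        freq_walk_sd: float = 0.01):
    """One synthetic spike-LFP pair with condition-dependent locking.

    Generates per-trial LFP (oscillator at the condition's locking
    frequency plus white noise), measures its wavelet phase on the
    band's frequency grid, and plants trough-locked spikes inside a 1 s
    central window.  Returns a ready-to-screen
    :class:`spikefield.sfc.PairPhaseData` — the substrate for
    peak-frequency-shift and selection-bias recovery experiments.

    ``freq_by_cond`` maps 'hit'/'miss' to the locking frequency (Hz).
    """
    from . import spectral
    from .sfc import PairPhaseData

    grid = spectral.grid_for_band(band)
    # trials long enough that the slowest wavelet fits and the analysis
    # window sits away from the edges
    trial_dur = 7.0 if band == "low" else 3.0
    win = ((trial_dur - 1.0) / 2.0, (trial_dur + 1.0) / 2.0)
    n_times = int(round(trial_dur * fs))
    w0 = int(round(win[0] * fs))
    w1 = int(round(win[1] * fs))
    rng = np.random.default_rng(seed)
    n_trials = n_hits + n_misses
    labels = np.array([HIT] * n_hits + [MISS] * n_misses)
    labels = labels[rng.permutation(n_trials)]
    lfp = np.empty((n_trials, n_times))
    spike_samples = []
    for tr in range(n_trials):
        f = freq_by_cond[labels[tr]]
        osc = gen_nonstationary_oscillator(
            OscillatorSpec(mean_freq=f,
                           freq_range=(f - freq_halfrange, f + freq_halfrange),
                           freq_walk_sd=freq_walk_sd,
                           duration=trial_dur, fs=fs),
            rng.integers(2**31))
        lfp[tr] = osc.samples[:n_times] + rng.normal(0.0, noise_sd, n_times)
        spk = gen_locked_spikes(
            osc.phase[w0:w1], fs,
            LockingSpec(kappa=kappa, base_rate=rate, preferred_phase=-np.pi),
            rng.integers(2**31))
        idx = np.clip(np.floor(spk * fs).astype(int), 0, w1 - w0 - 1)
        spike_samples.append(idx)
    coef = spectral.wavelet_transform(lfp, fs, grid=grid)
    phases = np.angle(coef[:, :, w0:w1]).astype(np.float32)
    return PairPhaseData(unit_id=unit_id, channel=channel, locality=locality,
                         freqs=grid.freqs, trial_phases=phases,
                         spike_samples=spike_samples, labels=labels)


def _locked_trial_spikes(phase, fs, design, kappa, win_lo, win_hi, t0, rng):
    """Locked spikes inside the window of interest, Poisson background
    outside; times in seconds relative to cue."""
    spec = LockingSpec(kappa=kappa, base_rate=design.locked_rate,
                       preferred_phase=-np.pi)
    win_phase = phase[win_lo:win_hi]
    locked = gen_locked_spikes(win_phase, fs, spec, rng.integers(2**31))
    locked = locked + win_lo / fs
    n_bg = rng.poisson(design.background_rate * (len(phase) - (win_hi - win_lo)) / fs)
    bg = rng.uniform(0.0, len(phase) / fs, max(n_bg, 0))
    bg = bg[(bg < win_lo / fs) | (bg >= win_hi / fs)]
    out = np.sort(np.concatenate([locked, bg]))
    return out + t0
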