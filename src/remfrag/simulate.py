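"""Synthetic two-condition REM-fragmentation cohort with planted ground truth.

Generates, for each subject of a within-subject two-condition design
(CTR = undisturbed control night, FRG = vibrotactile REM-fragmentation
night), every data modality the analysis pipeline consumes:

* full-night hypnograms drawn from condition-specific five-state Markov
  stage dynamics, with a rule-based stimulation protocol played out inside
  the REM periods of the FRG night (escalating intensity steps, 3-s
  vibration / 3-s pause, 40-s suspension after an elicited arousal,
  restart at minimum intensity in each new REM period);
* stimulation-locked EEG epochs: 1/f background noise plus band-limited
  bursts (amplitude-modulated band-passed noise) of configured dB effect
  and topographic weighting, emulating the cortical arousal signature;
* per-trial autonomic physiology: inter-beat intervals with a raised-cosine
  heart-rate deceleration of planted, condition- and session-dependent
  amplitude (CTR habituates from T0 to T1, FRG stays flat), and EDA traces
  with Bateman-shaped skin-conductance responses;
* old/new recognition responses from an equal-variance signal-detection
  model with session-dependent d'.

A subject-level latent coupling links the planted posterior alpha-burst
power (dB) on the FRG night to the planted change in heart-rate
deceleration (T1 minus T0), with configurable correlation; every generator
is a pure function of (config, subject, condition, session) so any subset
of the cohort is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .autonomic import TrialPhysio, bateman
from .hypnogram import STAGES, Hypnogram
from .io import CH_NAMES_19, POSTERIOR_CHANNELS

CONDITIONS = ("CTR", "FRG")
SESSIONS = ("T0", "T1", "T2")

# fixed stream offsets deriving per-generator rngs from the global seed
_STREAM_SUBJECT = 101
_STREAM_HYPNO = 11
_STREAM_EEG = 21
_STREAM_AUTONOMIC = 31
_STREAM_MEMORY = 41
_STREAM_STIMID = 77
_STREAM_TOPO = 91


def _default_transitions() -> dict[str, np.ndarray]:
    # rows/cols ordered W, N1, N2, N3, REM; stationary distributions chosen
    # to emulate an ~88% sleep-efficiency night with ~20% REM / ~8% N1 of
    # sleep under CTR and ~12% REM / ~13% N1 under FRG
    ctr = np.array([
        [0.770, 0.125, 0.085, 0.005, 0.015],
        [0.110, 0.420, 0.380, 0.030, 0.060],
        [0.028, 0.040, 0.830, 0.077, 0.025],
        [0.012, 0.008, 0.165, 0.808, 0.007],
        [0.028, 0.032, 0.030, 0.005, 0.905],
    ])
    frg = ctr.copy()
    # fragmentation: REM less self-continuous, exits mostly into N1;
    # N1 less likely to settle into N2; wake transitions untouched
    frg[4] = [0.028, 0.147, 0.030, 0.005, 0.790]
    frg[1] = [0.110, 0.560, 0.240, 0.030, 0.060]
    return {"CTR": ctr, "FRG": frg}


@dataclass(frozen=True)
class StimProtocolParams:
    n_intensity_steps: int = 7
    stim_on_s: float = 3.0
    stim_off_s: float = 3.0
    suspension_s: float = 40.0
    #: probability that a stimulation at each intensity step elicits an arousal
    arousal_prob: tuple[float, ...] = (0.15, 0.25, 0.35, 0.50, 0.65, 0.80, 0.90)
    #: stimulations accidentally delivered outside REM (per night)
    stray_stims: int = 2


@dataclass(frozen=True)
class BandBurst:
    band: str
    effect_db: float
    duration_s: float
    fmin: float
    fmax: float
    #: per-channel weighting of the dB effect (1.0 = full effect)
    weights: tuple[float, ...]


def _weights(frontal: float, central: float, posterior: float) -> tuple[float, ...]:
    w = []
    for ch in CH_NAMES_19:
        if ch in POSTERIOR_CHANNELS:
            w.append(posterior)
        elif ch in ("T7", "C3", "Cz", "C4", "T8"):
            w.append(central)
        else:
            w.append(frontal)
    return tuple(w)


def _default_bursts() -> tuple[BandBurst, ...]:
    return (
        BandBurst("alpha", 3.0, 6.0, 8.0, 11.8, _weights(0.5, 0.7, 1.0)),
        BandBurst("sigma", 2.5, 6.0, 12.0, 15.8, _weights(1.0, 1.0, 1.0)),
        BandBurst("beta", 2.0, 6.0, 16.0, 29.8, _weights(1.0, 1.0, 1.0)),
        BandBurst("low_gamma", 1.5, 2.0, 30.0, 40.0, _weights(0.3, 0.8, 1.0)),
    )


@dataclass(frozen=True)
class EegParams:
    sfreq: float = 125.0
    montage: str = "standard_1020"
    ch_names: tuple[str, ...] = CH_NAMES_19
    noise_exponent: float = 1.0
    bursts: tuple[BandBurst, ...] = field(default_factory=_default_bursts)
    window_s: tuple[float, float] = (-3.0, 15.0)
    #: between-subject SD of the alpha-burst dB effect
    alpha_subject_sd_db: float = 1.0
    #: topography of the between-subject alpha deviation: the posterior
    #: "wake-like" alpha intrusion is where subjects differ most
    alpha_dev_weights: tuple[float, ...] = field(
        default_factory=lambda: _weights(0.15, 0.4, 1.0))
    #: channel-level noise of a measured band topography (dB), emulating
    #: finite-epoch ERSP estimation error in topography-level simulations
    topo_noise_db: float = 0.5
    max_epochs_per_subject: int = 10


def _default_hrd_amp() -> dict[str, tuple[float, float, float]]:
    # negative-stimulus HRD amplitude (bpm) per session (T0, T1, T2):
    # control habituates after the undisturbed night, fragmentation does not
    return {"CTR": (8.0, 4.5, 4.5), "FRG": (8.0, 8.0, 8.0)}


@dataclass(frozen=True)
class AutonomicParams:
    baseline_hr_bpm: float = 65.0
    hrd_amp_bpm: dict[str, tuple[float, float, float]] = field(default_factory=_default_hrd_amp)
    neutral_scale: float = 0.5
    trial_noise_sd_bpm: float = 2.0
    subject_sd_bpm: float = 1.0
    #: SD of subject-level session-change deviations of HRD (bpm); in the FRG
    #: condition this deviation is the coupling target (shared T1/T2)
    session_dev_sd_bpm: float = 2.0
    stimulus_sd_bpm: float = 0.8
    dip_onset_s: float = 0.5
    dip_duration_s: float = 4.0
    scr_amp_us: dict[str, float] = field(default_factory=lambda: {"negative": 0.35, "neutral": 0.15})
    scr_session_scale: tuple[float, float, float] = (1.0, 0.8, 0.7)
    scr_response_prob: dict[str, float] = field(default_factory=lambda: {"negative": 0.80, "neutral": 0.45})
    nonresponder_prob: float = 0.10
    nonresponder_response_prob: float = 0.10
    scr_latency_s: tuple[float, float] = (1.2, 3.0)
    tau_rise_s: float = 0.75
    tau_decay_s: float = 2.0
    eda_fs: float = 100.0
    eda_noise_us: float = 0.005
    n_negative: int = 14
    n_neutral: int = 14
    trial_duration_s: float = 15.0
    stim_onset_s: float = 5.0


@dataclass(frozen=True)
class MemoryParams:
    dprime: dict[str, float] = field(default_factory=lambda: {"T0": 2.2, "T1": 1.8, "T2": 1.5})
    criterion: float = 0.25
    subject_sd: float = 0.3
    n_old: int = 40
    n_new: int = 40


@dataclass(frozen=True)
class CouplingParams:
    #: planted correlation between subject posterior alpha dB and the
    #: subject's HRD change (T1 - T0) on the fragmentation night
    r: float = 0.7


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 17
    seed: int = 0
    epoch_sec: float = 30.0
    n_epochs: int = 960
    transitions: dict[str, np.ndarray] = field(default_factory=_default_transitions)
    stim: StimProtocolParams = field(default_factory=StimProtocolParams)
    eeg: EegParams = field(default_factory=EegParams)
    autonomic: AutonomicParams = field(default_factory=AutonomicParams)
    memory: MemoryParams = field(default_factory=MemoryParams)
    coupling: CouplingParams = field(default_factory=CouplingParams)
    #: spontaneous event rates (independent of the stimulation protocol)
    spontaneous_arousals_per_h_rem: float = 12.0
    body_movements_per_h_sleep: float = 2.0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.epoch_sec <= 0 or self.n_epochs < 2:
            raise ValueError("invalid epoch grid")
        for cond, P in self.transitions.items():
            P = np.asarray(P, float)
            if P.shape != (5, 5) or np.any(P < 0):
                raise ValueError(f"{cond}: transition matrix must be 5x5 non-negative")
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{cond}: transition rows must sum to 1")
        s = self.stim
        if min(s.stim_on_s, s.stim_off_s, s.suspension_s) <= 0:
            raise ValueError("stimulation durations must be positive")
        if len(s.arousal_prob) != s.n_intensity_steps or not all(
            0 <= p <= 1 for p in s.arousal_prob
        ):
            raise ValueError("arousal_prob must give one probability in [0,1] per step")
        for b in self.eeg.bursts:
            if not math.isfinite(b.effect_db):
                raise ValueError("burst dB effects must be finite")
            if b.duration_s <= 0:
                raise ValueError("burst durations must be positive")
            if b.duration_s > self.eeg.window_s[1]:
                raise ValueError("epoch window shorter than burst duration")
        if self.autonomic.baseline_hr_bpm <= 0:
            raise ValueError("baseline HR must be positive")
        if any(v < 0 for v in self.autonomic.scr_amp_us.values()):
            raise ValueError("SCR driver amplitudes must be non-negative")
        if any(v < 0 for v in self.memory.dprime.values()):
            raise ValueError("d' must be non-negative")
        if not -1 <= self.coupling.r <= 1:
            raise ValueError("coupling r must be in [-1, 1]")


def _rng(config: CohortConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng((int(config.seed),) + tuple(int(k) for k in keys))


# ---------------------------------------------------------------------------
# subject-level latent truth

@dataclass(frozen=True)
class SubjectTruth:
    subject: int
    alpha_dev_db: float          # deviation of the alpha-burst effect (dB)
    delta_hrd_dev_bpm: float     # FRG session-change deviation (coupled)
    ctr_session_dev_bpm: tuple[float, float]   # CTR T1/T2 change deviations
    hr0_bpm: float
    hrd_offset_bpm: float
    scr_scale: float
    nonresponder: bool
    dprime_offset: float

    @property
    def posterior_alpha_db(self) -> float:
        """Planted posterior-channel alpha effect for this subject (dB)."""
        return self.alpha_dev_db   # reported as deviation; base added by callers


def subject_truth(config: CohortConfig, subject: int) -> SubjectTruth:
    """Deterministic subject-level latent parameters (pure in config, subject)."""
    rng = _rng(config, _STREAM_SUBJECT, subject)
    z_alpha = rng.standard_normal()
    eps = rng.standard_normal()
    r = config.coupling.r
    sd_d = config.autonomic.session_dev_sd_bpm
    delta = sd_d * (r * z_alpha + math.sqrt(max(0.0, 1 - r * r)) * eps)
    return SubjectTruth(
        subject=subject,
        alpha_dev_db=config.eeg.alpha_subject_sd_db * z_alpha,
        delta_hrd_dev_bpm=delta,
        ctr_session_dev_bpm=tuple(rng.normal(0.0, sd_d, size=2)),
        hr0_bpm=config.autonomic.baseline_hr_bpm + rng.normal(0.0, 4.0),
        hrd_offset_bpm=rng.normal(0.0, config.autonomic.subject_sd_bpm),
        scr_scale=float(np.exp(rng.normal(0.0, 0.4))),
        nonresponder=bool(rng.random() < config.autonomic.nonresponder_prob),
        dprime_offset=rng.normal(0.0, config.memory.subject_sd),
    )


# ---------------------------------------------------------------------------
# hypnogram + stimulation protocol

def _markov_walk(P: np.ndarray, n: int, rng: np.random.Generator, start: int = 0) -> np.ndarray:
    cdf = np.cumsum(P, axis=1)
    out = np.empty(n, dtype=np.int64)
    out[0] = start
    u = rng.random(n)
    for i in range(1, n):
        out[i] = np.searchsorted(cdf[out[i - 1]], u[i])
    return out


def _rem_runs(stages: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of REM epochs as (start, stop_exclusive)."""
    runs = []
    i = 0
    rem = STAGES.index("REM")
    n = stages.size
    while i < n:
        if stages[i] == rem:
            j = i
            while j < n and stages[j] == rem:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def generate_hypnogram(
    config: CohortConfig, subject: int, condition: str
) -> tuple[Hypnogram, pd.DataFrame]:
    """One night: stage sequence plus the event log of that night.

    The stage sequence is a first-order Markov walk under the condition's
    transition matrix.  On FRG nights the stimulation protocol is played
    inside every REM period: start at minimum intensity at each new REM
    period, escalate one step per non-effective stimulation, suspend 40 s
    after an elicited arousal (keeping the effective intensity), stop when
    the REM period ends (the train's outcome is then a stage shift).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    rng = _rng(config, _STREAM_HYPNO, subject, CONDITIONS.index(condition))
    stages_idx = _markov_walk(
        np.asarray(config.transitions[condition], float), config.n_epochs, rng
    )
    stages = tuple(STAGES[i] for i in stages_idx)
    h = Hypnogram(stages=stages, lights_off_index=0, lights_on_index=config.n_epochs,
                  epoch_sec=config.epoch_sec)

    ev: list[dict] = []
    ep = config.epoch_sec
    rem_code = STAGES.index("REM")

    # spontaneous arousals / body movements
    p_arousal = config.spontaneous_arousals_per_h_rem * ep / 3600.0
    p_move = config.body_movements_per_h_sleep * ep / 3600.0
    for i, code in enumerate(stages_idx):
        if code == rem_code and rng.random() < p_arousal:
            ev.append({"onset_s": i * ep + rng.uniform(0, ep - 3), "duration_s": 3.0,
                       "type": "arousal"})
        if code != 0 and rng.random() < p_move:
            ev.append({"onset_s": i * ep + rng.uniform(0, ep - 2), "duration_s": 2.0,
                       "type": "body_movement"})
    # awakening markers at W-bout starts after the first sleep epoch
    first_sleep = next((i for i, c in enumerate(stages_idx) if c != 0), None)
    if first_sleep is not None:
        for i in range(first_sleep + 1, config.n_epochs):
            if stages_idx[i] == 0 and stages_idx[i - 1] != 0:
                ev.append({"onset_s": i * ep, "duration_s": ep, "type": "awakening"})

    if condition == "FRG":
        s = config.stim
        train = 0
        for a, b in _rem_runs(stages_idx):
            t = a * ep + 1.0
            run_end = b * ep
            intensity = 1
            while t + s.stim_on_s <= run_end:
                aroused = rng.random() < s.arousal_prob[intensity - 1]
                dur = float(rng.uniform(1.0, s.stim_on_s)) if aroused else s.stim_on_s
                if aroused and run_end - (t + dur) <= ep:
                    outcome = "stage_shift"
                else:
                    outcome = "arousal" if aroused else "none"
                ev.append({"onset_s": t, "duration_s": dur, "type": "stim_on",
                           "intensity_step": intensity, "train_id": train,
                           "outcome": outcome, "in_rem": True})
                if aroused:
                    ev.append({"onset_s": t + dur, "duration_s": 3.0, "type": "arousal"})
                    if outcome == "stage_shift":
                        break
                    t += dur + s.suspension_s
                    train += 1          # suspension gap starts a new train
                else:
                    t += s.stim_on_s + s.stim_off_s
                    intensity = min(intensity + 1, s.n_intensity_steps)
            train += 1
        # stray stimulations delivered outside REM (protocol slippage)
        non_rem = np.flatnonzero(stages_idx != rem_code)
        for k in range(s.stray_stims):
            i = int(rng.choice(non_rem))
            ev.append({"onset_s": i * ep + rng.uniform(0, ep - 3), "duration_s": 3.0,
                       "type": "stim_on", "intensity_step": 1,
                       "train_id": train + k + 1, "outcome": "none", "in_rem": False})

    events = pd.DataFrame(ev, columns=["onset_s", "duration_s", "type",
                                       "intensity_step", "train_id", "outcome",
                                       "in_rem"])
    events = events.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return h, events


# ---------------------------------------------------------------------------
# EEG epochs

def one_over_f_noise(
    rng: np.random.Generator, n_ch: int, n_samp: int, sfreq: float, exponent: float = 1.0
) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit-ish variance."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal((n_ch, freqs.size))
                  + 1j * rng.standard_normal((n_ch, freqs.size)))
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    return x / x.std(axis=1, keepdims=True)


@dataclass(frozen=True)
class EegTruth:
    """Planted spectral ground truth for one subject's stimulation epochs."""
    subject: int
    effects_db: dict[str, float]            # band -> planted base dB at weight 1
    alpha_dev_db: float
    weights: dict[str, tuple[float, ...]]
    channel_db: dict[str, np.ndarray]       # band -> planted per-channel dB
    posterior_alpha_db: float               # planted posterior alpha effect incl. deviation


def band_limited_noise(
    rng: np.random.Generator, n_ch: int, n_samp: int, sfreq: float,
    fmin: float, fmax: float,
) -> np.ndarray:
    """Unit-variance Gaussian noise with a flat spectrum on [fmin, fmax]."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / sfreq)
    amp = ((freqs >= fmin) & (freqs <= fmax)).astype(float)
    spec = amp * (rng.standard_normal((n_ch, freqs.size))
                  + 1j * rng.standard_normal((n_ch, freqs.size)))
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _calibrated_burst_variance(
    eeg: EegParams, effects_db: dict[str, np.ndarray], n_samp: int,
    topo_window_s: float = 6.0,
) -> dict[str, np.ndarray]:
    """Per-channel burst variances whose measured band-average ERSP hits the target.

    The Morlet analysis smooths spectra with a Gaussian kernel of width
    sigma_f = f / n_cycles, which attenuates a band-limited burst at its own
    band edges and leaks neighboring bursts in.  This solves, by fixed-point
    iteration over all bursts jointly, for the in-band burst variances V
    such that the expected band-averaged dB (relative to the 1/f
    background, over the band's effective time window) equals the planted
    per-channel effect.
    """
    from .timefreq import cycles_for

    fgrid = np.round(np.arange(5.0, 40.0 + 1e-9, 0.2), 10)
    sigma_f = fgrid / cycles_for(fgrid)
    F = np.fft.rfftfreq(n_samp, 1.0 / eeg.sfreq)
    S_bg = np.zeros_like(F)
    S_bg[1:] = F[1:] ** (-eeg.noise_exponent)
    S_bg /= S_bg.sum()
    # Gaussian smoothing weights: rows = wavelet bins, cols = FFT bins
    K = np.exp(-0.5 * ((F[None, :] - fgrid[:, None]) / sigma_f[:, None]) ** 2)
    G = K @ S_bg                                     # smoothed background

    bursts = eeg.bursts
    band_bins = {}
    burst_shape = []                                 # unit-variance burst spectra, smoothed
    for b in bursts:
        sel = (F >= b.fmin) & (F <= b.fmax)
        band_bins[b.band] = (fgrid >= b.fmin - 1e-9) & (fgrid <= b.fmax + 1e-9)
        shape = np.zeros_like(F)
        shape[sel] = 1.0 / sel.sum()
        burst_shape.append(K @ shape)                # per unit total variance
    # effective fraction of each burst's power inside another band's window
    window = {b.band: min(b.duration_s, topo_window_s) for b in bursts}
    n_ch = len(eeg.ch_names)
    target_r = {b.band: 10.0 ** (effects_db[b.band] / 10.0) - 1.0 for b in bursts}
    V = {b.band: np.maximum(target_r[b.band], 0.0) * S_bg[(F >= b.fmin) & (F <= b.fmax)].sum()
         for b in bursts}
    for _ in range(12):
        for i, b in enumerate(bursts):
            jb = band_bins[b.band]
            w_b = window[b.band]
            # summed burst power at this band's bins during this band's window
            num = np.zeros((n_ch, jb.sum()))
            for k, b2 in enumerate(bursts):
                tfrac = min(window[b2.band], w_b) / w_b
                num += tfrac * V[b2.band][:, None] * burst_shape[k][None, jb]
            measured = 10.0 * np.log10(1.0 + num / G[None, jb]).mean(axis=1)
            r_meas = 10.0 ** (measured / 10.0) - 1.0
            with np.errstate(invalid="ignore", divide="ignore"):
                adj = np.where(r_meas > 1e-12,
                               np.maximum(target_r[b.band], 0.0) / r_meas, 1.0)
            V[b.band] = V[b.band] * np.clip(adj, 0.2, 5.0)
    return V


def generate_eeg_epochs(
    config: CohortConfig, subject: int, n_epochs: int
) -> tuple[np.ndarray, EegTruth]:
    """Stimulation-locked EEG epochs with planted post-stimulus band bursts.

    Each epoch spans the analysis window (default -3..+15 s at 125 Hz):
    independent 1/f background per channel, plus, from t=0, band-limited
    noise bursts scaled so the added in-band power lifts the band by the
    configured dB effect (times the channel's topographic weight; the alpha
    effect additionally carries the subject's latent deviation).  Burst
    spectra are flat and extend slightly past the measurement band so the
    band-averaged ERSP recovers the planted dB without edge attenuation.
    """
    eeg = config.eeg
    rng = _rng(config, _STREAM_EEG, subject)
    truth_sub = subject_truth(config, subject)
    n_ch = len(eeg.ch_names)
    n_samp = int(round((eeg.window_s[1] - eeg.window_s[0]) * eeg.sfreq)) + 1
    t = eeg.window_s[0] + np.arange(n_samp) / eeg.sfreq
    post0 = np.searchsorted(t, 0.0)

    effects = {}
    weights = {}
    effects_db_ch = {}
    for b in eeg.bursts:
        effects[b.band] = b.effect_db
        weights[b.band] = b.weights
        db_ch = b.effect_db * np.asarray(b.weights)
        if b.band == "alpha":
            db_ch = db_ch + truth_sub.alpha_dev_db * np.asarray(eeg.alpha_dev_weights)
        effects_db_ch[b.band] = db_ch
    V = _calibrated_burst_variance(eeg, effects_db_ch, n_samp)

    epochs = np.empty((n_epochs, n_ch, n_samp))
    for e in range(n_epochs):
        x = one_over_f_noise(rng, n_ch, n_samp, eeg.sfreq, eeg.noise_exponent)
        for b in eeg.bursts:
            n_burst = int(round(b.duration_s * eeg.sfreq))
            sl = slice(post0, post0 + n_burst)
            burst = band_limited_noise(rng, n_ch, n_samp, eeg.sfreq, b.fmin, b.fmax)
            env = np.zeros(n_samp)
            env[sl] = sp_signal.windows.tukey(n_burst, alpha=0.05)
            x += np.sqrt(V[b.band])[:, None] * burst * env[None, :]
        epochs[e] = x

    post_idx = [i for i, ch in enumerate(eeg.ch_names) if ch in POSTERIOR_CHANNELS]
    truth = EegTruth(
        subject=subject, effects_db=effects, alpha_dev_db=truth_sub.alpha_dev_db,
        weights=weights, channel_db=effects_db_ch,
        posterior_alpha_db=float(np.mean(effects_db_ch["alpha"][post_idx]))
        if "alpha" in effects_db_ch else 0.0,
    )
    return epochs, truth


def generate_continuous_eeg(
    config: CohortConfig, duration_s: float, subject: int = 0, key: int = 0
) -> np.ndarray:
    """Continuous multichannel 1/f background (uV-scale), for epoching/EDF tests."""
    eeg = config.eeg
    rng = _rng(config, _STREAM_EEG, subject, 999, key)
    n = int(round(duration_s * eeg.sfreq))
    return 20.0 * one_over_f_noise(rng, len(eeg.ch_names), n, eeg.sfreq,
                                   eeg.noise_exponent)


# ---------------------------------------------------------------------------
# autonomic trials

def _hrd_amplitude(config, truth: SubjectTruth, condition, session, stimulus_type,
                   stim_dev: float, rng) -> float:
    a = config.autonomic
    amp = a.hrd_amp_bpm[condition][SESSIONS.index(session)]
    if stimulus_type == "neutral":
        amp *= a.neutral_scale
    amp += truth.hrd_offset_bpm + stim_dev
    if session != "T0":
        if condition == "FRG":
            amp += truth.delta_hrd_dev_bpm
        else:
            amp += truth.ctr_session_dev_bpm[SESSIONS.index(session) - 1]
    return amp + rng.normal(0.0, a.trial_noise_sd_bpm)


def stimulus_effects(config: CohortConfig, condition: str) -> np.ndarray:
    """Planted per-stimulus HRD offsets (bpm), shared by all subjects."""
    a = config.autonomic
    rng = _rng(config, _STREAM_STIMID, CONDITIONS.index(condition))
    return rng.normal(0.0, a.stimulus_sd_bpm, size=a.n_negative + a.n_neutral)


def generate_autonomic_trials(
    config: CohortConfig, subject: int, condition: str, session: str
) -> list[TrialPhysio]:
    """One emotional-reactivity session: 28 trials of IBI + EDA around onset.

    Heart rate dips as a raised cosine starting 0.5 s after stimulus onset
    (peak depth = the planted HRD amplitude); skin conductance carries a
    Bateman-shaped response at 1.2-3 s latency whose peak amplitude depends
    on stimulus type, session and the subject's responder status.
    """
    if condition not in CONDITIONS or session not in SESSIONS:
        raise ValueError("invalid condition or session label")
    a = config.autonomic
    rng = _rng(config, _STREAM_AUTONOMIC, subject, CONDITIONS.index(condition),
               SESSIONS.index(session))
    truth = subject_truth(config, subject)
    stim_dev = stimulus_effects(config, condition)
    peak = _bateman_peak(a.tau_rise_s, a.tau_decay_s)

    trials = []
    types = ["negative"] * a.n_negative + ["neutral"] * a.n_neutral
    for k, stype in enumerate(types):
        amp = _hrd_amplitude(config, truth, condition, session, stype, stim_dev[k], rng)
        t0 = a.stim_onset_s

        # beats: integrate instantaneous HR with the planted deceleration dip
        def hr_at(tt):
            d = 0.0
            if a.dip_onset_s <= tt - t0 <= a.dip_onset_s + a.dip_duration_s:
                phase = (tt - t0 - a.dip_onset_s) / a.dip_duration_s
                d = amp * 0.5 * (1 - math.cos(2 * math.pi * phase))
            return max(truth.hr0_bpm - d, 20.0)

        beats = [0.0]
        while beats[-1] < a.trial_duration_s:
            beats.append(beats[-1] + 60.0 / hr_at(beats[-1]))
        bt = np.array(beats[1:]) * 1000.0
        ibi = np.diff(np.array(beats)) * 1000.0

        # EDA: tonic level + drift + Bateman SCR + noise
        n = int(round(a.trial_duration_s * a.eda_fs))
        tt = np.arange(n) / a.eda_fs
        tonic = 2.0 + 0.3 * truth.scr_scale + 0.01 * np.sin(2 * np.pi * tt / 60.0)
        eda = tonic + rng.normal(0.0, a.eda_noise_us, size=n)
        p_resp = a.scr_response_prob[stype]
        if truth.nonresponder and stype == "negative":
            p_resp = a.nonresponder_response_prob
        if rng.random() < p_resp:
            sess_scale = a.scr_session_scale[SESSIONS.index(session)]
            amp_scr = (a.scr_amp_us[stype] * sess_scale * truth.scr_scale
                       * float(np.exp(rng.normal(0.0, 0.3))))
            lat = rng.uniform(*a.scr_latency_s)
            mass = amp_scr / peak
            eda += mass * bateman(tt - t0 - lat, a.tau_rise_s, a.tau_decay_s)
        trials.append(TrialPhysio(
            beat_times_ms=bt, ibi_ms=ibi, eda=eda, eda_fs=a.eda_fs,
            stim_onset_s=t0, stimulus_type=stype, session=session,
            condition=condition,
        ))
    return trials


def _bateman_peak(tau_rise: float, tau_decay: float) -> float:
    tpk = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    return float(bateman(np.array([tpk]), tau_rise, tau_decay)[0])


def planted_hrd_mean(config: CohortConfig, condition: str, session: str,
                     stimulus_type: str) -> float:
    """Planted population-mean HRD of one condition x session x type cell (bpm)."""
    a = config.autonomic
    amp = a.hrd_amp_bpm[condition][SESSIONS.index(session)]
    if stimulus_type == "neutral":
        amp *= a.neutral_scale
    return amp


def generate_hrd_trial_table(config: CohortConfig) -> pd.DataFrame:
    """Trial-level HRD values of the whole cohort from the planted linear model.

    Skips the beat-series biophysics and draws each trial's HRD directly
    from the planted amplitude model (condition x session x stimulus-type
    cell mean + subject offset + stimulus offset + session deviation +
    trial noise): the fast path for operating-characteristic studies of the
    mixed-model stage.
    """
    a = config.autonomic
    rows = []
    for s in range(config.n_subjects):
        truth = subject_truth(config, s)
        for cond in CONDITIONS:
            stim_dev = stimulus_effects(config, cond)
            for sess in SESSIONS:
                rng = _rng(config, _STREAM_AUTONOMIC, s, CONDITIONS.index(cond),
                           SESSIONS.index(sess), 5)
                types = ["negative"] * a.n_negative + ["neutral"] * a.n_neutral
                for k, stype in enumerate(types):
                    hrd = _hrd_amplitude(config, truth, cond, sess, stype,
                                         stim_dev[k], rng)
                    rows.append({
                        "subject": s, "condition": cond, "session": sess,
                        "stimulus_type": stype, "stimulus_id": f"{cond}_{k}",
                        "hrd": hrd,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recognition memory

def generate_recognition(
    config: CohortConfig, subject: int, condition: str, session: str
) -> pd.DataFrame:
    """Old/new responses from an equal-variance signal-detection model."""
    if condition not in CONDITIONS or session not in SESSIONS:
        raise ValueError("invalid condition or session label")
    m = config.memory
    rng = _rng(config, _STREAM_MEMORY, subject, CONDITIONS.index(condition),
               SESSIONS.index(session))
    truth = subject_truth(config, subject)
    d = max(m.dprime[session] + truth.dprime_offset, 0.0)
    c = m.criterion
    rows = []
    half_old, half_new = m.n_old // 2, m.n_new // 2
    for k in range(m.n_old + m.n_new):
        old = k < m.n_old
        stype = "negative" if (k % (m.n_old if old else m.n_new)) < (
            half_old if old else half_new) else "neutral"
        evidence = rng.normal(d if old else 0.0, 1.0)
        rows.append({
            "trial": k, "truth": "OLD" if old else "NEW",
            "response": "OLD" if evidence > c else "NEW",
            "stimulus_type": stype, "session": session, "condition": condition,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# topography-level cohort (fast analogue of the EEG stage)

def generate_band_topography_cohort(
    config: CohortConfig, band: str = "alpha", effect_db: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-level band topographies plus measured HRD changes.

    Emulates the output of the ERSP/band-topography stage directly at the
    subject level: planted per-channel dB (band effect x topographic weight,
    alpha carrying the subject deviation) plus channel-level measurement
    noise, paired with each subject's measured FRG HRD change
    (T1 - T0, session deviation plus 28-trial averaging noise).  Used for
    calibration and operating-characteristic studies of the cluster tests.

    Returns (maps (n_subjects, n_channels), delta_hrd (n_subjects,)).
    """
    eeg = config.eeg
    burst = next(b for b in eeg.bursts if b.band == band)
    base = burst.effect_db if effect_db is None else effect_db
    w = np.asarray(burst.weights)
    n_ch = len(eeg.ch_names)
    a = config.autonomic
    maps = np.empty((config.n_subjects, n_ch))
    delta = np.empty(config.n_subjects)
    w_dev = np.asarray(eeg.alpha_dev_weights)
    for s in range(config.n_subjects):
        truth = subject_truth(config, s)
        rng = _rng(config, _STREAM_TOPO, s)
        dev = truth.alpha_dev_db if band == "alpha" else 0.0
        maps[s] = base * w + dev * w_dev + rng.normal(0.0, eeg.topo_noise_db, size=n_ch)
        trial_se = a.trial_noise_sd_bpm * math.sqrt(2.0 / (a.n_negative + a.n_neutral))
        delta[s] = truth.delta_hrd_dev_bpm + (
            a.hrd_amp_bpm["FRG"][1] - a.hrd_amp_bpm["FRG"][0]
        ) + rng.normal(0.0, trial_se)
    return maps, delta


# ---------------------------------------------------------------------------
# cohort writer

def write_cohort(config: CohortConfig, outdir) -> None:
    """Write the cohort to disk: hypnograms, event logs, trial and response tables."""
    from pathlib import Path

    from . import io as rio
    from .autonomic import trial_metrics

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pos = rio.montage_positions(config.eeg.ch_names, config.eeg.montage)
    rio.write_montage_tsv(out / "montage.tsv", config.eeg.ch_names, pos)
    cfg = {"n_subjects": config.n_subjects, "seed": config.seed,
           "epoch_sec": config.epoch_sec, "n_epochs": config.n_epochs}
    rio.write_json(cfg, out / "config.json")
    trial_rows, memory_rows = [], []
    for s in range(config.n_subjects):
        for cond in CONDITIONS:
            h, ev = generate_hypnogram(config, s, cond)
            rio.write_hypnogram_tsv(h, out / f"sub{s:02d}_{cond}_hypnogram.tsv")
            rio.write_events_tsv(ev, out / f"sub{s:02d}_{cond}_events.tsv")
            for sess in SESSIONS:
                tm = trial_metrics(generate_autonomic_trials(config, s, cond, sess))
                tm.insert(0, "subject", s)
                trial_rows.append(tm)
                mem = generate_recognition(config, s, cond, sess)
                mem.insert(0, "subject", s)
                memory_rows.append(mem)
    pd.concat(trial_rows, ignore_index=True).to_csv(
        out / "autonomic_trials.tsv", sep="\t", index=False)
    pd.concat(memory_rows, ignore_index=True).to_csv(
        out / "recognition.tsv", sep="\t", index=False)
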