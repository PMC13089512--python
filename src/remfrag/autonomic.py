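"""Trial-level autonomic reactivity: cardiac deceleration and electrodermal response.

The cardiac side works on inter-beat intervals (IBIs, ms): distribution-based
artifact detection with cubic-spline correction, the heart-rate deceleration
(HRD) orienting response (pre-stimulus mean HR minus post-stimulus minimum
HR, in bpm, positive = deceleration), and basic time-domain resting HRV.

The electrodermal side filters the skin-conductance trace (10 Hz
down-sampling, 1 Hz second-order low-pass Butterworth, 1-s Gaussian
smoothing) and recovers phasic driver activity by regularized non-negative
deconvolution with a Bateman impulse response; CDA.SCR is the mean driver in
the 1-6 s response window and a trial counts as a response when the
reconstructed phasic amplitude reaches 0.05 uS in that window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.optimize import nnls

#: SCR amplitude threshold (uS) within the response window
SCR_THRESHOLD_US = 0.05
#: SCR response window, seconds after stimulus onset
SCR_WINDOW = (1.0, 6.0)
#: HRD windows, seconds relative to stimulus onset
HRD_PRE_WINDOW = (-2.0, 0.0)
HRD_POST_WINDOW = (0.0, 6.0)


class IbiRejectError(ValueError):
    """Raised when more than half of a record's beats are flagged as artifacts."""


@dataclass(frozen=True)
class TrialPhysio:
    """Per-trial physiology: beat series, EDA trace and stimulus metadata.

    ``beat_times_ms`` are beat timestamps relative to the trace start;
    ``ibi_ms[i]`` is the interval ending at ``beat_times_ms[i]``.
    """

    beat_times_ms: np.ndarray
    ibi_ms: np.ndarray
    eda: np.ndarray | None
    eda_fs: float | None
    stim_onset_s: float
    stimulus_type: str = "neutral"
    session: str = "T0"
    condition: str = "CTR"

    def __post_init__(self):
        object.__setattr__(self, "beat_times_ms", np.asarray(self.beat_times_ms, float))
        object.__setattr__(self, "ibi_ms", np.asarray(self.ibi_ms, float))
        if self.beat_times_ms.shape != self.ibi_ms.shape:
            raise ValueError("beat_times_ms and ibi_ms must align")
        if np.any(self.ibi_ms <= 0):
            raise ValueError("IBIs must be positive")
        if self.eda is not None:
            object.__setattr__(self, "eda", np.asarray(self.eda, float))
            if not np.all(np.isfinite(self.eda)):
                raise ValueError("EDA trace must be finite")


@dataclass(frozen=True)
class IbiCorrection:
    corrected_ms: np.ndarray
    flagged: np.ndarray            # indices of replaced beats
    criterion_ms: float


def ibi_artifact_criterion(ibi_ms: np.ndarray) -> float:
    """Distribution-based artifact criterion (ms) for an IBI series.

    Built from robust spread estimates: the quartile deviation QD of the
    successive IBI differences gives a maximum expected difference
    (3.32 * QD), blended with a minimal-artifact bound derived from the
    median IBI ((median - 2.9 * QD) / 3).
    """
    ibi = np.asarray(ibi_ms, float)
    d = np.diff(ibi)
    qd = (np.percentile(d, 75) - np.percentile(d, 25)) / 2.0 if d.size else 0.0
    med = np.median(ibi)
    mxd = 3.32 * qd
    mad = max((med - 2.9 * qd) / 3.0, 0.0)
    return (mxd + mad) / 2.0


def correct_ibi(
    ibi_ms: np.ndarray, window: int = 5, max_flagged_fraction: float = 0.5
) -> IbiCorrection:
    """Flag artifactual IBIs against a rolling median and spline-interpolate them.

    A beat is flagged when its IBI deviates from the local (window-size 5)
    median by more than the distribution-based criterion; flagged values are
    replaced by a cubic spline through the unflagged beats.  Records with
    more than ``max_flagged_fraction`` flagged beats are rejected.
    """
    ibi = np.asarray(ibi_ms, float)
    if ibi.size < 4:
        raise ValueError("need at least 4 beats")
    crit = ibi_artifact_criterion(ibi)
    local = pd.Series(ibi).rolling(window, center=True, min_periods=1).median().to_numpy()
    flagged = np.flatnonzero(np.abs(ibi - local) > crit)
    if flagged.size > max_flagged_fraction * ibi.size:
        raise IbiRejectError(
            f"{flagged.size}/{ibi.size} beats flagged (criterion {crit:.1f} ms)"
        )
    corrected = ibi.copy()
    if flagged.size:
        good = np.setdiff1d(np.arange(ibi.size), flagged)
        spl = CubicSpline(good, ibi[good])
        corrected[flagged] = spl(flagged)
    return IbiCorrection(corrected_ms=corrected, flagged=flagged, criterion_ms=crit)


def instantaneous_hr(
    beat_times_ms: np.ndarray, ibi_ms: np.ndarray, grid_s: np.ndarray
) -> np.ndarray:
    """Instantaneous HR (bpm = 60000/IBI) linearly interpolated onto ``grid_s``."""
    t = np.asarray(beat_times_ms, float) / 1000.0
    hr = 60000.0 / np.asarray(ibi_ms, float)
    return np.interp(np.asarray(grid_s, float), t, hr)


def hrd(trial: TrialPhysio, grid_hz: float = 10.0) -> float:
    """Heart-rate deceleration: pre-stimulus mean HR minus post-stimulus minimum HR.

    The beat-wise HR series is resampled to a uniform ``grid_hz`` grid; HRD =
    mean HR in the 2 s before onset minus the minimum HR within 6 s after
    onset.  Positive values indicate deceleration.
    """
    t0 = trial.stim_onset_s
    beats_s = trial.beat_times_ms / 1000.0
    if beats_s.min() > t0 + HRD_PRE_WINDOW[0] or beats_s.max() < t0 + HRD_POST_WINDOW[1]:
        raise ValueError("beats do not cover the -2 s .. +6 s HRD window")
    step = 1.0 / grid_hz
    pre_grid = t0 + np.arange(HRD_PRE_WINDOW[0], HRD_PRE_WINDOW[1], step)
    post_grid = t0 + np.arange(HRD_POST_WINDOW[0] + step, HRD_POST_WINDOW[1] + step / 2, step)
    pre = instantaneous_hr(trial.beat_times_ms, trial.ibi_ms, pre_grid)
    post = instantaneous_hr(trial.beat_times_ms, trial.ibi_ms, post_grid)
    return float(pre.mean() - post.min())


def preprocess_eda(trace: np.ndarray, fs: float, fs_out: float = 10.0) -> np.ndarray:
    """Standard skin-conductance pre-processing chain.

    Anti-aliased down-sampling to 10 Hz, zero-phase second-order low-pass
    Butterworth at 1 Hz, then smoothing with a normalized Gaussian window of
    10 samples (1 s).  A constant trace passes through unchanged.
    """
    x = np.asarray(trace, float)
    if fs < fs_out:
        raise ValueError(f"sampling rate {fs} Hz below target {fs_out} Hz")
    factor = fs / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("sampling rate must be an integer multiple of 10 Hz")
    factor = int(round(factor))
    if factor > 1:
        if x.size < 3 * 2 * 5:
            raise ValueError("trace shorter than decimation filter warm-up")
        b, a = signal.butter(4, 0.8 / factor)
        x = signal.filtfilt(b, a, x)[::factor]
    b, a = signal.butter(2, 1.0 / (fs_out / 2.0))
    if x.size <= 3 * max(len(a), len(b)):
        raise ValueError("trace shorter than filter warm-up")
    x = signal.filtfilt(b, a, x)
    win = signal.windows.gaussian(10, std=10 / 6.0)
    win /= win.sum()
    pad = np.r_[x[9::-1], x, x[:-11:-1]]
    x = np.convolve(pad, win, mode="same")[10:-10]
    return x


def bateman(t: np.ndarray, tau_rise: float = 0.75, tau_decay: float = 2.0) -> np.ndarray:
    """Bateman impulse response, normalized to unit area (1 uS*s driver -> 1 uS*s SC)."""
    t = np.asarray(t, float)
    h = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau_decay)
                 - np.exp(-np.clip(t, 0, None) / tau_rise), 0.0)
    return h / (tau_decay - tau_rise)


@dataclass(frozen=True)
class CdaScr:
    """Continuous-decomposition SCR summary for one trial."""
    value: float                   # mean phasic driver in the response window, uS/s
    responded: bool                # reconstructed SCR amplitude >= 0.05 uS in window
    driver: np.ndarray = field(repr=False, default=None)
    driver_times_s: np.ndarray = field(repr=False, default=None)


def cda_scr(
    trial: TrialPhysio,
    tau_rise: float = 0.75,
    tau_decay: float = 2.0,
    ridge: float = 0.01,
) -> CdaScr:
    """Mean phasic driver activity in the 1-6 s post-stimulus response window.

    The pre-processed skin-conductance segment from stimulus onset to +6 s
    (tonic level removed as the segment minimum) is deconvolved with the
    Bateman kernel under a non-negativity constraint and an L2 (ridge)
    penalty.  The driver is a rate in uS/s; its mean over the 5-s response
    window equals planted driver mass / 5 for an isolated SCR.
    """
    if trial.eda is None or trial.eda_fs is None:
        raise ValueError("trial carries no EDA trace")
    fs = float(trial.eda_fs)
    t = np.arange(trial.eda.size) / fs
    t0 = trial.stim_onset_s
    sel = (t >= t0) & (t <= t0 + SCR_WINDOW[1] + 1e-9)
    if sel.sum() < 2 or t[sel][-1] < t0 + SCR_WINDOW[1] - 1.0 / fs - 1e-9:
        raise ValueError("EDA trace does not cover onset .. onset+6 s")
    y = trial.eda[sel]
    y = y - y.min()                     # remove tonic level
    ts = t[sel] - t0                    # 0 .. 6 s
    dt = 1.0 / fs
    n = ts.size
    # causal convolution matrix: driver bins share the data grid
    A = bateman(ts[:, None] - ts[None, :], tau_rise, tau_decay) * dt
    aug = np.vstack([A, np.sqrt(ridge) * np.eye(n)])
    rhs = np.r_[y, np.zeros(n)]
    d, _ = nnls(aug, rhs)
    recon = A @ d
    win = (ts > SCR_WINDOW[0]) & (ts <= SCR_WINDOW[1])
    value = float(d[win].sum() * dt / (SCR_WINDOW[1] - SCR_WINDOW[0]))
    responded = bool(recon[win].max(initial=0.0) >= SCR_THRESHOLD_US)
    return CdaScr(value=value, responded=responded, driver=d, driver_times_s=ts)


def screen_nonresponders(
    trials: pd.DataFrame, min_fraction: float = 0.20
) -> pd.DataFrame:
    """Flag subjects responding to fewer than 20% of negative baseline stimuli.

    ``trials`` must carry columns subject, condition, session, stimulus_type
    and responded.  A subject is excluded from EDA analyses when the
    responded fraction among negative T0 trials falls below ``min_fraction``
    in either condition.
    """
    t0 = trials[(trials["session"] == "T0") & (trials["stimulus_type"] == "negative")]
    if t0.empty:
        raise ValueError("no negative T0 trials present")
    frac = (
        t0.groupby(["subject", "condition"])["responded"].mean().unstack("condition")
    )
    if frac.isna().any().any():
        missing = frac[frac.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing a T0 condition for subjects {missing}")
    out = frac.copy()
    out.columns = [f"frac_{c}" for c in frac.columns]
    out["keep"] = (frac >= min_fraction).all(axis=1)
    return out.reset_index()


def resting_hrv(ibi_ms: np.ndarray, min_duration_s: float = 120.0) -> dict[str, float]:
    """Basic time-domain HRV indices of a resting IBI segment.

    SDNN: standard deviation of IBIs (ms); RMSSD: root-mean-square of
    successive differences (ms); mean_hr: 60000 / mean IBI (bpm).
    """
    ibi = np.asarray(ibi_ms, float)
    if ibi.sum() < min_duration_s * 1000.0:
        raise ValueError(f"segment shorter than {min_duration_s} s of corrected IBIs")
    d = np.diff(ibi)
    return {
        "SDNN": float(ibi.std(ddof=1)),
        "RMSSD": float(np.sqrt(np.mean(d**2))),
        "mean_hr": float(60000.0 / ibi.mean()),
    }


def trial_metrics(trials: list[TrialPhysio], **cda_kwargs) -> pd.DataFrame:
    """HRD and CDA.SCR for a list of trials as a tidy table.

    EDA traces are passed through the standard pre-processing chain (10-Hz
    down-sampling, low-pass, smoothing) before deconvolution.
    """
    rows = []
    for k, tr in enumerate(trials):
        row = {
            "trial": k, "condition": tr.condition, "session": tr.session,
            "stimulus_type": tr.stimulus_type,
        }
        try:
            row["hrd"] = hrd(tr)
        except ValueError:
            row["hrd"] = np.nan
        if tr.eda is not None:
            if tr.eda_fs != 10.0:
                tr = replace(tr, eda=preprocess_eda(tr.eda, tr.eda_fs), eda_fs=10.0)
            scr = cda_scr(tr, **cda_kwargs)
            row["cda_scr"] = scr.value
            row["responded"] = scr.responded
        rows.append(row)
    return pd.DataFrame(rows)
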