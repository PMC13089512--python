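"""Morlet-wavelet ERSP with decibel baseline correction and band topographies.

Event-related spectral perturbation (ERSP) of stimulation-locked epochs:
complex Morlet convolution over 5-40 Hz in 0.2-Hz steps at a 16-ms time
step, wavelet cycles increasing linearly from 7 (5 Hz) to 42 (40 Hz) to
favor frequency precision.  Power is averaged across epochs per channel,
then divided by the mean power of the -2000..-1000 ms pre-stimulus window
at the same frequency and converted to dB (10*log10).  Time points whose
wavelet support spills over the epoch edge are marked invalid (NaN) and
excluded from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from mne.time_frequency import tfr_array_morlet

FMIN, FMAX, FSTEP = 5.0, 40.0, 0.2
CYCLES_MIN, CYCLES_MAX = 7.0, 42.0
TIME_STEP_MS = 16.0
BASELINE_WINDOW_MS = (-2000.0, -1000.0)
POST_WINDOW_MS = (0.0, 6000.0)

#: frequency bands (Hz, inclusive bounds on the 0.2-Hz grid)
BANDS: dict[str, tuple[float, float]] = {
    "theta": (5.0, 7.8),
    "alpha": (8.0, 11.8),
    "sigma": (12.0, 15.8),
    "beta": (16.0, 29.8),
    "low_gamma": (30.0, 40.0),
}


def default_freqs() -> np.ndarray:
    return np.round(np.arange(FMIN, FMAX + FSTEP / 2, FSTEP), 10)


def cycles_for(freqs: np.ndarray) -> np.ndarray:
    """Wavelet cycle counts, linear in frequency from 7 at 5 Hz to 42 at 40 Hz."""
    f = np.asarray(freqs, float)
    return CYCLES_MIN + (f - FMIN) * (CYCLES_MAX - CYCLES_MIN) / (FMAX - FMIN)


@dataclass(frozen=True)
class ErspResult:
    """Channel x frequency x time spectral power, linear or dB.

    ``values`` carries NaN at edge-invalid time points (wavelet support
    exceeding the epoch) and, after baseline correction, at
    channel-frequency rows whose baseline power was zero.
    """

    values: np.ndarray          # (n_ch, n_freq, n_time)
    freqs: np.ndarray           # Hz
    times_ms: np.ndarray
    ch_names: tuple[str, ...]
    kind: str = "power"         # "power" (linear) or "db"
    baseline_window_ms: tuple[float, float] | None = None
    n_epochs: int = 0

    def __post_init__(self):
        if self.values.shape != (len(self.ch_names), self.freqs.size, self.times_ms.size):
            raise ValueError("values shape does not match axes")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        return (self.times_ms >= lo - 1e-9) & (self.times_ms <= hi + 1e-9)

    def freq_mask(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.freqs >= lo - 1e-6) & (self.freqs <= hi + 1e-6)


@dataclass(frozen=True)
class BandTopography:
    """Per-channel mean dB of one band over a post-stimulus window."""

    band: str
    window_ms: tuple[float, float]
    values: np.ndarray          # (n_ch,)
    ch_names: tuple[str, ...]


def morlet_ersp(
    epochs: np.ndarray,
    sfreq: float,
    tmin_ms: float = -3000.0,
    freqs: np.ndarray | None = None,
    mask_edges: bool = True,
) -> ErspResult:
    """Epoch-averaged Morlet-wavelet power on the canonical 5-40 Hz grid.

    Parameters
    ----------
    epochs
        Array (n_epochs, n_channels, n_times) of stimulation-locked EEG.
    sfreq
        Sampling rate in Hz; must exceed twice the highest analysis
        frequency and yield an integer decimation to the 16-ms step.
    tmin_ms
        Time of the first sample relative to stimulation onset.
    """
    epochs = np.atleast_3d(np.asarray(epochs, float))
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("epochs must be (n_epochs, n_channels, n_times)")
    if freqs is None:
        freqs = default_freqs()
    if sfreq <= 2 * freqs[-1]:
        raise ValueError(f"sampling rate {sfreq} Hz violates Nyquist for {freqs[-1]} Hz")
    decim = sfreq * TIME_STEP_MS / 1000.0
    if abs(decim - round(decim)) > 1e-9:
        raise ValueError(f"sampling rate {sfreq} Hz has no integer 16-ms decimation")
    decim = int(round(decim))
    n_cycles = cycles_for(freqs)
    power = tfr_array_morlet(
        epochs, sfreq, freqs, n_cycles=n_cycles, output="avg_power",
        decim=decim, verbose="error",
    )
    n_times_in = epochs.shape[2]
    times_ms = tmin_ms + np.arange(0, n_times_in, decim) * 1000.0 / sfreq
    if mask_edges:
        # wavelet length in mne is 5 sigma_t on each side, sigma_t = n_cycles/(2 pi f)
        half_support_ms = 5.0 * n_cycles / (2.0 * np.pi * freqs) * 1000.0
        tmax_ms = tmin_ms + (n_times_in - 1) * 1000.0 / sfreq
        bad = (times_ms[None, :] < tmin_ms + half_support_ms[:, None]) | (
            times_ms[None, :] > tmax_ms - half_support_ms[:, None]
        )
        power = power.copy()
        power[:, bad] = np.nan
    ch_names = tuple(f"ch{i}" for i in range(epochs.shape[1]))
    return ErspResult(
        values=power, freqs=np.asarray(freqs, float), times_ms=times_ms,
        ch_names=ch_names, kind="power", n_epochs=epochs.shape[0],
    )


def baseline_db(
    ersp: ErspResult, baseline_window_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> ErspResult:
    """Convert epoch-averaged power to dB relative to the pre-stimulus baseline.

    value(c, f, t) = 10 * log10(power(c, f, t) / mean baseline power(c, f)),
    the baseline mean taken over valid time bins of the window.  A zero (or
    all-invalid) baseline flags the whole channel-frequency row as NaN.
    """
    if ersp.kind != "power":
        raise ValueError("baseline_db expects linear power input")
    tmask = ersp.time_mask(baseline_window_ms)
    if not tmask.any():
        raise ValueError("baseline window outside the time grid")
    with np.errstate(invalid="ignore"):
        base = np.nanmean(ersp.values[:, :, tmask], axis=2)  # (n_ch, n_freq)
    bad = ~np.isfinite(base) | (base <= 0)
    base = np.where(bad, np.nan, base)
    with np.errstate(invalid="ignore", divide="ignore"):
        db = 10.0 * np.log10(ersp.values / base[:, :, None])
    return replace(
        ersp, values=db, kind="db", baseline_window_ms=tuple(baseline_window_ms)
    )


def band_topography(
    ersp_db: ErspResult,
    band: str,
    window_ms: tuple[float, float] = POST_WINDOW_MS,
    ch_names: tuple[str, ...] | None = None,
) -> BandTopography:
    """Mean dB per channel within one frequency band and time window."""
    if ersp_db.kind != "db":
        raise ValueError("band_topography expects baseline-corrected dB input")
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; choose from {sorted(BANDS)}")
    fmask = ersp_db.freq_mask(BANDS[band])
    tmask = ersp_db.time_mask(window_ms)
    if not fmask.any() or not tmask.any():
        raise ValueError("band/window does not intersect the grid")
    sub = ersp_db.values[:, fmask][:, :, tmask]
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(sub, axis=(1, 2))
    return BandTopography(
        band=band, window_ms=tuple(window_ms), values=vals,
        ch_names=ch_names or ersp_db.ch_names,
    )


def band_topographies(
    ersp_db: ErspResult, window_ms: tuple[float, float] = POST_WINDOW_MS,
    ch_names: tuple[str, ...] | None = None,
) -> dict[str, BandTopography]:
    """All five canonical band topographies of one dB ERSP."""
    return {b: band_topography(ersp_db, b, window_ms, ch_names) for b in BANDS}
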