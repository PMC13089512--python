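"""Sleep macrostructure, REM fragmentation and stage-transition statistics.

Operates on manually staged hypnograms: one label per 30-s epoch from the
five-stage AASM alphabet (W, N1, N2, N3, REM), bracketed by lights-off
("ready to sleep") and lights-on (final awakening) markers.  All durations
are reported in minutes, the REM fragmentation index in events per hour of
REM sleep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")
STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}
#: sleep-onset stages per the SOL definition (first N1 or N2 epoch)
SLEEP_ONSET_STAGES = ("N1", "N2")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")

EPOCH_SEC_DEFAULT = 30.0

#: event-log types understood by this module
EVENT_TYPES = ("stim_on", "stim_off", "arousal", "body_movement", "awakening")


@dataclass(frozen=True)
class Hypnogram:
    """An ordered sequence of 30-s sleep-stage labels with bed markers.

    Parameters
    ----------
    stages
        One label per epoch, each in ``{"W","N1","N2","N3","REM"}``.
    lights_off_index
        Epoch index at which the participant signalled readiness to sleep.
    lights_on_index
        Epoch index of the final awakening (exclusive end of the
        time-in-bed window).  Defaults to the record length.
    epoch_sec
        Epoch duration in seconds (AASM standard 30 s).
    """

    stages: tuple[str, ...]
    lights_off_index: int = 0
    lights_on_index: int | None = None
    epoch_sec: float = EPOCH_SEC_DEFAULT

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        if self.lights_on_index is None:
            object.__setattr__(self, "lights_on_index", len(self.stages))
        bad = sorted({s for s in self.stages} - set(STAGES))
        if bad:
            raise ValueError(f"unknown stage labels: {bad}")
        if not (0 <= self.lights_off_index < self.lights_on_index <= len(self.stages)):
            raise ValueError(
                "require 0 <= lights_off_index < lights_on_index <= n_epochs, got "
                f"{self.lights_off_index}, {self.lights_on_index}, {len(self.stages)}"
            )
        if self.epoch_sec <= 0:
            raise ValueError("epoch_sec must be positive")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def in_bed(self) -> tuple[str, ...]:
        """Stages within the lights-off .. lights-on window."""
        return self.stages[self.lights_off_index : self.lights_on_index]

    def codes(self) -> np.ndarray:
        """Integer stage codes (W=0 .. REM=4) for the in-bed window."""
        return np.array([STAGE_INDEX[s] for s in self.in_bed], dtype=np.int64)

    def epoch_of_time(self, t_sec: float) -> int:
        """Epoch index containing absolute time ``t_sec`` (0 = record start)."""
        return int(math.floor(t_sec / self.epoch_sec))


@dataclass(frozen=True)
class MacroParams:
    """Macrostructural sleep parameters of one record.

    ``None`` marks an undefined quantity (e.g. SOL when no sleep occurred,
    REM latency when REM never appeared) rather than raising.
    """

    TST: float
    SOL: float | None
    WASO: float
    SE: float
    stage_minutes: dict[str, float]
    stage_percent: dict[str, float | None]
    REM_latency: float | None
    n_awakenings: int
    REMfr: float | None

    def as_series(self) -> pd.Series:
        d: dict[str, float | None] = {
            "TST": self.TST,
            "SOL": self.SOL,
            "WASO": self.WASO,
            "SE": self.SE,
        }
        for s in SLEEP_STAGES:
            d[f"{s}_min"] = self.stage_minutes[s]
        for s in SLEEP_STAGES:
            d[f"{s}_pct"] = self.stage_percent[s]
        d["REM_latency"] = self.REM_latency
        d["n_awakenings"] = self.n_awakenings
        d["REMfr"] = self.REMfr
        return pd.Series(d, dtype=object).astype(float)


@dataclass(frozen=True)
class TransitionMatrix:
    """First-order Markov stage-transition counts and probabilities.

    ``P[i, j]`` is the conditional probability that an epoch in stage ``i``
    is immediately followed by stage ``j``; rows whose stage was never a
    transition origin are NaN (undefined, not zero).
    """

    counts: np.ndarray
    P: np.ndarray
    stages: tuple[str, ...] = STAGES

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (5, 5):
            raise ValueError("counts must be 5x5")
        row = c.sum(axis=1)
        p = np.asarray(self.P, dtype=float)
        for i in range(5):
            if row[i] > 0 and not math.isclose(p[i].sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"row {self.stages[i]} does not sum to 1")

    @property
    def defined_rows(self) -> np.ndarray:
        return np.asarray(self.counts).sum(axis=1) > 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=list(self.stages), columns=list(self.stages))


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=["onset_s", "duration_s", "type"])


def _sleep_onset_epoch(h: Hypnogram) -> int | None:
    for i in range(h.lights_off_index, h.lights_on_index):
        if h.stages[i] in SLEEP_ONSET_STAGES:
            return i
    return None


def _last_sleep_epoch(h: Hypnogram) -> int | None:
    for i in range(h.lights_on_index - 1, h.lights_off_index - 1, -1):
        if h.stages[i] in SLEEP_STAGES:
            return i
    return None


def _bouts(labels: Sequence[str]) -> list[tuple[int, int, str]]:
    """Maximal runs of identical labels as (start, stop_exclusive, label)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


def rem_fragmentation_index(h: Hypnogram, events: pd.DataFrame | None = None) -> float | None:
    """REM fragmentation index in events per hour of REM sleep.

    The numerator counts, within the in-bed window: cortical arousals whose
    onset falls in a REM epoch, body movements during REM, and distinct
    bouts of NREM/wake that interrupt a REM period (REM on both sides).
    An arousal or movement logged in the REM epoch immediately preceding an
    interrupting bout is not double-counted (the bout subsumes it).

    Returns ``None`` when the record contains no REM sleep.
    """
    if events is None:
        events = _empty_events()
    rem_epochs = [
        i for i in range(h.lights_off_index, h.lights_on_index) if h.stages[i] == "REM"
    ]
    rem_hours = len(rem_epochs) * h.epoch_sec / 3600.0
    if rem_hours == 0:
        return None

    # interrupting bouts: maximal non-REM runs (any stage mix) flanked by REM
    window = ["REM" if s == "REM" else "nonREM" for s in h.in_bed]
    off = h.lights_off_index
    interrupting: list[tuple[int, int]] = []  # absolute epoch ranges
    runs = _bouts(window)
    for k, (a, b, lab) in enumerate(runs):
        if lab == "nonREM" and 0 < k < len(runs) - 1:
            interrupting.append((a + off, b + off))
    n = len(interrupting)
    pre_bout_epochs = {a - 1 for a, _ in interrupting}

    rem_set = set(rem_epochs)
    for _, ev in events.iterrows():
        if ev["type"] not in ("arousal", "body_movement"):
            continue
        ep = h.epoch_of_time(float(ev["onset_s"]))
        if ep in rem_set and ep not in pre_bout_epochs:
            n += 1
    return n / rem_hours


def score_macrostructure(h: Hypnogram, events: pd.DataFrame | None = None) -> MacroParams:
    """Compute the standard PSG macrostructure variables of one record.

    TST sums all N1/N2/N3/REM minutes in bed; SOL runs from lights-off to
    the first N1 or N2 epoch; WASO is wake between sleep onset and the last
    sleep epoch; SE = TST / time-in-bed x 100; REM latency runs from sleep
    onset to the first REM epoch; awakenings are maximal W bouts between
    sleep onset and the final awakening.
    """
    ep_min = h.epoch_sec / 60.0
    tib = (h.lights_on_index - h.lights_off_index) * ep_min
    window = list(h.in_bed)
    off = h.lights_off_index

    stage_minutes = {s: window.count(s) * ep_min for s in SLEEP_STAGES}
    tst = sum(stage_minutes.values())
    se = 100.0 * tst / tib if tib > 0 else 0.0
    stage_percent: dict[str, float | None] = {
        s: (100.0 * stage_minutes[s] / tst if tst > 0 else None) for s in SLEEP_STAGES
    }

    onset = _sleep_onset_epoch(h)
    if onset is None or tst == 0:
        return MacroParams(
            TST=tst, SOL=None, WASO=0.0, SE=se, stage_minutes=stage_minutes,
            stage_percent=stage_percent, REM_latency=None, n_awakenings=0,
            REMfr=rem_fragmentation_index(h, events),
        )
    sol = (onset - off) * ep_min

    last_sleep = _last_sleep_epoch(h)
    assert last_sleep is not None
    waso = sum(
        1 for i in range(onset, last_sleep + 1) if h.stages[i] == "W"
    ) * ep_min

    rem_latency = None
    for i in range(onset, h.lights_on_index):
        if h.stages[i] == "REM":
            rem_latency = (i - onset) * ep_min
            break

    # W bouts strictly inside the sleep period
    n_awake = 0
    inner = list(h.stages[onset : last_sleep + 1])
    for _, _, lab in _bouts(inner):
        if lab == "W":
            n_awake += 1

    return MacroParams(
        TST=tst, SOL=sol, WASO=waso, SE=se, stage_minutes=stage_minutes,
        stage_percent=stage_percent, REM_latency=rem_latency,
        n_awakenings=n_awake, REMfr=rem_fragmentation_index(h, events),
    )


def transition_matrix(h: Hypnogram) -> TransitionMatrix:
    """First-order transition counts/probabilities over consecutive in-bed epochs."""
    codes = h.codes()
    if codes.size < 2:
        raise ValueError("need at least 2 in-bed epochs for a transition matrix")
    counts = np.zeros((5, 5), dtype=np.int64)
    np.add.at(counts, (codes[:-1], codes[1:]), 1)
    row = counts.sum(axis=1)
    P = np.full((5, 5), np.nan)
    nz = row > 0
    P[nz] = counts[nz] / row[nz, None]
    return TransitionMatrix(counts=counts, P=P)


@dataclass(frozen=True)
class MatrixComparison:
    """Cell-wise paired-t comparison of two sets of transition matrices."""

    t: np.ndarray                 # 5x5, NaN where not computable
    p_raw: np.ndarray             # 5x5 uncorrected
    p_bonferroni: np.ndarray      # 5x5, multiplied by n_computable, capped at 1
    n_pairs: np.ndarray           # complete pairs per cell
    n_computable: int
    mean_diff: np.ndarray         # mean A - B per cell

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p_bonferroni < alpha


def compare_transition_matrices(
    A: Sequence[TransitionMatrix], B: Sequence[TransitionMatrix]
) -> MatrixComparison:
    """Paired t-test per transition cell with Bonferroni correction.

    ``A`` and ``B`` hold one matrix per subject, in the same subject order.
    Cells undefined for a subject in either condition are excluded pairwise;
    a cell with fewer than 2 complete pairs, or zero-variance differences,
    is flagged not-computable (NaN).  The Bonferroni factor is the number of
    computable cells in this comparison.
    """
    if len(A) != len(B):
        raise ValueError("A and B must contain the same subjects in order")
    if len(A) < 2:
        raise ValueError("need at least 2 subjects")
    a = np.stack([m.P for m in A])  # (n, 5, 5)
    b = np.stack([m.P for m in B])
    t = np.full((5, 5), np.nan)
    p = np.full((5, 5), np.nan)
    md = np.full((5, 5), np.nan)
    npairs = np.zeros((5, 5), dtype=int)
    for i in range(5):
        for j in range(5):
            x, y = a[:, i, j], b[:, i, j]
            ok = np.isfinite(x) & np.isfinite(y)
            npairs[i, j] = int(ok.sum())
            if npairs[i, j] < 2:
                continue
            d = x[ok] - y[ok]
            md[i, j] = d.mean()
            if np.allclose(d, d[0]):
                if d[0] == 0:
                    # identical matrices: t = 0, p = 1 (defined, null)
                    t[i, j], p[i, j] = 0.0, 1.0
                continue  # zero-variance nonzero difference: degenerate t
            res = stats.ttest_rel(x[ok], y[ok])
            t[i, j], p[i, j] = float(res.statistic), float(res.pvalue)
    n_comp = int(np.isfinite(t).sum())
    p_bonf = np.minimum(p * n_comp, 1.0)
    return MatrixComparison(
        t=t, p_raw=p, p_bonferroni=p_bonf, n_pairs=npairs,
        n_computable=n_comp, mean_diff=md,
    )


def macro_table(records: dict[str, tuple[Hypnogram, pd.DataFrame | None]]) -> pd.DataFrame:
    """MacroParams for several records as one DataFrame (index = record id)."""
    rows = {k: score_macrostructure(h, ev).as_series() for k, (h, ev) in records.items()}
    return pd.DataFrame(rows).T
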