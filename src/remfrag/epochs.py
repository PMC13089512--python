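"""Selection and extraction of stimulation-locked EEG epochs.

A stimulation "train" is the run of consecutive 3-s vibrations delivered
until a cortical arousal (or a stage change) ends it; consecutive
stimulations whose onsets are at most 40 s apart (the protocol's suspension
time) belong to the same train.  Candidate epochs are screened by four
rules, applied in order with mutually exclusive drop reasons:

1. ``outside_REM``    - the stimulation onset does not fall in a REM epoch;
2. ``not_final_in_train`` - only the last (arousal-eliciting) stimulation of
   each train is kept;
3. ``artifact``       - the -3..+15 s epoch window intersects a marked
   artifact interval;
4. ``full_awakening`` - a wake epoch intersects the 15-s post-stimulus
   window (the stimulation woke the participant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram

TRAIN_GAP_S = 40.0
EPOCH_WINDOW_S = (-3.0, 15.0)

DROP_REASONS = ("outside_REM", "not_final_in_train", "artifact", "full_awakening")


@dataclass(frozen=True)
class StimEpochSelection:
    """Kept and dropped stimulation epochs; drop reasons are exclusive."""

    kept: pd.DataFrame
    dropped: pd.DataFrame     # extra column "reason"

    @property
    def n_candidates(self) -> int:
        return len(self.kept) + len(self.dropped)

    def n_dropped(self, reason: str) -> int:
        if reason not in DROP_REASONS:
            raise ValueError(f"unknown reason {reason!r}")
        return int((self.dropped["reason"] == reason).sum())


def assign_trains(stims: pd.DataFrame, gap_s: float = TRAIN_GAP_S) -> np.ndarray:
    """Train index per stimulation: onset gaps larger than ``gap_s`` split trains."""
    onsets = stims["onset_s"].to_numpy(float)
    order = np.argsort(onsets, kind="stable")
    train = np.zeros(len(stims), dtype=int)
    tid = 0
    for k, idx in enumerate(order):
        if k > 0 and onsets[idx] - onsets[order[k - 1]] > gap_s:
            tid += 1
        train[idx] = tid
    return train


def select_epochs(
    events: pd.DataFrame,
    h: Hypnogram,
    artifact_intervals: list[tuple[float, float]] | None = None,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
) -> StimEpochSelection:
    """Apply the four-rule screening to the stimulation events of one night.

    ``events`` is an event log with columns onset_s, duration_s, type; rows
    of type ``stim_on`` are the candidates.  A ``train_id`` column is used
    when present, otherwise trains are derived from the 40-s onset-gap rule.
    """
    stims = events[events["type"] == "stim_on"].copy()
    stims = stims.sort_values("onset_s", kind="stable").reset_index(drop=True)
    if stims.empty:
        empty = stims.assign(reason=pd.Series(dtype=str))
        return StimEpochSelection(kept=stims, dropped=empty)
    if "train_id" in stims.columns and stims["train_id"].notna().all():
        train = stims["train_id"].to_numpy()
    else:
        train = assign_trains(stims)
    stims["train_id"] = train

    reasons = np.array([None] * len(stims), dtype=object)

    # rule 1: outside REM
    for i, onset in enumerate(stims["onset_s"]):
        ep = h.epoch_of_time(float(onset))
        if ep >= len(h) or h.stages[ep] != "REM":
            reasons[i] = "outside_REM"

    # rule 2: keep the final stimulation per train (among rule-1 survivors)
    alive = reasons == None  # noqa: E711
    for tid in np.unique(train):
        idx = np.flatnonzero((train == tid) & alive)
        if idx.size > 1:
            reasons[idx[:-1]] = "not_final_in_train"

    # rule 3: artifact intervals intersecting the epoch window
    for i in np.flatnonzero(reasons == None):  # noqa: E711
        onset = float(stims.at[i, "onset_s"])
        lo, hi = onset + window_s[0], onset + window_s[1]
        for a, b in artifact_intervals or []:
            if a < hi and b > lo:
                reasons[i] = "artifact"
                break

    # rule 4: full awakening (a W epoch intersects the post-stimulus window)
    for i in np.flatnonzero(reasons == None):  # noqa: E711
        onset = float(stims.at[i, "onset_s"])
        ep_lo = h.epoch_of_time(onset)
        ep_hi = h.epoch_of_time(min(onset + window_s[1],
                                    len(h) * h.epoch_sec - 1e-9))
        if any(h.stages[e] == "W" for e in range(ep_lo, ep_hi + 1) if e < len(h)):
            reasons[i] = "full_awakening"

    keep_mask = reasons == None  # noqa: E711
    kept = stims[keep_mask].reset_index(drop=True)
    dropped = stims[~keep_mask].assign(reason=reasons[~keep_mask]).reset_index(drop=True)
    return StimEpochSelection(kept=kept, dropped=dropped)


def extract_epochs(
    data: np.ndarray,
    sfreq: float,
    onsets_s: np.ndarray,
    window_s: tuple[float, float] = EPOCH_WINDOW_S,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cut stimulation-locked windows out of a continuous recording.

    Returns (epochs, report): epochs is (n_kept, n_channels, n_times) with
    t=0 at stimulation onset; onsets whose window exceeds the recording are
    dropped and listed in the report (column ``reason`` =
    ``window_out_of_bounds``), never silently truncated.
    """
    data = np.atleast_2d(np.asarray(data, float))
    n_samp = data.shape[1]
    lo_off = int(round(window_s[0] * sfreq))
    hi_off = int(round(window_s[1] * sfreq))
    n_t = hi_off - lo_off + 1
    out, rows = [], []
    for onset in np.atleast_1d(np.asarray(onsets_s, float)):
        center = int(round(onset * sfreq))
        a, b = center + lo_off, center + hi_off + 1
        if a < 0 or b > n_samp:
            rows.append({"onset_s": onset, "kept": False,
                         "reason": "window_out_of_bounds"})
            continue
        out.append(data[:, a:b])
        rows.append({"onset_s": onset, "kept": True, "reason": ""})
    epochs = np.stack(out) if out else np.empty((0, data.shape[0], n_t))
    return epochs, pd.DataFrame(rows)
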