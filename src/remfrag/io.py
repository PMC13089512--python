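"""File interfaces: TSV tables, montage text files and EDF recordings.

Tabular data (hypnograms, event logs, IBI/EDA traces, trial tables) moves
as plain TSV through pandas.  Continuous EEG is read from EDF via mne;
since no writer is available among the runtime dependencies, a minimal
16-bit EDF writer is implemented here (single data-record layout checks,
physical/digital scaling per channel) and round-tripped against mne's
reader in the test suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram

CH_NAMES_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)
#: parieto-occipital channel set used for posterior summaries
POSTERIOR_CHANNELS = ("P7", "P3", "Pz", "P4", "P8", "O1", "O2")


# ---------------------------------------------------------------------------
# hypnogram / event TSV

def write_hypnogram_tsv(h: Hypnogram, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# lights_off_index={h.lights_off_index}\n")
        f.write(f"# lights_on_index={h.lights_on_index}\n")
        f.write(f"# epoch_sec={h.epoch_sec}\n")
        f.write("epoch_index\tstage\n")
        for i, s in enumerate(h.stages):
            f.write(f"{i}\t{s}\n")


def read_hypnogram_tsv(path: str | Path) -> Hypnogram:
    meta = {}
    with open(path) as f:
        lines = f.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            k, v = line[1:].strip().split("=")
            meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    df = df.sort_values("epoch_index")
    return Hypnogram(
        stages=tuple(df["stage"]),
        lights_off_index=int(meta.get("lights_off_index", 0)),
        lights_on_index=int(meta["lights_on_index"]) if "lights_on_index" in meta else None,
        epoch_sec=float(meta.get("epoch_sec", 30.0)),
    )


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# IBI / EDA traces

def write_ibi_tsv(beat_times_ms: np.ndarray, ibi_ms: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"beat_time_ms": beat_times_ms, "ibi_ms": ibi_ms}).to_csv(
        path, sep="\t", index=False)


def read_ibi_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["beat_time_ms"].to_numpy(float), df["ibi_ms"].to_numpy(float)


def write_eda_tsv(trace_us: np.ndarray, fs: float, path: str | Path) -> None:
    t = np.arange(len(trace_us)) / fs
    pd.DataFrame({"time_s": t, "conductance_uS": trace_us}).to_csv(
        path, sep="\t", index=False)


def read_eda_tsv(path: str | Path) -> tuple[np.ndarray, float]:
    """Returns (trace in uS, sampling rate inferred from the time column)."""
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy(float)
    if t.size < 2:
        raise ValueError("EDA trace needs at least 2 samples")
    fs = 1.0 / np.median(np.diff(t))
    return df["conductance_uS"].to_numpy(float), float(round(fs, 6))


# ---------------------------------------------------------------------------
# montage

def montage_positions(
    ch_names: tuple[str, ...] = CH_NAMES_19, montage: str = "standard_1020"
) -> np.ndarray:
    """3D electrode positions (m) for ``ch_names`` from a standard montage."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mon = mne.channels.make_standard_montage(montage)
    pos = mon.get_positions()["ch_pos"]
    missing = [c for c in ch_names if c not in pos]
    if missing:
        raise ValueError(f"channels missing from montage {montage}: {missing}")
    return np.array([pos[c] for c in ch_names])


def write_montage_tsv(path: str | Path, ch_names, pos3d: np.ndarray) -> None:
    df = pd.DataFrame(pos3d, columns=["x", "y", "z"])
    df.insert(0, "name", list(ch_names))
    df.to_csv(path, sep="\t", index=False)


def read_montage_tsv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return tuple(df["name"]), df[["x", "y", "z"]].to_numpy(float)


# ---------------------------------------------------------------------------
# EDF

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    sfreq: float,
    ch_names,
    record_duration_s: float = 1.0,
) -> None:
    """Write a multichannel signal (uV) as a plain EDF file.

    The signal length must be a whole number of data records
    (``record_duration_s * sfreq`` samples).  Each channel is scaled to the
    full 16-bit digital range with its own physical min/max.
    """
    data = np.atleast_2d(np.asarray(data_uv, float))
    n_ch, n_samp = data.shape
    spr = record_duration_s * sfreq
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("record duration times sampling rate must be integer")
    spr = int(round(spr))
    if n_samp % spr:
        raise ValueError(
            f"signal length {n_samp} is not a whole number of {spr}-sample records"
        )
    n_rec = n_samp // spr

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767

    hdr = b""
    hdr += _pad("0", 8)
    hdr += _pad("X X X X", 80)           # patient
    hdr += _pad("Startdate X X X X", 80)  # recording
    hdr += _pad("01.01.00", 8)
    hdr += _pad("00.00.00", 8)
    hdr += _pad(str(256 * (1 + n_ch)), 8)
    hdr += _pad("", 44)
    hdr += _pad(str(n_rec), 8)
    hdr += _pad(f"{record_duration_s:g}", 8)
    hdr += _pad(str(n_ch), 4)

    def field(vals, width):
        return b"".join(_pad(str(v), width) for v in vals)

    hdr += field(ch_names, 16)
    hdr += field(["EEG"] * n_ch, 80)            # transducer
    hdr += field(["uV"] * n_ch, 8)
    hdr += field([f"{v:.6g}"[:8] for v in pmin], 8)
    hdr += field([f"{v:.6g}"[:8] for v in pmax], 8)
    hdr += field([dmin] * n_ch, 8)
    hdr += field([dmax] * n_ch, 8)
    hdr += field([""] * n_ch, 80)               # prefilter
    hdr += field([spr] * n_ch, 8)
    hdr += field([""] * n_ch, 32)               # reserved

    # re-read the printed physical bounds so scaling matches the header exactly
    pmin_h = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_h = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    gain = (dmax - dmin) / (pmax_h - pmin_h)
    dig = np.rint((data - pmin_h[:, None]) * gain[:, None] + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")

    with open(path, "wb") as f:
        f.write(hdr)
        for r in range(n_rec):
            block = dig[:, r * spr : (r + 1) * spr]
            f.write(block.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read an EDF file; returns (data in uV, sfreq, channel names)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(units="uV"), float(raw.info["sfreq"]), tuple(raw.ch_names)


# ---------------------------------------------------------------------------
# config / report JSON

def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
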