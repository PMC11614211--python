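"""File I/O: EDF recordings, BIDS-style event/electrode TSVs, HDF5 epochs.

Recordings are written as plain 16-bit EDF (European Data Format) with
physical units in microvolts; a compact writer is included here, and
reading goes through :func:`mne.io.read_raw_edf`.  Event tables use a
BIDS-style ``events.tsv`` dialect (onset, duration, trial_type, quantity,
is_catch, plus the jitter durations used for baseline-epoch placement);
electrode tables are two-column TSVs (name, region).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import EpochSet, Recording
from .synth import TaskSchedule

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _edf_float(value: float, width: int = 8) -> bytes:
    """Format a float into an EDF numeric field, at most ``width`` chars."""
    for fmt in (f"{{:.{p}g}}" for p in range(7, 0, -1)):
        s = fmt.format(value)
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(path: str | Path, rec: Recording, recording_id: str = "synthetic") -> None:
    """Write a recording to 16-bit EDF (physical units: microvolts).

    The sampling rate must be an integer (one data record per second).  The
    recording is zero-padded to a whole number of seconds.
    """
    sfreq = rec.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1-s record
    n_records = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((rec.n_channels, n_records * spr))
    data[:, : rec.n_samples] = rec.data

    # physical ranges per channel; re-parse the header strings so the scaling
    # used for quantization matches what a reader will see
    pmins, pmaxs, pmin_b, pmax_b = [], [], [], []
    for ch in data:
        lo, hi = float(ch.min()), float(ch.max())
        if hi <= lo:
            hi = lo + 1.0
        bmin, bmax = _edf_float(lo), _edf_float(hi)
        pmin_b.append(bmin)
        pmax_b.append(bmax)
        pmins.append(float(bmin))
        pmaxs.append(float(bmax))

    ns = rec.n_channels
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X", 80),
            _edf_field(recording_id[:80], 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (ns + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),
            _edf_field(ns, 4),
        ]
    )
    sig = b"".join(_edf_field(name[:16], 16) for name in rec.ch_names)
    sig += b"".join(_edf_field("", 80) for _ in range(ns))
    sig += b"".join(_edf_field("uV", 8) for _ in range(ns))
    sig += b"".join(pmin_b)
    sig += b"".join(pmax_b)
    sig += b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in range(ns))
    sig += b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in range(ns))
    sig += b"".join(_edf_field("", 80) for _ in range(ns))
    sig += b"".join(_edf_field(spr, 8) for _ in range(ns))
    sig += b"".join(_edf_field("", 32) for _ in range(ns))

    scale = (np.array(pmaxs) - np.array(pmins)) / (_EDF_DIG_MAX - _EDF_DIG_MIN)
    digital = np.rint(
        (data - np.array(pmins)[:, None]) / scale[:, None] + _EDF_DIG_MIN
    )
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # record-major layout: per record, all samples of ch0, then ch1, ...
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF recording via MNE; returns voltages in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        data=raw.get_data() * 1e6,
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
    )


def write_events_tsv(schedule: TaskSchedule, path: str | Path) -> None:
    schedule.to_events_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path: str | Path) -> TaskSchedule:
    return TaskSchedule.from_events_frame(pd.read_csv(path, sep="\t"))


def write_electrodes_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table[["name", "region"]].to_csv(path, sep="\t", index=False)


def read_electrodes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("name", "region") if c not in df.columns]
    if missing:
        raise ValueError(f"electrodes table is missing columns: {missing}")
    return df


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.attrs["window"] = epochs.window
        f.attrs["sfreq"] = epochs.sfreq
        f.create_dataset("condition", data=np.asarray(epochs.condition, dtype="S16"))
        f.create_dataset("modality", data=np.asarray(epochs.modality, dtype="S16"))
        f.create_dataset("kept_mask", data=epochs.kept_mask)
        f.create_dataset("centers_s", data=epochs.centers_s)
        f.create_dataset("ch_names", data=np.asarray(epochs.ch_names, dtype="S32"))


def load_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            window=tuple(f.attrs["window"]),
            condition=np.array([s.decode() for s in f["condition"][()]], dtype=object),
            modality=np.array([s.decode() for s in f["modality"][()]], dtype=object),
            sfreq=float(f.attrs["sfreq"]),
            ch_names=[s.decode() for s in f["ch_names"][()]],
            centers_s=f["centers_s"][()],
            kept_mask=f["kept_mask"][()],
        )
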