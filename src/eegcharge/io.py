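"""Session container, EDF interchange, events TSV and unit-bearing CSVs.

The internal per-session container is one HDF5 file holding the data array
(μV), the event schedule, the montage geometry and a provenance JSON blob.
EDF is kept as a lossy (16-bit) interchange format: reading goes through
mne's EDF reader; writing uses a minimal EDF writer implemented here
(no installed library writes EDF).
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import Montage
from .simulate import RawSession, TrialSchedule

__all__ = [
    "save_session",
    "load_session",
    "write_events_tsv",
    "read_events_tsv",
    "write_edf",
    "read_edf",
    "write_charge_csv",
    "write_frequency_csv",
]


class FormatError(ValueError):
    pass


def save_session(path: str | Path, raw: RawSession) -> None:
    """Write a session to the internal HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data_uV", data=raw.data, compression="gzip",
                         compression_opts=4)
        f.attrs["sampling_rate_hz"] = raw.sampling_rate
        ev = raw.schedule.to_frame()
        f.create_dataset("event_onsets_s", data=ev["onset_s"].to_numpy())
        f.create_dataset(
            "event_conditions",
            data=np.array(ev["condition"], dtype=h5py.string_dtype()))
        f.create_dataset("montage/positions_m", data=raw.montage.positions)
        f.create_dataset(
            "montage/channel_ids",
            data=np.array(raw.montage.channel_ids,
                          dtype=h5py.string_dtype()))
        f.attrs["scalp_radius_m"] = raw.montage.scalp_radius
        f.attrs["provenance"] = json.dumps(raw.truth)


def load_session(path: str | Path) -> RawSession:
    with h5py.File(path, "r") as f:
        data = f["data_uV"][()]
        fs = float(f.attrs["sampling_rate_hz"])
        onsets = f["event_onsets_s"][()]
        conds = [c.decode() for c in f["event_conditions"][()]]
        montage = Montage(
            channel_ids=tuple(c.decode()
                              for c in f["montage/channel_ids"][()]),
            positions=f["montage/positions_m"][()],
            scalp_radius=float(f.attrs["scalp_radius_m"]))
        truth = json.loads(f.attrs["provenance"])
    schedule = TrialSchedule(events=tuple(zip(onsets.tolist(), conds)))
    return RawSession(data=data, sampling_rate=fs, schedule=schedule,
                      montage=montage, truth=truth)


def write_events_tsv(path: str | Path, schedule: TrialSchedule) -> None:
    schedule.to_frame().to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> TrialSchedule:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["onset_s", "condition"]:
        raise FormatError("events TSV needs columns onset_s, condition")
    return TrialSchedule(events=tuple(
        zip(df["onset_s"].astype(float), df["condition"])))


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, raw: RawSession) -> None:
    """Minimal 16-bit EDF export (physical dimension μV).

    One data record per second; a trailing partial second is dropped.  Event
    markers are not embedded — keep them in the sidecar TSV.
    """
    fs = raw.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF export needs an integer sampling rate")
    n_records = raw.n_samples // spr
    if n_records < 1:
        raise FormatError("session shorter than one EDF record")
    data = raw.data[:, :n_records * spr]
    n_sig = data.shape[0]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    gain = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.rint((data - pmin[:, None]) * gain[:, None] + dmin),
                      dmin, dmax).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + n_sig)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_sig), 4),
    ])
    ids = raw.montage.channel_ids
    fields = [
        b"".join(_pad(f"EEG {c}", 16) for c in ids),
        b"".join(_pad("AgAgCl electrode", 80) for _ in ids),
        b"".join(_pad("uV", 8) for _ in ids),
        b"".join(_pad(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(_pad(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(_pad(str(dmin), 8) for _ in ids),
        b"".join(_pad(str(dmax), 8) for _ in ids),
        b"".join(_pad("", 80) for _ in ids),
        b"".join(_pad(str(spr), 8) for _ in ids),
        b"".join(_pad("", 32) for _ in ids),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        rec = digital.reshape(n_sig, n_records, spr)
        for r in range(n_records):
            fh.write(rec[:, r, :].tobytes())


def read_edf(path: str | Path, events_tsv: str | Path,
             montage: Montage) -> RawSession:
    """Load an EDF recording (via mne) plus its events sidecar."""
    import mne

    edf = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = edf.get_data() * 1e6  # V -> μV
    if data.shape[0] != montage.n_channels:
        raise FormatError("EDF channel count does not match the montage")
    schedule = read_events_tsv(events_tsv)
    return RawSession(data=data, sampling_rate=float(edf.info["sfreq"]),
                      schedule=schedule, montage=montage)


def write_charge_csv(path: str | Path, table: pd.DataFrame) -> None:
    """Tidy per-parcel charge table; the iota column carries its unit."""
    cols = ["subject", "condition", "band", "parcel", "iota_uC"]
    table[cols].to_csv(path, index=False)


def write_frequency_csv(path: str | Path, table: pd.DataFrame) -> None:
    table[["band", "condition", "parcel", "count"]].to_csv(path, index=False)
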