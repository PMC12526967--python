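"""Readers and writers for recordings and the packaged accuracy fixtures.

Two on-disk dialects are supported:

* **native** — a plain-text columnar file (header lines with sampling rate
  and channel names, one tab-separated row per sample, ``%.17g`` floats, so
  the round trip is bit-exact) plus a ``<path>.events.csv`` sidecar holding
  the event table.  Chosen for diffability.
* **edf** — European Data Format, 16-bit.  Reading goes through
  :func:`mne.io.read_raw_edf`; writing uses a minimal EDF encoder (one 1-s
  data record per second, per-channel physical scaling recorded in the
  header), so exported potentials are quantized to the 16-bit grid.  Events
  use the same sidecar convention, since plain EDF has no annotation stream.
"""

from __future__ import annotations

import csv
import io as _io
import math
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, default_montage
from .recording import EventTable, Label, Paradigm, RawRecording
from .stats import PairedAccuracyTable

_NATIVE_MAGIC = "# mibci-recording v1"

__all__ = [
    "read_recording",
    "write_recording",
    "load_accuracy_fixture",
    "save_epochs",
    "load_epochs",
]


# ---------------------------------------------------------------------------
# native dialect


def _write_native(rec: RawRecording, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_NATIVE_MAGIC + "\n")
        fh.write(f"# fs={rec.fs!r}\n")
        fh.write("# channels=" + ",".join(rec.montage.channel_names) + "\n")
        fh.write("# units=uV\n")
        np.savetxt(fh, rec.data.T, fmt="%.17g", delimiter="\t")


def _read_native(path: Path) -> tuple[np.ndarray, float, list[str]]:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _NATIVE_MAGIC:
            raise ValueError(f"{path}: not a native recording file")
        header: dict[str, str] = {}
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
            pos = fh.tell()
        fs = float(header["fs"])
        channels = header["channels"].split(",")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    return data, fs, channels


# ---------------------------------------------------------------------------
# events sidecar


def _events_path(path: Path) -> Path:
    return path.with_name(path.name + ".events.csv")


def _write_events(events: EventTable, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_sample", "label", "paradigm", "run_id"])
        for onset, lbl, par in zip(events.onsets, events.labels, events.paradigm):
            w.writerow([int(onset), lbl.value, par.value, events.run_id])


def _read_events(path: Path) -> EventTable | None:
    if not path.exists():
        return None
    df = pd.read_csv(path)
    if len(df) == 0:
        return None
    run_ids = set(df["run_id"].astype(str))
    onsets = df["onset_sample"].to_numpy(dtype=np.int64)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"{path}: event onsets are not strictly increasing")
    return EventTable(
        onsets=onsets,
        labels=tuple(Label(v) for v in df["label"]),
        paradigm=tuple(Paradigm(v) for v in df["paradigm"]),
        run_id=df["run_id"].astype(str).iloc[0] if len(run_ids) == 1 else "mixed",
    )


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _edf_number(v: float) -> str:
    """Densest representation of ``v`` that fits EDF's 8-char numeric fields."""
    for prec in range(7, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def _write_edf(rec: RawRecording, path: Path) -> None:
    """Minimal 16-bit EDF export with 1-s data records.

    Each channel is scaled linearly from its physical range (data min/max,
    stored in the header) onto the digital range [-32768, 32767]; the
    reconstruction error is bounded by half a quantization step.  The final
    record is zero-padded when the duration is not a whole second.
    """
    n_ch, n_samp = rec.data.shape
    spr = int(round(rec.fs))  # samples per 1-s record
    if abs(spr - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = math.ceil(n_samp / spr)
    pmin = rec.data.min(axis=1)
    pmax = rec.data.max(axis=1)
    flat = pmax - pmin == 0
    pmax = np.where(flat, pmin + 1.0, pmax)  # avoid zero physical span
    # Header numeric fields hold 8 ASCII chars: widen the range slightly and
    # use the values as actually written, so reader-side scaling matches the
    # scaling used to digitize.
    margin = 1e-3 * (pmax - pmin)
    pmin = np.array([float(_edf_number(v)) for v in pmin - margin])
    pmax = np.array([float(_edf_number(v)) for v in pmax + margin])
    dmin, dmax = -32768, 32767

    hdr = _io.BytesIO()
    hdr.write(_edf_field("0", 8))  # version
    hdr.write(_edf_field("X X X X", 80))  # patient id (anonymous)
    hdr.write(_edf_field("Startdate X X X X", 80))  # recording id
    hdr.write(_edf_field("01.01.00", 8))
    hdr.write(_edf_field("00.00.00", 8))
    hdr.write(_edf_field(str(256 * (n_ch + 1)), 8))
    hdr.write(_edf_field("", 44))
    hdr.write(_edf_field(str(n_rec), 8))
    hdr.write(_edf_field("1", 8))  # record duration, seconds
    hdr.write(_edf_field(str(n_ch), 4))
    for name in rec.montage.channel_names:
        hdr.write(_edf_field(f"EEG {name}", 16))
    for _ in range(n_ch):
        hdr.write(_edf_field("", 80))  # transducer
    for _ in range(n_ch):
        hdr.write(_edf_field("uV", 8))
    for v in pmin:
        hdr.write(_edf_field(_edf_number(v), 8))
    for v in pmax:
        hdr.write(_edf_field(_edf_number(v), 8))
    hdr.write(_edf_field(str(dmin), 8) * n_ch)
    hdr.write(_edf_field(str(dmax), 8) * n_ch)
    for _ in range(n_ch):
        hdr.write(_edf_field("", 80))  # prefiltering
    hdr.write(_edf_field(str(spr), 8) * n_ch)
    hdr.write(_edf_field("", 32) * n_ch)

    gain = (dmax - dmin) / (pmax - pmin)
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = rec.data
    padded[:, n_samp:] = pmin[:, None]  # pad at the bottom of the range
    digital = np.rint((padded - pmin[:, None]) * gain[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())  # channel-major within each record


def _read_edf(path: Path, montage: Montage) -> tuple[np.ndarray, float, list[str]]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = []
    for ch in raw.ch_names:
        name = ch.removeprefix("EEG ").strip()
        labels.append(name)
    data_uv = raw.get_data() * 1e6  # mne returns volts for EEG channels
    return data_uv, float(raw.info["sfreq"]), labels


# ---------------------------------------------------------------------------
# public API


def read_recording(
    path: str | Path,
    format: str = "native",
    montage: Montage | None = None,
    fs_expected: float | None = None,
) -> RawRecording:
    """Read a recording, normalizing channel order to the montage.

    Parameters
    ----------
    path
        Recording file; an adjacent ``<path>.events.csv`` sidecar, if
        present, supplies the event table.
    format
        ``"native"`` or ``"edf"``.
    montage
        Target montage (default: the 16-channel study montage).  Every
        montage channel must appear among the file's labels.
    fs_expected
        If given and the header disagrees, a warning is issued and the
        header wins.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    montage = montage or default_montage()
    if format == "native":
        data, fs, labels = _read_native(path)
    elif format == "edf":
        data, fs, labels = _read_edf(path, montage)
    else:
        raise ValueError(f"unknown format {format!r}")

    missing = [ch for ch in montage.channel_names if ch not in labels]
    if missing:
        raise ValueError(f"{path}: montage channels absent from file: {missing}")
    order = [labels.index(ch) for ch in montage.channel_names]
    data = data[order]

    if fs_expected is not None and abs(fs - fs_expected) > 1e-9:
        warnings.warn(
            f"{path}: header fs={fs:g} Hz differs from expected "
            f"{fs_expected:g} Hz; using the header value",
            stacklevel=2,
        )
    events = _read_events(_events_path(path))
    return RawRecording(data=data, fs=fs, montage=montage, events=events)


def write_recording(rec: RawRecording, path: str | Path, format: str = "native") -> None:
    """Write a recording (and its events sidecar, if any) to disk."""
    path = Path(path)
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording")
    if format == "native":
        _write_native(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if rec.events is not None and len(rec.events):
        _write_events(rec.events, _events_path(path))


def save_epochs(epochs, prefix: str | Path) -> None:
    """Serialize an epoch set: ``<prefix>.npy`` array + CSV label sheet.

    The label sheet carries one row per trial (label, paradigm) and the
    sheet header encodes fs, time0 and channel names.
    """
    from .epoching import EpochSet  # local import avoids a cycle

    assert isinstance(epochs, EpochSet)
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), epochs.data)
    with open(prefix.with_suffix(".labels.csv"), "w", newline="") as fh:
        fh.write(f"# fs={epochs.fs!r}\n")
        fh.write(f"# time0={epochs.time0!r}\n")
        fh.write("# channels=" + ",".join(epochs.channel_names) + "\n")
        w = csv.writer(fh)
        w.writerow(["label", "paradigm"])
        paradigms = epochs.paradigm or (("",) * epochs.n_trials)
        for lbl, par in zip(epochs.labels, paradigms):
            w.writerow([lbl.value, par.value if par else ""])


def load_epochs(prefix: str | Path):
    """Inverse of :func:`save_epochs`."""
    from .epoching import EpochSet

    prefix = Path(prefix)
    data = np.load(prefix.with_suffix(".npy"))
    header: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(prefix.with_suffix(".labels.csv")) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val.strip()
            else:
                rows.append(line.strip().split(","))
    body = rows[1:]  # drop the column header
    labels = tuple(Label(r[0]) for r in body)
    paradigms = tuple(Paradigm(r[1]) for r in body) if body and body[0][1] else ()
    return EpochSet(
        data=data,
        labels=labels,
        fs=float(header["fs"]),
        time0=float(header["time0"]),
        paradigm=paradigms,
        channel_names=tuple(header["channels"].split(",")) if header["channels"] else (),
    )


def load_accuracy_fixture(name: str) -> PairedAccuracyTable:
    """Load a packaged session-accuracy grid.

    ``"table2"`` is the 10-subject x (3 paradigms x 2 windows x 3
    classifiers) grid without common-average referencing; ``"table3"`` the
    T = 2 s grid after CAR.  Values are percentages.
    """
    if name not in {"table2", "table3"}:
        raise ValueError("fixture name must be 'table2' or 'table3'")
    ref = resources.files("mibci.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as p:
        df = pd.read_csv(p)
    expected = {"table2": 180, "table3": 90}[name]
    if len(df) != expected or df["accuracy_pct"].isna().any():
        raise ValueError(f"fixture {name} is incomplete")
    return PairedAccuracyTable(frame=df, car=(name == "table3"), name=name)
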