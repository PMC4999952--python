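"""Core domain types and waveform / feature-table I/O.

All quantities are carried in SI-ish base units internally: times and
intervals in seconds, spectral powers in s^2.  Sampling rates are Hz.

Waveform CSV layout (one channel per file)::

    # fs=250
    # channel=ECG_II
    # t0=0
    sample
    0.01318
    ...

Feature tables are plain CSV with one column per parameter in the fixed
order of :data:`FEATURE_NAMES` plus ``source_id`` and ``label``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "WaveformRecord",
    "FeatureVector",
    "LabeledWindow",
    "FEATURE_NAMES",
    "HRV_FEATURES",
    "RRV_FEATURES",
    "read_record",
    "write_record",
    "read_feature_table",
    "write_feature_table",
]


class Channel(str, Enum):
    """Signal channel identity."""

    ECG_II = "ECG_II"
    RESP = "RESP"


#: Fixed feature ordering used in every table and model input.
FEATURE_NAMES: tuple[str, ...] = (
    "mean_nn",
    "sdnn",
    "rmssd",
    "pnn50",
    "vlf",
    "lf",
    "hf",
    "lf_hf",
    "sd1",
    "sd2",
    "sd1_sd2",
    "rpdm",
    "rpdsd",
    "rpdv",
)

#: The 11 heart-rate-variability parameters.
HRV_FEATURES: tuple[str, ...] = FEATURE_NAMES[:11]

#: The 3 respiratory-rate-variability parameters.
RRV_FEATURES: tuple[str, ...] = FEATURE_NAMES[11:]


@dataclass(frozen=True)
class WaveformRecord:
    """A uniformly sampled physiological signal.

    Parameters
    ----------
    samples:
        Signal values (mV for ECG, arbitrary units for respiration).
    fs:
        Sampling rate in Hz, > 0.
    channel:
        Channel identity (:class:`Channel`).
    t0:
        Window start time in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    channel: Channel
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("empty signal")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channel", Channel(self.channel))

    @property
    def duration(self) -> float:
        """Signal duration in seconds (``len(samples)/fs``)."""
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at ``t0``."""
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass(frozen=True)
class FeatureVector:
    """The 14 variability parameters for one 5-minute window.

    Intervals are seconds, band powers s^2, ``pnn50`` a proportion in
    [0, 1], ``rpdv`` a percentage.  Ratio fields may be NaN when their
    denominator vanishes.
    """

    mean_nn: float
    sdnn: float
    rmssd: float
    pnn50: float
    vlf: float
    lf: float
    hf: float
    lf_hf: float
    sd1: float
    sd2: float
    sd1_sd2: float
    rpdm: float
    rpdsd: float
    rpdv: float

    def to_array(self, names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        """Return the selected features as a float array in table order."""
        return np.array([getattr(self, n) for n in names], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "FeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values, got {values.shape}")
        return cls(**dict(zip(FEATURE_NAMES, values.tolist())))

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class LabeledWindow:
    """A paired ECG + respiration window with its class label.

    ``label`` is +1 for the pre-VT class and -1 for control.
    """

    ecg: WaveformRecord
    resp: WaveformRecord
    label: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.ecg.channel is not Channel.ECG_II:
            raise ValueError("ecg record must be on channel ECG_II")
        if self.resp.channel is not Channel.RESP:
            raise ValueError("resp record must be on channel RESP")
        if self.label not in (-1, 1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")


# ---------------------------------------------------------------------------
# Waveform I/O
# ---------------------------------------------------------------------------

def write_record(record: WaveformRecord, path: str | Path) -> Path:
    """Write a single-channel waveform CSV; round-trips bit-exactly."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={record.fs!r}\n")
        fh.write(f"# channel={record.channel.value}\n")
        fh.write(f"# t0={record.t0!r}\n")
        fh.write("sample\n")
        for v in record.samples:
            fh.write(f"{float(v)!r}\n")
    return path


def _read_csv_record(path: Path) -> list[WaveformRecord]:
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                data_lines.append(line)
    if "fs" not in meta:
        raise ValueError(f"{path}: missing sampling rate (no 'fs=' metadata line)")
    if not data_lines:
        raise ValueError(f"{path}: empty signal")
    header = data_lines[0]
    body = data_lines[1:] if not _is_number(header) else data_lines
    if not body:
        raise ValueError(f"{path}: empty signal")
    samples = np.array([float(x) for x in body])
    channel = Channel(meta.get("channel", Channel.ECG_II.value))
    t0 = float(meta.get("t0", 0.0))
    return [WaveformRecord(samples=samples, fs=float(meta["fs"]), channel=channel, t0=t0)]


def _is_number(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def _read_edf_record(path: Path) -> list[WaveformRecord]:
    try:
        import pyedflib  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the optional 'pyedflib' package") from exc
    records = []
    with pyedflib.EdfReader(str(path)) as reader:  # pragma: no cover
        for i in range(reader.signals_in_file):
            label = reader.getLabel(i).upper()
            channel = Channel.RESP if "RESP" in label else Channel.ECG_II
            records.append(
                WaveformRecord(
                    samples=reader.readSignal(i),
                    fs=float(reader.getSampleFrequency(i)),
                    channel=channel,
                )
            )
    return records


def _read_wfdb_record(path: Path) -> list[WaveformRecord]:
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("WFDB support requires the optional 'wfdb' package") from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    records = []
    for i, name in enumerate(rec.sig_name):  # pragma: no cover
        channel = Channel.RESP if "RESP" in name.upper() else Channel.ECG_II
        records.append(
            WaveformRecord(samples=rec.p_signal[:, i], fs=float(rec.fs), channel=channel)
        )
    return records


_READERS = {"csv": _read_csv_record, "edf": _read_edf_record, "wfdb": _read_wfdb_record}


def read_record(path: str | Path, format: str = "csv") -> list[WaveformRecord]:
    """Read waveform record(s) from ``path``.

    Parameters
    ----------
    path:
        File (CSV/EDF) or record prefix (WFDB).
    format:
        One of ``csv`` (native format, always available), ``edf`` or
        ``wfdb`` (require optional dependencies).

    Returns
    -------
    list of :class:`WaveformRecord`, one per channel.
    """
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_READERS)}")
    path = Path(path)
    if format == "csv" and not path.exists():
        raise FileNotFoundError(path)
    return _READERS[format](path)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def write_feature_table(
    rows: Iterable[tuple[str, FeatureVector, int]], path: str | Path
) -> Path:
    """Write ``(source_id, FeatureVector, label)`` rows to CSV.

    Columns: ``source_id``, the 14 parameters in table order, ``label``.
    Values survive a read-back round trip to full double precision.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("empty feature table")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(("source_id", *FEATURE_NAMES, "label")) + "\n")
        for source_id, fv, label in rows:
            vals = ",".join(repr(float(getattr(fv, n))) for n in FEATURE_NAMES)
            fh.write(f"{source_id},{vals},{int(label)}\n")
    return path


def read_feature_table(path: str | Path) -> list[tuple[str, FeatureVector, int]]:
    """Read back a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path, dtype={"source_id": str}, float_precision="round_trip")
    expected = ["source_id", *FEATURE_NAMES, "label"]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected feature-table columns: {list(df.columns)}")
    out = []
    for _, row in df.iterrows():
        fv = FeatureVector(**{n: float(row[n]) for n in FEATURE_NAMES})
        out.append((str(row["source_id"]), fv, int(row["label"])))
    return out


def feature_frame(rows: Iterable[tuple[str, FeatureVector, int]]) -> pd.DataFrame:
    """Rows as a DataFrame with ``source_id`` index and ``label`` column."""
    records = {}
    labels = {}
    for source_id, fv, label in rows:
        records[source_id] = {n: getattr(fv, n) for n in FEATURE_NAMES}
        labels[source_id] = int(label)
    df = pd.DataFrame.from_dict(records, orient="index")
    df["label"] = pd.Series(labels)
    df.index.name = "source_id"
    return df
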