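"""Recording container and readers/writers for recordings and cohort tables.

Recordings are channels x samples arrays with a sampling rate and channel
labels. On-disk interchange uses plain CSV (one file per recording: first
column time in seconds, remaining columns one per channel) or EDF (read-only,
via :mod:`mne`). Cohort tables are CSV with one row per subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Classic 19-electrode subset of the international 10-20 montage.
MONTAGE_10_20 = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
]


@dataclass
class Recording:
    """A multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values (microvolts for EEG-like data; arbitrary units for
        simulated dynamical systems).
    fs : float
        Sampling rate in Hz. For discrete maps this is 1.0 (one sample per
        iteration).
    ch_names : list of str
        One label per channel.
    meta : dict
        Free-form provenance (generator name, parameters, subject id ...).
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be a positive finite number")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.ch_names.index(name)]


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """Write one recording as CSV: first column ``time_s``, one column per
    channel, header row with channel labels."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for name, row in zip(rec.ch_names, rec.data):
        df[name] = row
    df.to_csv(path, index=False)
    return path


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording from CSV or EDF.

    The format is inferred from the suffix unless ``fmt`` is given. CSV files
    must carry a ``time_s`` first column from which the sampling rate is
    recovered; EDF files are read through :func:`mne.io.read_raw_edf`.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown recording format: {fmt!r}")


def _read_csv(path: Path) -> Recording:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus >= 1 channel")
    tcol = df.columns[0]
    t = df[tcol].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    if df.isna().any().any():
        bad = [c for c in df.columns if df[c].isna().any()]
        raise ValueError(f"{path}: channel(s) {bad} have missing samples")
    names = list(df.columns[1:])
    data = df[names].to_numpy(dtype=float).T
    return Recording(data=data, fs=1.0 / dt[0], ch_names=names,
                     meta={"source": str(path), "format": "csv"})


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts; store microvolts
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     ch_names=list(raw.ch_names),
                     meta={"source": str(path), "format": "edf"})


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "age_months"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject ids in cohort table")
    return df


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def load_json(path: str | Path) -> dict:
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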