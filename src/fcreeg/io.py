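"""Reading multi-channel EEG recordings and persisting tabular results.

Recordings are channels x samples matrices.  The CSV layout is rows =
channels, columns = samples, with an optional first column of channel
names (self-describing; matches the plain-text layout of public
resting-state EEG archives).  EDF files are read through :mod:`mne`.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .montage import CANONICAL_CHANNELS, N_CHANNELS

GROUPS = ("SZ", "HC")


@dataclass
class EEGRecording:
    """One subject's labelled multi-channel resting-state EEG.

    data is a channels x samples float array; units are carried through
    unchanged (microvolts for the reference data, arbitrary for synthetic
    cohorts).
    """

    subject_id: str
    group: str
    channel_names: list[str]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"channel count mismatch: {self.data.shape[0]} rows vs "
                f"{len(self.channel_names)} channel names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _reorder_to_montage(names: Sequence[str], data: np.ndarray,
                        strict_montage: bool) -> tuple[list[str], np.ndarray]:
    """Reorder channel rows to the canonical montage.

    Values are never altered, only row order.  Under strict_montage the
    channel set must equal the canonical 16; the error names offenders.
    """
    names = [str(n).strip() for n in names]
    if strict_montage:
        missing = [c for c in CANONICAL_CHANNELS if c not in names]
        extra = [c for c in names if c not in CANONICAL_CHANNELS]
        if missing or extra:
            raise ValueError(
                "channel set does not match the canonical 16-channel montage: "
                f"missing={missing}, unexpected={extra}"
            )
        order = [names.index(c) for c in CANONICAL_CHANNELS]
        return list(CANONICAL_CHANNELS), data[order]
    return names, data


def read_recording(path: str | Path, format: str | None = None, *,
                   subject_id: str, group: str, fs: float | None = None,
                   strict_montage: bool = True) -> EEGRecording:
    """Read one subject's EEG from an EDF file or a CSV/TSV matrix.

    For CSV, ``fs`` must be supplied; for EDF it comes from the header.
    Rows are reordered to the canonical montage when channel names are
    available.  Short recordings are accepted here and rejected later by
    segmentation.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        return _read_edf(path, subject_id=subject_id, group=group,
                         strict_montage=strict_montage)
    if format == "csv":
        if fs is None:
            raise ValueError("fs must be supplied for CSV recordings")
        return _read_csv(path, subject_id=subject_id, group=group, fs=fs,
                         strict_montage=strict_montage)
    raise ValueError(f"unknown format {format!r}; expected 'edf' or 'csv'")


def _read_csv(path: Path, *, subject_id: str, group: str, fs: float,
              strict_montage: bool) -> EEGRecording:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, header=None, sep=sep,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise IOError(f"empty recording file: {path}") from None
    first_col = df.iloc[:, 0]
    has_names = first_col.dtype == object and not np.all(
        [_is_number(v) for v in first_col])
    if has_names:
        names = [str(v).strip() for v in first_col]
        body = df.iloc[:, 1:]
    else:
        if strict_montage and len(df) != N_CHANNELS:
            raise ValueError(
                f"{path}: expected {N_CHANNELS} channel rows, found {len(df)}")
        names = list(CANONICAL_CHANNELS[: len(df)]) if len(df) <= N_CHANNELS \
            else [f"ch{i}" for i in range(len(df))]
        body = df
    data = np.empty((len(body), body.shape[1]), dtype=float)
    for i in range(len(body)):
        for j, v in enumerate(body.iloc[i]):
            if not _is_number(v):
                raise ValueError(
                    f"{path}: non-numeric cell at row {i}, column {j}: {v!r}")
            data[i, j] = float(v)
    names, data = _reorder_to_montage(names, data, strict_montage)
    return EEGRecording(subject_id=subject_id, group=group,
                        channel_names=names, fs=float(fs), data=data)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _read_edf(path: Path, *, subject_id: str, group: str,
              strict_montage: bool) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts; EEG convention is microvolts
    names, data = _reorder_to_montage(list(raw.ch_names), data, strict_montage)
    return EEGRecording(subject_id=subject_id, group=group,
                        channel_names=names, fs=float(raw.info["sfreq"]),
                        data=data)


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as CSV (channel-name first column, %.17g floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, row in zip(rec.channel_names, rec.data):
            fh.write(name + "," + ",".join(f"{v:.17g}" for v in row) + "\n")
    return path


def save_table(records: Iterable, path: str | Path) -> Path:
    """Persist a homogeneous list of result dataclasses as CSV.

    Column order is the dataclass field order; floats carry >= 6
    significant digits so a re-load reproduces values to serialization
    precision.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    first_type = type(records[0])
    if not dataclasses.is_dataclass(records[0]):
        raise ValueError("records must be dataclass instances")
    if any(type(r) is not first_type for r in records):
        raise ValueError("records must all be of the same type")
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        rows.append({k: v for k, v in d.items()
                     if np.ndim(v) == 0})  # scalar fields only
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        df.to_csv(path, index=False, float_format="%.10g")
    except OSError as exc:
        raise IOError(f"cannot write table to {path}: {exc}") from exc
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    """Load a table written by :func:`save_table`."""
    return pd.read_csv(path)
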