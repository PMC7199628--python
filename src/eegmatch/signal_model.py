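"""Core data containers and plain-text I/O for labeled EEG segments.

An :class:`EEGSegment` is one fixed-length window of a single-channel
recording together with its sampling rate and a clinical label.  A
:class:`Dataset` is a homogeneous collection of such segments (all sharing
one sampling rate) plus free-form provenance metadata.

Two on-disk layouts are supported, both plain CSV:

``per-file``
    a directory containing ``manifest.csv`` (columns ``filename,label,fs``)
    and one single-column file of sample values per segment.

``long``
    a single table with columns ``segment_id,sample_index,value`` plus a
    sibling ``manifest.csv`` (columns ``segment_id,label,fs``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "EEGSegment",
    "Dataset",
    "load_csv_dataset",
    "write_csv_dataset",
    "segment_signal",
    "load_edf_segment",
]

LABELS = ("normal", "abnormal", "unknown")

# full round-trip precision for float64 in decimal text
_FLOAT_FMT = "%.17g"


@dataclass
class EEGSegment:
    """One labeled single-channel EEG window.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    samples : array-like of float
        Sample values (microvolts or any consistent amplitude unit).
    fs : float
        Sampling rate in Hz; must be positive.
    label : {"normal", "abnormal", "unknown"}
        Ground-truth status of the window.
    """

    id: str
    samples: np.ndarray
    fs: float
    label: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError(f"segment {self.id!r}: samples must be 1-D")
        if self.samples.size < 2:
            raise ValueError(f"segment {self.id!r}: need at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(
                f"segment {self.id!r}: non-finite sample at index {bad}"
            )
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"segment {self.id!r}: fs must be positive, got {self.fs}")
        if self.label not in LABELS:
            raise ValueError(
                f"segment {self.id!r}: label {self.label!r} not in {LABELS}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Window length in seconds."""
        return self.samples.size / self.fs


@dataclass
class Dataset:
    """A collection of EEG segments sharing one sampling rate."""

    segments: list[EEGSegment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = {s.fs for s in self.segments}
        if len(rates) > 1:
            raise ValueError(f"inconsistent sampling rates across segments: {sorted(rates)}")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids in dataset")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    @property
    def fs(self) -> float:
        if not self.segments:
            raise ValueError("empty dataset has no sampling rate")
        return self.segments[0].fs

    def with_label(self, label: str) -> list[EEGSegment]:
        return [s for s in self.segments if s.label == label]

    def get(self, segment_id: str) -> EEGSegment:
        for s in self.segments:
            if s.id == segment_id:
                return s
        raise KeyError(segment_id)


def _read_sample_column(path: Path) -> np.ndarray:
    frame = pd.read_csv(path, header=None, float_precision="round_trip")
    if frame.shape[1] != 1:
        raise ValueError(f"{path}: expected a single column of samples")
    values = pd.to_numeric(frame.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"{path}: non-finite or unparseable value at row {int(bad[0])}")
    return values


def load_csv_dataset(
    path: str | Path,
    layout: str = "per-file",
    manifest: str | Path | None = None,
) -> Dataset:
    """Load a labeled EEG dataset from plain CSV files.

    Parameters
    ----------
    path : path
        Directory (``per-file`` layout) or long-table CSV file (``long``).
    layout : {"per-file", "long"}
    manifest : path, optional
        Manifest CSV; defaults to ``manifest.csv`` inside/next to *path*.
    """
    path = Path(path)
    if layout == "per-file":
        if not path.is_dir():
            raise FileNotFoundError(f"dataset directory not found: {path}")
        mpath = Path(manifest) if manifest else path / "manifest.csv"
        if not mpath.is_file():
            raise FileNotFoundError(f"manifest not found: {mpath}")
        man = pd.read_csv(mpath)
        _require_columns(man, mpath, ["filename", "label", "fs"])
        segments = []
        for row in man.itertuples(index=False):
            fpath = path / str(row.filename)
            if not fpath.is_file():
                raise FileNotFoundError(f"segment file not found: {fpath}")
            samples = _read_sample_column(fpath)
            segments.append(
                EEGSegment(id=Path(str(row.filename)).stem, samples=samples,
                           fs=float(row.fs), label=str(row.label))
            )
        return Dataset(segments, metadata={"source": str(path), "layout": layout})

    if layout == "long":
        if not path.is_file():
            raise FileNotFoundError(f"long-table file not found: {path}")
        mpath = Path(manifest) if manifest else path.parent / "manifest.csv"
        if not mpath.is_file():
            raise FileNotFoundError(f"manifest not found: {mpath}")
        man = pd.read_csv(mpath)
        _require_columns(man, mpath, ["segment_id", "label", "fs"])
        table = pd.read_csv(path, float_precision="round_trip")
        _require_columns(table, path, ["segment_id", "sample_index", "value"])
        meta = {str(r.segment_id): (str(r.label), float(r.fs))
                for r in man.itertuples(index=False)}
        segments = []
        for seg_id, group in table.groupby("segment_id", sort=True):
            seg_id = str(seg_id)
            if seg_id not in meta:
                raise ValueError(f"{path}: segment {seg_id!r} missing from manifest {mpath}")
            group = group.sort_values("sample_index")
            values = pd.to_numeric(group["value"], errors="coerce").to_numpy(dtype=float)
            bad = np.flatnonzero(~np.isfinite(values))
            if bad.size:
                row = int(group.index[bad[0]])
                raise ValueError(
                    f"{path}: non-finite or unparseable value for segment "
                    f"{seg_id!r} at table row {row}"
                )
            label, fs = meta[seg_id]
            segments.append(EEGSegment(id=seg_id, samples=values, fs=fs, label=label))
        return Dataset(segments, metadata={"source": str(path), "layout": layout})

    raise ValueError(f"unknown layout {layout!r}; expected 'per-file' or 'long'")


def _require_columns(frame: pd.DataFrame, path: Path, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def write_csv_dataset(dataset: Dataset, path: str | Path, layout: str = "per-file") -> Path:
    """Write a dataset to disk in one of the CSV layouts; returns the manifest path."""
    path = Path(path)
    if layout == "per-file":
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for seg in dataset:
            fname = f"{seg.id}.csv"
            np.savetxt(path / fname, seg.samples, fmt=_FLOAT_FMT)
            rows.append({"filename": fname, "label": seg.label, "fs": seg.fs})
        mpath = path / "manifest.csv"
        pd.DataFrame(rows, columns=["filename", "label", "fs"]).to_csv(mpath, index=False)
        return mpath

    if layout == "long":
        path.parent.mkdir(parents=True, exist_ok=True)
        chunks = []
        rows = []
        for seg in dataset:
            chunks.append(pd.DataFrame({
                "segment_id": seg.id,
                "sample_index": np.arange(seg.n_samples),
                "value": seg.samples,
            }))
            rows.append({"segment_id": seg.id, "label": seg.label, "fs": seg.fs})
        pd.concat(chunks, ignore_index=True).to_csv(
            path, index=False, float_format=_FLOAT_FMT)
        mpath = path.parent / "manifest.csv"
        pd.DataFrame(rows, columns=["segment_id", "label", "fs"]).to_csv(mpath, index=False)
        return mpath

    raise ValueError(f"unknown layout {layout!r}; expected 'per-file' or 'long'")


def segment_signal(
    signal: Iterable[float],
    fs: float,
    window_samples: int,
    overlap_samples: int = 0,
    label: str = "unknown",
    id_prefix: str = "seg",
) -> list[EEGSegment]:
    """Cut a long recording into fixed-length windows.

    Windows advance by ``window_samples - overlap_samples``; a trailing
    partial window is discarded.  With zero overlap the windows tile the
    first ``floor(len/window) * window`` samples exactly.
    """
    signal = np.asarray(signal, dtype=float)
    if window_samples <= 0:
        raise ValueError("window_samples must be positive")
    if not 0 <= overlap_samples < window_samples:
        raise ValueError("overlap_samples must satisfy 0 <= overlap < window")
    if window_samples > signal.size:
        raise ValueError(
            f"window of {window_samples} samples exceeds signal length {signal.size}"
        )
    step = window_samples - overlap_samples
    starts = range(0, signal.size - window_samples + 1, step)
    return [
        EEGSegment(
            id=f"{id_prefix}-{k:04d}",
            samples=signal[s: s + window_samples],
            fs=fs,
            label=label,
        )
        for k, s in enumerate(starts)
    ]


def load_edf_segment(path: str | Path, channel: str, label: str = "unknown") -> EEGSegment:
    """Read one channel from an EDF recording (requires the optional ``mne`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF support requires the optional dependency 'mne' "
            "(install with: pip install eegmatch[edf])"
        ) from exc
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    if channel not in raw.ch_names:  # pragma: no cover - depends on file contents
        raise ValueError(f"{path}: channel {channel!r} not present")
    data = raw.get_data(picks=[channel])[0]
    return EEGSegment(id=f"{path.stem}:{channel}", samples=data,
                      fs=float(raw.info["sfreq"]), label=label)
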