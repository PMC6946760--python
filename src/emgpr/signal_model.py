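"""Core data containers for multi-channel surface EMG sessions.

A :class:`Recording` holds the raw channel-by-sample matrix together with its
sampling rate and a :class:`MovementSchedule` — the ordered list of labelled
contraction (and rest) intervals.  Windowing a recording produces a
:class:`WindowSet`; feature extraction turns a window set into a
:class:`FeatureMatrix` whose columns are named ``block.feature.index``.

File formats
------------
* Recording CSV: a leading comment line ``# fs=<Hz>``, then one row per
  sample with one column per channel.
* Recording WAV: multi-channel PCM or float WAV (sampling rate from the
  header), read/written with :mod:`scipy.io.wavfile`.
* Schedule sidecar CSV: header ``class,start,end`` with half-open, 0-based
  sample intervals.
* Feature CSV: header of ``block.feature.index`` names plus a final
  ``label`` column, one row per window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "ScheduleEntry",
    "MovementSchedule",
    "Recording",
    "WindowSet",
    "FeatureColumn",
    "FeatureMatrix",
    "read_recording",
    "write_recording",
    "read_schedule",
    "write_schedule",
    "read_feature_matrix",
    "write_feature_matrix",
]

#: The 11-class movement vocabulary (10 hand/wrist movements plus rest).
MOVEMENT_CLASSES = (
    "open hand",
    "close hand",
    "flex hand",
    "extend hand",
    "pronation",
    "supination",
    "side grip",
    "fine grip",
    "agree",
    "pointer",
    "rest",
)


class FormatError(ValueError):
    """Raised when an input file does not follow the documented dialect."""


class ValidationError(ValueError):
    """Raised when data violate a container invariant."""


class ScheduleEntry(NamedTuple):
    label: str
    start: int
    end: int


@dataclass(frozen=True)
class MovementSchedule:
    """Ordered, non-overlapping labelled sample intervals.

    Intervals are half-open ``[start, end)`` with 0-based sample indices.
    """

    entries: tuple[ScheduleEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(ScheduleEntry(str(l), int(s), int(e)) for l, s, e in self.entries)
        object.__setattr__(self, "entries", entries)
        prev_end = -1
        for ent in entries:
            if not 0 <= ent.start < ent.end:
                raise ValidationError(f"bad interval {ent}")
            if ent.start < prev_end:
                raise ValidationError(f"overlapping or unsorted schedule at {ent}")
            prev_end = ent.end

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass
class Recording:
    """A multi-channel EMG recording (channels x samples, millivolts)."""

    samples: np.ndarray
    fs: float
    schedule: MovementSchedule
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a channels x n_samples matrix")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValidationError("need at least one channel and one sample")
        if not self.fs > 0:
            raise ValidationError("fs must be positive")
        if self.schedule.entries and self.schedule.entries[-1].end > self.n_samples:
            raise ValidationError("schedule extends past the recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class WindowSet:
    """Fixed-length labelled analysis windows cut from one recording.

    ``windows`` is a ``w x channels x N`` tensor.  ``entry_index`` records
    which schedule entry each window came from, preserving within-entry
    window order (needed by sequence features such as the MAV slope).
    """

    windows: np.ndarray
    labels: np.ndarray
    N: int
    step: int
    fs: float
    entry_index: np.ndarray

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.entry_index = np.asarray(self.entry_index, dtype=int)
        if self.windows.ndim != 3:
            raise ValidationError("windows must be w x channels x N")
        if self.windows.shape[2] != self.N:
            raise ValidationError("window length mismatch")
        if len(self.labels) != self.windows.shape[0]:
            raise ValidationError("one label per window required")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]


class FeatureColumn(NamedTuple):
    block: str
    feature: str
    index: str

    @property
    def name(self) -> str:
        return f"{self.block}.{self.feature}.{self.index}"


@dataclass
class FeatureMatrix:
    """Windows x named feature columns, plus one class label per window."""

    values: np.ndarray
    columns: tuple[FeatureColumn, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.columns = tuple(FeatureColumn(*c) for c in self.columns)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D")
        if self.values.shape[1] != len(self.columns):
            raise ValidationError("column count mismatch")
        if self.values.shape[0] != len(self.labels):
            raise ValidationError("one label per row required")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    def select_columns(self, mask: np.ndarray) -> "FeatureMatrix":
        cols = tuple(c for c, m in zip(self.columns, mask) if m)
        return FeatureMatrix(self.values[:, np.asarray(mask, bool)], cols, self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "wav"):
        return suffix
    raise FormatError(f"cannot infer format from {path.name!r}; pass format=")


def read_schedule(path: str | Path) -> MovementSchedule:
    """Read a schedule sidecar CSV with columns ``class,start,end``."""
    df = pd.read_csv(path)
    expected = ["class", "start", "end"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"schedule must have columns {expected}, got {list(df.columns)}")
    entries = [ScheduleEntry(str(r["class"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()]
    return MovementSchedule(tuple(entries))


def write_schedule(schedule: MovementSchedule, path: str | Path) -> None:
    df = pd.DataFrame(schedule.entries, columns=["class", "start", "end"])
    df.to_csv(path, index=False)


def read_recording(
    path: str | Path,
    format: str | None = None,
    schedule: str | Path | MovementSchedule | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a recording from CSV or multi-channel WAV.

    ``schedule`` may be a sidecar CSV path or an in-memory schedule; if
    omitted, the whole recording becomes a single unlabelled entry-free
    schedule.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path) as fh:
            header = fh.readline().strip()
        if not header.startswith("#") or "fs=" not in header:
            raise FormatError("recording CSV must start with a '# fs=<Hz>' comment line")
        try:
            fs = float(header.split("fs=")[1].split()[0].rstrip(","))
        except (IndexError, ValueError) as exc:
            raise FormatError(f"malformed fs header {header!r}") from exc
        data = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        samples = data.T  # file has one column per channel
    elif fmt == "wav":
        fs, data = wavfile.read(path)
        data = np.asarray(data, dtype=float)
        if data.dtype.kind != "f":
            data = data.astype(float)
        if data.ndim == 1:
            data = data[:, None]
        samples = data.T
    else:
        raise FormatError(f"unsupported format {fmt!r}")

    if schedule is None:
        sched = MovementSchedule(())
    elif isinstance(schedule, MovementSchedule):
        sched = schedule
    else:
        sched = read_schedule(schedule)
    return Recording(samples, float(fs), sched, subject_id or path.stem)


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording to CSV (full precision) or float32 WAV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(f"# fs={rec.fs:.10g}\n")
            np.savetxt(fh, rec.samples.T, delimiter=",", fmt="%.17g")
    elif fmt == "wav":
        wavfile.write(path, int(round(rec.fs)), rec.samples.T.astype(np.float32))
    else:
        raise FormatError(f"unsupported format {fmt!r}")


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: header, one row per window, final label column."""
    with open(Path(path), "w") as fh:
        fh.write(",".join(fm.column_names + ["label"]) + "\n")
        for row, label in zip(fm.values, fm.labels):
            fh.write(",".join(f"{v:.17g}" for v in row) + f",{label}\n")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    if df.shape[1] < 1 or df.columns[-1] != "label":
        raise FormatError("feature CSV must end with a 'label' column")
    cols = []
    for name in df.columns[:-1]:
        parts = name.split(".")
        if len(parts) != 3:
            raise FormatError(f"bad feature column name {name!r} (want block.feature.index)")
        cols.append(FeatureColumn(*parts))
    values = df.iloc[:, :-1].to_numpy(dtype=float) if len(cols) else np.empty((len(df), 0))
    return FeatureMatrix(values, tuple(cols), df["label"].to_numpy(dtype=object))
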