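"""Readers and writers for bilateral functional TCD recordings.

A recording holds the left and right middle-cerebral-artery blood-flow
velocity traces plus a numeric event-marker channel, uniformly sampled
(100 Hz on the Multi-Dop / DopplerBox class of devices this dialect
mirrors).  Two on-disk dialects are supported:

``canonical-tsv``
    Tab-separated with header ``time  left  right  marker``; the format
    this package writes.  Values round-trip exactly (17 significant
    digits).

``exp-export``
    Tolerant reader for device text exports: any metadata lines are
    skipped and the first four columns of the numeric block are taken as
    time, left, right, marker.

All tabular outputs are UTF-8 CSV with '.' as the decimal separator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("time", "left", "right", "marker")

#: relative tolerance on the uniformity of the time axis (seconds)
TIME_TOLERANCE_S = 1e-6


class FormatError(ValueError):
    """The file does not conform to the expected dialect."""


class ParseError(ValueError):
    """The file parsed but its content violates a recording invariant."""


class EmptyRecordingError(ValueError):
    """Fewer than two samples: no recording can be built."""


@dataclass
class RawRecording:
    """Two-channel Doppler velocity time series with an event channel.

    Velocities are in device units (arbitrary, proportional to cm/s);
    ``meta`` carries participant id, language label, task label and
    paradigm id where known.
    """

    sample_rate: float
    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    marker: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.marker = np.asarray(self.marker, dtype=float)
        n = self.time.size
        if n < 2:
            raise EmptyRecordingError(f"recording has {n} samples; need >= 2")
        for name in ("left", "right", "marker"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ParseError(
                    f"channel '{name}' has {arr.size} samples, time has {n}"
                )
            if np.isnan(arr).any():
                raise ParseError(f"channel '{name}' contains NaN")
        if np.isnan(self.time).any():
            raise ParseError("time axis contains NaN")
        if self.sample_rate <= 0:
            raise ParseError(f"sample_rate must be > 0, got {self.sample_rate}")
        steps = np.diff(self.time)
        bad = np.nonzero(steps <= 0)[0]
        if bad.size:
            raise ParseError(f"non-monotonic time axis at row {bad[0] + 1}")
        expected = 1.0 / self.sample_rate
        if np.max(np.abs(steps - expected)) > TIME_TOLERANCE_S:
            raise ParseError(
                "time axis is not uniform at the stated sample rate "
                f"({self.sample_rate} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0]) + 1.0 / self.sample_rate


@dataclass(frozen=True)
class TrialMarker:
    """A single event-marker onset (rising edge of the marker channel)."""

    sample_index: int
    onset_s: float
    code: int = 1


def _infer_rate(time: np.ndarray) -> float:
    steps = np.diff(time)
    good = steps[steps > 0]
    if good.size == 0:
        raise ParseError("cannot infer sample rate: no positive time steps")
    return float(1.0 / np.median(good))


def read_raw(path, dialect: str = "canonical-tsv") -> RawRecording:
    """Read a bilateral Doppler recording from ``path``.

    Parameters
    ----------
    path : path-like
        Input file.
    dialect : {'canonical-tsv', 'exp-export'}
        On-disk dialect (see module docstring).

    Returns
    -------
    RawRecording
        With ``sample_rate`` inferred from the median time step.
    """
    path = Path(path)
    if dialect == "canonical-tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        df.columns = [str(c).strip().lower() for c in df.columns]
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing column '{col}' in {path.name}")
        cols = {c: df[c].to_numpy(dtype=float) for c in CANONICAL_COLUMNS}
    elif dialect == "exp-export":
        rows = []
        with open(path, encoding="utf-8", errors="replace") as fh:
            for line in fh:
                parts = line.replace(",", " ").split()
                if len(parts) < 4:
                    continue
                try:
                    vals = [float(p) for p in parts[:4]]
                except ValueError:
                    continue
                rows.append(vals)
        if len(rows) < 2:
            raise EmptyRecordingError(
                f"{path.name}: fewer than 2 numeric samples found"
            )
        arr = np.asarray(rows, dtype=float)
        cols = dict(zip(CANONICAL_COLUMNS, arr.T))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if cols["time"].size < 2:
        raise EmptyRecordingError(f"{path.name}: fewer than 2 samples")
    if np.isnan(np.concatenate(list(cols.values()))).any():
        raise ParseError(f"{path.name}: unreadable (NaN) samples")
    rate = _infer_rate(cols["time"])
    meta = dict(path=str(path))
    meta.update(parse_dataset_name(path.stem))
    return RawRecording(
        sample_rate=rate,
        time=cols["time"],
        left=cols["left"],
        right=cols["right"],
        marker=cols["marker"],
        meta=meta,
    )


def write_raw(rec: RawRecording, path) -> Path:
    """Write ``rec`` as canonical TSV (exact round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in zip(rec.time, rec.left, rec.right, rec.marker):
            fh.write("\t".join(format(v, ".17g") for v in row) + "\n")
    return path


def parse_dataset_name(stem: str) -> dict:
    """Parse ``<participant>_<language>_<task>`` from a file stem.

    Returns an empty dict when the stem does not match.
    """
    parts = stem.split("_")
    if len(parts) >= 3:
        return {
            "participant": parts[0],
            "language": parts[1],
            "task": "_".join(parts[2:]),
        }
    return {}


def extract_markers(
    rec: RawRecording, threshold: float = 1.0, min_gap_s: float = 10.0
) -> list[TrialMarker]:
    """Detect trial onsets as rising edges of the marker channel.

    An onset is a sample where the marker crosses from below ``threshold``
    to at or above it, debounced so successive onsets are at least
    ``min_gap_s`` apart.  A marker channel already high at sample 0 counts
    as an onset at 0 (acquisition started mid-pulse).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_gap_s < 0:
        raise ValueError("min_gap_s must be >= 0")
    high = rec.marker >= threshold
    rising = np.nonzero(high[1:] & ~high[:-1])[0] + 1
    if high[0]:
        rising = np.concatenate([[0], rising])
    markers: list[TrialMarker] = []
    last = -np.inf
    for idx in rising:
        onset = idx / rec.sample_rate
        if onset - last >= min_gap_s:
            markers.append(TrialMarker(int(idx), float(onset)))
            last = onset
    if not markers:
        logger.warning("no event markers found (threshold=%s)", threshold)
    return markers


# ---------------------------------------------------------------------------
# tabular outputs

SUMMARY_COLUMNS = [
    "task",
    "language",
    "n_participants",
    "mean_trials",
    "mean_li",
    "se_li",
    "pct_left",
    "pct_bilateral",
    "pct_right",
]


def summarize_participants(participants: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary, one row per (task, language).

    Columns mirror the conventional per-condition laterality table: mean
    usable trials, mean LI, SE of the mean LI across participants, and
    the percentage of participants in each laterality category.  Excluded
    participants (too few trials or SE outliers) do not contribute.
    """
    if participants.empty:
        raise ValueError("no participant results to summarize")
    kept = participants[~participants["excluded"]]
    if kept.empty:
        raise ValueError("all participants are excluded")
    rows = []
    for (task, language), grp in kept.groupby(["task", "language"], sort=True):
        n = len(grp)
        cats = grp["category"].value_counts()
        rows.append(
            {
                "task": task,
                "language": language,
                "n_participants": n,
                "mean_trials": grp["n_usable_trials"].mean(),
                "mean_li": grp["li_mean"].mean(),
                "se_li": grp["li_mean"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "pct_left": 100.0 * cats.get("left", 0) / n,
                "pct_bilateral": 100.0 * cats.get("bilateral", 0) / n,
                "pct_right": 100.0 * cats.get("right", 0) / n,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_cohort_table(participants: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write ``cohort_summary.csv`` and ``participants.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = summarize_participants(participants)
    paths = {
        "cohort_summary": out_dir / "cohort_summary.csv",
        "participants": out_dir / "participants.csv",
    }
    summary.to_csv(paths["cohort_summary"], index=False)
    participants.to_csv(paths["participants"], index=False)
    return paths


def write_trials_table(trials: pd.DataFrame, out_dir) -> Path:
    """Write the per-trial long table (``trials.csv``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "trials.csv"
    trials.to_csv(path, index=False)
    return path


def read_exclusion_file(path) -> list[int]:
    """Read a manual trial-exclusion sidecar: one 0-based index per line."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                out.append(int(line))
    return out


def write_exclusion_file(indices, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{int(i)}\n" for i in indices), encoding="utf-8")
    return path
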