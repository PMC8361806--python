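"""The eight-step CBFV preprocessing chain.

Raw bilateral blood-flow-velocity recordings are turned into
artifact-screened, normalized, heart-cycle-integrated, baseline-corrected
epochs:

1. downsample (block means, 100 -> 25 Hz)
2. epochize relative to the "Clear Mind" cue
3. manual exclusion of trials with obvious spiking/dropout artifacts
4. automated extreme-value screening (0.0001-0.999 empirical quantiles;
   one extreme sample -> replaced by the trial/channel mean, two or
   more -> trial excluded)
5. normalization of each channel to a grand mean of 100
6. heart-cycle integration (peak-to-peak averaging of the cardiac pulse)
7. baseline correction (mean over -10..0 s subtracted per trial/channel)
8. rejection of trials with normalized values outside 60-140

Each step is a pure function of (EpochSet, config).  Steps must be
applied in order; the ``stage`` field makes the runner refuse
out-of-order application.  Exclusion is monotone: no step re-includes a
previously excluded trial.  Note on step 8: although listed after
baseline correction, the 60-140 window can only refer to the normalized
(mean-100) scale, so the screen is evaluated on the pre-baseline values,
which :func:`baseline_correct` snapshots for that purpose.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import find_peaks

from .io import RawRecording, TrialMarker

logger = logging.getLogger(__name__)

LEFT, RIGHT = 0, 1
CHANNEL_NAMES = ("left", "right")

#: processing stages in mandatory order
STAGES = (
    "epoched",
    "manual",
    "screened",
    "normalized",
    "integrated",
    "baselined",
    "ranged",
)
_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}

#: exclusion reason codes
REASONS = ("manual", "multi-extreme", "no-pulse", "out-of-range")


class PipelineOrderError(RuntimeError):
    """A preprocessing step was applied out of order."""


@dataclass
class ParadigmConfig:
    """Timing and screening parameters of one word-generation paradigm.

    All times are seconds relative to the onset of the "Clear Mind"
    cue.  ``marker_offset_s`` is the delay from that cue to the event the
    device actually flagged (the letter cue, 5 s, in the covert study-1
    paradigm; the cue stimulus, 3 s, in the overt study-2 paradigm).
    """

    name: str = "study1_wordgen"
    epoch_start_s: float = -11.0
    epoch_end_s: float = 30.0
    baseline: tuple[float, float] = (-10.0, 0.0)
    poi: tuple[float, float] = (8.0, 20.0)
    marker_offset_s: float = 5.0
    target_rate: float = 25.0
    extreme_quantiles: tuple[float, float] = (0.0001, 0.999)
    range_limits: tuple[float, float] = (60.0, 140.0)
    min_trials: int = 15
    min_hr_bpm: float = 40.0
    max_hr_bpm: float = 150.0
    heart_integration: bool = True
    marker_threshold: float = 1.0
    marker_min_gap_s: float = 10.0

    def __post_init__(self) -> None:
        b0, b1 = self.baseline
        p0, p1 = self.poi
        if not (self.epoch_start_s < b0 < b1 <= p0 < p1 <= self.epoch_end_s):
            raise ValueError(
                "window order must be epoch_start < baseline < poi <= epoch_end"
            )
        q0, q1 = self.extreme_quantiles
        if not 0 <= q0 < q1 <= 1:
            raise ValueError("extreme_quantiles must satisfy 0 <= lo < hi <= 1")
        lo, hi = self.range_limits
        if not lo < hi:
            raise ValueError("range_limits must satisfy lo < hi")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")
        if not 0 < self.min_hr_bpm < self.max_hr_bpm:
            raise ValueError("need 0 < min_hr_bpm < max_hr_bpm")

    def to_file(self, path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
        return path

    @classmethod
    def from_file(cls, path) -> "ParadigmConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for k in ("baseline", "poi", "extreme_quantiles", "range_limits"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


#: shipped presets
STUDY1_WORDGEN = ParadigmConfig()
STUDY2_FLUENCY = ParadigmConfig(
    name="study2_fluency",
    epoch_end_s=26.0,
    poi=(6.0, 20.0),
    marker_offset_s=3.0,
)
PARADIGMS = {p.name: p for p in (STUDY1_WORDGEN, STUDY2_FLUENCY)}


def get_paradigm(name: str) -> ParadigmConfig:
    try:
        return dataclasses.replace(PARADIGMS[name])
    except KeyError:
        raise ValueError(
            f"unknown paradigm {name!r}; available: {sorted(PARADIGMS)}"
        ) from None


@dataclass
class EpochSet:
    """Trials x time x {left, right} array of velocities with flags.

    ``time_axis`` is seconds relative to the "Clear Mind" onset.
    ``included`` and ``reasons`` track trial exclusions; excluded trials
    keep their data (transformed alongside, for diagnostics) but never
    re-enter any statistic.  ``prebaseline`` holds the normalized,
    pre-baseline-corrected values once step 7 has run (used by step 8).
    """

    data: np.ndarray
    time_axis: np.ndarray
    included: np.ndarray
    reasons: list
    stage: str
    sample_rate: float
    prebaseline: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 2:
            raise ValueError("data must be (trials, timepoints, 2)")
        self.included = np.asarray(self.included, dtype=bool)
        if self.stage not in _STAGE_INDEX:
            raise ValueError(f"unknown stage {self.stage!r}")
        step = np.diff(self.time_axis)
        if step.size and np.max(np.abs(step - 1.0 / self.sample_rate)) > 1e-9:
            raise ValueError("time axis spacing must be 1/sample_rate")

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            time_axis=self.time_axis.copy(),
            included=self.included.copy(),
            reasons=list(self.reasons),
            stage=self.stage,
            sample_rate=self.sample_rate,
            prebaseline=None if self.prebaseline is None else self.prebaseline.copy(),
            meta=dict(self.meta),
        )

    def exclusion_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in REASONS}
        for r in self.reasons:
            if r is not None:
                counts[r] = counts.get(r, 0) + 1
        counts["included"] = self.n_included
        return counts


def _advance(es: EpochSet, new_stage: str, allow_rerun: bool = True) -> EpochSet:
    """Stage bookkeeping: refuse out-of-order (backwards) application."""
    cur, new = _STAGE_INDEX[es.stage], _STAGE_INDEX[new_stage]
    if cur > new or (cur == new and not allow_rerun):
        raise PipelineOrderError(
            f"cannot apply step '{new_stage}' to an EpochSet at stage "
            f"'{es.stage}': steps must run in order {STAGES}"
        )
    out = es.copy()
    out.stage = new_stage
    return out


def _exclude(es: EpochSet, idx: int, reason: str) -> None:
    if es.included[idx]:
        es.included[idx] = False
        es.reasons[idx] = reason


# ---------------------------------------------------------------------------
# step 1: downsampling


def downsample(rec: RawRecording, target_rate: float) -> RawRecording:
    """Block-mean downsampling; the marker channel uses block max.

    Each output sample is the mean of ``sample_rate/target_rate``
    consecutive input samples (this is also a crude anti-alias filter);
    the marker channel takes the block maximum so no rising edge is lost.
    """
    ratio = rec.sample_rate / target_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"sample rate {rec.sample_rate} Hz is not an integer multiple of "
            f"{target_rate} Hz; resample externally first"
        )
    ratio = int(round(ratio))
    if ratio == 1:
        return rec
    n_blocks = rec.n_samples // ratio
    if n_blocks < 2:
        raise ValueError("recording too short to downsample")

    def block(x, reduce):
        return reduce(x[: n_blocks * ratio].reshape(n_blocks, ratio), axis=1)

    return RawRecording(
        sample_rate=target_rate,
        time=block(rec.time, np.min),
        left=block(rec.left, np.mean),
        right=block(rec.right, np.mean),
        marker=block(rec.marker, np.max),
        meta=dict(rec.meta),
    )


# ---------------------------------------------------------------------------
# step 2: epoching


def epochize(
    rec: RawRecording, markers: list[TrialMarker], cfg: ParadigmConfig
) -> EpochSet:
    """Cut one epoch per event marker, anchored at the "Clear Mind" onset.

    The cue onset is ``marker.onset_s - cfg.marker_offset_s``; the epoch
    covers ``[epoch_start_s, epoch_end_s)`` around it.  Epochs extending
    past the recording are dropped with a warning.
    """
    if not markers:
        raise ValueError("no markers: cannot epoch")
    rate = rec.sample_rate
    n_pts = int(round((cfg.epoch_end_s - cfg.epoch_start_s) * rate))
    t0 = float(rec.time[0])
    epochs, dropped = [], 0
    for m in markers:
        cue = m.onset_s - cfg.marker_offset_s
        i0 = int(round((cue + cfg.epoch_start_s - t0) * rate))
        if i0 < 0 or i0 + n_pts > rec.n_samples:
            dropped += 1
            logger.warning(
                "epoch at marker %.2f s extends past the recording; dropped",
                m.onset_s,
            )
            continue
        epochs.append(
            np.stack([rec.left[i0 : i0 + n_pts], rec.right[i0 : i0 + n_pts]], axis=1)
        )
    if not epochs:
        raise ValueError("all epochs fall outside the recording")
    data = np.stack(epochs)
    time_axis = cfg.epoch_start_s + np.arange(n_pts) / rate
    return EpochSet(
        data=data,
        time_axis=time_axis,
        included=np.ones(len(epochs), dtype=bool),
        reasons=[None] * len(epochs),
        stage="epoched",
        sample_rate=rate,
        meta={**rec.meta, "dropped_epochs": dropped, "n_markers": len(markers)},
    )


# ---------------------------------------------------------------------------
# step 3: manual exclusions


def apply_manual_exclusions(es: EpochSet, excluded_trials) -> EpochSet:
    """Flag the listed trial indices as excluded (reason ``manual``).

    ``excluded_trials`` are 0-based indices in presentation order, e.g.
    loaded from a per-participant sidecar file so deposited exclusion
    lists can reproduce a study run.
    """
    out = _advance(es, "manual")
    for idx in excluded_trials:
        idx = int(idx)
        if idx < 0 or idx >= out.n_trials:
            raise IndexError(
                f"manual exclusion index {idx} out of range (n={out.n_trials})"
            )
        _exclude(out, idx, "manual")
    return out


# ---------------------------------------------------------------------------
# step 4: extreme-value screening


def screen_extremes(es: EpochSet, cfg: ParadigmConfig) -> EpochSet:
    """Flag samples beyond the per-channel extreme quantiles.

    Thresholds are the empirical (linear-interpolation) quantiles over
    all samples of all currently included trials, per channel.  A trial
    with exactly one extreme sample (across both channels) has that
    sample replaced by the mean of that trial's epoch for that channel,
    computed excluding the extreme sample itself; a trial with two or
    more is excluded with reason ``multi-extreme``.
    """
    out = _advance(es, "screened")
    if out.n_included == 0:
        raise ValueError("no included trials to screen")
    if cfg.extreme_quantiles is None:
        return out
    qlo, qhi = cfg.extreme_quantiles
    pool = out.data[out.included]  # (n_inc, t, 2)
    lo = np.quantile(pool.reshape(-1, 2), qlo, axis=0)
    hi = np.quantile(pool.reshape(-1, 2), qhi, axis=0)
    for i in range(out.n_trials):
        if not out.included[i]:
            continue
        trial = out.data[i]  # (t, 2)
        mask = (trial < lo) | (trial > hi)
        n_ext = int(mask.sum())
        if n_ext == 0:
            continue
        if n_ext == 1:
            t_idx, ch = map(int, np.argwhere(mask)[0])
            clean = np.delete(trial[:, ch], t_idx)
            out.data[i, t_idx, ch] = clean.mean()
        else:
            _exclude(out, i, "multi-extreme")
    return out


# ---------------------------------------------------------------------------
# step 5: normalization


def normalize(es: EpochSet) -> EpochSet:
    """Scale each channel so its grand mean over included trials is 100.

    Excluded trials are transformed too (diagnostics) but do not enter
    the mean.
    """
    out = _advance(es, "normalized")
    if out.n_included == 0:
        raise ValueError("no included trials to normalize")
    means = out.data[out.included].reshape(-1, 2).mean(axis=0)
    if np.any(means == 0):
        bad = CHANNEL_NAMES[int(np.nonzero(means == 0)[0][0])]
        raise ValueError(f"degenerate signal: zero mean on channel '{bad}'")
    out.data = out.data / means * 100.0
    return out


# ---------------------------------------------------------------------------
# step 6: heart-cycle integration


def _cycle_average(sig_2ch: np.ndarray, peaks: np.ndarray, time_axis: np.ndarray):
    """Replace each channel by its per-cardiac-cycle mean, interpolated.

    Cycle means are anchored at cycle midpoints and linearly interpolated
    back onto the original time grid; samples before the first / after
    the last midpoint take the nearest cycle's mean (np.interp clamps).
    """
    mids = (time_axis[peaks[:-1]] + time_axis[peaks[1:]]) / 2.0
    out = np.empty_like(sig_2ch)
    for ch in range(2):
        means = np.array(
            [
                sig_2ch[peaks[j] : peaks[j + 1], ch].mean()
                for j in range(len(peaks) - 1)
            ]
        )
        out[:, ch] = np.interp(time_axis, mids, means)
    return out


def heart_cycle_integrate(
    es: EpochSet, min_hr_bpm: float = 40.0, max_hr_bpm: float = 150.0
) -> EpochSet:
    """Average the signal from systolic peak to peak of the heartbeat.

    Peaks are detected on the mean of the two channels (both arteries
    share the cardiac cycle) with a minimum peak distance of
    ``60/max_hr_bpm`` seconds and a prominence floor of a quarter of the
    10-90 percentile spread of the epoch.  Epochs in which fewer than two
    peaks are found are excluded with reason ``no-pulse``.
    """
    out = _advance(es, "integrated", allow_rerun=False)
    rate = out.sample_rate
    distance = max(1, int(round(rate * 60.0 / max_hr_bpm)))
    for i in range(out.n_trials):
        if not out.included[i]:
            continue
        sig = out.data[i].mean(axis=1)
        p10, p90 = np.percentile(sig, [10, 90])
        prominence = max(0.25 * (p90 - p10), 1e-9)
        peaks, _ = find_peaks(sig, distance=distance, prominence=prominence)
        if peaks.size < 2:
            logger.warning("trial %d: < 2 cardiac peaks; excluded (no-pulse)", i)
            _exclude(out, i, "no-pulse")
            continue
        out.data[i] = _cycle_average(out.data[i], peaks, out.time_axis)
    if out.n_included == 0:
        logger.warning("heart-cycle integration left no included trials")
    return out


# ---------------------------------------------------------------------------
# step 7: baseline correction


def baseline_correct(es: EpochSet, cfg: ParadigmConfig) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    out = _advance(es, "baselined")
    b0, b1 = cfg.baseline
    mask = (out.time_axis >= b0) & (out.time_axis < b1)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    if out.prebaseline is None:  # idempotent on rerun
        out.prebaseline = out.data.copy()
    base = out.data[:, mask, :].mean(axis=1, keepdims=True)
    out.data = out.data - base
    return out


# ---------------------------------------------------------------------------
# step 8: range rejection


def reject_range(es: EpochSet, cfg: ParadigmConfig) -> EpochSet:
    """Exclude trials with normalized values outside ``range_limits``.

    Evaluated on the normalized, pre-baseline-corrected values (after
    baseline correction the series is centred on 0, so a 60-140 window
    would exclude everything); :func:`baseline_correct` snapshots those
    values.
    """
    if _STAGE_INDEX[es.stage] < _STAGE_INDEX["normalized"]:
        raise PipelineOrderError("range rejection requires normalization first")
    out = _advance(es, "ranged")
    values = out.prebaseline if out.prebaseline is not None else out.data
    lo, hi = cfg.range_limits
    for i in range(out.n_trials):
        if not out.included[i]:
            continue
        trial = values[i]
        if (trial < lo).any() or (trial > hi).any():
            _exclude(out, i, "out-of-range")
    return out


# ---------------------------------------------------------------------------
# participant-level inclusion


def enforce_min_trials(trial_counts, cfg: ParadigmConfig) -> bool:
    """True iff every condition retains at least ``cfg.min_trials`` trials.

    ``trial_counts`` maps condition labels (e.g. language, or
    language x task) to usable-trial counts; "fewer than" is strict, so
    a count equal to ``min_trials`` is still included.
    """
    counts = trial_counts.values() if hasattr(trial_counts, "values") else trial_counts
    return all(int(c) >= cfg.min_trials for c in counts)


# ---------------------------------------------------------------------------
# runner


def preprocess_recording(
    rec: RawRecording,
    cfg: ParadigmConfig,
    manual_exclusions=(),
    markers: list[TrialMarker] | None = None,
) -> EpochSet:
    """Run steps 1-8 on one recording and return the final EpochSet.

    Markers are extracted from the raw (full-rate) recording before
    downsampling so onsets keep full temporal precision.
    """
    if markers is None:
        from .io import extract_markers

        markers = extract_markers(
            rec, threshold=cfg.marker_threshold, min_gap_s=cfg.marker_min_gap_s
        )
    rec_ds = downsample(rec, cfg.target_rate)
    es = epochize(rec_ds, markers, cfg)
    es = apply_manual_exclusions(es, manual_exclusions)
    es = screen_extremes(es, cfg)
    es = normalize(es)
    if cfg.heart_integration:
        es = heart_cycle_integrate(es, cfg.min_hr_bpm, cfg.max_hr_bpm)
    es = baseline_correct(es, cfg)
    es = reject_range(es, cfg)
    return es
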