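"""Laterality indices and participant-level screening.

The laterality index (LI) is the mean left-minus-right normalized CBFV
difference over the period of interest (POI); positive values indicate
left-hemisphere dominance.  Two estimators are provided:

``li_mean``
    mean of L-R across the whole POI (the default; approximately
    normally distributed across participants);
``li_peak``
    the legacy estimator: mean of L-R in a narrow window centred on the
    largest absolute difference within the POI.  It forces a sign even
    when the waveform hovers near zero, producing bimodal LIs.

Per-trial LIs give a standard error, a t confidence interval used to
categorize participants as left / bilateral / right, and feed the
Hoaglin-Iglewicz style SE-outlier rule (Q3 + 2.2 * IQR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .preprocess import LEFT, RIGHT, EpochSet

logger = logging.getLogger(__name__)

CATEGORIES = ("left", "bilateral", "right")


def _poi_mask(time_axis: np.ndarray, poi) -> np.ndarray:
    p0, p1 = poi
    mask = (time_axis >= p0) & (time_axis < p1)
    if not mask.any():
        raise ValueError(f"POI {poi} contains no samples of the time axis")
    return mask


def grand_average(es: EpochSet) -> np.ndarray:
    """Pointwise mean over included trials, per channel -> (time, 2)."""
    if es.n_included == 0:
        raise ValueError("no included trials to average")
    return es.data[es.included].mean(axis=0)


def li_mean(wave: np.ndarray, time_axis: np.ndarray, poi) -> float:
    """Mean of (left - right) over the POI of an averaged waveform."""
    mask = _poi_mask(time_axis, poi)
    diff = wave[mask, LEFT] - wave[mask, RIGHT]
    return float(diff.mean())


def li_peak(
    wave: np.ndarray, time_axis: np.ndarray, poi, window_s: float = 2.0
) -> float:
    """Windowed mean of (left - right) around the peak |difference|.

    The peak is the POI sample maximizing |left - right| (earliest wins
    on ties); the value is the mean of the signed difference over
    ``window_s`` seconds centred there, clipped to the POI.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    mask = _poi_mask(time_axis, poi)
    t = time_axis[mask]
    diff = wave[mask, LEFT] - wave[mask, RIGHT]
    k = int(np.argmax(np.abs(diff)))  # argmax returns the earliest maximum
    w = (t >= t[k] - window_s / 2) & (t <= t[k] + window_s / 2)
    return float(diff[w].mean())


def trial_lis(es: EpochSet, poi) -> tuple[np.ndarray, float]:
    """Per-included-trial LIs and their standard error.

    The mean of the trial LIs equals the mean-method LI of the grand
    average (both are the same linear operation on the data).
    """
    if es.n_included < 2:
        raise ValueError("need >= 2 included trials for a standard error")
    mask = _poi_mask(es.time_axis, poi)
    diffs = es.data[es.included][:, mask, LEFT] - es.data[es.included][:, mask, RIGHT]
    lis = diffs.mean(axis=1)
    se = float(lis.std(ddof=1) / np.sqrt(lis.size))
    return lis, se


def confidence_interval(
    li: float, se: float, n_trials: int, conf_level: float = 0.95
) -> tuple[float, float]:
    """Student-t CI around the LI with ``n_trials - 1`` degrees of freedom."""
    if n_trials < 2:
        raise ValueError("need n_trials >= 2")
    tq = float(sps.t.ppf(0.5 + conf_level / 2.0, df=n_trials - 1))
    return (li - tq * se, li + tq * se)


def categorize(
    li: float, se: float, n_trials: int, conf_level: float = 0.95
) -> str:
    """left / bilateral / right by whether the LI's CI includes zero."""
    if se < 0:
        raise ValueError("se must be >= 0")
    lo, hi = confidence_interval(li, se, n_trials, conf_level)
    if lo > 0:
        return "left"
    if hi < 0:
        return "right"
    return "bilateral"


@dataclass
class ParticipantResult:
    """Laterality summary for one participant x language x task dataset."""

    participant: str
    language: str
    task: str
    n_usable_trials: int
    li_mean: float
    li_peak: float
    trial_lis: np.ndarray
    se: float
    ci: tuple[float, float]
    category: str
    trial_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    excluded_outlier: bool = False


def participant_result(
    es: EpochSet,
    poi,
    participant: str = "",
    language: str = "",
    task: str = "",
    conf_level: float = 0.95,
    peak_window_s: float = 2.0,
) -> ParticipantResult:
    """Compute all laterality quantities for one preprocessed EpochSet."""
    wave = grand_average(es)
    lis, se = trial_lis(es, poi)
    li = li_mean(wave, es.time_axis, poi)
    n = es.n_included
    return ParticipantResult(
        participant=participant or es.meta.get("participant", ""),
        language=language or es.meta.get("language", ""),
        task=task or es.meta.get("task", ""),
        n_usable_trials=n,
        li_mean=li,
        li_peak=li_peak(wave, es.time_axis, poi, peak_window_s),
        trial_lis=lis,
        se=se,
        ci=confidence_interval(li, se, n, conf_level),
        category=categorize(li, se, n, conf_level),
        trial_index=np.nonzero(es.included)[0],
    )


@dataclass
class SEOutlierStats:
    """Quartile statistics behind the SE-based outlier exclusion."""

    q1: float
    q3: float
    threshold: float
    flagged: frozenset
    whisker: float = 2.2


def se_outlier_filter(
    se_by_dataset: dict, whisker: float = 2.2, min_participants: int = 4
) -> SEOutlierStats:
    """Flag participants with unusually high trial-by-trial variability.

    ``se_by_dataset`` maps dataset keys -- tuples whose first element is
    the participant id, e.g. ``(participant, language)`` -- to the SE of
    that dataset's single-trial LIs.  Quartiles (linear-interpolation
    convention, the "type 7" default) are computed over the pooled SEs of
    all datasets; a participant is flagged when any of their datasets has
    SE strictly above ``Q3 + whisker * (Q3 - Q1)``.

    With fewer than ``min_participants`` distinct participants the
    quartiles are not meaningful: a warning is logged and nobody is
    flagged.
    """
    ses = np.asarray(list(se_by_dataset.values()), dtype=float)
    pids = {k[0] if isinstance(k, tuple) else k for k in se_by_dataset}
    if len(pids) < min_participants:
        logger.warning(
            "only %d participants: SE-outlier filter skipped", len(pids)
        )
        return SEOutlierStats(
            q1=float("nan"),
            q3=float("nan"),
            threshold=float("nan"),
            flagged=frozenset(),
            whisker=whisker,
        )
    q1, q3 = np.quantile(ses, [0.25, 0.75])
    threshold = q3 + whisker * (q3 - q1)
    flagged = frozenset(
        (k[0] if isinstance(k, tuple) else k)
        for k, se in se_by_dataset.items()
        if se > threshold
    )
    return SEOutlierStats(
        q1=float(q1),
        q3=float(q3),
        threshold=float(threshold),
        flagged=flagged,
        whisker=whisker,
    )
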