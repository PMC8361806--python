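"""Synthetic bilateral Doppler recordings with known ground truth.

Generates raw two-channel CBFV recordings (100 Hz) emulating the cued
word-generation paradigms, so every pipeline stage and statistic can be
tested without real data.  The signal model per channel is

    v_ch(t) = g(t) * B_ch * (1 + A * c(t)) * (1 + r_ch(t)/100) + eps(t)

where ``B_ch`` is the baseline velocity in device units, ``c(t)`` a
unit-amplitude raised-cosine systolic pulse train at the participant's
(jittered) heart rate, ``g(t)`` a slow multiplicative gain drift
(piecewise linear between trial onsets), ``r_ch(t)`` the task-evoked
response in percent -- a lagged ramp to plateau during word generation,
amplitude ``gain + lambda/2`` on the left and ``gain - lambda/2`` on the
right -- and ``eps`` white Gaussian noise.  Marker pulses are placed at
the event the device flags (the letter cue in the covert paradigm).

Two realism features matter specifically to the preprocessing chain:

* The response amplitudes are pre-compensated for the pipeline's
  normalization denominator (the per-channel mean over whole epochs,
  which includes the response itself), so that the population
  left-minus-right POI difference after normalization and baseline
  correction equals ``lambda`` exactly by construction.
* The empirical-quantile artifact screen flags a fixed fraction of
  samples wherever they lie; in real recordings those tails come from
  artifacts and slow drift concentrated in a few trials.  The generator
  reproduces that tail structure via the gain drift and burst-shaped
  spike/dropout artifacts; without it the screen would scatter its flags
  over clean trials.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .io import RawRecording, write_raw
from .preprocess import ParadigmConfig, get_paradigm


@dataclass(frozen=True)
class ParadigmTiming:
    """Structural timing of one paradigm (seconds, relative to cue)."""

    name: str
    trial_len_s: float
    gen_onset_s: float  # word generation begins (also the flagged event)
    gen_end_s: float
    n_trials: int


TIMINGS = {
    # "Clear Mind" 5 s, covert generation 15 s, overt 5 s, rest 25 s
    "study1_wordgen": ParadigmTiming("study1_wordgen", 50.0, 5.0, 25.0, 23),
    # cue 3 s, overt generation 17 s, rest 16 s
    "study2_fluency": ParadigmTiming("study2_fluency", 36.0, 3.0, 20.0, 20),
}


#: default task label per paradigm (used in dataset keys and filenames)
TASK_LABELS = {"study1_wordgen": "wordgen", "study2_fluency": "fluency"}


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings.

    ``lambda_dist`` is the (mean, sd) of the true lateralization lambda
    in percentage-point units -- the quantity the pipeline's LI
    estimates.  ``trial_lambda_sd`` is the trial-to-trial jitter of the
    lateralized response (attentional fluctuation), which is what gives
    single-trial LIs a nonzero standard error.  ``trial_gain_sd`` is the
    slow multiplicative drift between trial onsets.  Rates are expected
    events per trial.
    """

    n_participants: int = 24
    trials_per_condition: int | None = None  # None -> paradigm default
    paradigm: str = "study1_wordgen"
    languages: tuple[str, ...] = ("L1", "L2")
    shared_lambda: bool = True
    lambda_dist: tuple[float, float] = (2.7, 1.0)
    response_gain: float = 4.0  # mean bilateral task response, % of baseline
    response_lag_s: float = 3.0
    response_decay_s: float = 5.0
    heart_rate_bpm: tuple[float, float] = (70.0, 8.0)
    cycle_jitter: float = 0.03  # per-cycle period sd, truncated at +/-10%
    pulsatility_amplitude: float = 0.35
    noise_sd: float = 3.0  # % of baseline velocity
    trial_lambda_sd: float = 1.0
    trial_gain_sd: float = 0.03
    spike_rate: float = 0.06
    dropout_rate: float = 0.04
    spike_width_s: tuple[float, float] = (0.2, 0.8)
    dropout_width_s: tuple[float, float] = (0.2, 0.5)
    baseline_velocity: tuple[float, float] = (60.0, 55.0)
    sample_rate: float = 100.0
    lead_in_s: float = 20.0
    tail_s: float = 10.0
    marker_amplitude: float = 5.0
    marker_width_s: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.paradigm not in TIMINGS:
            raise ValueError(
                f"unknown paradigm {self.paradigm!r}; available: {sorted(TIMINGS)}"
            )
        for name in ("noise_sd", "spike_rate", "dropout_rate", "trial_lambda_sd",
                     "trial_gain_sd", "pulsatility_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_condition is not None and self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.lambda_dist[1] < 0:
            raise ValueError("lambda sd must be >= 0")

    @property
    def timing(self) -> ParadigmTiming:
        t = TIMINGS[self.paradigm]
        if self.trials_per_condition is None:
            return t
        return dataclasses.replace(t, n_trials=int(self.trials_per_condition))

    def noiseless(self) -> "SyntheticConfig":
        """Deterministic-response variant: stochastic terms switched off.

        Cardiac pulsatility, heart-rate jitter and the slow gain drift
        stay on (they are structure, not noise, and the screening steps
        need them to behave as on real data).
        """
        return dataclasses.replace(
            self, noise_sd=0.0, spike_rate=0.0, dropout_rate=0.0,
            trial_lambda_sd=0.0,
        )

    def to_file(self, path):
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    lam: dict = field(default_factory=dict)  # (pid, language) -> lambda
    marker_onsets: dict = field(default_factory=dict)  # (pid, language) -> array (s)
    cue_onsets: dict = field(default_factory=dict)  # "Clear Mind" onsets (s)
    artifacts: dict = field(default_factory=dict)  # (pid, language) -> list of dicts
    trial_lambdas: dict = field(default_factory=dict)  # per-trial injected lambda
    config: SyntheticConfig | None = None


def _response_shape(t_rel: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Unit response shape s(t) on trial-relative time (0 = cue onset)."""
    tm = cfg.timing
    up0, up1 = tm.gen_onset_s, tm.gen_onset_s + cfg.response_lag_s
    dn0, dn1 = tm.gen_end_s, tm.gen_end_s + cfg.response_decay_s
    s = np.zeros_like(t_rel)
    ramp = (t_rel >= up0) & (t_rel < up1)
    s[ramp] = (t_rel[ramp] - up0) / (up1 - up0)
    s[(t_rel >= up1) & (t_rel < dn0)] = 1.0
    decay = (t_rel >= dn0) & (t_rel < dn1)
    s[decay] = 1.0 - (t_rel[decay] - dn0) / (dn1 - dn0)
    return s


def _epoch_shape_mean(cfg: SyntheticConfig, paradigm: ParadigmConfig) -> float:
    """Mean of the response shape over the analysis epoch window."""
    fs = cfg.sample_rate
    n = int(round((paradigm.epoch_end_s - paradigm.epoch_start_s) * fs))
    t_rel = paradigm.epoch_start_s + np.arange(n) / fs
    return float(_response_shape(t_rel, cfg).mean())


def _cardiac_pulse(
    n: int, fs: float, hr_bpm: float, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Raised-cosine systolic pulse train in [0, 1] with jittered periods."""
    period = 60.0 / hr_bpm
    t_end = n / fs
    n_beats = int(np.ceil(t_end / period * 1.3)) + 4
    jit = rng.normal(0.0, cfg.cycle_jitter, size=n_beats).clip(-0.1, 0.1)
    periods = period * (1.0 + jit)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    starts += -rng.uniform(0, period)  # random initial phase
    t = np.arange(n) / fs
    beat = np.searchsorted(starts, t, side="right") - 1
    beat = beat.clip(0, n_beats - 1)
    phase = (t - starts[beat]) / periods[beat]
    w = 0.4  # systolic pulse occupies 40% of the cycle
    c = np.where(phase < w, 0.5 * (1.0 - np.cos(2.0 * np.pi * phase / w)), 0.0)
    return c


def inject_artifacts(
    rec: RawRecording,
    spike_rate: float,
    dropout_rate: float,
    rng: np.random.Generator,
    windows: list[tuple[float, float]] | None = None,
    spike_width_s=(0.2, 0.8),
    dropout_width_s=(0.2, 0.5),
) -> tuple[RawRecording, list[dict]]:
    """Add spike and dropout artifacts in place; return the exact log.

    Spikes are short multiplicative bursts (factor drawn from [3, 10])
    affecting both channels, as probe/headset motion does; dropouts
    zero-clamp one channel for a short window (signal loss on one
    probe).  Rates are expected events per window; ``windows`` defaults
    to the whole recording treated as one trial.
    """
    if spike_rate < 0 or dropout_rate < 0:
        raise ValueError("rates must be >= 0")
    fs = rec.sample_rate
    n = rec.n_samples
    if windows is None:
        windows = [(float(rec.time[0]), float(rec.time[-1]))]
    log: list[dict] = []
    channels = (rec.left, rec.right)
    for k, (w0, w1) in enumerate(windows):
        for kind, rate in (("spike", spike_rate), ("dropout", dropout_rate)):
            for _ in range(rng.poisson(rate)):
                width = rng.uniform(*(spike_width_s if kind == "spike" else dropout_width_s))
                t0 = rng.uniform(w0, max(w0, w1 - width))
                i0 = int(round((t0 - rec.time[0]) * fs))
                i1 = min(n, i0 + max(1, int(round(width * fs))))
                i0 = max(0, i0)
                if kind == "spike":
                    factor = rng.uniform(3.0, 10.0)
                    rec.left[i0:i1] *= factor
                    rec.right[i0:i1] *= factor
                    log.append(
                        dict(trial=k, kind="spike", channel="both",
                             start=i0, stop=i1, factor=float(factor))
                    )
                else:
                    ch = int(rng.integers(2))
                    channels[ch][i0:i1] = 0.0
                    log.append(
                        dict(trial=k, kind="dropout", channel=("left", "right")[ch],
                             start=i0, stop=i1, factor=0.0)
                    )
    return rec, log


def gen_session(
    cfg: SyntheticConfig,
    lam: float,
    rng: np.random.Generator,
    participant: str = "sub-01",
    language: str = "L1",
    task: str | None = None,
) -> tuple[RawRecording, dict]:
    """One raw recording (participant x language) plus its ground truth."""
    tm = cfg.timing
    paradigm = get_paradigm(cfg.paradigm)
    fs = cfg.sample_rate
    n_trials = tm.n_trials
    T = cfg.lead_in_s + n_trials * tm.trial_len_s + cfg.tail_s
    n = int(round(T * fs))
    t = np.arange(n) / fs
    cue_onsets = cfg.lead_in_s + np.arange(n_trials) * tm.trial_len_s

    # cardiac pulsatility, shared by both channels
    hr = float(np.clip(rng.normal(*cfg.heart_rate_bpm), 45.0, 110.0))
    c = _cardiac_pulse(n, fs, hr, cfg, rng)

    # per-trial response amplitudes, pre-compensated for the pipeline's
    # whole-epoch normalization (see module docstring)
    f = _epoch_shape_mean(cfg, paradigm)
    lam_trials = lam + rng.normal(0.0, cfg.trial_lambda_sd, size=n_trials)
    rho_nom = {
        "left": cfg.response_gain + lam / 2.0,
        "right": cfg.response_gain - lam / 2.0,
    }
    kappa = {
        ch: (f * rho / 100.0) / (1.0 - f * rho / 100.0)
        for ch, rho in rho_nom.items()
    }

    r = {"left": np.zeros(n), "right": np.zeros(n)}
    for k, cue in enumerate(cue_onsets):
        i0 = int(round(cue * fs))
        i1 = min(n, int(round((cue + tm.gen_end_s + cfg.response_decay_s) * fs)) + 1)
        shape = _response_shape(t[i0:i1] - cue, cfg)
        r["left"][i0:i1] += (cfg.response_gain + lam_trials[k] / 2.0) * (
            1.0 + kappa["left"]
        ) * shape
        r["right"][i0:i1] += (cfg.response_gain - lam_trials[k] / 2.0) * (
            1.0 + kappa["right"]
        ) * shape

    # slow multiplicative gain drift, piecewise linear between trial onsets
    nodes_t = np.concatenate([[0.0], cue_onsets, [T]])
    nodes_g = np.concatenate(
        [[1.0], 1.0 + rng.normal(0.0, cfg.trial_gain_sd, size=n_trials), [1.0]]
    )
    g = np.interp(t, nodes_t, nodes_g)

    A = cfg.pulsatility_amplitude
    left = g * cfg.baseline_velocity[0] * (1.0 + A * c) * (1.0 + r["left"] / 100.0)
    right = g * cfg.baseline_velocity[1] * (1.0 + A * c) * (1.0 + r["right"] / 100.0)
    if cfg.noise_sd > 0:
        left = left + rng.normal(0, cfg.noise_sd / 100.0 * cfg.baseline_velocity[0], n)
        right = right + rng.normal(0, cfg.noise_sd / 100.0 * cfg.baseline_velocity[1], n)

    marker = np.zeros(n)
    marker_onsets = cue_onsets + tm.gen_onset_s  # device flags the letter cue
    for onset in marker_onsets:
        i0 = int(round(onset * fs))
        marker[i0 : i0 + max(1, int(round(cfg.marker_width_s * fs)))] = (
            cfg.marker_amplitude
        )

    rec = RawRecording(
        sample_rate=fs,
        time=t,
        left=left,
        right=right,
        marker=marker,
        meta={
            "participant": participant,
            "language": language,
            "task": task or TASK_LABELS[cfg.paradigm],
            "paradigm": cfg.paradigm,
        },
    )

    windows = [
        (cue + paradigm.epoch_start_s, cue + paradigm.epoch_end_s)
        for cue in cue_onsets
    ]
    rec, artifact_log = inject_artifacts(
        rec, cfg.spike_rate, cfg.dropout_rate, rng, windows=windows,
        spike_width_s=cfg.spike_width_s, dropout_width_s=cfg.dropout_width_s,
    )
    truth = {
        "lambda": float(lam),
        "trial_lambdas": lam_trials,
        "marker_onsets": marker_onsets,
        "cue_onsets": cue_onsets,
        "artifacts": artifact_log,
        "heart_rate_bpm": hr,
    }
    return rec, truth


def _participant_rng(seed: int, participant_index: int, stream: int = 0):
    """Substream per participant: adding participants never reshuffles
    earlier ones."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(participant_index, stream))
    return np.random.default_rng(ss)


def gen_cohort(cfg: SyntheticConfig) -> tuple[dict, GroundTruth]:
    """Generate recordings for a whole cohort.

    Returns ``(recordings, ground_truth)`` where ``recordings`` maps
    ``(participant, language)`` to a :class:`RawRecording`.  With
    ``shared_lambda`` both languages of a participant use the same true
    lambda (independent noise, artifacts and drift otherwise).
    """
    recordings: dict[tuple[str, str], RawRecording] = {}
    gt = GroundTruth(config=cfg)
    mean, sd = cfg.lambda_dist
    for i in range(cfg.n_participants):
        pid = f"sub-{i + 1:02d}"
        lam_shared = float(_participant_rng(cfg.seed, i, 0).normal(mean, sd))
        for j, language in enumerate(cfg.languages):
            rng = _participant_rng(cfg.seed, i, 1 + j)
            lam = lam_shared if cfg.shared_lambda else float(rng.normal(mean, sd))
            rec, truth = gen_session(
                cfg, lam, rng, participant=pid, language=language
            )
            key = (pid, language)
            recordings[key] = rec
            gt.lam[key] = truth["lambda"]
            gt.trial_lambdas[key] = truth["trial_lambdas"]
            gt.marker_onsets[key] = truth["marker_onsets"]
            gt.cue_onsets[key] = truth["cue_onsets"]
            gt.artifacts[key] = truth["artifacts"]
    return recordings, gt


def write_cohort(recordings: dict, gt: GroundTruth, out_dir) -> None:
    """Write canonical TSVs, ground_truth.csv and the config used."""
    from pathlib import Path

    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (pid, language), rec in recordings.items():
        task = rec.meta.get("task", "wordgen")
        write_raw(rec, out_dir / f"{pid}_{language}_{task}.tsv")
        rows.append(
            {"participant": pid, "language": language, "task": task,
             "lambda": gt.lam[(pid, language)]}
        )
    pd.DataFrame(rows).to_csv(out_dir / "ground_truth.csv", index=False)
    if gt.config is not None:
        gt.config.to_file(out_dir / "synthetic_config.yaml")
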