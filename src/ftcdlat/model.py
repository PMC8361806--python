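"""Cohort-level model objects tying the pipeline together.

:class:`BilingualLateralityModel` holds the raw recordings of a
bilingual FTCD cohort plus a paradigm configuration;
:meth:`~BilingualLateralityModel.fit` runs preprocessing, laterality
estimation, participant screening and the group statistics, returning a
:class:`LateralityResults` with participant and trial tables, a
cohort summary, and ``summary()`` in the familiar fitted-model style.

    >>> from ftcdlat.synthetic import SyntheticConfig
    >>> model = BilingualLateralityModel.from_synthetic(SyntheticConfig(seed=1))
    >>> res = model.fit()
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from . import laterality as lat
from . import stats as st
from .preprocess import (
    EpochSet,
    ParadigmConfig,
    enforce_min_trials,
    get_paradigm,
    preprocess_recording,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def _normalize_key(key, rec=None) -> tuple[str, str, str]:
    """Dataset keys are (participant, language[, task]); a missing task
    label falls back to the recording's metadata."""
    if len(key) == 2:
        task = rec.meta.get("task", "wordgen") if rec is not None else "wordgen"
        return (key[0], key[1], task)
    return tuple(key)


class BilingualLateralityModel:
    """Laterality analysis of one cohort of bilateral FTCD recordings.

    Parameters
    ----------
    recordings : dict
        Maps ``(participant, language)`` or ``(participant, language,
        task)`` to :class:`~ftcdlat.io.RawRecording`.
    paradigm : ParadigmConfig or str
        Timing/screening configuration or the name of a shipped preset
        (``study1_wordgen``, ``study2_fluency``).
    manual_exclusions : dict, optional
        Same keys, mapping to iterables of 0-based trial indices to
        exclude manually (visible spiking/dropout artifacts).
    ground_truth : GroundTruth, optional
        Carried through to the results for recovery diagnostics when the
        cohort is synthetic.
    """

    def __init__(
        self,
        recordings: dict,
        paradigm: ParadigmConfig | str = "study1_wordgen",
        manual_exclusions: dict | None = None,
        ground_truth=None,
    ):
        if not recordings:
            raise ValueError("no recordings supplied")
        self.recordings = {
            _normalize_key(k, v): v for k, v in recordings.items()
        }
        self.paradigm = (
            get_paradigm(paradigm) if isinstance(paradigm, str) else paradigm
        )
        short = {(k[0], k[1]): k for k in self.recordings}
        self.manual_exclusions = {}
        for k, v in (manual_exclusions or {}).items():
            kk = _normalize_key(k)
            if kk not in self.recordings and (k[0], k[1]) in short:
                kk = short[(k[0], k[1])]
            self.manual_exclusions[kk] = list(v)
        self.ground_truth = ground_truth

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_directory(
        cls,
        path,
        paradigm: ParadigmConfig | str = "study1_wordgen",
        dialect: str = "canonical-tsv",
        exclusions_dir=None,
    ) -> "BilingualLateralityModel":
        """Load every ``<participant>_<language>_<task>`` recording in a
        directory (``.tsv`` for canonical, ``.txt``/``.exp`` for device
        exports), with optional manual-exclusion sidecars."""
        path = Path(path)
        patterns = ("*.tsv",) if dialect == "canonical-tsv" else ("*.txt", "*.exp")
        files = sorted(p for pat in patterns for p in path.glob(pat))
        recordings, exclusions = {}, {}
        for f in files:
            meta = dio.parse_dataset_name(f.stem)
            if not meta:
                logger.warning("skipping %s: name is not participant_language_task", f.name)
                continue
            key = (meta["participant"], meta["language"], meta["task"])
            recordings[key] = dio.read_raw(f, dialect=dialect)
            if exclusions_dir is not None:
                side = Path(exclusions_dir) / f"{f.stem}.txt"
                if side.exists():
                    exclusions[key] = dio.read_exclusion_file(side)
        if not recordings:
            raise ValueError(f"no usable recordings found in {path}")
        return cls(recordings, paradigm, manual_exclusions=exclusions)

    @classmethod
    def from_synthetic(cls, cfg) -> "BilingualLateralityModel":
        """Generate a synthetic cohort and wrap it, keeping ground truth."""
        from .synthetic import gen_cohort

        recordings, gt = gen_cohort(cfg)
        return cls(recordings, paradigm=cfg.paradigm, ground_truth=gt)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        conf_level: float = 0.95,
        equivalence_bound: float = st.DEFAULT_EQUIVALENCE_BOUND,
        rscale: float = st.DEFAULT_RSCALE,
        peak_window_s: float = 2.0,
        outlier_filter: bool = True,
    ) -> "LateralityResults":
        cfg = self.paradigm
        epochsets: dict[tuple, EpochSet] = {}
        results: dict[tuple, lat.ParticipantResult] = {}
        manifest_datasets = {}

        for key, rec in self.recordings.items():
            es = preprocess_recording(
                rec, cfg, manual_exclusions=self.manual_exclusions.get(key, ())
            )
            epochsets[key] = es
            counts = es.exclusion_counts()
            manifest_datasets["/".join(key)] = {
                "n_markers": int(es.meta.get("n_markers", es.n_trials)),
                "dropped_epochs": int(es.meta.get("dropped_epochs", 0)),
                "n_epochs": es.n_trials,
                **{k: int(v) for k, v in counts.items()},
            }

        # participant-level inclusion: enough trials in every condition
        pids = sorted({k[0] for k in epochsets})
        min_trial_ok = {}
        for pid in pids:
            counts = {
                k[1:]: epochsets[k].n_included for k in epochsets if k[0] == pid
            }
            min_trial_ok[pid] = enforce_min_trials(counts, cfg)

        for key, es in epochsets.items():
            if not min_trial_ok[key[0]]:
                continue
            if es.n_included < 2:
                min_trial_ok[key[0]] = False
                continue
            results[key] = lat.participant_result(
                es,
                cfg.poi,
                participant=key[0],
                language=key[1],
                task=key[2],
                conf_level=conf_level,
                peak_window_s=peak_window_s,
            )
        # drop datasets of participants demoted inside the loop
        results = {k: v for k, v in results.items() if min_trial_ok[k[0]]}

        # SE-based outlier exclusion across the pooled datasets
        se_by_dataset = {k: r.se for k, r in results.items()}
        if outlier_filter and se_by_dataset:
            outliers = lat.se_outlier_filter(se_by_dataset)
        else:
            outliers = lat.SEOutlierStats(
                float("nan"), float("nan"), float("nan"), frozenset()
            )
        for k, r in results.items():
            r.excluded_outlier = k[0] in outliers.flagged

        res = LateralityResults(
            model=self,
            config=cfg,
            epochsets=epochsets,
            participant_results=results,
            min_trial_ok=min_trial_ok,
            outliers=outliers,
            conf_level=conf_level,
            equivalence_bound=equivalence_bound,
            rscale=rscale,
        )
        res._build_tables()
        res._build_stats()
        res._build_manifest(manifest_datasets)
        return res


@dataclass
class LateralityResults:
    """Fitted cohort results: tables, group statistics, summary."""

    model: BilingualLateralityModel
    config: ParadigmConfig
    epochsets: dict
    participant_results: dict
    min_trial_ok: dict
    outliers: lat.SEOutlierStats
    conf_level: float
    equivalence_bound: float
    rscale: float
    participants: pd.DataFrame = field(default=None, repr=False)
    trials: pd.DataFrame = field(default=None, repr=False)
    cohort_summary: pd.DataFrame = field(default=None, repr=False)
    stats_report: pd.DataFrame = field(default=None, repr=False)
    group_stats: dict = field(default_factory=dict, repr=False)
    manifest: dict = field(default_factory=dict, repr=False)

    # -- assembly ----------------------------------------------------------

    def _build_tables(self) -> None:
        prows, trows = [], []
        for key, es in sorted(self.epochsets.items()):
            pid, language, task = key
            r = self.participant_results.get(key)
            excluded = (not self.min_trial_ok[pid]) or (
                r is not None and r.excluded_outlier
            )
            if r is not None:
                prows.append(
                    {
                        "participant": pid,
                        "language": language,
                        "task": task,
                        "n_usable_trials": r.n_usable_trials,
                        "li_mean": r.li_mean,
                        "li_peak": r.li_peak,
                        "se": r.se,
                        "ci_lo": r.ci[0],
                        "ci_hi": r.ci[1],
                        "category": r.category,
                        "excluded_min_trials": not self.min_trial_ok[pid],
                        "excluded_outlier": r.excluded_outlier,
                        "excluded": excluded,
                    }
                )
            else:
                prows.append(
                    {
                        "participant": pid, "language": language, "task": task,
                        "n_usable_trials": es.n_included,
                        "li_mean": np.nan, "li_peak": np.nan, "se": np.nan,
                        "ci_lo": np.nan, "ci_hi": np.nan, "category": "excluded",
                        "excluded_min_trials": True, "excluded_outlier": False,
                        "excluded": True,
                    }
                )
            li_by_trial = {}
            if r is not None:
                li_by_trial = dict(zip(r.trial_index, r.trial_lis))
            for i in range(es.n_trials):
                trows.append(
                    {
                        "participant": pid, "language": language, "task": task,
                        "trial": i,
                        "li": li_by_trial.get(i, np.nan),
                        "included": bool(es.included[i]),
                        "reason": es.reasons[i] or "",
                    }
                )
        self.participants = pd.DataFrame(prows)
        self.trials = pd.DataFrame(trows)
        self.cohort_summary = dio.summarize_participants(self.participants)

    def _kept(self) -> pd.DataFrame:
        return self.participants[~self.participants["excluded"]]

    def _build_stats(self) -> None:
        """Per task: paired-language association/equivalence statistics."""
        kept = self._kept()
        gs: dict = {}
        rows = []
        for task, grp in kept.groupby("task"):
            languages = sorted(grp["language"].unique())
            tstats: dict = {"languages": languages}
            for language in languages:
                sub = grp[grp["language"] == language]
                lis = sub["li_mean"].to_numpy()
                entry: dict = {"n": len(sub), "mean_li": float(lis.mean())}
                if len(sub) >= 2 and lis.std(ddof=1) > 0:
                    t, df, p = st.one_sample_t(lis, 0.0)
                    entry.update(t_leftward=t, df=df, p_leftward=p)
                entry.update(self._split_half(task, language))
                tstats[language] = entry
            if len(languages) >= 2:
                l1, l2 = languages[0], languages[1]
                merged = self._paired_lis(kept, task, l1, l2)
                if len(merged) >= 3:
                    x, y = merged[f"li_{l1}"].to_numpy(), merged[f"li_{l2}"].to_numpy()
                    tstats["spearman"] = st.spearman(x, y)
                    tstats["equivalence"] = st.bland_altman_equivalence(
                        x, y, self.equivalence_bound
                    )
                    tstats["bayes_factor"] = st.jzs_bf_paired(x, y, self.rscale)
            gs[task] = tstats
            rows.extend(self._stats_rows(task, tstats))
        self.group_stats = gs
        self.stats_report = pd.DataFrame(
            rows, columns=["task", "statistic", "value", "n"]
        )

    def _paired_lis(self, kept, task, l1, l2) -> pd.DataFrame:
        a = kept[(kept["task"] == task) & (kept["language"] == l1)]
        b = kept[(kept["task"] == task) & (kept["language"] == l2)]
        m = a.merge(b, on="participant", suffixes=(f"_{l1}", f"_{l2}"))
        return m.rename(
            columns={f"li_mean_{l1}": f"li_{l1}", f"li_mean_{l2}": f"li_{l2}"}
        )

    def _split_half(self, task, language) -> dict:
        """Cohort split-half reliability: Spearman of odd- vs even-trial LIs."""
        odd, even = [], []
        for key, es in self.epochsets.items():
            if key[1] != language or key[2] != task:
                continue
            if not self.min_trial_ok[key[0]]:
                continue
            r = self.participant_results.get(key)
            if r is None or r.excluded_outlier:
                continue
            try:
                lo, le = st.split_half_li(es, self.config.poi)
            except ValueError:
                continue
            odd.append(lo)
            even.append(le)
        if len(odd) >= 3:
            try:
                return {
                    "split_half_rho": st.spearman(odd, even),
                    "li_odd": odd,
                    "li_even": even,
                }
            except ValueError:
                pass
        return {}

    def _stats_rows(self, task, tstats) -> list[dict]:
        rows = []
        for language in tstats["languages"]:
            e = tstats[language]
            rows.append(dict(task=task, statistic=f"mean_li_{language}",
                             value=e["mean_li"], n=e["n"]))
            if "t_leftward" in e:
                rows.append(dict(task=task, statistic=f"t_leftward_{language}",
                                 value=e["t_leftward"], n=e["n"]))
                rows.append(dict(task=task, statistic=f"p_leftward_{language}",
                                 value=e["p_leftward"], n=e["n"]))
            if "split_half_rho" in e:
                rows.append(dict(task=task, statistic=f"split_half_rho_{language}",
                                 value=e["split_half_rho"], n=e["n"]))
        if "spearman" in tstats:
            n = tstats["equivalence"].n
            rows.append(dict(task=task, statistic="spearman_l1_l2",
                             value=tstats["spearman"], n=n))
            rows.append(dict(task=task, statistic="prop_within_bounds",
                             value=tstats["equivalence"].prop_within, n=n))
            bf = tstats["bayes_factor"]
            rows.append(dict(task=task, statistic="bf10_equivalence",
                             value=bf.bf10, n=n))
            rows.append(dict(task=task, statistic="bf01_equivalence",
                             value=bf.bf01, n=n))
        return rows

    def _build_manifest(self, datasets: dict) -> None:
        totals = {"n_epochs": 0, "included": 0}
        for d in datasets.values():
            totals["n_epochs"] += d["n_epochs"]
            totals["included"] += d["included"]
            for reason in ("manual", "multi-extreme", "no-pulse", "out-of-range"):
                totals[reason] = totals.get(reason, 0) + d.get(reason, 0)
        excluded = sum(
            v for k, v in totals.items() if k not in ("n_epochs", "included")
        )
        assert totals["included"] + excluded == totals["n_epochs"], (
            "trial counts not conserved"
        )
        pids = sorted(self.min_trial_ok)
        self.manifest = {
            "version": __version__,
            "paradigm": self.config.name,
            "datasets": datasets,
            "totals": totals,
            "participants": {
                "total": len(pids),
                "excluded_min_trials": sum(
                    1 for p in pids if not self.min_trial_ok[p]
                ),
                "excluded_se_outlier": len(self.outliers.flagged),
                "included": sum(
                    1
                    for p in pids
                    if self.min_trial_ok[p] and p not in self.outliers.flagged
                ),
            },
            "se_outlier": {
                "q1": self.outliers.q1,
                "q3": self.outliers.q3,
                "threshold": self.outliers.threshold,
                "flagged": sorted(self.outliers.flagged),
            },
        }

    # -- convenience -------------------------------------------------------

    def pct_trials_excluded(self, language: str, task: str | None = None) -> float:
        """Percent of epochs excluded (any reason) among analyzed
        participants of one language."""
        t = self.trials
        mask = t["language"] == language
        if task is not None:
            mask &= t["task"] == task
        kept_pids = set(self._kept()["participant"])
        mask &= t["participant"].isin(kept_pids)
        sub = t[mask]
        if sub.empty:
            raise ValueError(f"no trials for language {language!r}")
        return 100.0 * (~sub["included"]).mean()

    def recovery(self) -> pd.DataFrame:
        """Estimated LI vs injected ground-truth lambda (synthetic only)."""
        gt = self.model.ground_truth
        if gt is None:
            raise ValueError("no ground truth attached to this model")
        rows = []
        for key, r in self.participant_results.items():
            lam = gt.lam.get((key[0], key[1]))
            if lam is None:
                continue
            rows.append(
                {
                    "participant": key[0], "language": key[1], "task": key[2],
                    "lambda": lam, "li_mean": r.li_mean, "li_peak": r.li_peak,
                    "abs_err": abs(r.li_mean - lam),
                    "excluded_outlier": r.excluded_outlier,
                }
            )
        return pd.DataFrame(rows)

    def grand_average_waveforms(self) -> pd.DataFrame:
        """Cohort-mean left/right waveforms per language x task (long CSV
        analogue of the usual epoch-average figures)."""
        rows = []
        for (task, language) in sorted(
            {(k[2], k[1]) for k in self.participant_results}
        ):
            waves = [
                lat.grand_average(self.epochsets[k])
                for k in self.participant_results
                if k[1] == language and k[2] == task
            ]
            mean = np.mean(waves, axis=0)
            t = next(iter(self.epochsets.values())).time_axis
            for ti, (l, r) in zip(t, mean):
                rows.append(
                    {"task": task, "language": language, "time_s": ti,
                     "left": l, "right": r}
                )
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = []
        w = 78
        lines.append("Bilingual FTCD Laterality Analysis".center(w))
        lines.append("=" * w)
        m = self.manifest["participants"]
        lines.append(
            f"Paradigm: {self.config.name}    POI: {self.config.poi[0]:g}-"
            f"{self.config.poi[1]:g} s    Participants: {m['included']}/"
            f"{m['total']} analyzed"
        )
        lines.append(
            f"Excluded: {m['excluded_min_trials']} (<{self.config.min_trials} "
            f"usable trials), {m['excluded_se_outlier']} (SE outlier, "
            f"threshold Q3+2.2*IQR)"
        )
        lines.append("-" * w)
        lines.append(
            f"{'task':<16}{'language':<10}{'trials':>7}{'mean LI':>9}"
            f"{'se LI':>8}{'% left':>8}{'% bilat':>9}{'% right':>9}"
        )
        for _, row in self.cohort_summary.iterrows():
            lines.append(
                f"{row['task']:<16}{row['language']:<10}"
                f"{row['mean_trials']:>7.2f}{row['mean_li']:>9.2f}"
                f"{row['se_li']:>8.2f}{row['pct_left']:>8.0f}"
                f"{row['pct_bilateral']:>9.0f}{row['pct_right']:>9.0f}"
            )
        lines.append("-" * w)
        for task, tstats in self.group_stats.items():
            if "spearman" in tstats:
                eq = tstats["equivalence"]
                bf = tstats["bayes_factor"]
                lines.append(
                    f"{task}: Spearman(L1, L2) = {tstats['spearman']:.3f}; "
                    f"{100 * eq.prop_within:.0f}% of LI differences within "
                    f"+/-{eq.bound:g}; BF (JZS, r={bf.rscale:.3f}) = "
                    f"{bf.bf10:.3f}"
                )
            for language in tstats["languages"]:
                e = tstats[language]
                parts = [f"  {language}: mean LI = {e['mean_li']:.2f}"]
                if "t_leftward" in e:
                    parts.append(
                        f"leftward bias t({e['df']}) = {e['t_leftward']:.2f}, "
                        f"p = {e['p_leftward']:.2g}"
                    )
                if "split_half_rho" in e:
                    parts.append(f"split-half rho = {e['split_half_rho']:.2f}")
                lines.append("; ".join(parts))
        lines.append("=" * w)
        return "\n".join(lines)

    def save(self, out_dir) -> dict[str, Path]:
        """Write trials.csv, participants.csv, cohort_summary.csv,
        stats_report.csv/.txt and manifest.json."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = dio.write_cohort_table(self.participants, out_dir)
        paths["trials"] = dio.write_trials_table(self.trials, out_dir)
        paths["stats_report"] = out_dir / "stats_report.csv"
        self.stats_report.to_csv(paths["stats_report"], index=False)
        paths["report_txt"] = out_dir / "stats_report.txt"
        paths["report_txt"].write_text(self.summary() + "\n", encoding="utf-8")
        paths["manifest"] = out_dir / "manifest.json"
        paths["manifest"].write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        return paths
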