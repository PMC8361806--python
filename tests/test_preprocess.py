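"""The eight preprocessing steps against brute-force oracles."""

import numpy as np
import pytest

from ftcdlat import preprocess as pp
from ftcdlat.io import RawRecording, TrialMarker, extract_markers
from ftcdlat.laterality import grand_average, li_mean


def _rec(left, right=None, marker=None, rate=100.0):
    left = np.asarray(left, dtype=float)
    n = left.size
    return RawRecording(
        sample_rate=rate,
        time=np.arange(n) / rate,
        left=left,
        right=left.copy() if right is None else np.asarray(right, float),
        marker=np.zeros(n) if marker is None else np.asarray(marker, float),
    )


class TestDownsample:
    def test_block_means(self):
        rec = _rec(np.arange(1, 9))
        out = pp.downsample(rec, 25.0)
        np.testing.assert_allclose(out.left, [2.5, 6.5])
        assert out.sample_rate == 25.0

    def test_constant_stays_constant(self):
        out = pp.downsample(_rec(np.full(80, 60.0)), 25.0)
        np.testing.assert_allclose(out.left, 60.0)

    def test_marker_block_max_preserves_edge(self):
        rec = _rec(np.ones(8), marker=[0, 0, 0, 5, 0, 0, 0, 0])
        out = pp.downsample(rec, 25.0)
        np.testing.assert_array_equal(out.marker, [5.0, 0.0])

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            pp.downsample(_rec(np.ones(100)), 33.0)


class TestEpochize:
    def _study1_rec(self, n_markers=23, duration=2000.0, rate=25.0):
        n = int(duration * rate)
        marker = np.zeros(n)
        onsets = 50.0 + 50.0 * np.arange(n_markers)
        for o in onsets:
            marker[int(o * rate)] = 5.0
        rec = _rec(np.full(n, 60.0), right=np.full(n, 55.0), marker=marker, rate=rate)
        markers = [TrialMarker(int(o * rate), float(o)) for o in onsets]
        return rec, markers

    def test_window_arithmetic(self):
        rec, markers = self._study1_rec()
        es = pp.epochize(rec, markers, pp.STUDY1_WORDGEN)
        assert es.data.shape == (23, 1025, 2)  # 41 s at 25 Hz
        assert es.time_axis[0] == pytest.approx(-11.0)
        # zero of the time axis is the "Clear Mind" onset
        assert np.min(np.abs(es.time_axis)) < 1e-9

    def test_out_of_range_epoch_dropped_with_warning(self, caplog):
        rec, _ = self._study1_rec(n_markers=1)
        markers = [TrialMarker(25, 1.0)]  # cue would start at -15 s
        with pytest.raises(ValueError, match="outside"):
            pp.epochize(rec, markers, pp.STUDY1_WORDGEN)

    def test_partial_drop_keeps_remaining(self, caplog):
        rec, markers = self._study1_rec()
        markers = [TrialMarker(25, 1.0)] + markers
        es = pp.epochize(rec, markers, pp.STUDY1_WORDGEN)
        assert es.n_trials == 23
        assert es.meta["dropped_epochs"] == 1

    def test_no_markers_is_an_error(self):
        rec, _ = self._study1_rec()
        with pytest.raises(ValueError, match="no markers"):
            pp.epochize(rec, [], pp.STUDY1_WORDGEN)


class TestManualExclusions:
    def test_empty_list_is_identity(self, study1_epochs):
        es = study1_epochs([2.0] * 23)
        out = pp.apply_manual_exclusions(es, [])
        assert out.n_included == 23
        np.testing.assert_array_equal(out.data, es.data)

    def test_exclude_two_of_23(self, study1_epochs):
        out = pp.apply_manual_exclusions(study1_epochs([2.0] * 23), [0, 5])
        assert out.n_included == 21
        assert out.reasons[0] == "manual" and out.reasons[5] == "manual"

    def test_out_of_range_index(self, study1_epochs):
        with pytest.raises(IndexError):
            pp.apply_manual_exclusions(study1_epochs([2.0] * 3), [3])


def _type7_quantile(values, q):
    """Independent linear-interpolation quantile (oracle)."""
    x = np.sort(np.asarray(values, dtype=float))
    pos = (x.size - 1) * q
    lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
    return x[lo] if frac == 0 else x[lo] + frac * (x[lo + 1] - x[lo])


class TestScreenExtremes:
    def _toy(self, epochset_factory, rng_seed=0):
        # discrete-valued baseline: the extreme quantiles land on tied
        # values, so clean data has no sample strictly beyond them
        rng = np.random.default_rng(rng_seed)
        data = 100.0 + rng.integers(-2, 3, size=(5, 200, 2)).astype(float)
        return epochset_factory(data, rate=25.0, t0=0.0)

    def test_no_extremes_unchanged(self, epochset_factory):
        es = self._toy(epochset_factory)
        out = pp.screen_extremes(es, pp.STUDY1_WORDGEN)
        np.testing.assert_array_equal(out.data, es.data)
        assert out.n_included == 5

    def test_single_spike_replaced_by_trial_mean(self, epochset_factory):
        es = self._toy(epochset_factory)
        es.data[2, 50, 0] = 1000.0  # one extreme sample, left channel
        expected = np.delete(es.data[2, :, 0], 50).mean()  # oracle
        # oracle membership check: the spike must be the only flagged sample
        for ch in range(2):
            hi = _type7_quantile(es.data[:, :, ch].ravel(), 0.999)
            lo = _type7_quantile(es.data[:, :, ch].ravel(), 0.0001)
            flagged = np.sum((es.data[:, :, ch] > hi) | (es.data[:, :, ch] < lo))
            assert flagged == (1 if ch == 0 else 0)
        out = pp.screen_extremes(es, pp.STUDY1_WORDGEN)
        assert out.n_included == 5
        assert out.data[2, 50, 0] == pytest.approx(expected)

    def test_two_spikes_exclude_the_trial(self, epochset_factory):
        es = self._toy(epochset_factory)
        es.data[3, 10, 0] = 1000.0  # left channel extreme
        es.data[3, 90, 1] = -1000.0  # right channel extreme, same trial
        out = pp.screen_extremes(es, pp.STUDY1_WORDGEN)
        assert not out.included[3]
        assert out.reasons[3] == "multi-extreme"
        assert out.n_included == 4


class TestNormalize:
    def test_constant_becomes_100(self, epochset_factory):
        es = epochset_factory(np.full((3, 40, 2), 50.0), t0=0.0)
        out = pp.normalize(es)
        np.testing.assert_allclose(out.data, 100.0)

    def test_single_high_sample(self, epochset_factory):
        data = np.full((1, 100, 2), 50.0)
        es = epochset_factory(data, t0=0.0)
        es.data[0, 0, 0] = 55.0
        out = pp.normalize(es)
        mean_left = (50.0 * 99 + 55.0) / 100
        assert out.data[0, 0, 0] == pytest.approx(55.0 / mean_left * 100)

    def test_grand_mean_invariant(self, epochset_factory):
        rng = np.random.default_rng(1)
        es = epochset_factory(60 + rng.normal(0, 5, (6, 80, 2)), t0=0.0,
                              included=[1, 1, 0, 1, 1, 1])
        out = pp.normalize(es)
        np.testing.assert_allclose(
            out.data[out.included].reshape(-1, 2).mean(axis=0), 100.0, atol=1e-6
        )

    def test_zero_mean_is_degenerate(self, epochset_factory):
        es = epochset_factory(np.zeros((2, 10, 2)), t0=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            pp.normalize(es)

    def test_idempotent(self, epochset_factory):
        rng = np.random.default_rng(2)
        es = epochset_factory(60 + rng.normal(0, 5, (4, 50, 2)), t0=0.0)
        once = pp.normalize(es)
        twice = pp.normalize(once)
        np.testing.assert_allclose(twice.data, once.data)


class TestHeartCycleIntegration:
    # pulse frequencies commensurate with the 25 Hz grid (whole samples
    # per cycle), so the analytic cycle mean of the cosine is exactly
    # zero; phased so the epoch starts at a trough and every peak keeps
    # its full prominence
    def _pulse_epochs(self, epochset_factory, base, rate=25.0, f_hz=1.25, amp=15.0):
        n = int(41 * rate)
        t = np.arange(n) / rate
        sig = base(t) + amp * np.cos(2 * np.pi * f_hz * t - np.pi)
        data = np.stack([sig, sig], axis=1)[None, :, :]
        return epochset_factory(data, rate=rate, t0=-11.0, stage="normalized"), t

    def test_constant_plus_pulsatility_recovers_constant(self, epochset_factory):
        # analytic cycle mean of a zero-mean cosine is 0 -> output ~ 100
        es, _ = self._pulse_epochs(epochset_factory, lambda t: np.full_like(t, 100.0))
        out = pp.heart_cycle_integrate(es)
        assert out.included[0]
        assert np.max(np.abs(out.data[0] - 100.0)) < 1.0  # within 1%

    def test_slow_trend_recovered(self, epochset_factory):
        trend = lambda t: 100.0 + 0.2 * t
        es, t = self._pulse_epochs(epochset_factory, trend, f_hz=2.5)
        out = pp.heart_cycle_integrate(es)
        expected = trend(t)
        rng_range = expected.max() - expected.min()
        assert np.max(np.abs(out.data[0, :, 0] - expected)) < 0.02 * rng_range

    def test_no_pulse_excludes_epoch(self, epochset_factory):
        es = epochset_factory(np.full((1, 200, 2), 100.0), t0=0.0,
                              stage="normalized")
        out = pp.heart_cycle_integrate(es)
        assert not out.included[0]
        assert out.reasons[0] == "no-pulse"

    def test_rerun_refused(self, epochset_factory):
        es, _ = self._pulse_epochs(epochset_factory, lambda t: np.full_like(t, 100.0))
        out = pp.heart_cycle_integrate(es)
        with pytest.raises(pp.PipelineOrderError):
            pp.heart_cycle_integrate(out)


class TestBaselineCorrect:
    def test_constant_goes_to_zero(self, study1_epochs):
        es = study1_epochs([0.0])
        out = pp.baseline_correct(es, pp.STUDY1_WORDGEN)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_poi_offset_survives(self, study1_epochs):
        es = study1_epochs([4.0])  # +4 on left inside POI only
        out = pp.baseline_correct(es, pp.STUDY1_WORDGEN)
        poi = (out.time_axis >= 8) & (out.time_axis < 20)
        np.testing.assert_allclose(out.data[0, poi, 0], 4.0)
        np.testing.assert_allclose(out.data[0, poi, 1], 0.0, atol=1e-12)

    def test_order_oracle_normalize_then_baseline(self, epochset_factory):
        # constant-plus-step toy, hand computation as the oracle
        rate, t0, n = 25.0, -11.0, 1025
        t = t0 + np.arange(n) / rate
        step = ((t >= 8) & (t < 20)).astype(float)
        left = 50.0 + 5.0 * step
        right = 40.0 + 2.0 * step
        data = np.stack([left, right], axis=1)[None, :, :]
        es = epochset_factory(data, rate=rate, t0=t0)
        out = pp.baseline_correct(pp.normalize(es), pp.STUDY1_WORDGEN)
        # oracle: x / mean(x) * 100 - baseline_mean, elementwise
        for ch, sig in ((0, left), (1, right)):
            norm = sig / sig.mean() * 100.0
            base = norm[(t >= -10) & (t < 0)].mean()
            np.testing.assert_allclose(out.data[0, :, ch], norm - base, atol=1e-9)

    def test_idempotent(self, study1_epochs):
        es = study1_epochs([4.0, 2.0])
        once = pp.baseline_correct(es, pp.STUDY1_WORDGEN)
        twice = pp.baseline_correct(once, pp.STUDY1_WORDGEN)
        np.testing.assert_allclose(twice.data, once.data)
        np.testing.assert_array_equal(twice.prebaseline, once.prebaseline)


class TestRejectRange:
    def test_in_range_unchanged(self, epochset_factory):
        es = epochset_factory(
            np.random.default_rng(0).uniform(90, 110, (4, 50, 2)),
            t0=0.0, stage="normalized",
        )
        out = pp.reject_range(es, pp.STUDY1_WORDGEN)
        assert out.n_included == 4

    def test_single_150_sample_excludes_trial(self, epochset_factory):
        es = epochset_factory(np.full((2, 50, 2), 100.0), t0=0.0, stage="normalized")
        es.data[1, 10, 0] = 150.0
        out = pp.reject_range(es, pp.STUDY1_WORDGEN)
        assert out.included[0] and not out.included[1]
        assert out.reasons[1] == "out-of-range"

    def test_survivor_count_matches_enumeration(self, epochset_factory):
        rng = np.random.default_rng(3)
        data = rng.uniform(70, 130, (8, 60, 2))
        data[1, 5, 0] = 59.0
        data[4, 0, 1] = 141.0
        data[6, 30, 0] = 20.0
        es = epochset_factory(data, t0=0.0, stage="normalized")
        out = pp.reject_range(es, pp.STUDY1_WORDGEN)
        expected = [
            bool(np.all((data[i] >= 60) & (data[i] <= 140))) for i in range(8)
        ]
        np.testing.assert_array_equal(out.included, expected)

    def test_uses_pre_baseline_values_after_step7(self, study1_epochs):
        es = study1_epochs([4.0], base=100.0)
        es = pp.baseline_correct(es, pp.STUDY1_WORDGEN)
        # data now centred on 0; the screen must consult the snapshot
        out = pp.reject_range(es, pp.STUDY1_WORDGEN)
        assert out.included[0]

    def test_requires_normalization_first(self, study1_epochs):
        with pytest.raises(pp.PipelineOrderError):
            pp.reject_range(study1_epochs([2.0]), pp.STUDY1_WORDGEN)


class TestMinTrials:
    @pytest.mark.parametrize(
        "counts,expected",
        [((21, 22), True), ((14, 23), False), ((15, 15), True)],
    )
    def test_strict_fewer_than(self, counts, expected):
        assert pp.enforce_min_trials(counts, pp.STUDY1_WORDGEN) is expected


class TestPipelineDiscipline:
    def test_out_of_order_refused(self, study1_epochs):
        es = pp.baseline_correct(pp.normalize(study1_epochs([2.0])),
                                 pp.STUDY1_WORDGEN)
        with pytest.raises(pp.PipelineOrderError):
            pp.normalize(es)
        with pytest.raises(pp.PipelineOrderError):
            pp.screen_extremes(es, pp.STUDY1_WORDGEN)

    def test_exclusion_is_monotone(self, epochset_factory):
        rng = np.random.default_rng(4)
        data = 100 + rng.normal(0, 3, (6, 1025, 2))
        data[0, 3, 0] = 500.0
        data[0, 7, 1] = 500.0
        es = epochset_factory(data, t0=-11.0)
        included = [es.included.copy()]
        es = pp.apply_manual_exclusions(es, [2])
        included.append(es.included.copy())
        es = pp.screen_extremes(es, pp.STUDY1_WORDGEN)
        included.append(es.included.copy())
        es = pp.normalize(es)
        included.append(es.included.copy())
        es = pp.baseline_correct(es, pp.STUDY1_WORDGEN)
        included.append(es.included.copy())
        es = pp.reject_range(es, pp.STUDY1_WORDGEN)
        included.append(es.included.copy())
        for before, after in zip(included, included[1:]):
            assert np.all(before | ~after), "a step re-included a trial"


class TestNoiselessStepResponse:
    def test_final_poi_difference_equals_injected_difference(self):
        """Pulsatility-free, noise-free step of +a%/+b% -> LI == a-b.

        The input is built the way the synthetic generator builds task
        responses: amplitudes pre-compensated for the whole-epoch
        normalization mean, which makes the pipeline exact.
        """
        a, b = 5.0, 2.0
        fs, n_trials, trial_len, lead_in = 100.0, 4, 50.0, 20.0
        cfg = pp.STUDY1_WORDGEN
        T = lead_in + n_trials * trial_len + 10.0
        t = np.arange(int(T * fs)) / fs
        cues = lead_in + trial_len * np.arange(n_trials)
        marker = np.zeros(t.size)
        s = np.zeros(t.size)
        for cue in cues:
            marker[int((cue + cfg.marker_offset_s) * fs)] = 5.0
            s[(t >= cue + 8.0) & (t < cue + 20.0)] = 1.0
        f = 12.0 / 41.0  # epoch fraction occupied by the step
        chans = []
        for rho, base in ((a, 60.0), (b, 55.0)):
            kappa = (f * rho / 100.0) / (1.0 - f * rho / 100.0)
            chans.append(base * (1.0 + rho * (1.0 + kappa) * s / 100.0))
        rec = RawRecording(100.0, t, chans[0], chans[1], marker)
        markers = extract_markers(rec)
        rec25 = pp.downsample(rec, cfg.target_rate)
        es = pp.epochize(rec25, markers, cfg)
        es = pp.apply_manual_exclusions(es, [])
        es = pp.screen_extremes(es, cfg)
        es = pp.normalize(es)
        es = pp.baseline_correct(es, cfg)  # no cardiac pulse to integrate
        es = pp.reject_range(es, cfg)
        assert es.n_included == n_trials
        li = li_mean(grand_average(es), es.time_axis, cfg.poi)
        assert li == pytest.approx(a - b, abs=1e-9)


class TestParadigmConfig:
    def test_presets(self):
        s2 = pp.get_paradigm("study2_fluency")
        assert s2.poi == (6.0, 20.0)
        assert s2.marker_offset_s == 3.0
        assert pp.get_paradigm("study1_wordgen").poi == (8.0, 20.0)

    def test_unknown_paradigm(self):
        with pytest.raises(ValueError, match="unknown paradigm"):
            pp.get_paradigm("study3")

    def test_window_order_validated(self):
        with pytest.raises(ValueError):
            pp.ParadigmConfig(baseline=(0.0, -10.0))

    def test_yaml_roundtrip(self, tmp_path):
        cfg = pp.get_paradigm("study2_fluency")
        path = cfg.to_file(tmp_path / "cfg.yaml")
        assert pp.ParadigmConfig.from_file(path) == cfg
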