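import dataclasses

import numpy as np
import pytest

from prefall.activity_scripts import make_script, static_script
from prefall.detector import (
    DetectorConfig,
    compute_features,
    detect,
    detect_features,
    detect_trial,
    sweep_thresholds,
)
from prefall.orientation import estimate_series
from prefall.signals import lowpass
from prefall.synthetic import MotionScript, NoiseModel, synthesize

from conftest import random_trial


def brute_force_detect_index(feat, cfg):
    """Independent O(n*w) re-scan of the window-coincidence rule."""
    t = feat.t
    w = int(round(cfg.window_s * feat.rate_hz))
    warm = (t - t[0]) < cfg.warmup_s
    angle = ((np.abs(feat.roll) > cfg.th_roll) | (feat.pitch > cfg.th_pitch)) & ~warm
    wc = (feat.wsvm > cfg.th_wsvm) & ~warm
    ac = (feat.asvm < cfg.th_asvm) & ~warm
    for i in range(len(t)):
        lo = max(0, i - w)
        sl = slice(lo, i + 1)
        if angle[sl].any() and wc[sl].any() and ac[sl].any():
            return i
    return None


class TestDetect:
    def test_quiet_standing_is_not_a_fall(self):
        trial = synthesize(static_script(duration_s=6.0), NoiseModel(seed=1))
        assert detect_trial(trial.series) is None

    def test_backward_fall_detected_before_impact(self):
        trial = synthesize(make_script("backward_fall", np.random.default_rng(2)), NoiseModel(seed=2))
        event = detect_trial(trial.series)
        assert event is not None
        assert event.t_detect < trial.t_impact  # strictly positive lead time
        assert event.triggered_by in ("pitch", "roll+pitch")

    def test_slow_lying_down_is_not_a_fall(self):
        """The vertical angle reaches ~90 deg as in a fall, but the body
        stays supported: no aSVM dip, low wSVM, hence no detection."""
        trial = synthesize(make_script("lying_down", np.random.default_rng(3)), NoiseModel(seed=3))
        feat = compute_features(trial.series)
        assert feat.pitch.max() > 80.0
        assert detect_features(feat) is None

    def test_misaligned_angles_rejected(self):
        trial = synthesize(static_script(duration_s=4.0), NoiseModel(seed=4))
        filt = lowpass(trial.series)
        track = estimate_series(filt)
        track.t = track.t + 0.5  # break the 1:1 alignment
        with pytest.raises(ValueError):
            detect(filt, track, DetectorConfig())

    def test_deterministic(self):
        trial = random_trial(77)
        a = detect_trial(trial.series)
        b = detect_trial(trial.series)
        assert a == b

    def test_window_zero_forces_same_sample_coincidence(self):
        trial = synthesize(make_script("backward_fall", np.random.default_rng(5)), NoiseModel(seed=5))
        feat = compute_features(trial.series)
        windowed = detect_features(feat, DetectorConfig(window_s=0.10))
        same_sample = detect_features(feat, DetectorConfig(window_s=0.0))
        assert windowed is not None
        assert same_sample is None or same_sample.t_detect >= windowed.t_detect

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_brute_force_oracle(self, seed):
        feat = compute_features(random_trial(1000 + seed).series)
        cfg = DetectorConfig()
        event = detect_features(feat, cfg)
        oracle = brute_force_detect_index(feat, cfg)
        assert (None if event is None else event.index) == oracle

    def test_threshold_monotonicity_small_sample(self):
        feats = [compute_features(random_trial(2000 + s).series) for s in range(20)]

        def n_detected(cfg):
            return sum(detect_features(f, cfg) is not None for f in feats)

        base = DetectorConfig()
        n_base = n_detected(base)
        for tight in (
            dataclasses.replace(base, th_roll=40.0),
            dataclasses.replace(base, th_pitch=60.0),
            dataclasses.replace(base, th_wsvm=90.0),
            dataclasses.replace(base, th_asvm=0.5),
        ):
            assert n_detected(tight) <= n_base


class TestSweep:
    def _separable_set(self):
        """Falls reach pitch ~90, ADLs never exceed 20 deg: separable."""
        trials = []
        for s in range(3):
            trials.append(synthesize(make_script("backward_fall", np.random.default_rng(s)), NoiseModel(seed=s)))
            trials.append(synthesize(static_script(0.0, 15.0, 6.0, name="adl_tilt"), NoiseModel(seed=10 + s)))
            trials.append(synthesize(make_script("walking", np.random.default_rng(s)), NoiseModel(seed=20 + s)))
        return trials

    def test_single_point_grid_matches_direct_evaluation(self):
        trials = self._separable_set()
        cfg = DetectorConfig()
        res = sweep_thresholds(trials, {"th_asvm": [cfg.th_asvm]})
        assert len(res.table) == 1
        row = res.table.iloc[0]
        detected = sum(detect_trial(tr.series, cfg) is not None for tr in trials)
        assert row["tp"] + row["fp"] == detected

    def test_separable_set_reaches_perfect_point(self):
        trials = self._separable_set()
        res = sweep_thresholds(
            trials,
            {"th_pitch": [30.0, 45.0, 60.0], "th_asvm": [0.7, 0.82]},
        )
        assert res.best is not None
        assert res.best["sensitivity"] == 100.0
        assert res.best["specificity"] == 100.0
        # tie-break prefers the smallest aSVM threshold
        perfect = res.table[(res.table.sensitivity == 100.0) & (res.table.specificity == 100.0)]
        assert res.best["th_asvm"] == perfect["th_asvm"].min()

    def test_default_thresholds_row_present_with_finite_metrics(self):
        trials = self._separable_set()
        res = sweep_thresholds(
            trials,
            {"th_asvm": [0.82], "th_wsvm": [47.3], "th_roll": [28.0], "th_pitch": [45.0]},
        )
        row = res.table.iloc[0]
        assert np.isfinite(row["sensitivity"]) and np.isfinite(row["specificity"])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_thresholds(self._separable_set(), {"th_asvm": []})

    def test_needs_both_classes(self):
        adls = [synthesize(make_script("walking", np.random.default_rng(s)), NoiseModel(seed=s)) for s in range(2)]
        with pytest.raises(ValueError):
            sweep_thresholds(adls, {"th_asvm": [0.82]})
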