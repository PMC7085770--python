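import math

import numpy as np
import pytest

from prefall.activity_scripts import static_script
from prefall.orientation import (
    FilterGains,
    OrientationState,
    UndefinedInclinationError,
    accel_angles,
    estimate_series,
    euler_rates,
    fuse_step,
)
from prefall.signals import ImuSample, ImuSeries
from prefall.synthetic import MotionScript, NoiseModel, synthesize

from conftest import make_static_series


class TestAccelAngles:
    @pytest.mark.parametrize(
        "a, roll, pitch",
        [
            ((0.0, 0.0, 1.0), 0.0, 0.0),
            ((0.0, 0.5, 0.8660254), 30.0, 0.0),  # gravity rotated 30 deg about x
            ((0.7071068, 0.0, 0.7071068), 0.0, 45.0),  # rotated 45 deg about y
        ],
    )
    def test_known_tilts(self, a, roll, pitch):
        r, p = accel_angles(*a)
        assert r == pytest.approx(roll, abs=0.01)
        assert p == pytest.approx(pitch, abs=0.01)

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedInclinationError):
            accel_angles(0.0, 0.0, 0.0)


class TestEulerRates:
    @pytest.mark.parametrize(
        "g, roll, pitch, expected",
        [
            ((10.0, 0.0, 0.0), 37.0, 0.0, (10.0, 0.0)),  # x-rate passes through level
            ((0.0, 10.0, 0.0), 0.0, 0.0, (0.0, 10.0)),
            # hand-substitution: roll_rate = cos(90)tan(45)*10 = 0, pitch_rate = -sin(90)*10
            ((0.0, 0.0, 10.0), 90.0, 45.0, (0.0, -10.0)),
        ],
    )
    def test_kinematic_map(self, g, roll, pitch, expected):
        rr, pr = euler_rates(*g, roll, pitch)
        assert rr == pytest.approx(expected[0], abs=1e-9)
        assert pr == pytest.approx(expected[1], abs=1e-9)

    def test_gimbal_guard_clamps_tan(self):
        rr_at_89, _ = euler_rates(0.0, 0.0, 10.0, 0.0, 89.0)
        rr_beyond, _ = euler_rates(0.0, 0.0, 10.0, 0.0, 89.9)
        assert rr_beyond == pytest.approx(rr_at_89)


class TestFuseStep:
    def test_zero_gains_zero_gyro_is_identity(self):
        state = OrientationState(roll=12.0, pitch=-7.0)
        sample = ImuSample(0.01, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0)
        out = fuse_step(state, sample, FilterGains(kp=0.0, ki=0.0), dt=0.01)
        assert out.roll == pytest.approx(12.0)
        assert out.pitch == pytest.approx(-7.0)

    def test_proportional_decay_half_life(self):
        """Static upright + kp-only correction decays the offset like a
        first-order system: half-life must match ln(2)/kp within 10%."""
        kp, dt = 1.0, 0.01
        gains = FilterGains(kp=kp, ki=0.0)
        state = OrientationState(roll=10.0, pitch=0.0)
        sample_at = lambda t: ImuSample(t, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0)
        t, half_life = 0.0, None
        for _ in range(500):
            t += dt
            state = fuse_step(state, sample_at(t), gains, dt)
            if half_life is None and abs(state.roll) <= 5.0:
                half_life = t
        assert half_life == pytest.approx(math.log(2) / kp, rel=0.10)

    def test_non_finite_sample_leaves_state_unchanged(self):
        state = OrientationState(roll=3.0, pitch=4.0, i_roll=1.0)
        bad = ImuSample.__new__(ImuSample)  # bypass validation to craft NaN
        object.__setattr__(bad, "t", 0.01)
        for f, v in zip(("ax", "ay", "az", "gx", "gy", "gz"), (0, 0, float("nan"), 0, 0, 0)):
            object.__setattr__(bad, f, float(v))
        out = fuse_step(state, bad, FilterGains(), dt=0.01)
        assert (out.roll, out.pitch, out.i_roll) == (3.0, 4.0, 1.0)


class TestBiasRejection:
    def _biased_series(self, seconds=35.0, bias=2.0):
        n = int(seconds * 100) + 1
        return make_static_series(n=n, gyr=(bias, 0.0, 0.0))

    def test_pi_cancels_constant_gyro_bias(self):
        """With the integral term, a 2 deg/s bias leaves <0.5 deg of
        steady-state roll error after 30 s."""
        series = self._biased_series()
        track = estimate_series(series, FilterGains(kp=1.0, ki=0.1))
        i30 = np.searchsorted(series.t, 30.0)
        assert abs(track.roll[i30]) < 0.5
        # the integrator has learned the bias (roll channel, deg/s)
        assert track.i_roll[i30] == pytest.approx(-2.0, abs=0.3)

    def test_proportional_only_plateaus_at_nonzero_error(self):
        series = self._biased_series()
        track = estimate_series(series, FilterGains(kp=1.0, ki=0.0))
        tail = track.roll[-200:]
        assert np.all(np.abs(tail) > 1.0)  # plateau near bias/kp = 2 deg
        assert np.ptp(tail) < 0.1


class TestEstimateSeries:
    def test_matches_repeated_fuse_step(self):
        trial = synthesize(
            MotionScript("wiggle", False, 2.0, [(0, 0, 0), (1.0, 25, 10), (2.0, 5, -5)]),
            NoiseModel(seed=3),
        )
        track = estimate_series(trial.series)
        state = None
        for i, sample in enumerate(trial.series):
            if state is None:
                r, p = accel_angles(sample.ax, sample.ay, sample.az)
                state = OrientationState(r, p, t=sample.t)
            else:
                state = fuse_step(state, sample, FilterGains(), trial.series.dt)
            assert state.roll == pytest.approx(track.roll[i], abs=1e-9)
            assert state.pitch == pytest.approx(track.pitch[i], abs=1e-9)

    def test_zero_gains_equal_pure_euler_integration_oracle(self):
        """kp=ki=0 must reduce to plain Euler integration of the gyro;
        verified against an independent step-by-step reimplementation."""
        rng = np.random.default_rng(11)
        n, rate = 100, 100.0
        t = np.arange(n) / rate
        acc = np.tile((0.0, 0.0, 1.0), (n, 1))
        gyr = rng.uniform(-30, 30, (n, 3))
        series = ImuSeries(t, acc, gyr, rate)
        track = estimate_series(series, FilterGains(kp=0.0, ki=0.0))

        roll, pitch, dt = 0.0, 0.0, 1.0 / rate
        for i in range(1, n):
            gx, gy, gz = gyr[i]
            tp = math.tan(math.radians(max(-89.0, min(89.0, pitch))))
            sr, cr = math.sin(math.radians(roll)), math.cos(math.radians(roll))
            roll += (gx + sr * tp * gy + cr * tp * gz) * dt
            pitch += (cr * gy - sr * gz) * dt
            assert track.roll[i] == pytest.approx(roll, abs=1e-6)
            assert track.pitch[i] == pytest.approx(pitch, abs=1e-6)

    def test_large_kp_tracks_accel_angles_on_static_input(self):
        series = make_static_series(n=400, acc=(0.0, 0.5, 0.8660254))
        track = estimate_series(series, FilterGains(kp=50.0, ki=0.0))
        assert abs(track.roll[-1] - 30.0) < 1.0
        assert abs(track.pitch[-1]) < 1.0

    def test_invariant_to_timestamp_offset(self):
        trial = synthesize(static_script(10.0, 5.0, 3.0), NoiseModel(seed=4))
        s = trial.series
        shifted = ImuSeries(s.t + 1234.5, s.acc, s.gyr, s.rate_hz)
        a = estimate_series(s)
        b = estimate_series(shifted)
        assert np.array_equal(a.roll, b.roll)
        assert np.array_equal(a.pitch, b.pitch)

    def test_quiet_standing_stays_upright(self, quiet_standing_series):
        track = estimate_series(quiet_standing_series)
        post = slice(50, None)
        assert np.all(np.abs(track.roll[post]) < 3.0)
        assert np.all(np.abs(track.pitch[post]) < 3.0)

    def test_recovers_scripted_90_degree_roll(self):
        script = MotionScript(
            "roll90", False, 3.0,
            [(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (2.0, 90.0, 0.0), (3.0, 90.0, 0.0)],
            interp="linear",
        )
        trial = synthesize(script, NoiseModel(0.0, 0.0))
        track = estimate_series(trial.series)
        assert abs(track.roll[-1] - 90.0) < 2.0

    def test_starts_from_accelerometer_angles_when_lying(self):
        series = make_static_series(n=300, acc=(0.9848078, 0.0, 0.1736482))  # pitch 80
        track = estimate_series(series)
        assert track.pitch[0] == pytest.approx(80.0, abs=0.01)
        assert np.all(np.abs(track.pitch - 80.0) < 1.0)

    def test_bounded_on_wild_input_no_windup(self):
        rng = np.random.default_rng(5)
        n, rate = 3000, 100.0
        acc = rng.uniform(-3, 3, (n, 3))
        acc[np.abs(acc).sum(axis=1) == 0] = (0, 0, 1)
        gyr = rng.uniform(-500, 500, (n, 3))
        series = ImuSeries(np.arange(n) / rate, acc, gyr, rate)
        track = estimate_series(series, i_limit_deg=20.0)
        assert np.all(np.abs(track.roll) <= 180.0)
        assert np.all(np.abs(track.pitch) < 90.0)
        assert np.all(np.abs(track.i_roll) <= 20.0)
        assert np.all(np.abs(track.i_pitch) <= 20.0)

    def test_pre_and_post_correction_agree_at_small_angles(self):
        trial = synthesize(static_script(3.0, 2.0, 5.0), NoiseModel(seed=9))
        a = estimate_series(trial.series, correction="post")
        b = estimate_series(trial.series, correction="pre")
        assert np.allclose(a.roll, b.roll, atol=0.2)
        assert np.allclose(a.pitch, b.pitch, atol=0.2)
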