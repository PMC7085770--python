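"""Script library: parameterised motion scripts for the 20 study activities.

Every builder takes a seeded ``numpy.random.Generator`` and returns a
:class:`~prefall.synthetic.MotionScript` with per-trial timing and
amplitude jitter.  All tunable kinematic parameters live in
``SCRIPT_PARAMS`` below, so the whole activity repertoire can be edited
in one place.

Design notes (no kinematic profiles exist for the original trials, so
these are plausible morphologies, not fits):

* falls descend in 0.4-0.8 s with a free-fall dip of the acceleration
  SVM before impact and a >2 g spike at the scripted impact time;
* slow lying/sitting takes seconds, keeps the acceleration SVM near
  1 g and the angular-velocity SVM below the detector threshold;
* highly dynamic ADLs (jogging, jumping, quick sits, ...) exceed 2 g
  peak acceleration SVM, the rest stay below 2 g;
* jogging includes a "curve section" with a sustained lateral lean
  whose jittered amplitude straddles the 28 deg roll threshold, and the
  quick-sit activities a backward pitch overshoot straddling 45 deg —
  so a realistic minority of highly dynamic trials become false
  positives, mimicking the known failure modes of the detector;
* forward leans (waist bending, stumbling) use *negative* pitch and can
  never trip the signed backward-pitch condition.
"""

from __future__ import annotations

import numpy as np

from .activities import ADL_ACTIVITIES, FALL_ACTIVITIES
from .synthetic import AngularOscillation, MotionScript, SupportOscillation

__all__ = ["SCRIPT_PARAMS", "make_script", "static_script"]


SCRIPT_PARAMS: dict[str, dict] = {
    # --- ADLs ---------------------------------------------------------
    "walking": dict(duration=8.0, stride_hz=(1.6, 2.0), load_amp=(0.2, 0.3),
                    sway_roll=(1.5, 2.5), sway_pitch=(1.5, 2.0)),
    "jogging": dict(duration=8.0, stride_hz=(2.5, 3.0), load_amp=(1.05, 1.25),
                    sway_roll=(3.0, 5.0), sway_pitch=(2.0, 4.0),
                    curve_roll=(8.0, 27.0), curve_start=(2.5, 3.5), curve_len=(1.5, 2.5),
                    curve_lean=(3.0, 6.0)),
    "squatting": dict(duration=7.0, pitch_lean=(8.0, 15.0), load=(0.85, 1.25)),
    "waist_bending": dict(duration=7.0, bend=(40.0, 60.0)),
    "lying_down": dict(duration=10.0, final_pitch=(85.0, 88.5)),
    "running_in_place": dict(duration=6.0, stride_hz=(2.6, 3.0), load_amp=(1.05, 1.25),
                             sway_roll=(2.0, 3.5), shift_roll=(10.0, 25.5)),
    "jumping": dict(duration=7.0, n_jumps=3, landing=(2.2, 2.6), flight=0.12),
    "stairs": dict(duration=8.0, stride_hz=(1.4, 1.7), load_amp=(0.25, 0.35),
                   sway_roll=(1.5, 2.5)),
    "slow_sit_stool": dict(duration=7.0, pitch_peak=(15.0, 22.0), contact=(1.15, 1.3)),
    "quick_sit_chair": dict(duration=6.0, descent=0.35, pitch_peak=(28.0, 46.2),
                            dip=0.5, spike=(2.1, 2.4)),
    "collapse_chair": dict(duration=6.0, descent=0.3, pitch_peak=(30.0, 45.7),
                           dip=0.5, spike=(2.1, 2.5)),
    "stumble_walking": dict(duration=7.0, stride_hz=(1.6, 1.8), load_amp=(0.25, 0.3),
                            lurch=(15.0, 25.0), spike=(2.2, 2.6)),
    "slow_sit_mattress": dict(duration=7.0, pitch_peak=(20.0, 30.0), contact=(1.3, 1.6)),
    "quick_sit_mattress": dict(duration=6.0, descent=0.42, pitch_peak=(29.0, 46.5),
                               dip=0.48, spike=(2.3, 2.7)),
    # --- falls --------------------------------------------------------
    "slip_backward_fall": dict(descent=(0.5, 0.6), pitch_peak=(80.0, 86.0),
                               dip=0.3, spike=(3.2, 3.8)),
    "sitdown_backward_fall": dict(descent=(0.42, 0.5), pitch_peak=(60.0, 70.0),
                                  rest_extra=5.0, dip=0.5, spike=(2.4, 2.8)),
    "sit_backward_fall": dict(descent=(0.55, 0.65), pitch_peak=(75.0, 82.0),
                              start_pitch=(10.0, 14.0), dip=0.45, spike=(2.6, 3.0)),
    "backward_fall": dict(descent=(0.65, 0.75), pitch_peak=(78.0, 85.0),
                          dip=0.35, spike=(2.8, 3.4)),
    "lateral_fall": dict(descent=(0.6, 0.7), roll_peak=(75.0, 83.0),
                         pitch_peak=(2.0, 6.0), dip=0.4, spike=(2.8, 3.2)),
    "twist_fall": dict(descent=(0.7, 0.8), roll_peak=(74.0, 82.0),
                       mid_pitch=(35.0, 43.0), mid_roll=(16.0, 22.0),
                       dip=0.4, spike=(2.6, 3.0)),
}


def _u(rng: np.random.Generator, bounds) -> float:
    lo, hi = bounds
    return float(rng.uniform(lo, hi))


def static_script(roll: float = 0.0, pitch: float = 0.0, duration_s: float = 10.0,
                  name: str = "static") -> MotionScript:
    """A motionless placement at a fixed tilt (prism-style validation)."""
    return MotionScript(
        name, False, duration_s,
        [(0.0, roll, pitch), (duration_s, roll, pitch)], interp="linear",
    )


# --------------------------------------------------------------------------
# ADL builders

def _walking_like(name: str, rng) -> MotionScript:
    p = SCRIPT_PARAMS[name]
    dur = p["duration"]
    f = _u(rng, p["stride_hz"])
    osc_span = (0.5, dur - 0.5)
    ang = [
        AngularOscillation("roll", _u(rng, p["sway_roll"]), f, *osc_span,
                           phase=rng.uniform(0, 2 * np.pi)),
    ]
    if "sway_pitch" in p:
        ang.append(AngularOscillation("pitch", _u(rng, p["sway_pitch"]), f, *osc_span,
                                      phase=rng.uniform(0, 2 * np.pi)))
    sup = [SupportOscillation(_u(rng, p["load_amp"]), f, *osc_span)]
    kf = [(0.0, 0.0, 0.0), (dur, 0.0, 0.0)]
    return MotionScript(name, False, dur, kf, ang_osc=ang, sup_osc=sup)


def _walking(rng) -> MotionScript:
    return _walking_like("walking", rng)


def _stairs(rng) -> MotionScript:
    return _walking_like("stairs", rng)


def _jogging(rng) -> MotionScript:
    p = SCRIPT_PARAMS["jogging"]
    dur = p["duration"]
    f = _u(rng, p["stride_hz"])
    tc = _u(rng, p["curve_start"])
    tl = _u(rng, p["curve_len"])
    c = _u(rng, p["curve_roll"]) * (1 if rng.random() < 0.5 else -1)
    lean = _u(rng, p["curve_lean"])
    kf = [
        (0.0, 0.0, 0.0),
        (tc, 0.0, 0.0),
        (tc + 0.4, c, lean),
        (tc + tl - 0.4, c, lean),
        (tc + tl, 0.0, 0.0),
        (dur, 0.0, 0.0),
    ]
    osc_span = (0.5, dur - 0.5)
    ang = [
        AngularOscillation("roll", _u(rng, p["sway_roll"]), f, *osc_span,
                           phase=rng.uniform(0, 2 * np.pi)),
        AngularOscillation("pitch", _u(rng, p["sway_pitch"]), f, *osc_span,
                           phase=rng.uniform(0, 2 * np.pi)),
    ]
    sup = [SupportOscillation(_u(rng, p["load_amp"]), f, *osc_span)]
    return MotionScript("jogging", False, dur, kf, ang_osc=ang, sup_osc=sup)


def _running_in_place(rng) -> MotionScript:
    p = SCRIPT_PARAMS["running_in_place"]
    dur = p["duration"]
    f = _u(rng, p["stride_hz"])
    c = _u(rng, p["shift_roll"]) * (1 if rng.random() < 0.5 else -1)
    kf = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.5, c, 0.0), (4.3, c, 0.0),
          (5.2, 0.0, 0.0), (dur, 0.0, 0.0)]
    osc_span = (0.5, dur - 0.5)
    ang = [AngularOscillation("roll", _u(rng, p["sway_roll"]), f, *osc_span,
                              phase=rng.uniform(0, 2 * np.pi))]
    sup = [SupportOscillation(_u(rng, p["load_amp"]), f, *osc_span)]
    return MotionScript("running_in_place", False, dur, kf, ang_osc=ang, sup_osc=sup)


def _squatting(rng) -> MotionScript:
    p = SCRIPT_PARAMS["squatting"]
    dur = p["duration"]
    lean = _u(rng, p["pitch_lean"])
    lo, hi = p["load"]
    kf = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.3, 0.0, -lean), (3.1, 0.0, 0.0),
          (4.0, 0.0, -lean), (4.8, 0.0, 0.0), (dur, 0.0, 0.0)]
    support = [(0.0, 1.0), (1.9, lo), (2.7, hi), (3.5, lo), (4.4, hi), (5.2, 1.0)]
    return MotionScript("squatting", False, dur, kf, support=support)


def _waist_bending(rng) -> MotionScript:
    p = SCRIPT_PARAMS["waist_bending"]
    dur = p["duration"]
    bend = _u(rng, p["bend"])
    kf = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.7, 0.0, -bend), (3.8, 0.0, -bend),
          (5.0, 0.0, 0.0), (dur, 0.0, 0.0)]
    support = [(0.0, 1.0), (2.1, 0.95), (3.0, 1.08), (4.5, 0.95), (5.4, 1.0)]
    return MotionScript("waist_bending", False, dur, kf, support=support)


def _lying_down(rng) -> MotionScript:
    p = SCRIPT_PARAMS["lying_down"]
    dur = p["duration"]
    fp = _u(rng, p["final_pitch"])
    kf = [(0.0, 0.0, 0.0), (2.0, 0.0, 0.0), (3.5, 0.0, 0.40 * fp),
          (5.0, 0.0, 0.75 * fp), (6.0, 0.0, fp), (dur, 0.0, fp)]
    support = [(0.0, 1.0), (5.0, 1.0), (6.0, 1.08), (6.5, 0.96), (7.2, 1.0)]
    return MotionScript("lying_down", False, dur, kf, support=support)


def _jumping(rng) -> MotionScript:
    p = SCRIPT_PARAMS["jumping"]
    dur = p["duration"]
    support = [(0.0, 1.0)]
    tj = 1.5
    for _ in range(p["n_jumps"]):
        support += [(tj, 1.0), (tj + 0.15, 0.45), (tj + 0.30, p["flight"]),
                    (tj + 0.42, _u(rng, p["landing"])), (tj + 0.55, 1.2), (tj + 0.70, 1.0)]
        tj += 1.5
    kf = [(0.0, 0.0, 0.0), (dur, 0.0, 0.0)]
    ang = [AngularOscillation("roll", 1.5, 2.0, 1.0, dur - 1.0)]
    return MotionScript("jumping", False, dur, kf, support=support, ang_osc=ang)


def _slow_sit(name: str, rng) -> MotionScript:
    p = SCRIPT_PARAMS[name]
    dur = p["duration"]
    peak = _u(rng, p["pitch_peak"])
    contact = _u(rng, p["contact"])
    kf = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.8, 0.0, peak), (3.6, 0.0, 0.4 * peak),
          (5.0, 0.0, 0.3 * peak), (5.8, 0.0, -3.0), (dur, 0.0, 0.0)]
    support = [(0.0, 1.0), (2.4, 0.82), (3.1, contact), (3.8, 1.0),
               (5.6, 0.9), (6.1, 1.12), (dur, 1.0)]
    return MotionScript(name, False, dur, kf, support=support)


def _slow_sit_stool(rng) -> MotionScript:
    return _slow_sit("slow_sit_stool", rng)


def _slow_sit_mattress(rng) -> MotionScript:
    return _slow_sit("slow_sit_mattress", rng)


def _quick_sit(name: str, rng) -> MotionScript:
    p = SCRIPT_PARAMS[name]
    dur = p["duration"]
    d = p["descent"]
    t0 = _u(rng, (1.2, 1.8))
    peak = _u(rng, p["pitch_peak"])
    spike = _u(rng, p["spike"])
    kf = [(0.0, 0.0, 0.0), (t0, 0.0, 0.0), (t0 + d, 0.0, peak),
          (t0 + 1.0, 0.0, _u(rng, (8.0, 14.0))), (t0 + 2.2, 0.0, 10.0),
          (t0 + 2.6, 0.0, -4.0), (t0 + 3.2, 0.0, 0.0), (dur, 0.0, 0.0)]
    support = [(0.0, 1.0), (t0, 1.0), (t0 + 0.4 * d, 0.62), (t0 + 0.75 * d, p["dip"]),
               (t0 + d + 0.03, spike), (t0 + d + 0.2, 1.1), (t0 + 2.0, 1.0),
               (t0 + 2.35, 1.35), (t0 + 2.7, 1.0)]
    return MotionScript(name, False, dur, kf, support=support)


def _quick_sit_chair(rng) -> MotionScript:
    return _quick_sit("quick_sit_chair", rng)


def _quick_sit_mattress(rng) -> MotionScript:
    return _quick_sit("quick_sit_mattress", rng)


def _collapse_chair(rng) -> MotionScript:
    p = SCRIPT_PARAMS["collapse_chair"]
    dur = p["duration"]
    s0 = _u(rng, (8.0, 12.0))
    tc = 2.1
    peak = _u(rng, p["pitch_peak"])
    spike = _u(rng, p["spike"])
    kf = [(0.0, 0.0, s0), (1.2, 0.0, s0), (1.7, 0.0, _u(rng, (0.0, 4.0))),
          (tc, 0.0, 2.0), (tc + p["descent"], 0.0, peak), (tc + 1.2, 0.0, 12.0),
          (dur, 0.0, 12.0)]
    support = [(0.0, 1.0), (1.5, 1.15), (tc, 0.95), (tc + 0.12, 0.55),
               (tc + 0.25, p["dip"]), (tc + 0.36, spike), (tc + 0.55, 1.1), (dur, 1.0)]
    return MotionScript("collapse_chair", False, dur, kf, support=support)


def _stumble_walking(rng) -> MotionScript:
    p = SCRIPT_PARAMS["stumble_walking"]
    dur = p["duration"]
    f = _u(rng, p["stride_hz"])
    ts = _u(rng, (3.0, 4.0))
    lurch = _u(rng, p["lurch"])
    spike = _u(rng, p["spike"])
    kf = [(0.0, 0.0, 0.0), (ts, 0.0, 0.0), (ts + 0.25, 0.0, -lurch),
          (ts + 0.7, 0.0, -5.0), (ts + 1.2, 0.0, 0.0), (dur, 0.0, 0.0)]
    support = [(0.0, 1.0), (ts + 0.1, 0.6), (ts + 0.22, 0.55), (ts + 0.34, spike),
               (ts + 0.5, 1.1), (dur, 1.0)]
    sup = [SupportOscillation(_u(rng, p["load_amp"]), f, 0.5, dur - 0.5)]
    ang = [AngularOscillation("roll", 2.0, f, 0.5, dur - 0.5,
                              phase=rng.uniform(0, 2 * np.pi))]
    return MotionScript("stumble_walking", False, dur, kf, support=support,
                        ang_osc=ang, sup_osc=sup)


# --------------------------------------------------------------------------
# fall builders

def _fall(name: str, rng, *, descent, pitch_peak=(0.0, 0.0), roll_peak=None,
          start_pitch=(0.0, 0.0), dip=0.35, spike=(3.0, 3.0), rest_extra=-2.0) -> MotionScript:
    td = _u(rng, descent)
    t0 = 1.5 + float(rng.uniform(0.0, 0.5))
    ti = t0 + td
    dur = ti + 1.8
    sp = _u(rng, start_pitch)
    pp = _u(rng, pitch_peak)
    if roll_peak is None:
        rp = rr = 0.0
    else:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        rp = sign * _u(rng, roll_peak)
        rr = rp - 3.0 * sign
    pr = pp + rest_extra if pp else pp
    kf = [
        (0.0, 0.0, sp),
        (t0, 0.0, sp),
        (t0 + 0.6 * td, 0.55 * rp, sp + 0.55 * (pp - sp)),
        (ti, rp, pp),
        (ti + 0.5, rr, pr),
        (dur, rr, pr),
    ]
    support = [(0.0, 1.0), (t0 + 0.25 * td, 1.0), (t0 + 0.6 * td, dip + 0.15),
               (ti - 0.04, dip), (ti, _u(rng, spike)), (ti + 0.1, 1.15), (ti + 0.5, 1.0)]
    return MotionScript(name, True, dur, kf, support=support, t_impact=ti)


def _slip_backward(rng) -> MotionScript:
    p = SCRIPT_PARAMS["slip_backward_fall"]
    return _fall("slip_backward_fall", rng, descent=p["descent"],
                 pitch_peak=p["pitch_peak"], dip=p["dip"], spike=p["spike"])


def _sitdown_backward(rng) -> MotionScript:
    p = SCRIPT_PARAMS["sitdown_backward_fall"]
    return _fall("sitdown_backward_fall", rng, descent=p["descent"],
                 pitch_peak=p["pitch_peak"], dip=p["dip"], spike=p["spike"],
                 rest_extra=p["rest_extra"])


def _sit_backward(rng) -> MotionScript:
    p = SCRIPT_PARAMS["sit_backward_fall"]
    return _fall("sit_backward_fall", rng, descent=p["descent"],
                 pitch_peak=p["pitch_peak"], start_pitch=p["start_pitch"],
                 dip=p["dip"], spike=p["spike"])


def _backward(rng) -> MotionScript:
    p = SCRIPT_PARAMS["backward_fall"]
    return _fall("backward_fall", rng, descent=p["descent"],
                 pitch_peak=p["pitch_peak"], dip=p["dip"], spike=p["spike"])


def _lateral(rng) -> MotionScript:
    p = SCRIPT_PARAMS["lateral_fall"]
    return _fall("lateral_fall", rng, descent=p["descent"],
                 pitch_peak=p["pitch_peak"], roll_peak=p["roll_peak"],
                 dip=p["dip"], spike=p["spike"], rest_extra=0.0)


def _twist(rng) -> MotionScript:
    p = SCRIPT_PARAMS["twist_fall"]
    td = _u(rng, p["descent"])
    t0 = 1.5 + float(rng.uniform(0.0, 0.5))
    ti = t0 + td
    dur = ti + 1.8
    sign = 1.0 if rng.random() < 0.5 else -1.0
    rp = sign * _u(rng, p["roll_peak"])
    kf = [
        (0.0, 0.0, 0.0),
        (t0, 0.0, 0.0),
        (t0 + 0.5 * td, sign * _u(rng, p["mid_roll"]), _u(rng, p["mid_pitch"])),
        (ti, rp, _u(rng, (10.0, 14.0))),
        (ti + 0.5, rp + 2.0 * sign, 5.0),
        (dur, rp + 2.0 * sign, 5.0),
    ]
    support = [(0.0, 1.0), (t0 + 0.25 * td, 1.0), (t0 + 0.6 * td, p["dip"] + 0.15),
               (ti - 0.04, p["dip"]), (ti, _u(rng, p["spike"])), (ti + 0.1, 1.15),
               (ti + 0.5, 1.0)]
    return MotionScript("twist_fall", True, dur, kf, support=support, t_impact=ti)


_BUILDERS = {
    "walking": _walking,
    "jogging": _jogging,
    "squatting": _squatting,
    "waist_bending": _waist_bending,
    "lying_down": _lying_down,
    "running_in_place": _running_in_place,
    "jumping": _jumping,
    "stairs": _stairs,
    "slow_sit_stool": _slow_sit_stool,
    "quick_sit_chair": _quick_sit_chair,
    "collapse_chair": _collapse_chair,
    "stumble_walking": _stumble_walking,
    "slow_sit_mattress": _slow_sit_mattress,
    "quick_sit_mattress": _quick_sit_mattress,
    "slip_backward_fall": _slip_backward,
    "sitdown_backward_fall": _sitdown_backward,
    "sit_backward_fall": _sit_backward,
    "backward_fall": _backward,
    "lateral_fall": _lateral,
    "twist_fall": _twist,
}

assert set(_BUILDERS) == set(ADL_ACTIVITIES) | set(FALL_ACTIVITIES)


def make_script(activity: str, rng: np.random.Generator) -> MotionScript:
    """Build one jittered script for a named study activity."""
    try:
        builder = _BUILDERS[activity]
    except KeyError:
        raise ValueError(f"unknown activity {activity!r}") from None
    return builder(rng)
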