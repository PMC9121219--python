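import math

import numpy as np
import pytest

from drawcog import (FEATURE_NAMES, DeviceProfile, DrawingFeatureExtractor,
                     PenStream, detect_pauses, extract_features,
                     inclination_sds, instantaneous_speeds, make_session_plan,
                     pause_ratio, pressure_mad, segment_strokes,
                     simulate_session, speed_features)
from drawcog.simulate import SessionPlan

from oracles import features_bruteforce, pauses_bruteforce

DT = 1 / 180.0


def _stream(t, x, y, pressure, incl_h=None, incl_v=None):
    n = len(t)
    hover = np.where(np.asarray(pressure) > 0, 0.0, 1.0)
    return PenStream(t=t, x=x, y=y, pressure=pressure,
                     incl_h=incl_h if incl_h is not None else np.full(n, 60.0),
                     incl_v=incl_v if incl_v is not None else np.full(n, 55.0),
                     hover=hover)


# -- stroke segmentation -----------------------------------------------------

@pytest.mark.parametrize("pressure,expected", [
    ([0, 0, 0, 0], []),
    ([0.5, 0.5, 0.5], [(0, 2)]),
    ([0, 1, 1, 0, 1, 0], [(1, 2), (4, 4)]),
])
def test_segment_strokes_run_lengths(pressure, expected):
    n = len(pressure)
    s = _stream(np.arange(n) * DT, np.arange(n, dtype=float), np.zeros(n),
                np.asarray(pressure, dtype=float))
    assert [(st.start, st.end) for st in segment_strokes(s)] == expected


# -- speeds ------------------------------------------------------------------

def test_stationary_pen_gives_zero_speeds():
    n = 10
    s = _stream(np.arange(n) * DT, np.full(n, 5.0), np.full(n, 5.0),
                np.full(n, 0.5))
    speeds = instantaneous_speeds(s, segment_strokes(s))
    assert speeds.shape == (n - 1,)
    assert np.all(speeds == 0)


def test_three_four_five_triangle_speed():
    s = _stream([0.0, 0.5], [0.0, 3.0], [0.0, 4.0], [0.5, 0.5])
    speeds = instantaneous_speeds(s, segment_strokes(s))
    assert speeds == pytest.approx([10.0])


def test_speeds_exclude_stroke_boundaries_and_match_bruteforce(walk_stream_factory):
    from oracles import speeds_bruteforce, strokes_bruteforce

    s = walk_stream_factory(3, n=500, n_gaps=3)
    strokes = segment_strokes(s)
    got = instantaneous_speeds(s, strokes)
    expected = speeds_bruteforce(list(s.t), list(s.x), list(s.y),
                                 strokes_bruteforce(list(s.pressure)))
    np.testing.assert_allclose(got, expected, rtol=1e-12)


def test_speed_features_examples():
    assert speed_features(np.array([3.0, 3.0, 3.0])) == (3.0, 0.0)
    mean, cv = speed_features(np.array([1.0, 2.0, 3.0]))
    assert (mean, cv) == pytest.approx((2.0, 0.5))
    # CV is scale invariant, the mean scales
    mean_k, cv_k = speed_features(np.array([1.0, 2.0, 3.0]) * 7.0)
    assert mean_k == pytest.approx(14.0) and cv_k == pytest.approx(cv)
    with pytest.raises(ValueError, match="undefined"):
        speed_features(np.array([1.0, -1.0]))


# -- pressure MAD and inclination SDs ---------------------------------------

def test_pressure_mad_examples():
    n = 5
    t = np.arange(n) * DT
    const = _stream(t, np.arange(n, dtype=float), np.zeros(n), np.full(n, 0.4))
    assert pressure_mad(const, segment_strokes(const)) == 0.0
    # scaled version of the {1,2,3,4,100} outlier example: MAD = 1 unit
    p = np.array([0.01, 0.02, 0.03, 0.04, 1.0])
    s = _stream(t, np.arange(n, dtype=float), np.zeros(n), p)
    assert pressure_mad(s, segment_strokes(s)) == pytest.approx(0.01)


def test_inclination_sd_examples():
    t = np.arange(2) * DT
    s = _stream(t, [0.0, 1.0], [0.0, 0.0], [0.5, 0.5],
                incl_h=[10.0, 20.0], incl_v=[40.0, 40.0])
    h, v = inclination_sds(s, segment_strokes(s))
    assert h == pytest.approx(math.sqrt(50.0))
    assert v == 0.0


# -- pause detection ---------------------------------------------------------

def test_fast_motion_has_no_within_stroke_pauses():
    # 50 mm/s leaves the 0.25-mm radius in ~5 ms
    n = 200
    t = np.arange(n) * DT
    s = _stream(t, 50.0 * t, np.zeros(n), np.full(n, 0.5))
    pauses = detect_pauses(s, segment_strokes(s))
    assert pauses == []


def test_stationary_hold_detected_as_pause():
    n = 200
    t = np.arange(n) * DT
    x = 50.0 * t.copy()
    hold = (t >= 0.3) & (t <= 0.8)
    x[hold] = x[np.argmax(hold)]
    x[t > 0.8] -= (x[np.argmax(t > 0.8)] - x[np.argmax(hold)]) - 50.0 * DT
    s = _stream(t, x, np.zeros(n), np.full(n, 0.5))
    within = [p for p in detect_pauses(s, segment_strokes(s))
              if p.kind == "within_stroke"]
    assert len(within) == 1
    assert within[0].duration == pytest.approx(0.5, abs=2 * DT)


@pytest.mark.parametrize("seed", range(6))
def test_pause_scan_matches_quadratic_oracle(walk_stream_factory, seed):
    s = walk_stream_factory(seed, n=400, step_mm=0.05, n_gaps=seed % 3)
    strokes = segment_strokes(s)
    got = [(p.kind, p.start_t, p.end_t) for p in detect_pauses(s, strokes)]
    expected = pauses_bruteforce(list(s.t), list(s.x), list(s.y),
                                 [(st.start, st.end) for st in strokes])
    assert len(got) == len(expected)
    for g, e in zip(got, expected):
        assert g[0] == e[0]
        assert g[1] == pytest.approx(e[1], abs=1e-12)
        assert g[2] == pytest.approx(e[2], abs=1e-12)


def test_detect_pauses_rejects_bad_parameters(walk_stream_factory):
    s = walk_stream_factory(0)
    strokes = segment_strokes(s)
    with pytest.raises(ValueError):
        detect_pauses(s, strokes, radius_mm=0.0)
    with pytest.raises(ValueError):
        detect_pauses(s, strokes, min_duration_s=-1.0)


def test_pause_ratio_hand_example():
    """Strokes of 2.0 s and 1.5 s, a 0.5 s dwell, a 1.0 s pen-up gap -> 0.5."""
    dt = 0.05
    rows_t, rows_x, rows_p = [], [], []
    x = 0.0
    for k in range(91):  # t in [0, 4.5]
        t = k * dt
        on = t <= 2.0 + 1e-9 or t >= 3.0 - 1e-9
        if 0.8 + 1e-9 < t <= 1.3 + 1e-9:
            pass  # dwell: hold the position reached at t = 0.8
        elif on:
            x += 0.5  # 10 mm/s: leaves the radius every sample
        rows_t.append(t)
        rows_x.append(x)
        rows_p.append(0.5 if on else 0.0)
    s = _stream(np.array(rows_t), np.array(rows_x), np.zeros(len(rows_t)),
                np.array(rows_p))
    strokes = segment_strokes(s)
    pauses = detect_pauses(s, strokes)
    kinds = sorted(p.kind for p in pauses)
    assert kinds == ["between_strokes", "within_stroke"]
    assert pause_ratio(s, strokes, pauses) == pytest.approx(0.5)


def test_no_pauses_single_stroke_ratio_zero():
    n = 100
    t = np.arange(n) * DT
    s = _stream(t, 50.0 * t, np.zeros(n), np.full(n, 0.5))
    strokes = segment_strokes(s)
    assert pause_ratio(s, strokes, detect_pauses(s, strokes)) == 0.0


# -- full extraction against the independent oracle --------------------------

def test_noiseless_constant_speed_session(device):
    line = np.array([[20.0, 30.0], [120.0, 30.0], [120.0, 130.0], [20.0, 130.0]])
    plan = SessionPlan(target_positions=line,
                       stroke_speeds_mm_s=np.full(3, 60.0),
                       speed_log_sd=0.0, dwells=(),
                       gap_durations_s=np.zeros(2),
                       pressure_base=0.5, pressure_disp=0.0,
                       incl_h_base_deg=60.0, incl_h_disp_deg=0.0,
                       incl_v_base_deg=55.0, incl_v_disp_deg=0.0)
    fv = extract_features(simulate_session(plan, device, seed=0))
    assert fv.pause_ratio == 0.0
    assert fv.speed_cv < 0.05
    assert fv.pressure_mad == 0.0
    assert fv.incl_h_sd == 0.0 and fv.incl_v_sd == 0.0
    assert fv.speed_mean == pytest.approx(60.0, rel=0.05)


def test_planned_dwell_produces_positive_pause_ratio(device):
    from drawcog.simulate import Dwell

    line = np.array([[20.0, 30.0], [120.0, 30.0]])
    plan = SessionPlan(target_positions=line,
                       stroke_speeds_mm_s=np.array([50.0]),
                       speed_log_sd=0.0,
                       dwells=(Dwell(0, 0.5, 0.5),),
                       gap_durations_s=np.zeros(0),
                       pressure_base=0.5, pressure_disp=0.0,
                       incl_h_base_deg=60.0, incl_h_disp_deg=0.0,
                       incl_v_base_deg=55.0, incl_v_disp_deg=0.0)
    fv = extract_features(simulate_session(plan, device, seed=0))
    assert fv.pause_ratio > 0.2


@pytest.mark.parametrize("seed", range(8))
def test_features_match_bruteforce_oracle(session_factory, seed):
    stream = session_factory(seed)
    got = extract_features(stream).as_dict()
    expected = features_bruteforce(stream)
    for name in FEATURE_NAMES:
        assert got[name] == pytest.approx(expected[name], rel=1e-9), name


# -- invariance properties ---------------------------------------------------

def _shifted(stream, dt_shift):
    return PenStream(t=stream.t + dt_shift, x=stream.x, y=stream.y,
                     pressure=stream.pressure, incl_h=stream.incl_h,
                     incl_v=stream.incl_v, hover=stream.hover,
                     device=stream.device)


def _rotated(stream, theta, shift):
    c, s = math.cos(theta), math.sin(theta)
    x = c * stream.x - s * stream.y + shift[0]
    y = s * stream.x + c * stream.y + shift[1]
    return PenStream(t=stream.t, x=x, y=y, pressure=stream.pressure,
                     incl_h=stream.incl_h, incl_v=stream.incl_v,
                     hover=stream.hover, device=stream.device)


@pytest.mark.parametrize("seed", [11, 12, 13])
def test_time_shift_invariance(session_factory, seed):
    stream = session_factory(seed)
    a = extract_features(stream).as_array()
    b = extract_features(_shifted(stream, 137.25)).as_array()
    np.testing.assert_allclose(a, b, rtol=1e-9)


@pytest.mark.parametrize("seed", [21, 22, 23])
def test_spatial_isometry_invariance(session_factory, seed):
    stream = session_factory(seed)
    a = extract_features(stream).as_array()
    b = extract_features(_rotated(stream, 0.7, (-40.0, 25.0))).as_array()
    np.testing.assert_allclose(a, b, rtol=1e-8)


@pytest.mark.parametrize("seed", [31, 32])
def test_speed_cv_invariant_under_time_compression(session_factory, seed):
    stream = session_factory(seed)
    compressed = PenStream(t=stream.t / 3.0, x=stream.x, y=stream.y,
                           pressure=stream.pressure, incl_h=stream.incl_h,
                           incl_v=stream.incl_v, hover=stream.hover,
                           device=stream.device)
    strokes = segment_strokes(stream)
    _, cv_a = speed_features(instantaneous_speeds(stream, strokes))
    _, cv_b = speed_features(instantaneous_speeds(compressed, strokes))
    assert cv_b == pytest.approx(cv_a, rel=1e-9)


@pytest.mark.parametrize("seed", [41, 42, 43])
def test_inserting_dwell_never_decreases_pause_ratio(session_factory, seed):
    stream = session_factory(seed)
    strokes = segment_strokes(stream)
    before = pause_ratio(stream, strokes, detect_pauses(stream, strokes))
    # splice a 0.4 s stationary hold into the middle of the longest stroke
    longest = max(strokes, key=lambda s: s.n_samples())
    at = (longest.start + longest.end) // 2
    dt = stream.device.dt_s
    n_hold = int(round(0.4 / dt))

    def splice(channel, value):
        return np.concatenate([channel[:at + 1], np.full(n_hold, value),
                               channel[at + 1:]])

    t = np.concatenate([stream.t[:at + 1],
                        stream.t[at] + dt * np.arange(1, n_hold + 1),
                        stream.t[at + 1:] + n_hold * dt])
    modified = PenStream(t=t, x=splice(stream.x, stream.x[at]),
                         y=splice(stream.y, stream.y[at]),
                         pressure=splice(stream.pressure, stream.pressure[at]),
                         incl_h=splice(stream.incl_h, stream.incl_h[at]),
                         incl_v=splice(stream.incl_v, stream.incl_v[at]),
                         hover=splice(stream.hover, 0.0), device=stream.device)
    strokes_m = segment_strokes(modified)
    after = pause_ratio(modified, strokes_m, detect_pauses(modified, strokes_m))
    assert after >= before - 1e-12


def test_transformer_interface(session_factory):
    streams = [session_factory(s) for s in (51, 52)]
    X = DrawingFeatureExtractor().fit_transform(streams)
    assert X.shape == (2, 6)
    np.testing.assert_allclose(X[0], extract_features(streams[0]).as_array())
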