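"""Gating, spline smoothing, ATP conversion and baseline correction."""

import numpy as np
import pandas as pd
import pytest

from atpflux import synthetic
from atpflux.calibration import atp_to_ratio, theta_to_atp
from atpflux.timecourse import (
    AtpTrace,
    EventStream,
    InsufficientEventsError,
    UndefinedCorrectionError,
    baseline_correct,
    density_grid,
    gate_events,
    smooth_ratio_trace,
    trace_to_atp,
    window_mean,
)


def _stream(times, egfp, fret, window=None):
    df = pd.DataFrame({"time_s": times, "egfp": egfp, "fret": fret})
    if window is None:
        window = (0.0, float(max(times)) + 1.0)
    return EventStream(df, window)


class TestGating:
    def test_all_below_floor_gives_empty_stream(self):
        s = _stream([1, 2, 3], [500, 600, 700], [400, 500, 600])
        assert len(gate_events(s)) == 0

    def test_matches_brute_force_filter(self, rng):
        n = 10
        s = _stream(
            np.arange(n, dtype=float),
            rng.uniform(500, 5000, n),
            rng.uniform(500, 5000, n),
        )
        gated = gate_events(s, mfi_floor=1000, top_fraction=0.5)
        # oracle: exhaustive filter with the same quantile definition
        ev = s.events
        above = ev[(ev.egfp > 1000) & (ev.fret > 1000)]
        te = np.quantile(above.egfp, 0.5)
        tf = np.quantile(above.fret, 0.5)
        expected = above[(above.egfp >= te) & (above.fret >= tf)]
        assert sorted(gated.events.time_s) == sorted(expected.time_s)

    def test_top_fraction_one_reduces_to_floor(self, rng):
        n = 50
        s = _stream(np.arange(n, dtype=float), rng.uniform(0, 4000, n), rng.uniform(0, 4000, n))
        gated = gate_events(s, mfi_floor=1000, top_fraction=1.0)
        ev = s.events
        assert len(gated) == int(((ev.egfp > 1000) & (ev.fret > 1000)).sum())

    def test_gating_is_idempotent(self, rng):
        n = 200
        s = _stream(np.arange(n, dtype=float), rng.uniform(0, 8000, n), rng.uniform(0, 8000, n))
        once = gate_events(s, top_fraction=0.45)
        twice = gate_events(once, top_fraction=0.45)
        pd.testing.assert_frame_equal(once.events, twice.events)


class TestSmoothing:
    def test_constant_ratio_reproduced_exactly(self, rng):
        t = rng.uniform(0, 100, 200)
        s = _stream(t, np.full(200, 5000.0), np.full(200, 5000.0) * 1.8, window=(0, 100))
        grid, fitted, _ = smooth_ratio_trace(s)
        assert np.allclose(fitted, 1.8, atol=1e-8)

    def test_linear_trend_in_penalty_null_space(self, rng):
        t = np.sort(rng.uniform(0, 100, 500))
        ratio = 1.5 + 0.004 * t
        s = _stream(t, np.full(500, 5000.0), 5000.0 * ratio, window=(0, 100))
        grid, fitted, _ = smooth_ratio_trace(s)
        expected = 1.5 + 0.004 * np.clip(grid, t.min(), t.max())
        assert np.allclose(fitted, expected, atol=1e-6)

    def test_too_few_events_raises(self):
        s = _stream([1.0, 2.0], [2000, 2000], [3000, 3000])
        with pytest.raises(InsufficientEventsError):
            smooth_ratio_trace(s)

    def test_translation_equivariance_at_fixed_penalty(self, rng):
        t = np.sort(rng.uniform(0, 100, 400))
        ratio = 1.8 + 0.1 * np.sin(t / 10)
        egfp = np.full(400, 5000.0)
        s1 = _stream(t, egfp, egfp * ratio, window=(0, 100))
        s2 = _stream(t, egfp, egfp * (ratio + 0.25), window=(0, 100))
        _, f1, meta = smooth_ratio_trace(s1, alpha=10.0)
        _, f2, _ = smooth_ratio_trace(s2, alpha=10.0)
        assert np.allclose(f2 - f1, 0.25, atol=1e-8)

    def test_recovers_sigmoid_trajectory_under_noise(self, scenarios, calib):
        scen = scenarios["oxphos_inhibited"]
        stream = synthetic.gen_event_stream(scen, 5000, 900.0, calib, seed=11)
        gated = gate_events(stream)
        grid, fitted, _ = smooth_ratio_trace(gated)
        truth = atp_to_ratio(scen.atp_trajectory(grid), calib)
        rmse = float(np.sqrt(np.mean((fitted - truth) ** 2)))
        noise_sd = scen.noise_model["event_cv"] * float(np.mean(truth))
        assert rmse < noise_sd


class TestAtpTraceOps:
    def test_flat_ratio_converts_to_half_saturation(self, calib):
        grid = np.arange(0.0, 10.0)
        trace = trace_to_atp(grid, np.full(10, 1.96), calib)
        assert np.allclose(trace.atp, 0.84699, rtol=1e-9)

    def test_offset_ratio_converts_to_clip_floor(self, calib):
        trace = trace_to_atp(np.arange(3.0), np.full(3, 1.46), calib)
        floor = theta_to_atp(1e-6, calib, mode="clip")  # ~0.01 mM
        assert np.allclose(trace.atp, floor)

    def test_monotone_ratio_gives_monotone_atp(self, calib):
        ratios = np.linspace(2.2, 1.6, 20)
        trace = trace_to_atp(np.arange(20.0), ratios, calib)
        assert np.all(np.diff(trace.atp) < 0)

    def test_baseline_correct_identical_traces_is_identity(self):
        grid = np.arange(0.0, 5.0)
        a = AtpTrace(grid, np.array([1.0, 0.9, 0.8, 0.7, 0.6]))
        out = baseline_correct(a, AtpTrace(grid, a.atp.copy()))
        assert out.correction_factor == 1.0
        assert np.allclose(out.atp, a.atp)

    def test_baseline_correct_halves_control(self):
        grid = np.arange(0.0, 4.0)
        control = AtpTrace(grid, np.array([1.0, 1.0, 0.8, 0.8]))
        treated = AtpTrace(grid, np.array([0.5, 0.4, 0.3, 0.2]))
        out = baseline_correct(control, treated)
        assert out.correction_factor == pytest.approx(0.5)
        assert np.allclose(out.atp, control.atp * 0.5)
        assert out.at_time(0.0) == treated.at_time(0.0)  # defining property

    def test_baseline_correct_zero_anchor_rejected(self):
        grid = np.arange(0.0, 3.0)
        control = AtpTrace(grid, np.zeros(3))
        treated = AtpTrace(grid, np.ones(3))
        with pytest.raises(UndefinedCorrectionError):
            baseline_correct(control, treated)

    def test_window_mean_constant_and_linear(self):
        grid = np.arange(0.0, 101.0)
        const = AtpTrace(grid, np.full(101, 0.7))
        assert window_mean(const, 40, 60) == pytest.approx(0.7)
        lin = AtpTrace(grid, 0.2 + 0.003 * grid)
        # closed form: mean of a + b t over [T-d, T] = a + b (T - d/2)
        assert window_mean(lin, 80, 100) == pytest.approx(0.2 + 0.003 * 90.0)

    def test_window_mean_matches_direct_average(self, rng):
        grid = np.arange(0.0, 50.0)
        vals = rng.uniform(0.1, 1.0, 50)
        trace = AtpTrace(grid, vals)
        assert window_mean(trace, 0, 49) == pytest.approx(vals.mean())
        with pytest.raises(ValueError):
            window_mean(trace, 60, 70)


def test_density_grid_integrates_to_one(scenarios, calib):
    scen = scenarios["quiescent"]
    stream = synthetic.gen_event_stream(scen, 500, 100.0, calib, seed=2)
    tg, rg, dens = density_grid(stream, n_time=32, n_ratio=32)
    mass = np.trapezoid(np.trapezoid(dens, rg, axis=1), tg)
    assert mass == pytest.approx(1.0, abs=0.15)  # grid truncation tolerance
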