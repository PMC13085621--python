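import numpy as np
import pytest

from dvoscope import features as feat
from dvoscope import preprocess as pp
from dvoscope import synth_cohort as sc
from dvoscope.features import (
    VO2_CONVERSION,
    FeatureError,
    delta_hbo,
    delta_hbt,
    extract_features,
    hemoglobin_flow,
    interval_slopes,
    oxygen_consumption,
    plateau_time,
)
from dvoscope.optics import HemoTrace


def _trace_from_hbt(protocol, hbt, hbd=None):
    t = protocol.time_axis()
    hbd = np.zeros_like(t) if hbd is None else hbd
    return HemoTrace(time_s=t, hbo=hbt - hbd, hbd=hbd)


def _piecewise_hbt(protocol, slopes, start_s, before=0.0):
    """HbT that is piecewise-linear with the given slope in each 5-s
    interval from start_s, flat elsewhere."""
    t = protocol.time_axis()
    hbt = np.full_like(t, before)
    level = before
    for k, slope in enumerate(slopes):
        lo, hi = start_s + 5 * k, start_s + 5 * (k + 1)
        seg = (t >= lo) & (t < hi)
        hbt[seg] = level + slope * (t[seg] - lo)
        level += slope * 5.0
    hbt[t >= start_s + 5 * len(slopes)] = level
    return hbt


class TestDeltaHbo:
    def test_printed_fixture_value(self, protocol):
        # pre-occlusion HbO mean 10, occlusion max 16.81 -> 6.81
        t = protocol.time_axis()
        occ = protocol.phase("occ60")
        hbo = np.full_like(t, 10.0)
        hbo[(t >= occ.start_s) & (t < occ.end_s)] = 16.81
        trace = HemoTrace(time_s=t, hbo=hbo, hbd=np.zeros_like(t))
        assert delta_hbo(trace, occ) == pytest.approx(6.81)

    def test_flat_trace_zero(self, protocol):
        occ = protocol.phase("occ60")
        trace = _trace_from_hbt(protocol, np.full(protocol.n_samples, 4.0))
        assert delta_hbo(trace, occ) == pytest.approx(0.0)

    def test_monotone_rise_returns_amplitude(self, protocol):
        occ = protocol.phase("occ60")
        t = protocol.time_axis()
        a = 7.3
        hbo = np.clip((t - occ.start_s) / occ.duration_s, 0, None) * a
        hbo[t >= occ.end_s] = a
        trace = HemoTrace(time_s=t, hbo=hbo, hbd=np.zeros_like(t))
        # max attained at the last occlusion sample, one dt short of a
        assert delta_hbo(trace, occ) == pytest.approx(a, rel=0.01)

    def test_insufficient_pre_window_rejected(self, protocol):
        t = protocol.time_axis()[:10]
        trace = HemoTrace(time_s=t, hbo=np.zeros(10), hbd=np.zeros(10))
        with pytest.raises(FeatureError):
            delta_hbo(trace, protocol.phase("occ60"))


class TestIntervalSlopes:
    def test_exact_line_all_slopes_equal(self, protocol):
        t = protocol.time_axis()
        grid = interval_slopes(2.7 * t + 1.0, t, 60.0)
        assert np.allclose(grid.slopes, 2.7, atol=1e-10)
        assert len(grid.slopes) == 6

    def test_piecewise_analytic(self, protocol):
        hbt = _piecewise_hbt(protocol, [3.0, 0, 0, 0, 0, 0], 60.0)
        grid = interval_slopes(hbt, protocol.time_axis(), 60.0)
        assert grid.slopes[0] == pytest.approx(3.0, abs=1e-9)
        assert np.allclose(grid.slopes[1:], 0.0, atol=1e-9)

    def test_normal_equations_oracle(self, protocol, rng):
        # brute-force OLS by explicit normal equations per window
        t = protocol.time_axis()
        y = rng.normal(size=len(t))
        grid = interval_slopes(y, t, 60.0)
        for k in range(6):
            sel = (t >= 60 + 5 * k) & (t < 60 + 5 * (k + 1))
            tk, yk = t[sel], y[sel]
            A = np.column_stack([np.ones_like(tk), tk])
            beta = np.linalg.solve(A.T @ A, A.T @ yk)
            assert grid.slopes[k] == pytest.approx(beta[1], rel=1e-9)

    def test_monte_carlo_unbiased(self, protocol):
        t = protocol.time_axis()
        b = 1.3
        est = []
        for seed in range(100):
            y = b * t + np.random.default_rng(seed).normal(0, 0.5, len(t))
            est.append(interval_slopes(y, t, 60.0).slopes)
        assert np.allclose(np.mean(est, axis=0), b, atol=0.02)

    def test_short_data_rejected(self, protocol):
        t = protocol.time_axis()[:80]
        with pytest.raises(FeatureError):
            interval_slopes(np.zeros(80), t, 60.0)


class TestHemoglobinFlow:
    def test_printed_grid_fixture(self, protocol):
        slopes = [0.5, 2.48, 1.0, 0.3, 0.1, 0.0]
        trace = _trace_from_hbt(protocol, _piecewise_hbt(protocol, slopes, 60.0))
        assert hemoglobin_flow(trace, protocol.phase("occ60")) == pytest.approx(2.48, abs=1e-9)

    def test_flat_zero(self, protocol):
        trace = _trace_from_hbt(protocol, np.zeros(protocol.n_samples))
        assert hemoglobin_flow(trace, protocol.phase("occ60")) == pytest.approx(0.0)

    def test_strictly_decreasing_gives_negative(self, protocol):
        t = protocol.time_axis()
        trace = _trace_from_hbt(protocol, -0.2 * t)
        hf = hemoglobin_flow(trace, protocol.phase("occ60"))
        assert hf == pytest.approx(-0.2, abs=1e-9)

    def test_max_dominates_every_interval_slope(self, protocol, rng):
        t = protocol.time_axis()
        y = rng.normal(size=len(t)).cumsum() * 0.1
        trace = _trace_from_hbt(protocol, y)
        grid = interval_slopes(trace.hbt, t, 60.0)
        assert hemoglobin_flow(trace, protocol.phase("occ60")) >= max(grid.slopes) - 1e-12


class TestOxygenConsumption:
    def test_conversion_factor_dimensional_oracle(self):
        # independent dimensional analysis: 4 O2 per Hb tetramer,
        # 22.4 L/mol -> 22400 mL/mol -> 0.0224 mL/umol; per-second ->
        # per-minute (x60); per litre -> per 100 mL (/10)
        o2_per_hb = 4
        ml_o2_per_umol = 22400.0 / 1e6
        s_per_min = 60.0
        litre_to_100ml = 1.0 / 10.0
        assert o2_per_hb * ml_o2_per_umol * s_per_min * litre_to_100ml == \
            pytest.approx(VO2_CONVERSION)
        assert VO2_CONVERSION == pytest.approx(0.5376)

    def test_known_slope(self, protocol):
        t = protocol.time_axis()
        hbd = _piecewise_hbt(protocol, [0.1] * 6, 60.0)
        trace = HemoTrace(time_s=t, hbo=np.zeros_like(t), hbd=hbd)
        assert oxygen_consumption(trace, protocol.phase("occ60")) == \
            pytest.approx(0.05376, abs=1e-9)

    def test_flat_zero(self, protocol):
        t = protocol.time_axis()
        trace = HemoTrace(time_s=t, hbo=np.zeros_like(t), hbd=np.zeros_like(t))
        assert oxygen_consumption(trace, protocol.phase("occ60")) == pytest.approx(0.0)

    def test_table_scale_anchor(self, protocol):
        # slope 0.1228 umol/L/s converts to ~0.066 (non-PAD scale)
        t = protocol.time_axis()
        hbd = _piecewise_hbt(protocol, [0.1228] * 6, 60.0)
        trace = HemoTrace(time_s=t, hbo=np.zeros_like(t), hbd=hbd)
        assert oxygen_consumption(trace, protocol.phase("occ60")) == \
            pytest.approx(0.066, abs=0.001)


class TestPlateauTime:
    def test_hand_geometry(self, protocol):
        # rise 0->10 over first 50 s of occlusion, hold 10 s, fall at
        # 0.5 umol/L/s: t1 = 45 s, t2 = 62 s -> Tp = 17 s
        t = protocol.time_axis()
        occ = protocol.phase("occ60")
        rel = t - occ.start_s
        hbt = np.zeros_like(t)
        hbt[(rel >= 0) & (rel < 50)] = 10.0 / 50.0 * rel[(rel >= 0) & (rel < 50)]
        hbt[(rel >= 50) & (rel < 60)] = 10.0
        fall = rel >= 60
        hbt[fall] = np.clip(10.0 - 0.5 * (rel[fall] - 60.0), 0.0, None)
        trace = _trace_from_hbt(protocol, hbt)
        tp, flagged = plateau_time(trace, occ, protocol.phase("recovery1").end_s)
        assert not flagged
        assert tp == pytest.approx(17.0, abs=0.05)

    def test_instant_rise_and_drop_limit(self, protocol):
        t = protocol.time_axis()
        occ = protocol.phase("occ60")
        hbt = np.where((t >= occ.start_s) & (t < occ.end_s), 5.0, 0.0)
        trace = _trace_from_hbt(protocol, hbt)
        tp, flagged = plateau_time(trace, occ, protocol.phase("recovery1").end_s)
        assert tp == pytest.approx(occ.duration_s, abs=2 / 2.56)

    def test_symmetric_triangle(self, protocol):
        t = protocol.time_axis()
        occ = protocol.phase("occ60")
        rel = t - occ.start_s
        hbt = np.clip(10.0 - np.abs(rel - 60.0) / 6.0, 0.0, None)
        trace = _trace_from_hbt(protocol, hbt)
        tp, flagged = plateau_time(trace, occ, protocol.phase("recovery1").end_s)
        # crossings equidistant from the peak at deflation: drop of
        # 0.1 * peak on each side at slope 1/6 -> Tp = 2 * 1 * 6 = 12 s
        assert tp == pytest.approx(12.0, abs=0.3)

    def test_never_falling_truncated_and_flagged(self, protocol):
        t = protocol.time_axis()
        occ = protocol.phase("occ60")
        hbt = np.where(t >= occ.start_s, 5.0, 0.0)  # stays high forever
        trace = _trace_from_hbt(protocol, hbt)
        tp, flagged = plateau_time(trace, occ, protocol.phase("recovery1").end_s)
        assert flagged

    def test_flat_occlusion_flagged(self, protocol):
        trace = _trace_from_hbt(protocol, np.zeros(protocol.n_samples))
        tp, flagged = plateau_time(trace, protocol.phase("occ60"),
                                   protocol.phase("recovery1").end_s)
        assert flagged


class TestExtractFeatures:
    def test_round_trip_with_synth(self, protocol, mean_targets_nonpad,
                                   mean_trace_nonpad):
        ex = extract_features(mean_trace_nonpad, protocol)
        for pressure in (60, 100):
            want, got = mean_targets_nonpad.at(pressure), ex.at(pressure)
            for key in ("delta_hbo", "hf", "vo2"):
                assert getattr(got, key) == pytest.approx(getattr(want, key), rel=0.05)
            assert got.tp == pytest.approx(want.tp, abs=2 / 2.56)

    def test_all_zero_trace(self, protocol):
        trace = _trace_from_hbt(protocol, np.zeros(protocol.n_samples))
        ex = extract_features(trace, protocol)
        pf = ex.at(60)
        assert pf.delta_hbo == 0.0 and pf.hf == 0.0 and pf.vo2 == 0.0
        assert pf.tp_truncated  # flagged: Tp undefined on a flat trace

    @pytest.mark.parametrize("shift", [-5.0, 3.25])
    def test_shift_invariance(self, protocol, mean_trace_nonpad, shift):
        t = mean_trace_nonpad
        shifted = HemoTrace(time_s=t.time_s, hbo=t.hbo + shift, hbd=t.hbd + shift)
        a, b = extract_features(t, protocol), extract_features(shifted, protocol)
        for pressure in (60, 100):
            for key in ("delta_hbo", "hf", "vo2", "tp"):
                assert getattr(b.at(pressure), key) == pytest.approx(
                    getattr(a.at(pressure), key), rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_scale_equivariance(self, protocol, mean_trace_nonpad, c):
        t = mean_trace_nonpad
        scaled = HemoTrace(time_s=t.time_s, hbo=c * t.hbo, hbd=c * t.hbd)
        a, b = extract_features(t, protocol), extract_features(scaled, protocol)
        for pressure in (60, 100):
            for key in ("delta_hbo", "hf", "vo2"):
                assert getattr(b.at(pressure), key) == pytest.approx(
                    c * getattr(a.at(pressure), key), rel=1e-9)
            assert b.at(pressure).tp == pytest.approx(a.at(pressure).tp, abs=1e-6)

    def test_filter_distortion_below_2pct(self, protocol, mean_targets_nonpad,
                                          mean_targets_pad):
        for targets in (mean_targets_nonpad, mean_targets_pad):
            tr = sc.construct_trace(targets, protocol)
            fs = protocol.sampling_rate_hz
            filtered = HemoTrace(time_s=tr.time_s,
                                 hbo=pp.lowpass_filter(tr.hbo, fs),
                                 hbd=pp.lowpass_filter(tr.hbd, fs))
            a, b = extract_features(tr, protocol), extract_features(filtered, protocol)
            for pressure in (60, 100):
                for key in ("delta_hbo", "hf", "vo2"):
                    assert getattr(b.at(pressure), key) == pytest.approx(
                        getattr(a.at(pressure), key), rel=0.02)

    def test_delta_hbt_companion(self, protocol, mean_trace_nonpad):
        occ = protocol.phase("occ60")
        d = delta_hbt(mean_trace_nonpad, occ)
        assert d >= delta_hbo(mean_trace_nonpad, occ)  # HbD adds volume
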