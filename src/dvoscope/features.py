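"""Hemodynamic feature extraction from reconstructed hemoglobin traces.

Four parameters per occlusion pressure:

* ``delta_hbo`` — maximum HbO during occlusion minus the mean HbO over
  the 5 s immediately preceding occlusion (umol/L).
* ``hf`` — hemoglobin flow: the maximum ordinary-least-squares slope of
  HbT over six 5-s intervals spanning the first 30 s of occlusion
  (umol/L/s).
* ``vo2`` — tissue oxygen consumption: the maximum interval slope of HbD
  over the same six intervals, converted to mL O2 / 100 mL tissue / min.
* ``tp`` — plateau time: seconds between the 90%-of-maximum crossings of
  HbT on the way up (during occlusion) and on the way down (after cuff
  deflation), with linear interpolation at both crossings.

Negative slopes are never clipped; a pathological trace can yield a
negative hf or vo2 and this is surfaced rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import HemoTrace
from .protocol import CuffProtocol, Phase

#: Seconds of pre-occlusion HbO averaged for the delta_hbo reference.
PRE_OCCLUSION_WINDOW_S = 5.0
#: Interval scheme for slope features: six 5-s windows over the first 30 s.
N_INTERVALS = 6
INTERVAL_LENGTH_S = 5.0

# umol/L/s -> mL O2 / 100 mL tissue / min:
# 4 O2 per hemoglobin tetramer x 0.0224 mL O2 per umol O2 (22.4 L/mol)
# x 60 s/min / 10 (per litre -> per 100 mL).
VO2_CONVERSION = 4.0 * 0.0224 * 60.0 / 10.0  # = 0.5376


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class SlopeGrid:
    """Per-interval OLS slopes over the six half-open 5-s windows."""

    boundaries_s: tuple[float, ...]  # 7 edges
    slopes: tuple[float, ...]  # 6 slopes, umol/L/s

    def __post_init__(self) -> None:
        if len(self.slopes) != N_INTERVALS or len(self.boundaries_s) != N_INTERVALS + 1:
            raise FeatureError("slope grid must have exactly 6 intervals")

    @property
    def max_slope(self) -> float:
        return max(self.slopes)


@dataclass(frozen=True)
class PressureFeatures:
    delta_hbo: float = np.nan
    hf: float = np.nan
    vo2: float = np.nan
    tp: float = np.nan
    tp_truncated: bool = False
    complete: bool = True
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class FeatureSet:
    """The four parameters at each occlusion pressure (the analysis unit)."""

    at_60: PressureFeatures = field(default_factory=PressureFeatures)
    at_100: PressureFeatures = field(default_factory=PressureFeatures)

    def at(self, pressure: int) -> PressureFeatures:
        if pressure == 60:
            return self.at_60
        if pressure == 100:
            return self.at_100
        raise KeyError(pressure)

    def as_dict(self) -> dict[str, float]:
        out = {}
        for pressure in (60, 100):
            pf = self.at(pressure)
            for key in ("delta_hbo", "hf", "vo2", "tp"):
                out[f"{key}_{pressure}"] = getattr(pf, key)
        return out


def delta_hbo(trace: HemoTrace, occlusion: Phase) -> float:
    """max(HbO during occlusion) - mean(HbO over the 5 s before onset)."""
    t = trace.time_s
    pre = (t >= occlusion.start_s - PRE_OCCLUSION_WINDOW_S) & (t < occlusion.start_s)
    if np.count_nonzero(pre) < 2:
        raise FeatureError("insufficient pre-occlusion samples for delta_hbo")
    during = (t >= occlusion.start_s) & (t < occlusion.end_s)
    if not during.any():
        raise FeatureError("trace does not cover the occlusion phase")
    return float(np.max(trace.hbo[during]) - np.mean(trace.hbo[pre]))


def _ols_slope(t: np.ndarray, y: np.ndarray) -> float:
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def interval_slopes(series: np.ndarray, time_s: np.ndarray, occlusion_start_s: float) -> SlopeGrid:
    """OLS slope of ``series`` in each window [start+5k, start+5(k+1))."""
    series = np.asarray(series, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    edges = occlusion_start_s + INTERVAL_LENGTH_S * np.arange(N_INTERVALS + 1)
    if time_s[-1] < edges[-1] - 1.0 / (2 * 2.56):
        raise FeatureError("need >= 30 s of occlusion data for interval slopes")
    slopes = []
    for k in range(N_INTERVALS):
        sel = (time_s >= edges[k]) & (time_s < edges[k + 1])
        if np.count_nonzero(sel) < 3:
            raise FeatureError(f"interval {k} has < 3 samples")
        slopes.append(_ols_slope(time_s[sel], series[sel]))
    return SlopeGrid(boundaries_s=tuple(edges), slopes=tuple(slopes))


def hemoglobin_flow(trace: HemoTrace, occlusion: Phase) -> float:
    """Maximum of the six HbT interval slopes (umol/L/s)."""
    return interval_slopes(trace.hbt, trace.time_s, occlusion.start_s).max_slope


def oxygen_consumption(trace: HemoTrace, occlusion: Phase) -> float:
    """Maximum HbD interval slope, converted to mL O2/100 mL tissue/min."""
    slope = interval_slopes(trace.hbd, trace.time_s, occlusion.start_s).max_slope
    return slope * VO2_CONVERSION


def _interp_crossing(t0: float, y0: float, t1: float, y1: float, level: float) -> float:
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def plateau_time(trace: HemoTrace, occlusion: Phase,
                 recovery_end_s: float | None = None) -> tuple[float, bool]:
    """Tp: time between the rising and falling 90%-of-maximum crossings.

    The 90% level is referenced to the 5-s pre-occlusion HbT mean, which
    makes the feature invariant to constant offsets. Returns
    ``(tp, flagged)``; ``flagged`` is True when HbT never falls below the
    level during recovery (crossing truncated at the recovery end) or
    when the occlusion segment is degenerate (flat).
    """
    t, hbt = trace.time_s, trace.hbt
    during = (t >= occlusion.start_s) & (t < occlusion.end_s)
    if not during.any():
        raise FeatureError("trace does not cover occlusion")
    pre = (t >= occlusion.start_s - PRE_OCCLUSION_WINDOW_S) & (t < occlusion.start_s)
    ref = float(np.mean(hbt[pre])) if pre.any() else float(hbt[np.flatnonzero(during)[0]])
    if np.ptp(hbt[during]) == 0.0:  # flat occlusion: Tp undefined
        return float(occlusion.duration_s), True
    m = float(np.max(hbt[during]))
    level = ref + 0.9 * (m - ref)
    idx_occ = np.flatnonzero(during)
    # rising crossing: first occlusion sample at/above the level
    above = hbt[idx_occ] >= level
    i = int(idx_occ[np.argmax(above)])
    if i > 0 and hbt[i - 1] < level <= hbt[i]:
        t1 = _interp_crossing(t[i - 1], hbt[i - 1], t[i], hbt[i], level)
    else:
        t1 = float(t[i])
    # falling crossing: first sample after deflation at/below the level
    deflation = occlusion.end_s
    if recovery_end_s is None:
        recovery_end_s = float(t[-1])
    after = (t >= deflation) & (t <= recovery_end_s)
    idx_after = np.flatnonzero(after)
    if idx_after.size == 0:
        raise FeatureError("trace does not cover recovery")
    below = hbt[idx_after] <= level
    if not below.any():
        return float(recovery_end_s - t1), True
    j = int(idx_after[np.argmax(below)])
    if j > 0 and hbt[j - 1] > level >= hbt[j]:
        t2 = _interp_crossing(t[j - 1], hbt[j - 1], t[j], hbt[j], level)
    else:
        t2 = float(t[j])
    return float(t2 - t1), False


def extract_pressure(trace: HemoTrace, occlusion: Phase, recovery: Phase) -> PressureFeatures:
    vals: dict = {}
    notes: list[str] = []
    complete = True
    for name, fn in (
        ("delta_hbo", lambda: delta_hbo(trace, occlusion)),
        ("hf", lambda: hemoglobin_flow(trace, occlusion)),
        ("vo2", lambda: oxygen_consumption(trace, occlusion)),
    ):
        try:
            vals[name] = fn()
        except FeatureError as exc:  # invalidate only this entry
            vals[name] = np.nan
            notes.append(f"{name}: {exc}")
            complete = False
    try:
        tp, truncated = plateau_time(trace, occlusion, recovery.end_s)
        vals["tp"] = tp
        vals["tp_truncated"] = truncated
        if truncated:
            notes.append("tp: truncated at recovery end")
    except FeatureError as exc:
        vals["tp"] = np.nan
        vals["tp_truncated"] = False
        notes.append(f"tp: {exc}")
        complete = False
    return PressureFeatures(complete=complete, notes=tuple(notes), **vals)


def extract_features(trace: HemoTrace, protocol: CuffProtocol) -> FeatureSet:
    """Apply the four parameter definitions at both occlusion pressures."""
    occ60, occ100 = protocol.occlusion_phases()
    return FeatureSet(
        at_60=extract_pressure(trace, occ60, protocol.phase("recovery1")),
        at_100=extract_pressure(trace, occ100, protocol.phase("recovery2")),
    )


def delta_hbt(trace: HemoTrace, occlusion: Phase) -> float:
    """Companion quantity for the correlation check (not a model input):
    max HbT during occlusion minus the 5-s pre-occlusion HbT mean."""
    t = trace.time_s
    pre = (t >= occlusion.start_s - PRE_OCCLUSION_WINDOW_S) & (t < occlusion.start_s)
    during = (t >= occlusion.start_s) & (t < occlusion.end_s)
    if np.count_nonzero(pre) < 2 or not during.any():
        raise FeatureError("trace does not cover occlusion or pre-occlusion window")
    return float(np.max(trace.hbt[during]) - np.mean(trace.hbt[pre]))
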