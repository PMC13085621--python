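"""Cuff-pressure protocol timeline.

The five-phase occlusion protocol (baseline, 60 mmHg occlusion, recovery,
100 mmHg occlusion, recovery) anchors every window definition downstream:
baseline SNR windows, pre-occlusion reference means, slope intervals, and
plateau-time crossings are all expressed relative to phase boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default per-phase duration in seconds.
DEFAULT_PHASE_DURATION_S = 60.0
#: Default acquisition rate of the instrument (scans per second).
DEFAULT_SAMPLING_RATE_HZ = 2.56

PHASE_LABELS = ("baseline", "occ60", "recovery1", "occ100", "recovery2")


@dataclass(frozen=True)
class Phase:
    label: str
    start_s: float
    duration_s: float
    pressure_mmHg: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class CuffProtocol:
    """Ordered, contiguous five-phase pressure timeline.

    Parameters
    ----------
    phases
        Exactly five contiguous, non-overlapping phases labelled
        ``baseline, occ60, recovery1, occ100, recovery2``.
    sampling_rate_hz
        Acquisition rate; must exceed twice the low-pass cutoff used in
        preprocessing so the filtered band is representable.
    """

    phases: tuple[Phase, ...] = field(default_factory=tuple)
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        if len(self.phases) != 5:
            raise ValueError(f"protocol requires exactly 5 phases, got {len(self.phases)}")
        labels = tuple(p.label for p in self.phases)
        if labels != PHASE_LABELS:
            raise ValueError(f"phase labels must be {PHASE_LABELS}, got {labels}")
        for prev, nxt in zip(self.phases, self.phases[1:]):
            if not np.isclose(prev.end_s, nxt.start_s):
                raise ValueError(
                    f"phases must be contiguous: {prev.label} ends at {prev.end_s}, "
                    f"{nxt.label} starts at {nxt.start_s}"
                )
        for p in self.phases:
            if p.duration_s <= 0 or p.pressure_mmHg < 0:
                raise ValueError(f"invalid phase {p}")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    def phase(self, label: str) -> Phase:
        for p in self.phases:
            if p.label == label:
                return p
        raise KeyError(label)

    @property
    def total_duration_s(self) -> float:
        return self.phases[-1].end_s - self.phases[0].start_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_s * self.sampling_rate_hz))

    def time_axis(self) -> np.ndarray:
        """Sample timestamps, starting at the protocol origin."""
        dt = 1.0 / self.sampling_rate_hz
        return self.phases[0].start_s + np.arange(self.n_samples) * dt

    def occlusion_phases(self) -> tuple[Phase, Phase]:
        return self.phase("occ60"), self.phase("occ100")


def default_protocol(sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ) -> CuffProtocol:
    """Five one-minute phases: baseline, 60 mmHg, recovery, 100 mmHg, recovery."""
    d = DEFAULT_PHASE_DURATION_S
    pressures = (5.0, 60.0, 5.0, 100.0, 5.0)
    phases = tuple(
        Phase(label, i * d, d, pressures[i]) for i, label in enumerate(PHASE_LABELS)
    )
    return CuffProtocol(phases=phases, sampling_rate_hz=sampling_rate_hz)
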