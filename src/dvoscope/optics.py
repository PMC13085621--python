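"""Forward and inverse optics via the modified Beer-Lambert law.

The forward model turns hemoglobin concentration changes into per-channel
optical intensities; the inverse solves the per-timepoint least-squares
chromophore system referenced to the baseline-phase mean intensity.

NOTE: the reconstruction here is deliberately the modified Beer-Lambert
law with a fixed configurable differential pathlength factor (DPF). It is
a desk-scale surrogate for a full multispectral reconstruction; every
downstream feature depends only on relative concentration dynamics, which
the MBLL preserves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .protocol import CuffProtocol

DEVICE_WAVELENGTHS_NM = (670.0, 780.0, 808.0, 850.0)
DEFAULT_DPF = 4.0
DEFAULT_PATHLENGTH_CM = 3.0
EXTINCTION_VERSION = "extinction_hb_v1"

PATCH_IDS = ("medial_plantar", "lateral_plantar", "dorsalis_pedis", "posterior_tibial")

#: umol/L <-> mmol/L, handled inside the inversion/forward model only.
_UMOL_PER_MMOL = 1000.0


class OpticsError(ValueError):
    pass


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients, L mmol^-1 cm^-1, base-10 convention."""

    wavelengths_nm: tuple[float, ...]
    eps_hbo: tuple[float, ...]
    eps_hbd: tuple[float, ...]
    source: str = ""

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        if n < 2 or len(self.eps_hbo) != n or len(self.eps_hbd) != n:
            raise OpticsError("extinction table needs >= 2 wavelengths with both coefficients")
        if any(e <= 0 for e in self.eps_hbo + self.eps_hbd):
            raise OpticsError("extinction coefficients must be positive")
        if np.linalg.matrix_rank(self.matrix(self.wavelengths_nm)) < 2:
            raise OpticsError("extinction matrix is rank deficient; wavelengths cannot "
                              "distinguish HbO from HbD")

    def matrix(self, wavelengths: tuple[float, ...] | list[float]) -> np.ndarray:
        """(n_wavelengths, 2) coefficient matrix [eps_hbo, eps_hbd]."""
        idx = {w: i for i, w in enumerate(self.wavelengths_nm)}
        rows = []
        for w in wavelengths:
            if w not in idx:
                raise OpticsError(f"wavelength {w} nm missing from extinction table")
            i = idx[w]
            rows.append([self.eps_hbo[i], self.eps_hbd[i]])
        return np.asarray(rows, dtype=float)


def load_extinction_table(version: str = EXTINCTION_VERSION) -> ExtinctionTable:
    """Load the shipped 3-column extinction file ('#' comments carry the source)."""
    text = resources.files("dvoscope.data").joinpath(f"{version}.tsv").read_text()
    source_lines, rows = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            source_lines.append(line.lstrip("# "))
            continue
        w, ehbo, ehbd = line.split("\t")
        rows.append((float(w), float(ehbo), float(ehbd)))
    return ExtinctionTable(
        wavelengths_nm=tuple(r[0] for r in rows),
        eps_hbo=tuple(r[1] for r in rows),
        eps_hbd=tuple(r[2] for r in rows),
        source=" ".join(source_lines),
    )


@dataclass(frozen=True)
class OpticalChannel:
    detector_id: int
    wavelength_nm: float
    intensity: np.ndarray
    gain: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if np.any(self.intensity <= 0):
            raise OpticsError("channel intensity must be strictly positive")
        if self.gain <= 0:
            raise OpticsError("channel gain must be positive")


@dataclass(frozen=True)
class OpticalRecording:
    subject_id: str
    patch_id: str
    channels: tuple[OpticalChannel, ...]
    protocol: CuffProtocol
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM
    dpf: float = DEFAULT_DPF

    def __post_init__(self) -> None:
        if self.patch_id not in PATCH_IDS:
            raise OpticsError(f"unknown patch_id {self.patch_id!r}")
        n = self.protocol.n_samples
        for ch in self.channels:
            if len(ch.intensity) != n:
                raise OpticsError(
                    f"channel ({ch.detector_id}, {ch.wavelength_nm} nm) has "
                    f"{len(ch.intensity)} samples, protocol implies {n}"
                )

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted({ch.wavelength_nm for ch in self.channels}))

    @property
    def detectors(self) -> tuple[int, ...]:
        return tuple(sorted({ch.detector_id for ch in self.channels}))


@dataclass(frozen=True)
class HemoTrace:
    """Concentration changes from baseline, umol/L, on the protocol time base."""

    time_s: np.ndarray
    hbo: np.ndarray
    hbd: np.ndarray
    hbt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        time_s = np.asarray(self.time_s, dtype=float)
        hbo = np.asarray(self.hbo, dtype=float)
        hbd = np.asarray(self.hbd, dtype=float)
        hbt = self.hbt
        hbt = hbo + hbd if hbt is None else np.asarray(hbt, dtype=float)
        if not (len(time_s) == len(hbo) == len(hbd) == len(hbt)):
            raise OpticsError("trace vectors must share one length")
        if np.any(np.diff(time_s) <= 0):
            raise OpticsError("time axis must be strictly increasing")
        # tolerance admits 9-significant-digit file round trips
        if not np.allclose(hbt, hbo + hbd, atol=1e-6, rtol=1e-9):
            raise OpticsError("hbt must equal hbo + hbd")
        for name, v in (("time_s", time_s), ("hbo", hbo), ("hbd", hbd), ("hbt", hbt)):
            object.__setattr__(self, name, v)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement imperfections applied by the forward model.

    multiplicative_sd: relative Gaussian noise on intensity.
    drift_per_minute: additive linear drift, fraction of the channel's
    nominal intensity per minute; each channel's rate is drawn uniformly
    in +/- this value.
    motion_rate_per_minute: expected count of injected step/spike
    artifacts (0 disables; disabled by default).
    """

    multiplicative_sd: float = 0.001
    drift_per_minute: float = 0.0005
    motion_rate_per_minute: float = 0.0
    motion_step_amplitude: float = 0.05
    motion_spike_amplitude: float = 0.2

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(multiplicative_sd=0.0, drift_per_minute=0.0, motion_rate_per_minute=0.0)


def _delta_od(trace: HemoTrace, eps_row: np.ndarray, pathlength_cm: float, dpf: float):
    conc = np.stack([trace.hbo, trace.hbd]) / _UMOL_PER_MMOL  # mmol/L
    return (eps_row @ conc) * pathlength_cm * dpf


def forward_model(
    trace: HemoTrace,
    ext: ExtinctionTable,
    protocol: CuffProtocol,
    rng: np.random.Generator | None = None,
    *,
    subject_id: str = "synthetic",
    patch_id: str = "medial_plantar",
    wavelengths: tuple[float, ...] = DEVICE_WAVELENGTHS_NM,
    detectors: tuple[int, ...] = (0, 1),
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
    dpf: float = DEFAULT_DPF,
    noise: NoiseConfig | None = None,
    base_intensity: float = 1000.0,
) -> OpticalRecording:
    """Render a hemoglobin trace as multi-channel optical intensities.

    Per wavelength, ``dOD(t) = [eps_hbo dHbO + eps_hbd dHbD] * L * DPF``
    (concentrations in mmol/L) and ``I(t) = I0 * 10^(-dOD) * gain``, then
    multiplicative noise, additive drift, and optional motion artifacts.
    """
    noise = noise or NoiseConfig()
    if rng is None:
        rng = np.random.default_rng()
    eps = ext.matrix(wavelengths)
    n = len(trace.time_s)
    if n != protocol.n_samples:
        raise OpticsError("trace length does not match protocol")
    channels = []
    minutes = trace.time_s / 60.0
    for det in detectors:
        for iw, wav in enumerate(wavelengths):
            dod = _delta_od(trace, eps[iw], pathlength_cm, dpf)
            # wavelength/detector dependent nominal intensity and gain
            i0 = base_intensity * (1.0 + 0.1 * iw + 0.05 * det)
            gain = float(np.exp(rng.normal(0.0, 0.1))) if noise.multiplicative_sd > 0 else 1.0
            intensity = i0 * np.power(10.0, -dod)
            if noise.multiplicative_sd > 0:
                intensity = intensity * (1.0 + rng.normal(0.0, noise.multiplicative_sd, n))
            if noise.drift_per_minute > 0:
                rate = rng.uniform(-noise.drift_per_minute, noise.drift_per_minute)
                intensity = intensity + i0 * rate * minutes
            if noise.motion_rate_per_minute > 0:
                intensity = _inject_motion(intensity, i0, noise, trace.time_s, rng)
            intensity = np.maximum(intensity, 1e-9 * i0)
            channels.append(
                OpticalChannel(detector_id=det, wavelength_nm=wav,
                               intensity=intensity * gain, gain=gain)
            )
    return OpticalRecording(
        subject_id=subject_id, patch_id=patch_id, channels=tuple(channels),
        protocol=protocol, pathlength_cm=pathlength_cm, dpf=dpf,
    )


def _inject_motion(intensity, i0, noise: NoiseConfig, time_s, rng):
    out = intensity.copy()
    n_events = rng.poisson(noise.motion_rate_per_minute * time_s[-1] / 60.0)
    for _ in range(n_events):
        idx = int(rng.integers(1, len(out)))
        if rng.uniform() < 0.5:  # step
            out[idx:] += rng.choice([-1, 1]) * noise.motion_step_amplitude * i0
        else:  # spike, 1-2 samples
            width = int(rng.integers(1, 3))
            out[idx:idx + width] += rng.choice([-1, 1]) * noise.motion_spike_amplitude * i0
    return out


def invert_hemoglobin(rec: OpticalRecording, ext: ExtinctionTable) -> HemoTrace:
    """Reconstruct (dHbO, dHbD) per timepoint by least squares.

    dOD is referenced to each channel's mean intensity over the baseline
    phase (gain therefore cancels); detectors are inverted independently
    and averaged afterwards. Output concentrations are umol/L.
    """
    wavelengths = rec.wavelengths
    if len(wavelengths) < 2:
        raise OpticsError(
            f"recording {rec.subject_id}: only {len(wavelengths)} wavelength(s) "
            "survived QC; chromophore inversion refused"
        )
    eps = ext.matrix(wavelengths)
    if np.linalg.matrix_rank(eps) < 2:
        raise OpticsError("rank-deficient extinction submatrix; inversion refused")
    baseline = rec.protocol.phase("baseline")
    time_s = rec.protocol.time_axis()
    in_baseline = (time_s >= baseline.start_s) & (time_s < baseline.end_s)
    scale = rec.pathlength_cm * rec.dpf
    per_detector = []
    for det in rec.detectors:
        dods, used = [], []
        for wav in wavelengths:
            chans = [c for c in rec.channels
                     if c.detector_id == det and c.wavelength_nm == wav]
            if not chans:
                continue
            inten = np.mean([c.intensity for c in chans], axis=0)
            ref = float(np.mean(inten[in_baseline]))
            dods.append(-np.log10(inten / ref))
            used.append(wav)
        if len(used) < 2:
            continue
        eps_d = ext.matrix(used)
        sol, *_ = np.linalg.lstsq(eps_d * scale, np.asarray(dods), rcond=None)
        per_detector.append(sol * _UMOL_PER_MMOL)
    if not per_detector:
        raise OpticsError(f"recording {rec.subject_id}: no detector with >= 2 wavelengths")
    conc = np.mean(per_detector, axis=0)
    return HemoTrace(time_s=time_s, hbo=conc[0], hbd=conc[1])


def restrict_channels(rec: OpticalRecording, keep: list[OpticalChannel]) -> OpticalRecording:
    return replace(rec, channels=tuple(keep))
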