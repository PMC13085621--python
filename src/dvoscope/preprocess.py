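"""Channel quality control and signal conditioning.

SNR screening happens on raw intensities over the baseline (resting)
phase; low-pass filtering is zero-phase so interval-slope features are
not delayed by filter group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .optics import OpticalChannel, OpticalRecording

DEFAULT_SNR_THRESHOLD = 4.0
DEFAULT_CUTOFF_HZ = 0.51
DEFAULT_FILTER_ORDER = 2


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class ChannelQC:
    detector_id: int
    wavelength_nm: float
    snr: float
    included: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.included and not self.reason:
            raise PreprocessError("excluded channel requires a reason")


def compute_snr(channel: OpticalChannel, baseline_window: tuple[float, float],
                fs: float, t0: float = 0.0) -> float:
    """Baseline SNR: temporal mean over the window divided by its SD.

    A constant (zero-SD) signal yields +inf and is retained by the screen.
    """
    start_s, end_s = baseline_window
    if end_s <= start_s:
        raise PreprocessError("empty baseline window")
    time_s = t0 + np.arange(len(channel.intensity)) / fs
    sel = (time_s >= start_s) & (time_s < end_s)
    if np.count_nonzero(sel) < 2:
        raise PreprocessError("baseline window must contain >= 2 samples")
    seg = channel.intensity[sel]
    sd = float(np.std(seg, ddof=0))
    mean = float(np.mean(seg))
    if sd == 0.0:
        return np.inf if mean != 0 else 0.0
    return mean / sd


def apply_snr_filter(
    rec: OpticalRecording, threshold: float = DEFAULT_SNR_THRESHOLD
) -> tuple[OpticalRecording, list[ChannelQC]]:
    """Drop channels whose baseline SNR falls below ``threshold``.

    The boundary is retained: the exclusion rule is strictly ``snr <
    threshold``. Returns the restricted recording and a QC row per
    channel. If the survivors span fewer than 2 distinct wavelengths the
    recording is unreconstructable (flagged via the QC report; no throw).
    """
    baseline = rec.protocol.phase("baseline")
    window = (baseline.start_s, baseline.end_s)
    fs = rec.protocol.sampling_rate_hz
    t0 = rec.protocol.phases[0].start_s
    report, keep = [], []
    for ch in rec.channels:
        snr = compute_snr(ch, window, fs, t0)
        included = snr >= threshold
        report.append(
            ChannelQC(
                detector_id=ch.detector_id, wavelength_nm=ch.wavelength_nm,
                snr=snr, included=included,
                reason="" if included else f"SNR {snr:.3g} < {threshold:g}",
            )
        )
        if included:
            keep.append(ch)
    return replace(rec, channels=tuple(keep)), report


def is_reconstructable(rec: OpticalRecording) -> bool:
    return len(rec.wavelengths) >= 2


def lowpass_filter(
    series: np.ndarray,
    fs: float = 2.56,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter with unit DC gain.

    Zero-phase (forward-backward) by default so slope timing is not
    shifted; a causal mode exists for sensitivity checks. Edge handling:
    reflective padding, ``3 * order`` samples.
    """
    series = np.asarray(series, dtype=float)
    nyquist = fs / 2.0
    if cutoff_hz >= nyquist:
        raise PreprocessError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if len(series) <= 3 * order:
        raise PreprocessError("series too short for filter padding")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, series, padtype="even", padlen=3 * order)
    return signal.sosfilt(sos, series)


def filter_recording(rec: OpticalRecording, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                     order: int = DEFAULT_FILTER_ORDER) -> OpticalRecording:
    fs = rec.protocol.sampling_rate_hz
    channels = tuple(
        replace(ch, intensity=lowpass_filter(ch.intensity, fs, cutoff_hz, order))
        for ch in rec.channels
    )
    return replace(rec, channels=channels)


def flag_motion(
    series: np.ndarray,
    spike_z: float = 6.0,
    step_threshold: float = 4.0,
    max_artifact_fraction: float = 0.02,
    window: int = 13,
) -> tuple[bool, list[tuple[int, int]]]:
    """Detect spike and step artifacts in a single series.

    Spikes: robust z-score (median/MAD) of the detrended series above
    ``spike_z``. Steps: jumps in the rolling median larger than
    ``step_threshold`` times the robust spread of the first differences.
    Returns (flagged, artifact sample intervals); flagged when the
    artifact fraction exceeds ``max_artifact_fraction`` or any step is
    found.

    Intended for series whose physiological content is slow (baseline or
    recovery segments, or detrended residuals); protocol-driven occlusion
    transients should be masked by the caller before screening.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise PreprocessError("empty series")
    if x.size < 3 or np.ptp(x) == 0:
        return False, []
    diffs = np.diff(x)
    mad_d = np.median(np.abs(diffs - np.median(diffs)))
    scale_d = 1.4826 * mad_d
    detrended = x - _rolling_median(x, window)
    mad = np.median(np.abs(detrended - np.median(detrended)))
    scale = 1.4826 * mad if mad > 0 else (np.std(detrended) or 1.0)
    spike_mask = np.abs(detrended - np.median(detrended)) > spike_z * scale
    step_mask = np.zeros_like(x, dtype=bool)
    if scale_d > 0:
        med = _rolling_median(x, window)
        med_jump = np.abs(np.diff(med))
        step_mask[1:] = med_jump > step_threshold * scale_d
    mask = spike_mask | step_mask
    intervals = _mask_to_intervals(mask)
    flagged = bool(step_mask.any() or mask.mean() > max_artifact_fraction)
    return flagged, intervals


def _rolling_median(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    return np.array([np.median(padded[i:i + window]) for i in range(len(x))])


def _mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    intervals, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, len(mask)))
    return intervals
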