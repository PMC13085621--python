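"""Self-describing columnar text formats for recordings and traces.

A trace file is '#'-prefixed ``key = value`` header lines followed by a
whitespace-delimited numeric table. Floats are written with 9 significant
digits ('.' decimal, no locale), which makes write->read->write
idempotent on the formatted payload.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .optics import HemoTrace, OpticalChannel, OpticalRecording, OpticsError
from .protocol import CuffProtocol, Phase

FLOAT_FMT = "%.9g"
HEMO_UNITS = "umol/L"
INTENSITY_UNITS = "au"


class TraceFileError(ValueError):
    pass


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _phases_to_header(protocol: CuffProtocol) -> str:
    return ";".join(
        f"{p.label}:{_fmt(p.start_s)}:{_fmt(p.duration_s)}:{_fmt(p.pressure_mmHg)}"
        for p in protocol.phases
    )


def _phases_from_header(text: str, sampling_rate_hz: float) -> CuffProtocol:
    phases = []
    for part in text.split(";"):
        label, start, dur, pressure = part.split(":")
        phases.append(Phase(label, float(start), float(dur), float(pressure)))
    return CuffProtocol(phases=tuple(phases), sampling_rate_hz=sampling_rate_hz)


def write_recording(path: str | Path, rec: OpticalRecording) -> None:
    buf = _io.StringIO()
    h = buf.write
    h("# type = optical_recording\n")
    h(f"# subject_id = {rec.subject_id}\n")
    h(f"# patch_id = {rec.patch_id}\n")
    h(f"# sampling_rate_hz = {_fmt(rec.protocol.sampling_rate_hz)}\n")
    h(f"# phases = {_phases_to_header(rec.protocol)}\n")
    h(f"# pathlength_cm = {_fmt(rec.pathlength_cm)}\n")
    h(f"# dpf = {_fmt(rec.dpf)}\n")
    h(f"# units = {INTENSITY_UNITS}\n")
    cols, names = [rec.protocol.time_axis()], ["time_s"]
    gains = []
    for ch in rec.channels:
        names.append(f"det{ch.detector_id}_w{ch.wavelength_nm:g}")
        gains.append(_fmt(ch.gain))
        cols.append(ch.intensity)
    h(f"# gains = {';'.join(gains)}\n")
    h(f"# columns = {' '.join(names)}\n")
    _write_table(buf, cols)
    Path(path).write_text(buf.getvalue())


def write_trace(path: str | Path, trace: HemoTrace, subject_id: str = "unknown",
                protocol: CuffProtocol | None = None) -> None:
    buf = _io.StringIO()
    h = buf.write
    h("# type = hemoglobin_trace\n")
    h(f"# subject_id = {subject_id}\n")
    if protocol is not None:
        h(f"# sampling_rate_hz = {_fmt(protocol.sampling_rate_hz)}\n")
        h(f"# phases = {_phases_to_header(protocol)}\n")
    h(f"# units = {HEMO_UNITS}\n")
    h("# columns = time_s hbo hbd hbt\n")
    _write_table(buf, [trace.time_s, trace.hbo, trace.hbd, trace.hbt])
    Path(path).write_text(buf.getvalue())


def _write_table(buf, cols) -> None:
    arr = np.column_stack([np.asarray(c, dtype=float) for c in cols])
    for row in arr:
        buf.write(" ".join(_fmt(v) for v in row) + "\n")


def read_trace_file(path: str | Path) -> OpticalRecording | HemoTrace:
    """Parse a trace file into its typed object, validating the payload."""
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" not in body:
                    raise TraceFileError(f"{path}:{lineno}: malformed header line")
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
                continue
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise TraceFileError(f"{path}:{lineno}: non-numeric value") from exc
            if rows and len(row) != len(rows[0]):
                raise TraceFileError(
                    f"{path}:{lineno}: ragged row ({len(row)} columns, "
                    f"expected {len(rows[0])})"
                )
            rows.append(row)
    if "type" not in header or "columns" not in header:
        raise TraceFileError(f"{path}: missing 'type' or 'columns' header")
    if not rows:
        raise TraceFileError(f"{path}: no data rows")
    data = np.asarray(rows)
    names = header["columns"].split()
    if data.shape[1] != len(names):
        raise TraceFileError(f"{path}: column count does not match header")
    time_s = data[:, 0]
    if np.any(np.diff(time_s) <= 0):
        bad = int(np.flatnonzero(np.diff(time_s) <= 0)[0]) + 2
        raise TraceFileError(f"{path}: non-monotone time column at data row {bad}")

    kind = header["type"]
    if kind == "hemoglobin_trace":
        if header.get("units") != HEMO_UNITS:
            raise TraceFileError(
                f"{path}: unknown units {header.get('units')!r}, expected {HEMO_UNITS!r}")
        cols = {n: data[:, i] for i, n in enumerate(names)}
        try:
            return HemoTrace(time_s=time_s, hbo=cols["hbo"], hbd=cols["hbd"],
                             hbt=cols.get("hbt"))
        except OpticsError as exc:
            raise TraceFileError(f"{path}: {exc}") from exc
    if kind == "optical_recording":
        if header.get("units") != INTENSITY_UNITS:
            raise TraceFileError(
                f"{path}: unknown units {header.get('units')!r}, expected {INTENSITY_UNITS!r}")
        protocol = _phases_from_header(header["phases"], float(header["sampling_rate_hz"]))
        gains = [float(g) for g in header.get("gains", "").split(";") if g]
        channels = []
        for i, name in enumerate(names[1:], start=1):
            det_part, w_part = name.split("_w")
            channels.append(OpticalChannel(
                detector_id=int(det_part.removeprefix("det")),
                wavelength_nm=float(w_part),
                intensity=data[:, i],
                gain=gains[i - 1] if i - 1 < len(gains) else 1.0,
            ))
        try:
            return OpticalRecording(
                subject_id=header.get("subject_id", "unknown"),
                patch_id=header.get("patch_id", "medial_plantar"),
                channels=tuple(channels), protocol=protocol,
                pathlength_cm=float(header.get("pathlength_cm", 3.0)),
                dpf=float(header.get("dpf", 4.0)),
            )
        except OpticsError as exc:
            raise TraceFileError(f"{path}: {exc}") from exc
    raise TraceFileError(f"{path}: unknown trace file type {kind!r}")
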