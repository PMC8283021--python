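"""Reading and writing the formats the pipeline touches.

EDF (European Data Format, 16-bit) is the polysomnography container;
telemetry and single channels travel as two-column CSV (``time_s,value``).
The EDF codec here implements the plain EDF header and record layout:
one data record per second, one signal per channel, physical scaling via
the per-signal physical/digital min/max fields.  EDF+ annotations are out
of scope.

Writing requires every trace to have an integer sampling rate and all
traces of a recording to share a whole-second duration; this matches the
signals the synthetic generators produce and keeps the round trip exact
to within the 16-bit quantization step.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Recording, Trace

__all__ = [
    "EDFFormatError",
    "read_edf",
    "write_edf",
    "read_csv_trace",
    "write_csv_trace",
    "resample",
    "write_annotations_json",
    "read_annotations_json",
]


class EDFFormatError(ValueError):
    """Raised when an EDF header field cannot be parsed."""


_HDR = 256  # bytes in the fixed part of an EDF header


def _ascii(field: bytes, name: str) -> str:
    try:
        return field.decode("ascii").strip()
    except UnicodeDecodeError as exc:
        raise EDFFormatError(f"non-ASCII bytes in EDF field '{name}'") from exc


def _number(field: bytes, name: str) -> float:
    text = _ascii(field, name)
    try:
        return float(text)
    except ValueError as exc:
        raise EDFFormatError(
            f"EDF field '{name}' is not numeric: {text!r}"
        ) from exc


def _pack(text: str, width: int) -> bytes:
    raw = text.encode("ascii")[:width]
    return raw.ljust(width)


def write_edf(path, rec: Recording) -> None:
    """Write a :class:`Recording` as 16-bit EDF, one signal per trace.

    Animal metadata is carried in the patient / recording-id header
    fields so that :func:`read_edf` can restore it.
    """
    path = Path(path)
    traces = list(rec.traces.values())
    if not traces:
        raise ValueError("recording has no traces to write")
    duration = traces[0].duration_s
    for tr in traces:
        if abs(tr.duration_s - duration) > 1e-9:
            raise ValueError("EDF export requires equal-duration traces")
        if abs(tr.rate - round(tr.rate)) > 1e-9:
            raise ValueError("EDF export requires integer sampling rates")
    n_records = int(round(duration))
    if abs(duration - n_records) > 1e-9 or n_records < 1:
        raise ValueError("EDF export requires a whole-second duration")

    ns = len(traces)
    start = traces[0].start_clock_s % 86400
    hh, rem = divmod(int(start), 3600)
    mm, ss = divmod(rem, 60)
    patient = f"{rec.animal_id}"
    recording_id = (
        f"group={rec.group} bw_g={rec.body_weight_g:g} "
        f"lights_on={rec.lights_on_hour:g}"
    )

    header = b"".join(
        [
            _pack("0", 8),
            _pack(patient, 80),
            _pack(recording_id, 80),
            _pack("01.01.01", 8),
            _pack(f"{hh:02d}.{mm:02d}.{ss:02d}", 8),
            _pack(str(_HDR * (ns + 1)), 8),
            _pack("", 44),
            _pack(str(n_records), 8),
            _pack("1", 8),
            _pack(str(ns), 4),
        ]
    )

    phys_min, phys_max, scaled = [], [], []
    for tr in traces:
        lo, hi = float(np.min(tr.values)), float(np.max(tr.values))
        if hi - lo < 1e-12:  # constant channel: widen to keep gain finite
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (hi - lo) / (32767 - (-32768))
        dig = np.round((tr.values - lo) / gain) + (-32768)
        scaled.append(np.clip(dig, -32768, 32767).astype("<i2"))

    def fmt8(x: float) -> str:
        for digits in range(8, 0, -1):
            text = f"{x:.{digits}g}"
            if len(text) <= 8:
                return text
        return f"{x:.0e}"[:8]

    sig = b"".join(
        [
            b"".join(_pack(tr.label, 16) for tr in traces),
            b"".join(_pack("", 80) for _ in traces),
            b"".join(_pack(tr.units, 8) for tr in traces),
            b"".join(_pack(fmt8(lo), 8) for lo in phys_min),
            b"".join(_pack(fmt8(hi), 8) for hi in phys_max),
            b"".join(_pack("-32768", 8) for _ in traces),
            b"".join(_pack("32767", 8) for _ in traces),
            b"".join(_pack("", 80) for _ in traces),
            b"".join(_pack(str(int(round(tr.rate))), 8) for tr in traces),
            b"".join(_pack("", 32) for _ in traces),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        spr = [int(round(tr.rate)) for tr in traces]
        for r in range(n_records):
            for arr, n in zip(scaled, spr):
                fh.write(arr[r * n : (r + 1) * n].tobytes())


def read_edf(path) -> Recording:
    """Read a plain EDF file into a :class:`Recording`.

    One :class:`Trace` per EDF signal, with the physical-dimension
    scaling applied; sampling rates come from samples-per-record divided
    by the data-record duration.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HDR:
        raise EDFFormatError("file shorter than the 256-byte EDF header")
    patient = _ascii(blob[8:88], "patient identification")
    recording_id = _ascii(blob[88:168], "recording identification")
    starttime = _ascii(blob[176:184], "starttime")
    n_records = int(_number(blob[236:244], "number of data records"))
    rec_dur = _number(blob[244:252], "duration of a data record")
    ns = int(_number(blob[252:256], "number of signals"))
    if ns <= 0:
        raise EDFFormatError("number of signals must be positive")
    if n_records <= 0:
        raise EDFFormatError("number of data records must be positive")
    if rec_dur <= 0:
        raise EDFFormatError("duration of a data record must be positive")

    need = _HDR + ns * 256
    if len(blob) < need:
        raise EDFFormatError("file truncated inside the signal header")
    off = _HDR

    def col(width: int, name: str, numeric: bool):
        nonlocal off
        out = []
        for i in range(ns):
            raw = blob[off + i * width : off + (i + 1) * width]
            out.append(
                _number(raw, f"{name}[{i}]")
                if numeric
                else _ascii(raw, f"{name}[{i}]")
            )
        off += ns * width
        return out

    labels = col(16, "label", False)
    col(80, "transducer", False)
    units = col(8, "physical dimension", False)
    pmin = col(8, "physical minimum", True)
    pmax = col(8, "physical maximum", True)
    dmin = col(8, "digital minimum", True)
    dmax = col(8, "digital maximum", True)
    col(80, "prefiltering", False)
    spr = [int(x) for x in col(8, "samples per record", True)]

    m = re.fullmatch(r"(\d\d)\.(\d\d)\.(\d\d)", starttime)
    if not m:
        raise EDFFormatError(f"EDF field 'starttime' malformed: {starttime!r}")
    start_clock = int(m[1]) * 3600 + int(m[2]) * 60 + int(m[3])

    meta = dict(
        re.findall(r"(\w+)=([^\s]+)", recording_id)
    )  # written by write_edf; absent in foreign files
    rec = Recording(
        animal_id=patient or path.stem,
        group=meta.get("group", "other"),
        body_weight_g=float(meta.get("bw_g", 1.0)),
        lights_on_hour=float(meta.get("lights_on", 9.0)),
    )

    rec_bytes = 2 * sum(spr)
    data = blob[_HDR + ns * 256 :]
    if len(data) < n_records * rec_bytes:
        raise EDFFormatError("data section shorter than header promises")
    raw = np.frombuffer(data[: n_records * rec_bytes], dtype="<i2")
    raw = raw.reshape(n_records, sum(spr))
    bounds = np.cumsum([0] + spr)
    for i, label in enumerate(labels):
        dig = raw[:, bounds[i] : bounds[i + 1]].reshape(-1).astype(float)
        if dmax[i] == dmin[i]:
            raise EDFFormatError(f"digital min equals max for signal {i}")
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        values = (dig - dmin[i]) * gain + pmin[i]
        rec.traces[label] = Trace(
            label=label,
            values=values,
            rate=spr[i] / rec_dur,
            units=units[i],
            start_clock_s=float(start_clock),
        )
    return rec


def read_csv_trace(path, rate: float, label: str = "", units: str = "") -> Trace:
    """Read a two-column ``time_s,value`` CSV and resample to ``rate`` Hz.

    The input time base may be irregular; values are linearly
    interpolated onto a uniform grid starting at the first time stamp.
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError("expected a non-empty two-column time_s,value CSV")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    if t.size == 1:
        grid = np.array([t[0]])
    else:
        n = int(math.floor((t[-1] - t[0]) * rate)) + 1
        grid = t[0] + np.arange(n) / rate
    values = np.interp(grid, t, v)
    return Trace(label=label or str(df.columns[1]), values=values, rate=rate,
                 units=units)


def write_csv_trace(path, trace: Trace) -> None:
    pd.DataFrame(
        {"time_s": trace.times(), "value": trace.values}
    ).to_csv(path, index=False)


def resample(trace: Trace, new_rate: float) -> Trace:
    """Linear-interpolation resampling onto a uniform grid at ``new_rate``.

    Duration is preserved to within one sample period of the coarser of
    the two rates.
    """
    if not new_rate > 0:
        raise ValueError("new_rate must be positive")
    if abs(new_rate - trace.rate) < 1e-12:
        return Trace(trace.label, trace.values.copy(), trace.rate,
                     trace.units, trace.start_clock_s,
                     None if trace.valid is None else trace.valid.copy())
    t_old = trace.times()
    n_new = max(1, int(round(trace.duration_s * new_rate)))
    t_new = np.arange(n_new) / new_rate
    values = np.interp(t_new, t_old, trace.values)
    return Trace(trace.label, values, new_rate, trace.units,
                 trace.start_clock_s)


def write_annotations_json(path, annotations: dict) -> None:
    """Ground-truth sidecar: hypnogram, event list, hourly BP, etc."""

    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(annotations, default=default, indent=1))


def read_annotations_json(path) -> dict:
    return json.loads(Path(path).read_text())
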