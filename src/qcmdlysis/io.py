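"""Reading and writing the QCMD-CSV trace dialect.

A trace file is a plain CSV with ``#``-prefixed header lines carrying
``key: value`` metadata, followed by one header row and the data columns
``time_min`` then, per overtone ``n``, ``df{n}_hz`` and ``dD{n}_e6``::

    # sensor_id: sim-00-control
    # fundamental_frequency_hz: 5000000.0
    # overtones: 3,5,7,9,11
    # label: control
    # phase: baseline_pbs,0,20,PBS,30
    # phase: bacteria_injection,20,50,bacteria_in_medium,30
    ...
    time_min,df3_hz,dD3_e6,...,df11_hz,dD11_e6
    0.0,0.0,0.0,...

The phase schedule is embedded in the header (one ``phase:`` line per
phase, ``name,start,end,medium,flow_rate``), so a file is self-contained.
Floats are written with 17 significant digits, which round-trips IEEE
doubles exactly; writing the same experiment twice yields byte-identical
files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import pandas as pd

from .traces import (
    OvertoneTrace,
    Phase,
    PhaseSchedule,
    QcmdExperiment,
)

__all__ = ["read_trace", "write_trace", "TraceParseError"]

PathLike = Union[str, Path]


class TraceParseError(ValueError):
    """A trace file violates the QCMD-CSV dialect."""


def write_trace(exp: QcmdExperiment, path: PathLike) -> None:
    """Write an experiment to ``path`` in the QCMD-CSV dialect."""
    path = Path(path)
    overtones = sorted(exp.traces)
    lines = [
        f"# sensor_id: {exp.sensor_id}",
        f"# fundamental_frequency_hz: {exp.fundamental_frequency!r}",
        f"# overtones: {','.join(str(n) for n in overtones)}",
    ]
    if exp.label is not None:
        lines.append(f"# label: {exp.label}")
    reserved = {"sensor_id", "fundamental_frequency_hz", "overtones", "label", "phase"}
    for key, value in exp.metadata.items():
        if key not in reserved:
            lines.append(f"# {key}: {value}")
    for ph in exp.schedule:
        lines.append(
            f"# phase: {ph.name},{ph.start!r},{ph.end!r},{ph.medium},{ph.flow_rate!r}"
        )
    cols = {"time_min": exp.time}
    for n in overtones:
        cols[f"df{n}_hz"] = exp.traces[n].delta_f
        cols[f"dD{n}_e6"] = exp.traces[n].delta_D
    frame = pd.DataFrame(cols)
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.17g", lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


def _parse_header(lines: list[str], path: Path) -> dict:
    meta = {"phases": []}
    for lineno, line in enumerate(lines, start=1):
        body = line[1:].strip()
        if not body:
            continue
        if ":" not in body:
            raise TraceParseError(f"{path}:{lineno}: malformed metadata line {line!r}")
        key, _, value = body.partition(":")
        key, value = key.strip(), value.strip()
        try:
            if key == "sensor_id":
                meta["sensor_id"] = value
            elif key == "fundamental_frequency_hz":
                meta["fundamental_frequency"] = float(value)
            elif key == "overtones":
                meta["overtones"] = [int(v) for v in value.split(",")]
            elif key == "label":
                meta["label"] = value
            elif key == "phase":
                name, start, end, medium, flow = value.split(",")
                meta["phases"].append(
                    Phase(name, float(start), float(end), medium, float(flow))
                )
            # unknown keys are preserved as free-form metadata
            else:
                try:
                    value = float(value)
                except ValueError:
                    pass
                meta.setdefault("extra", {})[key] = value
        except TraceParseError:
            raise
        except Exception as err:
            raise TraceParseError(
                f"{path}:{lineno}: cannot parse metadata line {line!r}: {err}"
            ) from err
    return meta


def read_trace(
    path: PathLike, schedule: PhaseSchedule | None = None
) -> QcmdExperiment:
    """Parse a QCMD-CSV trace file into a :class:`QcmdExperiment`.

    The phase schedule is taken from the file header unless one is passed
    explicitly (sidecar configuration).  Raises
    :class:`TraceParseError` naming the offending column or line on
    missing columns, non-monotone time or malformed metadata.
    """
    path = Path(path)
    text = path.read_text()
    header_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    meta = _parse_header(header_lines, path)
    if "overtones" not in meta:
        raise TraceParseError(f"{path}: missing 'overtones' metadata line")
    try:
        frame = pd.read_csv(_io.StringIO(text), comment="#", float_precision="round_trip")
    except Exception as err:
        raise TraceParseError(f"{path}: cannot parse CSV body: {err}") from err
    if "time_min" not in frame.columns:
        raise TraceParseError(f"{path}: missing column 'time_min'")
    time = frame["time_min"].to_numpy(dtype=float)
    if len(time) == 0:
        raise TraceParseError(f"{path}: no data rows")
    if (pd.Series(time).diff().dropna() <= 0).any():
        raise TraceParseError(f"{path}: non-monotone time in column 'time_min'")
    traces = {}
    for n in meta["overtones"]:
        for col in (f"df{n}_hz", f"dD{n}_e6"):
            if col not in frame.columns:
                raise TraceParseError(f"{path}: missing column '{col}'")
        traces[n] = OvertoneTrace(
            n,
            time,
            frame[f"df{n}_hz"].to_numpy(dtype=float),
            frame[f"dD{n}_e6"].to_numpy(dtype=float),
        )
    if schedule is None:
        if not meta["phases"]:
            raise TraceParseError(
                f"{path}: no phase schedule in header and none supplied"
            )
        schedule = PhaseSchedule(meta["phases"])
    return QcmdExperiment(
        sensor_id=meta.get("sensor_id", path.stem),
        traces=traces,
        schedule=schedule,
        fundamental_frequency=meta.get("fundamental_frequency", 5e6),
        label=meta.get("label"),
        metadata=meta.get("extra", {}),
    )
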