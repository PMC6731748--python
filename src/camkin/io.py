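"""Plain-text I/O: trace and titration CSVs, config files.

Trace files are two-column CSV (``time_s,absorbance``) preceded by ``#``
comment lines carrying the assay conditions and seed as ``key=value`` pairs,
so a trace round-trips losslessly (12 significant digits) together with its
metadata.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .stopped_flow import AbsorbanceTrace, AssayConditions
from .titration import TitrationConfig, TitrationCurve

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_titration_csv",
    "read_titration_csv",
    "load_config_file",
]

_FMT = "%.12g"


def _format(value: object) -> str:
    if isinstance(value, float):
        return _FMT % value
    return str(value)


def write_trace_csv(trace: AbsorbanceTrace, path: str | Path) -> None:
    """Write one absorbance trace with its conditions in the header."""
    path = Path(path)
    lines = ["# camkin absorbance trace"]
    if trace.seed is not None:
        lines.append(f"# seed={trace.seed}")
    for f in dataclasses.fields(AssayConditions):
        lines.append(f"# {f.name}={_format(getattr(trace.conditions, f.name))}")
    lines.append("time_s,absorbance")
    for t, a in zip(trace.times, trace.absorbance):
        lines.append(f"{_FMT % t},{_FMT % a}")
    path.write_text("\n".join(lines) + "\n")


def _parse_header(lines: list[str]) -> tuple[AssayConditions | None, int | None]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
    seed = int(meta["seed"]) if "seed" in meta else None
    known = {f.name for f in dataclasses.fields(AssayConditions)}
    kwargs: dict[str, float | None] = {}
    for key, val in meta.items():
        if key in known:
            kwargs[key] = None if val == "None" else float(val)
    cond = AssayConditions(**kwargs) if kwargs else None
    return cond, seed


def read_trace_csv(path: str | Path) -> AbsorbanceTrace:
    """Read a trace CSV written by :func:`write_trace_csv`.

    Comment lines anywhere in the file are ignored as data but the header
    ``key=value`` pairs are parsed back into :class:`AssayConditions`.
    """
    path = Path(path)
    text = path.read_text()
    comments = [ln for ln in text.splitlines() if ln.startswith("#")]
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty trace file")
    header = rows[0].split(",")
    if [h.strip() for h in header] != ["time_s", "absorbance"]:
        raise ValueError(f"{path}: expected columns time_s,absorbance, got {rows[0]!r}")
    try:
        data = np.array([[float(x) for x in ln.split(",")] for ln in rows[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed data row ({exc})") from exc
    if data.size == 0:
        raise ValueError(f"{path}: no data rows")
    times, absorbance = data[:, 0], data[:, 1]
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    cond, seed = _parse_header(comments)
    return AbsorbanceTrace(times, absorbance, cond or AssayConditions(), seed)


def write_titration_csv(curve: TitrationCurve, path: str | Path) -> None:
    """Write a titration curve as ``volume_mL,pH`` with the config in the header."""
    path = Path(path)
    lines = ["# camkin titration curve"]
    for f in dataclasses.fields(TitrationConfig):
        lines.append(f"# {f.name}={_format(getattr(curve.config, f.name))}")
    lines.append("volume_mL,pH")
    for v, p in zip(curve.titrant_volumes, curve.pH_values):
        lines.append(f"{_FMT % (v * 1e3)},{_FMT % p}")
    path.write_text("\n".join(lines) + "\n")


def read_titration_csv(path: str | Path) -> TitrationCurve:
    """Read a titration CSV written by :func:`write_titration_csv`."""
    path = Path(path)
    text = path.read_text()
    comments = [ln for ln in text.splitlines() if ln.startswith("#")]
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    if not rows or [h.strip() for h in rows[0].split(",")] != ["volume_mL", "pH"]:
        raise ValueError(f"{path}: expected columns volume_mL,pH")
    data = np.array([[float(x) for x in ln.split(",")] for ln in rows[1:]])
    if data.size == 0:
        raise ValueError(f"{path}: no data rows")
    meta: dict[str, str] = {}
    for line in comments:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            meta[key.strip()] = val.strip()
    known = {f.name: f for f in dataclasses.fields(TitrationConfig)}
    kwargs: dict[str, object] = {}
    for key, val in meta.items():
        if key in known:
            kwargs[key] = int(val) if known[key].type == "int" else float(val)
    config = TitrationConfig(**kwargs) if kwargs else TitrationConfig()
    return TitrationCurve(data[:, 0] / 1e3, data[:, 1], config)


def load_config_file(path: str | Path) -> dict:
    """Load a JSON or YAML configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data
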