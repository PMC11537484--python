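"""Trace and parameter-set file I/O.

Trace files are two-column delimited text (time_s, value) with a ``#``
header block of ``key: value`` metadata; ``units`` and ``dt`` are required.
Values are serialized at full precision so write/read round trips are
bit-exact.  Parameter sets round trip through YAML.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import yaml

from .cascade import CascadeParams, Trace
from .linear import LinearFilterParams

__all__ = ["read_trace", "write_trace", "load_params", "save_params",
           "load_linear_filter", "save_linear_filter", "TraceParseError"]

_REQUIRED_KEYS = ("units", "dt")


class TraceParseError(ValueError):
    pass


def write_trace(trace: Trace, path, **metadata) -> None:
    """Write a trace with a metadata header.  Extra keyword metadata
    (cell_type, seed, provenance, ...) is stored in the header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# units: {trace.units}\n")
        fh.write(f"# dt: {float(trace.dt)!r}\n")
        for key, val in metadata.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# time_s\tvalue\n")
        dt = float(trace.dt)
        for i, v in enumerate(trace.values):
            fh.write(f"{i * dt!r}\t{float(v)!r}\n")


def read_trace(path) -> tuple[Trace, dict]:
    """Read a trace file; returns ``(trace, metadata)``.

    Raises :class:`TraceParseError` (with line numbers) for missing header
    keys, malformed rows, or body spacing inconsistent with the header dt.
    """
    path = Path(path)
    meta: dict = {}
    times, values = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TraceParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError:
                raise TraceParseError(
                    f"{path}:{lineno}: non-numeric sample {line!r}"
                ) from None
    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise TraceParseError(
            f"{path}: header missing required keys {missing}; "
            f"required: {list(_REQUIRED_KEYS)}"
        )
    dt = float(meta["dt"])
    t = np.asarray(times)
    if len(t) > 1:
        spacing = np.diff(t)
        bad = np.flatnonzero(np.abs(spacing - dt) > 1e-9)
        if len(bad):
            raise TraceParseError(
                f"{path}: sample spacing {spacing[bad[0]]!r} at row {bad[0] + 2} "
                f"inconsistent with header dt={dt!r}"
            )
    return Trace(dt, np.asarray(values), meta["units"]), meta


def save_params(params: CascadeParams, path) -> None:
    data = {k: getattr(params, k) for k in
            ("gamma", "sigma", "phi", "eta", "k", "n", "m", "beta",
             "K_GC", "C_D", "cell_type")}
    Path(path).write_text(yaml.safe_dump({"cascade": data}, sort_keys=False))


def load_params(path) -> CascadeParams:
    data = yaml.safe_load(Path(path).read_text())["cascade"]
    return CascadeParams(**data)


def save_linear_filter(lfp: LinearFilterParams, path, **extra) -> None:
    data = {k: getattr(lfp, k) for k in
            ("alpha", "tau_R", "tau_D", "mean_level", "cell_type")}
    data.update(extra)
    Path(path).write_text(yaml.safe_dump({"linear_filter": data}, sort_keys=False))


def load_linear_filter(path) -> LinearFilterParams:
    data = yaml.safe_load(Path(path).read_text())["linear_filter"]
    keep = {k: data[k] for k in ("alpha", "tau_R", "tau_D", "mean_level", "cell_type")}
    return LinearFilterParams(**keep)
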