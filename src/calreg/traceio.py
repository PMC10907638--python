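"""Reading and writing voltage/calcium traces as columnar text.

Format: CSV with header ``time_ms,V_mV`` or ``time_ms,V_mV,c_mM``, values
printed with 17 significant digits so a write/read round trip is lossless.
An optional JSON sidecar (``<name>.meta.json``) carries provenance: units,
sampling mode, solver tolerances, seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cell_model import Trace
from .errors import TraceFormatError

__all__ = ["read_trace", "write_trace"]

_HEADER2 = "time_ms,V_mV"
_HEADER3 = "time_ms,V_mV,c_mM"


def write_trace(trace: Trace, path: str | Path, *, sidecar: bool = True) -> Path:
    """Write a trace as CSV (17 significant digits); returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    has_ca = trace.calcium is not None
    with open(path, "w") as fh:
        fh.write((_HEADER3 if has_ca else _HEADER2) + "\n")
        for i in range(len(trace)):
            row = f"{trace.time_ms[i]:.17g},{trace.voltage[i]:.17g}"
            if has_ca:
                row += f",{trace.calcium[i]:.17g}"
            fh.write(row + "\n")
    if sidecar and trace.metadata:
        meta = {
            k: v for k, v in trace.metadata.items() if not isinstance(v, np.ndarray)
        }
        sidecar_path = path.with_suffix(path.suffix + ".meta.json")
        sidecar_path.write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_trace(path: str | Path) -> Trace:
    """Read a trace CSV; errors name the offending line (1-based)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TraceFormatError("empty trace file", line=1)
    header = lines[0].strip()
    if header == _HEADER3:
        ncol, has_ca = 3, True
    elif header == _HEADER2:
        ncol, has_ca = 2, False
    else:
        raise TraceFormatError(
            f"unrecognised header {header!r}; expected {_HEADER2!r} or {_HEADER3!r}",
            line=1,
        )
    t, v, c = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != ncol:
            raise TraceFormatError(
                f"expected {ncol} columns, found {len(parts)}", line=lineno
            )
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            raise TraceFormatError(f"non-numeric value in row", line=lineno) from None
        t.append(vals[0])
        v.append(vals[1])
        if has_ca:
            c.append(vals[2])
    ta = np.asarray(t)
    if ta.size >= 2:
        bad = np.flatnonzero(np.diff(ta) <= 0)
        if bad.size:
            raise TraceFormatError(
                "time not strictly increasing", line=int(bad[0]) + 3
            )
    metadata: dict = {}
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    if sidecar_path.exists():
        metadata = json.loads(sidecar_path.read_text())
    return Trace(
        time_ms=ta,
        voltage=np.asarray(v),
        calcium=np.asarray(c) if has_ca else None,
        metadata=metadata,
    )
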