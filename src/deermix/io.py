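"""Two-column ASCII trace files.

Format: '#'-prefixed header lines carrying ``key = value`` metadata,
followed by whitespace-separated rows of time (us) and echo amplitude.
``noise_sd`` in the header populates the trace's noise level; all other
keys land in ``trace.meta``.  Values round-trip at full double precision.
"""

from __future__ import annotations

import numpy as np

from .forward import DeerTrace

__all__ = ["TraceParseError", "read_trace", "write_trace"]


class TraceParseError(ValueError):
    """Malformed trace file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_trace(trace: DeerTrace, path) -> None:
    if isinstance(trace.noise_sd, np.ndarray):
        raise ValueError("only scalar noise_sd is supported by the ASCII format")
    with open(path, "w") as fh:
        fh.write("# deermix trace v1\n")
        if trace.noise_sd is not None:
            fh.write(f"# noise_sd = {trace.noise_sd!r}\n")
        for key, value in sorted(trace.meta.items()):
            fh.write(f"# {key} = {value!r}\n")
        for t, v in zip(trace.times, trace.signal):
            fh.write(f"{t:.17e} {v:.17e}\n")


def _parse_meta_value(text: str):
    text = text.strip().strip("'\"")
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    return text


def read_trace(path) -> DeerTrace:
    times, signal = [], []
    meta: dict = {}
    noise_sd = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    key = key.strip()
                    if key == "noise_sd":
                        noise_sd = float(_parse_meta_value(value))
                    elif key:
                        meta[key] = _parse_meta_value(value)
                continue
            parts = line.split()
            if len(parts) != 2:
                raise TraceParseError(f"expected two columns, got {len(parts)}", lineno)
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError:
                raise TraceParseError(f"non-numeric row {line!r}", lineno) from None
            if times and t <= times[-1]:
                raise TraceParseError(
                    f"time {t!r} does not increase past {times[-1]!r}", lineno
                )
            times.append(t)
            signal.append(v)
    if not times:
        raise TraceParseError("no data rows", 0)
    return DeerTrace(np.array(times), np.array(signal), noise_sd=noise_sd, meta=meta)
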