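"""Flat key=value text serialization with embedded CSV array blocks.

The format is deliberately trivial so that serialized models and surfaces
survive version-control diffs and can be inspected by eye:

    # comment
    key = value
    @array name rows cols
    1.0,2.0
    3.0,4.0
    @end

Floats are written with ``repr`` so the round-trip is bit exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dumps", "loads"]


def _fmt_scalar(v) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def dumps(scalars: dict, arrays: dict | None = None, header: str = "krigdoe/v1") -> str:
    lines = [f"# {header}"]
    for key, value in scalars.items():
        if isinstance(value, (list, tuple)):
            lines.append(f"{key} = {','.join(_fmt_scalar(v) for v in value)}")
        else:
            lines.append(f"{key} = {_fmt_scalar(value)}")
    for name, arr in (arrays or {}).items():
        a = np.atleast_2d(np.asarray(arr, dtype=float))
        lines.append(f"@array {name} {a.shape[0]} {a.shape[1]}")
        for row in a:
            lines.append(",".join(repr(float(x)) for x in row))
        lines.append("@end")
    return "\n".join(lines) + "\n"


def loads(text: str) -> tuple[dict, dict]:
    """Parse flat text; returns (scalars, arrays). Scalars stay strings."""
    scalars: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if line.startswith("@array"):
            _, name, nr, nc = line.split()
            nr, nc = int(nr), int(nc)
            rows = []
            while i < len(lines) and lines[i].strip() != "@end":
                rows.append([float(x) for x in lines[i].split(",")])
                i += 1
            i += 1  # skip @end
            arr = np.array(rows, dtype=float).reshape(nr, nc) if rows else np.zeros((nr, nc))
            arrays[name] = arr
        elif "=" in line:
            key, _, value = line.partition("=")
            scalars[key.strip()] = value.strip()
    return scalars, arrays


def parse_list(s: str) -> list[str]:
    return [t.strip() for t in s.split(",")] if s else []


def parse_floats(s: str) -> list[float]:
    return [float(t) for t in parse_list(s)]
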