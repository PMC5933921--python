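"""Minimal TOML emission for network specifications and presets.

Reading goes through the standard-library ``tomllib``; writing covers the
small value domain these documents need (tables, arrays of tables, strings,
bools, ints, floats, flat lists).
"""

from __future__ import annotations

import math

__all__ = ["dumps_toml"]


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v) or math.isinf(v):
            raise ValueError("TOML cannot represent non-finite floats")
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt_value(x) for x in v) + "]"
    raise TypeError(f"unsupported TOML value type {type(v).__name__}")


def dumps_toml(doc: dict) -> str:
    """Serialize a dict to TOML text.

    Top-level scalars first, then sub-tables (``[name]``) and lists of dicts
    as arrays of tables (``[[name]]``).
    """
    lines = []
    tables = []
    for key, val in doc.items():
        if isinstance(val, dict):
            tables.append((key, [val], True))
        elif (isinstance(val, list) and val
              and all(isinstance(x, dict) for x in val)):
            tables.append((key, val, False))
        else:
            lines.append(f"{key} = {_fmt_value(val)}")
    for key, items, single in tables:
        for item in items:
            lines.append("")
            lines.append(f"[{key}]" if single else f"[[{key}]]")
            for k, v in item.items():
                lines.append(f"{k} = {_fmt_value(v)}")
    return "\n".join(lines) + "\n"
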