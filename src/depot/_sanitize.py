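"""Mapping of arbitrary attribute values to safe path components.

Values are kept verbatim wherever possible (``left_DL`` stays ``left_DL``);
path separators, control characters and other reserved characters become
``_``.  Because that replacement can merge distinct values, a set-aware
variant appends an 8-hex digest of the original value to altered values
that would otherwise coincide, keeping the mapping injective over any
given sibling set.
"""

from __future__ import annotations

import hashlib
import re

_SAFE_RE = re.compile(r"[^A-Za-z0-9._+=@,()\[\]{}' -]")
_EMPTY = "_EMPTY_"


def _suffix(value: str) -> str:
    return hashlib.sha256(value.encode()).hexdigest()[:8]


def sanitize_component(value: str) -> str:
    """Deterministic path-safe form of one value (no set context)."""
    if value == "":
        return _EMPTY
    out = _SAFE_RE.sub("_", value)
    out = out.strip()
    if out in ("", ".", ".."):
        return _EMPTY if not out else "_" * len(out) + "_"
    return out


def sanitize_components(values: set[str] | list[str]) -> dict[str, str]:
    """Sanitize a sibling set injectively.

    A value whose sanitized form required no change keeps it; an altered
    value whose sanitized form collides with any other member of the set
    gets ``_<8hex-of-original>`` appended.  The result is independent of
    iteration order.
    """
    uniq = set(values)
    plain = {v: sanitize_component(v) for v in uniq}
    counts: dict[str, int] = {}
    for s in plain.values():
        counts[s] = counts.get(s, 0) + 1
    out = {}
    for v, s in plain.items():
        if counts[s] > 1 and s != v:
            out[v] = f"{s}_{_suffix(v)}"
        else:
            out[v] = s
    return out
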