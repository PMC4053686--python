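"""Content addressing of data units.

A data unit is a named, ordered set of immutable files.  Its identity is a
pure function of content: each member file is hashed with SHA-256, then the
unit id is the SHA-256 of the concatenation of one line per member of the
form ``name + NUL + file_hex + newline``, with lines sorted bytewise by the
member name.  Sorting makes the id invariant to the order in which members
are presented; the NUL separator keeps names and digests unambiguous.
"""

from __future__ import annotations

import hashlib
import os
from typing import Iterable, Sequence

from .errors import ValidationError

_CHUNK = 1 << 20


def file_digest(path: str | os.PathLike) -> str:
    """SHA-256 hex digest of a file's bytes, streamed."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        while chunk := fh.read(_CHUNK):
            h.update(chunk)
    return h.hexdigest()


def bytes_digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _check_names(names: Sequence[str]) -> None:
    if not names:
        raise ValidationError("a data unit needs at least one member file")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate member names in unit: {dupes}")


def unit_id_from_digests(named_digests: Iterable[tuple[str, str]]) -> str:
    """Combine per-file digests into the unit id.

    ``named_digests`` is an iterable of (relative_name, file_hex) pairs.
    The result is independent of the pair order.
    """
    pairs = list(named_digests)
    _check_names([n for n, _ in pairs])
    h = hashlib.sha256()
    for name, hexd in sorted(pairs, key=lambda p: p[0].encode()):
        h.update(name.encode())
        h.update(b"\x00")
        h.update(hexd.encode())
        h.update(b"\n")
    return h.hexdigest()


def compute_unit_id(members: Iterable[tuple[str, bytes]]) -> str:
    """Unit id for in-memory members given as (name, byte-content) pairs."""
    pairs = list(members)
    return unit_id_from_digests((name, bytes_digest(data)) for name, data in pairs)


def compute_unit_id_from_paths(named_paths: Iterable[tuple[str, str | os.PathLike]]) -> str:
    """Unit id for on-disk members given as (relative_name, path) pairs."""
    return unit_id_from_digests((name, file_digest(p)) for name, p in named_paths)
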