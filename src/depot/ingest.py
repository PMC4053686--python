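"""Floating-folder ingestion: scan, group, assign, and processing hooks.

New files land in a writable *floating* folder (typically populated by a
sync client).  A scan groups stable files into candidate data units using
three rules, applied in priority order:

1. **directory-as-unit** — a first-level subdirectory becomes one
   candidate holding all files beneath it, whatever they are named;
2. **numeric-suffix set** — sibling files sharing a stem and differing
   only in a numeric suffix (``stack_001.tiff`` … ``stack_040.tiff``)
   form one multi-file candidate (the image-stack case);
3. **single-file fallback** — every remaining file is its own candidate.

Assignment ingests a candidate into the flat store, attaches metadata,
removes the originals from the floating folder and journals each step so
that an interrupted assignment can be rolled forward or back by
:func:`recover` — the observable state is always either pre- or
post-assignment, never half-ingested.

Hooks are advisory processing steps plugged into the workflow (e.g.
morphology-summary extraction on every new SWC file).  External hooks
receive a JSON description on stdin and may print a JSON object of extra
attributes, merged under a ``HOOK_<NAME>_`` namespace; crashes and
timeouts are captured and journaled, never propagated.
"""

from __future__ import annotations

import json
import os
import re
import shutil
import subprocess
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .errors import StaleCandidateError, ValidationError
from .hashing import compute_unit_id_from_paths
from .store import DataUnit, Store, normalize_key
from .swc import parse_swc, swc_summary

DEFAULT_SETTLE_SECONDS = 5.0
_NUMERIC_SUFFIX_RE = re.compile(r"^(?P<stem>.+?)[_-](?P<num>\d+)$")
_LOCK_PREFIX = ".assign-"


@dataclass(frozen=True)
class FloatingCandidate:
    """A detected-but-unassigned group of files awaiting metadata."""

    candidate_id: str                   # the unit id the files would receive
    files: tuple[str, ...]              # absolute paths
    names: tuple[str, ...]              # relative names inside the future unit
    grouping_rule_matched: str          # directory | numeric_suffix | single
    floating_root: str
    detected_at: str

    @property
    def n_files(self) -> int:
        return len(self.files)


@dataclass(frozen=True)
class HookSpec:
    """One pluggable processing step.

    ``command`` is either an external executable (string or argv list,
    JSON-over-stdio protocol) or a Python callable taking the payload dict
    and returning an optional dict of extra attributes.  ``suffixes`` and
    ``match_attrs`` restrict which units the hook sees; both empty means
    match everything.  Timeouts apply to external commands.
    """

    name: str
    event: str                          # on_detect | on_assign | on_project
    command: object
    suffixes: tuple[str, ...] = ()
    match_attrs: tuple[tuple[str, str], ...] = ()
    timeout: float = 30.0

    def __post_init__(self):
        if self.event not in ("on_detect", "on_assign", "on_project"):
            raise ValidationError(f"hook {self.name!r}: unknown event {self.event!r}")
        if self.timeout <= 0:
            raise ValidationError(f"hook {self.name!r}: timeout must be positive")

    def matches(self, member_names: Iterable[str], attrs: Mapping[str, str]) -> bool:
        if self.suffixes and not any(
                n.lower().endswith(s.lower()) for n in member_names
                for s in self.suffixes):
            return False
        return all(attrs.get(k) == v for k, v in self.match_attrs)


@dataclass
class HookResult:
    name: str
    status: str                         # ok | error | timeout
    attributes: dict[str, str] = field(default_factory=dict)
    detail: str = ""
    duration: float = 0.0


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _is_hidden(name: str) -> bool:
    return name.startswith(".")


def scan_floating(floating_root: str | os.PathLike,
                  settle_seconds: float = DEFAULT_SETTLE_SECONDS
                  ) -> list[FloatingCandidate]:
    """Group the floating folder's stable files into candidates.

    A file is *stable* once its mtime is at least ``settle_seconds`` old
    (sync clients write incrementally); unstable files are left for the
    next scan.  Hidden entries and assignment locks are ignored.  The
    returned list is sorted by candidate id and disjoint by construction.
    """
    root = Path(floating_root)
    if not root.is_dir():
        raise ValidationError(f"floating root does not exist: {root}")
    cutoff = time.time() - settle_seconds
    candidates: list[FloatingCandidate] = []

    def stable(p: Path) -> bool:
        try:
            return p.stat().st_mtime <= cutoff
        except OSError:
            return False

    top_files: list[Path] = []
    for entry in sorted(root.iterdir()):
        if _is_hidden(entry.name):
            continue
        if entry.is_dir():
            files = sorted(p for p in entry.rglob("*")
                           if p.is_file() and not _is_hidden(p.name))
            if not files or not all(stable(p) for p in files):
                continue
            names = tuple(p.relative_to(entry).as_posix() for p in files)
            cid = compute_unit_id_from_paths(zip(names, files))
            candidates.append(FloatingCandidate(
                cid, tuple(str(p) for p in files), names, "directory",
                str(root), _now()))
        elif entry.is_file() and stable(entry):
            top_files.append(entry)

    groups: dict[tuple[str, str], list[tuple[int, Path]]] = {}
    leftovers: list[Path] = []
    for p in top_files:
        stem, ext = os.path.splitext(p.name)
        m = _NUMERIC_SUFFIX_RE.match(stem)
        if m:
            groups.setdefault((m.group("stem"), ext), []).append(
                (int(m.group("num")), p))
        else:
            leftovers.append(p)
    for (_stem, _ext), numbered in sorted(groups.items()):
        if len(numbered) < 2:
            leftovers.extend(p for _, p in numbered)
            continue
        files = [p for _, p in sorted(numbered)]
        names = tuple(p.name for p in files)
        cid = compute_unit_id_from_paths(zip(names, files))
        candidates.append(FloatingCandidate(
            cid, tuple(str(p) for p in files), names, "numeric_suffix",
            str(root), _now()))
    for p in sorted(leftovers):
        cid = compute_unit_id_from_paths([(p.name, p)])
        candidates.append(FloatingCandidate(
            cid, (str(p),), (p.name,), "single", str(root), _now()))

    candidates.sort(key=lambda c: c.candidate_id)
    return candidates


class _AssignLock:
    """O_EXCL lock file fencing concurrent assignment of one candidate."""

    def __init__(self, floating_root: str, candidate_id: str):
        self.path = Path(floating_root) / f"{_LOCK_PREFIX}{candidate_id[:16]}.lock"

    def __enter__(self):
        try:
            fd = os.open(self.path, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
            os.close(fd)
        except FileExistsError:
            raise StaleCandidateError(
                f"candidate {self.path.name} is being assigned by another process")
        return self

    def __exit__(self, *exc):
        try:
            self.path.unlink()
        except OSError:
            pass
        return False


def assign_candidate(store: Store, candidate: FloatingCandidate,
                     attributes: Mapping[str, object],
                     hooks: Sequence[HookSpec] = (),
                     crash_hook: Callable[[str], None] | None = None
                     ) -> DataUnit:
    """Ingest a candidate, attach metadata, clear the floating files.

    Revalidates the candidate first (files present and byte-identical to
    the scan, else :class:`StaleCandidateError`), then performs the
    journaled sequence ingest → assign → delete originals → commit.  After
    an interruption :func:`recover` restores either the pre- or the
    post-assignment state from the journal.  ``on_assign`` hooks run after
    commit; their failures are journaled, never raised.

    ``crash_hook`` is a fault-injection seam called at each step boundary;
    production callers leave it None.
    """
    crash = crash_hook or (lambda tag: None)
    paths = [Path(f) for f in candidate.files]

    with _AssignLock(candidate.floating_root, candidate.candidate_id):
        if not all(p.is_file() for p in paths):
            raise StaleCandidateError("candidate files vanished; rescan required")
        current_id = compute_unit_id_from_paths(zip(candidate.names, paths))
        if current_id != candidate.candidate_id:
            raise StaleCandidateError(
                "candidate files changed since scan; rescan required")
        store.journal.append("assign_begin", candidate.candidate_id, {
            "files": list(candidate.files),
            "names": list(candidate.names),
            "attributes": {str(k): str(v) for k, v in attributes.items()},
        })
        crash("after_begin")
        unit = store.ingest_unit(candidate.files, names=candidate.names)
        crash("after_ingest")
        store.assign_metadata(unit.unit_id, attributes)
        crash("after_metadata")
        for i, p in enumerate(paths):
            p.unlink(missing_ok=True)
            crash(f"mid_delete_{i}")
        _cleanup_dirs(candidate)
        crash("after_delete")
        store.journal.append("assign_commit", unit.unit_id,
                             {"candidate_id": candidate.candidate_id})

    results = run_hooks(store, "on_assign", unit.unit_id, hooks)
    for r in results:
        if r.status != "ok":
            store.journal.append("hook_failure", unit.unit_id,
                                 {"hook": r.name, "status": r.status,
                                  "detail": r.detail})
    return store.get_unit(unit.unit_id)


def _cleanup_dirs(candidate: FloatingCandidate) -> None:
    """Remove now-empty subdirectories of a directory-as-unit candidate."""
    if candidate.grouping_rule_matched != "directory":
        return
    root = Path(candidate.floating_root)
    dirs = {Path(f).parent for f in candidate.files}
    for d in sorted(dirs, key=lambda p: len(p.parts), reverse=True):
        while d != root and d.is_dir() and not any(d.iterdir()):
            d.rmdir()
            d = d.parent


def recover(store: Store, floating_root: str | os.PathLike | None = None) -> dict:
    """Replay the journal after a crash; return a summary of actions.

    Every ``assign_begin`` without a matching ``assign_commit`` is either
    rolled forward (the unit reached the database: finish deleting its
    floating originals and commit) or rolled back (it did not: drop any
    half-placed store directory, leaving the floating files untouched).
    Stale temp directories and lock files are always swept.
    """
    summary = {"rolled_forward": [], "rolled_back": [], "swept": 0}
    events, _ = store.journal.read()
    begun: dict[str, dict] = {}
    for ev in events:
        if ev.action == "assign_begin":
            begun[ev.unit_id] = ev.payload
        elif ev.action == "assign_commit":
            begun.pop(ev.payload.get("candidate_id", ev.unit_id), None)
        elif ev.action == "assign_abort":
            begun.pop(ev.unit_id, None)

    for cid, payload in begun.items():
        unit = store.get_unit(cid, missing_ok=True)
        if unit is not None:
            if payload.get("attributes"):
                store.assign_metadata(cid, payload["attributes"])
            for f in payload.get("files", []):
                Path(f).unlink(missing_ok=True)
            store.journal.append("assign_commit", cid,
                                 {"candidate_id": cid, "recovered": True})
            summary["rolled_forward"].append(cid)
        else:
            udir = store.store_root / cid
            if udir.exists():
                shutil.rmtree(udir)
            store.journal.append("assign_abort", cid, {"recovered": True})
            summary["rolled_back"].append(cid)

    for tmp in store.store_root.glob(".tmp-*"):
        shutil.rmtree(tmp, ignore_errors=True)
        summary["swept"] += 1
    if floating_root:
        root = Path(floating_root)
        for lock in root.glob(f"{_LOCK_PREFIX}*.lock"):
            lock.unlink(missing_ok=True)
            summary["swept"] += 1
        if summary["rolled_forward"]:
            for d in sorted((p for p in root.rglob("*") if p.is_dir()),
                            key=lambda p: len(p.parts), reverse=True):
                if not any(d.iterdir()):
                    d.rmdir()
    return summary


# -- hooks ---------------------------------------------------------------

def builtin_swc_hook(payload: dict) -> dict:
    """Morphology-summary extraction for every ``.swc`` member."""
    out: dict[str, object] = {}
    for path in payload["files"]:
        if path.lower().endswith(".swc"):
            summary = swc_summary(parse_swc(Path(path).read_text()))
            for k, v in summary.items():
                out[k] = round(v, 6) if isinstance(v, float) else v
    return out


BUILTIN_HOOKS: dict[str, Callable[[dict], dict]] = {
    "builtin:swc": builtin_swc_hook,
}


def run_hooks(store: Store, event: str, unit_id: str,
              hooks: Sequence[HookSpec]) -> list[HookResult]:
    """Run every hook matching ``event`` and the unit; merge returned attrs.

    Extra attributes land under ``HOOK_<NAME>_<KEY>`` so hooks can never
    clobber user metadata.  External commands get the JSON payload on
    stdin; timeout or crash yields a captured failure result.
    """
    unit = store.get_unit(unit_id)
    attrs = store.get_attributes(unit_id)
    payload = {
        "event": event,
        "unit_id": unit_id,
        "files": [str(store.member_path(unit_id, m.name)) for m in unit.members],
        "attributes": attrs,
    }
    results: list[HookResult] = []
    for spec in hooks:
        if spec.event != event or not spec.matches(unit.member_names, attrs):
            continue
        start = time.monotonic()
        result = _run_one(spec, payload)
        result.duration = time.monotonic() - start
        if result.status == "ok" and result.attributes:
            ns = normalize_key(spec.name)
            store.assign_metadata(unit_id, {
                f"HOOK_{ns}_{k}": v for k, v in result.attributes.items()})
        store.journal.append("hook", unit_id,
                             {"hook": spec.name, "event": event,
                              "status": result.status,
                              "attributes": result.attributes})
        results.append(result)
    return results


def _run_one(spec: HookSpec, payload: dict) -> HookResult:
    command = spec.command
    if isinstance(command, str) and command in BUILTIN_HOOKS:
        command = BUILTIN_HOOKS[command]
    if callable(command):
        try:
            out = command(payload) or {}
            return HookResult(spec.name, "ok",
                              {str(k): str(v) for k, v in out.items()})
        except Exception as exc:
            return HookResult(spec.name, "error", detail=f"{type(exc).__name__}: {exc}")
    argv = command if isinstance(command, (list, tuple)) else [str(command)]
    try:
        proc = subprocess.run(
            [str(a) for a in argv], input=json.dumps(payload).encode(),
            capture_output=True, timeout=spec.timeout)
    except subprocess.TimeoutExpired:
        return HookResult(spec.name, "timeout",
                          detail=f"killed after {spec.timeout}s")
    except OSError as exc:
        return HookResult(spec.name, "error", detail=str(exc))
    if proc.returncode != 0:
        return HookResult(spec.name, "error",
                          detail=f"exit {proc.returncode}: "
                                 f"{proc.stderr.decode(errors='replace')[:500]}")
    extra: dict[str, str] = {}
    text = proc.stdout.decode(errors="replace").strip()
    if text:
        try:
            obj = json.loads(text)
            if isinstance(obj, dict):
                extra = {str(k): str(v) for k, v in obj.items()}
        except json.JSONDecodeError:
            return HookResult(spec.name, "error",
                              detail=f"hook stdout is not JSON: {text[:200]}")
    return HookResult(spec.name, "ok", extra)
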