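"""Materialized context trees: read-only link hierarchies on disk.

A projection realizes one rule's context tree under a target directory as
links into the flat store — the filesystem analogue of a materialized
database view.  A JSON manifest at ``<target>/.projection.json`` records
every managed entry plus a fingerprint of the inputs, so a refresh on
unchanged inputs is a byte-level no-op and a metadata edit moves exactly
the affected entries.  Unmanaged (foreign) files found in a target are
reported and left alone.

Link modes: ``symlink`` (default), ``hardlink``, ``copy``; on failure the
engine falls through that chain per entry (some filesystems and sync
clients cannot represent symlinks) and records the mode actually used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import stat
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from ._sanitize import sanitize_component, sanitize_components  # noqa: F401  (public surface)
from .context import ContextTree, ContextTreeRule, build_tree
from .errors import ProjectionError, StoreIOError

log = logging.getLogger(__name__)

MANIFEST_NAME = ".projection.json"
_CHAIN = ("symlink", "hardlink", "copy")


@dataclass(frozen=True)
class ManifestEntry:
    path: str        # relative, "/"-separated
    unit_id: str
    member: str
    kind: str        # symlink | hardlink | copy


@dataclass
class ProjectionManifest:
    rule_name: str
    target_root: str
    link_mode: str
    built_at: str
    graph_fingerprint: str
    entries: list[ManifestEntry] = field(default_factory=list)
    # not serialized: what the last apply actually did / noticed
    ops: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def entry_map(self) -> dict[str, ManifestEntry]:
        return {e.path: e for e in self.entries}

    def save(self) -> None:
        doc = {
            "schema_version": 1,
            "rule_name": self.rule_name,
            "link_mode": self.link_mode,
            "built_at": self.built_at,
            "graph_fingerprint": self.graph_fingerprint,
            "entries": [asdict(e) for e in self.entries],
        }
        path = Path(self.target_root) / MANIFEST_NAME
        if path.exists():
            path.chmod(0o644)
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, target_root: str | os.PathLike) -> "ProjectionManifest | None":
        path = Path(target_root) / MANIFEST_NAME
        if not path.exists():
            return None
        doc = json.loads(path.read_text())
        return cls(rule_name=doc["rule_name"], target_root=str(target_root),
                   link_mode=doc.get("link_mode", "symlink"),
                   built_at=doc["built_at"],
                   graph_fingerprint=doc["graph_fingerprint"],
                   entries=[ManifestEntry(**e) for e in doc["entries"]])


def graph_fingerprint(rule: ContextTreeRule, graph) -> str:
    """Hash of everything a projection depends on.

    Covers the rule itself and, for every unit passing the filter, its
    attributes and member names.  Unit ids are content hashes, so content
    changes surface as id changes and are covered implicitly.
    """
    units = {}
    for uid in sorted(graph.query_units(rule.filter_dict)):
        units[uid] = {"attrs": graph.get_attributes(uid),
                      "members": list(graph.get_unit(uid).member_names)}
    doc = {"rule": {"name": rule.name, "filter": list(rule.filter),
                    "grouping": list(rule.grouping),
                    "leaf_template": rule.leaf_template,
                    "on_missing": rule.on_missing,
                    "on_collision": rule.on_collision},
           "units": units}
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def _store_root_of(store) -> Path:
    return Path(getattr(store, "store_root", store))


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _create_link(src: Path, dest: Path, mode: str) -> str:
    """Create one leaf entry, falling back along the link-mode chain."""
    chain = _CHAIN[_CHAIN.index(mode):]
    last_err: OSError | None = None
    for kind in chain:
        try:
            if kind == "symlink":
                os.symlink(os.path.relpath(src, dest.parent), dest)
            elif kind == "hardlink":
                os.link(src, dest)
            else:
                shutil.copy2(src, dest)
            if kind != mode:
                log.warning("link mode %s unavailable for %s; downgraded to %s",
                            mode, dest, kind)
            return kind
        except OSError as exc:
            last_err = exc
    raise StoreIOError(f"cannot create projection entry {dest}: {last_err}")


def _make_tree_writable(target_root: Path) -> None:
    for dirpath, _dirnames, _files in os.walk(target_root):
        mode = os.stat(dirpath).st_mode
        if not mode & stat.S_IWUSR:
            os.chmod(dirpath, mode | stat.S_IWUSR | stat.S_IXUSR)


def _prune_empty_dirs(target_root: Path) -> list[str]:
    removed = []
    for dirpath, _dirnames, _filenames in os.walk(target_root, topdown=False):
        p = Path(dirpath)
        if p == target_root:
            continue
        try:
            if not any(p.iterdir()):
                p.rmdir()
                removed.append(str(p.relative_to(target_root)))
        except OSError:
            pass
    return removed


def _scan_foreign(target_root: Path, managed: set[str]) -> list[str]:
    foreign = []
    for p in target_root.rglob("*"):
        if p.is_dir():
            continue
        rel = p.relative_to(target_root).as_posix()
        if rel != MANIFEST_NAME and rel not in managed:
            foreign.append(rel)
    return sorted(foreign)


def _apply(tree: ContextTree, store, target_root: Path, link_mode: str,
           fingerprint: str, previous: ProjectionManifest | None
           ) -> ProjectionManifest:
    """Diff the desired entry set against the manifest and touch only diffs."""
    store_root = _store_root_of(store)
    desired: dict[str, tuple[str, str]] = {
        lf.relative_path: (lf.unit_id, lf.member_name) for lf in tree.iter_files()}
    current = previous.entry_map() if previous else {}

    manifest = ProjectionManifest(
        rule_name=tree.rule.name, target_root=str(target_root),
        link_mode=link_mode, built_at=_now(), graph_fingerprint=fingerprint)

    mode_changed = previous is not None and previous.link_mode != link_mode
    to_remove = [p for p in current if p not in desired]
    to_keep: dict[str, ManifestEntry] = {}
    to_create: list[str] = []
    for path, (uid, member) in desired.items():
        cur = current.get(path)
        leaf = target_root / path
        if (cur and cur.unit_id == uid and cur.member == member
                and leaf.exists()
                and (not mode_changed or cur.kind == link_mode)):
            to_keep[path] = cur
        else:
            if cur:
                to_remove.append(path)
            to_create.append(path)

    if not to_remove and not to_create and previous is not None:
        # entries untouched; record a fingerprint change if one was computed
        previous.ops = []
        if fingerprint and previous.graph_fingerprint != fingerprint:
            previous.graph_fingerprint = fingerprint
            previous.save()
        previous.warnings = _scan_foreign(target_root, set(current))
        return previous

    target_root.mkdir(parents=True, exist_ok=True)
    _make_tree_writable(target_root)

    for path in to_remove:
        leaf = target_root / path
        if leaf.is_symlink() or leaf.exists():
            if leaf.is_file() and not leaf.is_symlink():
                leaf.chmod(0o644)
            leaf.unlink()
            manifest.ops.append(("unlink", path))
    for path in sorted(to_create):
        uid, member = desired[path]
        src = store_root / uid / member
        if not src.is_file():
            raise StoreIOError(f"store member missing: {src}")
        leaf = target_root / path
        leaf.parent.mkdir(parents=True, exist_ok=True)
        kind = _create_link(src, leaf, link_mode)
        manifest.ops.append(("link", path))
        to_keep[path] = ManifestEntry(path, uid, member, kind)
    for rel in _prune_empty_dirs(target_root):
        manifest.ops.append(("rmdir", rel))

    manifest.entries = sorted(to_keep.values(), key=lambda e: e.path.encode())
    manifest.save()
    manifest.warnings = _scan_foreign(target_root, set(to_keep))
    for w in manifest.warnings:
        log.warning("foreign file in projection %s: %s", target_root, w)
    return manifest


def materialize(tree: ContextTree, store, target_root: str | os.PathLike,
                link_mode: str = "symlink", graph=None) -> ProjectionManifest:
    """Build (or rebuild) the tree under ``target_root``.

    The target must be empty, absent, or owned by a previous manifest of
    the same rule; anything else is refused rather than clobbered.
    ``store`` is a :class:`~depot.store.Store` or a bare store-root path;
    when it (or ``graph``) exposes the metadata view, the manifest gets a
    fingerprint enabling cheap no-op refreshes later.
    """
    if link_mode not in _CHAIN:
        raise ProjectionError(f"unknown link mode {link_mode!r}")
    target_root = Path(target_root)
    previous = ProjectionManifest.load(target_root)
    if previous is None and target_root.exists() and any(target_root.iterdir()):
        raise ProjectionError(
            f"target {target_root} is non-empty and has no manifest; refusing")
    if previous is not None and previous.rule_name != tree.rule.name:
        raise ProjectionError(
            f"target {target_root} belongs to rule {previous.rule_name!r}, "
            f"not {tree.rule.name!r}")
    view = graph if graph is not None else store
    fingerprint = (graph_fingerprint(tree.rule, view)
                   if hasattr(view, "query_units") else "")
    return _apply(tree, store, target_root, link_mode, fingerprint, previous)


def refresh(rule: ContextTreeRule, graph, store, target_root: str | os.PathLike,
            link_mode: str = "symlink") -> ProjectionManifest:
    """Bring the target up to date with minimal filesystem traffic.

    If the fingerprint of (rule, relevant metadata) matches the manifest,
    nothing is touched at all; otherwise only added/removed/moved entries
    are created or unlinked and unchanged leaves keep their mtimes.
    """
    if link_mode not in _CHAIN:
        raise ProjectionError(f"unknown link mode {link_mode!r}")
    target_root = Path(target_root)
    previous = ProjectionManifest.load(target_root)
    if previous is None and target_root.exists() and any(target_root.iterdir()):
        raise ProjectionError(
            f"target {target_root} is non-empty and has no manifest; refusing")
    if previous is not None and previous.rule_name != rule.name:
        raise ProjectionError(
            f"target {target_root} belongs to rule {previous.rule_name!r}, "
            f"not {rule.name!r}")
    fingerprint = graph_fingerprint(rule, graph)
    if (previous is not None and previous.graph_fingerprint == fingerprint
            and previous.link_mode == link_mode):
        previous.ops = []
        previous.warnings = []
        return previous
    tree = build_tree(rule, graph)
    return _apply(tree, store, target_root, link_mode, fingerprint, previous)


def enforce_read_only(target_root: str | os.PathLike) -> None:
    """Best-effort removal of write permission on projected entries.

    Directories become ``r-x``, regular-file leaves ``r--``; symlinks are
    left alone (their permissions are immaterial and chmod would follow
    them into the store).  Privileged processes can still write through
    POSIX bits — :func:`depot.store.Store.verify` remains the safety net.
    """
    target_root = Path(target_root)
    for p in sorted(target_root.rglob("*"), reverse=True):
        try:
            if p.is_symlink():
                continue
            if p.is_dir():
                p.chmod(0o555)
            elif p.name != MANIFEST_NAME:
                p.chmod(0o444)
        except OSError as exc:  # pragma: no cover - unsupported permission model
            log.warning("cannot chmod %s: %s", p, exc)
    try:
        target_root.chmod(0o555)
    except OSError as exc:  # pragma: no cover
        log.warning("cannot chmod %s: %s", target_root, exc)
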