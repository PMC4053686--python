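"""Flat content-addressed store plus the metadata/provenance graph.

The store keeps every data unit in one top-level directory named by its
content hash (``<store>/<unit_id>/<relative_name>``): all organisation
lives in metadata, never in the storage layout.  Metadata are key-value
attributes attached to unit ids, held in an embedded SQLite database next
to the store; provenance edges record which input units and parameters a
process consumed to produce an output unit, and must keep the derivation
graph acyclic.

A unit starts *floating* (present, not yet described) and becomes
*assigned* once metadata are attached; only assigned units are visible to
queries and projections.
"""

from __future__ import annotations

import json
import os
import re
import shutil
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import (CycleError, NotFoundError, StoreIOError, ValidationError)
from .hashing import file_digest, unit_id_from_digests
from .journal import Journal

_KEY_RE = re.compile(r"^[A-Z0-9_]+$")


def normalize_key(key: str) -> str:
    """Normalize an attribute key: uppercase, non-alphanumerics to ``_``.

    Raises :class:`ValidationError` if nothing alphanumeric survives.
    """
    if not isinstance(key, str) or not key.strip():
        raise ValidationError(f"empty attribute key: {key!r}")
    norm = re.sub(r"[^A-Z0-9]", "_", key.strip().upper())
    if not re.search(r"[A-Z0-9]", norm):
        raise ValidationError(f"attribute key has no alphanumeric content: {key!r}")
    return norm


def normalize_attributes(attributes: Mapping[str, object]) -> dict[str, str]:
    """Normalize keys and stringify values; reject empties.

    All offending keys are reported in one error so the caller can fix the
    whole batch at once.
    """
    bad: list[str] = []
    out: dict[str, str] = {}
    for key, value in attributes.items():
        try:
            norm = normalize_key(key)
        except ValidationError:
            bad.append(repr(key))
            continue
        sval = str(value)
        if not sval:
            bad.append(f"{key!r} (empty value)")
            continue
        out[norm] = sval
    if bad:
        raise ValidationError("malformed attribute keys/values: " + ", ".join(bad))
    return out


@dataclass(frozen=True)
class Member:
    name: str
    digest: str
    size: int


@dataclass
class DataUnit:
    unit_id: str
    members: list[Member]
    state: str  # "floating" | "assigned"
    created_at: str

    @property
    def member_names(self) -> list[str]:
        return [m.name for m in self.members]


@dataclass(frozen=True)
class ProvenanceEdge:
    input_ids: frozenset[str]
    process_name: str
    params: dict
    output_id: str
    recorded_at: str


@dataclass(frozen=True)
class Finding:
    kind: str       # corrupted | orphan_dir | dangling_unit | missing_member | extra_file
    subject: str    # unit id or path
    detail: str


@dataclass
class IntegrityReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.findings

    def by_kind(self, kind: str) -> list[Finding]:
        return [f for f in self.findings if f.kind == kind]

    def __str__(self) -> str:
        if self.is_clean:
            return "store OK: no findings"
        lines = [f"{len(self.findings)} finding(s):"]
        lines += [f"  [{f.kind}] {f.subject}: {f.detail}" for f in self.findings]
        return "\n".join(lines)


_SCHEMA = """
CREATE TABLE IF NOT EXISTS units (
    unit_id TEXT PRIMARY KEY,
    state TEXT NOT NULL CHECK (state IN ('floating','assigned')),
    created_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS members (
    unit_id TEXT NOT NULL REFERENCES units(unit_id),
    seq INTEGER NOT NULL,
    name TEXT NOT NULL,
    digest TEXT NOT NULL,
    size INTEGER NOT NULL,
    PRIMARY KEY (unit_id, name)
);
CREATE TABLE IF NOT EXISTS attributes (
    unit_id TEXT NOT NULL REFERENCES units(unit_id),
    key TEXT NOT NULL,
    value TEXT NOT NULL,
    PRIMARY KEY (unit_id, key)
);
CREATE TABLE IF NOT EXISTS prov_edges (
    edge_id INTEGER PRIMARY KEY AUTOINCREMENT,
    process_name TEXT NOT NULL,
    params_json TEXT NOT NULL,
    output_id TEXT NOT NULL REFERENCES units(unit_id),
    recorded_at TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS prov_inputs (
    edge_id INTEGER NOT NULL REFERENCES prov_edges(edge_id),
    input_id TEXT NOT NULL REFERENCES units(unit_id),
    PRIMARY KEY (edge_id, input_id)
);
CREATE INDEX IF NOT EXISTS idx_attr_kv ON attributes (key, value);
"""


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


class Store:
    """A depot project root: flat store + metadata DB + journal.

    Layout under ``root``::

        root/store/<unit_id>/<member files>   flat, one level
        root/depot.sqlite                     metadata + provenance
        root/journal.jsonl                    append-only event log
    """

    DB_NAME = "depot.sqlite"
    JOURNAL_NAME = "journal.jsonl"
    STORE_DIRNAME = "store"

    def __init__(self, root: str | os.PathLike, create: bool = True):
        self.root = Path(root)
        self.store_root = self.root / self.STORE_DIRNAME
        self.db_path = self.root / self.DB_NAME
        if create:
            self.root.mkdir(parents=True, exist_ok=True)
            self.store_root.mkdir(exist_ok=True)
        elif not self.db_path.exists():
            raise NotFoundError(f"no depot at {self.root}")
        self.journal = Journal(self.root / self.JOURNAL_NAME)
        self._conn = sqlite3.connect(self.db_path, check_same_thread=False)
        self._conn.execute("PRAGMA busy_timeout = 10000")
        self._conn.executescript(_SCHEMA)
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- units -----------------------------------------------------------

    def ingest_unit(self, files: Sequence[str | os.PathLike],
                    names: Sequence[str] | None = None,
                    journal_action: str = "ingest") -> DataUnit:
        """Copy ``files`` into the flat store as one unit; dedup by content.

        ``names`` are the relative names inside the unit (default: the file
        basenames).  Re-ingesting identical content returns the existing
        unit without touching the store.  A failed copy is rolled back.
        """
        paths = [Path(p) for p in files]
        if names is None:
            names = [p.name for p in paths]
        if len(names) != len(paths):
            raise ValidationError("names and files length mismatch")
        for p in paths:
            if not p.is_file():
                raise StoreIOError(f"not a readable file: {p}")
        digests = [file_digest(p) for p in paths]
        sizes = [p.stat().st_size for p in paths]
        unit_id = unit_id_from_digests(zip(names, digests))

        existing = self.get_unit(unit_id, missing_ok=True)
        if existing is not None:
            return existing

        self._stage_into_store(unit_id, list(zip(names, paths)))
        self._insert_unit(unit_id, list(zip(names, digests, sizes)))
        self.journal.append(journal_action, unit_id,
                            {"members": list(names), "n_files": len(names)})
        return self.get_unit(unit_id)

    def _stage_into_store(self, unit_id: str,
                          named_paths: list[tuple[str, Path]]) -> None:
        """Copy files to a temp dir, then atomically rename into place."""
        final = self.store_root / unit_id
        if final.exists():
            return
        tmp = self.store_root / f".tmp-{unit_id[:12]}-{os.getpid()}"
        try:
            tmp.mkdir(parents=True)
            for name, src in named_paths:
                dest = tmp / name
                dest.parent.mkdir(parents=True, exist_ok=True)
                shutil.copy2(src, dest)
            os.replace(tmp, final)
        except OSError as exc:
            shutil.rmtree(tmp, ignore_errors=True)
            raise StoreIOError(f"ingest of {unit_id[:12]} failed: {exc}") from exc

    def _insert_unit(self, unit_id: str,
                     rows: list[tuple[str, str, int]]) -> None:
        with self._conn:
            self._conn.execute(
                "INSERT OR IGNORE INTO units (unit_id, state, created_at) VALUES (?,?,?)",
                (unit_id, "floating", _now()))
            self._conn.executemany(
                "INSERT OR IGNORE INTO members (unit_id, seq, name, digest, size)"
                " VALUES (?,?,?,?,?)",
                [(unit_id, i, n, d, s) for i, (n, d, s) in enumerate(rows)])

    def get_unit(self, unit_id: str, missing_ok: bool = False) -> DataUnit | None:
        row = self._conn.execute(
            "SELECT state, created_at FROM units WHERE unit_id = ?",
            (unit_id,)).fetchone()
        if row is None:
            if missing_ok:
                return None
            raise NotFoundError(f"unknown unit: {unit_id}")
        members = [Member(n, d, s) for n, d, s in self._conn.execute(
            "SELECT name, digest, size FROM members WHERE unit_id = ? ORDER BY seq",
            (unit_id,))]
        return DataUnit(unit_id=unit_id, members=members,
                        state=row[0], created_at=row[1])

    def unit_ids(self, state: str | None = None) -> list[str]:
        if state is None:
            rows = self._conn.execute("SELECT unit_id FROM units ORDER BY unit_id")
        else:
            rows = self._conn.execute(
                "SELECT unit_id FROM units WHERE state = ? ORDER BY unit_id", (state,))
        return [r[0] for r in rows]

    def unit_dir(self, unit_id: str) -> Path:
        return self.store_root / unit_id

    def member_path(self, unit_id: str, member_name: str) -> Path:
        return self.store_root / unit_id / member_name

    # -- attributes ------------------------------------------------------

    def assign_metadata(self, unit_id: str,
                        attributes: Mapping[str, object]) -> dict[str, str]:
        """Upsert attributes on a unit and mark it assigned.

        Returns the normalized attribute map now on the unit.  An empty map
        is rejected: assignment means the unit is described by something.
        """
        self.get_unit(unit_id)  # raises NotFoundError
        if not attributes:
            raise ValidationError("cannot assign an empty attribute map")
        norm = normalize_attributes(attributes)
        changes = self._upsert_attributes(unit_id, norm)
        with self._conn:
            self._conn.execute(
                "UPDATE units SET state = 'assigned' WHERE unit_id = ?", (unit_id,))
        self.journal.append("assign", unit_id, {"attributes": norm, "changes": changes})
        return self.get_attributes(unit_id)

    def _upsert_attributes(self, unit_id: str,
                           norm: dict[str, str]) -> dict[str, list]:
        old = self.get_attributes(unit_id)
        changes = {k: [old.get(k), v] for k, v in norm.items() if old.get(k) != v}
        with self._conn:
            self._conn.executemany(
                "INSERT INTO attributes (unit_id, key, value) VALUES (?,?,?) "
                "ON CONFLICT(unit_id, key) DO UPDATE SET value = excluded.value",
                [(unit_id, k, v) for k, v in norm.items()])
        return changes

    def get_attributes(self, unit_id: str) -> dict[str, str]:
        return dict(self._conn.execute(
            "SELECT key, value FROM attributes WHERE unit_id = ? ORDER BY key",
            (unit_id,)))

    def attribute_records(self) -> list[tuple[str, str, str]]:
        """All (unit_id, key, value) rows — the raw metadata graph."""
        return list(self._conn.execute(
            "SELECT unit_id, key, value FROM attributes ORDER BY unit_id, key"))

    def query_units(self, filter: Mapping[str, str] | Iterable[tuple[str, str]] | None = None
                    ) -> set[str]:
        """Assigned units matching every ``key=value`` term (conjunction).

        An empty/None filter returns all assigned units.  Unknown keys match
        nothing.  Duplicate contradictory terms (K=a and K=b) therefore
        yield the empty set, attributes being single-valued.
        """
        terms = list(filter.items()) if isinstance(filter, Mapping) else list(filter or [])
        result = set(self.unit_ids(state="assigned"))
        for key, value in terms:
            key = normalize_key(key)
            hits = {r[0] for r in self._conn.execute(
                "SELECT unit_id FROM attributes WHERE key = ? AND value = ?",
                (key, str(value)))}
            result &= hits
        return result

    # -- provenance ------------------------------------------------------

    def record_provenance(self, input_ids: Iterable[str], process_name: str,
                          params: Mapping[str, object], output_id: str) -> ProvenanceEdge:
        """Record that ``process_name(params)`` turned inputs into output.

        The parameters are also materialized as attributes on the output
        unit, prefixed with the normalized process name (e.g. process
        ``SIGEN`` with param ``PARAMETERS`` becomes ``SIGEN_PARAMETERS``),
        so they can serve as grouping attributes.
        """
        inputs = sorted(set(input_ids))
        if not inputs:
            raise ValidationError("provenance edge needs at least one input")
        for uid in inputs + [output_id]:
            self.get_unit(uid)
        if output_id in inputs:
            raise CycleError(f"unit {output_id[:12]} cannot be its own input",
                             path=[output_id, output_id])
        graph = self.provenance_graph()
        graph.add_node(output_id)
        for uid in inputs:
            graph.add_edge(uid, output_id)
        try:
            cyc = nx.find_cycle(graph, source=output_id)
        except nx.NetworkXNoCycle:
            cyc = None
        if cyc:
            path = [e[0] for e in cyc] + [cyc[-1][1]]
            raise CycleError("provenance edge would create a cycle: "
                             + " -> ".join(p[:12] for p in path), path=path)

        recorded_at = _now()
        params_norm = normalize_attributes(params) if params else {}
        with self._conn:
            cur = self._conn.execute(
                "INSERT INTO prov_edges (process_name, params_json, output_id, recorded_at)"
                " VALUES (?,?,?,?)",
                (process_name, json.dumps(params_norm, sort_keys=True),
                 output_id, recorded_at))
            edge_id = cur.lastrowid
            self._conn.executemany(
                "INSERT INTO prov_inputs (edge_id, input_id) VALUES (?,?)",
                [(edge_id, uid) for uid in inputs])
        if params_norm:
            proc = normalize_key(process_name)
            self._upsert_attributes(
                output_id, {f"{proc}_{k}": v for k, v in params_norm.items()})
        self.journal.append("provenance", output_id,
                            {"process": process_name, "inputs": inputs,
                             "params": params_norm})
        return ProvenanceEdge(frozenset(inputs), process_name, params_norm,
                              output_id, recorded_at)

    def provenance_edges(self) -> list[ProvenanceEdge]:
        edges = []
        for edge_id, proc, pj, out, ts in self._conn.execute(
                "SELECT edge_id, process_name, params_json, output_id, recorded_at"
                " FROM prov_edges ORDER BY edge_id"):
            ins = frozenset(r[0] for r in self._conn.execute(
                "SELECT input_id FROM prov_inputs WHERE edge_id = ?", (edge_id,)))
            edges.append(ProvenanceEdge(ins, proc, json.loads(pj), out, ts))
        return edges

    def provenance_graph(self) -> nx.DiGraph:
        """Directed graph over unit ids: input -> output per recorded edge."""
        g = nx.DiGraph()
        g.add_nodes_from(self.unit_ids())
        for edge in self.provenance_edges():
            for uid in edge.input_ids:
                g.add_edge(uid, edge.output_id, process=edge.process_name)
        return g

    def ancestors(self, unit_id: str) -> set[str]:
        self.get_unit(unit_id)
        return set(nx.ancestors(self.provenance_graph(), unit_id))

    # -- integrity -------------------------------------------------------

    def verify(self) -> IntegrityReport:
        """Recompute every stored digest and cross-check store vs metadata.

        Problems are report entries, never exceptions: corrupted members,
        store directories with no metadata row (orphans), metadata rows
        whose store directory is gone (dangling), members missing on disk,
        and unexpected extra files inside a unit directory.
        """
        report = IntegrityReport()
        known = set(self.unit_ids())
        on_disk = {p.name for p in self.store_root.iterdir()
                   if p.is_dir() and not p.name.startswith(".tmp-")}
        for name in sorted(on_disk - known):
            report.findings.append(Finding(
                "orphan_dir", name, "store directory has no metadata record"))
        for uid in sorted(known - on_disk):
            report.findings.append(Finding(
                "dangling_unit", uid, "metadata references a missing store directory"))
        for uid in sorted(known & on_disk):
            unit = self.get_unit(uid)
            udir = self.store_root / uid
            expected = set()
            for m in unit.members:
                expected.add(m.name)
                path = udir / m.name
                if not path.is_file():
                    report.findings.append(Finding(
                        "missing_member", uid, f"member {m.name!r} missing on disk"))
                    continue
                if file_digest(path) != m.digest:
                    report.findings.append(Finding(
                        "corrupted", uid, f"member {m.name!r} digest mismatch"))
            actual = {str(p.relative_to(udir)) for p in udir.rglob("*") if p.is_file()}
            for extra in sorted(actual - expected):
                report.findings.append(Finding(
                    "extra_file", uid, f"unexpected file {extra!r} in unit directory"))
            intact = all((udir / m.name).is_file() for m in unit.members)
            if intact:
                recomputed = unit_id_from_digests(
                    (m.name, file_digest(udir / m.name)) for m in unit.members)
                if recomputed != uid and not any(
                        f.subject == uid and f.kind == "corrupted"
                        for f in report.findings):
                    report.findings.append(Finding(
                        "corrupted", uid, "recomputed unit id mismatch"))
        self.journal.append("verify", None,
                            {"findings": len(report.findings)})
        return report
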