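"""Context trees: rule-driven hierarchical views over the flat store.

A *context path* is the ordered list of attribute values that places one
data unit inside a chosen hierarchy: the rule picks a subset of units with
an equality filter (e.g. ``FORMAT=SWC``), orders a list of grouping
attributes (e.g. ``LABOR_STATE, REGION, HONEYBEE_ID, SIGEN_PARAMETERS``),
and names the leaf with a template.  Arranging all selected units by their
context paths yields the *context tree* — nodes are attribute values,
leaves are data units.  Permuting the grouping list permutes the path
segments identically, which is how the same data serve different analyses.

Rules are declarative YAML, so users reshape their views without touching
code.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import yaml

from ._sanitize import sanitize_component, sanitize_components
from .errors import (CollisionError, MissingAttributeError,
                     RuleConfigError, RuleNotApplicableError)
from .store import normalize_key

UNASSIGNED_BUCKET = "UNASSIGNED"
_PLACEHOLDER_RE = re.compile(r"\{([A-Z0-9_]+)\}")

ON_MISSING = ("fail", "skip", "unassigned")
ON_COLLISION = ("fail", "suffix")


@dataclass(frozen=True)
class ContextTreeRule:
    """One named view of the project.

    ``filter`` is a conjunction of attribute equality terms; ``grouping``
    the ordered attribute keys that become directory levels; the
    ``leaf_template`` may reference attribute keys plus the specials
    ``{MEMBER_NAME}`` (render one leaf per member file) and ``{UNIT_ID8}``
    (first 8 hex of the unit id).
    """

    name: str
    filter: tuple[tuple[str, str], ...] = ()
    grouping: tuple[str, ...] = ()
    leaf_template: str = "{MEMBER_NAME}"
    on_missing: str = "unassigned"
    on_collision: str = "fail"

    def __post_init__(self):
        groups = [normalize_key(k) for k in self.grouping]
        object.__setattr__(self, "grouping", tuple(groups))
        object.__setattr__(self, "filter",
                           tuple((normalize_key(k), str(v)) for k, v in self.filter))
        if len(set(self.grouping)) != len(self.grouping):
            raise RuleConfigError(f"rule {self.name!r}: repeated grouping key",
                                  field_path=f"rules.{self.name}.grouping")
        fixed = {k for k, _ in self.filter}
        overlap = fixed & set(self.grouping)
        if overlap:
            raise RuleConfigError(
                f"rule {self.name!r}: keys {sorted(overlap)} appear in both "
                f"filter and grouping", field_path=f"rules.{self.name}.grouping")
        if self.on_missing not in ON_MISSING:
            raise RuleConfigError(f"rule {self.name!r}: on_missing must be one of "
                                  f"{ON_MISSING}", field_path=f"rules.{self.name}.on_missing")
        if self.on_collision not in ON_COLLISION:
            raise RuleConfigError(f"rule {self.name!r}: on_collision must be one of "
                                  f"{ON_COLLISION}", field_path=f"rules.{self.name}.on_collision")

    @property
    def filter_dict(self) -> dict[str, str]:
        return dict(self.filter)

    @classmethod
    def make(cls, name: str, filter: Mapping[str, str] | None = None,
             grouping: Iterable[str] = (), leaf_template: str = "{MEMBER_NAME}",
             on_missing: str = "unassigned", on_collision: str = "fail") -> "ContextTreeRule":
        return cls(name=name, filter=tuple((filter or {}).items()),
                   grouping=tuple(grouping), leaf_template=leaf_template,
                   on_missing=on_missing, on_collision=on_collision)


@dataclass(frozen=True)
class ContextPath:
    """Where one unit sits in one rule's hierarchy."""

    segments: tuple[str, ...]
    leaf_name: str      # may still contain {MEMBER_NAME}
    unit_id: str

    def as_posix(self) -> str:
        return "/".join(self.segments + (self.leaf_name,))


@dataclass(frozen=True)
class LeafFile:
    """One projected file: segments + leaf-relative path -> (unit, member)."""

    segments: tuple[str, ...]
    leaf_path: str          # filename, or "leafdir/member" for multi-file leaf dirs
    unit_id: str
    member_name: str

    @property
    def relative_path(self) -> str:
        return "/".join(self.segments + (self.leaf_path,))


def _matches(attrs: Mapping[str, str], filter_terms: Iterable[tuple[str, str]]) -> bool:
    return all(attrs.get(k) == v for k, v in filter_terms)


def _render_template(template: str, attrs: Mapping[str, str], unit_id: str,
                     rule: ContextTreeRule) -> str:
    """Substitute {KEY} and {UNIT_ID8}; leave {MEMBER_NAME} for expansion."""
    def sub(m: re.Match) -> str:
        key = m.group(1)
        if key == "MEMBER_NAME":
            return m.group(0)
        if key == "UNIT_ID8":
            return unit_id[:8]
        if key in attrs:
            return sanitize_component(attrs[key])
        if rule.on_missing == "unassigned":
            warnings.warn(f"unit {unit_id[:12]}: attribute {key} missing in "
                          f"leaf template of rule {rule.name!r}; using "
                          f"{UNASSIGNED_BUCKET}", stacklevel=4)
            return UNASSIGNED_BUCKET
        raise MissingAttributeError(
            f"unit {unit_id[:12]} lacks attribute {key} used by leaf template "
            f"of rule {rule.name!r}")
    return _PLACEHOLDER_RE.sub(sub, template)


def context_path(unit_id: str, rule: ContextTreeRule, graph) -> ContextPath:
    """Compute the unit's path under ``rule``.

    ``graph`` is any object exposing ``get_attributes(unit_id)`` (the
    metadata view); :class:`~depot.store.Store` qualifies.  Raises
    :class:`RuleNotApplicableError` when the filter does not match and
    :class:`MissingAttributeError` for absent grouping attributes under the
    ``fail``/``skip`` policies; the default policy buckets them under
    ``UNASSIGNED`` with a warning.
    """
    attrs = graph.get_attributes(unit_id)
    if not _matches(attrs, rule.filter):
        raise RuleNotApplicableError(
            f"unit {unit_id[:12]} does not match filter of rule {rule.name!r}")
    segments: list[str] = []
    for key in rule.grouping:
        if key in attrs:
            segments.append(sanitize_component(attrs[key]))
        elif rule.on_missing == "unassigned":
            warnings.warn(f"unit {unit_id[:12]}: grouping attribute {key} "
                          f"missing; bucketed under {UNASSIGNED_BUCKET}",
                          stacklevel=2)
            segments.append(UNASSIGNED_BUCKET)
        else:
            raise MissingAttributeError(
                f"unit {unit_id[:12]} lacks grouping attribute {key} "
                f"of rule {rule.name!r}")
    leaf = _render_template(rule.leaf_template, attrs, unit_id, rule)
    return ContextPath(tuple(segments), leaf, unit_id)


def _leaf_keys(path: ContextPath, member_names: list[str]
               ) -> set[tuple[tuple[str, ...], str]]:
    """The (segments, leaf_name) identities a unit occupies under a rule."""
    if "{MEMBER_NAME}" in path.leaf_name:
        return {(path.segments, path.leaf_name.replace("{MEMBER_NAME}", m))
                for m in member_names}
    return {(path.segments, path.leaf_name)}


def _selected_paths(rule: ContextTreeRule, graph
                    ) -> tuple[dict[str, ContextPath], list[str]]:
    """Context paths for every unit passing the filter; skipped ids second."""
    paths: dict[str, ContextPath] = {}
    skipped: list[str] = []
    for uid in sorted(graph.query_units(rule.filter_dict)):
        try:
            paths[uid] = context_path(uid, rule, graph)
        except MissingAttributeError:
            if rule.on_missing == "skip":
                skipped.append(uid)
            else:
                raise
    return paths, skipped


def validate_uniqueness(rule: ContextTreeRule, graph) -> list[list[str]]:
    """Collision groups: units mapping to an identical (segments, leaf name).

    Leaf names are expanded per member when the template contains
    ``{MEMBER_NAME}``, so two units collide exactly when they would fight
    over at least one projected file path.  Empty list iff the rule is
    injective over the filtered units.
    """
    paths, _ = _selected_paths(rule, graph)
    by_key: dict[tuple, set[str]] = {}
    for uid, cpath in paths.items():
        members = graph.get_unit(uid).member_names
        for key in _leaf_keys(cpath, members):
            by_key.setdefault(key, set()).add(uid)
    # merge overlapping collision sets (a unit may share paths with several)
    colliding = [ids for ids in by_key.values() if len(ids) > 1]
    merged: list[set[str]] = []
    for ids in colliding:
        hit = [g for g in merged if g & ids]
        for g in hit:
            merged.remove(g)
            ids = ids | g
        merged.append(set(ids))
    return sorted((sorted(g) for g in merged), key=lambda g: g[0])


@dataclass
class TreeNode:
    name: str
    children: dict[str, "TreeNode"] = field(default_factory=dict)
    leaf_files: list[LeafFile] = field(default_factory=list)

    def child(self, name: str) -> "TreeNode":
        if name not in self.children:
            self.children[name] = TreeNode(name)
            self.children = dict(sorted(self.children.items(),
                                        key=lambda kv: kv[0].encode()))
        return self.children[name]


@dataclass
class ContextTree:
    """The abstract (not yet materialized) tree for one rule."""

    rule: ContextTreeRule
    root: TreeNode
    unit_ids: set[str]                  # units appearing as leaves
    files: list[LeafFile]               # every projected file, sorted by path
    skipped: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        """Number of data units placed in the tree."""
        return len(self.unit_ids)

    @property
    def n_files(self) -> int:
        return len(self.files)

    def iter_files(self) -> Iterator[LeafFile]:
        return iter(self.files)

    def render_text(self) -> str:
        """Indented listing, two spaces per level, leaves marked ``*``."""
        lines: list[str] = []

        def walk(node: TreeNode, depth: int) -> None:
            for name, child in node.children.items():
                lines.append("  " * depth + name + "/")
                walk(child, depth + 1)
            for lf in sorted(node.leaf_files, key=lambda l: l.leaf_path):
                lines.append("  " * depth + "* " + lf.leaf_path
                             + f"  [{lf.unit_id[:8]}]")
        walk(self.root, 0)
        return "\n".join(lines)


def build_tree(rule: ContextTreeRule, graph) -> ContextTree:
    """Arrange the filtered units into the rule's hierarchy.

    Raises :class:`CollisionError` when two units claim the same path and
    the rule's collision policy is ``fail``; with policy ``suffix`` the
    first 8 hex of the unit id are appended to the colliding leaf names.
    Sibling directories are bytewise sorted; segment values that sanitize
    to the same component are disambiguated injectively.
    """
    paths, skipped = _selected_paths(rule, graph)
    collisions = validate_uniqueness(rule, graph)
    suffixed: set[str] = set()
    if collisions:
        if rule.on_collision == "fail":
            raise CollisionError(
                f"rule {rule.name!r}: {len(collisions)} collision group(s): "
                + "; ".join(",".join(u[:8] for u in g) for g in collisions),
                groups=collisions)
        suffixed = {uid for g in collisions for uid in g}

    # injective sanitization of raw segment values per grouping level
    level_values: dict[int, set[str]] = {}
    raw_segments: dict[str, list[str]] = {}
    for uid in paths:
        attrs = graph.get_attributes(uid)
        raws = [attrs.get(k, UNASSIGNED_BUCKET) for k in rule.grouping]
        raw_segments[uid] = raws
        for i, v in enumerate(raws):
            level_values.setdefault(i, set()).add(v)
    level_maps = {i: sanitize_components(vals) for i, vals in level_values.items()}

    files: list[LeafFile] = []
    for uid, cpath in paths.items():
        segments = tuple(level_maps[i][v] for i, v in enumerate(raw_segments[uid]))
        leaf = cpath.leaf_name
        if uid in suffixed:
            leaf = leaf + "_" + uid[:8]
        members = graph.get_unit(uid).member_names
        if "{MEMBER_NAME}" in leaf:
            for m in members:
                files.append(LeafFile(segments, leaf.replace("{MEMBER_NAME}", m),
                                      uid, m))
        elif len(members) == 1:
            files.append(LeafFile(segments, leaf, uid, members[0]))
        else:
            for m in members:
                files.append(LeafFile(segments, f"{leaf}/{m}", uid, m))

    files.sort(key=lambda f: f.relative_path.encode())
    root = TreeNode("")
    for lf in files:
        node = root
        for seg in lf.segments:
            node = node.child(seg)
        extra_dirs = lf.leaf_path.split("/")[:-1]
        for seg in extra_dirs:
            node = node.child(seg)
        node.leaf_files.append(
            LeafFile(lf.segments + tuple(extra_dirs),
                     lf.leaf_path.split("/")[-1], lf.unit_id, lf.member_name))
    return ContextTree(rule=rule, root=root, unit_ids=set(paths) ,
                       files=files, skipped=skipped)


# -- rule config ---------------------------------------------------------

_RULE_FIELDS = {"name", "filter", "grouping", "leaf_template",
                "on_missing", "on_collision"}
_TOP_FIELDS = {"version", "rules"}


def load_rules(config_text: str) -> list[ContextTreeRule]:
    """Parse a YAML rules config into validated :class:`ContextTreeRule`.

    Schema::

        rules:
          - name: morphology-by-bee
            filter: {FORMAT: SWC}
            grouping: [LABOR_STATE, REGION, HONEYBEE_ID, SIGEN_PARAMETERS]
            leaf_template: morphology.swc
            on_missing: unassigned      # fail | skip | unassigned
            on_collision: fail          # fail | suffix

    Violations raise :class:`RuleConfigError` carrying the path to the
    offending field.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise RuleConfigError(f"invalid YAML: {exc}") from exc
    if doc is None:
        return []
    if isinstance(doc, list):    # bare list of rules is accepted
        doc = {"rules": doc}
    if not isinstance(doc, dict):
        raise RuleConfigError("rules config must be a mapping or list")
    unknown = set(doc) - _TOP_FIELDS
    if unknown:
        raise RuleConfigError(f"unknown top-level field(s): {sorted(unknown)}",
                              field_path=sorted(unknown)[0])
    items = doc.get("rules", [])
    if not isinstance(items, list):
        raise RuleConfigError("'rules' must be a list", field_path="rules")
    rules: list[ContextTreeRule] = []
    seen: set[str] = set()
    for i, item in enumerate(items):
        where = f"rules[{i}]"
        if not isinstance(item, dict):
            raise RuleConfigError(f"{where} must be a mapping", field_path=where)
        unknown = set(item) - _RULE_FIELDS
        if unknown:
            raise RuleConfigError(
                f"{where}: unknown field(s) {sorted(unknown)}",
                field_path=f"{where}.{sorted(unknown)[0]}")
        if "name" not in item or not item["name"]:
            raise RuleConfigError(f"{where}: missing 'name'",
                                  field_path=f"{where}.name")
        name = str(item["name"])
        if name in seen:
            raise RuleConfigError(f"{where}: duplicate rule name {name!r}",
                                  field_path=f"{where}.name")
        seen.add(name)
        filt = item.get("filter") or {}
        if not isinstance(filt, dict):
            raise RuleConfigError(f"{where}.filter must be a mapping",
                                  field_path=f"{where}.filter")
        grouping = item.get("grouping") or []
        if not isinstance(grouping, list):
            raise RuleConfigError(f"{where}.grouping must be a list",
                                  field_path=f"{where}.grouping")
        try:
            rules.append(ContextTreeRule.make(
                name=name, filter={str(k): str(v) for k, v in filt.items()},
                grouping=[str(g) for g in grouping],
                leaf_template=str(item.get("leaf_template", "{MEMBER_NAME}")),
                on_missing=str(item.get("on_missing", "unassigned")),
                on_collision=str(item.get("on_collision", "fail"))))
        except RuleConfigError as exc:
            if exc.field_path is None:
                exc.field_path = where
            raise
    return rules


class InMemoryGraph:
    """Minimal in-memory metadata view, handy for rule dry-runs and tests.

    Mirrors the slice of the :class:`~depot.store.Store` API the context
    engine consumes: ``query_units``, ``get_attributes``, ``get_unit``.
    """

    class _Unit:
        def __init__(self, member_names: list[str]):
            self.member_names = member_names

    def __init__(self) -> None:
        self._attrs: dict[str, dict[str, str]] = {}
        self._members: dict[str, list[str]] = {}

    def add_unit(self, unit_id: str, attributes: Mapping[str, str],
                 member_names: Iterable[str] = ("data.bin",)) -> None:
        self._attrs[unit_id] = {normalize_key(k): str(v)
                                for k, v in attributes.items()}
        self._members[unit_id] = list(member_names)

    def query_units(self, filter: Mapping[str, str] | None = None) -> set[str]:
        terms = [(normalize_key(k), str(v)) for k, v in (filter or {}).items()]
        return {uid for uid, attrs in self._attrs.items()
                if all(attrs.get(k) == v for k, v in terms)}

    def get_attributes(self, unit_id: str) -> dict[str, str]:
        return dict(self._attrs[unit_id])

    def get_unit(self, unit_id: str) -> "InMemoryGraph._Unit":
        return self._Unit(list(self._members[unit_id]))
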