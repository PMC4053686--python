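"""Project configuration: one ``.depot.yaml`` at the project root.

All paths are relative to the config file's directory, so a whole project
(store, floating folder, projections) can be moved or synchronized as a
unit.  The file carries the context-tree rules, the projection targets,
and the hook registrations; ``depot init`` writes a starter config.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .context import ContextTreeRule, load_rules
from .errors import RuleConfigError
from .ingest import DEFAULT_SETTLE_SECONDS, HookSpec

CONFIG_NAME = ".depot.yaml"

DEFAULT_CONFIG_YAML = """\
version: 1
floating_root: floating
settle_seconds: 5
rules:
  - name: morphology-by-bee
    filter: {FORMAT: SWC}
    grouping: [LABOR_STATE, REGION, HONEYBEE_ID, SIGEN_PARAMETERS]
    leaf_template: morphology.swc
  - name: stacks-by-bee
    filter: {FORMAT: TIFF_STACK}
    grouping: [HONEYBEE_ID, REGION]
    leaf_template: "{MEMBER_NAME}"
projections:
  - rule: morphology-by-bee
    target: views/morphology
  - rule: stacks-by-bee
    target: views/imaging
hooks:
  - name: swc
    event: on_assign
    suffixes: [".swc"]
    command: "builtin:swc"
    timeout: 30
"""

_TOP_FIELDS = {"version", "floating_root", "settle_seconds", "rules",
               "projections", "hooks"}
_PROJ_FIELDS = {"rule", "target", "link_mode"}
_HOOK_FIELDS = {"name", "event", "suffixes", "attrs", "command", "timeout"}


@dataclass(frozen=True)
class ProjectionTarget:
    rule_name: str
    target_root: Path
    link_mode: str = "symlink"


@dataclass
class ProjectConfig:
    root: Path                      # directory holding .depot.yaml
    floating_root: Path
    settle_seconds: float
    rules: list[ContextTreeRule] = field(default_factory=list)
    projections: list[ProjectionTarget] = field(default_factory=list)
    hooks: list[HookSpec] = field(default_factory=list)

    def rule(self, name: str) -> ContextTreeRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise RuleConfigError(f"no rule named {name!r} in config")


def load_config(path: str | os.PathLike) -> ProjectConfig:
    """Parse and validate ``.depot.yaml`` (``path`` may be the file or its dir)."""
    path = Path(path)
    if path.is_dir():
        path = path / CONFIG_NAME
    if not path.exists():
        raise RuleConfigError(f"no project config at {path}")
    try:
        doc = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise RuleConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise RuleConfigError(f"{path} must contain a mapping")
    unknown = set(doc) - _TOP_FIELDS
    if unknown:
        raise RuleConfigError(f"unknown top-level field(s): {sorted(unknown)}",
                              field_path=sorted(unknown)[0])
    root = path.parent.resolve()
    rules = load_rules(yaml.safe_dump({"rules": doc.get("rules", [])}))

    projections: list[ProjectionTarget] = []
    known = {r.name for r in rules}
    targets_seen: set[Path] = set()
    for i, item in enumerate(doc.get("projections", []) or []):
        where = f"projections[{i}]"
        if not isinstance(item, dict):
            raise RuleConfigError(f"{where} must be a mapping", field_path=where)
        unknown = set(item) - _PROJ_FIELDS
        if unknown:
            raise RuleConfigError(f"{where}: unknown field(s) {sorted(unknown)}",
                                  field_path=f"{where}.{sorted(unknown)[0]}")
        rule_name = item.get("rule")
        if rule_name not in known:
            raise RuleConfigError(f"{where}: unknown rule {rule_name!r}",
                                  field_path=f"{where}.rule")
        target = root / str(item.get("target", f"views/{rule_name}"))
        if target in targets_seen:
            raise RuleConfigError(f"{where}: duplicate target {target}",
                                  field_path=f"{where}.target")
        targets_seen.add(target)
        projections.append(ProjectionTarget(
            rule_name, target, str(item.get("link_mode", "symlink"))))

    hooks: list[HookSpec] = []
    for i, item in enumerate(doc.get("hooks", []) or []):
        where = f"hooks[{i}]"
        if not isinstance(item, dict):
            raise RuleConfigError(f"{where} must be a mapping", field_path=where)
        unknown = set(item) - _HOOK_FIELDS
        if unknown:
            raise RuleConfigError(f"{where}: unknown field(s) {sorted(unknown)}",
                                  field_path=f"{where}.{sorted(unknown)[0]}")
        hooks.append(HookSpec(
            name=str(item.get("name", f"hook{i}")),
            event=str(item.get("event", "on_assign")),
            command=item.get("command"),
            suffixes=tuple(item.get("suffixes", []) or []),
            match_attrs=tuple((str(k), str(v))
                              for k, v in (item.get("attrs") or {}).items()),
            timeout=float(item.get("timeout", 30.0))))

    floating = root / str(doc.get("floating_root", "floating"))
    return ProjectConfig(
        root=root, floating_root=floating,
        settle_seconds=float(doc.get("settle_seconds", DEFAULT_SETTLE_SECONDS)),
        rules=rules, projections=projections, hooks=hooks)


def write_default_config(root: str | os.PathLike) -> Path:
    path = Path(root) / CONFIG_NAME
    if path.exists():
        raise RuleConfigError(f"{path} already exists")
    path.write_text(DEFAULT_CONFIG_YAML)
    return path
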