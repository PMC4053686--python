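"""State and recent-changes reports.

Both reports are pure functions of (metadata graph, store, journal): they
render the same content as a plain-text table for the terminal and as a
small standalone HTML document, and re-rendering without a state change is
byte-identical apart from the generation timestamp.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Sequence

import pandas as pd

from .context import ContextTreeRule, build_tree
from .errors import CollisionError
from .ingest import FloatingCandidate
from .journal import Journal, JournalEvent
from .store import Store

_CSS = ("body{font-family:sans-serif;margin:2em}table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 8px}h2{margin-top:1.2em}")


def _html_doc(title: str, sections: list[tuple[str, str]]) -> str:
    body = "\n".join(f"<h2>{html.escape(h)}</h2>\n{content}"
                     for h, content in sections)
    return (f"<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            f"<title>{html.escape(title)}</title><style>{_CSS}</style></head>"
            f"<body><h1>{html.escape(title)}</h1>\n{body}\n</body></html>\n")


@dataclass
class StateReport:
    """Current contents of the depot, summarized."""

    generated_at: str
    unit_counts: dict[str, int]                 # by state
    attribute_counts: pd.DataFrame              # key, value, n_units
    floating_candidates: list[FloatingCandidate] = field(default_factory=list)
    rule_leaf_counts: dict[str, object] = field(default_factory=dict)

    @property
    def total_units(self) -> int:
        return sum(self.unit_counts.values())

    def to_text(self) -> str:
        lines = [f"depot state  ({self.generated_at})", ""]
        lines.append("units by state:")
        for state in ("floating", "assigned"):
            lines.append(f"  {state:<10} {self.unit_counts.get(state, 0)}")
        lines.append(f"  {'total':<10} {self.total_units}")
        if not self.attribute_counts.empty:
            lines += ["", "attribute values (assigned units):",
                      self.attribute_counts.to_string(index=False)]
        if self.floating_candidates:
            lines += ["", f"floating candidates ({len(self.floating_candidates)}):"]
            for c in self.floating_candidates:
                lines.append(f"  {c.candidate_id[:12]}  {c.grouping_rule_matched:<14}"
                             f" {c.n_files:>4} file(s)  {c.names[0]}")
        if self.rule_leaf_counts:
            lines += ["", "projection rules:"]
            for name, n in sorted(self.rule_leaf_counts.items()):
                lines.append(f"  {name:<24} {n}")
        return "\n".join(lines) + "\n"

    def to_html(self) -> str:
        sections = []
        counts = pd.DataFrame(
            [(s, self.unit_counts.get(s, 0)) for s in ("floating", "assigned")]
            + [("total", self.total_units)], columns=["state", "units"])
        sections.append(("Units by state", counts.to_html(index=False)))
        if not self.attribute_counts.empty:
            sections.append(("Attribute values",
                             self.attribute_counts.to_html(index=False)))
        if self.floating_candidates:
            cand = pd.DataFrame(
                [(c.candidate_id[:12], c.grouping_rule_matched, c.n_files,
                  c.names[0]) for c in self.floating_candidates],
                columns=["candidate", "rule", "files", "first member"])
            sections.append(("Floating candidates", cand.to_html(index=False)))
        if self.rule_leaf_counts:
            rules = pd.DataFrame(sorted(self.rule_leaf_counts.items()),
                                 columns=["rule", "leaves"])
            sections.append(("Projection rules", rules.to_html(index=False)))
        return _html_doc("Depot state report", sections)


def state_report(store: Store, rules: Sequence[ContextTreeRule] = (),
                 floating_candidates: Sequence[FloatingCandidate] = ()
                 ) -> StateReport:
    """Counts of units by state and attribute value, plus per-rule leaves.

    A rule whose tree cannot be built (collisions under policy ``fail``)
    is reported as such instead of aborting the report.
    """
    unit_counts = {"floating": len(store.unit_ids("floating")),
                   "assigned": len(store.unit_ids("assigned"))}
    records = store.attribute_records()
    if records:
        df = pd.DataFrame(records, columns=["unit_id", "key", "value"])
        attr_counts = (df.groupby(["key", "value"], as_index=False)
                       .agg(n_units=("unit_id", "nunique"))
                       .sort_values(["key", "value"], kind="stable")
                       .reset_index(drop=True))
    else:
        attr_counts = pd.DataFrame(columns=["key", "value", "n_units"])
    leaf_counts: dict[str, object] = {}
    for rule in rules:
        try:
            leaf_counts[rule.name] = build_tree(rule, store).n_leaves
        except CollisionError as exc:
            leaf_counts[rule.name] = f"collisions ({len(exc.groups)} group(s))"
    return StateReport(
        generated_at=datetime.now(timezone.utc).isoformat(),
        unit_counts=unit_counts, attribute_counts=attr_counts,
        floating_candidates=list(floating_candidates),
        rule_leaf_counts=leaf_counts)


@dataclass
class ChangesReport:
    """Journal events after a cutoff, chronological, grouped by action."""

    generated_at: str
    since: str
    events: list[JournalEvent] = field(default_factory=list)
    malformed_lines: int = 0

    def by_action(self) -> dict[str, list[JournalEvent]]:
        out: dict[str, list[JournalEvent]] = {}
        for ev in self.events:
            out.setdefault(ev.action, []).append(ev)
        return out

    def to_text(self) -> str:
        lines = [f"depot changes since {self.since}  ({self.generated_at})", ""]
        if not self.events:
            lines.append("no events in window")
        for action, evs in sorted(self.by_action().items()):
            lines.append(f"{action} ({len(evs)}):")
            for ev in evs:
                uid = (ev.unit_id or "-")[:12]
                lines.append(f"  {ev.ts}  {uid}  {ev.actor}")
        if self.malformed_lines:
            lines += ["", f"warning: {self.malformed_lines} malformed "
                          f"journal line(s) skipped"]
        return "\n".join(lines) + "\n"

    def to_html(self) -> str:
        if self.events:
            df = pd.DataFrame(
                [(ev.ts, ev.action, (ev.unit_id or "-")[:12], ev.actor)
                 for ev in self.events],
                columns=["time", "action", "unit", "actor"])
            table = df.to_html(index=False)
        else:
            table = "<p>no events in window</p>"
        sections = [(f"Events since {self.since}", table)]
        if self.malformed_lines:
            sections.append(("Warnings",
                             f"<p>{self.malformed_lines} malformed journal "
                             f"line(s) skipped</p>"))
        return _html_doc("Depot changes report", sections)


def changes_report(journal: Journal, since: datetime) -> ChangesReport:
    all_events, malformed = journal.read()
    if since.tzinfo is None:
        since = since.replace(tzinfo=timezone.utc)
    events = [ev for ev in all_events if ev.timestamp > since]
    events.sort(key=lambda ev: ev.ts)
    return ChangesReport(
        generated_at=datetime.now(timezone.utc).isoformat(),
        since=since.isoformat(), events=events, malformed_lines=malformed)
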