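"""Append-only JSON-lines event journal.

One event object per line: ``{"ts": iso8601, "actor": str, "action": str,
"unit_id": str|null, "payload": {...}}``.  The journal is the audit trail
behind the recent-changes report and the crash-recovery replay: events are
written with an fsync'd append so a half-written trailing line is the worst
a crash can leave behind (readers skip it and count a warning).
"""

from __future__ import annotations

import getpass
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterator


def _now_iso() -> str:
    return datetime.now(timezone.utc).isoformat()


def _actor() -> str:
    try:
        return getpass.getuser()
    except Exception:  # pragma: no cover - no passwd entry
        return "unknown"


@dataclass
class JournalEvent:
    ts: str
    actor: str
    action: str
    unit_id: str | None = None
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"ts": self.ts, "actor": self.actor, "action": self.action,
             "unit_id": self.unit_id, "payload": self.payload},
            sort_keys=True,
        )

    @property
    def timestamp(self) -> datetime:
        return datetime.fromisoformat(self.ts)


class Journal:
    """Append-only event log stored at ``path`` (JSON lines)."""

    def __init__(self, path: str | os.PathLike):
        self.path = Path(path)

    def append(self, action: str, unit_id: str | None = None,
               payload: dict | None = None) -> JournalEvent:
        ev = JournalEvent(ts=_now_iso(), actor=_actor(), action=action,
                          unit_id=unit_id, payload=payload or {})
        line = ev.to_json() + "\n"
        fd = os.open(self.path, os.O_WRONLY | os.O_CREAT | os.O_APPEND, 0o644)
        try:
            os.write(fd, line.encode())
            os.fsync(fd)
        finally:
            os.close(fd)
        return ev

    def read(self, skip_malformed: bool = True) -> tuple[list[JournalEvent], int]:
        """All events plus the count of malformed lines skipped."""
        events: list[JournalEvent] = []
        bad = 0
        if not self.path.exists():
            return events, bad
        with open(self.path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                    events.append(JournalEvent(
                        ts=obj["ts"], actor=obj.get("actor", "?"),
                        action=obj["action"], unit_id=obj.get("unit_id"),
                        payload=obj.get("payload", {})))
                except (json.JSONDecodeError, KeyError, TypeError):
                    if not skip_malformed:
                        raise
                    bad += 1
        return events, bad

    def __iter__(self) -> Iterator[JournalEvent]:
        events, _ = self.read()
        return iter(events)

    def since(self, when: datetime) -> list[JournalEvent]:
        if when.tzinfo is None:
            when = when.replace(tzinfo=timezone.utc)
        return [ev for ev in self if ev.timestamp > when]

    def events_for(self, action: str) -> list[JournalEvent]:
        return [ev for ev in self if ev.action == action]
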