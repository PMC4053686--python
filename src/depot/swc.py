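"""SWC neuron-morphology reading, validation, writing, and summaries.

SWC is the plain-text interchange format for reconstructed neurons: one
node per line with seven whitespace-separated columns —

    index  type_code  x  y  z  radius  parent

``parent`` is the index of the parent node or ``-1`` for a root; ``#``
starts a comment.  Coordinates and radii are in micrometres.  Type codes
vary between producers, so any non-negative integer is accepted.

Validation guarantees the node set forms a forest: unique indices, every
parent resolvable, no cycles.  :func:`swc_summary` condenses a morphology
into the counts and total cable length used as extracted metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError


@dataclass(frozen=True)
class SwcNode:
    index: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    def distance_to(self, other: "SwcNode") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))


def parse_swc(text: str) -> list[SwcNode]:
    """Parse SWC text into validated nodes, preserving row order.

    Raises :class:`ValidationError` naming the offending line number for
    wrong column counts, non-numeric fields, duplicate indices, dangling
    parents, or parent cycles.
    """
    nodes: list[SwcNode] = []
    line_of: dict[int, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        cols = line.split()
        if len(cols) != 7:
            raise ValidationError(
                f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            idx = int(cols[0])
            type_code = int(cols[1])
            x, y, z, radius = (float(c) for c in cols[2:6])
            parent = int(cols[6])
        except ValueError as exc:
            raise ValidationError(f"line {lineno}: non-numeric field: {exc}") from exc
        if idx <= 0:
            raise ValidationError(f"line {lineno}: node index must be positive")
        if type_code < 0:
            raise ValidationError(f"line {lineno}: negative type code")
        if radius <= 0:
            raise ValidationError(f"line {lineno}: radius must be positive")
        if parent != -1 and parent <= 0:
            raise ValidationError(f"line {lineno}: parent must be -1 or a node index")
        if idx in line_of:
            raise ValidationError(
                f"line {lineno}: duplicate node index {idx} "
                f"(first seen at line {line_of[idx]})")
        line_of[idx] = lineno
        nodes.append(SwcNode(idx, type_code, x, y, z, radius, parent))

    index_set = set(line_of)
    for node in nodes:
        if node.parent != -1 and node.parent not in index_set:
            raise ValidationError(
                f"line {line_of[node.index]}: dangling parent {node.parent}")
    _check_forest(nodes, line_of)
    return nodes


def _check_forest(nodes: Sequence[SwcNode], line_of: dict[int, int]) -> None:
    parent = {n.index: n.parent for n in nodes}
    state: dict[int, int] = {}  # 1 = on current walk, 2 = cleared
    for start in parent:
        walk = []
        i = start
        while i != -1 and state.get(i) != 2:
            if state.get(i) == 1:
                cyc = walk[walk.index(i):] + [i]
                raise ValidationError(
                    "parent cycle through node(s) at line(s) "
                    + ", ".join(str(line_of[j]) for j in cyc[:-1]))
            state[i] = 1
            walk.append(i)
            i = parent[i]
        for j in walk:
            state[j] = 2


def write_swc(nodes: Iterable[SwcNode], header: str | None = None) -> str:
    """Serialize nodes back to SWC text (row order preserved)."""
    lines = []
    if header:
        lines += [f"# {h}" for h in header.splitlines()]
    for n in nodes:
        lines.append(f"{n.index} {n.type_code} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                     f"{n.radius:.6g} {n.parent}")
    return "\n".join(lines) + "\n"


def swc_summary(nodes: Sequence[SwcNode]) -> dict[str, float]:
    """Morphology summary used as extracted metadata.

    * ``N_NODES`` — number of nodes.
    * ``N_TREES`` — number of roots (``parent == -1``).
    * ``N_BRANCH_POINTS`` — nodes with two or more children.
    * ``TOTAL_LENGTH`` — sum of parent-child Euclidean distances (µm).

    An empty node list gives the all-zero summary.
    """
    if not nodes:
        return {"N_NODES": 0, "N_TREES": 0, "N_BRANCH_POINTS": 0,
                "TOTAL_LENGTH": 0.0}
    by_index = {n.index: n for n in nodes}
    children: dict[int, int] = {}
    total = 0.0
    roots = 0
    for n in nodes:
        if n.parent == -1:
            roots += 1
        else:
            children[n.parent] = children.get(n.parent, 0) + 1
            total += n.distance_to(by_index[n.parent])
    branch_points = sum(1 for c in children.values() if c >= 2)
    return {"N_NODES": len(nodes), "N_TREES": roots,
            "N_BRANCH_POINTS": branch_points, "TOTAL_LENGTH": total}
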