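"""Seeded synthetic multi-animal imaging project for end-to-end testing.

The generator emulates the data a small insect-neuroanatomy collaboration
produces per animal: a confocal image stack split over many numbered TIFF
files, a segmented neuron morphology in SWC, and an opaque
electrophysiology trace blob — dropped into a floating folder exactly the
way a sync client would deliver them, plus per-unit attribute sheets and a
ground-truth ledger recording every expected unit, attribute and
provenance edge so the whole pipeline can be asserted end to end.

Everything is reproducible from the seed: run the generator twice with the
same spec and the outputs are byte-identical.
"""

from __future__ import annotations

import csv
import json
import random
from dataclasses import asdict, dataclass, field
from io import BytesIO
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError
from .hashing import compute_unit_id
from .swc import SwcNode, write_swc


@dataclass(frozen=True)
class SyntheticProjectSpec:
    """Shape of the generated project.

    Defaults model one field season of a two-caste honeybee study: five
    animals, foragers and nurses, two imaged brain regions, 40-slice
    confocal stacks and ~60-node segmented morphologies.
    """

    n_bees: int = 5
    labor_states: tuple[str, ...] = ("forager", "nurse")
    regions: tuple[str, ...] = ("left_DL", "right_DL")
    stack_files_per_bee: int = 40
    swc_nodes_per_neuron: int = 60
    sigen_parameters: str = "D20V05C01S01"
    seed: int = 42

    def __post_init__(self):
        if self.n_bees < 1 or self.stack_files_per_bee < 1 \
                or self.swc_nodes_per_neuron < 1:
            raise ValidationError("all counts must be >= 1")
        if not self.labor_states or not self.regions:
            raise ValidationError("labor_states and regions must be non-empty")


@dataclass(frozen=True)
class LedgerUnit:
    kind: str                       # stack | swc | trace
    names: tuple[str, ...]          # member names inside the unit
    unit_id: str                    # content hash the files will receive
    attributes: dict[str, str]      # what assignment should attach

    @property
    def bee(self) -> str:
        return self.attributes["HONEYBEE_ID"]


@dataclass
class ProjectLedger:
    """Ground truth for everything the generator wrote."""

    spec: SyntheticProjectSpec
    units: list[LedgerUnit] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def by_kind(self, kind: str) -> list[LedgerUnit]:
        return [u for u in self.units if u.kind == kind]

    def unit_for_id(self, unit_id: str) -> LedgerUnit:
        return next(u for u in self.units if u.unit_id == unit_id)

    def expected_final_attributes(self, unit: LedgerUnit) -> dict[str, str]:
        """Attributes after assignment plus materialized provenance params."""
        attrs = dict(unit.attributes)
        for edge in self.provenance:
            if edge["output"] == unit.unit_id:
                proc = edge["process"]
                attrs.update({f"{proc}_{k}": v
                              for k, v in edge["params"].items()})
        return attrs

    def save(self, path: str | Path) -> None:
        doc = {"spec": asdict(self.spec),
               "units": [{**asdict(u), "names": list(u.names)} for u in self.units],
               "provenance": self.provenance}
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ProjectLedger":
        doc = json.loads(Path(path).read_text())
        spec_doc = dict(doc["spec"])
        for key in ("labor_states", "regions"):
            spec_doc[key] = tuple(spec_doc[key])
        spec = SyntheticProjectSpec(**spec_doc)
        units = [LedgerUnit(kind=u["kind"], names=tuple(u["names"]),
                            unit_id=u["unit_id"], attributes=u["attributes"])
                 for u in doc["units"]]
        return cls(spec=spec, units=units, provenance=doc["provenance"])


def _tiff_bytes(rng: random.Random) -> bytes:
    pixels = np.frombuffer(rng.randbytes(64), dtype=np.uint8).reshape(8, 8)
    buf = BytesIO()
    tifffile.imwrite(buf, pixels)
    return buf.getvalue()


def _random_morphology(rng: random.Random, n_nodes: int) -> list[SwcNode]:
    """A random rooted tree grown node by node (parent drawn uniformly)."""
    nodes = [SwcNode(1, 1, 0.0, 0.0, 0.0, round(rng.uniform(1.0, 3.0), 3), -1)]
    for i in range(2, n_nodes + 1):
        parent = nodes[rng.randrange(len(nodes))]
        nodes.append(SwcNode(
            i, rng.choice((3, 4)),
            round(parent.x + rng.uniform(-5, 5), 3),
            round(parent.y + rng.uniform(-5, 5), 3),
            round(parent.z + rng.uniform(-2, 2), 3),
            round(rng.uniform(0.2, 1.5), 3), parent.index))
    return nodes


def generate_project(spec: SyntheticProjectSpec,
                     floating_root: str | Path,
                     ledger_dir: str | Path) -> ProjectLedger:
    """Populate ``floating_root`` and write the ground-truth ledger.

    Per bee: one numbered TIFF stack, one SWC morphology, one opaque trace
    blob, and a ``key,value`` sidecar CSV (under ``ledger_dir/sidecars``)
    for scripted assignment.  Labor states and regions are assigned
    round-robin so the generated cohort is balanced.  Refuses to write
    into a non-empty floating folder.
    """
    floating = Path(floating_root)
    ledger_dir = Path(ledger_dir)
    floating.mkdir(parents=True, exist_ok=True)
    if any(p for p in floating.iterdir() if not p.name.startswith(".")):
        raise ValidationError(f"floating folder {floating} is not empty")
    sidecars = ledger_dir / "sidecars"
    sidecars.mkdir(parents=True, exist_ok=True)

    rng = random.Random(spec.seed)
    ledger = ProjectLedger(spec=spec)

    for i in range(spec.n_bees):
        bee = f"HB{130400 + i}"
        labor = spec.labor_states[i % len(spec.labor_states)]
        region = spec.regions[(i // len(spec.labor_states)) % len(spec.regions)]
        common = {
            "HONEYBEE_ID": bee,
            "REGION": region,
            "LABOR_STATE": labor,
            "AGE": str(rng.randint(5, 30)),
            "DATE": f"1305{rng.randint(1, 28):02d}",
        }

        stack_members = []
        for k in range(1, spec.stack_files_per_bee + 1):
            name = f"{bee}_{region}_{k:03d}.tiff"
            data = _tiff_bytes(rng)
            (floating / name).write_bytes(data)
            stack_members.append((name, data))
        stack_unit = LedgerUnit(
            "stack", tuple(n for n, _ in stack_members),
            compute_unit_id(stack_members),
            {**common, "FORMAT": "TIFF_STACK"})
        ledger.units.append(stack_unit)

        swc_name = f"{bee}_{region}_morphology.swc"
        swc_text = write_swc(_random_morphology(rng, spec.swc_nodes_per_neuron),
                             header=f"synthetic morphology {bee} {region}")
        (floating / swc_name).write_text(swc_text)
        swc_unit = LedgerUnit(
            "swc", (swc_name,),
            compute_unit_id([(swc_name, swc_text.encode())]),
            {**common, "FORMAT": "SWC"})
        ledger.units.append(swc_unit)

        trace_name = f"{bee}_{region}_trace.dat"
        trace_data = rng.randbytes(256)
        (floating / trace_name).write_bytes(trace_data)
        ledger.units.append(LedgerUnit(
            "trace", (trace_name,),
            compute_unit_id([(trace_name, trace_data)]),
            {**common, "FORMAT": "TRACE"}))

        ledger.provenance.append({
            "inputs": [stack_unit.unit_id],
            "process": "SIGEN",
            "params": {"PARAMETERS": spec.sigen_parameters},
            "output": swc_unit.unit_id,
        })

    for unit in ledger.units:
        sheet = sidecars / f"{unit.names[0]}.attrs.csv"
        with open(sheet, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["key", "value"])
            for k, v in sorted(unit.attributes.items()):
                writer.writerow([k, v])

    ledger.save(ledger_dir / "ledger.json")
    return ledger


def assign_from_ledger(store, ledger: ProjectLedger, candidates,
                       hooks=()) -> dict:
    """Assign scanned candidates using the ledger's ground-truth attributes.

    Candidates are matched to ledger units by content id (a candidate's id
    equals the unit id its files would receive).  Once all ledger units
    are in the store, the ledger's provenance edges are recorded, which
    materializes the process parameters (e.g. ``SIGEN_PARAMETERS``) as
    attributes on the output units.  Returns a summary dict.
    """
    from .ingest import assign_candidate

    by_id = {u.unit_id: u for u in ledger.units}
    assigned, unmatched = [], []
    for cand in candidates:
        unit = by_id.get(cand.candidate_id)
        if unit is None:
            unmatched.append(cand.candidate_id)
            continue
        assign_candidate(store, cand, unit.attributes, hooks=hooks)
        assigned.append(cand.candidate_id)
    edges = 0
    present = set(store.unit_ids())
    for edge in ledger.provenance:
        if edge["output"] in present and all(i in present for i in edge["inputs"]):
            store.record_provenance(edge["inputs"], edge["process"],
                                    edge["params"], edge["output"])
            edges += 1
    return {"assigned": assigned, "unmatched": unmatched,
            "provenance_edges": edges}
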