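# depot

A content-addressed data-unit store with metadata-driven filesystem
projections, for research collaborations that share files through folder
synchronization.

## The problem

Multi-lab projects — the motivating case is an insect-neuroanatomy
collaboration shuttling confocal image stacks, segmented neuron
morphologies (SWC) and electrophysiology traces between groups — usually
encode metadata in directory names: `forager/left_DL/HB130427/...`.  Every
collaborator wants a *different* hierarchy, and hand-maintaining several
copies of the same files in several layouts does not scale and silently
diverges.

`depot` separates storage from organization:

* **Data units.**  The atom is a *data unit*: one file or a set of files
  produced by a single process (a 40-slice TIFF stack, one SWC file).  A
  unit's identity is a content hash — per-file SHA-256, combined as the
  SHA-256 of the name-sorted `name⟂digest` lines — so identity is
  reproducible anywhere and re-ingesting identical content deduplicates.
  Units live in one **flat store**, `store/<unit_id>/<files>`, and are
  immutable; `depot verify` recomputes every digest.
* **Metadata graph.**  Key–value attributes (`HONEYBEE_ID=HB130427`,
  `FORMAT=SWC`, `LABOR_STATE=forager`) attach to unit ids in an embedded
  SQLite database, alongside **provenance edges** recording which inputs
  and parameters a process (e.g. a segmentation run) consumed to produce
  an output unit.  The provenance graph is kept acyclic; process
  parameters are materialized as attributes (`SIGEN_PARAMETERS=...`) so
  they can serve as grouping levels.
* **Context trees.**  A declarative rule — equality filter, ordered
  grouping attributes, leaf-name template — maps each selected unit to a
  *context path*: `filter FORMAT=SWC`, `grouping [LABOR_STATE, REGION,
  HONEYBEE_ID, SIGEN_PARAMETERS]` places a unit at
  `forager/left_DL/HB130427/D20V05C01S01/morphology.swc`.  Reordering the
  grouping list permutes the hierarchy; rules must map units to paths
  injectively (collisions are detected and reported).
* **Projections.**  A context tree is materialized as a read-only
  hierarchy of links into the flat store — the filesystem analogue of a
  materialized view.  A manifest plus input fingerprint makes refreshes
  idempotent and minimal: unchanged inputs touch nothing (so a folder-sync
  client transfers nothing), an attribute edit moves exactly the affected
  entries.
* **Floating-folder ingestion.**  New files land in a writable inbox,
  are grouped into candidate units (subdirectory, numeric-suffix stack,
  or single file), and become assigned units atomically — a journaled
  sequence that a crash can only leave in the pre- or post-assignment
  state (`depot recover` replays the journal).  Pluggable hooks run on
  assignment; the built-in SWC hook extracts `N_NODES`, `N_TREES`,
  `N_BRANCH_POINTS` and `TOTAL_LENGTH` from morphologies.

## Worked example

```sh
depot -C demo init
depot -C demo generate --bees 3 --stack-files 4 --swc-nodes 10 --seed 42
depot -C demo assign --from-ledger demo/ledger/ledger.json --settle 0
depot -C demo project --all
depot -C demo verify
```

which prints

```
initialized depot project at demo (.depot.yaml)
generated 9 expected units (3 bees) in demo/floating
assigned 9 unit(s), 0 unmatched candidate(s), 3 provenance edge(s)
morphology-by-bee: 3 entr(y/ies), 3 change(s) at demo/views/morphology
stacks-by-bee: 12 entr(y/ies), 12 change(s) at demo/views/imaging
store OK: no findings
```

The `generate` step fills the floating folder with a synthetic 3-bee
project (one TIFF stack, one SWC morphology, one trace blob per bee) and a
ground-truth ledger.  `assign` ingests all nine detected candidates into
the flat store, attaches their attributes, and records the three
stack→morphology provenance edges, whose parameters appear on the SWC
units as `SIGEN_PARAMETERS`.  `project` then materializes both configured
views — e.g.
`demo/views/morphology/forager/left_DL/HB130400/D20V05C01S01/morphology.swc`
is a symlink to the stored SWC bytes — and `verify` confirms every stored
digest.  Running `depot -C demo project --all` again reports
`0 change(s)`: the views are up to date and nothing is touched.

The same operations are available as a library (`depot.Store`,
`depot.context`, `depot.projection`, `depot.ingest`); the CLI is a thin
wrapper.

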