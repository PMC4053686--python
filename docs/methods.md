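# Methods

This note documents the model behind `depot`, the choices made where the
design was genuinely open, and what the synthetic fixture does and does
not establish.

## Content addressing

A data unit is an ordered set of `(relative_name, file)` members.  Its id
is computed as: SHA-256 of each member's bytes, then SHA-256 over the
concatenation of one line per member, `name + NUL + file_hex_digest +
newline`, with lines sorted bytewise by name.  Sorting makes the id
invariant to presentation order; the NUL separator makes the name/digest
framing unambiguous (names cannot contain NUL on POSIX filesystems).  Any
byte change in any member, any rename, and any membership change yields a
different id.  The recipe is deliberately simple enough to re-derive in a
few lines of any language; the test suite and the acceptance script each
carry an independent re-implementation.

Deduplication follows directly: ingesting content that hashes to an
existing id is a no-op returning the existing unit.

## Store layout and integrity

Units live flat: `store/<unit_id>/<members>`, one level, no hierarchy —
all organization is expressed in metadata.  Ingest stages files into a
temp directory and renames it into place, so a unit directory either
exists completely or not at all.  `verify` recomputes every member digest
and cross-checks store against metadata in both directions; problems are
report entries (corrupted / orphan directory / dangling metadata /
missing member / extra file), never exceptions, because integrity
checking must not abort on first fault.

Persistence is a single embedded SQLite file (units, members, attributes,
provenance); the journal is append-only JSON lines with an fsync per
event, so the worst a crash can leave is one torn trailing line, which
readers skip and count.

## Metadata model

Attributes are single-valued per (unit, key); keys are normalized to
uppercase `[A-Z0-9_]` (matching the field's conventional style:
`LABOR_STATE`, `HONEYBEE_ID`).  Single-valuedness is what makes context
paths well-defined — a unit must sit at exactly one place per view; a
genuinely multi-valued property can be encoded by key suffixing.  All
metadata attach at unit level; an entity layer (e.g. animal-level
attributes shared by several units) is a recognized extension, not
implemented.

Queries are conjunctions of equality terms over assigned units.  Floating
(unassigned) units are invisible to queries and projections by design:
assignment is the act of publishing.

Provenance edges record `(input units, process name, parameters, output
unit)` and must keep the derivation graph acyclic; cycle checks run
against the stored graph (via networkx) before an edge is accepted.
Parameters are additionally materialized on the output unit as
`<PROCESS>_<KEY>` attributes so that, e.g., a segmentation parameter set
can serve as a grouping level in a view.

## Context trees

A rule is `(name, filter, grouping, leaf_template, on_missing,
on_collision)`.  The context path of a unit is its attribute values for
the grouping keys, in rule order; the leaf name comes from the template,
which may reference attribute keys, `{UNIT_ID8}` (first 8 hex of the id)
and `{MEMBER_NAME}` (one leaf per member file).  Leaf semantics: a
single-file unit renders a leaf file; a multi-file unit under a
non-member template renders a leaf directory containing its members; a
member template renders one leaf per member.

Open points resolved as package policy:

* **Missing grouping values** default to an `UNASSIGNED` bucket with a
  warning (projections stay total and gaps stay visible); `skip` and
  `fail` are available per rule.
* **Collisions** (two units with identical segments and leaf identity)
  default to `fail`, because injectivity is definitional for a context
  path; policy `suffix` appends `_` + 8 hex of the unit id instead.
  Collision detection works on expanded leaf identities — per member for
  member templates, the leaf itself otherwise — i.e. exactly the
  granularity at which two units would fight over a filesystem path.
* **Filters are equality conjunctions only.**  Facet-style equality is
  all the views need; anything richer belongs in a query tool, not in a
  directory-layout rule.
* **Value sanitization** is verbatim where possible: path separators,
  control and reserved characters become `_`, an empty value becomes
  `_EMPTY_`.  Within any sibling set, altered values that would coincide
  after sanitization get an 8-hex digest suffix of the original value, so
  distinct values always map to distinct components and the mapping is
  independent of iteration order.  Hyphens and underscores are both safe
  and are *not* conflated (`left_DL` and `left-DL` are distinct values
  and stay distinct).

## Projections

Materialization mirrors the abstract tree under a target directory with
leaves linked into the flat store; a JSON manifest
(`.projection.json`) records every managed entry plus a fingerprint over
(rule, attributes and member lists of the filtered units).  Because unit
ids are content hashes, the fingerprint covers content changes implicitly.

Refresh semantics: if the fingerprint matches, nothing is touched (a
byte-level no-op, so sync clients see zero traffic); otherwise the desired
entry set is diffed against the manifest and only added/removed/moved
entries are created or unlinked, preserving mtimes of unchanged leaves.
Foreign files found inside a target are warned about and never deleted —
safety over tidiness.  A target that belongs to a different rule, or a
non-empty target with no manifest, is refused rather than clobbered.

Link modes form a fallback chain symlink → hardlink → copy (some
filesystems and sync clients cannot represent symlinks); the mode actually
used is recorded per entry, and all three produce identical logical
content.  `enforce_read_only` drops write bits on projected directories
and copied leaves (symlinks are skipped, since chmod would follow into
the store); this is best-effort — privileged processes bypass POSIX bits —
so digest verification remains the authoritative mutation detector.

## Ingestion and crash safety

Scanning groups stable files by three rules in fixed priority:
directory-as-unit, then numeric-suffix sets (`stem_001.tiff …`, at least
two files), then single-file fallback.  Stability means the mtime is at
least `settle_seconds` old (default 5 s — sync clients write
incrementally); unstable files simply wait for the next scan.  A
candidate's id is the unit id its files would receive, which is also how
assignment revalidates it: changed or vanished files raise a
stale-candidate error instead of ingesting drifted data.

Assignment is journaled as `begin → ingest → metadata → delete originals
→ commit`, fenced by an `O_EXCL` lock file per candidate (concurrent
assignment of the same candidate has exactly one winner).  Recovery
replays the journal: a `begin` without `commit` is rolled forward when
the unit reached the database (finish deletions, commit) and rolled back
otherwise (drop the half-placed store directory; floating files are
untouched because ingestion only ever copies).  The fault-injection seam
used by the tests calls a callback at every step boundary; production
code passes nothing.

Hooks are advisory: external executables receive a JSON payload (unit id,
absolute member paths, attributes) on stdin and may print a JSON object
of extra attributes, stored under `HOOK_<NAME>_<KEY>` so they can never
clobber user metadata.  Crashes, non-zero exits, bad output and timeouts
are captured as results and journaled; they never fail the assignment.
In-process callable hooks are supported for built-ins and testing; the
subprocess timeout does not apply to them.

## SWC handling

The parser accepts the 7-column whitespace dialect with `#` comments and
no header, preserves row order, and validates: unique positive indices,
numeric fields, positive radii, resolvable parents, and an acyclic parent
relation (the node set must be a forest).  Errors name the offending line.
Summaries: `N_NODES`, `N_TREES` (roots), `N_BRANCH_POINTS` (nodes with ≥2
children), `TOTAL_LENGTH` (sum of parent–child Euclidean distances, µm).
Unknown type codes are accepted because real-world producers disagree on
them.  Volume/surface analyses are out of scope; the summary is the
payload of the metadata-extraction hook.

## Synthetic project generator

The generator emulates one field season of a two-caste honeybee study:
per animal, a numbered single-page TIFF stack (default 40 files, 8×8
random pixels — projection logic is content-agnostic), a random ~60-node
SWC morphology grown by uniform parent attachment, and a 256-byte opaque
trace blob, all dropped flat into the floating folder the way a sync
client would deliver them.  Labor states and regions are assigned
round-robin so cohorts are balanced; animal ids are date-like
(`HB130400`, `HB130401`, …); the segmentation parameter string defaults
to `D20V05C01S01`.  A ground-truth ledger records every expected unit id,
attribute map and provenance edge, plus per-unit `key,value` CSV sidecars
for scripted assignment.  Everything derives from one `random.Random`
seed; two runs with the same spec are byte-identical.

What the fixture does *not* model: real image content, partial/corrupted
sync deliveries, concurrent multi-writer inboxes, very large files, or
entity-level metadata.  Passing the end-to-end suite therefore
demonstrates the bookkeeping contracts (identity, conservation,
idempotence, recoverability), not robustness to adversarial real-world
data streams.

## Problem sizes and numerical notes

The default test and acceptance runs use 3–5 animals, 4–40 stack files
per animal, ≤60-node morphologies, 200 random (graph, rule) projection
instances, 100 random units/trees for the hash and SWC oracles, and 20
crash-injection trials — sizes chosen so the full pipeline including
hundreds of real files and projections runs in seconds while still
exercising every rule branch.  Morphology lengths are plain double
`math.dist` sums; the only tolerance anywhere is float comparison noise
(~1e-13 relative) against the brute-force reference.  All randomized
checks run from fixed seeds (or a seed derived from the acceptance
script's `--seed`).
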