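# Methods

## The data model

A project is an ordered list of molecule entries plus an ordered property
schema. Each entry keeps the user's SMILES verbatim (`smiles_input`) and an
RDKit-canonical spelling (`smiles_canonical`) computed once at insertion;
every structural operation — de-duplication, matching, fingerprinting,
depiction — runs on the canonical form, so results never depend on how a
structure was typed. Property values are stored uniformly as strings, and
numeric meaning is assigned only at query/sort time. This mirrors how
chemists actually fill such tables: a column may hold `350.2` in one row and
`n/a` or `>1000` in the next, and a typed schema would either reject or
silently mangle those.

Persistence is one UTF-8 JSON file (`project.json`) holding the name, the
schema, and the entries in order, next to an `attachments/<id>/` tree and a
`lock.json` record. JSON over a binary table was a deliberate choice: the
folder diffs cleanly, survives file-sync services, and needs no reader
beyond a text editor. Saves are atomic (write-temp-then-rename), so a
crashed writer never leaves a half-written table.

## Lock arbitration

Projects shared through a synced folder have no server to arbitrate writes,
so the folder itself carries a single-writer lock: the first opener creates
`lock.json` with `O_CREAT|O_EXCL` (atomic on POSIX filesystems and honoured
by sync clients) and owns read/write access; every later opener is handed a
read-only session together with the owner's `user@host` identity. Because a
crashed process cannot remove its own lock file, a lock older than a TTL
(default 24 h) is considered stale — but it is only ever broken by the
explicit `steal` action, never implicitly, since a slow sync can make a
healthy lock look abandoned. The TTL default is our policy choice; there is
no principled value, only the trade-off between lockout time after a crash
and the risk of stealing from a live writer.

## Import semantics

All ingest paths (CSV, XLSX, SDF, CAS) share one policy, implemented in a
single helper so they cannot drift apart: the first instance of an ID wins —
whether the earlier instance is already in the project or earlier in the
same file — and every skipped row is reported with its 1-based data-row
number, either as a duplicate `(id, row)` pair or an invalid-structure
`(row, reason)` pair. The report satisfies
`n_imported = n_read − |duplicates| − |invalid|` by construction. Empty
table cells import as *absent* properties rather than empty strings,
because "no measurement" and "measured as empty" are different facts and
only absence has defined query semantics (below). SDF data fields are read
as verbatim strings (not auto-coerced to numbers) so export→import round
trips are exact.

## Query semantics

Property filters AND-combine; each applies one of eight comparators. The
four order comparators parse both the cell and the reference as decimal
numbers and evaluate to **false** when either fails to parse — in
mixed-content columns a non-numeric cell is a non-match, not an error.
Equality/inequality compare exact strings; containment is case-sensitive
substring search (case-folding would conflate aromatic/aliphatic SMILES
conventions in structure columns for no benefit in formula columns). An
absent cell fails every comparator except `NE` and `NOT_CONTAINS`, which
succeed: absence differs from any value. Queries return a new project with
copies of the matching entries; the source is never mutated (verified by
hashing its serialised form before and after).

Structural queries parse the query as SMILES, not SMARTS, and match with
RDKit's substructure machinery after both sides are perceived under the
same aromaticity model. Superstructure is the exact dual (the entry must
embed into the query), and the suite checks the duality explicitly.
Similarity uses Morgan fingerprints (radius 2, 2048 bits — the field's
default working point) with the Tanimoto coefficient computed from bit-set
counts; both-empty sets define T = 1. The similarity query thresholds at a
user-settable cutoff (default 0.7) and writes a 4-decimal `Similarity`
column into the result, so thresholding and ranking workflows are both
served.

## Descriptors

Nine descriptors form the closed set: MW (average atomic masses — the
inventory convention; monoisotopic masses belong to MS workflows), heavy
atoms, Hill formula, Crippen atomic-contribution logP, HBD, HBA, rotatable
bonds, ring count, TPSA. Computation re-parses the canonical spelling first
so float summation order — hence the exact value — is identical for every
spelling of a graph. Cells are formatted as strings (2 decimals for
MW/LogP/TPSA, bare integers otherwise) under fixed column names. The
project records which columns the calculator owns: recomputation silently
overwrites those (so a manual edit of a computed value is corrected on the
next run), but clobbering a same-named *user* column requires an explicit
flag.

Self-consistency is tested by an independent route: the emitted Hill
formula is re-parsed and priced against a local standard-atomic-mass table
(IUPAC 2005 values), which must agree with the MW descriptor to
0.01 g/mol on every fixture molecule; logP is cross-checked against the sum
of per-atom contributions over the explicit-hydrogen graph.

## CAS resolution

CAS numbers are validated structurally (2–7/2/1 digit groups) and by check
digit — the position-weighted digit sum mod 10, with positions counted
right-to-left — before any network activity. Resolution goes through a
client interface with two implementations: a recorded-fixture client
replaying a JSON map (the only one the test suite touches; it also counts
lookups so caching is observable) and a live PubChem PUG REST client using
stdlib HTTP with ≥200 ms between requests and three exponential-backoff
retries. Outcomes are statuses on the record (`resolved`, `not_found`,
`invalid_cas`, `network_error`), never exceptions, and results are cached
per CAS within a batch. Imported entries use the CAS number itself as the
ID (guaranteed unique, user-recognisable) and store the IUPAC name in an
`IUPAC name` column. When a CAS maps to several service records the first
is taken.

## Consensus toxicity scoring

Each endpoint is scored by an ensemble of probabilistic classifiers over
Morgan fingerprints; the consensus is the arithmetic mean of member
probabilities scaled to 0–100 and rounded half-up — the simplest rule that
satisfies the integer 0–100 contract, makes m identical members equal the
single model, and is monotone in every member. The training harness fits
logistic models on bootstrap resamples (each redrawn until both classes are
present, so `predict_proba` is always two-class), fully determined by
(dataset, member count, seed).

The bundled ensembles are *placeholders*: rather than shipping opaque model
binaries, `default_ensembles(seed)` rebuilds them deterministically at run
time from the seeded synthetic dataset, giving bit-identical scores across
processes with zero serialized artifacts. They recover a planted
structure–label signal and prove the plumbing; they say nothing about real
toxicity, and the package claims no toxicological validity.

## Synthetic libraries and what they do (not) show

The fixture generator assembles molecules from seven aromatic scaffolds and
two substituent slots drawn from small nitrogen-free and nitrogen-bearing
fragment lists. Three markers are planted with exact counts
(`round(n·fraction)`): the coumarin core, any-nitrogen, and the nitro
group; every flag is re-verified against RDKit substructure/atom checks
before the library is returned, and the test suite re-verifies them a third
way through a networkx subgraph-monomorphism oracle. Default fractions are
0.2 coumarin / 0.5 nitrogen / 0.15 nitro — enough positives of each kind
for stable statistics at n = 100 without the markers dominating the
library. The toxicity dataset uses nitro prevalence 0.5 with a 5 % label
flip, emulating a balanced assay with realistic annotation noise.

These libraries guarantee validity and exact planted truth, which is what
correctness tests need. They do **not** emulate real screening decks:
molecules are small (≤ ~20 heavy atoms), drawn from a narrow fragment
grammar, with none of the stereochemistry, charge states, tautomer
ambiguity, or scale diversity of vendor catalogues. Passing tests therefore
demonstrates correct mechanics (round trips, policies, matching, scoring
plumbing) — not retrieval performance on real chemistry.

## Problem sizes and numerical choices

The suite runs round trips at 500 molecules, query-oracle comparisons at
1,000 molecules × 200 random specs, structural-oracle comparisons at 100
molecules (all ≤ 30 heavy atoms, where the brute-force search is exact and
fast), Tanimoto properties at 10,000 random bit-set pairs, and the scale
sanity check — a substructure query over a 10,000-molecule library — as the
package's desk-scale working size. Ties in sorting and in the duplicate
policy always resolve to stable input order. Degenerate inputs are defined,
not rejected: empty projects save/load and export; empty similarity sets
compare as identical; an unparsable entry is skipped and reported by every
batch operation rather than aborting it.

## Known limitations

- No OR/nested boolean logic in property queries, and no SMARTS query
  input; queries are conjunctions over SMILES-entered structures.
- Stereochemistry is carried through SMILES canonicalisation but not
  specifically exercised; CAS resolution requests canonical (not isomeric)
  structures.
- The toxicity ensembles are declared placeholders (above).
- Concurrent lock stealing is last-writer-wins by design; the TTL guards
  against crashes, not against two users deliberately stealing at once.
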