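# molcabinet

Compound-library management for medicinal chemists, as a headless Python
library plus a `molcabinet` command-line tool. A *project* — an ordered table
of molecules with free-form property columns — lives on disk as a plain
folder (`project.json`, an `attachments/` tree, a `lock.json` single-writer
record), so it can be versioned, diffed, and shared through any
file-synchronisation service. On top of that store the package provides:

- **Entry management** — add molecules by SMILES (kept verbatim alongside an
  RDKit-canonical form used for all matching and de-duplication), edit
  properties in place, highlight rows green/yellow/red, sort any column
  numerically or lexicographically, and attach per-molecule files (spectra,
  PDFs, notes).
- **Import/export** — CSV (comma/semicolon/tab), XLSX, and V2000 SDF, with
  explicit ID/SMILES column mapping, a first-instance-wins duplicate policy,
  and an `ImportReport` listing every skipped row. Plus a self-contained
  HTML grid of 2-D depictions.
- **CAS resolution** — validate registry numbers by their positional
  check digit, resolve them to structures and IUPAC names through a
  PubChem-style REST client (or a recorded offline fixture client), and
  import the results.
- **Descriptors** — MW, heavy atoms, Hill formula, Crippen logP, HBD/HBA,
  rotatable bonds, rings, and TPSA written into project columns.
- **Queries** — conjunctions of eight property comparators
  (≥, >, <, ≤, =, ≠, contains, not-contains) and structural searches
  (substructure, superstructure, Morgan/Tanimoto similarity), each returning
  a new project and never touching the source.
- **Consensus toxicity scores** — per-endpoint 0–100 scores
  (mutagenicity, carcinogenicity, estrogenicity, hepatotoxicity) defined as
  `round(100 · mean(p₁…p_m))` over an ensemble of fingerprint-based
  probabilistic classifiers, computed entirely offline. The bundled
  ensembles are deterministic placeholders trained on synthetic data; they
  exercise the scoring contract and carry no toxicological validity.
- **Synthetic fixtures** — a seeded scaffold × substituent generator that
  plants exact counts of coumarin cores, nitrogen atoms, and nitro groups,
  so every feature above is testable offline against known ground truth.

The similarity machinery is the standard cheminformatics pairing: hashed
circular (Morgan) fingerprints of radius 2 folded to 2048 bits, compared by
the Tanimoto coefficient `T(A,B) = |A∩B| / |A∪B|`.

## Worked example

```python
from molcabinet import (create_project, save_project, close_project,
    compute_project_properties, QuerySpec, PropertyFilter, apply_property_query,
    StructuralQuery, apply_structural_query, default_ensembles, predict_project)

project = create_project("demo_project", "demo")
project.add_molecule("aspirin", "CC(=O)Oc1ccccc1C(=O)O", {"Source": "shelf"})
project.add_molecule("coumarin", "O=c1ccc2ccccc2o1", {"Source": "vendor"})
project.add_molecule("paracetamol", "CC(=O)Nc1ccc(O)cc1", {"Source": "shelf"})

compute_project_properties(project, ["molecular_weight", "logp", "molecular_formula"])
for e in project.entries:
    print(e.id, e.properties["MW"], e.properties["LogP"], e.properties["Formula"])

spec = QuerySpec([PropertyFilter("MW", "GE", "150"),
                  PropertyFilter("Formula", "CONTAINS", "N")])
print("matches:", apply_property_query(project, spec).ids())

hits, _ = apply_structural_query(project, StructuralQuery("substructure", "O=c1ccc2ccccc2o1"))
print("coumarin core:", hits.ids())

predict_project(project, ["mutagenicity"], default_ensembles(seed=2023, n_models=2, n_train=60))
for e in project.entries:
    print(e.id, "Tox_Mutagenicity =", e.properties["Tox_Mutagenicity"])

save_project(project)
close_project(project)
```

prints

```
aspirin 180.16 1.31 C9H8O4
coumarin 146.14 1.79 C9H6O2
paracetamol 151.16 1.35 C8H9NO2
matches: ['paracetamol']
coumarin core: ['coumarin']
aspirin Tox_Mutagenicity = 3
coumarin Tox_Mutagenicity = 8
paracetamol Tox_Mutagenicity = 3
```

The descriptor columns are stored as strings (two decimals for MW/LogP);
the property query keeps exactly the rows whose MW parses to ≥ 150 *and*
whose Hill formula contains the symbol `N` — only paracetamol, since
coumarin is below the mass cut and aspirin has no nitrogen. The structural
query retains the one molecule containing the 2H-chromen-2-one (coumarin)
core as a subgraph. The toxicity column holds the 0–100 consensus of the
deterministic placeholder ensemble (seeded, so these exact integers
reproduce).

The same pipeline from the shell:

```
molcabinet new ./p --name demo
molcabinet add ./p --id aspirin --smiles "CC(=O)Oc1ccccc1C(=O)O"
molcabinet props ./p --set MW,LogP,Formula
molcabinet query ./p --where "MW>=150" --where "Formula~N"
molcabinet squery ./p --mode substructure --smiles "O=c1ccc2ccccc2o1" --out ./hits
```

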