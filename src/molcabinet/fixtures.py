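"""Deterministic synthetic molecule libraries with planted ground truth.

Molecules are assembled from a scaffold × substituent grammar — aromatic
scaffolds (benzene, naphthalene, furan, thiophene, pyridine, indole,
coumarin) with two substitution slots drawn from small nitrogen-free and
nitrogen-bearing fragment lists — so every generated SMILES is valid by
construction and three structural markers are planted exactly:

* carries the coumarin core (the coumarin scaffold),
* contains at least one nitrogen atom,
* carries a nitro group.

The requested marker fractions are hit exactly (to rounding), and the flags
recorded per molecule are re-verified against RDKit substructure/atom checks
before the library is returned. Generation is fully determined by the seed.

These libraries emulate a screening-scale compound collection for offline
testing; they are not drawn from any external database and make no claim of
drug-likeness or chemical diversity beyond the grammar above.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem

from .chem import mol_from_smiles
from .errors import MolCabinetError
from . import io_formats
from .project import Project, create_project, save_project, close_project

COUMARIN_CORE_SMILES = "O=c1ccc2ccccc2o1"
NITRO_SMARTS = "[N+](=O)[O-]"

# Two-slot templates; {A} and {B} are substituent attachment points whose
# fragments attach through their first atom. "[H]" is the null substituent.
_TEMPLATES = {
    "benzene": "c1cc({A})ccc1{B}",
    "naphthalene": "c1ccc2cc({A})ccc2c1{B}",
    "furan": "c1cc({A})oc1{B}",
    "thiophene": "c1cc({A})sc1{B}",
    "pyridine": "c1cc({A})ncc1{B}",
    "indole": "c1cc({B})c2c(c1)cc({A})[nH]2",
    "coumarin": "O=c1cc({B})c2cc({A})ccc2o1",
}
_N_FREE_SCAFFOLDS = ("benzene", "naphthalene", "furan", "thiophene")
_N_SCAFFOLDS = ("pyridine", "indole")

_N_FREE_SUBS = (
    "[H]", "C", "CC", "CCC", "C(C)C", "O", "OC", "CO", "CCO", "Cl", "F", "Br",
    "C(=O)O", "C(=O)OC", "C(F)(F)F", "CC(C)O", "SC", "C=C", "CC=O", "OCCO",
)
_N_SUBS = ("N", "NC", "N(C)C", "C#N", "C(=O)N", "CN", "CCN", "NC(C)=O")
_NITRO_SUB = "[N+](=O)[O-]"

_coumarin_query = Chem.MolFromSmiles(COUMARIN_CORE_SMILES)
_nitro_query = Chem.MolFromSmarts(NITRO_SMARTS)


@dataclass(frozen=True)
class FixtureSpec:
    """Size, seed, and planted-marker fractions of a synthetic library."""

    n: int
    seed: int
    coumarin_fraction: float = 0.2
    nitrogen_fraction: float = 0.5
    nitro_fraction: float = 0.15

    def __post_init__(self):
        if self.n < 1:
            raise MolCabinetError("library size must be >= 1")
        for name in ("coumarin_fraction", "nitrogen_fraction", "nitro_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MolCabinetError(f"{name} must lie in [0, 1], got {v}")
        if self.nitro_fraction > self.nitrogen_fraction:
            raise MolCabinetError(
                "nitro_fraction cannot exceed nitrogen_fraction "
                "(every nitro group contains nitrogen)"
            )


@dataclass(frozen=True)
class LibraryMolecule:
    id: str
    smiles: str
    scaffold: str
    has_coumarin: bool
    has_nitrogen: bool
    has_nitro: bool


def _verify_flags(mol: Chem.Mol, m: LibraryMolecule) -> None:
    if mol.HasSubstructMatch(_coumarin_query) != m.has_coumarin:
        raise RuntimeError(f"coumarin flag mismatch for {m.smiles}")
    if mol.HasSubstructMatch(_nitro_query) != m.has_nitro:
        raise RuntimeError(f"nitro flag mismatch for {m.smiles}")
    if any(a.GetSymbol() == "N" for a in mol.GetAtoms()) != m.has_nitrogen:
        raise RuntimeError(f"nitrogen flag mismatch for {m.smiles}")


def generate_library(spec: FixtureSpec) -> list[LibraryMolecule]:
    """Generate ``spec.n`` molecules with exactly-planted markers.

    Marker counts are ``round(n * fraction)``. Every molecule's flags are
    re-verified against RDKit before return, so the planted ground truth is
    exact by construction *and* by independent check.
    """
    rng = random.Random(spec.seed)
    n = spec.n
    k_coumarin = round(n * spec.coumarin_fraction)
    k_nitrogen = round(n * spec.nitrogen_fraction)
    k_nitro = round(n * spec.nitro_fraction)
    if k_nitro > k_nitrogen:  # rounding can re-introduce the conflict
        k_nitrogen = k_nitro

    indices = list(range(n))
    coumarin_set = set(rng.sample(indices, k_coumarin))
    nitrogen_set = set(rng.sample(indices, k_nitrogen))
    nitro_set = set(rng.sample(sorted(nitrogen_set), k_nitro))

    width = max(4, len(str(n)))
    out: list[LibraryMolecule] = []
    for i in indices:
        in_coumarin = i in coumarin_set
        in_nitrogen = i in nitrogen_set
        in_nitro = i in nitro_set
        if in_coumarin:
            scaffold = "coumarin"
        elif in_nitrogen and not in_nitro and rng.random() < 0.5:
            scaffold = rng.choice(_N_SCAFFOLDS)
        else:
            scaffold = rng.choice(_N_FREE_SCAFFOLDS)

        scaffold_has_n = scaffold in _N_SCAFFOLDS
        if in_nitro:
            slot_a = _NITRO_SUB
            slot_b = rng.choice(_N_FREE_SUBS)
        elif in_nitrogen and not scaffold_has_n:
            slot_a = rng.choice(_N_SUBS)
            slot_b = rng.choice(_N_FREE_SUBS)
        elif in_nitrogen:
            # scaffold supplies the nitrogen; substituents may add more
            slot_a = rng.choice(_N_FREE_SUBS + _N_SUBS)
            slot_b = rng.choice(_N_FREE_SUBS)
        else:
            slot_a = rng.choice(_N_FREE_SUBS)
            slot_b = rng.choice(_N_FREE_SUBS)

        smiles = _TEMPLATES[scaffold].format(A=slot_a, B=slot_b)
        mol = mol_from_smiles(smiles)
        record = LibraryMolecule(
            id=f"MOL{i + 1:0{width}d}",
            smiles=smiles,
            scaffold=scaffold,
            has_coumarin=in_coumarin,
            has_nitrogen=in_nitrogen or in_nitro or scaffold_has_n
            or slot_a in _N_SUBS or slot_a == _NITRO_SUB,
            has_nitro=in_nitro,
        )
        _verify_flags(mol, record)
        if record.has_nitrogen != (in_nitrogen or in_nitro):
            raise RuntimeError("nitrogen bookkeeping error")  # grammar bug guard
        out.append(record)
    return out


def library_to_project(library: list[LibraryMolecule], name: str = "fixture") -> Project:
    """In-memory project from a generated library.

    Each molecule gets a ``Series`` property (its scaffold) and a seeded
    2-decimal ``Activity`` value, so property queries and sorting have
    realistic mixed columns to work on.
    """
    project = Project(name)
    rng = random.Random(sum(ord(c) for c in name) + len(library))
    for m in library:
        project.add_molecule(m.id, m.smiles, {
            "Series": m.scaffold,
            "Activity": f"{rng.uniform(0.1, 9999.9):.2f}",
        })
    return project


#: Recorded CAS→(SMILES, IUPAC name) map used by the offline resolver
#: fixture. All registry numbers carry valid check digits.
CAS_FIXTURE_MAP = {
    "50-00-0": ["C=O", "formaldehyde"],
    "64-17-5": ["CCO", "ethanol"],
    "71-43-2": ["c1ccccc1", "benzene"],
    "67-64-1": ["CC(C)=O", "propan-2-one"],
    "64-19-7": ["CC(=O)O", "acetic acid"],
    "108-88-3": ["Cc1ccccc1", "methylbenzene"],
    "103-90-2": ["CC(=O)Nc1ccc(O)cc1", "N-(4-hydroxyphenyl)acetamide"],
    "69-72-7": ["O=C(O)c1ccccc1O", "2-hydroxybenzoic acid"],
    "50-78-2": ["CC(=O)Oc1ccccc1C(=O)O", "2-acetyloxybenzoic acid"],
    "58-08-2": ["Cn1cnc2c1c(=O)n(C)c(=O)n2C", "1,3,7-trimethylpurine-2,6-dione"],
    "91-20-3": ["c1ccc2ccccc2c1", "naphthalene"],
    "62-53-3": ["Nc1ccccc1", "aniline"],
}


def write_fixture_files(library: list[LibraryMolecule], directory, name: str = "fixture") -> dict[str, Path]:
    """Emit every dialect the importers read, all describing ``library``.

    Writes comma- and semicolon-CSV, XLSX, SDF, the recorded CAS map as
    JSON, and a ready-to-open project folder. Returns a name→path map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    project = library_to_project(library, name)

    paths = {
        "csv": directory / f"{name}.csv",
        "csv_semicolon": directory / f"{name}_semicolon.csv",
        "xlsx": directory / f"{name}.xlsx",
        "sdf": directory / f"{name}.sdf",
        "cas_json": directory / "cas_fixture.json",
        "project": directory / f"{name}_project",
    }
    io_formats.export_table(project, paths["csv"], "csv", separator=",")
    io_formats.export_table(project, paths["csv_semicolon"], "csv", separator=";")
    io_formats.export_table(project, paths["xlsx"], "xlsx")
    io_formats.export_sdf(project, paths["sdf"])
    paths["cas_json"].write_text(json.dumps(CAS_FIXTURE_MAP, indent=1), encoding="utf-8")

    on_disk = create_project(paths["project"], name)
    on_disk.entries = [e.copy() for e in project.entries]
    on_disk.schema = list(project.schema)
    on_disk._rebuild_index()
    save_project(on_disk)
    close_project(on_disk)
    return paths


def generate_tox_dataset(n: int, seed: int, noise_rate: float = 0.05) -> list[tuple[str, int]]:
    """Labelled (SMILES, 0/1) pairs with a planted nitro-group signal.

    The true label is the presence of a nitro group (planted in half the
    library); each label is flipped independently with probability
    ``noise_rate``, emulating assay noise. Class balance stays within
    [0.3, 0.7] by construction. Seed-deterministic.
    """
    if n < 20:
        raise MolCabinetError("toxicity dataset needs n >= 20 to stratify")
    library = generate_library(FixtureSpec(
        n=n, seed=seed, coumarin_fraction=0.1, nitrogen_fraction=0.75, nitro_fraction=0.5
    ))
    rng = random.Random(seed ^ 0x5F5E1)
    return [
        (m.smiles, int(m.has_nitro) ^ int(rng.random() < noise_rate))
        for m in library
    ]
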