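"""Physicochemical descriptors written into project property columns.

Nine descriptors form the closed set: molecular weight (g/mol, average
atomic masses — the chemistry-inventory convention, not monoisotopic),
heavy-atom count, Hill-order molecular formula, Crippen atomic-contribution
logP, hydrogen-bond donors and acceptors, rotatable bonds, ring count, and
topological polar surface area (Å²).  All are computed on the canonical
molecular graph, so two spellings of the same SMILES give identical values.

Values land in the project as strings under fixed column names (``MW``,
``HeavyAtoms``, ``Formula``, ``LogP``, ``HBD``, ``HBA``, ``RotB``,
``Rings``, ``TPSA``): real-valued descriptors with 2 decimals, counts as
unpadded integers.  Descriptor columns are tracked so a recompute may
overwrite them freely, while clobbering a same-named user column requires
an explicit flag.
"""

from __future__ import annotations

from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem import mol_from_smiles, try_mol
from .errors import MolCabinetError
from .project import Project

# name -> (project column, computation, string formatter)
_DESCRIPTORS = {
    "molecular_weight": ("MW", Descriptors.MolWt, lambda v: f"{v:.2f}"),
    "heavy_atom_count": ("HeavyAtoms", lambda m: m.GetNumHeavyAtoms(), str),
    "molecular_formula": ("Formula", rdMolDescriptors.CalcMolFormula, str),
    "logp": ("LogP", Crippen.MolLogP, lambda v: f"{v:.2f}"),
    "hbd": ("HBD", rdMolDescriptors.CalcNumHBD, str),
    "hba": ("HBA", rdMolDescriptors.CalcNumHBA, str),
    "rotatable_bonds": ("RotB", rdMolDescriptors.CalcNumRotatableBonds, str),
    "ring_count": ("Rings", rdMolDescriptors.CalcNumRings, str),
    "tpsa": ("TPSA", rdMolDescriptors.CalcTPSA, lambda v: f"{v:.2f}"),
}

DESCRIPTOR_NAMES = tuple(_DESCRIPTORS)
DESCRIPTOR_COLUMNS = {name: col for name, (col, _, _) in _DESCRIPTORS.items()}


def _validate_selection(selected) -> tuple[str, ...]:
    names = tuple(selected) if selected is not None else DESCRIPTOR_NAMES
    if not names:
        raise MolCabinetError("descriptor selection must be non-empty")
    unknown = [n for n in names if n not in _DESCRIPTORS]
    if unknown:
        raise MolCabinetError(f"unknown descriptors: {', '.join(unknown)}")
    return names


def calc_descriptors(smiles: str, selected=None) -> dict[str, float | int | str]:
    """Compute the selected descriptors for one molecule.

    Returns raw values (floats/ints/str) keyed by descriptor name;
    raises :class:`InvalidSmilesError` for an unparsable structure.
    """
    names = _validate_selection(selected)
    # re-parse the canonical spelling so atom order (hence float summation
    # order) is identical for every spelling of the same graph
    from rdkit import Chem

    mol = mol_from_smiles(Chem.MolToSmiles(mol_from_smiles(smiles)))
    return {n: _DESCRIPTORS[n][1](mol) for n in names}


def compute_project_properties(
    project: Project, selected=None, overwrite_user_columns: bool = False
) -> list[tuple[str, str]]:
    """Fill one column per selected descriptor for every entry.

    Descriptor-owned columns are recomputed in place (a recompute overwrites
    manual edits). If a selected column name already exists as a *user*
    column, the call refuses unless ``overwrite_user_columns`` is set.
    Entries whose stored SMILES no longer parses keep an absent cell and are
    returned as ``(id, reason)`` pairs; one bad entry never aborts the batch.
    """
    if project.mode != "read_write":
        raise MolCabinetError("descriptor calculation requires a read/write session")
    names = _validate_selection(selected)
    for n in names:
        col = DESCRIPTOR_COLUMNS[n]
        if col in project.schema and col not in project.descriptor_columns and not overwrite_user_columns:
            raise MolCabinetError(
                f"column {col!r} already exists as a user column; "
                "pass overwrite_user_columns=True to replace it"
            )
    failures: list[tuple[str, str]] = []
    for entry in project.entries:
        mol = try_mol(entry.smiles_canonical)
        if mol is None:
            failures.append((entry.id, f"invalid SMILES: {entry.smiles_canonical!r}"))
            continue
        for n in names:
            col, func, fmt = _DESCRIPTORS[n]
            project.set_property(entry.id, col, fmt(func(mol)))
    for n in names:
        project.descriptor_columns.add(DESCRIPTOR_COLUMNS[n])
    return failures
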