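"""Thin RDKit wrappers shared across the package.

All structure handling goes through RDKit; these helpers centralise the
parse-or-raise convention and silence RDKit's per-molecule logging so batch
imports report failures through return values instead of stderr noise.
"""

from __future__ import annotations

from rdkit import Chem, RDLogger

from .errors import InvalidSmilesError

RDLogger.DisableLog("rdApp.*")


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse ``smiles`` or raise :class:`InvalidSmilesError`."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmilesError(smiles if isinstance(smiles, str) else repr(smiles), "empty")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical spelling of the molecular graph encoded by ``smiles``."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def try_mol(smiles: str) -> Chem.Mol | None:
    """Parse ``smiles``, returning ``None`` instead of raising."""
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles)
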