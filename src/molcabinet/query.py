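"""Property and structural queries over a project.

Property queries combine any number of single-column filters conjunctively;
eight comparators are supported: the four numeric order comparisons
(``GE``/``GT``/``LT``/``LE``), exact string match (``EQ``/``NE``), and
case-sensitive substring containment (``CONTAINS``/``NOT_CONTAINS``).
Numeric comparators parse both the cell and the reference as decimal
numbers, and evaluate to False if either fails to parse — mixed
string/number columns are the norm, so a parse failure is a non-match, not
an error.  An absent cell is False for every comparator except ``NE`` and
``NOT_CONTAINS`` (absence differs from any value).

Structural queries filter by substructure, superstructure, or Morgan
fingerprint Tanimoto similarity, the query entered as a SMILES string.
Both query and target are perceived with the same aromaticity model, so an
aromatic query matches aromatic targets consistently.

Every query returns a *new* project; the source is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit.Chem import rdFingerprintGenerator

from .chem import mol_from_smiles, try_mol
from .errors import MolCabinetError, UnknownColumnError
from .project import MoleculeEntry, Project

COMPARATORS = ("GE", "GT", "LT", "LE", "EQ", "NE", "CONTAINS", "NOT_CONTAINS")
_NUMERIC = {"GE", "GT", "LT", "LE"}

STRUCTURAL_MODES = ("substructure", "superstructure", "similarity")

#: Fingerprint settings backing the similarity mode: hashed circular
#: (Morgan) environments of radius 2 folded to 2048 bits.
FP_RADIUS = 2
FP_BITS = 2048

#: Column added to similarity-query results (4-decimal coefficient).
SIMILARITY_COLUMN = "Similarity"

DEFAULT_SIMILARITY_THRESHOLD = 0.7


@dataclass(frozen=True)
class PropertyFilter:
    column: str
    comparator: str
    reference: str

    def __post_init__(self):
        if self.comparator not in COMPARATORS:
            raise MolCabinetError(
                f"unknown comparator {self.comparator!r}; choose from {', '.join(COMPARATORS)}"
            )


@dataclass(frozen=True)
class QuerySpec:
    """A conjunction of property filters (all must hold)."""

    filters: tuple[PropertyFilter, ...]

    def __init__(self, filters):
        object.__setattr__(self, "filters", tuple(filters))
        if not self.filters:
            raise MolCabinetError("a query needs at least one filter")


@dataclass(frozen=True)
class StructuralQuery:
    mode: str
    query_smiles: str
    threshold: float | None = None

    def __post_init__(self):
        if self.mode not in STRUCTURAL_MODES:
            raise MolCabinetError(f"unknown structural mode {self.mode!r}")
        if self.mode == "similarity":
            if self.threshold is None:
                object.__setattr__(self, "threshold", DEFAULT_SIMILARITY_THRESHOLD)
            if not 0.0 <= self.threshold <= 1.0:
                raise MolCabinetError("similarity threshold must lie in [0, 1]")
        elif self.threshold is not None:
            raise MolCabinetError(f"threshold only applies to similarity mode, not {self.mode}")
        mol_from_smiles(self.query_smiles)  # must parse


def _cell(entry: MoleculeEntry, column: str) -> str | None:
    if column == "ID":
        return entry.id
    if column == "SMILES":
        return entry.smiles_canonical
    return entry.properties.get(column)


def match_filter(entry: MoleculeEntry, flt: PropertyFilter) -> bool:
    """Evaluate one filter against one entry (see module rules)."""
    cell = _cell(entry, flt.column)
    if cell is None:
        return flt.comparator in ("NE", "NOT_CONTAINS")
    if flt.comparator in _NUMERIC:
        try:
            value, ref = float(cell), float(flt.reference)
        except ValueError:
            return False
        return {
            "GE": value >= ref,
            "GT": value > ref,
            "LT": value < ref,
            "LE": value <= ref,
        }[flt.comparator]
    if flt.comparator == "EQ":
        return cell == flt.reference
    if flt.comparator == "NE":
        return cell != flt.reference
    if flt.comparator == "CONTAINS":
        return flt.reference in cell
    return flt.reference not in cell  # NOT_CONTAINS


def apply_property_query(project: Project, spec: QuerySpec) -> Project:
    """New project holding exactly the entries that satisfy every filter.

    Order, schema, highlights and attachment references are preserved;
    the source project is untouched.
    """
    known = {"ID", "SMILES", *project.schema}
    for flt in spec.filters:
        if flt.column not in known:
            raise UnknownColumnError(flt.column)
    result = Project(project.name, path=None)
    result.schema = list(project.schema)
    result.descriptor_columns = set(project.descriptor_columns)
    for entry in project.entries:
        if all(match_filter(entry, f) for f in spec.filters):
            result.entries.append(entry.copy())
    result._rebuild_index()
    return result


# ---------------------------------------------------------------------------
# fingerprints and similarity
# ---------------------------------------------------------------------------

_fp_generator = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


def fingerprint(smiles: str):
    """2048-bit Morgan (radius 2) fingerprint of the molecular graph.

    Deterministic, and identical for all spellings of the same graph.
    """
    return _fp_generator.GetFingerprint(mol_from_smiles(smiles))


def tanimoto(a, b) -> float:
    """|a∧b| / |a∨b| over equal-length bit sets; 1.0 when both are empty."""
    if len(a) != len(b):
        raise MolCabinetError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    union = (a | b).GetNumOnBits()
    if union == 0:
        return 1.0
    return (a & b).GetNumOnBits() / union


def apply_structural_query(project: Project, query: StructuralQuery) -> tuple[Project, list[tuple[str, str]]]:
    """Filter the project by structure; returns ``(result, skipped)``.

    * substructure — keep entries whose graph contains the query as a
      subgraph;
    * superstructure — keep entries whose graph is contained in the query;
    * similarity — keep entries whose Tanimoto coefficient against the
      query fingerprint reaches the threshold, and add a ``Similarity``
      column (4 decimals) to the result.

    Entries whose stored SMILES fails to parse are skipped and returned as
    ``(id, reason)`` pairs. The source project is never mutated.
    """
    qmol = mol_from_smiles(query.query_smiles)
    qfp = _fp_generator.GetFingerprint(qmol) if query.mode == "similarity" else None

    result = Project(project.name, path=None)
    result.schema = list(project.schema)
    result.descriptor_columns = set(project.descriptor_columns)
    skipped: list[tuple[str, str]] = []
    for entry in project.entries:
        mol = try_mol(entry.smiles_canonical)
        if mol is None:
            skipped.append((entry.id, f"invalid SMILES: {entry.smiles_canonical!r}"))
            continue
        if query.mode == "substructure":
            keep = mol.HasSubstructMatch(qmol)
        elif query.mode == "superstructure":
            keep = qmol.HasSubstructMatch(mol)
        else:
            sim = tanimoto(_fp_generator.GetFingerprint(mol), qfp)
            keep = sim >= query.threshold
        if keep:
            kept = entry.copy()
            if query.mode == "similarity":
                kept.properties[SIMILARITY_COLUMN] = f"{sim:.4f}"
            result.entries.append(kept)
    if query.mode == "similarity" and SIMILARITY_COLUMN not in result.schema:
        result.schema.append(SIMILARITY_COLUMN)
    result._rebuild_index()
    return result, skipped
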