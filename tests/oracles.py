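"""Independent brute-force oracles used to cross-check the implementation.

Nothing in here calls the code path it checks: the CAS check digit is
recomputed from its definition with an explicit loop, molecular weight is
re-derived by parsing the Hill formula string against a local atomic-mass
table, substructure decisions come from a networkx subgraph-monomorphism
search over element/bond-labelled graphs, and property filters are
re-evaluated by a straightforward row scan.
"""

from __future__ import annotations

import re

import networkx as nx
from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match
from rdkit import Chem

# ---------------------------------------------------------------------------
# CAS check digit
# ---------------------------------------------------------------------------


def cas_check_digit(digits: str) -> int:
    """Check digit for the digits preceding it, per the registry rule:
    weight each digit by its position counted right-to-left (1, 2, 3, ...),
    sum, take mod 10."""
    total = 0
    position = 1
    for ch in reversed(digits):
        total += position * int(ch)
        position += 1
    return total % 10


def random_cas(rng, valid: bool) -> str:
    """A random CAS-shaped string with a correct or perturbed check digit."""
    body = str(rng.randint(10, 9999999))
    suffix = f"{rng.randint(0, 99):02d}"
    check = cas_check_digit(body + suffix)
    if not valid:
        check = (check + rng.randint(1, 9)) % 10
    return f"{body}-{suffix}-{check}"


# ---------------------------------------------------------------------------
# molecular weight from a Hill formula string
# ---------------------------------------------------------------------------

# Standard average atomic masses (IUPAC 2005) for the fixture elements.
ATOMIC_MASSES = {
    "C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999,
    "S": 32.065, "F": 18.998, "Cl": 35.453, "Br": 79.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if not m.group(1):
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def mw_from_formula(formula: str) -> float:
    return sum(ATOMIC_MASSES[el] * n for el, n in parse_formula(formula).items())


# ---------------------------------------------------------------------------
# substructure via networkx subgraph monomorphism
# ---------------------------------------------------------------------------


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(
            atom.GetIdx(),
            z=atom.GetAtomicNum(),
            aromatic=atom.GetIsAromatic(),
            charge=atom.GetFormalCharge(),
        )
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=str(bond.GetBondType()))
    return g


_node_match = categorical_node_match(["z", "aromatic", "charge"], [0, False, 0])


def _edge_match(e1, e2):
    return e1["order"] == e2["order"]


def brute_has_substructure(target: Chem.Mol, query: Chem.Mol) -> bool:
    """True iff ``query`` maps into ``target`` as a subgraph monomorphism
    with matching element/aromaticity/charge labels and bond orders."""
    matcher = GraphMatcher(
        mol_graph(target), mol_graph(query), node_match=_node_match, edge_match=_edge_match
    )
    return matcher.subgraph_is_monomorphic()


# ---------------------------------------------------------------------------
# property-filter row scan
# ---------------------------------------------------------------------------


def brute_match(cell: str | None, comparator: str, reference: str) -> bool:
    """Straightforward re-statement of the filter semantics."""
    if cell is None:
        return comparator in ("NE", "NOT_CONTAINS")
    if comparator in ("GE", "GT", "LT", "LE"):
        try:
            v = float(cell)
            r = float(reference)
        except ValueError:
            return False
        if comparator == "GE":
            return v >= r
        if comparator == "GT":
            return v > r
        if comparator == "LT":
            return v < r
        return v <= r
    if comparator == "EQ":
        return cell == reference
    if comparator == "NE":
        return cell != reference
    if comparator == "CONTAINS":
        return reference in cell
    if comparator == "NOT_CONTAINS":
        return reference not in cell
    raise ValueError(comparator)


def brute_property_query(rows: list[dict], filters: list[tuple[str, str, str]]) -> list[str]:
    """Row-scan evaluation; ``rows`` are dicts with 'ID', 'SMILES', and
    property keys (missing key = absent cell). Returns matching IDs."""
    out = []
    for row in rows:
        if all(brute_match(row.get(col), cmp_, ref) for col, cmp_, ref in filters):
            out.append(row["ID"])
    return out
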