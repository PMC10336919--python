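"""Property and structural queries against independent brute-force oracles."""

import json
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molcabinet import (
    FixtureSpec,
    MolCabinetError,
    PropertyFilter,
    QuerySpec,
    StructuralQuery,
    UnknownColumnError,
    apply_property_query,
    apply_structural_query,
    compute_project_properties,
    fingerprint,
    generate_library,
    library_to_project,
    match_filter,
    tanimoto,
)
from molcabinet.project import MoleculeEntry, Project
from molcabinet.query import SIMILARITY_COLUMN

from oracles import brute_has_substructure, brute_match, brute_property_query


def entry(props=None, eid="e1", smiles="CCO"):
    return MoleculeEntry(id=eid, smiles_input=smiles, smiles_canonical=smiles,
                         properties=props or {})


class TestMatchFilter:
    @pytest.mark.parametrize("cell,comparator,reference,expected", [
        ("350.20", "GE", "300", True),       # numeric at-least
        ("C20H18N2O3", "CONTAINS", "N", True),
        ("n/a", "LE", "2.0", False),         # unparsable cell -> False
        ("300", "GE", "n/a", False),         # unparsable reference -> False
        ("1.5", "LE", "2.0", True),
        ("2.5", "LT", "2.5", False),
        ("abc", "EQ", "abc", True),
        ("abc", "NE", "abc", False),
        ("Formula", "NOT_CONTAINS", "x", True),
        ("aBc", "CONTAINS", "b", False),     # case-sensitive
    ])
    def test_comparator_semantics(self, cell, comparator, reference, expected):
        e = entry({"P": cell})
        assert match_filter(e, PropertyFilter("P", comparator, reference)) is expected

    @pytest.mark.parametrize("comparator,expected", [
        ("GE", False), ("GT", False), ("LT", False), ("LE", False),
        ("EQ", False), ("NE", True), ("CONTAINS", False), ("NOT_CONTAINS", True),
    ])
    def test_absent_cell_rules(self, comparator, expected):
        assert match_filter(entry({}), PropertyFilter("P", comparator, "x")) is expected

    def test_id_and_smiles_pseudo_columns(self):
        e = entry(eid="mol7", smiles="c1ccccc1")
        assert match_filter(e, PropertyFilter("ID", "CONTAINS", "7"))
        assert match_filter(e, PropertyFilter("SMILES", "EQ", "c1ccccc1"))

    def test_unknown_comparator_rejected(self):
        with pytest.raises(MolCabinetError):
            PropertyFilter("P", "LIKE", "x")


class TestPropertyQuery:
    @pytest.fixture
    def toy(self):
        p = Project("toy")
        p.add_molecule("A", "CCO", {"MW": "350.2", "LogP": "1.5", "Formula": "C20H18N2O3"})
        p.add_molecule("B", "CCC", {"MW": "250.0", "LogP": "1.0", "Formula": "C15H14O4"})
        p.add_molecule("C", "CCN", {"MW": "410.5", "LogP": "3.2", "Formula": "C25H22N2O2"})
        return p

    def test_conjunction_mw_logp_formula(self, toy):
        """MW >= 300 and LogP <= 2.0 and formula contains N selects only A."""
        spec = QuerySpec([
            PropertyFilter("MW", "GE", "300"),
            PropertyFilter("LogP", "LE", "2.0"),
            PropertyFilter("Formula", "CONTAINS", "N"),
        ])
        assert apply_property_query(toy, spec).ids() == ["A"]

    def test_empty_result_is_valid_project(self, toy):
        out = apply_property_query(toy, QuerySpec([PropertyFilter("MW", "GE", "9999")]))
        assert out.ids() == [] and out.schema == toy.schema

    def test_always_true_filter_copies_project(self, toy):
        out = apply_property_query(toy, QuerySpec([PropertyFilter("MW", "NE", "never-a-value")]))
        assert out.ids() == toy.ids()

    def test_unknown_column_named(self, toy):
        with pytest.raises(UnknownColumnError, match="Ghost"):
            apply_property_query(toy, QuerySpec([PropertyFilter("Ghost", "EQ", "1")]))

    def test_source_project_not_mutated(self, toy):
        snapshot = json.dumps(toy.to_dict(), sort_keys=True)
        apply_property_query(toy, QuerySpec([PropertyFilter("MW", "GE", "300")]))
        assert json.dumps(toy.to_dict(), sort_keys=True) == snapshot

    def test_agrees_with_brute_force_row_scan(self):
        """Random query specs over a descriptor-annotated library agree 100%
        with an independent straightforward row-scan implementation."""
        library = generate_library(FixtureSpec(n=300, seed=7))
        project = library_to_project(library, "oracle")
        compute_project_properties(project, ["molecular_weight", "logp", "molecular_formula"])
        rows = [{"ID": e.id, "SMILES": e.smiles_canonical, **e.properties}
                for e in project.entries]
        columns = ["ID", "SMILES", *project.schema]
        comparators = ["GE", "GT", "LT", "LE", "EQ", "NE", "CONTAINS", "NOT_CONTAINS"]
        rng = random.Random(99)
        for _ in range(100):
            filters = [
                (rng.choice(columns), rng.choice(comparators),
                 rng.choice(["300", "2.0", "N", "benzene", "MOL00", "1.5", "xyz", "c1"]))
                for _ in range(rng.randint(1, 3))
            ]
            spec = QuerySpec([PropertyFilter(*f) for f in filters])
            assert apply_property_query(project, spec).ids() == \
                   brute_property_query(rows, filters)


class TestFingerprintAndTanimoto:
    def test_spelling_invariant(self):
        assert list(fingerprint("CCO")) == list(fingerprint("OCC"))

    def test_distinct_molecules_differ(self):
        assert list(fingerprint("CCO")) != list(fingerprint("c1ccccc1"))

    def test_any_molecule_sets_bits(self, small_library):
        for m in small_library[:30]:
            assert fingerprint(m.smiles).GetNumOnBits() > 0

    def test_identity_and_disjoint(self):
        x = fingerprint("O=c1ccc2ccccc2o1")
        assert tanimoto(x, x) == 1.0
        from rdkit.DataStructs import ExplicitBitVect
        a, b = ExplicitBitVect(8), ExplicitBitVect(8)
        a.SetBit(0); a.SetBit(1)
        b.SetBit(5)
        assert tanimoto(a, b) == 0.0
        assert tanimoto(ExplicitBitVect(8), ExplicitBitVect(8)) == 1.0

    def test_direct_count_example(self):
        from rdkit.DataStructs import ExplicitBitVect
        a, b = ExplicitBitVect(3), ExplicitBitVect(3)
        a.SetBit(0); a.SetBit(1)          # 110
        b.SetBit(1); b.SetBit(2)          # 011
        assert tanimoto(a, b) == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        from rdkit.DataStructs import ExplicitBitVect
        with pytest.raises(MolCabinetError):
            tanimoto(ExplicitBitVect(8), ExplicitBitVect(16))

    def test_agrees_with_rdkit_similarity(self, small_library):
        # cross-check the hand-computed coefficient against RDKit's
        from rdkit.DataStructs import TanimotoSimilarity
        fps = [fingerprint(m.smiles) for m in small_library[:20]]
        for i in range(len(fps)):
            for j in range(i, len(fps)):
                assert tanimoto(fps[i], fps[j]) == pytest.approx(
                    TanimotoSimilarity(fps[i], fps[j]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_symmetry_bounds_and_identity_property(self, data):
        from rdkit.DataStructs import ExplicitBitVect
        n = 64
        bits_a = data.draw(st.sets(st.integers(0, n - 1)))
        bits_b = data.draw(st.sets(st.integers(0, n - 1)))
        a, b = ExplicitBitVect(n), ExplicitBitVect(n)
        for i in bits_a:
            a.SetBit(i)
        for i in bits_b:
            b.SetBit(i)
        t = tanimoto(a, b)
        assert 0.0 <= t <= 1.0
        assert t == tanimoto(b, a)
        assert (t == 1.0) == (bits_a == bits_b)


COUMARIN = "O=c1ccc2ccccc2o1"


class TestStructuralQuery:
    def test_coumarin_substructure_finds_exactly_planted(self, small_library, small_project):
        result, skipped = apply_structural_query(
            small_project, StructuralQuery("substructure", COUMARIN))
        assert skipped == []
        expected = {m.id for m in small_library if m.has_coumarin}
        assert set(result.ids()) == expected
        assert len(expected) == 20

    def test_substructure_agrees_with_subgraph_oracle(self, small_library):
        from molcabinet.chem import mol_from_smiles
        qmol = mol_from_smiles(COUMARIN)
        project = library_to_project(small_library, "x")
        result, _ = apply_structural_query(project, StructuralQuery("substructure", COUMARIN))
        hits = set(result.ids())
        for m in small_library:
            mol = mol_from_smiles(m.smiles)
            assert (m.id in hits) == brute_has_substructure(mol, qmol), m.smiles

    def test_superstructure_toluene_keeps_benzene(self):
        p = Project("s")
        p.add_molecule("benzene", "c1ccccc1")
        p.add_molecule("naphthalene", "c1ccc2ccccc2c1")
        result, _ = apply_structural_query(p, StructuralQuery("superstructure", "Cc1ccccc1"))
        assert result.ids() == ["benzene"]

    def test_substructure_superstructure_duality(self, small_library):
        probes = [m.smiles for m in small_library[:8]]
        targets = [m.smiles for m in small_library[8:16]]
        for q in probes:
            p = Project("d")
            for i, t in enumerate(targets):
                p.add_molecule(f"t{i}", t)
            sub, _ = apply_structural_query(p, StructuralQuery("substructure", q))
            # E matches substructure query Q  <=>  Q matches superstructure query E
            for i, t in enumerate(targets):
                single = Project("one")
                single.add_molecule("q", q)
                sup, _ = apply_structural_query(single, StructuralQuery("superstructure", t))
                assert (f"t{i}" in sub.ids()) == (len(sup) == 1)

    def test_similarity_threshold_zero_returns_all(self, small_project):
        result, _ = apply_structural_query(
            small_project, StructuralQuery("similarity", COUMARIN, threshold=0.0))
        assert result.ids() == small_project.ids()
        assert SIMILARITY_COLUMN in result.schema
        for e in result.entries:
            v = float(e.properties[SIMILARITY_COLUMN])
            assert 0.0 <= v <= 1.0

    def test_similarity_threshold_filters(self, small_project):
        hi, _ = apply_structural_query(
            small_project, StructuralQuery("similarity", COUMARIN, threshold=0.5))
        lo, _ = apply_structural_query(
            small_project, StructuralQuery("similarity", COUMARIN, threshold=0.1))
        assert set(hi.ids()) <= set(lo.ids())

    def test_unparsable_entry_skipped_and_reported(self, small_project):
        small_project.entries[0].smiles_canonical = "broken("
        result, skipped = apply_structural_query(
            small_project, StructuralQuery("substructure", "C"))
        assert skipped == [(small_project.entries[0].id,
                            "invalid SMILES: 'broken('")]
        assert small_project.entries[0].id not in result.ids()

    def test_threshold_only_valid_for_similarity(self):
        with pytest.raises(MolCabinetError):
            StructuralQuery("substructure", "CCO", threshold=0.5)
        with pytest.raises(MolCabinetError):
            StructuralQuery("similarity", "CCO", threshold=1.5)

    def test_invalid_query_smiles(self):
        with pytest.raises(MolCabinetError):
            StructuralQuery("substructure", "C1CC")

    def test_source_untouched_by_structural_query(self, small_project):
        snapshot = json.dumps(small_project.to_dict(), sort_keys=True)
        apply_structural_query(small_project, StructuralQuery("similarity", COUMARIN, threshold=0.3))
        assert json.dumps(small_project.to_dict(), sort_keys=True) == snapshot
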