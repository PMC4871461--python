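"""Presence/absence inference, propagation, matrix assembly, conflict
detection, and NEXUS export."""

import numpy as np
import pytest

from phenomic.annotations import (
    AnnotationCorpus,
    EntityExpression,
    EQStatement,
    SourceKind,
)
from phenomic.ontology import BOTH_RELATIONS, RelationKind
from phenomic.supermatrix import (
    AssertionOrigin,
    CellState,
    ConflictSeverity,
    PresenceAssertion,
    build_supermatrix,
    direct_assertions,
    find_conflicts,
    propagate,
    write_nexus,
)

from conftest import FIN_LIMB_ROOTS, brute_force_closure, build_graph, random_dag


def _stmt(i, entity, quality, kind=SourceKind.MATRIX, taxon="Panderichthys",
          source="matr01", related=None):
    return EQStatement(
        statement_id=f"s{i}",
        taxon=taxon,
        entity=entity,
        quality=quality,
        related_entity=related,
        source_id=source,
        source_kind=kind,
    )


def _assertion(taxon, entity, state, origin=AssertionOrigin.ASSERTED,
               source="src", stmt="s1", chain=()):
    return PresenceAssertion(
        taxon=taxon, entity=entity, state=state, origin=origin,
        source_id=source, statement_id=stmt, chain=chain,
    )


class TestDirectAssertions:
    def test_size_quality_implies_presence(self, fin_limb_graph, quality_graph):
        # 'postaxial process of fibula', quality 'decreased size'
        corpus = AnnotationCorpus(
            "matr01", SourceKind.MATRIX,
            [_stmt(1, EntityExpression(core="UBERON:4200132"), "PATO:0000587")],
        )
        (a,) = direct_assertions(
            corpus, fin_limb_graph, quality_graph, FIN_LIMB_ROOTS
        )
        assert a.state is CellState.PRESENT
        assert a.origin is AssertionOrigin.IMPLIED_BY_QUALITY
        assert a.entity == "UBERON:4200132"

    def test_absent_quality_asserts_absence_of_core(self, fin_limb_graph, quality_graph):
        corpus = AnnotationCorpus(
            "matr01", SourceKind.MATRIX,
            [_stmt(1, EntityExpression(core="UBERON:4200022"), "PATO:0000462",
                   taxon="Acanthostega")],
        )
        (a,) = direct_assertions(
            corpus, fin_limb_graph, quality_graph, FIN_LIMB_ROOTS
        )
        assert a.state is CellState.ABSENT
        assert a.origin is AssertionOrigin.ASSERTED
        assert a.entity == "UBERON:4200022"  # scapular blade

    def test_generalized_core_yields_assertion_for_filler_only(
        self, fin_limb_graph, quality_graph
    ):
        entity = EntityExpression(
            core="UBERON:0004529",  # anatomical projection (generalized)
            differentia=(
                (RelationKind.PART_OF, EntityExpression(core="UBERON:0004753")),
            ),
        )
        corpus = AnnotationCorpus(
            "matr01", SourceKind.MATRIX,
            [_stmt(1, entity, "PATO:0000052")],
        )
        assertions = direct_assertions(
            corpus, fin_limb_graph, quality_graph, FIN_LIMB_ROOTS
        )
        assert {a.entity for a in assertions} == {"UBERON:0004753"}

    def test_no_statement_yields_nothing(self, fin_limb_graph, quality_graph):
        corpus = AnnotationCorpus("matr01", SourceKind.MATRIX, [])
        assert direct_assertions(
            corpus, fin_limb_graph, quality_graph, FIN_LIMB_ROOTS
        ) == []


class TestPropagate:
    def _digit_limb(self):
        return build_graph(
            [("digit", "digit"), ("limb", "limb")],
            [("digit", RelationKind.PART_OF, "limb")],
        )

    def test_presence_propagates_up(self):
        g = self._digit_limb()
        out = propagate(g, [_assertion("t", "digit", CellState.PRESENT)])
        states = {(a.entity, a.state) for a in out}
        assert ("limb", CellState.PRESENT) in states

    def test_absence_propagates_down(self):
        g = self._digit_limb()
        out = propagate(g, [_assertion("t", "limb", CellState.ABSENT)])
        states = {(a.entity, a.state) for a in out}
        assert ("digit", CellState.ABSENT) in states

    def test_propagated_carries_chain(self):
        g = self._digit_limb()
        out = propagate(g, [_assertion("t", "digit", CellState.PRESENT)])
        prop = [a for a in out if a.origin is AssertionOrigin.PROPAGATED]
        assert prop[0].chain == ("digit", "limb")

    @pytest.mark.parametrize("seed", range(20))
    def test_closure_exactness_on_random_dags(self, seed):
        """Propagated PRESENT is exactly the upward closure and ABSENT
        exactly the downward closure of the inputs."""
        rng = np.random.default_rng(3000 + seed)
        g, edges = random_dag(rng, int(rng.integers(5, 41)))
        nodes = sorted(g.terms)
        picks = rng.choice(nodes, size=min(4, len(nodes)), replace=False)
        inputs = [
            _assertion(
                "t", str(p),
                CellState.PRESENT if i % 2 == 0 else CellState.ABSENT,
            )
            for i, p in enumerate(picks)
        ]
        out = propagate(g, inputs)
        present = {a.entity for a in out if a.state is CellState.PRESENT}
        absent = {a.entity for a in out if a.state is CellState.ABSENT}
        exp_present, exp_absent = set(), set()
        for a in inputs:
            closure = brute_force_closure(
                edges, a.entity, BOTH_RELATIONS,
                reverse=(a.state is CellState.ABSENT),
            )
            if a.state is CellState.PRESENT:
                exp_present |= {a.entity} | closure
            else:
                exp_absent |= {a.entity} | closure
        assert present == exp_present
        assert absent == exp_absent


class TestBuildMatrix:
    def test_cell_rules(self):
        present = _assertion("t1", "e1", CellState.PRESENT, source="mono01")
        absent = _assertion("t1", "e1", CellState.ABSENT, source="matr01")
        m = build_supermatrix([[present], [absent]], ["t1", "t2"], ["e1", "e2"])
        assert m.state("t1", "e1") is CellState.POLYMORPHIC
        assert m.state("t2", "e2") is CellState.UNKNOWN
        assert len(m.provenance[("t1", "e1")]) == 2

    def test_single_present_support(self):
        m = build_supermatrix(
            [[_assertion("t1", "e1", CellState.PRESENT)]], ["t1"], ["e1"]
        )
        assert m.state("t1", "e1") is CellState.PRESENT
        assert len(m.provenance[("t1", "e1")]) == 1

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_supermatrix([], ["t1", "t1"], ["e1"])


class TestConflicts:
    def test_scapular_blade_fixture(self, fin_limb_graph, quality_graph):
        """A matrix absence against a monograph statement implying
        presence yields exactly one conflict at the scapular blade."""
        blade = "UBERON:4200022"
        matrix = AnnotationCorpus(
            "matr01", SourceKind.MATRIX,
            [_stmt(1, EntityExpression(core=blade), "PATO:0000462",
                   taxon="Acanthostega")],
        )
        monograph = AnnotationCorpus(
            "mono01", SourceKind.MONOGRAPH,
            [_stmt(1, EntityExpression(core=blade), "PATO:0000141",
                   kind=SourceKind.MONOGRAPH, taxon="Acanthostega",
                   source="mono01")],
        )
        collections = [
            propagate(
                fin_limb_graph,
                direct_assertions(c, fin_limb_graph, quality_graph, FIN_LIMB_ROOTS),
            )
            for c in (matrix, monograph)
        ]
        space = fin_limb_graph.class_space(FIN_LIMB_ROOTS)
        m = build_supermatrix(
            collections, ["Acanthostega"],
            sorted(t for t in space if not fin_limb_graph.term(t).generalized),
        )
        conflicts = find_conflicts(m)
        assert len(conflicts) == 1
        c = conflicts[0]
        assert (c.taxon, c.entity) == ("Acanthostega", blade)
        assert c.severity is ConflictSeverity.DIRECT
        assert c.present_support and c.absent_support

    def test_no_absences_no_conflicts(self, fin_limb_graph, quality_graph):
        corpus = AnnotationCorpus(
            "matr01", SourceKind.MATRIX,
            [_stmt(1, EntityExpression(core="UBERON:0001446"), "PATO:0000052")],
        )
        assertions = propagate(
            fin_limb_graph,
            direct_assertions(corpus, fin_limb_graph, quality_graph, FIN_LIMB_ROOTS),
        )
        space = fin_limb_graph.class_space(FIN_LIMB_ROOTS)
        m = build_supermatrix([assertions], ["Panderichthys"], sorted(space))
        assert find_conflicts(m) == []

    def test_propagated_only_conflict_tagged_inferred(self):
        g = build_graph(
            [("a", "a"), ("b", "b"), ("c", "c")],
            [("a", RelationKind.PART_OF, "b"),
             ("b", RelationKind.PART_OF, "c")],
        )
        present = propagate(g, [_assertion("t", "a", CellState.PRESENT)])
        absent = propagate(g, [_assertion("t", "c", CellState.ABSENT)])
        m = build_supermatrix([present, absent], ["t"], ["a", "b", "c"])
        conflicts = {c.entity: c.severity for c in find_conflicts(m)}
        # the middle entity is contradicted only via propagation
        assert conflicts["b"] is ConflictSeverity.INFERRED
        assert conflicts["a"] is ConflictSeverity.MIXED
        assert conflicts["c"] is ConflictSeverity.MIXED


class TestNexus:
    def _tiny_matrix(self):
        cells = {
            ("tax1", "e1"): CellState.PRESENT,
            ("tax1", "e2"): CellState.ABSENT,
            ("tax2", "e1"): CellState.POLYMORPHIC,
        }
        prov = {
            k: (_assertion(k[0], k[1], CellState.PRESENT),) for k in cells
        }
        from phenomic.supermatrix import Supermatrix

        return Supermatrix(
            taxa=("tax1", "tax2"), entities=("e1", "e2"),
            cells=cells, provenance=prov,
        )

    def test_coding_tokens(self, tmp_path):
        path = tmp_path / "m.nex"
        write_nexus(self._tiny_matrix(), path)
        text = path.read_text()
        assert "tax1" in text and "10" in text
        assert "{01}" in text
        assert "?" in text

    def test_single_present_cell(self, tmp_path):
        from phenomic.supermatrix import Supermatrix

        m = Supermatrix(
            taxa=("taxon",), entities=("e1",),
            cells={("taxon", "e1"): CellState.PRESENT},
            provenance={("taxon", "e1"): ()},
        )
        path = tmp_path / "one.nex"
        write_nexus(m, path)
        matrix_lines = [
            ln.strip() for ln in path.read_text().splitlines()
            if ln.strip().startswith("taxon")
        ]
        assert matrix_lines and matrix_lines[0].split() == ["taxon", "1"]

    def test_round_trip_via_independent_parser(self, tmp_path):
        """A generated 5x8 grid re-read by dendropy reproduces every cell."""
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(17)
        taxa = [f"tax{i}" for i in range(5)]
        entities = [f"E:{i:02d}" for i in range(8)]
        states = [
            CellState.PRESENT, CellState.ABSENT,
            CellState.POLYMORPHIC, CellState.UNKNOWN,
        ]
        cells = {}
        prov = {}
        for t in taxa:
            for e in entities:
                s = states[int(rng.integers(len(states)))]
                if s is not CellState.UNKNOWN:
                    cells[(t, e)] = s
                    prov[(t, e)] = (_assertion(t, e, CellState.PRESENT),)
        from phenomic.supermatrix import Supermatrix

        m = Supermatrix(
            taxa=tuple(taxa), entities=tuple(entities),
            cells=cells, provenance=prov,
        )
        path = tmp_path / "grid.nex"
        write_nexus(m, path)

        dm = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus"
        )
        symbol_to_state = {
            "1": CellState.PRESENT, "0": CellState.ABSENT,
            "?": CellState.UNKNOWN,
        }
        for taxon in dm.taxon_namespace:
            for j, cell in enumerate(dm[taxon]):
                entity = sorted(entities)[j]
                expected = m.state(taxon.label, entity)
                symbol = str(cell)
                if symbol in symbol_to_state:
                    assert symbol_to_state[symbol] is expected
                else:
                    members = {str(s.symbol) for s in cell.member_states}
                    assert members == {"0", "1"}
                    assert expected is CellState.POLYMORPHIC

    def test_empty_matrix_rejected(self, tmp_path):
        from phenomic.supermatrix import Supermatrix

        m = Supermatrix(taxa=(), entities=(), cells={}, provenance={})
        with pytest.raises(ValueError):
            write_nexus(m, tmp_path / "x.nex")
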