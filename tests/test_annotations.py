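"""EQ statements: expression grammar, complexity scoring, quality
classification, and corpus TSV round-trips."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from phenomic.annotations import (
    AnnotationCorpus,
    CorpusFormatError,
    DEFAULT_ANCHORS,
    EntityExpression,
    EQStatement,
    ExpressionParseError,
    QualityClass,
    SourceKind,
    classify_quality,
    eq_complexity,
    parse_entity_expression,
    read_corpus_tsv,
    serialize_entity_expression,
    write_corpus_tsv,
)
from phenomic.ontology import RelationKind


def _eq(entity, quality="PATO:0000462", related=None, kind=SourceKind.MONOGRAPH):
    return EQStatement(
        statement_id="s1",
        taxon="TAX:0001",
        entity=entity,
        quality=quality,
        related_entity=related,
        source_id="pub1",
        source_kind=kind,
    )


class TestExpressionGrammar:
    def test_bare_curie(self):
        expr = parse_entity_expression("UBERON:0000970")
        assert expr == EntityExpression(core="UBERON:0000970")
        assert (expr.n_terms, expr.n_relations) == (1, 0)

    def test_post_composed_label_expression(self, fin_limb_graph):
        expr = parse_entity_expression(
            "'proximal region' part_of some ('pectoral fin lepidotrichium')",
            fin_limb_graph,
        )
        assert expr.core == "BSPO:0000077"
        assert len(expr.differentia) == 1
        rel, sub = expr.differentia[0]
        assert rel is RelationKind.PART_OF
        assert sub.core == "UBERON:4000175"

    def test_depth_three_chain_counts(self):
        expr = parse_entity_expression("A part_of (B part_of (C))")
        assert expr.n_terms == 3
        assert expr.n_relations == 2

    def test_unbalanced_parentheses_position(self):
        with pytest.raises(ExpressionParseError, match="position"):
            parse_entity_expression("A part_of (B")

    def test_ambiguous_label_lists_candidates(self):
        from conftest import build_graph

        g = build_graph([("X:1", "blade"), ("X:2", "blade")], [])
        with pytest.raises(ExpressionParseError, match="X:1.*X:2"):
            parse_entity_expression("'blade'", g)

    def test_lenient_mode_flags_unresolved(self, fin_limb_graph):
        expr = parse_entity_expression(
            "'no such bone'", fin_limb_graph, strict=False
        )
        assert expr.unresolved_terms() == {"UNRESOLVED:no such bone"}
        with pytest.raises(ExpressionParseError):
            parse_entity_expression("'no such bone'", fin_limb_graph)

    @given(
        st.recursive(
            st.from_regex(r"[A-Z]+:[0-9]{4}", fullmatch=True).map(
                lambda c: EntityExpression(core=c)
            ),
            lambda children: st.builds(
                EntityExpression,
                core=st.from_regex(r"[A-Z]+:[0-9]{4}", fullmatch=True),
                differentia=st.lists(
                    st.tuples(st.sampled_from(list(RelationKind)), children),
                    max_size=3,
                ).map(tuple),
            ),
            max_leaves=8,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_serialize_parse_round_trip(self, expr):
        assert parse_entity_expression(serialize_entity_expression(expr)) == expr


class TestComplexity:
    def test_minimal_statement_scores_two(self, fin_limb_graph):
        entity = parse_entity_expression("'opercle'", fin_limb_graph)
        assert eq_complexity(_eq(entity)) == 2

    def test_post_composed_with_related_entity_scores_seven(self, fin_limb_graph):
        entity = parse_entity_expression(
            "'anatomical projection' part_of some "
            "('dorsal surface' part_of some ('scapulocoracoid'))",
            fin_limb_graph,
        )
        related = parse_entity_expression("'cleithrum'", fin_limb_graph)
        stmt = _eq(entity, quality="PATO:0001667", related=related)
        assert eq_complexity(stmt) == 7

    def test_post_composed_pair_scores_four(self, fin_limb_graph):
        entity = parse_entity_expression(
            "'proximal region' part_of ('pectoral fin lepidotrichium')",
            fin_limb_graph,
        )
        assert eq_complexity(_eq(entity)) == 4

    def test_equals_token_counting_oracle(self):
        """Complexity equals term tokens + relation tokens in the
        serialised statement, + 1 for the quality."""
        entity = parse_entity_expression("A:1 part_of (B:2 part_of (C:3))")
        related = parse_entity_expression("D:4 part_of (E:5)")
        stmt = _eq(entity, related=related)
        text = " ".join(
            serialize_entity_expression(x) for x in (entity, related)
        )
        tokens = re.findall(r"[A-Z]+:\d+|part_of|is_a", text)
        assert eq_complexity(stmt) == len(tokens) + 1

    @given(st.integers(min_value=1, max_value=6), st.booleans())
    @settings(max_examples=30, deadline=None)
    def test_minimum_is_two(self, depth, with_re):
        expr = EntityExpression(core="X:0")
        for i in range(depth - 1):
            expr = EntityExpression(
                core=f"X:{i + 1}",
                differentia=((RelationKind.PART_OF, expr),),
            )
        stmt = _eq(
            expr, related=EntityExpression(core="Y:0") if with_re else None
        )
        assert eq_complexity(stmt) >= 2


class TestQualityClassification:
    @pytest.mark.parametrize(
        "quality,expected",
        [
            ("PATO:0000462", QualityClass.NEOMORPHIC),   # absent
            ("PATO:0000467", QualityClass.NEOMORPHIC),   # present
            ("PATO:0000052", QualityClass.MORPHOLOGY),   # shape
            ("PATO:0000587", QualityClass.MORPHOLOGY),   # decreased size
            ("PATO:0000133", QualityClass.POSITION),     # orientation
            ("PATO:0000070", QualityClass.NUMBER),       # amount itself
            ("PATO:0000470", QualityClass.NUMBER),       # increased amount
            ("PATO:0001667", QualityClass.MORPHOLOGY),   # attached to
            ("PATO:0000001", QualityClass.OTHER),        # bare quality root
        ],
    )
    def test_classification(self, quality_graph, quality, expected):
        assert classify_quality(quality_graph, quality) is expected

    def test_neomorphic_precedes_number(self, quality_graph):
        """present/absent are subtypes of 'amount'; precedence keeps them
        out of the NUMBER class."""
        assert (
            classify_quality(quality_graph, DEFAULT_ANCHORS.present)
            is QualityClass.NEOMORPHIC
        )

    def test_unknown_quality(self, quality_graph):
        with pytest.raises(KeyError):
            classify_quality(quality_graph, "PATO:9999999")
        assert (
            classify_quality(quality_graph, "PATO:9999999", lenient=True)
            is QualityClass.OTHER
        )

    def test_total_and_single_valued(self, quality_graph):
        for term_id in quality_graph.terms:
            cls = classify_quality(quality_graph, term_id)
            assert isinstance(cls, QualityClass)


class TestCorpusInvariants:
    def test_comparative_only_in_monographs(self):
        with pytest.raises(ValueError, match="comparative"):
            EQStatement(
                statement_id="s1",
                taxon="t",
                entity=EntityExpression(core="X:1"),
                quality="PATO:0000462",
                source_id="m1",
                source_kind=SourceKind.MATRIX,
                comparative=True,
            )

    def test_duplicate_statement_ids_rejected(self):
        s = _eq(EntityExpression(core="X:1"))
        with pytest.raises(ValueError, match="duplicate"):
            AnnotationCorpus("pub1", SourceKind.MONOGRAPH, [s, s])

    def test_statement_count_groups_by_character(self):
        stmts = [
            EQStatement(
                statement_id=f"s{i}", taxon="t",
                entity=EntityExpression(core="X:1"),
                quality="PATO:0000462", source_id="p",
                source_kind=SourceKind.MATRIX,
                character_id=f"c{i // 2}",
            )
            for i in range(4)
        ]
        corpus = AnnotationCorpus("p", SourceKind.MATRIX, stmts)
        assert corpus.n_eqs == 4
        assert corpus.n_statements == 2


class TestCorpusTSV:
    HEADER = (
        "source_id\tsource_kind\tstatement_id\tcharacter_id\ttaxon\t"
        "entity\tquality\trelated_entity\tcomparative\n"
    )

    def test_grouping_by_source(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            self.HEADER
            + "m1\tmonograph\ts1\t\tT1\tX:1\tPATO:0000462\t\t1\n"
            + "x1\tmatrix\ts1\t\tT1\tX:1\tPATO:0000462\t\t0\n"
        )
        corpora = read_corpus_tsv(path)
        assert len(corpora) == 2
        kinds = {c.publication_id: c.source_kind for c in corpora}
        assert kinds == {"m1": SourceKind.MONOGRAPH, "x1": SourceKind.MATRIX}

    def test_empty_related_entity_absent(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            self.HEADER + "m1\tmonograph\ts1\t\tT1\tX:1\tPATO:0000462\t\t0\n"
        )
        (corpus,) = read_corpus_tsv(path)
        assert corpus.statements[0].related_entity is None

    def test_unknown_source_kind_row_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            self.HEADER + "m1\tnovel\ts1\t\tT1\tX:1\tPATO:0000462\t\t0\n"
        )
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_corpus_tsv(path)

    def test_duplicate_statement_id_error(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            self.HEADER
            + "m1\tmonograph\ts1\t\tT1\tX:1\tPATO:0000462\t\t0\n"
            + "m1\tmonograph\ts1\t\tT2\tX:2\tPATO:0000462\t\t0\n"
        )
        with pytest.raises(CorpusFormatError, match="duplicate"):
            read_corpus_tsv(path)

    def test_write_read_round_trip(self, tmp_path):
        from phenomic.simulate import (
            GeneratorConfig, OntologyConfig, generate_study,
        )

        cfg = GeneratorConfig(seed=13, ontology=OntologyConfig(n_terms=40))
        for c in (cfg.monograph, cfg.matrix):
            c.n_publications = 1
            c.statements_mean = 8
        study = generate_study(cfg)
        path = tmp_path / "rt.tsv"
        write_corpus_tsv(study.monograph_corpora, path)
        reread = read_corpus_tsv(path)
        assert len(reread) == len(study.monograph_corpora)
        for before, after in zip(study.monograph_corpora, reread):
            assert after.statements == before.statements
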