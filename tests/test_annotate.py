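"""Semantic mapping layer: annotation graphs and materialized closure."""

import pandas as pd
import pytest
from rdflib import Graph
from rdflib.namespace import OWL

from fairfed import (
    ColumnMetadata,
    MappingError,
    MappingSpec,
    TabularSource,
    build_annotation_graph,
    canonical_nt,
    extract_owl_schema,
    materialize_closure,
    triplify_table,
    validate_mapping,
)
from fairfed.vocab import NCIT, SEX, T_STAGE

T4, T4A, T4B = NCIT["C48732"], NCIT["C48733"], NCIT["C48734"]


@pytest.fixture
def staged_node(vocab):
    """A node coding T stage as {1, 2, 4a, 4b} and sex as {M, F}."""
    frame = pd.DataFrame(
        {
            "pid": ["a", "b", "c", "d", "e"],
            "tcat": ["4a", "4b", "1", "2", "4a"],
            "gender": ["M", "F", "M", "M", "F"],
        }
    )
    source = TabularSource(frame, node_id="STAGED")
    meta = [
        ColumnMetadata("pid", "identifier"),
        ColumnMetadata("tcat", "categorical_ordinal"),
        ColumnMetadata("gender", "categorical_nominal"),
    ]
    spec = MappingSpec(
        node_id="STAGED",
        class_mappings={"tcat": "Tumour stage", "gender": "Sex"},
        value_mappings={
            "tcat": {"4a": "T4a", "4b": "T4b", "1": "T1", "2": "T2"},
            "gender": {"M": "Male", "F": "Female"},
        },
    )
    data = triplify_table(source, meta)
    schema = extract_owl_schema(source, meta)
    return source, meta, spec, data, schema


class TestBuildAnnotation:
    def test_class_mapping_yields_equivalence_axiom(self, staged_node, vocab):
        source, _, spec, _, schema = staged_node
        ann = build_annotation_graph(spec, schema, vocab)
        assert (source.column_uri("gender"), OWL.equivalentClass, SEX) in ann

    def test_value_mappings_one_node_per_code(self, staged_node, vocab):
        from fairfed.vocab import FF

        source, _, spec, _, schema = staged_node
        ann = build_annotation_graph(spec, schema, vocab)
        sex_maps = [
            n for n in ann.subjects(FF.mapsColumn, source.column_uri("gender"))
        ]
        assert len(sex_maps) == 2

    def test_unknown_vocabulary_term_is_named(self, staged_node, vocab):
        _, _, spec, _, schema = staged_node
        bad = MappingSpec(node_id="X", class_mappings={"gender": "Sex"},
                          value_mappings={"gender": {"M": "NotATerm"}})
        with pytest.raises(MappingError, match="NotATerm"):
            build_annotation_graph(bad, schema, vocab)

    def test_column_absent_from_schema_rejected(self, staged_node, vocab):
        _, _, _, _, schema = staged_node
        bad = MappingSpec(node_id="X", class_mappings={"ghost": "Sex"})
        with pytest.raises(MappingError, match="ghost"):
            build_annotation_graph(bad, schema, vocab)

    def test_annotation_graph_contains_no_patient_data(self, staged_node, vocab):
        _, _, spec, _, schema = staged_node
        text = build_annotation_graph(spec, schema, vocab).serialize(format="nt")
        for ident in ("\"a\"", "\"b\"", "\"c\"", "\"d\"", "\"e\"", "/patient/"):
            assert ident not in text


class TestValidateMapping:
    def test_fully_covered_spec_is_clean(self, staged_node, vocab):
        source, _, spec, _, schema = staged_node
        observed = {"tcat": {"4a", "4b", "1", "2"}, "gender": {"M", "F"}}
        issues = validate_mapping(spec, schema, observed, vocab)
        assert [i for i in issues if i.kind != "unmapped_column"] == []

    def test_uncovered_code_is_reported(self, staged_node, vocab):
        _, _, spec, _, schema = staged_node
        issues = validate_mapping(spec, schema, {"gender": {"M", "F", "X"}}, vocab)
        uncovered = [i for i in issues if i.kind == "uncovered_code"]
        assert len(uncovered) == 1 and "X" in uncovered[0].detail

    def test_unmapped_default_rule_covers_stray_codes(self, staged_node, vocab):
        _, _, spec, _, schema = staged_node
        spec2 = MappingSpec(
            node_id=spec.node_id,
            class_mappings=spec.class_mappings,
            value_mappings=spec.value_mappings,
            unmapped_defaults={"gender": "Male"},
        )
        issues = validate_mapping(spec2, schema, {"gender": {"M", "F", "X"}}, vocab)
        assert [i for i in issues if i.kind == "uncovered_code"] == []

    def test_dangling_term_is_reported(self, staged_node, vocab):
        _, _, _, _, schema = staged_node
        bad = MappingSpec(node_id="X", class_mappings={"gender": "NoSuchVariable"})
        issues = validate_mapping(bad, schema, {}, vocab)
        assert any(i.kind == "dangling_term" for i in issues)


class TestClosure:
    def test_t4a_subject_matches_t4_and_not_t4b(self, staged_node, vocab):
        source, _, spec, data, schema = staged_node
        ann = build_annotation_graph(spec, schema, vocab)
        inf = materialize_closure(data, ann, vocab)
        subj = source.subject_uri("a")
        assert (subj, T_STAGE, T4A) in inf
        assert (subj, T_STAGE, T4) in inf
        assert (subj, T_STAGE, T4B) not in inf

    def test_empty_annotation_is_identity(self, staged_node, vocab):
        _, _, _, data, _ = staged_node
        inf = materialize_closure(data, Graph(), vocab)
        assert set(inf) == set(data)

    def test_closure_is_idempotent(self, staged_node, vocab):
        _, _, spec, data, schema = staged_node
        ann = build_annotation_graph(spec, schema, vocab)
        once = materialize_closure(data, ann, vocab)
        twice = materialize_closure(once, ann, vocab)
        assert set(once) == set(twice)

    def test_hierarchy_cycle_is_rejected(self, staged_node, vocab):
        _, _, spec, data, schema = staged_node
        looped = MappingSpec(
            node_id=spec.node_id,
            class_mappings=spec.class_mappings,
            value_mappings=spec.value_mappings,
            hierarchy_extensions=[(str(T4), str(T4A))],  # closes a loop below T4
        )
        ann = build_annotation_graph(looped, schema, vocab)
        with pytest.raises(MappingError, match="cycle"):
            materialize_closure(data, ann, vocab)

    def test_hierarchy_monotonicity(self, staged_node, vocab):
        _, _, spec, data, schema = staged_node
        ann = build_annotation_graph(spec, schema, vocab)
        inf = materialize_closure(data, ann, vocab)
        count = lambda term: len(set(inf.subjects(T_STAGE, term)))  # noqa: E731
        assert count(T4) >= count(T4A)
        assert count(T4) >= count(T4B)
        assert count(T4) == count(T4A) + count(T4B)

    def test_local_and_consortium_counts_agree(self, staged_node, vocab):
        source, _, spec, data, schema = staged_node
        ann = build_annotation_graph(spec, schema, vocab)
        inf = materialize_closure(data, ann, vocab)
        local = len(set(data.subjects(source.column_uri("gender"), None)))
        consortium = len(set(inf.subjects(SEX, None)))
        assert local == consortium == 5

    def test_schema_on_read_reannotation_leaves_data_untouched(self, staged_node, vocab):
        """Two different mapping layers coexist over one immutable data graph."""
        source, _, spec, data, schema = staged_node
        before = canonical_nt(data)
        ann1 = build_annotation_graph(spec, schema, vocab)
        spec2 = MappingSpec(
            node_id="STAGED",
            class_mappings={"gender": "Sex"},
            value_mappings={"gender": {"M": "Male", "F": "Female"}},
        )
        ann2 = build_annotation_graph(spec2, schema, vocab)
        inf1 = materialize_closure(data, ann1, vocab)
        inf2 = materialize_closure(data, ann2, vocab)
        assert canonical_nt(data) == before
        assert len(set(inf1.subjects(SEX, None))) == len(set(inf2.subjects(SEX, None)))
        assert (None, T_STAGE, None) not in inf2  # second layer maps sex only

    def test_empty_mapping_spec_yields_unqueryable_node(self, staged_node, vocab):
        _, _, _, data, schema = staged_node
        empty = build_annotation_graph(MappingSpec(node_id="STAGED"), schema, vocab)
        inf = materialize_closure(data, empty, vocab)
        assert (None, SEX, None) not in inf
        assert (None, T_STAGE, None) not in inf
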