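"""Tabular-to-RDF conversion and OWL schema extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdflib import Graph
from rdflib.namespace import RDF

from fairfed import (
    ColumnMetadata,
    SchemaError,
    TabularSource,
    canonical_nt,
    extract_owl_schema,
    infer_schema,
    readout_table,
    triplify_table,
)
from fairfed.triplify import metadata_from_dict, metadata_to_dict


def make_source(rows, columns, node_id="NODE"):
    return TabularSource(pd.DataFrame(rows, columns=columns), node_id=node_id)


@pytest.fixture
def small_source():
    return make_source(
        [["p1", "61", "M"], ["p2", "54", "F"]], ["id", "age", "sex"]
    )


@pytest.fixture
def small_metadata():
    return [
        ColumnMetadata("id", "identifier"),
        ColumnMetadata("age", "continuous", unit="years"),
        ColumnMetadata("sex", "categorical_nominal"),
    ]


class TestInferSchema:
    def test_guesses_identifier_numeric_and_categorical(self, small_source):
        drafts = infer_schema(small_source)
        assert [m.kind for m in drafts] == ["identifier", "continuous", "categorical_nominal"]
        assert not any(m.confirmed for m in drafts)

    def test_zero_column_table_is_a_schema_error(self):
        with pytest.raises(SchemaError):
            TabularSource(pd.DataFrame(), node_id="X")

    def test_duplicate_column_names_are_named(self):
        df = pd.DataFrame([[1, 2]])
        df.columns = ["a", "a"]
        with pytest.raises(SchemaError, match="a"):
            TabularSource(df, node_id="X")

    def test_config_overrides_numeric_guess_to_ordinal(self):
        source = make_source([["p1", "1"], ["p2", "4"]], ["id", "grade"])
        drafts = infer_schema(source)
        assert drafts[1].kind == "continuous"
        # round-trip through the config representation with an override
        raw = metadata_to_dict(drafts)
        raw["columns"]["grade"]["kind"] = "categorical_ordinal"
        confirmed = metadata_from_dict(raw)
        assert {m.column_name: m.kind for m in confirmed}["grade"] == "categorical_ordinal"


class TestTriplify:
    def test_two_rows_three_columns_gives_eight_triples(self, small_source, small_metadata):
        g = triplify_table(small_source, small_metadata)
        assert len(g) == 2 + 2 * 3 - 2  # 2 type triples + 4 value triples (id excluded)
        assert len(list(g.triples((None, RDF.type, None)))) == 2

    def test_zero_row_table_gives_empty_graph(self, small_metadata):
        source = make_source([], ["id", "age", "sex"])
        assert len(triplify_table(source, small_metadata)) == 0

    def test_patient_zero_sex_triple(self):
        source = make_source([["0", "M"]], ["id", "sex"])
        meta = [ColumnMetadata("id", "identifier"), ColumnMetadata("sex", "categorical_nominal")]
        g = triplify_table(source, meta)
        subj = source.subject_uri("0")
        assert (subj, source.column_uri("sex"), None) in g
        assert str(g.value(subj, source.column_uri("sex"))) == "M"

    def test_missing_cells_produce_no_triple(self, small_metadata):
        source = make_source([["p1", "", "M"], ["p2", "54", ""]], ["id", "age", "sex"])
        g = triplify_table(source, small_metadata)
        assert len(g) == 2 + 2  # 2 type + 2 value

    def test_duplicate_identifiers_rejected(self, small_metadata):
        source = make_source([["p1", "1", "M"], ["p1", "2", "F"]], ["id", "age", "sex"])
        with pytest.raises(SchemaError, match="p1"):
            triplify_table(source, small_metadata)

    def test_missing_identifier_cell_reports_row(self, small_metadata):
        source = make_source([["p1", "1", "M"], ["", "2", "F"]], ["id", "age", "sex"])
        with pytest.raises(SchemaError, match="row index 1"):
            triplify_table(source, small_metadata)

    @pytest.mark.parametrize("seed", range(4))
    def test_triple_count_law_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n_rows = int(rng.integers(1, 30))
        n_cols = int(rng.integers(1, 6))
        data = {"id": [f"s{i}" for i in range(n_rows)]}
        meta = [ColumnMetadata("id", "identifier")]
        expected_cells = 0
        for c in range(n_cols):
            vals = [str(rng.integers(0, 5)) if rng.random() > 0.3 else "" for _ in range(n_rows)]
            expected_cells += sum(1 for v in vals if v != "")
            data[f"c{c}"] = vals
            meta.append(ColumnMetadata(f"c{c}", "categorical_nominal"))
        source = TabularSource(pd.DataFrame(data), node_id="R")
        assert len(triplify_table(source, meta)) == n_rows + expected_cells

    def test_readout_round_trip(self, small_source, small_metadata):
        g = triplify_table(small_source, small_metadata)
        table = readout_table(g, small_source.base_namespace)
        assert sorted(table.index) == ["p1", "p2"]
        assert table.loc["p1", "sex"] == "M"
        assert float(table.loc["p2", "age"]) == 54.0

    def test_deterministic_canonical_serialization(self, small_source, small_metadata):
        a = canonical_nt(triplify_table(small_source, small_metadata))
        b = canonical_nt(triplify_table(small_source, small_metadata))
        assert a == b


class TestTriplifyProperties:
    """Hypothesis-driven invariants over arbitrary small tables."""

    values = st.text(
        alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), max_codepoint=0x2FF),
        max_size=6,
    )

    @given(
        st.lists(st.tuples(values, values), min_size=0, max_size=15),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_triple_count_and_round_trip(self, cells):
        rows = [[f"r{i}", a, b] for i, (a, b) in enumerate(cells)]
        source = make_source(rows, ["id", "u", "v"])
        meta = [
            ColumnMetadata("id", "identifier"),
            ColumnMetadata("u", "categorical_nominal"),
            ColumnMetadata("v", "categorical_nominal"),
        ]
        g = triplify_table(source, meta)
        non_missing = sum(1 for a, b in cells for x in (a, b) if x != "")
        assert len(g) == len(rows) + non_missing
        table = readout_table(g, source.base_namespace)
        for i, (a, b) in enumerate(cells):
            if a != "":
                assert table.loc[f"r{i}", "u"] == a
            if b != "":
                assert table.loc[f"r{i}", "v"] == b

    @given(
        st.lists(
            values.filter(lambda s: s not in {"", "id", "u", "v", "clinical"}),
            min_size=1, max_size=10, unique=True,
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_schema_never_leaks_cell_values(self, cell_values):
        rows = [[f"r{i}", v] for i, v in enumerate(cell_values)]
        source = make_source(rows, ["id", "v"])
        meta = [ColumnMetadata("id", "identifier"), ColumnMetadata("v", "categorical_nominal")]
        text = extract_owl_schema(source, meta).serialize(format="nt")
        assert not any(f'"{v}"' in text for v in cell_values)


class TestSchemaExtraction:
    def test_column_and_table_classes(self, small_source, small_metadata):
        from rdflib.namespace import OWL

        g = extract_owl_schema(small_source, small_metadata)
        classes = set(g.subjects(RDF.type, OWL.Class))
        assert len(classes) == 4  # 3 columns + 1 table

    def test_schema_round_trips_through_turtle(self, small_source, small_metadata):
        g = extract_owl_schema(small_source, small_metadata)
        g2 = Graph().parse(data=g.serialize(format="turtle"), format="turtle")
        assert set(g) == set(g2)

    def test_schema_contains_no_cell_values(self, small_source, small_metadata):
        g = extract_owl_schema(small_source, small_metadata)
        text = g.serialize(format="nt")
        for value in ("p1", "p2", "61", "54"):
            assert f'"{value}"' not in text

    def test_schema_privacy_on_random_tables(self):
        rng = np.random.default_rng(7)
        values = [f"secret{rng.integers(1e6)}" for _ in range(10)]
        source = make_source([[f"s{i}", values[i]] for i in range(10)], ["id", "v"])
        meta = [ColumnMetadata("id", "identifier"), ColumnMetadata("v", "categorical_nominal")]
        text = extract_owl_schema(source, meta).serialize(format="nt")
        assert not any(v in text for v in values)
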