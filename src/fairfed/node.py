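"""Data stations: the node-side handle everything federated runs against.

A station owns one institution's private artefacts — the tabular sources,
their RDF data graphs, the OWL schema, the node's ``annotation.local``
mapping layer, its materialized closure, locally stored cohort marker sets
and locally stored linear-predictor columns.  None of these ever leave the
station; the federation hub only sees the aggregate payloads that the task
functions in :mod:`fairfed.casemix` and :mod:`fairfed.fedcox` return.

Stations come in two backings:

* :meth:`DataStation.from_directory` — the full schema-on-read stack over a
  node fixture directory (clinical CSV + metadata + mappings, optional
  radiomics CSV with its own dialect).
* :meth:`DataStation.from_frame` — an in-memory survival table for
  simulation studies, bypassing RDF while exercising the identical
  federated-computation code paths.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from rdflib import Graph, URIRef

from .annotate import MappingSpec, annotation_index, build_annotation_graph, materialize_closure
from .errors import QueryError
from .query import ConsortiumQuery, Filter, LocalResult, run_local_query
from .triplify import TabularSource, extract_owl_schema, load_metadata, triplify_table
from .vocab import DECEASED, SURVIVAL_DAYS, VITAL_STATUS, ConsortiumVocabulary


class DataStation:
    def __init__(self, node_id: str, vocab: ConsortiumVocabulary):
        self.node_id = node_id
        self.vocab = vocab
        # RDF backing
        self.source: TabularSource | None = None
        self.data: Graph | None = None
        self.schema: Graph | None = None
        self.annotation: Graph | None = None
        self.inferred: Graph | None = None
        self.radiomics_source: TabularSource | None = None
        self.radiomics_inferred: Graph | None = None
        self._resolvable: dict[URIRef, set[URIRef]] = {}
        self._rad_resolvable: dict[URIRef, set[URIRef]] = {}
        # frame backing
        self._frame: pd.DataFrame | None = None
        # node-local state
        self.cohorts: dict[str, frozenset[str]] = {}
        self.lp_store: dict[str, pd.Series] = {}
        self._series_cache: dict = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_directory(cls, path: str | Path, vocab: ConsortiumVocabulary | None = None) -> "DataStation":
        path = Path(path)
        vocab = vocab or ConsortiumVocabulary.load()
        node_id = path.name
        st = cls(node_id, vocab)
        st.source = TabularSource.from_csv(path / "clinical.csv", node_id)
        metadata = load_metadata(path / "clinical_metadata.yaml")
        spec = MappingSpec.from_yaml(path / "clinical_mappings.yaml")
        st.data = triplify_table(st.source, metadata)
        st.schema = extract_owl_schema(st.source, metadata)
        st.annotation = build_annotation_graph(spec, st.schema, vocab)
        st.inferred = materialize_closure(st.data, st.annotation, vocab)
        st._resolvable = _resolvable_terms(st.annotation, vocab)

        rad_csv = path / "radiomics.csv"
        if rad_csv.exists():
            st.radiomics_source = TabularSource.from_csv(rad_csv, node_id, table_name="radiomics")
            rmeta = load_metadata(path / "radiomics_metadata.yaml")
            rspec = MappingSpec.from_yaml(path / "radiomics_mappings.yaml")
            rdata = triplify_table(st.radiomics_source, rmeta)
            rschema = extract_owl_schema(st.radiomics_source, rmeta)
            rann = build_annotation_graph(rspec, rschema, vocab)
            st.radiomics_inferred = materialize_closure(rdata, rann, vocab)
            st._rad_resolvable = _resolvable_terms(rann, vocab)
        return st

    @classmethod
    def from_frame(
        cls,
        node_id: str,
        frame: pd.DataFrame,
        *,
        time_col: str = "time",
        event_col: str = "event",
        vocab: ConsortiumVocabulary | None = None,
    ) -> "DataStation":
        """In-memory station over a plain survival table (simulation backing)."""
        st = cls(node_id, vocab or ConsortiumVocabulary.load())
        df = frame.copy()
        df = df.rename(columns={time_col: "time", event_col: "event"})
        df.index = [f"{node_id}:{i}" for i in range(len(df))]
        st._frame = df
        return st

    # -- term resolvability ------------------------------------------------

    def resolves_variable(self, var_uri: URIRef) -> bool:
        return var_uri in self._resolvable or var_uri in self._rad_resolvable

    def resolves_value(self, var_uri: URIRef, term: URIRef) -> bool:
        targets = self._resolvable.get(var_uri, set()) | self._rad_resolvable.get(var_uri, set())
        return term in targets

    # -- querying ----------------------------------------------------------

    def run_query(self, q: ConsortiumQuery) -> LocalResult:
        return run_local_query(self, q, self.vocab)

    def observed_codes(self) -> dict[str, set[str]]:
        assert self.source is not None
        out: dict[str, set[str]] = {}
        for col in self.source.frame.columns:
            out[col] = {v for v in self.source.frame[col] if not self.source.is_missing(v)}
        return out

    # -- cohorts -----------------------------------------------------------

    def mark_cohort(self, name: str, filters: list[Filter], *, require_radiomics: bool = False) -> int:
        """Evaluate eligibility criteria locally and store the marker set.

        Only the eligible *count* is returned; the subject set stays here.
        """
        from .query import _filter_patterns
        from .vocab import PATIENT

        if self._frame is not None:
            subjects = frozenset(self._frame.index)
        else:
            assert self.inferred is not None
            patterns = [f"?s a <{PATIENT}> ."]
            fp = _filter_patterns(filters, self.vocab)
            if fp:
                patterns.append(fp)
            body = "\n  ".join(patterns)
            sparql = f"SELECT DISTINCT ?s\nWHERE {{\n  {body}\n}}"
            subjects = frozenset(str(r[0]) for r in self.inferred.query(sparql))
        if require_radiomics:
            subjects = frozenset(subjects & self.radiomics_subjects())
        self.cohorts[name] = subjects
        return len(subjects)

    def cohort(self, name: str | None) -> frozenset[str] | None:
        if name is None:
            return None
        if name not in self.cohorts:
            raise QueryError(f"node {self.node_id}: unknown cohort marker {name!r}")
        return self.cohorts[name]

    def radiomics_subjects(self) -> set[str]:
        if self._frame is not None:
            return set(self._frame.index)
        if self.radiomics_inferred is None:
            return set()
        from rdflib.namespace import RDF

        return {str(s) for s, _, _ in self.radiomics_inferred.triples((None, RDF.type, None))}

    # -- variable extraction (schema-on-read readout) ----------------------

    def variable_series(self, ref: str) -> pd.Series:
        """Values of one consortium variable per subject (labels for
        categorical variables rolled up to top-level categories, floats for
        continuous ones)."""
        if ref in self._series_cache:
            return self._series_cache[ref]
        if self._frame is not None:
            if ref not in self._frame.columns:
                raise QueryError(f"node {self.node_id}: unknown column {ref!r}")
            s = self._frame[ref]
            self._series_cache[ref] = s
            return s
        var = self.vocab.variable(ref)
        graph = self.inferred
        if not self.resolves_variable(var.uri) or graph is None:
            raise QueryError(f"node {self.node_id}: variable {var.label!r} unresolved")
        if var.uri in self._rad_resolvable and var.uri not in self._resolvable:
            graph = self.radiomics_inferred
        values: dict[str, object] = {}
        if var.kind == "continuous":
            for s, _, o in graph.triples((None, var.uri, None)):
                values[str(s)] = float(o.toPython())
            series = pd.Series(values, dtype=float)
        else:
            for s, _, o in graph.triples((None, var.uri, None)):
                if isinstance(o, URIRef):
                    top = self.vocab.top_category(var, o)
                    if top is not None:
                        values[str(s)] = self.vocab.labels[top]
            series = pd.Series(values, dtype=object)
        series.name = var.label
        self._series_cache[ref] = series
        return series

    def survival_frame(self, covariates: list[str], cohort: str | None = None) -> pd.DataFrame:
        """Follow-up time (days), event indicator and raw covariate columns
        for the marked cohort.  Covariates may be consortium variable
        refs/labels, plain column names (frame backing), or ``lp:<name>``
        references to locally stored linear predictors."""
        if self._frame is not None:
            cols = {"time": self._frame["time"].astype(float), "event": self._frame["event"].astype(int)}
        else:
            time = self.variable_series(str(SURVIVAL_DAYS))
            vital = self.variable_series(str(VITAL_STATUS))
            event = (vital == self.vocab.labels[DECEASED]).astype(int)
            cols = {"time": time, "event": event}
        frame = pd.DataFrame(cols)
        for ref in covariates:
            if ref.startswith("lp:"):
                name = ref[3:]
                if name not in self.lp_store:
                    raise QueryError(f"node {self.node_id}: no stored linear predictor {name!r}")
                frame[ref] = self.lp_store[name]
            else:
                frame[ref] = self.variable_series(ref)
        marked = self.cohort(cohort)
        if marked is not None:
            frame = frame.loc[frame.index.intersection(sorted(marked))]
        frame = frame[frame["time"].notna()]
        return frame.sort_index()


def _resolvable_terms(annotation: Graph, vocab: ConsortiumVocabulary) -> dict[URIRef, set[URIRef]]:
    """Per consortium variable, the value terms this node can answer for:
    every mapping target plus all its hierarchy ancestors."""
    equivalences, value_maps, defaults, parents, _ = annotation_index(annotation, vocab)
    out: dict[URIRef, set[URIRef]] = {}
    col_to_var = dict(equivalences)
    for var in col_to_var.values():
        out.setdefault(var, set())

    def add_with_ancestors(var, term):
        out[var].add(term)
        node = term
        while node in parents:
            node = parents[node]
            out[var].add(node)

    for (col, _code), term in value_maps.items():
        var = col_to_var.get(col)
        if var is not None and term is not None:
            add_with_ancestors(var, term)
    for col, term in defaults.items():
        var = col_to_var.get(col)
        if var is not None and term is not None:
            add_with_ancestors(var, term)
    return out
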