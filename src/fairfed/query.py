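"""Consortium-level queries compiled to SPARQL and executed node-locally.

A :class:`ConsortiumQuery` is phrased purely in consortium vocabulary terms;
the compiled SPARQL runs over a node's *materialized closure* graph, so the
same query text works at every node regardless of local column names or
category codings, and hierarchical value filters (query T4, match T4a/T4b)
need no reasoner.  Results are privacy-safe aggregates only: counts,
category tallies, or sufficient statistics (n, sum, sum of squares, min,
max) for continuous variables — never identifiers or subject URIs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import Decimal

from rdflib import Graph, URIRef

from .errors import QueryError
from .vocab import PATIENT, ConsortiumVocabulary

AGGREGATES = ("count", "count_by_category", "summary", "missing_count", "values_of")
RELATIONS = ("eq", "neq", "in", "lt", "le", "gt", "ge")


@dataclass(frozen=True)
class Filter:
    """One cohort-filter conjunct: (variable, relation, value)."""

    variable: str  # variable URI or label
    relation: str
    value: object  # term ref, list of term refs, or a numeric bound

    def to_dict(self) -> dict:
        return {"variable": self.variable, "relation": self.relation, "value": self.value}

    @classmethod
    def from_dict(cls, d: dict) -> "Filter":
        return cls(d["variable"], d["relation"], d["value"])


@dataclass(frozen=True)
class ConsortiumQuery:
    aggregate: str
    variable: str | None = None  # not needed for bare counts
    filters: tuple[Filter, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.aggregate not in AGGREGATES:
            raise QueryError(f"unknown aggregate {self.aggregate!r}")
        for f in self.filters:
            if f.relation not in RELATIONS:
                raise QueryError(f"unknown filter relation {f.relation!r}")
        if self.aggregate != "count" and self.variable is None:
            raise QueryError(f"aggregate {self.aggregate!r} requires a variable")

    def to_dict(self) -> dict:
        return {
            "aggregate": self.aggregate,
            "variable": self.variable,
            "filters": [f.to_dict() for f in self.filters],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConsortiumQuery":
        return cls(
            aggregate=d["aggregate"],
            variable=d.get("variable"),
            filters=tuple(Filter.from_dict(f) for f in d.get("filters", [])),
        )

    @property
    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class LocalResult:
    """Aggregate answer of one node; contains no patient-level payload."""

    node_id: str
    aggregate: str
    payload: dict
    fingerprint: str
    unresolved: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "node_id": self.node_id,
            "aggregate": self.aggregate,
            "payload": self.payload,
            "fingerprint": self.fingerprint,
            "unresolved": list(self.unresolved),
        }


# --------------------------------------------------------------------------
# compilation
# --------------------------------------------------------------------------

def _filter_patterns(filters, vocab: ConsortiumVocabulary) -> str:
    parts = []
    for i, f in enumerate(filters):
        var = vocab.variable(f.variable)
        if f.relation == "eq":
            term = vocab.value_term(var.uri, f.value)
            parts.append(f"?s <{var.uri}> <{term}> .")
        elif f.relation == "neq":
            term = vocab.value_term(var.uri, f.value)
            parts.append(f"FILTER NOT EXISTS {{ ?s <{var.uri}> <{term}> }}")
        elif f.relation == "in":
            terms = [vocab.value_term(var.uri, v) for v in f.value]
            opts = " ".join(f"<{t}>" for t in terms)
            parts.append(f"?s <{var.uri}> ?f{i} . VALUES ?f{i} {{ {opts} }}")
        else:
            op = {"lt": "<", "le": "<=", "gt": ">", "ge": ">="}[f.relation]
            bound = float(f.value)
            parts.append(f"?s <{var.uri}> ?f{i} . FILTER(?f{i} {op} {bound})")
    return "\n  ".join(parts)


def compile_query(q: ConsortiumQuery, vocab: ConsortiumVocabulary) -> str:
    """Emit deterministic SPARQL 1.1 for a consortium query.

    Raises :class:`QueryError` if any term is unknown to the vocabulary.
    """
    try:
        where = [f"?s a <{PATIENT}> ."]
        fp = _filter_patterns(q.filters, vocab)
        if fp:
            where.append(fp)
        if q.aggregate == "count":
            body = "\n  ".join(where)
            return f"SELECT (COUNT(DISTINCT ?s) AS ?n)\nWHERE {{\n  {body}\n}}"
        var = vocab.variable(q.variable)
        if q.aggregate == "count_by_category":
            if var.kind != "categorical":
                raise QueryError(f"{var.label!r} is not categorical")
            opts = " ".join(f"<{t}>" for t in var.categories)
            where.append(f"?s <{var.uri}> ?cat .\n  VALUES ?cat {{ {opts} }}")
            body = "\n  ".join(where)
            return (
                f"SELECT ?cat (COUNT(DISTINCT ?s) AS ?n)\nWHERE {{\n  {body}\n}}\n"
                "GROUP BY ?cat\nORDER BY ?cat"
            )
        if q.aggregate == "missing_count":
            where.append(f"FILTER NOT EXISTS {{ ?s <{var.uri}> ?v }}")
            body = "\n  ".join(where)
            return f"SELECT (COUNT(DISTINCT ?s) AS ?n)\nWHERE {{\n  {body}\n}}"
        if q.aggregate == "summary":
            if var.kind != "continuous":
                raise QueryError(f"{var.label!r} is not continuous")
            where.append(f"?s <{var.uri}> ?v .")
            body = "\n  ".join(where)
            return (
                "SELECT (COUNT(?v) AS ?n) (SUM(?v) AS ?sum) (SUM(?v*?v) AS ?sum_sq) "
                "(MIN(?v) AS ?min) (MAX(?v) AS ?max)\n"
                f"WHERE {{\n  {body}\n}}"
            )
        # values_of: identifier-free value list (e.g. event times)
        where.append(f"?s <{var.uri}> ?v .")
        body = "\n  ".join(where)
        return f"SELECT ?v\nWHERE {{\n  {body}\n}}\nORDER BY ?v"
    except KeyError as exc:
        raise QueryError(str(exc)) from exc


# --------------------------------------------------------------------------
# execution
# --------------------------------------------------------------------------

def _num(value) -> float:
    if value is None:
        return 0.0
    v = value.toPython()
    if isinstance(v, Decimal):
        return float(v)
    return float(v)


def run_local_query(store, q: ConsortiumQuery, vocab: ConsortiumVocabulary) -> LocalResult:
    """Execute a consortium query against one node's local closure graph.

    ``store`` is any object with ``node_id``, an ``inferred`` rdflib graph
    (the materialized closure), and term-resolvability predicates
    ``resolves_variable`` / ``resolves_value`` derived from its annotation
    graph.  Unresolved terms are *flagged*, never silently counted as zero —
    a consortium table distinguishes "variable absent at this node" from a
    true zero count.
    """
    graph: Graph = store.inferred
    if graph is None:
        raise QueryError("node store has no materialized closure; run materialize_closure first")
    unresolved: list[str] = []

    def check_var(ref) -> object:
        var = vocab.variable(ref)
        if not store.resolves_variable(var.uri):
            unresolved.append(str(var.uri))
        return var

    for f in q.filters:
        fvar = check_var(f.variable)
        if f.relation in ("eq", "neq"):
            term = vocab.value_term(fvar.uri, f.value)
            if not store.resolves_value(fvar.uri, term):
                unresolved.append(str(term))
        elif f.relation == "in":
            for v in f.value:
                term = vocab.value_term(fvar.uri, v)
                if not store.resolves_value(fvar.uri, term):
                    unresolved.append(str(term))

    sparql = compile_query(q, vocab)
    rows = list(graph.query(sparql))

    if q.aggregate == "count":
        payload = {"count": int(_num(rows[0][0]))}
    elif q.aggregate == "missing_count":
        var = check_var(q.variable)
        payload = {"missing": int(_num(rows[0][0]))}
    elif q.aggregate == "count_by_category":
        var = check_var(q.variable)
        tallies = {URIRef(str(r[0])): int(_num(r[1])) for r in rows}
        categories: dict[str, int | None] = {}
        for term in var.categories:
            label = vocab.labels[term]
            if store.resolves_value(var.uri, term):
                categories[label] = tallies.get(term, 0)
            else:
                categories[label] = None  # absent at node ("-"), not zero
                unresolved.append(str(term))
        missing_q = ConsortiumQuery("missing_count", q.variable, q.filters)
        mrows = list(graph.query(compile_query(missing_q, vocab)))
        payload = {"categories": categories, "missing": int(_num(mrows[0][0]))}
    elif q.aggregate == "summary":
        check_var(q.variable)
        r = rows[0]
        n = int(_num(r[0]))
        payload = {
            "n": n,
            "sum": _num(r[1]) if n else 0.0,
            "sum_sq": _num(r[2]) if n else 0.0,
            "min": _num(r[3]) if n else None,
            "max": _num(r[4]) if n else None,
        }
    else:  # values_of
        check_var(q.variable)
        payload = {"values": sorted(_num(r[0]) for r in rows)}

    return LocalResult(
        node_id=store.node_id,
        aggregate=q.aggregate,
        payload=payload,
        fingerprint=q.fingerprint,
        unresolved=sorted(set(unresolved)),
    )
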