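"""The node-local semantic mapping layer ("annotation.local").

A mapping spec links one node's local schema — column classes and raw
category codes — to the consortium vocabulary.  Building it yields an
*annotation graph*: equivalence axioms for columns, value-mapping nodes for
category codes, unit assertions and optional extra subclass axioms.  The
annotation graph contains no patient data and is the only artefact a node
shares with the consortium lead; several annotation graphs can coexist over
the same immutable data graph (schema-on-read).

Because the original triplifier's representation of value-level mappings is
not standardised, this package uses minted mapping nodes::

    <base>/mapping/<column>/<urlencoded code>
        ff:mapsColumn  <base>/column/<column> ;
        ff:localCode   "<code>" ;
        ff:targetTerm  <consortium term> .

``materialize_closure`` then entails, for every data triple whose predicate
is a mapped column, the corresponding consortium-term triple, plus one triple
per ancestor of the mapped term in the (vocabulary + extension) hierarchy —
so a subject coded ``T4a`` locally is returned by both T4a and T4 consortium
queries without any OWL reasoner at query time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote

import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .errors import MappingError
from .vocab import FF, PATIENT, ConsortiumVocabulary


@dataclass
class MappingSpec:
    """Declarative node-to-consortium mapping, as read from the config file."""

    node_id: str
    class_mappings: dict[str, str] = field(default_factory=dict)  # column -> variable ref
    value_mappings: dict[str, dict[str, str]] = field(default_factory=dict)  # column -> code -> value ref
    unmapped_defaults: dict[str, str] = field(default_factory=dict)  # column -> value ref
    unit_assertions: dict[str, str] = field(default_factory=dict)  # column -> unit label/URI
    hierarchy_extensions: list[tuple[str, str]] = field(default_factory=list)  # (child, parent)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MappingSpec":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "MappingSpec":
        return cls(
            node_id=str(raw.get("node_id", "")),
            class_mappings={str(k): str(v) for k, v in (raw.get("classes") or {}).items()},
            value_mappings={
                str(col): {str(c): str(t) for c, t in (codes or {}).items()}
                for col, codes in (raw.get("values") or {}).items()
            },
            unmapped_defaults={str(k): str(v) for k, v in (raw.get("unmapped") or {}).items()},
            unit_assertions={str(k): str(v) for k, v in (raw.get("units") or {}).items()},
            hierarchy_extensions=[(str(a), str(b)) for a, b in (raw.get("hierarchy") or [])],
        )

    def to_dict(self) -> dict:
        out: dict = {"node_id": self.node_id, "classes": dict(self.class_mappings)}
        if self.value_mappings:
            out["values"] = {c: dict(m) for c, m in self.value_mappings.items()}
        if self.unmapped_defaults:
            out["unmapped"] = dict(self.unmapped_defaults)
        if self.unit_assertions:
            out["units"] = dict(self.unit_assertions)
        if self.hierarchy_extensions:
            out["hierarchy"] = [list(e) for e in self.hierarchy_extensions]
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")


@dataclass(frozen=True)
class MappingIssue:
    kind: str  # unmapped_column | uncovered_code | dangling_term | missing_column
    column: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.column}: {self.detail}"


# --------------------------------------------------------------------------
# schema introspection helpers
# --------------------------------------------------------------------------

def _schema_columns(schema: Graph) -> dict[str, URIRef]:
    """Map column label -> column class URI from an OWL schema graph."""
    out = {}
    for cls, _, _ in schema.triples((None, FF.columnOf, None)):
        label = schema.value(cls, RDFS.label)
        out[str(label)] = cls
    return out


def _schema_table(schema: Graph) -> URIRef:
    for cls, _, _ in schema.triples((None, RDF.type, OWL.Class)):
        if schema.value(cls, FF.columnOf) is None:
            return cls
    raise MappingError("schema graph contains no table class")


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def build_annotation_graph(
    spec: MappingSpec, schema: Graph, vocab: ConsortiumVocabulary
) -> Graph:
    """Materialise the mapping spec as a standalone annotation graph."""
    columns = _schema_columns(schema)
    table = _schema_table(schema)
    base = str(table).rsplit("/table/", 1)[0]
    g = Graph()
    g.add((table, OWL.equivalentClass, PATIENT))

    var_of_column: dict[str, URIRef] = {}
    for col, ref in sorted(spec.class_mappings.items()):
        if col not in columns:
            raise MappingError(f"mapped column {col!r} absent from schema")
        try:
            var = vocab.variable(ref)
        except KeyError as exc:
            raise MappingError(str(exc)) from exc
        var_of_column[col] = var.uri
        g.add((columns[col], OWL.equivalentClass, var.uri))

    for col, codes in sorted(spec.value_mappings.items()):
        if col not in columns:
            raise MappingError(f"value-mapped column {col!r} absent from schema")
        if col not in var_of_column:
            raise MappingError(f"value-mapped column {col!r} has no class mapping")
        for code, ref in sorted(codes.items()):
            term = _resolve_value(vocab, var_of_column[col], ref)
            node = URIRef(f"{base}/mapping/{quote(col, safe='')}/{quote(code, safe='')}")
            g.add((node, FF.mapsColumn, columns[col]))
            g.add((node, FF.localCode, Literal(code)))
            g.add((node, FF.targetTerm, term))

    for col, ref in sorted(spec.unmapped_defaults.items()):
        if col not in var_of_column:
            raise MappingError(f"default-mapped column {col!r} has no class mapping")
        term = _resolve_value(vocab, var_of_column[col], ref)
        node = URIRef(f"{base}/mapping/{quote(col, safe='')}/__unmapped__")
        g.add((node, FF.mapsColumn, columns[col]))
        g.add((node, FF.isDefault, Literal(True)))
        g.add((node, FF.targetTerm, term))

    for col, ref in sorted(spec.unit_assertions.items()):
        if col not in columns:
            raise MappingError(f"unit-mapped column {col!r} absent from schema")
        term = _resolve_unit(vocab, ref)
        g.add((columns[col], FF.unit, term))

    for child_ref, parent_ref in spec.hierarchy_extensions:
        child = _resolve_term(vocab, child_ref)
        parent = _resolve_term(vocab, parent_ref)
        g.add((child, RDFS.subClassOf, parent))
    return g


def _resolve_value(vocab: ConsortiumVocabulary, var: URIRef, ref: str) -> URIRef:
    try:
        return vocab.value_term(var, ref)
    except KeyError as exc:
        raise MappingError(str(exc)) from exc


def _resolve_term(vocab: ConsortiumVocabulary, ref: str) -> URIRef:
    if URIRef(ref) in vocab:
        return URIRef(ref)
    for uri, label in vocab.labels.items():
        if label == ref:
            return uri
    raise MappingError(f"unknown vocabulary term {ref!r}")


def _resolve_unit(vocab: ConsortiumVocabulary, ref: str) -> URIRef:
    term = _resolve_term(vocab, ref)
    if (term, FF.isUnit, Literal(True)) not in vocab.graph:
        raise MappingError(f"term {ref!r} is not a unit term")
    return term


def validate_mapping(
    spec: MappingSpec,
    schema: Graph,
    observed_codes: dict[str, set[str]],
    vocab: ConsortiumVocabulary,
) -> list[MappingIssue]:
    """Dry-run check of a mapping spec.  Returns issues as data; an empty list
    means :func:`build_annotation_graph` will succeed and every mapped
    categorical code resolves to a consortium term.
    """
    issues: list[MappingIssue] = []
    columns = _schema_columns(schema)

    for col, ref in sorted(spec.class_mappings.items()):
        if col not in columns:
            issues.append(MappingIssue("missing_column", col, "mapped column absent from schema"))
            continue
        try:
            vocab.variable(ref)
        except KeyError:
            issues.append(MappingIssue("dangling_term", col, f"unknown variable {ref!r}"))

    for col in sorted(columns):
        if col not in spec.class_mappings:
            issues.append(MappingIssue("unmapped_column", col, "no consortium mapping"))

    for col, codes in sorted(spec.value_mappings.items()):
        var_ref = spec.class_mappings.get(col)
        if var_ref is None:
            continue
        try:
            var = vocab.variable(var_ref)
        except KeyError:
            continue
        for code, ref in sorted(codes.items()):
            try:
                vocab.value_term(var.uri, ref)
            except KeyError:
                issues.append(MappingIssue("dangling_term", col, f"unknown value term {ref!r} for code {code!r}"))

    for col, observed in sorted(observed_codes.items()):
        var_ref = spec.class_mappings.get(col)
        if var_ref is None:
            continue
        try:
            var = vocab.variable(var_ref)
        except KeyError:
            continue
        if var.kind != "categorical":
            continue
        covered = set(spec.value_mappings.get(col, {}))
        if col in spec.unmapped_defaults:
            continue
        for code in sorted(observed - covered):
            issues.append(MappingIssue("uncovered_code", col, f"observed code {code!r} has no mapping and no unmapped-default rule"))
    return issues


def annotation_index(annotation: Graph, vocab: ConsortiumVocabulary):
    """Digest an annotation graph into lookup tables used by the closure and
    by per-node term resolvability checks.
    """
    equivalences: dict[URIRef, URIRef] = {}
    for local, _, target in annotation.triples((None, OWL.equivalentClass, None)):
        equivalences[local] = target
    value_maps: dict[tuple[URIRef, str], URIRef] = {}
    defaults: dict[URIRef, URIRef] = {}
    for node, _, col in annotation.triples((None, FF.mapsColumn, None)):
        term = annotation.value(node, FF.targetTerm)
        if annotation.value(node, FF.isDefault) is not None:
            defaults[col] = term
        else:
            code = annotation.value(node, FF.localCode)
            value_maps[(col, str(code))] = term
    parents = dict(vocab.parents)
    for child, _, parent in annotation.triples((None, RDFS.subClassOf, None)):
        parents[child] = parent
    # cycle check on the extended hierarchy
    for start in parents:
        node, seen = start, {start}
        while node in parents:
            node = parents[node]
            if node in seen:
                raise MappingError(f"cycle in value-term hierarchy at {node}")
            seen.add(node)
    units: dict[URIRef, URIRef] = {}
    for col, _, term in annotation.triples((None, FF.unit, None)):
        units[col] = term
    return equivalences, value_maps, defaults, parents, units


def materialize_closure(
    data: Graph, annotation: Graph, vocab: ConsortiumVocabulary
) -> Graph:
    """Entail consortium-term triples over a data graph.

    The result contains the original data triples plus, for every mapped
    cell, triples under the consortium predicate for the mapped term and all
    its hierarchy ancestors.  Running the closure on its own output adds
    nothing (idempotence).
    """
    equivalences, value_maps, defaults, parents, units = annotation_index(annotation, vocab)

    def ancestors(term: URIRef) -> list[URIRef]:
        out, node = [], term
        while node in parents:
            node = parents[node]
            out.append(node)
        return out

    inferred = Graph()
    for s, p, o in data:
        inferred.add((s, p, o))
        if p == RDF.type:
            target = equivalences.get(o)
            if target is not None:
                inferred.add((s, RDF.type, target))
            continue
        target = equivalences.get(p)
        if target is not None:
            term = value_maps.get((p, str(o)))
            if term is None and isinstance(o, Literal):
                term = defaults.get(p)
            if term is not None:
                inferred.add((s, target, term))
                for anc in ancestors(term):
                    inferred.add((s, target, anc))
            elif isinstance(o, Literal):
                var = vocab.variables.get(target)
                if var is not None and var.kind == "continuous":
                    inferred.add((s, target, o))
        # idempotence: re-expand hierarchy for already-entailed term triples
        if p in vocab.variables and isinstance(o, URIRef):
            for anc in ancestors(o):
                inferred.add((s, p, anc))
    for col, term in units.items():
        var = equivalences.get(col)
        if var is not None:
            inferred.add((var, FF.unit, term))
    return inferred
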