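"""Consortium vocabulary: the shared terminology every node is annotated against.

The package ships a small curated Turtle vocabulary in the style of the
National Cancer Institute Thesaurus (value terms, OBO PURL URIs) and the
Radiation Oncology Ontology (P-coded variable predicates).  Each consortium
*variable* is a predicate (e.g. ``roo:P100018`` "Sex"); categorical variables
carry an ordered list of canonical category terms, and value terms may form a
subclass hierarchy (T4a/T4b below T4) that the materialized closure expands.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS

FF = Namespace("https://w3id.org/fairfed/vocab#")
NCIT = Namespace("http://purl.obolibrary.org/obo/NCIT_")
ROO = Namespace("http://www.cancerdata.org/roo/")

#: Root class every triplified patient is asserted into after annotation.
PATIENT = NCIT["C16960"]

# Frequently used variable predicates.
AGE = ROO["P100016"]
SEX = ROO["P100018"]
T_STAGE = ROO["P100242"]
N_STAGE = ROO["P100243"]
M_STAGE = ROO["P100244"]
OVERALL_STAGE = ROO["P100245"]
TUMOUR_LOCATION = ROO["P100202"]
HPV_STATUS = ROO["P100246"]
TREATMENT = ROO["P100231"]
VITAL_STATUS = ROO["P100028"]
SURVIVAL_DAYS = ROO["P100247"]
RADIOMICS_FEATURES = tuple(ROO[f"P20000{i}"] for i in range(1, 6))

# Frequently used value terms.
OROPHARYNX = NCIT["C12762"]
M1 = NCIT["C48700"]
RADIOTHERAPY = NCIT["C15313"]
CHEMORADIOTHERAPY = NCIT["C15632"]
DECEASED = NCIT["C28554"]
CENSORED = NCIT["C37987"]


@dataclass(frozen=True)
class Variable:
    """A consortium variable: a predicate plus its value domain."""

    uri: URIRef
    label: str
    kind: str  # "categorical" | "continuous"
    order: int
    unit: URIRef | None = None
    categories: tuple[URIRef, ...] = field(default_factory=tuple)


class ConsortiumVocabulary:
    """Parsed view of the consortium vocabulary graph.

    Parameters
    ----------
    graph:
        An rdflib graph holding the vocabulary triples.  Use
        :meth:`load` for the shipped default.
    """

    def __init__(self, graph: Graph):
        self.graph = graph
        self.labels: dict[URIRef, str] = {}
        self.parents: dict[URIRef, URIRef] = {}
        self.variables: dict[URIRef, Variable] = {}
        self._parse()

    @classmethod
    def load(cls, path: str | None = None) -> "ConsortiumVocabulary":
        """Load a vocabulary Turtle file (default: the shipped mini-vocabulary)."""
        g = Graph()
        if path is None:
            ref = importlib.resources.files("fairfed.data") / "vocabulary.ttl"
            g.parse(data=ref.read_text(encoding="utf-8"), format="turtle")
        else:
            g.parse(path, format="turtle")
        return cls(g)

    # -- parsing -----------------------------------------------------------

    def _parse(self) -> None:
        g = self.graph
        for s, _, o in g.triples((None, RDFS.label, None)):
            if isinstance(s, URIRef):
                self.labels[s] = str(o)
        for s, _, o in g.triples((None, RDFS.subClassOf, None)):
            if isinstance(s, URIRef) and isinstance(o, URIRef):
                if s in self.parents:
                    raise ValueError(f"term {s} has multiple parents (forest violated)")
                self.parents[s] = o
        self._check_acyclic()
        # variables: anything with an ff:kind annotation
        cats: dict[URIRef, list[tuple[int, URIRef]]] = {}
        for term, _, var in g.triples((None, FF.categoryOf, None)):
            order = g.value(term, FF.order)
            cats.setdefault(var, []).append((int(order), term))
        for var, _, kind in g.triples((None, FF.kind, None)):
            order = int(g.value(var, FF.order, default=Literal(0)))
            unit = g.value(var, FF.unit)
            members = tuple(t for _, t in sorted(cats.get(var, [])))
            self.variables[var] = Variable(
                uri=var,
                label=self.labels.get(var, str(var)),
                kind=str(kind),
                order=order,
                unit=unit if isinstance(unit, URIRef) else None,
                categories=members,
            )

    def _check_acyclic(self) -> None:
        for start in self.parents:
            seen = {start}
            node = start
            while node in self.parents:
                node = self.parents[node]
                if node in seen:
                    raise ValueError(f"cycle in vocabulary hierarchy at {node}")
                seen.add(node)

    # -- lookups -----------------------------------------------------------

    def __contains__(self, uri: URIRef) -> bool:
        return uri in self.labels

    def variables_in_order(self) -> list[Variable]:
        return sorted(self.variables.values(), key=lambda v: v.order)

    def variable(self, ref: URIRef | str) -> Variable:
        """Resolve a variable by URI or by its (unique) label."""
        if isinstance(ref, URIRef) and ref in self.variables:
            return self.variables[ref]
        candidates = [v for v in self.variables.values() if v.label == str(ref)]
        if len(candidates) == 1:
            return candidates[0]
        if URIRef(str(ref)) in self.variables:
            return self.variables[URIRef(str(ref))]
        raise KeyError(f"unknown consortium variable: {ref!r}")

    def value_term(self, variable: URIRef | str, label_or_uri: str | URIRef) -> URIRef:
        """Resolve a category term of ``variable`` by label or URI."""
        var = self.variable(variable)
        if URIRef(str(label_or_uri)) in self.labels:
            return URIRef(str(label_or_uri))
        domain = set(var.categories)
        for child, parent in self.parents.items():
            if parent in domain:
                domain.add(child)
        for t in sorted(domain):
            if self.labels.get(t) == str(label_or_uri):
                return t
        raise KeyError(f"unknown value {label_or_uri!r} for variable {var.label!r}")

    def ancestors(self, term: URIRef) -> list[URIRef]:
        """Strict ancestors of a term, nearest first."""
        out = []
        node = term
        while node in self.parents:
            node = self.parents[node]
            out.append(node)
        return out

    def descendants(self, term: URIRef) -> set[URIRef]:
        out: set[URIRef] = set()
        frontier = {term}
        while frontier:
            children = {c for c, p in self.parents.items() if p in frontier}
            children -= out
            out |= children
            frontier = children
        return out

    def top_category(self, variable: Variable, term: URIRef) -> URIRef | None:
        """Map a value term onto the canonical top-level category it falls under."""
        domain = set(variable.categories)
        if term in domain:
            return term
        for anc in self.ancestors(term):
            if anc in domain:
                return anc
        return None
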