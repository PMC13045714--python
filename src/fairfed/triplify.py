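"""Conversion of a node's tabular data into RDF, plus OWL schema extraction.

This mirrors the on-premises *triplification* step of a schema-on-read
FAIR-ification workflow: the patient-level table becomes a private RDF data
graph (one subject per patient, one value triple per non-missing cell) and
the table's organisational schema — column headers plus user-supplied column
metadata — becomes a shareable OWL graph that contains no patient data.

URI minting is deterministic and node-scoped::

    <https://fairfed.example/node/HN1>/patient/<urlencoded id>
    <https://fairfed.example/node/HN1>/column/<urlencoded name>
    <https://fairfed.example/node/HN1>/table/<urlencoded table name>

Missing cells (empty string, or a configured sentinel) produce no triple:
absence-as-missing matches RDF's open-world semantics.  Numeric literals are
emitted as ``xsd:decimal`` carrying the source's textual value, so values
round-trip without float drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import quote

import pandas as pd
import yaml
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import SchemaError
from .vocab import FF

NODE_BASE = "https://fairfed.example/node/"

COLUMN_KINDS = frozenset(
    {"continuous", "discrete", "categorical_ordinal", "categorical_nominal", "identifier"}
)


def node_namespace(node_id: str) -> str:
    return NODE_BASE + quote(node_id, safe="")


@dataclass(frozen=True)
class ColumnMetadata:
    """User-confirmed metadata for one column of a tabular source."""

    column_name: str
    kind: str
    description: str = ""
    unit: str | None = None
    confirmed: bool = True

    def __post_init__(self):
        if self.kind not in COLUMN_KINDS:
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.column_name!r}")


@dataclass
class TabularSource:
    """One node's patient-level table, values kept as text."""

    frame: pd.DataFrame
    node_id: str
    table_name: str = "clinical"
    missing_sentinels: frozenset[str] = field(default_factory=lambda: frozenset({""}))

    def __post_init__(self):
        cols = list(self.frame.columns)
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        if dupes:
            raise SchemaError(f"duplicate column names: {dupes}")
        if not cols:
            raise SchemaError("source has no columns")
        self.frame = self.frame.astype("string").fillna("")

    @classmethod
    def from_csv(cls, path: str | Path, node_id: str, *, delimiter: str = ",", table_name: str = "clinical") -> "TabularSource":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
        return cls(frame=df, node_id=node_id, table_name=table_name)

    @property
    def base_namespace(self) -> str:
        return node_namespace(self.node_id)

    def is_missing(self, value: str) -> bool:
        return value in self.missing_sentinels

    def subject_uri(self, patient_id: str) -> URIRef:
        return URIRef(f"{self.base_namespace}/patient/{quote(str(patient_id), safe='')}")

    def column_uri(self, column: str) -> URIRef:
        return URIRef(f"{self.base_namespace}/column/{quote(column, safe='')}")

    @property
    def table_uri(self) -> URIRef:
        return URIRef(f"{self.base_namespace}/table/{quote(self.table_name, safe='')}")


# --------------------------------------------------------------------------
# metadata inference and config round-trip
# --------------------------------------------------------------------------

def infer_schema(source: TabularSource) -> list[ColumnMetadata]:
    """Draft per-column metadata: numeric columns guessed continuous, the first
    all-unique column guessed as the patient identifier, everything else
    categorical.  All guesses come back unconfirmed; the metadata config file
    (see :func:`load_metadata`) is the authority.
    """
    out: list[ColumnMetadata] = []
    id_guessed = False
    for col in source.frame.columns:
        values = [v for v in source.frame[col] if not source.is_missing(v)]
        if not id_guessed and values and len(set(values)) == len(source.frame):
            out.append(ColumnMetadata(col, "identifier", confirmed=False))
            id_guessed = True
            continue
        if values and all(_is_number(v) for v in values):
            kind = "continuous"
        else:
            kind = "categorical_nominal"
        out.append(ColumnMetadata(col, kind, confirmed=False))
    return out


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def load_metadata(path: str | Path) -> list[ColumnMetadata]:
    """Read the per-column metadata config (YAML mapping column -> spec)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return metadata_from_dict(raw)


def metadata_from_dict(raw: dict) -> list[ColumnMetadata]:
    cols = raw.get("columns", {})
    out = []
    for name, spec in cols.items():
        spec = spec or {}
        out.append(
            ColumnMetadata(
                column_name=str(name),
                kind=spec.get("kind", "categorical_nominal"),
                description=spec.get("description", ""),
                unit=spec.get("unit"),
            )
        )
    return out


def metadata_to_dict(metadata: list[ColumnMetadata]) -> dict:
    cols: dict[str, dict] = {}
    for m in metadata:
        spec: dict = {"kind": m.kind}
        if m.description:
            spec["description"] = m.description
        if m.unit:
            spec["unit"] = m.unit
        cols[m.column_name] = spec
    return {"columns": cols}


def save_metadata(metadata: list[ColumnMetadata], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(metadata_to_dict(metadata), sort_keys=False), encoding="utf-8"
    )


def _validate(source: TabularSource, metadata: list[ColumnMetadata]) -> str:
    names = [m.column_name for m in metadata]
    if sorted(names) != sorted(source.frame.columns):
        missing = set(source.frame.columns) - set(names)
        extra = set(names) - set(source.frame.columns)
        raise SchemaError(f"metadata/source column mismatch: missing={sorted(missing)} extra={sorted(extra)}")
    if not all(m.confirmed for m in metadata):
        raise SchemaError("metadata contains unconfirmed column kinds")
    ids = [m.column_name for m in metadata if m.kind == "identifier"]
    if len(ids) != 1:
        raise SchemaError(f"exactly one identifier column required, got {ids}")
    id_col = ids[0]
    series = source.frame[id_col]
    empties = [i for i, v in enumerate(series) if source.is_missing(v)]
    if empties:
        raise SchemaError(f"missing identifier cell at row index {empties[0]}")
    counts = series.value_counts()
    dupes = sorted(counts[counts > 1].index.tolist())
    if dupes:
        raise SchemaError(f"duplicate identifier values: {dupes}")
    return id_col


# --------------------------------------------------------------------------
# triplification
# --------------------------------------------------------------------------

def triplify_table(source: TabularSource, metadata: list[ColumnMetadata]) -> Graph:
    """Convert a table to its private RDF data graph.

    Per row: one subject URI, one ``rdf:type`` triple asserting membership of
    the table class, and one value triple per non-missing, non-identifier
    cell.  Total triple count is ``n_rows + n_non_missing_cells``.
    """
    id_col = _validate(source, metadata)
    kinds = {m.column_name: m.kind for m in metadata}
    g = Graph()
    table = source.table_uri
    for _, row in source.frame.iterrows():
        subj = source.subject_uri(row[id_col])
        g.add((subj, RDF.type, table))
        for col in source.frame.columns:
            if col == id_col:
                continue
            value = row[col]
            if source.is_missing(value):
                continue
            if kinds[col] in ("continuous", "discrete"):
                lit = Literal(value, datatype=XSD.decimal)
            else:
                lit = Literal(value)
            g.add((subj, source.column_uri(col), lit))
    return g


def extract_owl_schema(source: TabularSource, metadata: list[ColumnMetadata]) -> Graph:
    """Extract the shareable OWL schema graph: one class per column plus one
    per table, annotated with the confirmed column metadata.  Contains no
    cell values — it is safe to send to the consortium lead.
    """
    _validate(source, metadata)
    g = Graph()
    table = source.table_uri
    g.add((table, RDF.type, OWL.Class))
    g.add((table, RDFS.label, Literal(source.table_name)))
    for m in metadata:
        cls = source.column_uri(m.column_name)
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.label, Literal(m.column_name)))
        g.add((cls, FF.columnOf, table))
        g.add((cls, FF.kind, Literal(m.kind)))
        if m.description:
            g.add((cls, RDFS.comment, Literal(m.description)))
        if m.unit:
            g.add((cls, FF.unitLabel, Literal(m.unit)))
    return g


def readout_table(data: Graph, source_base: str) -> pd.DataFrame:
    """Reconstruct the tabular view of a data graph (schema-on-read readout).

    Returns a frame indexed by patient identifier with one column per local
    predicate; missing cells come back as empty strings.  Column and row
    order follow sorted URI order, so the reconstruction is canonical rather
    than source-ordered.
    """
    from urllib.parse import unquote

    rows: dict[str, dict[str, str]] = {}
    cols: set[str] = set()
    prefix = source_base + "/column/"
    for s, p, o in data:
        sid = unquote(str(s).rsplit("/patient/", 1)[-1])
        rows.setdefault(sid, {})
        if str(p).startswith(prefix):
            col = unquote(str(p)[len(prefix):])
            cols.add(col)
            rows[sid][col] = str(o)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=sorted(cols))
    frame = frame.fillna("").sort_index()
    frame.index.name = "patient_id"
    return frame


def canonical_nt(graph: Graph) -> str:
    """Canonical serialization: sorted N-Triples, byte-stable for equal graphs."""
    lines = sorted(
        graph.serialize(format="nt").splitlines()
    )
    return "\n".join(line for line in lines if line.strip()) + "\n"
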