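"""Federated case-mix exploration: the data layer behind a consortium
dashboard.

One dispatched task per run asks every station for per-variable summaries of
its (optionally filtered) cohort: category tallies with an explicit missing
count for categorical variables, and (n, sum, sum of squares, min, max)
sufficient statistics for continuous ones.  The hub pools these into a
consortium table — one column per node plus a pooled column — exportable as
CSV in the familiar per-node case-mix layout.  A variable a node cannot
answer (no semantic mapping) is an explicit absent marker ("–"), never a
silent zero.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

from .errors import FederationError, QueryError
from .federation import SUPPRESSED, FederationHub, register_task
from .query import ConsortiumQuery, Filter
from .vocab import (
    CHEMORADIOTHERAPY,
    M1,
    M_STAGE,
    OROPHARYNX,
    RADIOTHERAPY,
    TREATMENT,
    TUMOUR_LOCATION,
    ConsortiumVocabulary,
)

ABSENT = None  # rendered as "–"
ABSENT_MARK = "–"


@dataclass(frozen=True)
class CasemixRequest:
    variables: tuple[str, ...]  # consortium variable refs (URI or label)
    nodes: tuple[str, ...] | None = None
    filters: tuple[Filter, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.variables:
            raise QueryError("casemix request needs at least one variable")


@dataclass
class CasemixReport:
    nodes: list[str]
    variables: list[str]  # variable URIs, vocabulary order
    per_node: dict[str, dict]  # node -> {"sample_size": ..., "variables": {...}}
    pooled: dict
    vocab: ConsortiumVocabulary


# --------------------------------------------------------------------------
# node-side task
# --------------------------------------------------------------------------

def _casemix_task(station, payload: dict) -> dict:
    filters = tuple(Filter.from_dict(f) for f in payload.get("filters", []))
    out: dict = {"variables": {}}
    size = station.run_query(ConsortiumQuery("count", filters=filters))
    out["sample_size"] = size.payload["count"]
    for ref in payload["variables"]:
        var = station.vocab.variable(ref)
        if not station.resolves_variable(var.uri):
            out["variables"][str(var.uri)] = {"absent": True}
            continue
        if var.kind == "categorical":
            res = station.run_query(ConsortiumQuery("count_by_category", str(var.uri), filters))
            out["variables"][str(var.uri)] = {
                "kind": "categorical",
                "categories": res.payload["categories"],
                "missing": res.payload["missing"],
            }
        else:
            res = station.run_query(ConsortiumQuery("summary", str(var.uri), filters))
            out["variables"][str(var.uri)] = {"kind": "continuous", **res.payload}
    return out


def _eligibility_task(station, payload: dict) -> dict:
    filters = [Filter.from_dict(f) for f in payload["criteria"]]
    unresolved = []
    for f in filters:
        var = station.vocab.variable(f.variable)
        if not station.resolves_variable(var.uri):
            unresolved.append(str(var.uri))
    count = station.mark_cohort(
        payload["store"], filters, require_radiomics=payload.get("require_radiomics", False)
    )
    return {"eligible": count, "store": payload["store"], "unresolved": unresolved}


register_task("casemix.summary", _casemix_task, guarded=True)
register_task("casemix.eligibility", _eligibility_task, guarded=True)


# --------------------------------------------------------------------------
# hub-side operations
# --------------------------------------------------------------------------

def casemix_summary(
    request: CasemixRequest, hub: FederationHub, *, k_min: int | None = None
) -> CasemixReport:
    """Run one federated case-mix task and pool the per-node summaries."""
    vocab = next(iter(hub.stations.values())).vocab
    var_uris = [str(vocab.variable(ref).uri) for ref in request.variables]
    payload = {
        "variables": var_uris,
        "filters": [f.to_dict() for f in request.filters],
    }
    nodes = list(request.nodes) if request.nodes else hub.node_ids
    results = hub.dispatch("casemix.summary", payload, nodes, k_min=k_min)
    per_node = {}
    for r in results:
        if not r.ok:
            raise FederationError(f"node {r.node_id} failed: {r.error}")
        per_node[r.node_id] = r.payload

    ordered = sorted(var_uris, key=lambda u: vocab.variables[_uri(vocab, u)].order)
    pooled: dict = {"sample_size": _sum_cells(p["sample_size"] for p in per_node.values()), "variables": {}}
    for uri in ordered:
        blocks = [p["variables"][uri] for p in per_node.values() if not p["variables"][uri].get("absent")]
        var = vocab.variables[_uri(vocab, uri)]
        if not blocks:
            pooled["variables"][uri] = {"absent": True}
        elif var.kind == "categorical":
            labels = [vocab.labels[t] for t in var.categories]
            pooled["variables"][uri] = {
                "kind": "categorical",
                "categories": {
                    lab: _sum_cells(b["categories"].get(lab) for b in blocks) for lab in labels
                },
                "missing": _sum_cells(b["missing"] for b in blocks),
            }
        else:
            if any(b["n"] == SUPPRESSED for b in blocks):
                pooled["variables"][uri] = {"kind": "continuous", "n": SUPPRESSED}
            else:
                pooled["variables"][uri] = {
                    "kind": "continuous",
                    "n": sum(b["n"] for b in blocks),
                    "sum": sum(b["sum"] for b in blocks),
                    "sum_sq": sum(b["sum_sq"] for b in blocks),
                    "min": min(b["min"] for b in blocks if b["min"] is not None),
                    "max": max(b["max"] for b in blocks if b["max"] is not None),
                }
    return CasemixReport(nodes=nodes, variables=ordered, per_node=per_node, pooled=pooled, vocab=vocab)


def _uri(vocab, uri_str):
    from rdflib import URIRef

    return URIRef(uri_str)


def _sum_cells(values):
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    if any(v == SUPPRESSED for v in vals):
        return SUPPRESSED
    return sum(vals)


def default_model_criteria(vocab: ConsortiumVocabulary) -> list[Filter]:
    """The consortium model-cohort selector: primary oropharyngeal site,
    nonmetastatic (not M1; Mx is not an M1 assertion), treated with
    radiotherapy or chemoradiotherapy."""
    return [
        Filter(str(TUMOUR_LOCATION), "eq", str(OROPHARYNX)),
        Filter(str(M_STAGE), "neq", str(M1)),
        Filter(str(TREATMENT), "in", [str(RADIOTHERAPY), str(CHEMORADIOTHERAPY)]),
    ]


def eligibility_filter(
    hub: FederationHub,
    criteria: list[Filter] | None = None,
    *,
    store: str = "eligible",
    nodes: list[str] | None = None,
    require_radiomics: bool = False,
    k_min: int | None = None,
) -> dict[str, int | str]:
    """Mark the eligible cohort at every station; return per-node counts only."""
    vocab = next(iter(hub.stations.values())).vocab
    criteria = default_model_criteria(vocab) if criteria is None else criteria
    payload = {
        "criteria": [f.to_dict() for f in criteria],
        "store": store,
        "require_radiomics": require_radiomics,
    }
    results = hub.dispatch("casemix.eligibility", payload, nodes, k_min=k_min)
    out = {}
    for r in results:
        if not r.ok:
            raise FederationError(f"node {r.node_id} failed: {r.error}")
        out[r.node_id] = r.payload["eligible"]
    return out


# --------------------------------------------------------------------------
# CSV export (consortium-table layout)
# --------------------------------------------------------------------------

def _cell(value) -> str:
    if value is None:
        return ABSENT_MARK
    if value == SUPPRESSED:
        return SUPPRESSED
    return str(value)


def export_casemix_csv(report: CasemixReport) -> str:
    """Render the pooled report as CSV: one row per category / statistic, one
    column per node plus a pooled column, vocabulary-fixed row order, absent
    cells rendered "–"."""
    vocab = report.vocab
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["Variable", "Category"] + report.nodes + ["Pooled"])

    def node_blocks(uri):
        return [report.per_node[n]["variables"][uri] for n in report.nodes]

    writer.writerow(
        ["Sample size", ""]
        + [_cell(report.per_node[n]["sample_size"]) for n in report.nodes]
        + [_cell(report.pooled["sample_size"])]
    )
    for uri in report.variables:
        var = vocab.variables[_uri(vocab, uri)]
        blocks = node_blocks(uri)
        pooled = report.pooled["variables"][uri]
        if var.kind == "continuous":
            def fmt_mean(b):
                if b.get("absent"):
                    return ABSENT_MARK
                if b["n"] == SUPPRESSED:
                    return SUPPRESSED
                return f"{b['sum'] / b['n']:.1f}" if b["n"] else ABSENT_MARK

            def fmt_range(b):
                if b.get("absent") or b.get("n") in (0, SUPPRESSED):
                    return ABSENT_MARK
                lo, hi = b["min"], b["max"]
                lo = int(lo) if float(lo).is_integer() else lo
                hi = int(hi) if float(hi).is_integer() else hi
                return f"{lo}-{hi}"

            writer.writerow([var.label, "Mean"] + [fmt_mean(b) for b in blocks] + [fmt_mean(pooled)])
            writer.writerow([var.label, "Range"] + [fmt_range(b) for b in blocks] + [fmt_range(pooled)])
        else:
            labels = [vocab.labels[t] for t in var.categories]
            for lab in labels:
                row = []
                for b in blocks:
                    if b.get("absent"):
                        row.append(ABSENT_MARK)
                    else:
                        row.append(_cell(b["categories"].get(lab)))
                pooled_cell = ABSENT_MARK if pooled.get("absent") else _cell(pooled["categories"].get(lab))
                writer.writerow([var.label, lab] + row + [pooled_cell])
            missing_cells = [
                b.get("missing", 0) if not b.get("absent") else None for b in blocks
            ]
            if any(c not in (0, None) for c in missing_cells):
                writer.writerow(
                    [var.label, "Missing"]
                    + [_cell(c if c != 0 else 0) for c in missing_cells]
                    + [_cell(pooled.get("missing"))]
                )
    return buf.getvalue()
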