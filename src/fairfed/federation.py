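"""In-process hub-and-spoke federation honouring the Personal Health Train
contract: tasks travel to the stations, only aggregates travel back, and
direct peer-to-peer access does not exist.

The network transport of a production deployment is replaced by direct
in-process calls, but the *message contract* is kept: every task and every
result crosses the hub boundary as a JSON-serialisable payload and is
appended to an auditable JSON-lines log.  The privacy invariant — no
patient-level payload ever crosses — is therefore a testable property of the
log, not an aspiration.  A thin transport adapter (replace
:meth:`FederationHub.dispatch`'s inner call) is the extension point for a
real network stack.

Disclosure control: category counts ``0 < c < k_min`` and continuous
summaries with ``n < k_min`` are suppressed before pooling (cell
suppression).  The default ``k_min`` is 5; exploration runs that must show
small cells (e.g. a consortium table reporting singletons) set ``k_min=1``
explicitly.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FederationError

SUPPRESSED = "suppressed"


def _jsonable(payload):
    """Round-trip through JSON: guarantees the payload is plain data and that
    what the audit log records is exactly what crossed the boundary."""
    return json.loads(json.dumps(payload))


@dataclass
class TaskMessage:
    kind: str
    payload: dict
    meta: dict = field(default_factory=dict)

    @property
    def fingerprint(self) -> str:
        blob = json.dumps({"kind": self.kind, "payload": self.payload}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ResultMessage:
    node_id: str
    kind: str
    payload: dict
    fingerprint: str
    status: str = "ok"  # "ok" | "failed"
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


class AuditLog:
    """Append-only message log; optionally mirrored to a JSON-lines file."""

    def __init__(self, path: str | Path | None = None):
        self.entries: list[dict] = []
        self.path = Path(path) if path else None
        if self.path:
            self.path.write_text("", encoding="utf-8")

    def append(self, entry: dict) -> None:
        entry = dict(entry, seq=len(self.entries), ts=time.time())
        self.entries.append(entry)
        if self.path:
            with self.path.open("a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry, sort_keys=True) + "\n")

    def __len__(self) -> int:
        return len(self.entries)

    def dumps(self) -> str:
        return "\n".join(json.dumps(e, sort_keys=True) for e in self.entries)


#: task kind -> (callable(station, payload) -> payload, guarded?)
_TASK_REGISTRY: dict[str, tuple[object, bool]] = {}


def register_task(kind: str, fn, *, guarded: bool = False) -> None:
    """Register a federated task.  ``guarded`` marks exploration-surface
    tasks whose results pass through cell suppression; model-fitting tasks
    exchange bounded sufficient statistics and are not count tables."""
    _TASK_REGISTRY[kind] = (fn, guarded)


class FederationHub:
    """Trusted aggregation hub over a registry of data stations."""

    def __init__(self, stations: dict, *, k_min: int = 5, audit_path: str | Path | None = None):
        if k_min < 1:
            raise FederationError("k_min must be >= 1")
        self.stations = dict(stations)
        self.k_min = k_min
        self.audit = AuditLog(audit_path)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.stations)

    def dispatch(
        self,
        kind: str,
        payload: dict,
        node_ids: list[str] | None = None,
        *,
        meta: dict | None = None,
        k_min: int | None = None,
    ) -> list[ResultMessage]:
        """Send one task to a set of stations; collect per-node results.

        Station failures are isolated: a raising node yields a marked-failed
        result, the others still answer.  The audit log grows by exactly two
        entries per addressed node (task out, result in).
        """
        if kind not in _TASK_REGISTRY:
            raise FederationError(f"unknown task kind {kind!r}")
        fn, guarded = _TASK_REGISTRY[kind]
        targets = self.node_ids if node_ids is None else list(node_ids)
        if not targets:
            raise FederationError("empty node set")
        unknown = [n for n in targets if n not in self.stations]
        if unknown:
            raise FederationError(f"unknown nodes: {unknown}")
        task = TaskMessage(kind=kind, payload=_jsonable(payload), meta=dict(meta or {}))
        effective_k = self.k_min if k_min is None else k_min
        results = []
        for node_id in targets:
            self.audit.append(
                {
                    "direction": "task",
                    "node": node_id,
                    "kind": kind,
                    "fingerprint": task.fingerprint,
                    "meta": task.meta,
                    "payload": task.payload,
                }
            )
            try:
                out = fn(self.stations[node_id], copy.deepcopy(task.payload))
                result = ResultMessage(node_id, kind, _jsonable(out), task.fingerprint)
            except Exception as exc:  # noqa: BLE001 - failure isolation is the contract
                result = ResultMessage(node_id, kind, {}, task.fingerprint, status="failed", error=str(exc))
            if guarded and result.ok:
                result = privacy_guard(result, effective_k)
            self.audit.append(
                {
                    "direction": "result",
                    "node": node_id,
                    "kind": kind,
                    "fingerprint": result.fingerprint,
                    "status": result.status,
                    "meta": task.meta,
                    "payload": result.payload,
                }
            )
            results.append(result)
        return results


# --------------------------------------------------------------------------
# disclosure control
# --------------------------------------------------------------------------

def _guard_block(block: dict, k_min: int, suppressed: list, prefix: str) -> dict:
    out = dict(block)
    if "categories" in out:
        cats = {}
        for label, c in out["categories"].items():
            if isinstance(c, int) and 0 < c < k_min:
                cats[label] = SUPPRESSED
                suppressed.append(f"{prefix}categories.{label}")
            else:
                cats[label] = c
        out["categories"] = cats
    if isinstance(out.get("missing"), int) and 0 < out["missing"] < k_min:
        out["missing"] = SUPPRESSED
        suppressed.append(f"{prefix}missing")
    if isinstance(out.get("count"), int) and 0 < out["count"] < k_min:
        out["count"] = SUPPRESSED
        suppressed.append(f"{prefix}count")
    if isinstance(out.get("n"), int) and 0 < out["n"] < k_min:
        # continuous summary on fewer than k_min subjects: withhold wholesale
        for key in ("n", "sum", "sum_sq", "min", "max", "mean"):
            if key in out:
                out[key] = SUPPRESSED
        suppressed.append(f"{prefix}summary")
    return out


def privacy_guard(result: ResultMessage, k_min: int) -> ResultMessage:
    """Apply cell suppression to an aggregate result payload.

    ``k_min=1`` is the identity.  Suppression is recorded in the payload
    under ``"suppressed"`` so that pooling can propagate it (a suppressed
    cell is never imputed as zero).
    """
    if k_min <= 1 or not result.ok:
        return result
    suppressed: list[str] = []
    payload = _guard_block(result.payload, k_min, suppressed, "")
    if "variables" in payload:
        payload["variables"] = {
            var: _guard_block(block, k_min, suppressed, f"{var}.")
            for var, block in payload["variables"].items()
        }
    if "eligible" in payload and isinstance(payload["eligible"], int) and 0 < payload["eligible"] < k_min:
        payload["eligible"] = SUPPRESSED
        suppressed.append("eligible")
    payload["suppressed"] = suppressed
    return ResultMessage(result.node_id, result.kind, payload, result.fingerprint, result.status, result.error)


# --------------------------------------------------------------------------
# pooling
# --------------------------------------------------------------------------

def _pool_cells(values):
    vals = [v for v in values if v is not None]
    if not vals:
        return None
    if any(v == SUPPRESSED for v in vals):
        return SUPPRESSED
    return sum(vals)


def aggregate(results: list[ResultMessage], scheme: str) -> dict:
    """Pool per-node aggregate payloads at the hub.

    ``scheme`` is ``"counts"`` (category tallies summed per category) or
    ``"summary"`` (sufficient statistics summed; min/max combined).  All
    results must answer the same task fingerprint.
    """
    ok = [r for r in results if r.ok]
    if not ok:
        raise FederationError("no successful results to aggregate")
    fps = {r.fingerprint for r in ok}
    if len(fps) > 1:
        raise FederationError(f"fingerprint mismatch across results: {sorted(fps)}")
    if scheme == "counts":
        if "categories" in ok[0].payload:
            labels: list[str] = []
            for r in ok:
                for label in r.payload["categories"]:
                    if label not in labels:
                        labels.append(label)
            pooled = {
                label: _pool_cells(r.payload["categories"].get(label) for r in ok)
                for label in labels
            }
            missing = _pool_cells(r.payload.get("missing", 0) for r in ok)
            return {"categories": pooled, "missing": missing}
        return {"count": _pool_cells(r.payload.get("count") for r in ok)}
    if scheme == "summary":
        if any(r.payload.get("n") == SUPPRESSED for r in ok):
            return {key: SUPPRESSED for key in ("n", "sum", "sum_sq", "min", "max")}
        n = sum(int(r.payload["n"]) for r in ok)
        total = sum(float(r.payload["sum"]) for r in ok)
        ssq = sum(float(r.payload["sum_sq"]) for r in ok)
        mins = [r.payload["min"] for r in ok if r.payload.get("min") is not None]
        maxs = [r.payload["max"] for r in ok if r.payload.get("max") is not None]
        return {
            "n": n,
            "sum": total,
            "sum_sq": ssq,
            "min": min(mins) if mins else None,
            "max": max(maxs) if maxs else None,
        }
    raise FederationError(f"unknown aggregation scheme {scheme!r}")
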