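"""Federated Cox proportional-hazards engine.

The model is the standard Cox regression under the Breslow partial
likelihood.  Breslow tie handling is not incidental: its risk-set sums
decompose additively over nodes, which is what makes the fit federable.
Writing ``D_t`` for the deaths at event time ``t`` and ``R_t`` for the risk
set, each node k returns, per global event time,

    d_t^k            local death count
    xsum_t^k         sum of covariate vectors over local deaths at t
    S0_t^k = sum_{j in R_t^k} exp(beta' x_j)
    S1_t^k = sum_{j in R_t^k} x_j exp(beta' x_j)
    S2_t^k = sum_{j in R_t^k} x_j x_j' exp(beta' x_j)

and the hub sums these, evaluates the Breslow partial log-likelihood

    ll(beta) = sum_t [ beta' xsum_t  -  d_t log S0_t ]

with score ``g = sum_t [xsum_t - d_t S1_t/S0_t]`` and Hessian
``H = -sum_t d_t [S2_t/S0_t - (S1_t/S0_t)(S1_t/S0_t)']``, and iterates
Newton-Raphson with step-halving.  Payload size is O(|grid| * p^2),
independent of any node's sample size.  The only patient-derived quantity
shared beyond these sums is the pooled list of unique event times (the
standard, accepted disclosure of distributed Cox fitting); an optional
coarsening rounds event times to a configurable bin width.

Covariate preparation is likewise federated: Box-Cox transforms for the
strictly positive radiomics features are chosen by a profile-likelihood grid
search over pooled moments, and centring/scaling constants come from pooled
first and second moments — so every node applies identical transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FederationError, FitError
from .federation import FederationHub, register_task

BOXCOX_GRID = [round(-2.0 + 0.1 * i, 1) for i in range(41)]


# --------------------------------------------------------------------------
# covariate encoding plan
# --------------------------------------------------------------------------

def _plan_entry(ref: str, vocab, transforms: dict | None) -> dict:
    transforms = transforms or {}
    if ref.startswith("lp:"):
        return {"ref": ref, "label": ref[3:], "kind": "lp", "levels": None, "transform": None}
    try:
        var = vocab.variable(ref)
        kind = var.kind
        label = var.label
        levels = [vocab.labels[t] for t in var.categories] if kind == "categorical" else None
    except KeyError:
        kind, label, levels = "continuous", ref, None
    return {
        "ref": ref,
        "label": label,
        "kind": kind,
        "levels": levels,
        "transform": transforms.get(ref),
    }


def build_plan(
    covariates: list[str],
    vocab,
    transforms: dict | None = None,
    level_counts: dict[str, dict[str, int]] | None = None,
) -> list[dict]:
    """Shared covariate-encoding plan: one entry per model term.

    Categorical terms are reference-coded against the vocabulary-ordered
    first *observed* level; levels unobserved anywhere in the training
    federation are pruned so no node ever emits an all-zero indicator.
    """
    plan = []
    for ref in covariates:
        entry = _plan_entry(ref, vocab, transforms)
        if entry["kind"] == "categorical" and level_counts is not None:
            observed = level_counts.get(ref, {})
            entry["levels"] = [lv for lv in entry["levels"] if observed.get(lv, 0) > 0]
            if len(entry["levels"]) < 2:
                raise FitError(f"categorical term {entry['label']!r} has <2 observed levels")
        plan.append(entry)
    return plan


def plan_columns(plan: list[dict]) -> list[str]:
    cols = []
    for e in plan:
        if e["kind"] == "categorical":
            cols.extend(f"{e['label']}={lv}" for lv in e["levels"][1:])
        else:
            cols.append(e["label"])
    return cols


def _boxcox(x: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def _design_matrix(frame: pd.DataFrame, plan: list[dict]):
    """Build (time, event, X) with complete-case filtering over the plan."""
    keep = frame["time"].notna() & frame["event"].notna()
    for e in plan:
        keep &= frame[e["ref"]].notna()
    sub = frame[keep]
    n = len(sub)
    blocks = []
    for e in plan:
        col = sub[e["ref"]]
        if e["kind"] == "categorical":
            mat = np.zeros((n, len(e["levels"]) - 1))
            for j, lv in enumerate(e["levels"][1:]):
                mat[:, j] = (col.to_numpy() == lv).astype(float)
            blocks.append(mat)
        else:
            x = col.to_numpy(dtype=float)
            tr = e.get("transform")
            if tr:
                if tr.get("lam") is not None:
                    if np.any(x <= 0):
                        raise FitError(f"non-positive values in Box-Cox feature {e['label']!r}")
                    x = _boxcox(x, tr["lam"])
                x = (x - tr["mu"]) / tr["sigma"]
            blocks.append(x[:, None])
    X = np.hstack(blocks) if blocks else np.zeros((n, 0))
    times = sub["time"].to_numpy(dtype=float)
    events = sub["event"].to_numpy(dtype=int)
    dropped = int(len(frame) - n)
    return times, events, X, dropped


# --------------------------------------------------------------------------
# node-side computations
# --------------------------------------------------------------------------

def _local_risk_stats(times, events, X, beta, grid):
    """Breslow sufficient statistics at every global event time.

    Suffix cumulative sums over subjects sorted by follow-up time give
    S0/S1/S2 for all grid times in one pass.
    """
    n, p = X.shape
    eta = X @ beta if p else np.zeros(n)
    if n and np.max(np.abs(eta)) > 500:
        raise FitError("linear predictor overflow; covariates should be standardized")
    w = np.exp(eta)
    order = np.argsort(times, kind="stable")
    ts, ws, Xs = times[order], w[order], X[order]
    S0c = np.cumsum(ws[::-1])[::-1]
    S1c = np.cumsum((ws[:, None] * Xs)[::-1], axis=0)[::-1] if p else np.zeros((n, 0))
    if p:
        WXX = ws[:, None, None] * Xs[:, :, None] * Xs[:, None, :]
        S2c = np.cumsum(WXX[::-1], axis=0)[::-1]
    else:
        S2c = np.zeros((n, 0, 0))
    grid = np.asarray(grid, dtype=float)
    idx = np.searchsorted(ts, grid, side="left")
    m = len(grid)
    S0 = np.zeros(m)
    S1 = np.zeros((m, p))
    S2 = np.zeros((m, p, p))
    inside = idx < n
    S0[inside] = S0c[idx[inside]]
    if p:
        S1[inside] = S1c[idx[inside]]
        S2[inside] = S2c[idx[inside]]
    # deaths at each grid time
    ev = events == 1
    evt, evX = times[ev], X[ev]
    d = np.zeros(m)
    xsum = np.zeros((m, p))
    pos = {t: i for i, t in enumerate(grid)}
    for t, x in zip(evt, evX):
        i = pos.get(float(t))
        if i is not None:
            d[i] += 1
            xsum[i] += x
    return d, xsum, S0, S1, S2


def _station_frame(station, payload):
    refs = [e["ref"] for e in payload["plan"]]
    return station.survival_frame(refs, payload.get("cohort"))


def _levels_task(station, payload):
    frame = station.survival_frame(payload["refs"], payload.get("cohort"))
    out = {}
    for ref in payload["refs"]:
        counts = frame[ref].dropna().value_counts()
        out[ref] = {str(k): int(v) for k, v in counts.items()}
    return out


def _moments_task(station, payload):
    frame = station.survival_frame(payload["refs"], payload.get("cohort"))
    want_log = set(payload.get("want_log", []))
    out = {}
    for ref in payload["refs"]:
        x = frame[ref].dropna().to_numpy(dtype=float)
        rec = {
            "n": int(x.size),
            "sum": float(x.sum()),
            "sum_sq": float((x**2).sum()),
            "min": float(x.min()) if x.size else None,
            "max": float(x.max()) if x.size else None,
        }
        if ref in want_log:
            nonpos = int((x <= 0).sum())
            rec["n_nonpositive"] = nonpos
            rec["sum_log"] = float(np.log(x[x > 0]).sum())
        out[ref] = rec
    return out


def _boxcox_task(station, payload):
    frame = station.survival_frame([payload["ref"]], payload.get("cohort"))
    x = frame[payload["ref"]].dropna().to_numpy(dtype=float)
    if np.any(x <= 0):
        raise FitError(
            f"Box-Cox requested for feature with {int((x <= 0).sum())} non-positive values"
        )
    per_lambda = []
    for lam in payload["lambdas"]:
        y = _boxcox(x, lam)
        per_lambda.append({"sum": float(y.sum()), "sum_sq": float((y**2).sum())})
    return {"n": int(x.size), "sum_log_x": float(np.log(x).sum()), "per_lambda": per_lambda}


def _event_times_task(station, payload):
    times, events, _, _ = _design_matrix(_station_frame(station, payload), payload["plan"])
    ev = times[events == 1]
    uniq, counts = np.unique(ev, return_counts=True)
    bin_width = payload.get("bin_width")
    if bin_width:
        uniq = np.ceil(uniq / bin_width) * bin_width
        agg: dict[float, int] = {}
        for t, c in zip(uniq, counts):
            agg[float(t)] = agg.get(float(t), 0) + int(c)
        uniq = np.array(sorted(agg))
        counts = np.array([agg[t] for t in uniq])
    return {"times": [float(t) for t in uniq], "counts": [int(c) for c in counts]}


def _local_stats_task(station, payload):
    times, events, X, dropped = _design_matrix(_station_frame(station, payload), payload["plan"])
    if payload.get("bin_width"):
        times = np.ceil(times / payload["bin_width"]) * payload["bin_width"]
    beta = np.asarray(payload["beta"], dtype=float)
    d, xsum, S0, S1, S2 = _local_risk_stats(times, events, X, beta, payload["grid"])
    return {
        "d": d.tolist(),
        "xsum": xsum.tolist(),
        "s0": S0.tolist(),
        "s1": S1.tolist(),
        "s2": S2.tolist(),
        "n": int(len(times)),
        "events": int(events.sum()),
        "dropped": dropped,
    }


def _store_lp_task(station, payload):
    frame = _station_frame(station, payload)
    plan = payload["plan"]
    keep = pd.Series(True, index=frame.index)
    for e in plan:
        keep &= frame[e["ref"]].notna()
    sub = frame[keep]
    _, _, X, _ = _design_matrix(sub, plan)
    lp = X @ np.asarray(payload["beta"], dtype=float) if X.shape[1] else np.zeros(len(sub))
    station.lp_store[payload["store"]] = pd.Series(lp, index=sub.index)
    return {"stored": payload["store"], "n": int(len(sub))}


def harrell_concordance(times, events, lp):
    """Harrell's C over all usable ordered pairs.

    A pair (i, j) is comparable when i dies strictly before j's follow-up
    ends, or when the times tie and exactly the i-th subject dies; it is
    concordant when the dying-first subject carries the higher predicted
    risk, and prediction ties count one half.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    lp = np.asarray(lp, dtype=float)
    ti, tj = times[:, None], times[None, :]
    ei, ej = events[:, None], events[None, :]
    comparable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    li, lj = lp[:, None], lp[None, :]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise FitError("no comparable pairs for concordance")
    n_conc = int((comparable & (li > lj)).sum())
    n_tied = int((comparable & (li == lj)).sum())
    return {
        "hci": (n_conc + 0.5 * n_tied) / n_comp,
        "concordant": n_conc,
        "tied_risk": n_tied,
        "comparable": n_comp,
    }


def _concordance_task(station, payload):
    if "lp_store" in payload:
        name = payload["lp_store"]
        if name not in station.lp_store:
            raise FitError(f"no stored linear predictor {name!r}")
        lp = station.lp_store[name]
        frame = station.survival_frame([], payload.get("cohort"))
        frame = frame.loc[frame.index.intersection(lp.index)]
        lpv = lp.loc[frame.index].to_numpy()
        times = frame["time"].to_numpy(dtype=float)
        events = frame["event"].to_numpy(dtype=int)
    else:
        frame = _station_frame(station, payload)
        times, events, X, _ = _design_matrix(frame, payload["plan"])
        lpv = X @ np.asarray(payload["beta"], dtype=float) if X.shape[1] else np.zeros(len(times))
    out = harrell_concordance(times, events, lpv)
    out["n"] = int(len(times))
    return out


register_task("cox.levels", _levels_task)
register_task("cox.moments", _moments_task)
register_task("cox.boxcox", _boxcox_task)
register_task("cox.event_times", _event_times_task)
register_task("cox.local_stats", _local_stats_task)
register_task("cox.store_lp", _store_lp_task)
register_task("cox.concordance", _concordance_task)


# --------------------------------------------------------------------------
# hub-side operations
# --------------------------------------------------------------------------

def _ok(results) -> list:
    failed = [r for r in results if not r.ok]
    if failed:
        msgs = "; ".join(f"{r.node_id}: {r.error}" for r in failed)
        raise FitError(f"station failure(s): {msgs}")
    return results


def federated_moments(
    hub: FederationHub,
    refs: list[str],
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    log_moments: bool = False,
    meta: dict | None = None,
) -> dict[str, dict]:
    """Pooled (n, mean, population variance, min, max[, sum log x]) per feature."""
    payload = {"refs": list(refs), "cohort": cohort}
    if log_moments:
        payload["want_log"] = list(refs)
    results = _ok(hub.dispatch("cox.moments", payload, nodes, meta=meta))
    out = {}
    for ref in refs:
        n = sum(r.payload[ref]["n"] for r in results)
        if n == 0:
            raise FitError(f"feature {ref!r} has no observed values in the federation")
        s = sum(r.payload[ref]["sum"] for r in results)
        ssq = sum(r.payload[ref]["sum_sq"] for r in results)
        mu = s / n
        var = max(ssq / n - mu * mu, 0.0)
        rec = {
            "n": n,
            "sum": s,
            "sum_sq": ssq,
            "mean": mu,
            "var": var,
            "sigma": math.sqrt(var),
            "min": min(r.payload[ref]["min"] for r in results if r.payload[ref]["min"] is not None),
            "max": max(r.payload[ref]["max"] for r in results if r.payload[ref]["max"] is not None),
        }
        if log_moments:
            nonpos = sum(r.payload[ref]["n_nonpositive"] for r in results)
            if nonpos:
                raise FitError(
                    f"log-moments requested for {ref!r} but {nonpos} non-positive values exist"
                )
            rec["sum_log"] = sum(r.payload[ref]["sum_log"] for r in results)
        out[ref] = rec
    return out


def federated_boxcox(
    hub: FederationHub,
    ref: str,
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    lambdas: list[float] | None = None,
    meta: dict | None = None,
):
    """Box-Cox exponent by federated profile-likelihood grid search.

    For each candidate exponent the nodes return moments of the transformed
    feature; the hub maximises
    ``LL(lam) = -(n/2) log(sigma_hat^2(lam)) + (lam - 1) sum(log x)``.
    Grid ties break toward the exponent closest to 1 (no transformation).
    """
    lambdas = BOXCOX_GRID if lambdas is None else list(lambdas)
    payload = {"ref": ref, "cohort": cohort, "lambdas": lambdas}
    results = _ok(hub.dispatch("cox.boxcox", payload, nodes, meta=meta))
    n = sum(r.payload["n"] for r in results)
    sum_log = sum(r.payload["sum_log_x"] for r in results)
    profile = []
    for i, lam in enumerate(lambdas):
        s = sum(r.payload["per_lambda"][i]["sum"] for r in results)
        ssq = sum(r.payload["per_lambda"][i]["sum_sq"] for r in results)
        mu = s / n
        var = max(ssq / n - mu * mu, 1e-300)
        ll = -(n / 2.0) * math.log(var) + (lam - 1.0) * sum_log
        profile.append({"lam": lam, "ll": ll, "mu": mu, "sigma": math.sqrt(var)})
    best_ll = max(p["ll"] for p in profile)
    candidates = [p for p in profile if p["ll"] >= best_ll - 1e-9]
    best = min(candidates, key=lambda p: (abs(p["lam"] - 1.0), p["lam"]))
    return best["lam"], {"profile": profile, "mu": best["mu"], "sigma": best["sigma"]}


def fit_transforms(
    hub: FederationHub,
    refs: list[str],
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    lambdas: list[float] | None = None,
    meta: dict | None = None,
) -> dict[str, dict]:
    """Per-feature Box-Cox exponent plus centring/scaling constants, all from
    the training federation only."""
    out = {}
    for ref in refs:
        lam, info = federated_boxcox(hub, ref, cohort, nodes, lambdas=lambdas, meta=meta)
        if info["sigma"] <= 0:
            raise FitError(f"degenerate (constant) feature {ref!r}")
        out[ref] = {"lam": lam, "mu": info["mu"], "sigma": info["sigma"]}
    return out


def collect_event_times(
    hub: FederationHub,
    plan: list[dict],
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    bin_width: float | None = None,
    meta: dict | None = None,
):
    """Pooled grid of unique event times with global death counts."""
    payload = {"plan": plan, "cohort": cohort, "bin_width": bin_width}
    results = _ok(hub.dispatch("cox.event_times", payload, nodes, meta=meta))
    agg: dict[float, int] = {}
    for r in results:
        for t, c in zip(r.payload["times"], r.payload["counts"]):
            agg[float(t)] = agg.get(float(t), 0) + int(c)
    if not agg:
        raise FitError("no events in training federation")
    times = sorted(agg)
    return times, [agg[t] for t in times]


@dataclass
class CoxModel:
    """A fitted federated Cox model, reproducible from its JSON record."""

    covariates: list[str]  # original term refs
    plan: list[dict]
    columns: list[str]
    beta: list[float]
    se: list[float]
    cov: list[list[float]]
    loglik: float
    iterations: int
    converged: bool
    grid: list[float]
    d: list[int]
    n: int
    n_events: int
    cohort: str | None = None
    dropped: dict[str, int] = field(default_factory=dict)
    elimination_trace: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "CoxModel":
        return cls(**d)

    def summary_frame(self) -> pd.DataFrame:
        beta = np.asarray(self.beta)
        se = np.asarray(self.se)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, beta / se, np.nan)
        p = 2 * sps.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"coef": beta, "se": se, "z": z, "p": p, "HR": np.exp(beta)},
            index=self.columns,
        )


def _pooled_stats(hub, plan, beta, grid, cohort, nodes, meta, bin_width):
    payload = {
        "plan": plan,
        "beta": [float(b) for b in beta],
        "grid": [float(t) for t in grid],
        "cohort": cohort,
        "bin_width": bin_width,
    }
    results = _ok(hub.dispatch("cox.local_stats", payload, nodes, meta=meta))
    m, p = len(grid), len(beta)
    d = np.zeros(m)
    xsum = np.zeros((m, p))
    S0 = np.zeros(m)
    S1 = np.zeros((m, p))
    S2 = np.zeros((m, p, p))
    info = {"n": 0, "events": 0, "dropped": {}}
    for r in results:
        d += np.asarray(r.payload["d"])
        xsum += np.asarray(r.payload["xsum"]).reshape(m, p)
        S0 += np.asarray(r.payload["s0"])
        S1 += np.asarray(r.payload["s1"]).reshape(m, p)
        S2 += np.asarray(r.payload["s2"]).reshape(m, p, p)
        info["n"] += r.payload["n"]
        info["events"] += r.payload["events"]
        info["dropped"][r.node_id] = r.payload["dropped"]
    return d, xsum, S0, S1, S2, info


def _llgh(beta, d, xsum, S0, S1, S2):
    live = S0 > 0
    ll = float(xsum.sum(axis=0) @ beta - (d[live] * np.log(S0[live])).sum())
    Sbar = np.zeros_like(S1)
    Sbar[live] = S1[live] / S0[live][:, None]
    g = (xsum - d[:, None] * Sbar).sum(axis=0)
    p = len(beta)
    H = np.zeros((p, p))
    if p:
        V = S2[live] / S0[live][:, None, None] - Sbar[live][:, :, None] * Sbar[live][:, None, :]
        H = -np.einsum("t,tij->ij", d[live], V)
    return ll, g, H


def cox_fit(
    hub: FederationHub,
    covariates: list[str],
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    transforms: dict | None = None,
    bin_width: float | None = None,
    max_iter: int = 50,
    tol_ll: float = 1e-9,
    tol_grad: float = 1e-6,
    meta: dict | None = None,
) -> CoxModel:
    """Fit the federated Breslow Cox model by distributed Newton-Raphson.

    Starts at beta=0, step-halves (at most 10 times) whenever a proposed
    update lowers the partial likelihood, and declares convergence when the
    likelihood gain drops below ``tol_ll`` or the score's sup-norm below
    ``tol_grad``.  Standard errors come from the inverse observed
    information at the optimum.
    """
    vocab = next(iter(hub.stations.values())).vocab
    nodes = nodes or hub.node_ids
    cat_refs = [r for r in covariates if _plan_entry(r, vocab, None)["kind"] == "categorical"]
    level_counts = None
    if cat_refs:
        results = _ok(hub.dispatch("cox.levels", {"refs": cat_refs, "cohort": cohort}, nodes, meta=meta))
        level_counts = {
            ref: _merge_counts([r.payload[ref] for r in results]) for ref in cat_refs
        }
    plan = build_plan(covariates, vocab, transforms, level_counts)
    columns = plan_columns(plan)
    p = len(columns)
    grid, _ = collect_event_times(hub, plan, cohort, nodes, bin_width=bin_width, meta=meta)

    beta = np.zeros(p)
    d, xsum, S0, S1, S2, info = _pooled_stats(hub, plan, beta, grid, cohort, nodes, meta, bin_width)
    if info["events"] == 0:
        raise FitError("no events in training federation")
    if p >= info["events"]:
        raise FitError(f"{p} parameters but only {info['events']} events")
    ll, g, H = _llgh(beta, d, xsum, S0, S1, S2)
    iterations, converged = 0, p == 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(g, ord=np.inf) < tol_grad:
            converged = True
            break
        try:
            delta = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix; check for collinear covariates") from exc
        step, accepted = 1.0, None
        for _ in range(11):
            trial = beta + step * delta
            dt, xt, s0t, s1t, s2t, _ = _pooled_stats(hub, plan, trial, grid, cohort, nodes, meta, bin_width)
            ll_t, g_t, H_t = _llgh(trial, dt, xt, s0t, s1t, s2t)
            if ll_t >= ll - 1e-12:
                accepted = (trial, ll_t, g_t, H_t)
                break
            step /= 2.0
        iterations = it
        if accepted is None:
            break  # likelihood cannot be improved along the Newton direction
        delta_ll = accepted[1] - ll
        beta, ll, g, H = accepted
        if abs(delta_ll) < tol_ll or np.linalg.norm(g, ord=np.inf) < tol_grad:
            converged = True
            break
    if p:
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular information matrix at optimum") from exc
        se = np.sqrt(np.diag(cov))
    else:
        cov, se = np.zeros((0, 0)), np.zeros(0)
    return CoxModel(
        covariates=list(covariates),
        plan=plan,
        columns=columns,
        beta=[float(b) for b in beta],
        se=[float(s) for s in se],
        cov=[[float(v) for v in row] for row in np.atleast_2d(cov)] if p else [],
        loglik=float(ll),
        iterations=iterations,
        converged=bool(converged),
        grid=[float(t) for t in grid],
        d=[int(x) for x in d],
        n=info["n"],
        n_events=info["events"],
        cohort=cohort,
        dropped=info["dropped"],
    )


def _merge_counts(dicts):
    out: dict[str, int] = {}
    for d in dicts:
        for k, v in d.items():
            out[k] = out.get(k, 0) + v
    return out


def backward_eliminate(
    hub: FederationHub,
    covariates: list[str],
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    alpha: float = 0.05,
    transforms: dict | None = None,
    meta: dict | None = None,
) -> CoxModel:
    """Stepwise backward elimination on Wald tests.

    Whole model terms are dropped one at a time: the term with the largest
    Wald p-value (group chi-square for multi-level categoricals, identical
    to the two-sided z-test for single-column terms) is removed while that
    p exceeds ``alpha``.  Returns the final model carrying the full
    elimination trace; eliminating everything is a legitimate outcome.
    """
    remaining = list(covariates)
    trace: list[dict] = []
    model = cox_fit(hub, remaining, cohort, nodes, transforms=transforms, meta=meta)
    while remaining:
        pvals = _term_pvalues(model)
        worst_ref, worst_p = max(pvals.items(), key=lambda kv: (kv[1], remaining.index(kv[0])))
        if worst_p <= alpha:
            break
        remaining = [r for r in remaining if r != worst_ref]
        trace.append({"dropped": worst_ref, "p": float(worst_p)})
        model = cox_fit(hub, remaining, cohort, nodes, transforms=transforms, meta=meta)
    model.elimination_trace = trace
    return model


def _term_pvalues(model: CoxModel) -> dict[str, float]:
    beta = np.asarray(model.beta)
    cov = np.asarray(model.cov)
    pvals = {}
    i = 0
    for e in model.plan:
        width = len(e["levels"]) - 1 if e["kind"] == "categorical" else 1
        idx = list(range(i, i + width))
        bg = beta[idx]
        vg = cov[np.ix_(idx, idx)]
        try:
            w = float(bg @ np.linalg.solve(vg, bg))
        except np.linalg.LinAlgError:
            w = np.inf
        pvals[e["ref"]] = float(sps.chi2.sf(w, df=width))
        i += width
    return pvals


def compute_linear_predictor(
    hub: FederationHub,
    model: CoxModel,
    store_name: str,
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    meta: dict | None = None,
) -> dict[str, int]:
    """Have each station compute and *locally store* the model's linear
    predictor; only per-node completion counts return to the hub."""
    payload = {
        "plan": model.plan,
        "beta": model.beta,
        "store": store_name,
        "cohort": cohort if cohort is not None else model.cohort,
    }
    results = _ok(hub.dispatch("cox.store_lp", payload, nodes, meta=meta))
    return {r.node_id: r.payload["n"] for r in results}


def fit_cr_model(
    hub: FederationHub,
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    lp_stores: tuple[str, str] = ("LP_C", "LP_R"),
    meta: dict | None = None,
) -> CoxModel:
    """Combined model over the locally stored clinical and radiomics linear
    predictors (a federated fit with two continuous inputs)."""
    return cox_fit(hub, [f"lp:{s}" for s in lp_stores], cohort, nodes, meta=meta)


def node_concordance(
    hub: FederationHub,
    model: CoxModel | None,
    cohort: str | None = None,
    nodes: list[str] | None = None,
    *,
    lp_store: str | None = None,
    meta: dict | None = None,
) -> dict[str, dict]:
    """Per-node Harrell concordance of a model (or stored LP column); only
    the scalar index and pair counts leave each node."""
    if lp_store is not None:
        payload: dict = {"lp_store": lp_store, "cohort": cohort}
    else:
        assert model is not None
        payload = {"plan": model.plan, "beta": model.beta, "cohort": cohort if cohort is not None else model.cohort}
    results = hub.dispatch("cox.concordance", payload, nodes, meta=meta)
    out = {}
    for r in results:
        out[r.node_id] = r.payload if r.ok else {"failed": r.error}
    return out


def lodo_validate(
    hub: FederationHub,
    covariates: list[str],
    cohort: str | None = None,
    *,
    boxcox_refs: tuple[str, ...] = (),
    alpha: float | None = None,
    nodes: list[str] | None = None,
) -> dict:
    """Leave-one-dataset-out internal-external validation.

    Each fold trains transforms and model on all nodes but one and scores
    Harrell concordance on the excluded node.  Training-phase messages are
    tagged with the fold so the audit log can prove the held-out node
    contributed nothing to training.
    """
    nodes = nodes or hub.node_ids
    if len(nodes) < 2:
        raise FederationError("leave-one-dataset-out needs at least 2 nodes")
    folds = {}
    for held_out in nodes:
        train = [n for n in nodes if n != held_out]
        train_meta = {"phase": "train", "fold": held_out}
        eval_meta = {"phase": "eval", "fold": held_out}
        try:
            transforms = (
                fit_transforms(hub, list(boxcox_refs), cohort, train, meta=train_meta)
                if boxcox_refs
                else None
            )
            if alpha is None:
                model = cox_fit(hub, covariates, cohort, train, transforms=transforms, meta=train_meta)
            else:
                model = backward_eliminate(
                    hub, covariates, cohort, train, alpha=alpha, transforms=transforms, meta=train_meta
                )
            held = node_concordance(hub, model, cohort, [held_out], meta=eval_meta)[held_out]
            apparent = node_concordance(hub, model, cohort, train, meta=eval_meta)
            folds[held_out] = {
                "status": "ok",
                "columns": model.columns,
                "beta": model.beta,
                "se": model.se,
                "transforms": transforms,
                "hci_held_out": held.get("hci"),
                "hci_apparent": {n: a.get("hci") for n, a in apparent.items()},
            }
        except (FitError, FederationError) as exc:
            folds[held_out] = {"status": "failed", "error": str(exc)}
    return {"folds": folds, "nodes": list(nodes)}
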