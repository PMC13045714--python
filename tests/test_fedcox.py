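"""Federated Cox engine: equivalence with centralized Breslow fits,
transform plumbing, concordance, elimination and LODO validation."""

import numpy as np
import pandas as pd
import pytest

from fairfed import (
    FitError,
    SimulationRecipe,
    backward_eliminate,
    collect_event_times,
    compute_linear_predictor,
    cox_fit,
    federated_boxcox,
    federated_moments,
    fit_cr_model,
    harrell_concordance,
    hub_from_frames,
    lodo_validate,
    simulate_cox_data,
)
from fairfed.fedcox import _local_risk_stats, build_plan, fit_transforms


def _split(df, k, seed=0):
    idx = np.random.default_rng(seed).permutation(len(df))
    return [df.iloc[part].reset_index(drop=True) for part in np.array_split(idx, k)]


def lifelines_fit(df, covs):
    from lifelines import CoxPHFitter

    cph = CoxPHFitter()
    cph.fit(df[["time", "event"] + covs], "time", "event")
    return cph


# --------------------------------------------------------------------------
# federated / pooled equivalence
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tied_data():
    rec = SimulationRecipe(sizes=(400,), beta=(0.6, -0.3), round_times=1, seed=11)
    return simulate_cox_data(rec)[0]


@pytest.fixture(scope="module")
def signal_hub():
    rec = SimulationRecipe(sizes=(400, 400), beta=(0.9, -0.7, 0.0, 0.0, 0.0), seed=23)
    frames = simulate_cox_data(rec)
    return hub_from_frames({f"N{i}": f for i, f in enumerate(frames)})


@pytest.fixture(scope="module")
def homogeneous_hub():
    rec = SimulationRecipe(sizes=(300, 300, 300), beta=(0.8, -0.5), seed=41)
    frames = simulate_cox_data(rec)
    return hub_from_frames({f"N{i}": f for i, f in enumerate(frames)})


class TestPooledEquivalence:
    def test_partition_invariance_and_sksurv_breslow(self, tied_data):
        """beta identical across 1/2/5-node partitions and equal to the
        centralized Breslow fit (scikit-survival oracle) on tied data."""
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        betas = []
        for k in (1, 2, 5):
            hub = hub_from_frames({f"N{i}": f for i, f in enumerate(_split(tied_data, k))})
            m = cox_fit(hub, ["x1", "x2"])
            assert m.converged
            betas.append(np.asarray(m.beta))
        assert np.allclose(betas[0], betas[1], atol=1e-9)
        assert np.allclose(betas[0], betas[2], atol=1e-9)
        y = np.array(
            list(zip(tied_data["event"].astype(bool), tied_data["time"])),
            dtype=[("e", bool), ("t", float)],
        )
        oracle = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12, n_iter=200)
        oracle.fit(tied_data[["x1", "x2"]].values, y)
        assert np.allclose(betas[0], oracle.coef_, atol=1e-6)

    def test_beta_se_loglik_match_lifelines_without_ties(self):
        """On tie-free data Breslow and Efron coincide, so lifelines checks
        the likelihood value and the standard errors as well."""
        rec = SimulationRecipe(sizes=(350,), beta=(0.8, -0.5, 0.0), seed=5)
        df = simulate_cox_data(rec)[0]
        hub = hub_from_frames({f"N{i}": f for i, f in enumerate(_split(df, 3, seed=1))})
        m = cox_fit(hub, ["x1", "x2", "x3"])
        cph = lifelines_fit(df, ["x1", "x2", "x3"])
        assert np.allclose(m.beta, cph.params_.values, atol=1e-6)
        assert np.allclose(m.se, cph.standard_errors_.values, atol=1e-6)
        assert m.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_one_covariate_matches_bisection_root(self):
        """Tiny hand dataset: the federated estimate equals the root of the
        Breslow score equation found by brute-force bisection."""
        df = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 0], "x1": [1.0, 0.0, 1.0, 0.0]}
        )

        def score(beta):
            # direct enumeration of sum_deaths [x_i - S1(t_i)/S0(t_i)]
            total = 0.0
            for i in range(len(df)):
                if df["event"][i] != 1:
                    continue
                risk = df[df["time"] >= df["time"][i]]
                w = np.exp(beta * risk["x1"])
                total += df["x1"][i] - (w * risk["x1"]).sum() / w.sum()
            return total

        lo, hi = -5.0, 5.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if score(lo) * score(mid) <= 0:
                hi = mid
            else:
                lo = mid
        hub = hub_from_frames({"A": df})
        m = cox_fit(hub, ["x1"])
        assert m.beta[0] == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_null_covariate_has_small_z(self):
        rec = SimulationRecipe(sizes=(1000,), beta=(0.0,), seed=17)
        df = simulate_cox_data(rec)[0]
        hub = hub_from_frames({"A": df})
        m = cox_fit(hub, ["x1"])
        assert abs(m.beta[0] / m.se[0]) < 3


class TestLocalStats:
    def test_beta_zero_gives_risk_set_sizes(self):
        times = np.array([3.0, 1.0, 2.0, 5.0])
        events = np.array([1, 1, 0, 1])
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        grid = [1.0, 3.0, 5.0]
        d, xsum, S0, S1, _ = _local_risk_stats(times, events, X, np.zeros(1), grid)
        assert S0.tolist() == [4.0, 2.0, 1.0]  # |R_t| at exp(0)=1
        assert d.tolist() == [1.0, 1.0, 1.0]
        assert S1[:, 0].tolist() == [10.0, 5.0, 4.0]

    def test_single_subject_event(self):
        d, _, S0, _, _ = _local_risk_stats(
            np.array([3.0]), np.array([1]), np.ones((1, 1)), np.zeros(1), [3.0]
        )
        assert d.tolist() == [1.0] and S0.tolist() == [1.0]

    def test_payload_size_independent_of_node_size(self):
        rec = SimulationRecipe(sizes=(50, 800), beta=(0.5,), seed=2)
        small, large = simulate_cox_data(rec)
        hub = hub_from_frames({"S": small, "L": large})
        plan = build_plan(["x1"], next(iter(hub.stations.values())).vocab)
        grid, _ = collect_event_times(hub, plan)
        res = hub.dispatch(
            "cox.local_stats",
            {"plan": plan, "beta": [0.0], "grid": grid, "cohort": None, "bin_width": None},
        )
        def n_scalars(payload):
            return sum(np.asarray(payload[k]).size for k in ("d", "xsum", "s0", "s1", "s2"))

        sizes = {r.node_id: n_scalars(r.payload) for r in res}
        # O(|grid| p^2) scalars regardless of the node's 50 vs 800 subjects
        assert sizes["S"] == sizes["L"] == 5 * len(grid)


class TestMomentsAndBoxCox:
    def test_federated_moments_match_pooled_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(1.0, 0.4, 900)
        frames = {
            f"N{i}": pd.DataFrame(
                {"time": np.ones(300), "event": np.zeros(300, int), "f": part}
            )
            for i, part in enumerate(np.split(x, 3))
        }
        hub = hub_from_frames(frames)
        mom = federated_moments(hub, ["f"], log_moments=True)["f"]
        assert mom["mean"] == pytest.approx(x.mean(), abs=1e-12)
        assert mom["var"] == pytest.approx(x.var(), abs=1e-10)
        assert mom["sum_log"] == pytest.approx(np.log(x).sum(), rel=1e-12)

    def test_single_node_equals_local_moments(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 1], "f": [2.0, 6.0]})
        mom = federated_moments(hub_from_frames({"A": df}), ["f"])["f"]
        assert (mom["n"], mom["mean"]) == (2, 4.0)

    def test_lognormal_feature_prefers_log_transform(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1.0, 0.5, 2000)
        df = pd.DataFrame({"time": np.ones(2000), "event": np.zeros(2000, int), "f": x})
        hub = hub_from_frames({"A": df.iloc[:900], "B": df.iloc[900:]})
        lam, _ = federated_boxcox(hub, "f")
        assert abs(lam) <= 0.1

    def test_profile_matches_scipy_mle_on_gaussian_feature(self):
        from scipy import stats as sps

        x = np.random.default_rng(7).normal(10, 1, 2000)
        df = pd.DataFrame({"time": np.ones(2000), "event": np.zeros(2000, int), "f": x})
        hub = hub_from_frames({"A": df.iloc[:700], "B": df.iloc[700:]})
        lam, _ = federated_boxcox(hub, "f")
        assert lam == pytest.approx(sps.boxcox_normmax(x, method="mle"), abs=0.1)

    def test_degenerate_grid_is_identity(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0], "f": [1.0, 2.0]})
        lam, _ = federated_boxcox(hub_from_frames({"A": df}), "f", lambdas=[1.0])
        assert lam == 1.0

    def test_nonpositive_feature_is_an_error(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0], "f": [0.0, 2.0]})
        with pytest.raises(FitError, match="non-positive"):
            federated_boxcox(hub_from_frames({"A": df}), "f")


class TestEventTimes:
    def test_union_of_local_event_times(self):
        a = pd.DataFrame({"time": [5.0, 9.0, 20.0], "event": [1, 1, 0]})
        b = pd.DataFrame({"time": [5.0, 12.0], "event": [1, 1]})
        hub = hub_from_frames({"A": a, "B": b})
        times, d = collect_event_times(hub, [])
        assert times == [5.0, 9.0, 12.0]
        assert d == [2, 1, 1]

    def test_all_censored_node_contributes_nothing(self):
        a = pd.DataFrame({"time": [5.0], "event": [1]})
        b = pd.DataFrame({"time": [7.0, 8.0], "event": [0, 0]})
        times, d = collect_event_times(hub_from_frames({"A": a, "B": b}), [])
        assert (times, d) == ([5.0], [1])

    def test_no_events_anywhere_is_an_error(self):
        df = pd.DataFrame({"time": [1.0], "event": [0]})
        with pytest.raises(FitError, match="no events"):
            collect_event_times(hub_from_frames({"A": df}), [])


class TestConcordance:
    def test_perfect_ranking_gives_one(self):
        out = harrell_concordance([1.0, 2.0, 3.0], [1, 1, 1], [3.0, 2.0, 1.0])
        assert out["hci"] == 1.0

    def test_constant_predictor_gives_half(self):
        out = harrell_concordance([1.0, 2.0, 3.0], [1, 1, 1], [0.0, 0.0, 0.0])
        assert out["hci"] == 0.5

    def test_no_comparable_pairs_is_an_error(self):
        with pytest.raises(FitError, match="comparable"):
            harrell_concordance([1.0, 2.0], [0, 0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        times = np.round(rng.exponential(1.0, n), 1)
        events = rng.integers(0, 2, n)
        lp = np.round(rng.normal(size=n), 1)
        if events.sum() == 0:
            events[0] = 1
        conc = tied = comp = 0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                usable = (times[i] < times[j] and events[i] == 1) or (
                    times[i] == times[j] and events[i] == 1 and events[j] == 0
                )
                if not usable:
                    continue
                comp += 1
                if lp[i] > lp[j]:
                    conc += 1
                elif lp[i] == lp[j]:
                    tied += 1
        out = harrell_concordance(times, events, lp)
        assert (out["concordant"], out["tied_risk"], out["comparable"]) == (conc, tied, comp)
        assert out["hci"] == pytest.approx((conc + 0.5 * tied) / comp)


class TestEliminationAndComposition:
    def test_alpha_one_keeps_full_model(self, signal_hub):
        m = backward_eliminate(signal_hub, ["x1", "x2", "x3"], alpha=1.0)
        assert m.columns == ["x1", "x2", "x3"] and m.elimination_trace == []

    def test_true_predictors_survive_noise_eliminated(self, signal_hub):
        m = backward_eliminate(signal_hub, ["x1", "x2", "x3", "x4", "x5"], alpha=0.05)
        assert {"x1", "x2"} <= set(m.columns)
        assert len(m.columns) <= 3  # at most one surviving noise term

    def test_pure_noise_model_can_empty_out(self):
        rec = SimulationRecipe(sizes=(500,), beta=(0.0,), seed=31)
        hub = hub_from_frames({"A": simulate_cox_data(rec)[0]})
        m = backward_eliminate(hub, ["x1"], alpha=1e-6)
        assert m.columns == [] and len(m.elimination_trace) == 1
        assert np.isfinite(m.loglik)

    def test_linear_predictor_stored_locally_and_correct(self, signal_hub):
        model = cox_fit(signal_hub, ["x1", "x2"])
        counts = compute_linear_predictor(signal_hub, model, "LP_T")
        assert set(counts) == {"N0", "N1"}
        station = signal_hub.stations["N0"]
        lp = station.lp_store["LP_T"]
        row = station._frame.iloc[0]
        expect = model.beta[0] * row["x1"] + model.beta[1] * row["x2"]
        assert lp.iloc[0] == pytest.approx(expect, abs=1e-12)
        # no LP values cross the hub boundary
        for entry in signal_hub.audit.entries:
            if entry["kind"] == "cox.store_lp" and entry["direction"] == "result":
                assert set(entry["payload"]) == {"stored", "n"}

    def test_zero_model_gives_zero_lp(self, signal_hub):
        model = cox_fit(signal_hub, ["x1", "x2"])
        model.beta = [0.0, 0.0]
        compute_linear_predictor(signal_hub, model, "LP_Z")
        assert (signal_hub.stations["N1"].lp_store["LP_Z"] == 0).all()

    def test_cr_model_calibration_slope_and_noise_lp(self, signal_hub):
        model = cox_fit(signal_hub, ["x1", "x2"])
        compute_linear_predictor(signal_hub, model, "LP_C")
        rng = np.random.default_rng(0)
        for st in signal_hub.stations.values():
            st.lp_store["LP_R"] = pd.Series(
                rng.normal(size=len(st._frame)), index=st._frame.index
            )
        cr = fit_cr_model(signal_hub)
        assert cr.beta[0] == pytest.approx(1.0, abs=0.1)  # well-calibrated C input
        assert abs(cr.beta[1]) < 3 * cr.se[1]  # noise input near zero

    def test_identical_lp_columns_are_singular(self, signal_hub):
        model = cox_fit(signal_hub, ["x1", "x2"])
        compute_linear_predictor(signal_hub, model, "LP_A")
        compute_linear_predictor(signal_hub, model, "LP_B")
        with pytest.raises(FitError, match="singular|collinear"):
            fit_cr_model(signal_hub, lp_stores=("LP_A", "LP_B"))


class TestLodo:
    def test_fold_structure(self, homogeneous_hub):
        report = lodo_validate(homogeneous_hub, ["x1", "x2"])
        assert set(report["folds"]) == {"N0", "N1", "N2"}
        for fold in report["folds"].values():
            assert fold["status"] == "ok"

    def test_held_out_close_to_apparent_under_homogeneity(self, homogeneous_hub):
        report = lodo_validate(homogeneous_hub, ["x1", "x2"])
        for fold in report["folds"].values():
            apparent = np.mean(list(fold["hci_apparent"].values()))
            assert abs(fold["hci_held_out"] - apparent) < 0.05

    def test_no_training_messages_reach_held_out_node(self, homogeneous_hub):
        lodo_validate(homogeneous_hub, ["x1", "x2"])
        for entry in homogeneous_hub.audit.entries:
            meta = entry.get("meta", {})
            if meta.get("phase") == "train":
                assert entry["node"] != meta["fold"]

    def test_fold_transforms_use_training_nodes_only(self):
        rng = np.random.default_rng(9)
        frames = {}
        for i, mu in enumerate((0.5, 1.0, 2.0)):  # deliberately shifted nodes
            x = rng.lognormal(mu, 0.5, 250)
            frames[f"N{i}"] = pd.DataFrame(
                {
                    "time": rng.exponential(2, 250),
                    "event": rng.integers(0, 2, 250),
                    "f": x,
                }
            )
        hub = hub_from_frames(frames)
        report = lodo_validate(hub, ["f"], boxcox_refs=("f",))
        for held_out, fold in report["folds"].items():
            train = [n for n in frames if n != held_out]
            expect = fit_transforms(hub, ["f"], nodes=train)
            assert fold["transforms"] == expect

    def test_single_node_federation_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 0]})
        with pytest.raises(Exception, match="at least 2"):
            lodo_validate(hub_from_frames({"A": df}), [])


class TestGuards:
    def test_more_parameters_than_events_rejected(self):
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0],
                "event": [1, 0, 0],
                "x1": [0.1, 0.2, 0.3],
                "x2": [1.0, 0.5, 0.2],
            }
        )
        with pytest.raises(FitError, match="events"):
            cox_fit(hub_from_frames({"A": df}), ["x1", "x2"])

    def test_collinear_covariates_report_singularity(self):
        rec = SimulationRecipe(sizes=(200,), beta=(0.5,), seed=1)
        df = simulate_cox_data(rec)[0]
        df["x2"] = 2 * df["x1"]
        with pytest.raises(FitError, match="singular|collinear"):
            cox_fit(hub_from_frames({"A": df}), ["x1", "x2"])
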