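"""Path-model estimation, fit indices, bootstrap and the selection ledger."""

import numpy as np
import pandas as pd
import pytest

from microsem.errors import ValidationError
from microsem.sem import (
    PathModel,
    bootstrap_se,
    enumerate_and_select,
    enumerate_orientations,
    fit_baseline,
    fit_indices,
    fit_ml,
    group_compare,
    implied_covariance,
    _vech,
)
from microsem.simulate import (
    StructuralModel,
    default_structural_model,
    generate_sem_sample,
)


def _truth_data(n, seed, noise="uniform"):
    model = default_structural_model(noise)
    cmp_col = (np.arange(n) % 2).astype(float)
    data = generate_sem_sample(model, n, seed=seed, exogenous={"Cmp": cmp_col})
    return model, data


def _truth_pathmodel(model, data):
    return PathModel(
        model.variables,
        tuple(model.edges.keys()),
        (),
        {"Cmp": float(data["Cmp"].var(ddof=1))},
    )


class TestImpliedCovariance:
    def test_no_edges_gives_psi(self):
        m = PathModel(("a", "b"), ())
        sigma = implied_covariance(m, np.array([2.0, 3.0]))
        np.testing.assert_allclose(sigma, np.diag([2.0, 3.0]))

    def test_chain_closed_form(self):
        m = PathModel(("x", "y"), (("x", "y"),))
        b = 1.7
        sigma = implied_covariance(m, np.array([b, 1.0, 1.0]))
        np.testing.assert_allclose(sigma, [[1.0, b], [b, b**2 + 1.0]])

    def test_monte_carlo_oracle(self):
        model = StructuralModel(
            ("a", "b", "c", "d"),
            {("a", "b"): 0.6, ("b", "c"): -0.4, ("a", "d"): 0.3, ("c", "d"): 0.5},
            {v: 1.0 for v in "abcd"},
            noise_family="gaussian",
        )
        pm = PathModel(model.variables, tuple(model.edges.keys()))
        theta = np.array([0.6, -0.4, 0.3, 0.5, 1.0, 1.0, 1.0, 1.0])
        sigma = implied_covariance(pm, theta)
        x = generate_sem_sample(model, 1_000_000, seed=99).to_numpy()
        np.testing.assert_allclose(sigma, np.cov(x, rowvar=False), atol=0.01)

    def test_cycle_rejected(self):
        with pytest.raises(ValidationError, match="acyclic"):
            PathModel(("a", "b"), (("a", "b"), ("b", "a")))


class TestFitMl:
    def test_saturated_model_perfect_fit(self, rng):
        x = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        x["b"] += x["a"]
        saturated = PathModel(
            ("a", "b", "c"),
            (("a", "b"), ("a", "c"), ("b", "c")),
        )
        fit = fit_ml(saturated, x)
        assert fit.df == 0
        assert fit.fmin < 1e-8
        assert fit.t_stat < 1e-6
        idx = fit_indices(fit, fit_baseline(("a", "b", "c"), x))
        assert idx["cfi"] == 1.0
        assert idx["rmsea"] == 0.0
        assert idx["srmr"] <= 1e-6
        assert idx["gfi"] >= 1.0 - 1e-8

    def test_estimates_match_ols_oracle_on_fixed_datasets(self):
        """For recursive diagonal-Psi models the ML solution equals
        per-equation OLS; check both routes on 5 fixed datasets."""
        for seed in range(5):
            model, data = _truth_data(400, seed=seed)
            pm = _truth_pathmodel(model, data)
            fit = fit_ml(pm, data)
            est = fit.estimates
            x = data.to_numpy()
            cols = list(model.variables)
            for child in cols:
                parents = model.parents(child)
                if not parents:
                    continue
                design = np.column_stack(
                    [np.ones(len(data))] + [data[p] for p in parents]
                )
                beta = np.linalg.lstsq(design, data[child], rcond=None)[0]
                for k, parent in enumerate(parents, start=1):
                    assert abs(est[f"{parent}->{child}"] - beta[k]) < 1e-3

    def test_indices_match_definitions(self):
        """Recompute every index from its formula, independent of fit code."""
        model, data = _truth_data(500, seed=7)
        pm = _truth_pathmodel(model, data)
        fit = fit_ml(pm, data)
        base = fit_baseline(pm.variables, data)
        idx = fit_indices(fit, base)
        n, p = fit.n, len(pm.variables)
        s, sigma = fit.s, fit.sigma
        t, df = fit.t_stat, fit.df
        t0, df0 = base.t_stat, base.df
        np.testing.assert_allclose(
            idx["cfi"],
            1 - max(t - df, 0) / max(t0 - df0, t - df, 0),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            idx["rmsea"], np.sqrt(max(t - df, 0) / (df * (n - 1))), atol=1e-12
        )
        m = np.linalg.inv(sigma) @ s
        gfi = 1 - np.trace((m - np.eye(p)) @ (m - np.eye(p))) / np.trace(m @ m)
        np.testing.assert_allclose(idx["gfi"], gfi, atol=1e-12)
        np.testing.assert_allclose(
            idx["agfi"], 1 - p * (p + 1) / (2 * df) * (1 - gfi), atol=1e-12
        )
        d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
        srmr = np.sqrt(np.mean(_vech((s - sigma) / d) ** 2))
        np.testing.assert_allclose(idx["srmr"], srmr, atol=1e-12)
        np.testing.assert_allclose(idx["aic"], -2 * fit.loglik + 2 * pm.q, atol=1e-9)

    def test_parameter_recovery_within_three_se(self):
        model = default_structural_model()
        truth = dict(model.edges)
        hits = 0
        for rep in range(100):
            _, data = _truth_data(600, seed=2000 + rep)
            pm = _truth_pathmodel(model, data)
            fit = fit_ml(pm, data)
            est = fit.estimates
            se = pd.Series(fit.se, index=est.index)
            ok = all(
                abs(est[f"{p}->{c}"] - b) <= 3 * se[f"{p}->{c}"]
                for (p, c), b in truth.items()
            )
            hits += ok
        assert hits >= 90

    def test_gaussian_scaling_factor_near_one(self):
        for seed in (0, 1, 2):
            model, data = _truth_data(2000, seed=seed, noise="gaussian")
            fit = fit_ml(_truth_pathmodel(model, data), data)
            assert 0.8 <= fit.scaling <= 1.2

    def test_baseline_as_target_gives_cfi_zero(self):
        model, data = _truth_data(300, seed=3)
        base = fit_baseline(model.variables, data)
        idx = fit_indices(base, base)
        np.testing.assert_allclose(idx["cfi"], 0.0, atol=1e-12)

    def test_nested_models_monotone_fmin(self):
        model, data = _truth_data(300, seed=4)
        edges = list(model.edges.keys())
        fmins = []
        for k in range(len(edges) + 1):
            pm = PathModel(
                model.variables, tuple(edges[:k]), (),
                {"Cmp": float(data["Cmp"].var(ddof=1))},
            )
            fmins.append(fit_ml(pm, data).fmin)
        assert all(a >= b - 1e-9 for a, b in zip(fmins, fmins[1:]))

    def test_zero_variance_column_rejected(self):
        data = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(ValidationError):
            fit_ml(PathModel(("a", "b"), (("a", "b"),)), data)


class TestBootstrap:
    def test_same_seed_identical(self):
        model, data = _truth_data(150, seed=5)
        pm = _truth_pathmodel(model, data)
        a = bootstrap_se(pm, data, n_boot=100, seed=9)
        b = bootstrap_se(pm, data, n_boot=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_root_n_scaling(self):
        model, data_small = _truth_data(300, seed=6)
        _, data_big = _truth_data(1200, seed=6)
        pm_s = _truth_pathmodel(model, data_small)
        pm_b = _truth_pathmodel(model, data_big)
        se_s = bootstrap_se(pm_s, data_small, n_boot=200, seed=1)["se"]
        se_b = bootstrap_se(pm_b, data_big, n_boot=200, seed=1)["se"]
        ratio = (se_b / se_s).median()
        assert 0.4 <= ratio <= 0.6

    def test_bootstrap_close_to_analytic_on_gaussian(self):
        model, data = _truth_data(2000, seed=8, noise="gaussian")
        pm = _truth_pathmodel(model, data)
        fit = fit_ml(pm, data)
        boot = bootstrap_se(pm, data, n_boot=300, seed=2)
        edge_names = [f"{p}->{c}" for p, c in pm.edges]
        analytic = pd.Series(fit.se, index=fit.estimates.index)[edge_names]
        rel = (boot["se"][edge_names] - analytic).abs() / analytic
        assert (rel <= 0.2).all()

    def test_min_replicates_enforced(self):
        model, data = _truth_data(100, seed=9)
        with pytest.raises(ValidationError):
            bootstrap_se(_truth_pathmodel(model, data), data, n_boot=50, seed=0)


class TestSelectionLedger:
    def _candidates(self, model, data):
        truth = PathModel(
            model.variables, tuple(model.edges.keys()), (),
            {"Cmp": float(data["Cmp"].var(ddof=1))}, name="truth",
        )
        edges = dict(model.edges)
        # drop a strong edge
        missing = {e: w for e, w in edges.items() if e != ("Cmp", "Ace")}
        # rewire: swap one edge for a wrong one (skeleton changes, so the
        # variant is not Markov-equivalent to the truth)
        rewired = dict(edges)
        rewired.pop(("Bty", "Ace"))
        rewired[("Rmb", "Ace")] = 1.0
        # prune two edges
        sparse = {e: w for e, w in edges.items() if e not in (("Rmb", "Trc"), ("Bty", "Ace"))}
        out = [truth]
        for name, ed in (
            ("missing", missing), ("rewired", rewired), ("sparse", sparse)
        ):
            out.append(
                PathModel(
                    model.variables, tuple(ed.keys()), (),
                    {"Cmp": float(data["Cmp"].var(ddof=1))}, name=name,
                )
            )
        return out

    def test_true_model_selected_over_misspecified(self):
        model = default_structural_model()
        wins = 0
        for rep in range(100):
            _, data = _truth_data(600, seed=4000 + rep)
            res = enumerate_and_select(self._candidates(model, data), data)
            wins += res.selected is not None and res.selected.model.name == "truth"
        assert wins >= 80

    def test_single_passing_candidate_wins_regardless_of_aic(self):
        model, data = _truth_data(600, seed=11)
        candidates = self._candidates(model, data)
        res = enumerate_and_select(candidates, data)
        table = res.table
        if table["stage1"].sum() == 1:
            only = table.index[table["stage1"]][0]
            assert res.selected.model.name == only

    def test_equal_gap_tie_broken_by_aic(self):
        # truth versus truth + a spurious extra edge: both pass, gaps agree
        # within the shortlist tolerance, and the lower-AIC (smaller) wins
        model, data = _truth_data(800, seed=12)
        truth = PathModel(
            model.variables, tuple(model.edges.keys()), (),
            {"Cmp": float(data["Cmp"].var(ddof=1))}, name="truth",
        )
        extra_edges = tuple(model.edges.keys()) + (("Rmb", "Ace"),)
        bigger = PathModel(
            model.variables, extra_edges, (),
            {"Cmp": float(data["Cmp"].var(ddof=1))}, name="bigger",
        )
        res = enumerate_and_select([truth, bigger], data)
        assert res.table["stage1"].all()
        assert res.selected.model.name == "truth"
        assert (
            res.table.loc["truth", "aic"] < res.table.loc["bigger", "aic"]
        )

    def test_no_passer_returns_diagnostics(self, rng):
        # two variables, strongly dependent, candidate omits the edge
        x = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        x["b"] = x["a"] * 1.2 + rng.normal(0, 0.3, 400)
        null = PathModel(("a", "b"), (), name="null")
        res = enumerate_and_select([null], x)
        assert res.selected is None
        assert not res.table["stage1"].any()
        assert "cfi_robust" in res.table.columns

    def test_enumerate_orientations_respects_exogenous(self):
        models = enumerate_orientations(
            ("Cmp", "x", "y"), [("Cmp", "x"), ("x", "y")], exogenous="Cmp"
        )
        for m in models:
            assert all(c != "Cmp" for _, c in m.edges)
        assert len(models) == 2  # x->y and y->x; Cmp->x forced


class TestGroupCompare:
    def test_symmetric_split_p_one(self):
        vals = np.array([1.0, 2.0, 5.0, 1.0, 2.0, 5.0])
        labs = np.array(["A", "A", "A", "B", "B", "B"])
        res = group_compare(vals, labs)
        assert res["p"] == pytest.approx(1.0)

    def test_exact_extreme_split(self):
        res = group_compare(
            np.array([1.0, 2, 3, 10, 11, 12]),
            np.array(["A", "A", "A", "B", "B", "B"]),
        )
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(0.1)

    def test_shift_alternative_power(self):
        hits = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            a = r.normal(0, 1, 20)
            b = r.normal(2, 1, 20)
            res = group_compare(
                np.concatenate([a, b]),
                np.array(["A"] * 20 + ["B"] * 20),
            )
            hits += res["p"] < 0.05
        assert hits >= 95

    def test_single_arm_rejected(self):
        with pytest.raises(ValidationError):
            group_compare(np.arange(6.0), np.array(["A"] * 6))
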