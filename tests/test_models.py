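import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from fedstats.federation import Node
from fedstats.models import (
    DesignSpec,
    RankDeficiencyError,
    cox_loglik_grad_hess,
    design_matrix,
    fed_cox,
    fed_ols,
    significance_by_ci,
)

from conftest import make_table


class TestDesignMatrix:
    def test_period_reference_is_after(self, fixture_tables):
        t = fixture_tables[0]
        X, y = design_matrix(t.df, DesignSpec("firstline_duration_days", ("period",)), t)
        assert list(X.columns) == ["intercept", "period[before]"]
        assert set(X["period[before]"]) == {0.0, 1.0}

    def test_reference_coding_drops_reference_level(self, fixture_tables):
        t = fixture_tables[0]
        X, _ = design_matrix(
            t.df, DesignSpec("firstline_duration_days", ("treatment_category",)), t
        )
        assert "treatment_category[Chemotherapy]" not in X.columns
        assert len([c for c in X.columns if c.startswith("treatment")]) == 3

    def test_custom_reference(self, fixture_tables):
        t = fixture_tables[0]
        X, _ = design_matrix(
            t.df,
            DesignSpec(
                "firstline_duration_days",
                ("treatment_category",),
                reference={"treatment_category": "Immunotherapy"},
            ),
            t,
        )
        assert "treatment_category[Immunotherapy]" not in X.columns
        assert "treatment_category[Chemotherapy]" in X.columns

    def test_unknown_reference_rejected(self, fixture_tables):
        t = fixture_tables[0]
        with pytest.raises(ValueError):
            design_matrix(
                t.df,
                DesignSpec(
                    "firstline_duration_days",
                    ("treatment_category",),
                    reference={"treatment_category": "Radiotherapy"},
                ),
                t,
            )

    def test_complete_cases_only(self, fixture_tables):
        # the fixture has one missing creatinemia value
        t = [t for t in fixture_tables if t.df["creatinemia"].isna().any()][0]
        X, y = design_matrix(t.df, DesignSpec("creatinemia", ("period",)), t)
        assert len(X) == len(t.df) - int(t.df["creatinemia"].isna().sum())
        assert not y.isna().any()

    def test_response_among_covariates_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec("creatinemia", ("creatinemia",))


class TestFedOLS:
    DESIGN = DesignSpec("firstline_duration_days", ("period", "treatment_category"))

    def _centralized(self, tables, design):
        frames = []
        for t in tables:
            X, y = design_matrix(t.df, design, t)
            frames.append(pd.concat([X, y], axis=1))
        allx = pd.concat(frames, ignore_index=True)
        Xv = allx.iloc[:, :-1].to_numpy(float)
        yv = allx.iloc[:, -1].to_numpy(float)
        beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
        return allx.columns[:-1], beta, Xv, yv

    def test_matches_centralized_lstsq(self, fixture_tables):
        fit = fed_ols(fixture_tables, self.DESIGN)
        cols, beta, _, _ = self._centralized(fixture_tables, self.DESIGN)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_matches_statsmodels_inference(self, fixture_tables):
        import statsmodels.api as sm

        fit = fed_ols(fixture_tables, self.DESIGN)
        _, _, Xv, yv = self._centralized(fixture_tables, self.DESIGN)
        ref = sm.OLS(yv, Xv).fit()
        assert np.allclose(fit.se.to_numpy(), ref.bse, rtol=1e-8)
        ci = ref.conf_int()
        assert np.allclose(fit.conf_int["lower"].to_numpy(), ci[:, 0], rtol=1e-8)
        assert np.allclose(fit.conf_int["upper"].to_numpy(), ci[:, 1], rtol=1e-8)

    def test_invariant_to_node_partition(self, fixture_tables, fixture_pooled):
        """Splitting the data differently across nodes changes nothing."""
        from fedstats.cohort import CohortTable

        split = [
            CohortTable(fixture_pooled.iloc[idx].reset_index(drop=True))
            for idx in np.array_split(np.arange(len(fixture_pooled)), 5)
        ]
        a = fed_ols(fixture_tables, self.DESIGN).params
        b = fed_ols(split, self.DESIGN).params
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_accepts_nodes_or_tables(self, fixture_tables):
        a = fed_ols(fixture_tables, self.DESIGN).params
        b = fed_ols([Node(t.center, t) for t in fixture_tables], self.DESIGN).params
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_rank_deficiency_names_columns(self):
        t = make_table(n=30, gender=np.array(["Female"] * 30))
        with pytest.raises(RankDeficiencyError, match="gender"):
            fed_ols([t], DesignSpec("firstline_duration_days", ("gender",)))

    def test_too_few_observations(self):
        t = make_table(n=2)
        with pytest.raises(ValueError):
            fed_ols([t], DesignSpec("firstline_duration_days", ("creatinemia",)))


def _cox_instance(seed, n_per_node=40, n_nodes=3):
    """Random multi-node survival data with continuous (tie-free) times."""
    rng = np.random.default_rng(seed)
    tables, outcomes = [], {}
    for ci in range(n_nodes):
        center = f"c{ci}"
        t = make_table(
            center=center,
            n=n_per_node,
            creatinemia=rng.normal(65, 15, n_per_node),
            seed=seed * 10 + ci,
        )
        # give the period covariate within-node variation
        half = n_per_node // 2
        t.df.loc[: half - 1, "period"] = "before"
        t.df.loc[half:, "period"] = "after"
        times = rng.exponential(300, n_per_node) + rng.uniform(0, 1e-3, n_per_node)
        events = (rng.random(n_per_node) < 0.7).astype(int)
        outcomes[center] = pd.DataFrame(
            {"patient_id": t.df["patient_id"], "time_days": times, "event": events}
        )
        tables.append(t)
    return tables, outcomes


def _lifelines_fit(tables, outcomes, covariates):
    rows = []
    for t in tables:
        X, _ = design_matrix(t.df, DesignSpec("time_days", covariates), t, include_response=False)
        X = X.drop(columns=["intercept"])
        oc = outcomes[t.center].set_index("patient_id")
        d = X.copy()
        d["time_days"] = oc.loc[t.df.loc[X.index, "patient_id"], "time_days"].to_numpy()
        d["event"] = oc.loc[t.df.loc[X.index, "patient_id"], "event"].to_numpy()
        d["center"] = t.center
        rows.append(d)
    df = pd.concat(rows, ignore_index=True)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time_days", event_col="event", strata=["center"])
    return cph


class TestFedCox:
    COVARIATES = ("period", "creatinemia")

    def test_matches_lifelines(self):
        tables, outcomes = _cox_instance(1)
        fit = fed_cox(tables, DesignSpec("time_days", self.COVARIATES), outcomes=outcomes)
        cph = _lifelines_fit(tables, outcomes, self.COVARIATES)
        assert fit.converged
        assert np.allclose(
            fit.params.to_numpy(), cph.params_.to_numpy(), atol=1e-6
        )
        assert np.allclose(fit.se.to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-6)

    def test_hazard_ratio_cis_match_lifelines(self):
        tables, outcomes = _cox_instance(2)
        fit = fed_cox(tables, DesignSpec("time_days", self.COVARIATES), outcomes=outcomes)
        cph = _lifelines_fit(tables, outcomes, self.COVARIATES)
        hr = fit.hazard_ratios()
        ref = np.exp(cph.confidence_intervals_.to_numpy())
        assert np.allclose(hr[["lower", "upper"]].to_numpy(), ref, rtol=1e-5)

    def test_invariant_to_node_order(self):
        tables, outcomes = _cox_instance(3)
        a = fed_cox(tables, DesignSpec("time_days", self.COVARIATES), outcomes=outcomes).params
        b = fed_cox(
            tables[::-1], DesignSpec("time_days", self.COVARIATES), outcomes=outcomes
        ).params
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_event_free_stratum_dropped(self):
        tables, outcomes = _cox_instance(4)
        outcomes["c2"]["event"] = 0
        fit = fed_cox(tables, DesignSpec("time_days", self.COVARIATES), outcomes=outcomes)
        ref = fed_cox(tables[:2], DesignSpec("time_days", self.COVARIATES), outcomes=outcomes)
        assert np.allclose(fit.params.to_numpy(), ref.params.to_numpy(), atol=1e-10)

    def test_no_events_anywhere_rejected(self):
        tables, outcomes = _cox_instance(5, n_nodes=2)
        for oc in outcomes.values():
            oc["event"] = 0
        with pytest.raises(ValueError):
            fed_cox(tables, DesignSpec("time_days", self.COVARIATES), outcomes=outcomes)

    def test_runs_on_derived_outcomes(self, fixture_nodes):
        fit = fed_cox(fixture_nodes, DesignSpec("time_days", ("period",)))
        assert fit.converged
        assert fit.n == 149
        assert "period[before]" in fit.params.index


class TestGradHess:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        n, p = 30, 2
        X = rng.normal(size=(n, p))
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.6).astype(float)
        beta = np.array([0.3, -0.2])
        ll, g, h = cox_loglik_grad_hess(X, time, event, beta)
        eps = 1e-6
        for j in range(p):
            e = np.zeros(p)
            e[j] = eps
            lp = cox_loglik_grad_hess(X, time, event, beta + e)[0]
            lm = cox_loglik_grad_hess(X, time, event, beta - e)[0]
            assert (lp - lm) / (2 * eps) == pytest.approx(g[j], abs=1e-4)

    def test_hessian_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        n, p = 25, 2
        X = rng.normal(size=(n, p))
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.6).astype(float)
        beta = np.array([0.1, 0.4])
        _, _, h = cox_loglik_grad_hess(X, time, event, beta)
        eps = 1e-5
        for j in range(p):
            e = np.zeros(p)
            e[j] = eps
            gp = cox_loglik_grad_hess(X, time, event, beta + e)[1]
            gm = cox_loglik_grad_hess(X, time, event, beta - e)[1]
            assert np.allclose((gp - gm) / (2 * eps), h[:, j], atol=1e-3)

    def test_tied_events_share_risk_set(self):
        """Breslow convention, checked against a naive direct implementation."""
        X = np.array([[1.0], [0.0], [1.0], [0.0], [1.0]])
        time = np.array([2.0, 2.0, 2.0, 5.0, 7.0])
        event = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        beta = np.array([0.5])
        ll, _, _ = cox_loglik_grad_hess(X, time, event, beta)

        eta = (X @ beta).ravel()
        eta_c = eta - eta.max()
        naive = 0.0
        for k in np.flatnonzero(event):
            risk = time >= time[k]
            naive += eta_c[k] - np.log(np.exp(eta_c[risk]).sum())
        assert ll == pytest.approx(naive, abs=1e-12)

    def test_loglik_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        n = 20
        X = rng.normal(size=(n, 2))
        time = rng.exponential(1.0, n)
        event = (rng.random(n) < 0.5).astype(float)
        beta = np.array([0.2, -0.3])
        ll1 = cox_loglik_grad_hess(X, time, event, beta)[0]
        perm = rng.permutation(n)
        ll2 = cox_loglik_grad_hess(X[perm], time[perm], event[perm], beta)[0]
        assert ll1 == pytest.approx(ll2, abs=1e-10)


class TestSignificance:
    def test_ols_null_zero(self, fixture_tables):
        fit = fed_ols(fixture_tables, DesignSpec("firstline_duration_days", ("period",)))
        sig = significance_by_ci(fit)
        for name in fit.params.index:
            lo, hi = fit.conf_int.loc[name]
            assert sig[name] == (lo > 0 or hi < 0)

    def test_cox_null_one_on_hr_scale(self, fixture_nodes):
        fit = fed_cox(fixture_nodes, DesignSpec("time_days", ("period",)))
        sig = significance_by_ci(fit)
        hr = fit.hazard_ratios()
        for name in fit.params.index:
            assert sig[name] == (hr.loc[name, "lower"] > 1 or hr.loc[name, "upper"] < 1)
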