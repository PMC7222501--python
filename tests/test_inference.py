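"""Model inference: OLS, type-II LRTs, effect sizes, vertex, diagnostics, cohort stats."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import mmratio as mm
from mmratio.inference import ALL_TERMS, MAIN_TERMS
from mmratio.simulate import Truth
from tests.conftest import pipeline_frame


def small_model_frame(rng, n=60, two_cohorts=True):
    cohort = np.where(np.arange(n) % 2 == 0, "A", "B") if two_cohorts else np.array(["A"] * n)
    df = pd.DataFrame(
        {
            "age": rng.normal(74, 4, n),
            "gender": rng.integers(0, 2, n).astype(float),
            "education": rng.integers(0, 2, n).astype(float),
            "cohort": cohort,
            "suvr_norm": rng.uniform(0.8, 1.6, n),
            "fdg_z": rng.normal(0, 1, n),
        }
    )
    df["mmr"] = (
        9 * df["suvr_norm"] - 4 * df["suvr_norm"] ** 2 + 0.5 * df["fdg_z"] + rng.normal(0, 1, n)
    )
    return df


class TestOLSAgainstClosedForm:
    def test_coefficients_match_normal_equations(self, rng):
        data = small_model_frame(rng, n=80)
        report = mm.fit_mmr_model(data, lrt=False, diagnostics=False)
        from mmratio.inference import _design, _prepare

        prep, _ = _prepare(data, None)
        X = _design(prep, ALL_TERMS, True).to_numpy()
        y = data["mmr"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(report.coefficients["estimate"].to_numpy(), beta, atol=1e-8)

    def test_rank_deficiency_names_aliased_terms(self, rng):
        data = small_model_frame(rng, n=50)
        data["fdg_z"] = data["suvr_norm"]  # alias fdg with av45
        with pytest.raises(mm.EstimationError, match="aliased"):
            mm.fit_mmr_model(data, lrt=False, diagnostics=False)

    def test_single_cohort_with_cohort_terms_rejected(self, rng):
        data = small_model_frame(rng, n=50, two_cohorts=False)
        with pytest.raises(mm.EstimationError, match="single cohort"):
            mm.fit_mmr_model(data)


class TestTypeIILRT:
    def test_identical_models_give_zero_statistic(self, rng):
        data = small_model_frame(rng)
        res = mm.lrt_compare(data, list(ALL_TERMS), list(ALL_TERMS))
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_marginality_violation_raises(self, rng):
        data = small_model_frame(rng)
        # dropping the fdg main effect while keeping av45:fdg violates marginality
        with pytest.raises(mm.ContractViolationError, match="marginality"):
            mm.lrt_compare(data, list(ALL_TERMS), [t for t in ALL_TERMS if t != "fdg"])

    def test_combined_av45_test_has_two_df(self, recovery_frame):
        res = mm.lrt_type2(recovery_frame, "av45")
        assert res.df == 2

    def test_strong_quadratic_signal_detected(self, recovery_frame):
        assert mm.lrt_type2(recovery_frame, "av45").pvalue < 0.001

    def test_null_pvalues_uniform(self):
        # no amyloid effect: the combined 2-df LRT p-value is uniform
        import dataclasses

        cfg = mm.recovery_config(truth=Truth(b_lin=0.0, b_quad=0.0))
        cfg = mm.recovery_config(
            truth=Truth(b_lin=0.0, b_quad=0.0),
            cohorts=tuple(dataclasses.replace(c, n=4 * c.n) for c in cfg.cohorts),
        )
        pvals = []
        for i in range(120):
            frame = pipeline_frame(mm.simulate_cohorts(cfg, seed=60000 + i))
            pvals.append(mm.lrt_type2(frame, "av45").pvalue)
        ks = st.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_gaussian_lrt_agrees_with_f_test_at_large_n(self):
        # asymptotic equivalence of the LRT and the F test of the same term
        import dataclasses

        cfg = mm.recovery_config(truth=Truth(b_lin=0.5, b_quad=-0.2))
        cfg = mm.recovery_config(
            truth=Truth(b_lin=0.5, b_quad=-0.2),
            cohorts=tuple(dataclasses.replace(c, n=11 * c.n) for c in cfg.cohorts),
        )
        frame = pipeline_frame(mm.simulate_cohorts(cfg, seed=77))
        from mmratio.inference import _design, _prepare, _type2_pair

        comparison, reduced = _type2_pair("av45", ALL_TERMS)
        prep, _ = _prepare(frame, None)
        y = frame["mmr"].to_numpy()
        import statsmodels.api as sm

        fit_c = sm.OLS(y, _design(prep, comparison, True)).fit()
        fit_r = sm.OLS(y, _design(prep, reduced, True)).fit()
        f_res = fit_c.compare_f_test(fit_r)
        lrt = mm.lrt_type2(frame, "av45")
        assert abs(lrt.pvalue - f_res[1]) < 0.01


class TestEffectSizeAndVertex:
    def test_f2_arithmetic(self):
        assert mm.cohens_f2(0.20, 0.10) == pytest.approx(0.125)

    def test_f2_zero_when_no_contribution(self):
        assert mm.cohens_f2(0.3, 0.3) == 0.0

    def test_f2_undefined_at_perfect_fit(self):
        with pytest.raises(mm.DegenerateInputError):
            mm.cohens_f2(1.0, 0.5)

    def test_f2_matches_rss_oracle(self, recovery_frame):
        from mmratio.inference import _design, _prepare, _type2_pair

        report = mm.fit_mmr_model(recovery_frame, diagnostics=False)
        prep, _ = _prepare(recovery_frame, None)
        y = recovery_frame["mmr"].to_numpy()
        tss = float(((y - y.mean()) ** 2).sum())
        for term in ("fdg", "av45", "age"):
            comparison, reduced = _type2_pair(term, ALL_TERMS)

            def r2(terms):
                X = _design(prep, terms, True).to_numpy()
                beta = np.linalg.solve(X.T @ X, X.T @ y)
                rss = float(((y - X @ beta) ** 2).sum())
                return 1.0 - rss / tss

            r2_full, r2_red = r2(comparison), r2(reduced)
            expected = (r2_full - r2_red) / (1 - r2_full)
            assert report.effect_sizes[term] == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize(
        "b_lin,b_quad,vertex,kind",
        [
            (2.0, -1.0, 1.0, "maximum"),
            (0.0, -3.0, 0.0, "maximum"),
            (10.31, -4.37, 1.1796, "maximum"),
            (2.0, 0.5, -2.0, "minimum"),
        ],
    )
    def test_vertex_values(self, b_lin, b_quad, vertex, kind):
        x, k = mm.quadratic_vertex(b_lin, b_quad)
        assert round(x, 4) == pytest.approx(vertex)
        assert k == kind

    def test_no_vertex_without_quadratic(self):
        with pytest.raises(mm.DegenerateInputError):
            mm.quadratic_vertex(1.0, 0.0)

    def test_report_vertex_consistent_with_coefficients(self, recovery_frame):
        report = mm.fit_mmr_model(recovery_frame, diagnostics=False, lrt=False)
        b_lin = report.coefficients.loc["av45", "estimate"]
        b_quad = report.coefficients.loc["av45_sq", "estimate"]
        assert report.vertex == pytest.approx(-b_lin / (2 * b_quad))
        assert report.vertex_kind == "maximum"
        assert report.vertex_main_effects is not None


class TestInfluence:
    @staticmethod
    def _fit(X, y):
        import statsmodels.api as sm

        return sm.OLS(y, X).fit()

    def test_hat_values_sum_to_parameter_count(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 3))])
        y = rng.normal(size=40)
        diag = mm.influence_diagnostics(self._fit(X, y))
        assert diag["hat_value"].sum() == pytest.approx(4.0)
        assert ((diag["hat_value"] > 0) & (diag["hat_value"] <= 1)).all()

    def test_duplicated_balanced_design_equal_hats(self):
        base = np.array([[1.0, 0.0], [1.0, 1.0]])
        X = np.vstack([base] * 10)
        y = np.tile([1.0, 2.0], 10) + np.linspace(0, 0.1, 20)
        diag = mm.influence_diagnostics(self._fit(X, y))
        assert np.allclose(diag["hat_value"], 0.1)

    def test_gross_outlier_attains_max_cooks(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 0.5, 30)
        y[17] += 25.0
        diag = mm.influence_diagnostics(self._fit(X, y))
        assert diag["cooks_distance"].idxmax() == 17

    def test_cooks_matches_leave_one_out_oracle(self, rng):
        # D_i from the closed form equals the explicit refit-without-row-i value
        n, p = 30, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = X @ np.array([0.5, 1.0, -2.0]) + rng.normal(0, 1, n)
        fit = self._fit(X, y)
        diag = mm.influence_diagnostics(fit)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        s2 = float(((y - X @ beta) ** 2).sum() / (n - p))
        XtX = X.T @ X
        for i in range(n):
            mask = np.arange(n) != i
            beta_i = np.linalg.solve(X[mask].T @ X[mask], X[mask].T @ y[mask])
            d = beta - beta_i
            D_i = float(d @ XtX @ d) / (p * s2)
            assert diag["cooks_distance"].iloc[i] == pytest.approx(D_i, abs=1e-8)

    def test_full_report_diagnostics(self, recovery_frame):
        report = mm.fit_mmr_model(recovery_frame)
        assert len(report.diagnostics) == report.n
        assert report.diagnostics["hat_value"].sum() == pytest.approx(
            len(report.coefficients), abs=1e-8
        )
        assert (report.diagnostics["cooks_distance"] >= 0).all()


class TestParameterRecovery:
    def test_estimates_within_three_se_of_truth(self, recovery_frame):
        report = mm.fit_mmr_model(recovery_frame, lrt=False, diagnostics=False)
        coef = report.coefficients
        for name, truth in [("av45", 9.0), ("av45_sq", -4.0)]:
            est, se = coef.loc[name, "estimate"], coef.loc[name, "se"]
            assert abs(est - truth) < 3 * se, f"{name}: {est} vs {truth} (se {se})"

    def test_quadratic_improves_loglik_on_quadratic_truth(self, recovery_frame):
        full = mm.fit_mmr_model(recovery_frame, lrt=False, diagnostics=False)
        linear_only = mm.fit_mmr_model(
            recovery_frame, include_quadratic=False, lrt=False, diagnostics=False
        )
        assert full.loglik > linear_only.loglik


class TestCohortDescriptives:
    def test_welch_t_reference_age_comparison(self):
        # printed cohort age summaries: 71.97±5.79 (n=158) vs 76.02±3.5 (n=290)
        res = mm.welch_t(71.97, 5.79, 158, 76.02, 3.5, 290)
        assert round(res.statistic, 2) == -8.03
        assert res.pvalue < 0.001

    def test_welch_identical_groups(self):
        res = mm.welch_t(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_welch_equals_pooled_under_equal_var_equal_n(self):
        ours = mm.welch_t(4.0, 1.5, 40, 5.0, 1.5, 40)
        pooled = st.ttest_ind_from_stats(4.0, 1.5, 40, 5.0, 1.5, 40, equal_var=True)
        assert ours.statistic == pytest.approx(pooled.statistic)
        assert ours.df == pytest.approx(78.0)

    def test_welch_degenerate_variance(self):
        with pytest.raises(mm.DegenerateInputError):
            mm.welch_t(1.0, 0.0, 10, 2.0, 0.0, 10)

    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[95, 63], [183, 107]], 0.27),  # female/male counts per cohort
            ([[157, 1], [196, 94]], 59.94),  # higher/lower education counts
        ],
    )
    def test_chi2_yates_reference_tables(self, table, expected):
        res = mm.chisq_2x2(table)
        assert round(res.statistic, 2) == expected

    def test_chi2_identical_proportions_without_correction(self):
        res = mm.chisq_2x2([[20, 30], [40, 60]], continuity_correction=False)
        assert res.statistic == pytest.approx(0.0)

    def test_chi2_zero_margin_rejected(self):
        with pytest.raises(mm.DegenerateInputError):
            mm.chisq_2x2([[0, 0], [10, 20]])

    def test_chi2_requires_integer_counts(self):
        with pytest.raises(mm.ValidationError):
            mm.chisq_2x2([[1.5, 2], [3, 4]])


class TestReportSerialization:
    def test_json_roundtrip_keys(self, recovery_frame, tmp_path):
        import json

        report = mm.fit_mmr_model(recovery_frame)
        path = tmp_path / "report.json"
        report.to_json(path)
        doc = json.loads(path.read_text())
        assert set(doc["coefficients"]) == set(report.coefficients.index)
        assert doc["lrt"]["av45"]["df"] == 2
        assert doc["n"] == report.n

    def test_table_layout(self, recovery_frame, tmp_path):
        report = mm.fit_mmr_model(recovery_frame)
        table = report.table()
        assert list(table.columns) == ["estimate", "se", "es", "p"]
        # linear and squared amyloid rows share the combined test's p-value
        assert table.loc["av45", "p"] == table.loc["av45_sq", "p"]
        path = tmp_path / "coef.csv"
        table.to_csv(path)
        assert path.exists()


class TestModelFrameAssembly:
    def test_misaligned_ids_rejected(self, default_sim):
        tables = list(default_sim.tables.values())
        mmrs = [mm.cohort_mmr(t) for t in tables]
        panels = [
            mm.harmonize(t, threshold=default_sim.truth["thresholds"][t.cohort_id])
            for t in tables
        ]
        broken = mm.MMRResult(
            cohort_id=mmrs[0].cohort_id,
            frame=mmrs[0].frame.set_axis([f"X{i}" for i in range(len(mmrs[0].frame))]),
        )
        with pytest.raises(mm.ValidationError, match="align"):
            mm.build_model_frame(tables, [broken, mmrs[1]], panels)

    def test_frame_has_one_row_per_participant(self, default_sim):
        frame = pipeline_frame(default_sim)
        assert len(frame) == sum(t.n for t in default_sim.tables.values())
        assert set(frame["cohort"]) == set(default_sim.tables)
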