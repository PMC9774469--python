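"""Quadratic response-surface fitting, ANOVA, optimization, perturbation."""

import numpy as np
import pytest

from mbester import rsm
from mbester.rsm import (
    REFERENCE_MODEL,
    QuadraticModel,
    SingularFitError,
    anova,
    design_matrix,
    fit_quadratic,
    model_hierarchy,
    optimize_response,
    perturbation_profiles,
    predict,
    predict_quiet,
)


def brute_force_eval(model: QuadraticModel, pt) -> float:
    """Independent term-by-term evaluation oracle."""
    A, B, C = pt
    return (
        model.b0 + model.bA * A + model.bB * B + model.bC * C
        + model.bAB * A * B + model.bAC * A * C + model.bBC * B * C
        + model.bAA * A * A + model.bBB * B * B + model.bCC * C * C
    )


class TestPredict:
    def test_center_point_returns_intercept(self):
        assert predict(REFERENCE_MODEL, (0.0, 0.0, 0.0)) == pytest.approx(88.68)

    def test_reported_optimum_prediction(self):
        # coded image of (ratio 23.73, catalyst 3.3 wt%, time 59.79 min)
        pt = (0.873, 0.32, 0.24475)
        assert predict(REFERENCE_MODEL, pt) == pytest.approx(99.10, abs=0.05)

    def test_all_high_corner_by_hand_summation(self):
        assert predict(REFERENCE_MODEL, (1.0, 1.0, 1.0)) == pytest.approx(99.45)

    def test_matches_brute_force_oracle_on_random_points(self, rng):
        pts = rng.uniform(-1, 1, (50, 3))
        for pt in pts:
            assert predict_quiet(REFERENCE_MODEL, pt) == pytest.approx(
                brute_force_eval(REFERENCE_MODEL, pt), abs=1e-12
            )

    def test_extrapolation_warns_and_clip_caps(self):
        with pytest.warns(UserWarning, match="extrapolation"):
            y = predict(REFERENCE_MODEL, (2.0, 0.0, 0.0))
        assert y == pytest.approx(88.68 + 2 * 3.27 - 4 * 1.74)
        big = QuadraticModel(101.0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
        assert predict(big, (0.0, 0.0, 0.0), clip=True) == 100.0


class TestFitQuadratic:
    def test_recovers_generating_coefficients_exactly(self, noiseless_table):
        model, diag = fit_quadratic(noiseless_table)
        assert np.allclose(
            model.coefficients, REFERENCE_MODEL.coefficients, atol=1e-8
        )
        assert diag.r2 == pytest.approx(1.0)
        assert diag.rmse == pytest.approx(0.0, abs=1e-8)

    def test_constant_response_gives_pure_intercept(self, bbd17):
        model, _ = fit_quadratic(bbd17.with_responses(np.full(17, 42.0)))
        assert model.b0 == pytest.approx(42.0)
        assert np.allclose(model.coefficients[1:], 0.0, atol=1e-10)

    def test_noiseless_linear_response(self, bbd17):
        model, diag = fit_quadratic(bbd17.with_responses(2.0 * bbd17.coded[:, 0]))
        assert model.bA == pytest.approx(2.0)
        others = np.delete(model.coefficients, 1)
        assert np.allclose(others, 0.0, atol=1e-10)
        assert diag.r2 == pytest.approx(1.0)

    def test_rmse_uses_population_divisor(self, bbd17, rng):
        y = rng.normal(80, 3, 17)
        model, diag = fit_quadratic(bbd17.with_responses(y))
        resid = y - design_matrix(bbd17.coded) @ model.coefficients
        assert diag.rmse == pytest.approx(np.sqrt(np.sum(resid**2) / 17))

    def test_rank_deficient_design_names_columns(self, bbd17):
        frame = bbd17.frame.copy()
        frame["C_coded"] = frame["B_coded"]  # collinear
        table = type(bbd17)(frame, bbd17.factors)
        with pytest.raises(SingularFitError, match="rank deficient"):
            fit_quadratic(table.with_responses(np.arange(17.0)))

    def test_linear_block_invariant_to_quadratic_terms(self, bbd17, rng):
        """On the BBD, linear/interaction estimates do not change when the
        pure-quadratic columns are dropped (block orthogonality)."""
        y = rng.normal(80, 5, 17)
        X_full = design_matrix(bbd17.coded)
        beta_full = np.linalg.lstsq(X_full, y, rcond=None)[0]
        X_sub = X_full[:, :7]
        beta_sub = np.linalg.lstsq(X_sub, y, rcond=None)[0]
        assert np.allclose(beta_full[1:7], beta_sub[1:7], atol=1e-9)


class TestAnova:
    def test_noiseless_fit_has_zero_residual_and_additive_ss(self, noiseless_table):
        model, _ = fit_quadratic(noiseless_table)
        tbl = anova(model, noiseless_table).set_index("source")
        assert tbl.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-8)
        total = tbl.loc["Total", "sum_sq"]
        assert tbl.loc["Model", "sum_sq"] + tbl.loc["Residual", "sum_sq"] == (
            pytest.approx(total, rel=1e-8)
        )

    def test_pure_error_df_from_center_replicates(self, bbd17, rng):
        y = rng.normal(80, 3.0832, 17)
        table = bbd17.with_responses(y)
        model, _ = fit_quadratic(table)
        tbl = anova(model, table).set_index("source")
        assert tbl.loc["Pure error", "df"] == 4  # 5 center runs -> 4 df
        assert tbl.loc["Lack of fit", "sum_sq"] + tbl.loc[
            "Pure error", "sum_sq"
        ] == pytest.approx(tbl.loc["Residual", "sum_sq"], rel=1e-8)
        assert (
            tbl.loc["Lack of fit", "df"] + tbl.loc["Pure error", "df"]
            == tbl.loc["Residual", "df"]
        )

    def test_catalyst_term_dominates_generated_data(self, bbd17):
        cfg_y = design_matrix(bbd17.coded) @ REFERENCE_MODEL.coefficients
        y = cfg_y + np.random.default_rng(0).normal(0, 3.0832, 17)
        table = bbd17.with_responses(y)
        model, _ = fit_quadratic(table)
        tbl = anova(model, table).set_index("source")
        terms = ["A", "B", "C", "AB", "AC", "BC", "A^2", "B^2", "C^2"]
        ss = tbl.loc[terms, "sum_sq"]
        # the catalyst linear effect (26.13 per coded unit) dominates linears
        assert ss["B"] == ss[["A", "B", "C", "AB", "AC", "BC"]].max()

    def test_no_replicates_warns_and_omits_lack_of_fit(self):
        from mbester.design import PAPER_FACTORS, build_bbd

        table = build_bbd(PAPER_FACTORS, n_center=1)
        y = design_matrix(table.coded) @ REFERENCE_MODEL.coefficients
        y = y + np.random.default_rng(1).normal(0, 1, len(y))
        table = table.with_responses(y)
        model, _ = fit_quadratic(table)
        with pytest.warns(UserWarning, match="lack-of-fit"):
            tbl = anova(model, table)
        assert "Lack of fit" not in set(tbl["source"])

    def test_linear_type_iii_equals_sequential_on_bbd(self, bbd17, rng):
        """For the orthogonal linear/interaction block, the partial SS equals
        the classical n·beta² sequential SS."""
        y = rng.normal(80, 5, 17)
        table = bbd17.with_responses(y)
        model, _ = fit_quadratic(table)
        tbl = anova(model, table).set_index("source")
        X = design_matrix(bbd17.coded)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        for j, name in [(1, "A"), (2, "B"), (3, "C")]:
            seq_ss = beta[j] ** 2 * np.sum(X[:, j] ** 2)
            assert tbl.loc[name, "sum_sq"] == pytest.approx(seq_ss, rel=1e-8)


class TestModelHierarchy:
    def test_quadratic_ranked_first_on_curved_data(self, bbd17):
        y = design_matrix(bbd17.coded) @ REFERENCE_MODEL.coefficients
        y = y + np.random.default_rng(3).normal(0, 1.0, 17)
        ranked = model_hierarchy(bbd17.with_responses(y))
        assert ranked[0][0] == "full quadratic"
        assert len(ranked) == 3

    def test_linear_ranked_first_on_linear_data(self, bbd17):
        y = bbd17.coded[:, 0] + np.random.default_rng(4).normal(0, 0.05, 17)
        ranked = model_hierarchy(bbd17.with_responses(y))
        assert ranked[0][0] == "linear"


class TestOptimize:
    def test_reference_model_optimum_is_on_the_boundary(self):
        report = optimize_response(REFERENCE_MODEL)
        assert report.location == "boundary"
        assert np.max(np.abs(report.coded)) == pytest.approx(1.0)
        assert report.predicted > 99.45
        # stationary point of the unconstrained gradient system lies outside
        x_stat = np.linalg.solve(
            REFERENCE_MODEL.hessian, -REFERENCE_MODEL.gradient_at_origin
        )
        assert np.any(np.abs(x_stat) > 1.0)
        assert x_stat[2] == pytest.approx(2.08, abs=0.05)

    def test_concave_bowl_has_interior_optimum_at_origin(self):
        bowl = QuadraticModel(0, 0, 0, 0, 0, 0, 0, -1, -1, -1)
        report = optimize_response(bowl)
        assert report.location == "interior stationary"
        assert np.allclose(report.coded, 0.0, atol=1e-12)
        assert report.predicted == pytest.approx(0.0)
        assert report.concave

    def test_exhaustive_grid_never_beats_reported_optimum(self, rng):
        """Face-enumeration optimum dominates a dense grid scan (oracle)."""
        for _ in range(5):
            coeffs = rng.normal(0, 3, 10)
            model = QuadraticModel(*coeffs)
            report = optimize_response(model)
            g = np.linspace(-1, 1, 21)
            pts = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
            grid_best = (design_matrix(pts) @ model.coefficients).max()
            assert report.predicted >= grid_best - 1e-9

    def test_explicit_evaluation_point_reproduces_reported_prediction(self):
        pt = (0.873, 0.32, 0.24475)
        assert predict_quiet(REFERENCE_MODEL, pt) == pytest.approx(99.10, abs=0.05)


class TestPerturbation:
    def test_factor_b_trace_endpoints(self):
        profiles = perturbation_profiles(REFERENCE_MODEL, n_points=3)
        b = profiles[profiles.factor == "B"].set_index("coded")["response"]
        assert b.loc[1.0] == pytest.approx(88.68 + 26.13 - 29.76)
        assert b.loc[-1.0] == pytest.approx(88.68 - 26.13 - 29.76)

    def test_symmetric_model_gives_symmetric_trace(self):
        model = QuadraticModel(0, 0, 0, 0, 0, 0, 0, 0, -1, 0)
        profiles = perturbation_profiles(model, n_points=5)
        b = profiles[profiles.factor == "B"]["response"].to_numpy()
        assert np.allclose(b, b[::-1])

    def test_all_traces_agree_at_the_center(self):
        center = (0.2, -0.3, 0.4)
        profiles = perturbation_profiles(REFERENCE_MODEL, center=center)
        want = predict_quiet(REFERENCE_MODEL, center)
        for name, k in (("A", 0), ("B", 1), ("C", 2)):
            tr = profiles[profiles.factor == name]
            at_center = tr[np.isclose(tr.coded, center[k])]["response"]
            assert at_center.iloc[0] == pytest.approx(want)


class TestSerialization:
    def test_model_dict_round_trip(self):
        d = REFERENCE_MODEL.to_dict()
        back = QuadraticModel.from_dict(d)
        assert np.allclose(back.coefficients, REFERENCE_MODEL.coefficients)
        assert back.factor_specs == REFERENCE_MODEL.factor_specs
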