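import numpy as np
import pandas as pd
import pytest

import qbdopt as q
from qbdopt.model import ResponseSurfaceModel
from qbdopt.simulate import TruthSpec, generate_bbd_study


class TestTermSets:
    @pytest.mark.parametrize("ctor,n", [(q.ar_terms, 13), (q.be_terms, 14), (q.cr_terms, 6)])
    def test_term_counts(self, ctor, n):
        assert len(ctor()) == n

    def test_cubic_cross_term_present(self):
        assert (2, 1, 0, 0) in q.ar_terms()

    def test_intercept_only(self):
        ts = q.make_term_set([(0, 0, 0, 0)])
        assert len(ts) == 1 and ts.names == ["1"]

    def test_duplicate_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            q.make_term_set([(1, 0, 0, 0), (1, 0, 0, 0)])

    def test_design_matrix_values(self):
        X = q.cr_terms().design_matrix(np.array([[0.5, 1.0, -1.0, 0.0]]))
        np.testing.assert_allclose(X[0], [1, 0.5, -1, 0, 0.25, 1])


class TestFitOnStudy:
    def test_linear_coefficients_match_bbd_contrast_oracle(self, study):
        """In this orthogonal design each linear coefficient equals its simple
        contrast (sum at +1 - sum at -1)/12 — an oracle independent of the
        linear-algebra path."""
        res = q.fit_ols(study, "z3", q.cr_terms())
        z = study.means("z3")
        for name in ("F1", "F3", "F4"):
            lv = study.coded[name]
            contrast = (z[lv == 1].sum() - z[lv == -1].sum()) / 12
            assert res.params[name] == pytest.approx(contrast, abs=1e-10)

    def test_recovery_fit_rounds_to_published_coefficients(self, study):
        res = q.fit_ols(study, "z3", q.cr_terms())
        assert round(res.params["1"], 1) == 76.4
        assert round(res.params["F1"], 1) == 7.0
        assert round(res.params["F3"], 1) == 34.6

    @pytest.mark.parametrize("response,terms", [
        ("z1", q.ar_terms()), ("z2", q.be_terms()), ("z3", q.cr_terms())])
    def test_residual_orthogonality(self, study, response, terms):
        """Normal equations: X'(y - Xb) = 0 on every fit."""
        model = ResponseSurfaceModel(study, response, terms)
        res = model.fit()
        resid = model.endog - model.exog @ res.params.to_numpy()
        np.testing.assert_allclose(model.exog.T @ resid, 0, atol=1e-8)

    def test_noiseless_synthetic_recovery(self):
        truth = TruthSpec(models={"z3": q.published_cr_model()}, noise_sd={"z3": 0.0})
        table = generate_bbd_study(truth)
        res = q.fit_ols(table, "z3", q.cr_terms())
        np.testing.assert_allclose(
            res.params.to_numpy(), q.published_cr_model().coefficients, atol=1e-9)
        assert res.rsquared == pytest.approx(1.0)
        assert res.mse_resid == pytest.approx(0.0, abs=1e-18)

    def test_rank_deficiency_names_terms(self, study):
        # on three-level columns F2 and F2^3 coincide
        bad = q.make_term_set([(0, 0, 0, 0), (0, 1, 0, 0), (0, 3, 0, 0)])
        with pytest.raises(ValueError, match="rank deficient"):
            ResponseSurfaceModel(study, "z3", bad)

    def test_replicate_level_fit_changes_df(self, study):
        truth = TruthSpec(models={"z3": q.published_cr_model()},
                          noise_sd={"z3": 5.0}, replicates=3, seed=1)
        table = generate_bbd_study(truth)
        means_fit = q.fit_ols(table, "z3", q.cr_terms(), level="means")
        reps_fit = q.fit_ols(table, "z3", q.cr_terms(), level="replicates")
        assert means_fit.df_resid == 21
        assert reps_fit.df_resid == 75
        with pytest.raises(ValueError, match="replicate"):
            q.fit_ols(study, "z3", q.cr_terms(), level="replicates")


class TestDiagnostics:
    def test_three_point_line_mse(self):
        """Closed-form least squares on a 3-observation toy: y = (0,1,0) at
        x = (-1,0,1) gives slope 0, intercept 1/3, SSE 2/3, MSE 2/3."""
        df = pd.DataFrame({"x": [-1.0, 0.0, 1.0], "y": [0.0, 1.0, 0.0]})
        terms = q.make_term_set([(0,), (1,)], factor_names=("x",))
        res = ResponseSurfaceModel.from_dataframe(df, "y", terms, factor_names=("x",)).fit()
        assert res.params["1"] == pytest.approx(1 / 3)
        assert res.params["x"] == pytest.approx(0.0, abs=1e-12)
        assert res.mse_resid == pytest.approx(2 / 3)

    def test_adjusted_r2_below_r2(self, study):
        res = q.fit_ols(study, "z3", q.cr_terms())
        assert 0 <= res.rsquared_adj <= res.rsquared <= 1
        assert res.df_resid == 27 - 6

    def test_summary_renders(self, study):
        text = q.fit_ols(study, "z3", q.cr_terms()).summary()
        assert "R2_adj" in text and "F3" in text


class TestPredict:
    def test_published_be_at_reported_optimum(self, pub_models):
        assert pub_models["z2"].predict([0.19, 1, 1, 0]) == pytest.approx(0.12, abs=0.005)

    def test_intercept_at_origin(self, pub_models):
        assert pub_models["z3"].predict([0, 0, 0, 0]) == pytest.approx(76.4)

    def test_recovery_corner_value(self, pub_models):
        assert pub_models["z3"].predict([1, 0, 1, -1]) == pytest.approx(118.0)

    def test_dimension_mismatch(self, pub_models):
        with pytest.raises(ValueError, match="coordinates"):
            pub_models["z3"].predict([1, 0, 1])

    def test_linear_in_coefficients(self):
        ts = q.cr_terms()
        rng = np.random.default_rng(3)
        c1, c2 = rng.normal(size=6), rng.normal(size=6)
        pts = rng.uniform(-1, 1, size=(10, 4))
        m1, m2 = q.PolynomialModel(ts, c1), q.PolynomialModel(ts, c2)
        combo = q.PolynomialModel(ts, 2.0 * c1 + 3.0 * c2)
        np.testing.assert_allclose(
            combo.predict(pts), 2.0 * m1.predict(pts) + 3.0 * m2.predict(pts))

    def test_json_round_trip(self, pub_models, tmp_path):
        p = tmp_path / "m.json"
        pub_models["z2"].to_json(p)
        again = q.PolynomialModel.from_json(p)
        np.testing.assert_allclose(again.coefficients, pub_models["z2"].coefficients)
        assert again.terms == pub_models["z2"].terms


class TestMarginalMeans:
    def test_recovery_by_sedds_level(self, study):
        mm = q.marginal_means(study, "z3", "F3")
        assert mm[1.0] == pytest.approx(108.7667, abs=1e-3)
        assert mm[-1.0] == pytest.approx(39.5833, abs=1e-3)

    def test_constant_response(self, space):
        table = generate_bbd_study(TruthSpec(
            models={"y": q.PolynomialModel(q.make_term_set([(0, 0, 0, 0)]), np.array([5.0]), "y")},
            noise_sd={"y": 0.0}))
        mm = q.marginal_means(table, "y", "F1")
        assert mm.nunique() == 1

    def test_unknown_factor(self, study):
        with pytest.raises(KeyError):
            q.marginal_means(study, "z3", "F9")


class TestEvaluateGrid:
    def test_grid_matches_pointwise_predict(self, pub_models):
        ax1, ax2, Z = q.evaluate_grid(pub_models["z3"], ("F1", "F3"),
                                      {"F2": 0.0, "F4": 0.0}, resolution=3)
        for i, a in enumerate(ax1):
            for j, b in enumerate(ax2):
                assert Z[i, j] == pytest.approx(
                    pub_models["z3"].predict([a, 0.0, b, 0.0]))

    def test_corner_value(self, pub_models):
        _, _, Z = q.evaluate_grid(pub_models["z3"], ("F1", "F3"),
                                  {"F2": 0.0, "F4": 0.0}, resolution=3)
        # 76.4 + 7.0 + 34.6 - 1.7 - 1.7
        assert Z[-1, -1] == pytest.approx(114.6)

    def test_refinement_never_lowers_maximum(self, pub_models):
        _, _, coarse = q.evaluate_grid(pub_models["z1"], ("F1", "F3"),
                                       {"F2": 0.0, "F4": 0.0}, resolution=5)
        _, _, fine = q.evaluate_grid(pub_models["z1"], ("F1", "F3"),
                                     {"F2": 0.0, "F4": 0.0}, resolution=9)
        assert fine.max() >= coarse.max()

    def test_discrete_free_factor_needs_explicit_relaxation(self, pub_models, space):
        with pytest.raises(ValueError, match="relax"):
            q.evaluate_grid(pub_models["z1"], ("F2", "F3"),
                            {"F1": 0.0, "F4": 0.0}, resolution=3, space=space)
        # explicit relaxation is allowed for visualisation
        q.evaluate_grid(pub_models["z1"], ("F2", "F3"), {"F1": 0.0, "F4": 0.0},
                        resolution=3, space=space, relax_discrete=True)

    def test_missing_fixed_level(self, pub_models):
        with pytest.raises(ValueError, match="missing"):
            q.evaluate_grid(pub_models["z3"], ("F1", "F3"), {"F2": 0.0})
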