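"""Statistical machinery against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from canopygrowth.errors import DomainError, InferenceError
from canopygrowth.inference import (
    GROWTH_DESIGN,
    ModelFit,
    akaike_weights,
    average_models,
    cooks_distance,
    enumerate_subsets,
    fit_lm,
    fit_sa_model,
    impute_missing_sa,
    path_analysis,
    screen_interactions,
    summarize_traits,
    transform_and_scale,
)
from canopygrowth.synthetic import generate_trait_table


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

class TestTransformAndScale:
    def test_scaled_columns_are_standardized(self, traits43):
        dm = transform_and_scale(traits43[0], GROWTH_DESIGN)
        numeric = [c for c in dm.X if not c.startswith("species[")]
        for c in numeric:
            assert dm.X[c].mean() == pytest.approx(0.0, abs=1e-12)
            assert dm.X[c].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert dm.y.mean() == pytest.approx(0.0, abs=1e-12)

    def test_sweetia_is_reference_level(self, traits43):
        dm = transform_and_scale(traits43[0], GROWTH_DESIGN)
        sp_cols = [c for c in dm.X if c.startswith("species[")]
        assert len(sp_cols) == 3
        assert "species[Sweetia]" not in dm.X.columns
        sweetia = dm.species.str.contains("Sweetia")
        assert (dm.X.loc[sweetia.to_numpy(), sp_cols] == 0).all().all()

    def test_log_of_nonpositive_names_tree(self, traits43):
        bad = traits43[0].copy()
        bad.loc[bad.index[3], "sa"] = -1.0
        tid = bad.iloc[3]["tree_id"]
        with pytest.raises(DomainError, match=str(tid)):
            transform_and_scale(bad, GROWTH_DESIGN)

    def test_permutation_invariance(self, traits43):
        t = traits43[0]
        shuffled = t.sample(frac=1.0, random_state=5)
        a = transform_and_scale(t, GROWTH_DESIGN)
        b = transform_and_scale(shuffled, GROWTH_DESIGN)
        assert set(a.scaling) == set(b.scaling)
        for k in a.scaling:
            np.testing.assert_allclose(a.scaling[k], b.scaling[k])


# ---------------------------------------------------------------------------
# OLS / Cook's distance
# ---------------------------------------------------------------------------

class TestFitLm:
    def test_noiseless_exact(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x1", "x2"])
        y = 2 * X["x1"] - X["x2"]
        fit = fit_lm(X, y)
        assert fit.params["x1"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["x2"] == pytest.approx(-1.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        y = pd.Series(rng.normal(size=20))
        fit = fit_lm(X, y)
        Xc = np.column_stack([np.ones(20), X.to_numpy()])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)

    def test_aic_identity_and_sigma_in_k(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        y = pd.Series(rng.normal(size=25))
        fit = fit_lm(X, y)
        assert fit.k == 4  # intercept + 2 slopes + residual variance
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)

    def test_rank_deficient_lists_aliased(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 1)), columns=["a"])
        X["b"] = 2 * X["a"]
        with pytest.raises(InferenceError, match="aliased"):
            fit_lm(X, pd.Series(rng.normal(size=20)))


class TestCooksDistance:
    def test_exact_fit_all_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 1)), columns=["x"])
        fit = fit_lm(X, 3 * X["x"] + 1)
        assert np.allclose(cooks_distance(fit)["cooks_d"], 0.0, atol=1e-20)

    def test_gross_outlier_flagged_as_maximum(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 1)), columns=["x"])
        y = 2 * X["x"] + rng.normal(scale=0.1, size=30)
        y.iloc[7] += 25.0
        d = cooks_distance(fit_lm(X, y))
        assert d["cooks_d"].idxmax() == 7
        assert d.loc[7, "flagged"]

    def test_matches_leave_one_out_definition(self, rng):
        """Cook's D_i == sum_j (yhat_j - yhat_j(i))^2 / (p * s^2)."""
        n = 10
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = pd.Series(rng.normal(size=n))
        fit = fit_lm(X, y)
        Xc = np.column_stack([np.ones(n), X.to_numpy()])
        p = Xc.shape[1]
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        resid = y.to_numpy() - Xc @ beta
        s2 = resid @ resid / (n - p)
        expected = []
        for i in range(n):
            keep = np.arange(n) != i
            beta_i = np.linalg.solve(Xc[keep].T @ Xc[keep], Xc[keep].T @ y[keep])
            diff = Xc @ beta - Xc @ beta_i
            expected.append(diff @ diff / (p * s2))
        np.testing.assert_allclose(cooks_distance(fit)["cooks_d"].to_numpy(),
                                   expected, atol=1e-10)


# ---------------------------------------------------------------------------
# subsets, weights, averaging
# ---------------------------------------------------------------------------

class TestEnumerateSubsets:
    def test_counts_and_intercept_only(self, traits43):
        spec = replace(GROWTH_DESIGN,
                       predictors=GROWTH_DESIGN.predictors[:3])
        dm = transform_and_scale(traits43[0], spec)
        fits = enumerate_subsets(dm)
        assert len(fits) == 2 ** 4  # 3 traits + species block
        assert any(f.terms == () for f in fits)
        aics = [f.aic for f in fits]
        assert aics == sorted(aics)

    def test_best_matches_exhaustive_oracle(self, traits43):
        """Independent enumeration: direct OLS + Gaussian AIC per subset."""
        spec = replace(GROWTH_DESIGN, predictors=GROWTH_DESIGN.predictors[:4])
        dm = transform_and_scale(traits43[0], spec)
        fits = enumerate_subsets(dm)

        def aic_of(cols):
            Xc = np.column_stack([np.ones(len(dm.y))]
                                 + [dm.X[c].to_numpy() for c in cols])
            beta, *_ = np.linalg.lstsq(Xc, dm.y.to_numpy(), rcond=None)
            r = dm.y.to_numpy() - Xc @ beta
            n = len(r)
            s2 = (r @ r) / n
            llf = -n / 2 * (np.log(2 * np.pi * s2) + 1)
            return 2 * (Xc.shape[1] + 1) - 2 * llf

        best_oracle, best_terms = np.inf, None
        names = [g.name for g in dm.groups]
        by = {g.name: g for g in dm.groups}
        for r_ in range(len(names) + 1):
            for combo in itertools.combinations(names, r_):
                cols = [c for nm in combo for c in by[nm].columns]
                a = aic_of(cols)
                if a < best_oracle - 1e-12:
                    best_oracle, best_terms = a, combo
        assert set(fits[0].terms) == set(best_terms)
        assert fits[0].aic == pytest.approx(best_oracle, abs=1e-8)

    def test_marginality_constraint(self, traits43):
        dm = transform_and_scale(traits43[0], GROWTH_DESIGN,
                                 interactions=["log(sa)"])
        fits = enumerate_subsets(dm)
        for f in fits:
            if "species:log(sa)" in f.terms:
                assert "species" in f.terms and "log(sa)" in f.terms

    def test_term_count_guard(self, traits43):
        dm = transform_and_scale(traits43[0], GROWTH_DESIGN)
        bloated = replace(dm, groups=dm.groups * 3)
        with pytest.raises(InferenceError, match="guard"):
            enumerate_subsets(bloated)


class TestAkaikeWeights:
    def test_symmetry_and_hand_value(self):
        np.testing.assert_allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])
        np.testing.assert_allclose(akaike_weights([10.0, 12.0]),
                                   [0.73106, 0.26894], atol=1e-4)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_weights_sum_to_one(self, aics):
        assert akaike_weights(aics).sum() == pytest.approx(1.0)


def _toy_fit(terms, cols, betas, ses, aic):
    idx = ["const"] + list(cols)
    params = pd.Series([0.0] + list(betas), index=idx)
    se = pd.Series([1.0] + list(ses), index=idx)
    return ModelFit(terms=tuple(terms), params=params, se=se,
                    tvalues=params / se, pvalues=se * 0 + 0.5,
                    loglik=-(aic - 2 * (len(idx) + 1)) / 2,
                    k=len(idx) + 1, aic=aic, n=50, rss=1.0)


class TestAverageModels:
    def test_single_model_is_identity(self):
        f = _toy_fit(["x"], ["x"], [0.5], [0.1], 100.0)
        g = _toy_fit(["x", "z"], ["x", "z"], [0.5, 0.2], [0.1, 0.1], 103.0)
        avg = average_models([f, g])
        assert len(avg.component_models) == 1
        assert avg.coefficients["x"] == pytest.approx(0.5)
        assert avg.importance["x"] == pytest.approx(1.0)

    def test_two_equal_weight_models_average(self):
        f = _toy_fit(["x"], ["x"], [0.5], [0.1], 100.0)
        g = _toy_fit(["x"], ["x"], [0.7], [0.1], 100.0)
        avg = average_models([f, g])
        assert avg.coefficients["x"] == pytest.approx(0.6)
        # Burnham-Anderson adjusted SE with equal weights
        expected = 0.5 * (np.sqrt(0.01 + 0.01) + np.sqrt(0.01 + 0.01))
        assert avg.se_adj["x"] == pytest.approx(expected)

    def test_importance_splits_by_weight(self):
        f = _toy_fit(["x"], ["x"], [0.5], [0.1], 100.0)
        g = _toy_fit(["z"], ["z"], [0.2], [0.1], 101.0)
        avg = average_models([f, g])
        w = akaike_weights([100.0, 101.0])
        assert avg.importance["x"] == pytest.approx(w[0])
        assert avg.importance["z"] == pytest.approx(w[1])
        assert avg.weights.sum() == pytest.approx(1.0)

    def test_conditional_average_within_component_range(self, traits430):
        dm = transform_and_scale(traits430[0], GROWTH_DESIGN)
        avg = average_models(enumerate_subsets(dm))
        for c in avg.coefficients.index:
            vals = [f.params[c] for f in avg.component_models
                    if c in f.params.index]
            assert min(vals) - 1e-12 <= avg.coefficients[c] <= max(vals) + 1e-12


# ---------------------------------------------------------------------------
# interaction screening
# ---------------------------------------------------------------------------

class TestScreenInteractions:
    def test_null_retention_near_alpha(self, cfg_unmasked):
        """Without true interactions the per-test retention rate ~ alpha."""
        hits = trials = 0
        for s in range(40):
            traits, _ = generate_trait_table(cfg_unmasked, seed=50_000 + s,
                                             n_scale=10)
            kept = screen_interactions(traits, GROWTH_DESIGN)
            hits += len(kept)
            trials += len(GROWTH_DESIGN.predictors)
        rate = hits / trials
        # binomial 99% envelope around alpha=0.05 for 240 trials
        assert 0.01 < rate < 0.10

    def test_strong_interaction_is_retained(self, cfg_unmasked):
        traits, _ = generate_trait_table(cfg_unmasked, seed=77, n_scale=10)
        # inject a 1-SD species-specific SA slope difference
        z = np.log(traits["sa"])
        z = (z - z.mean()) / z.std(ddof=1)
        bump = traits["species"].str.contains("Hura").astype(float)
        traits = traits.assign(agr=traits["agr"] * np.exp(0.68 * bump * z))
        kept = screen_interactions(traits, GROWTH_DESIGN)
        assert "log(sa)" in kept

    def test_single_species_yields_nothing(self, traits43):
        one = traits43[0][traits43[0]["species"].str.contains("Hura")]
        assert screen_interactions(one, GROWTH_DESIGN) == []


# ---------------------------------------------------------------------------
# imputation, SA model, path analysis, summary
# ---------------------------------------------------------------------------

class TestImputeMissingSa:
    def test_no_missing_is_identity(self, traits43):
        out = impute_missing_sa(traits43[0])
        pd.testing.assert_frame_equal(out, traits43[0])

    def test_imputed_values_track_hidden_truth(self, cfg):
        rs = []
        for s in range(60):
            masked, truth = generate_trait_table(cfg, seed=60_000 + s)
            filled = impute_missing_sa(masked)
            hide = masked["sa"].isna()
            r = np.corrcoef(np.log(filled.loc[hide, "sa"]),
                            np.log(truth.traits_full.loc[hide.to_numpy(), "sa"]))[0, 1]
            rs.append(r)
        assert np.mean(rs) > 0.8

    def test_growth_model_robust_to_imputation(self, cfg):
        """Coefficient signs/significance agree with and without the
        imputed species (the robustness the analysis relies on)."""
        from canopygrowth.inference import fit_growth_model

        masked, _ = generate_trait_table(cfg, seed=123, n_scale=10)
        with_imp, _, _ = fit_growth_model(impute_missing_sa(masked),
                                          screen=False)
        without, _, _ = fit_growth_model(masked[masked["sa"].notna()],
                                         screen=False)
        a, b = with_imp.coefficients, without.coefficients
        assert np.sign(a["log(sa)"]) == np.sign(b["log(sa)"]) == 1
        assert with_imp.pvalues["log(sa)"] < 0.001
        assert without.pvalues["log(sa)"] < 0.001

    def test_all_missing_rejected(self, traits43):
        t = traits43[0].copy()
        t["sa"] = np.nan
        with pytest.raises(InferenceError):
            impute_missing_sa(t)


class TestSaModel:
    def test_all_three_predictors_positive(self, traits430):
        fit = fit_sa_model(traits430[0])
        for term in ["sapwood_growth", "sapwood_lifespan", "log(ba)"]:
            assert fit.params[term] > 0

    def test_null_effect_config_recovers_zero(self, cfg_unmasked):
        null_cfg = replace(cfg_unmasked,
                           sa_coef=(("sapwood_growth", 0.0),
                                    ("sapwood_lifespan", 0.0), ("ba", 0.0)),
                           sa_resid_sd=1.0)
        ests = []
        for s in range(20):
            traits, _ = generate_trait_table(null_cfg, seed=70_000 + s,
                                             n_scale=10)
            ests.append(fit_sa_model(traits).params["sapwood_growth"])
        mean = np.mean(ests)
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean) < 3 * mc_se

    def test_excludes_imputed_rows(self, cfg):
        masked, _ = generate_trait_table(cfg, seed=5)
        filled = impute_missing_sa(masked)
        fit = fit_sa_model(filled)
        assert fit.n == masked["sa"].notna().sum()


class TestPathAnalysis:
    def test_matches_ols_on_centered_data(self, traits430):
        res = path_analysis(traits430[0])
        t = traits430[0]
        data = pd.DataFrame({
            "growth": np.log(t["agr"]), "height": t["height"],
            "sa": np.log(t["sa"]), "tla": np.sqrt(t["tla"]),
        })
        centered = data - data.groupby(t["species"].to_numpy()).transform("mean")
        centered /= centered.std(ddof=1)
        Xc = np.column_stack([np.ones(len(t)),
                              centered[["height", "sa", "tla"]].to_numpy()])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ centered["growth"].to_numpy())
        np.testing.assert_allclose(res.paths["coef"].to_numpy(), beta[1:],
                                   atol=1e-10)

    def test_correlations_bounded_and_symmetric(self, traits430):
        res = path_analysis(traits430[0])
        assert ((res.correlations["r"] >= -1) & (res.correlations["r"] <= 1)).all()
        assert len(res.correlations) == 3

    def test_sa_dominates_other_paths(self, traits430):
        res = path_analysis(traits430[0])
        coefs = res.paths["coef"].abs()
        assert coefs["sa"] == coefs.max()


class TestSummarizeTraits:
    def test_cv_is_sd_over_mean(self, traits43):
        s = summarize_traits(traits43[0])
        np.testing.assert_allclose(s["cv"], s["sd"] / s["mean"])

    def test_constant_column(self, traits43):
        t = traits43[0].copy()
        t["height"] = 25.0
        s = summarize_traits(t)
        assert s.loc["height", "sd"] == 0.0
        assert s.loc["height", "cv"] == 0.0

    def test_all_null_column_warns(self, traits43, caplog):
        t = traits43[0].copy()
        t["sa"] = np.nan
        with caplog.at_level("WARNING"):
            s = summarize_traits(t)
        assert np.isnan(s.loc["sa", "mean"])


def test_tla_sa_ratio_analysis_is_expressible(traits430):
    """The hydraulic-conductance check: growth ~ TLA:SA ratio + species is a
    derived column plus an ordinary species-factor fit."""
    t = traits430[0].copy()
    t = t[t["sa"].notna()].assign(ratio=lambda d: d["tla"] / d["sa"])
    spec_cols = pd.get_dummies(t["species"], drop_first=True).astype(float)
    X = pd.concat([pd.Series((t["ratio"] - t["ratio"].mean())
                             / t["ratio"].std(ddof=1), name="ratio"),
                   spec_cols], axis=1)
    fit = fit_lm(X, np.log(t["agr"]))
    assert np.isfinite(fit.tvalues["ratio"])
    assert 0 <= fit.pvalues["ratio"] <= 1
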