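"""Standardization, model-set generation, fitting, AICc, weights, averaging."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sdckit.multimodel import (
    DISPLAY_TERMS,
    CandidateModel,
    TopModelSet,
    aicc,
    akaike_weights,
    build_predictor_table,
    design_matrix,
    fit_glm,
    generate_model_set,
    model_average_zero,
    predict_response,
    rank_models,
    standardize,
)


class TestStandardize:
    def test_two_point_column_forced_values(self):
        df = pd.DataFrame({"x": [0.0, 2.0]})
        out, rec = standardize(df)
        np.testing.assert_allclose(out["x"], [-0.35355339, 0.35355339])
        mean, sd, lo, hi = rec.stats["x"]
        assert (mean, lo, hi) == (1.0, 0.0, 2.0)
        assert sd == pytest.approx(math.sqrt(2))

    def test_output_mean_zero_sd_half(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.normal(3, 5, 200)})
        out, _ = standardize(df)
        assert out["x"].mean() == pytest.approx(0, abs=1e-12)
        assert out["x"].std(ddof=1) == pytest.approx(0.5)

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(0, 1, 100)})
        once, _ = standardize(df)
        twice, _ = standardize(once)
        np.testing.assert_allclose(once["x"], twice["x"], atol=1e-12)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="'flat'"):
            standardize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))

    def test_age_squared_before_standardization(self):
        df = pd.DataFrame({
            "sdc": [1.0, 2.0, 3.0, 4.0], "age": [4, 10, 20, 30],
            "sex": ["F", "M", "F", "M"], "year": [2014, 2015, 2014, 2015],
        })
        table, rec = build_predictor_table(df, "sdc", ("age", "age2"))
        mean, _, lo, hi = rec.stats["age2"]
        assert (lo, hi) == (16.0, 900.0)
        assert mean == pytest.approx(np.mean([16.0, 100.0, 400.0, 900.0]))


def oracle_model_set(full_terms, exclusions, marginality=True):
    """Independent exhaustive enumeration with an explicit validity predicate."""
    def requires(term):
        if ":" in term:
            return term.split(":")
        if term.endswith("2") and term[:-1] in full_terms:
            return [term[:-1]]
        return []

    valid = []
    for r in range(len(full_terms) + 1):
        for sub in itertools.combinations(full_terms, r):
            s = set(sub)
            if marginality and not all(set(requires(t)) <= s for t in sub):
                continue
            if any({a, b} <= s for a, b in exclusions):
                continue
            valid.append(sub)
    return valid


class TestGenerateModelSet:
    def test_single_term(self):
        assert generate_model_set(["x"], exclusions=()) == [(), ("x",)]

    def test_quadratic_requires_main(self):
        models = generate_model_set(["age", "age2"], exclusions=())
        assert models == [(), ("age",), ("age", "age2")]

    def test_interaction_requires_both_mains(self):
        models = generate_model_set(["a", "b", "a:b"], exclusions=())
        assert ("a:b",) not in models
        assert ("a", "a:b") not in models
        assert ("a", "b", "a:b") in models

    def test_exclusion_pair_removed(self):
        models = generate_model_set(["g", "d"], exclusions=[("g", "d")])
        assert set(models) == {(), ("g",), ("d",)}

    def test_full_display_terms_match_oracle(self):
        got = generate_model_set(DISPLAY_TERMS)
        expected = oracle_model_set(DISPLAY_TERMS, [("group_size", "date")])
        assert sorted(got) == sorted(expected)
        assert () in got

    def test_max_terms_caps_model_size(self):
        models = generate_model_set(["a", "b", "c"], exclusions=(), max_terms=1)
        assert max(len(m) for m in models) == 1


def oracle_ols(y, X):
    """Hand-coded normal equations + gaussian ML log-likelihood."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    n = len(y)
    sigma2 = resid @ resid / n
    llf = -n / 2 * (math.log(2 * math.pi * sigma2) + 1)
    return beta, llf


class TestFitGLM:
    def _table(self, n=20, seed=3):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(0, 0.5, n)
        x2 = rng.normal(0, 0.5, n)
        y = 2.0 + 1.5 * x1 - 0.7 * x2 + rng.normal(0, 1, n)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2})

    def test_gaussian_matches_normal_equations_oracle(self):
        tbl = self._table()
        m = fit_glm(tbl, "y", ("x1", "x2"), "gaussian")
        X = np.column_stack([np.ones(len(tbl)), tbl["x1"], tbl["x2"]])
        beta, llf = oracle_ols(tbl["y"].to_numpy(), X)
        np.testing.assert_allclose(
            [m.params["Intercept"], m.params["x1"], m.params["x2"]], beta, rtol=1e-10
        )
        assert m.loglik == pytest.approx(llf, rel=1e-12)
        assert m.k == 4  # intercept + 2 slopes + residual variance

    def test_gaussian_exact_fit_flagged_degenerate(self):
        tbl = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [0.0, 1.0, 2.0, 3.0]})
        m = fit_glm(tbl, "y", ("x",), "gaussian")
        assert m.degenerate
        assert m.params["x"] == pytest.approx(1.0)

    def test_binomial_intercept_only_closed_form(self):
        y = np.array([1] * 13 + [0] * 43, dtype=float)
        tbl = pd.DataFrame({"breeder": y})
        m = fit_glm(tbl, "breeder", (), "binomial")
        assert m.params["Intercept"] == pytest.approx(math.log(13 / 43), rel=1e-6)
        assert m.k == 1
        # llf of the saturated-in-mean Bernoulli model
        p = 13 / 56
        llf = 13 * math.log(p) + 43 * math.log(1 - p)
        assert m.loglik == pytest.approx(llf, rel=1e-9)

    def test_binomial_separation_flagged(self):
        tbl = pd.DataFrame({"b": [0.0] * 10 + [1.0] * 10,
                            "x": list(range(10)) + list(range(20, 30))})
        tbl["x"] = (tbl["x"] - tbl["x"].mean()) / (2 * tbl["x"].std(ddof=1))
        m = fit_glm(tbl, "b", ("x",), "binomial")
        assert not m.converged

    def test_interaction_column_is_product(self):
        tbl = self._table()
        X = design_matrix(tbl, ("x1", "x2", "x1:x2"))
        np.testing.assert_allclose(X["x1:x2"], tbl["x1"] * tbl["x2"])


class TestAICc:
    @pytest.mark.parametrize(
        "loglik, k, n, expected",
        [(-479.75, 5, 100, 970.14), (-27.96, 2, 56, 60.15), (-177.51, 5, 100, 365.66)],
    )
    def test_printed_arithmetic(self, loglik, k, n, expected):
        assert aicc(loglik, k, n) == pytest.approx(expected, abs=0.011)

    def test_limits_to_aic_for_huge_n(self):
        assert aicc(-10, 2, 10**9) == pytest.approx(24.0, abs=1e-6)

    def test_undefined_correction_raises(self):
        with pytest.raises(ValueError):
            aicc(-10, 5, 6)

    def test_monotone_decreasing_in_loglik(self):
        assert aicc(-10, 3, 50) > aicc(-5, 3, 50)


class TestAkaikeWeights:
    def test_printed_weight_column(self):
        w = akaike_weights([970.14, 971.44, 972.04])  # deltas 0, 1.3, 1.9
        np.testing.assert_allclose(w, [0.52, 0.27, 0.20], atol=0.005)

    def test_single_model_weight_one(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_equal_aicc_symmetric(self):
        np.testing.assert_allclose(akaike_weights([10.0, 10.0]), [0.5, 0.5])

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        w = akaike_weights(rng.uniform(100, 200, 20))
        assert w.sum() == pytest.approx(1.0)
        assert np.all((w >= 0) & (w <= 1))


def _candidate(terms, params, bse, loglik, k, n):
    return CandidateModel(
        terms=terms, family="gaussian", params=params, bse=bse,
        loglik=loglik, k=k, n=n, aicc=aicc(loglik, k, n),
    )


class TestModelAveraging:
    def test_single_model_average_is_itself(self):
        m = _candidate(("x",), {"Intercept": 1.0, "x": 2.0},
                       {"Intercept": 0.1, "x": 0.2}, -50.0, 3, 30)
        _, top = rank_models([m])
        avg = model_average_zero(top)
        assert avg.loc["x", "estimate"] == pytest.approx(2.0)
        assert avg.loc["x", "se"] == pytest.approx(0.2)
        assert avg.loc["x", "sum_of_weights"] == pytest.approx(1.0)

    def test_absent_term_shrinks_toward_zero(self):
        # weight 0.6 model has x=2.0; weight 0.4 model lacks x -> estimate 1.2
        w = np.array([0.6, 0.4])
        m1 = _candidate(("x",), {"Intercept": 0.0, "x": 2.0},
                        {"Intercept": 0.1, "x": 0.5}, -50.0, 3, 40)
        m2 = _candidate((), {"Intercept": 0.0}, {"Intercept": 0.1}, -51.0, 2, 40)
        top = TopModelSet(models=[m1, m2], weights=w)
        avg = model_average_zero(top)
        assert avg.loc["x", "estimate"] == pytest.approx(1.2)
        assert avg.loc["x", "sum_of_weights"] == pytest.approx(0.6)

    def test_three_model_fixture_matches_hand_computation(self):
        # hand-specified betas, SEs and weights; expectations computed by the
        # zero-method formulas with an explicit loop (spreadsheet-style)
        weights = np.array([0.5, 0.3, 0.2])
        models = [
            _candidate(("a", "b"), {"Intercept": 1.0, "a": 3.0, "b": -1.0},
                       {"Intercept": 0.2, "a": 0.6, "b": 0.3}, -10.0, 4, 30),
            _candidate(("a",), {"Intercept": 1.2, "a": 2.5},
                       {"Intercept": 0.25, "a": 0.5}, -11.0, 3, 30),
            _candidate(("b",), {"Intercept": 0.8, "b": -0.6},
                       {"Intercept": 0.3, "b": 0.25}, -12.0, 3, 30),
        ]
        top = TopModelSet(models=models, weights=weights)
        avg = model_average_zero(top)

        for term, present in (("a", [True, True, False]), ("b", [True, False, True])):
            betas = np.array([m.params.get(term, 0.0) for m in models])
            variances = np.array([m.bse.get(term, 0.0) ** 2 for m in models])
            est = sum(w * b for w, b in zip(weights, betas))
            se = sum(w * math.sqrt(v + (b - est) ** 2)
                     for w, v, b in zip(weights, variances, betas))
            assert avg.loc[term, "estimate"] == pytest.approx(est)
            assert avg.loc[term, "se"] == pytest.approx(se)
            assert avg.loc[term, "ci_lower"] == pytest.approx(est - 1.96 * se)
            assert avg.loc[term, "ci_upper"] == pytest.approx(est + 1.96 * se)
            assert avg.loc[term, "sum_of_weights"] == pytest.approx(
                sum(w for w, p in zip(weights, present) if p))

    def test_estimate_bounded_by_max_coefficient(self):
        rng = np.random.default_rng(11)
        models = []
        for i in range(4):
            b = float(rng.normal(0, 2))
            models.append(_candidate(("x",), {"Intercept": 0.0, "x": b},
                                     {"Intercept": 0.1, "x": 0.2},
                                     -50.0 - i, 3, 40))
        _, top = rank_models(models, delta_threshold=10)
        avg = model_average_zero(top)
        assert abs(avg.loc["x", "estimate"]) <= max(
            abs(m.params["x"]) for m in models) + 1e-12

    def test_duplicate_model_recompute_path_stable(self):
        m1 = _candidate(("x",), {"Intercept": 0.0, "x": 1.0},
                        {"Intercept": 0.1, "x": 0.2}, -50.0, 3, 40)
        m2 = _candidate((), {"Intercept": 0.5}, {"Intercept": 0.1}, -50.5, 2, 40)
        _, top_a = rank_models([m1, m2], delta_threshold=10)
        est_a = model_average_zero(top_a).loc["x", "estimate"]
        dup = _candidate(("x",), {"Intercept": 0.0, "x": 1.0},
                         {"Intercept": 0.1, "x": 0.2}, -50.0, 3, 40)
        _, top_b = rank_models([m1, m2, dup], delta_threshold=10)
        est_b = model_average_zero(top_b).loc["x", "estimate"]
        # the duplicate doubles its model's weight share; weights were
        # recomputed so the averaged estimate shifts toward its coefficient
        d = m1.aicc - m2.aicc  # m2 (null) has the lower AICc here
        r = math.exp(-d / 2)
        assert est_b == pytest.approx(2 * r / (2 * r + 1) * 1.0)
        assert est_b != pytest.approx(est_a)


class TestRankModels:
    def test_top_set_weights_renormalized(self):
        models = [
            _candidate((), {"Intercept": 0.0}, {"Intercept": 0.1}, llf, 2, 40)
            for llf in (-50.0, -50.5, -53.0)
        ]
        ranked, top = rank_models(models, delta_threshold=2.0)
        assert len(top.models) == 2
        assert top.weights.sum() == pytest.approx(1.0)
        assert ranked[0].delta == 0.0

    def test_aicc_tie_broken_by_fewer_parameters(self):
        small = _candidate((), {"Intercept": 0.0}, {"Intercept": 0.1}, -51.1185, 2, 40)
        # pick loglik so both models have identical AICc
        big_llf = -(small.aicc - 2 * 3 - 2 * 3 * 4 / (40 - 3 - 1)) / 2
        big = _candidate(("x",), {"Intercept": 0.0, "x": 1.0},
                         {"Intercept": 0.1, "x": 0.2}, big_llf, 3, 40)
        assert big.aicc == pytest.approx(small.aicc)
        ranked, _ = rank_models([big, small])
        assert ranked[0].k == 2


class TestPredictResponse:
    def _scaling(self):
        df = pd.DataFrame({
            "sdc": np.zeros(5), "age": [4.0, 10, 20, 30, 37],
            "sex": ["F", "M", "F", "M", "F"], "year": [2014] * 3 + [2015] * 2,
            "date": [0.0, 40, 80, 120, 151],
        })
        return build_predictor_table(df, "sdc", ("age", "age2", "date"))[1]

    def test_zero_slopes_give_flat_curve(self):
        rec = self._scaling()
        out = predict_response({"Intercept": 7.0, "age": 0.0, "age2": 0.0, "date": 0.0},
                               rec, ages=[5, 15, 25])
        np.testing.assert_allclose(out["prediction"], 7.0)

    def test_quadratic_maximum_location(self):
        rec = self._scaling()
        coefs = {"Intercept": 10.0, "age": 1.0, "age2": -2.0}
        ages = np.linspace(4, 37, 331)
        out = predict_response(coefs, rec, ages)
        # maximum of b1*z1 + b2*z2 where z1, z2 standardize age, age^2:
        # d/dage = b1/(2 s1) + b2*age/s2 = 0  ->  age* = -b1 s2 / (2 s1 b2)
        _, s1, _, _ = rec.stats["age"]
        _, s2, _, _ = rec.stats["age2"]
        age_star = -1.0 * s2 / (2 * s1 * (-2.0))
        best = out.loc[out["prediction"].idxmax(), "age"]
        assert best == pytest.approx(age_star, abs=0.1)

    def test_dot_product_oracle_at_three_ages(self):
        rec = self._scaling()
        coefs = {"Intercept": 3.0, "age": 1.5, "age2": -0.8, "date": 0.4}
        ages = np.array([6.0, 20.0, 34.0])
        out = predict_response(coefs, rec, ages, fixed_date=94.0)
        for i, a in enumerate(ages):
            za = (a - rec.stats["age"][0]) / (2 * rec.stats["age"][1])
            za2 = (a**2 - rec.stats["age2"][0]) / (2 * rec.stats["age2"][1])
            zd = (94.0 - rec.stats["date"][0]) / (2 * rec.stats["date"][1])
            expected = 3.0 + 1.5 * za - 0.8 * za2 + 0.4 * zd
            assert out["prediction"].iloc[i] == pytest.approx(expected)

    def test_extrapolation_flagged(self):
        rec = self._scaling()
        out = predict_response({"Intercept": 0.0, "age": 1.0}, rec, ages=[2.0, 20.0, 50.0])
        assert list(out["extrapolated"]) == [True, False, True]

    def test_binomial_inverse_logit(self):
        rec = self._scaling()
        out = predict_response({"Intercept": 0.0}, rec, ages=[10.0], family="binomial")
        assert out["prediction"].iloc[0] == pytest.approx(0.5)
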