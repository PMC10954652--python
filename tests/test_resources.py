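"""Resource distributions: survey aggregation, crosswalk, count fitting,
special rules, and truncated sampling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from habitatshift.resources import (ADMISSIBLE_SCORES, ResourceDistribution,
                                    aggregate_survey, apply_special_rules,
                                    crop_weighted_value, crosswalk_distributions,
                                    fit_count_distribution, registry_from_frame,
                                    registry_to_frame, sample_value)
from habitatshift.resources import _ll_exponential, _ll_nb, _ll_zip, point_mass
from habitatshift.synthetic import gen_plot_samples


def _survey(scores, class_id="c", season="spring", resource="nectar"):
    return pd.DataFrame({
        "respondent_id": [f"r{i}" for i in range(len(scores))],
        "season": season, "resource": resource, "class_id": class_id,
        "score": scores})


class TestAggregateSurvey:
    def test_unanimous_scores(self):
        d = aggregate_survey(_survey([0.5, 0.5, 0.5]), "c", "spring", "nectar")
        assert d.mean == 0.5 and d.sd == 0.0 and d.family == "normal"

    def test_hand_computed_mean_sd(self):
        # {0.10, 0.50, 0.95}: mean 31/60, SD sqrt(((0.1-m)^2+(0.5-m)^2+(0.95-m)^2)/2)
        d = aggregate_survey(_survey([0.10, 0.50, 0.95]), "c", "spring", "nectar")
        assert d.mean == pytest.approx(0.5166667, abs=1e-6)
        assert d.sd == pytest.approx(0.4252450, abs=1e-6)

    def test_matches_direct_formulas_on_any_levels(self):
        for combo in itertools.combinations_with_replacement(ADMISSIBLE_SCORES, 4):
            d = aggregate_survey(_survey(list(combo)), "c", "spring", "nectar")
            arr = np.array(combo)
            assert d.mean == pytest.approx(arr.mean(), abs=1e-12)
            assert d.sd == pytest.approx(arr.std(ddof=1), abs=1e-12)

    def test_single_respondent_refused(self):
        with pytest.raises(ValueError, match="2 respondents"):
            aggregate_survey(_survey([0.5]), "c", "spring", "nectar")

    def test_off_scale_score_rejected(self):
        with pytest.raises(ValueError, match="admissible"):
            aggregate_survey(_survey([0.5, 0.4]), "c", "spring", "nectar")


def _norm(c, mean, sd):
    return ResourceDistribution(c, "spring", "nectar", "normal",
                                {"mean": mean, "sd": sd})


class TestCrosswalk:
    def test_identity_matrix_is_identity_map(self):
        src = {"a": _norm("a", 0.3, 0.1), "b": _norm("b", 0.7, 0.2)}
        am = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        out = crosswalk_distributions(src, am, "spring", "nectar")
        for k in src:
            assert out[k].mean == pytest.approx(src[k].mean)
            assert out[k].sd == pytest.approx(src[k].sd)

    def test_two_source_weighted_average(self):
        src = {"a": _norm("a", 0.2, 0.1), "b": _norm("b", 0.6, 0.3)}
        am = pd.DataFrame([[0.25, 0.75]], index=["t"], columns=["a", "b"])
        out = crosswalk_distributions(src, am, "spring", "nectar")
        assert out["t"].mean == pytest.approx(0.5)
        assert out["t"].sd == pytest.approx(0.25)  # weighted average of SDs

    def test_pooled_mode_at_least_weighted_sd(self):
        src = {"a": _norm("a", 0.2, 0.1), "b": _norm("b", 0.6, 0.3)}
        am = pd.DataFrame([[0.25, 0.75]], index=["t"], columns=["a", "b"])
        pooled = crosswalk_distributions(src, am, "spring", "nectar",
                                         sd_mode="pooled")["t"]
        # pooling adds between-class mean spread to the variance
        assert pooled.sd > 0.25
        assert pooled.mean == pytest.approx(0.5)

    def test_means_are_convex_combinations(self):
        rng = np.random.default_rng(0)
        src = {i: _norm(i, m, s) for i, (m, s) in enumerate(
            zip(rng.uniform(0, 1, 5), rng.uniform(0, 0.3, 5)))}
        rows = rng.dirichlet(np.ones(5), size=3)
        am = pd.DataFrame(rows, index=["t0", "t1", "t2"], columns=range(5))
        out = crosswalk_distributions(src, am, "spring", "nectar")
        means = [d.mean for d in src.values()]
        for d in out.values():
            assert min(means) - 1e-12 <= d.mean <= max(means) + 1e-12

    def test_bad_row_sum_rejected(self):
        src = {"a": _norm("a", 0.2, 0.1)}
        am = pd.DataFrame([[0.9]], index=["t"], columns=["a"])
        with pytest.raises(ValueError, match="sum to 1"):
            crosswalk_distributions(src, am, "spring", "nectar")

    def test_missing_source_distribution_rejected(self):
        src = {"a": _norm("a", 0.2, 0.1)}
        am = pd.DataFrame([[0.5, 0.5]], index=["t"], columns=["a", "b"])
        with pytest.raises(ValueError, match="no source distribution"):
            crosswalk_distributions(src, am, "spring", "nectar")


class TestCropWeighting:
    def test_single_crop_unchanged(self):
        df = pd.DataFrame({"crop": ["corn"], "mean": [0.3], "sd": [0.1],
                           "share": [1.0]})
        assert crop_weighted_value(df) == (pytest.approx(0.3), pytest.approx(0.1))

    def test_two_crops_equal_shares(self):
        df = pd.DataFrame({"crop": ["corn", "cotton"], "mean": [0.2, 0.4],
                           "sd": [0.1, 0.3], "share": [0.5, 0.5]})
        m, s = crop_weighted_value(df)
        assert m == pytest.approx(0.3) and s == pytest.approx(0.2)

    def test_exclusion_renormalizes_shares(self):
        df = pd.DataFrame({"crop": ["corn", "cotton", "sod"],
                           "mean": [0.2, 0.4, 0.9], "sd": [0.1, 0.3, 0.5],
                           "share": [0.3, 0.3, 0.4]})
        m, _ = crop_weighted_value(df, exclude=("sod",))
        assert m == pytest.approx(0.3)  # equal renormalized shares

    def test_empty_after_exclusion_rejected(self):
        df = pd.DataFrame({"crop": ["sod"], "mean": [0.9], "sd": [0.5],
                           "share": [1.0]})
        with pytest.raises(ValueError, match="no crops"):
            crop_weighted_value(df, exclude=("sod",))


class TestFitCountDistribution:
    def test_zip_parameter_recovery(self):
        samples = gen_plot_samples({"g": (0.7, {"lam": 8.0})}, n_per_class=1000,
                                   seed=7)
        fit = fit_count_distribution(samples, class_id="g")
        assert fit.best.family == "zero_inflated_poisson"
        assert fit.best.params["pi"] == pytest.approx(0.7, abs=0.05)
        assert fit.best.params["lam"] == pytest.approx(8.0, abs=0.5)
        assert 0.6 <= fit.zero_proportion <= 0.8
        assert not fit.sparse

    def test_all_zero_class_collapses_to_point_mass(self):
        df = pd.DataFrame({"class_id": "w", "density": np.zeros(50)})
        fit = fit_count_distribution(df, class_id="w")
        assert fit.best.family == "point_mass"
        assert fit.best.mean == 0 and fit.best.sd == 0
        assert fit.sparse

    def test_sparse_flag_below_threshold(self):
        samples = gen_plot_samples({"g": (0.5, {"lam": 4.0})}, n_per_class=10,
                                   seed=3)
        assert fit_count_distribution(samples, class_id="g").sparse

    def test_negative_density_rejected(self):
        df = pd.DataFrame({"class_id": "g", "density": [-1.0, 2.0]})
        with pytest.raises(ValueError, match="negative"):
            fit_count_distribution(df, class_id="g")

    def test_excluded_samples_dropped(self):
        df = pd.DataFrame({"class_id": "g",
                           "density": [0.0] * 30 + [5.0] * 10,
                           "quality_flag": ["include"] * 30 + ["exclude"] * 10})
        fit = fit_count_distribution(df, class_id="g")
        assert fit.n == 30
        assert fit.best.family == "point_mass"

    def test_aic_ranking_matches_brute_force_grid(self):
        """Fitted likelihoods must beat/equal a dense parameter grid search."""
        samples = gen_plot_samples({"g": (0.6, {"lam": 5.0})}, n_per_class=200,
                                   seed=11)
        x = samples["density"].to_numpy()
        k = np.round(x).astype(int)
        fit = fit_count_distribution(samples, class_id="g")
        grid_zip = max(_ll_zip(k, pi, lam)
                       for pi in np.linspace(0.05, 0.95, 46)
                       for lam in np.linspace(1.0, 10.0, 91))
        assert fit.loglik["zero_inflated_poisson"] >= grid_zip - 1e-3
        grid_nb = max(_ll_nb(k, mu, alpha)
                      for mu in np.linspace(0.5, 6.0, 56)
                      for alpha in np.linspace(0.05, 10.0, 100))
        assert fit.loglik["negative_binomial"] >= grid_nb - 1e-2
        assert fit.loglik["exponential"] == pytest.approx(
            _ll_exponential(x, x.mean()))

    def test_zip_mle_matches_statsmodels(self):
        """Independent oracle: statsmodels' zero-inflated Poisson MLE."""
        sm_zip = pytest.importorskip(
            "statsmodels.discrete.count_model").ZeroInflatedPoisson
        samples = gen_plot_samples({"g": (0.7, {"lam": 8.0})}, n_per_class=500,
                                   seed=5)
        k = np.round(samples["density"].to_numpy()).astype(int)
        res = sm_zip(k, np.ones_like(k)).fit(disp=0)
        pi_sm = 1.0 / (1.0 + math.exp(-res.params[0]))
        lam_sm = math.exp(res.params[1])
        fit = fit_count_distribution(samples, class_id="g")
        assert fit.best.params["pi"] == pytest.approx(pi_sm, abs=1e-3)
        assert fit.best.params["lam"] == pytest.approx(lam_sm, rel=1e-3)


class TestSpecialRules:
    def _dev(self, c, mean, sd):
        return ResourceDistribution(c, "spring", "milkweed", "normal",
                                    {"mean": mean, "sd": sd},
                                    units="plants_per_ha")

    def test_zero_classes_become_point_mass(self):
        dists = {"water": self._dev("water", 5.0, 2.0)}
        out = apply_special_rules(dists, zero_classes=("water",))
        assert out["water"].family == "point_mass"
        assert out["water"].mean == 0 and out["water"].sd == 0

    def test_midpoint_rule_same_family(self):
        dists = {"low": self._dev("low", 9.6, 23.0),
                 "high": self._dev("high", 3.3, 8.5)}
        out = apply_special_rules(
            dists, midpoint_rules={"med": ("low", "high")})
        assert out["med"].mean == pytest.approx(6.45)
        assert out["med"].sd == pytest.approx(15.75)
        assert out["med"].family == "normal"

    def test_midpoint_rule_mixed_family_falls_back_to_moments(self):
        dists = {"low": ResourceDistribution("low", "spring", "milkweed",
                                             "exponential", {"scale": 9.6},
                                             units="plants_per_ha"),
                 "high": self._dev("high", 3.3, 8.5)}
        out = apply_special_rules(dists, midpoint_rules={"med": ("low", "high")})
        assert out["med"].family == "normal"
        assert out["med"].mean == pytest.approx((9.6 + 3.3) / 2)
        assert "moment midpoint" in out["med"].notes

    def test_rules_idempotent_on_zero_class(self):
        dists = {"water": point_mass("water", "spring", "milkweed", 0.0)}
        out = apply_special_rules(dists, zero_classes=("water",))
        out2 = apply_special_rules(out, zero_classes=("water",))
        assert out2["water"].mean == 0 and out2["water"].family == "point_mass"

    def test_missing_neighbour_rejected(self):
        with pytest.raises(ValueError, match="midpoint"):
            apply_special_rules({"low": self._dev("low", 1, 1)},
                                midpoint_rules={"med": ("low", "high")})


class TestSampling:
    def test_point_mass_always_value(self):
        d = point_mass("w", "spring", "milkweed", 0.0)
        assert (sample_value(d, np.random.default_rng(0), 100) == 0).all()

    def test_degenerate_normal(self):
        d = _norm("c", 0.5, 0.0)
        assert (sample_value(d, np.random.default_rng(0), 100) == 0.5).all()

    def test_untruncated_normal_lln(self):
        d = _norm("c", 0.447, 0.272)
        x = sample_value(d, np.random.default_rng(123), 100_000,
                         truncation="none")
        se = 0.272 / math.sqrt(100_000)
        assert abs(x.mean() - 0.447) < 4 * se

    def test_seeded_draws_bit_identical(self):
        d = _norm("c", 0.4, 0.2)
        a = sample_value(d, np.random.default_rng(9), 1000)
        b = sample_value(d, np.random.default_rng(9), 1000)
        np.testing.assert_array_equal(a, b)

    def test_unknown_truncation_rejected(self):
        with pytest.raises(ValueError, match="truncation"):
            sample_value(_norm("c", 0.5, 0.1), np.random.default_rng(0),
                         truncation="fold")

    @given(st.sampled_from(["clip", "reject"]),
           st.floats(-0.5, 1.5), st.floats(0.01, 1.0), st.integers(0, 10_000))
    def test_score_draws_always_in_unit_interval(self, policy, mean, sd, seed):
        d = _norm("c", mean, sd)
        x = sample_value(d, np.random.default_rng(seed), 200, truncation=policy)
        assert (x >= 0).all() and (x <= 1).all()

    @given(st.sampled_from(["zero_inflated_poisson", "negative_binomial",
                            "exponential", "zero_inflated_bernoulli"]),
           st.integers(0, 10_000))
    def test_density_families_nonnegative(self, family, seed):
        params = {"zero_inflated_poisson": {"pi": 0.6, "lam": 5.0},
                  "negative_binomial": {"mu": 4.0, "alpha": 0.8},
                  "exponential": {"scale": 3.0},
                  "zero_inflated_bernoulli": {"pi": 0.5, "p": 0.7}}[family]
        d = ResourceDistribution("c", "spring", "milkweed", family, params,
                                 units="plants_per_ha")
        x = sample_value(d, np.random.default_rng(seed), 200)
        assert (x >= 0).all()

    def test_family_moments_match_empirical(self):
        """Closed-form mean/sd agree with large-sample draws per family."""
        cases = [
            ("zero_inflated_poisson", {"pi": 0.7, "lam": 8.0}),
            ("negative_binomial", {"mu": 4.0, "alpha": 0.8}),
            ("exponential", {"scale": 3.0}),
            ("zero_inflated_bernoulli", {"pi": 0.5, "p": 0.7}),
            ("beta", {"a": 2.0, "b": 5.0}),
        ]
        rng = np.random.default_rng(2024)
        for family, params in cases:
            d = ResourceDistribution("c", "s", "r", family, params,
                                     units="plants_per_ha")
            x = sample_value(d, rng, 200_000, truncation="none")
            assert x.mean() == pytest.approx(d.mean, abs=5 * d.sd / 400), family
            assert x.std(ddof=1) == pytest.approx(d.sd, rel=0.05), family


def test_registry_round_trip():
    dists = {"a": _norm("a", 0.3, 0.1),
             "w": point_mass("w", "spring", "nectar", 0.0)}
    back = registry_from_frame(registry_to_frame(dists))
    for k, d in dists.items():
        assert back[k].family == d.family
        assert back[k].params == d.params
        assert back[k].mean == pytest.approx(d.mean)
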