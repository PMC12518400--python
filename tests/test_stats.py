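"""AICc, model selection, feeding models, contact models and the survival
comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fledgelink.simulate import SimConfig, simulate_daily_contact_summaries, \
    simulate_feeding_observations
from fledgelink.stats import (
    ContactModel, FeedingCountModel, FeedingDistanceModel, ModelSpec,
    aicc, candidate_contact_models, model_selection_table, select_model,
    subsample_one_per_chick, survival_comparison,
)


class TestAicc:
    def test_closed_form_example(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(24 + 12 / 7)

    def test_limit_is_aic(self):
        assert aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_zero_parameters(self):
        assert aicc(-10.0, 0, 50) == pytest.approx(20.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 9, 10)

    def test_matches_two_step_computation_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            ll = rng.uniform(-500, 0)
            k = int(rng.integers(0, 20))
            n = int(rng.integers(k + 2, 500))
            aic = -2 * ll + 2 * k
            correction = 2 * k * (k + 1) / (n - k - 1)
            assert aicc(ll, k, n) == pytest.approx(aic + correction, rel=1e-12)


class FakeFit:
    def __init__(self, aicc, k, converged=True):
        self.aicc, self.k, self.converged = aicc, k, converged

    def __repr__(self):
        return f"FakeFit(aicc={self.aicc}, k={self.k})"


class TestSelectModel:
    def test_parsimony_within_two(self):
        fits = [FakeFit(100.0, 5), FakeFit(101.5, 3), FakeFit(103.0, 2)]
        assert select_model(fits).k == 3

    def test_single_model(self):
        f = FakeFit(50.0, 4)
        assert select_model([f]) is f

    def test_boundary_inclusive(self):
        fits = [FakeFit(100.0, 5), FakeFit(102.0, 2)]
        assert select_model(fits).k == 2

    def test_tie_on_k_breaks_by_aicc(self):
        fits = [FakeFit(100.0, 3), FakeFit(101.0, 3)]
        assert select_model(fits).aicc == 100.0

    def test_unconverged_excluded(self):
        fits = [FakeFit(90.0, 2, converged=False), FakeFit(100.0, 5)]
        assert select_model(fits).aicc == 100.0
        with pytest.raises(ValueError):
            select_model([FakeFit(90.0, 2, converged=False)])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            fits = [FakeFit(float(rng.uniform(100, 110)), int(rng.integers(1, 9)))
                    for _ in range(rng.integers(1, 8))]
            best = min(f.aicc for f in fits)
            candidates = [f for f in fits if f.aicc <= best + 2.0]
            expected = min(candidates, key=lambda f: (f.k, f.aicc))
            assert select_model(fits) is expected


class TestSurvival:
    def test_tagged_cohort_vs_reference(self):
        s = survival_comparison(15, 7, 0.56, 0.04)
        assert round(s.rate, 2) == 0.53
        assert round(s.se, 2) == 0.13
        assert round(s.z, 2) == -0.20

    def test_no_deaths(self):
        s = survival_comparison(10, 0, 0.56, 0.04)
        assert s.rate == 1.0 and s.se == 0.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            survival_comparison(10, 11, 0.5, 0.1)
        with pytest.raises(ValueError):
            survival_comparison(0, 0, 0.5, 0.1)


class TestFeedingModels:
    def test_subsample_is_seeded_and_one_per_chick(self):
        cfg = SimConfig(seed=21)
        rec = simulate_feeding_observations(cfg, n_chicks=60)
        s1 = subsample_one_per_chick(rec, seed=3)
        s2 = subsample_one_per_chick(rec, seed=3)
        pd.testing.assert_frame_equal(s1, s2)
        assert s1["chick_id"].is_unique
        assert set(s1["chick_id"]) == set(rec["chick_id"])

    def test_decline_recovered_with_negative_slope(self):
        cfg = SimConfig(seed=22, feeding_log_slope=-0.05, n_ringed_chicks=200)
        rec = simulate_feeding_observations(cfg)
        res = FeedingCountModel(rec).fit(seed=0)
        assert res.slope < 0
        assert abs(res.zvalue) > 3

    def test_flat_world_ci_covers_zero(self):
        # with no age trend, the fitted age coefficient's 95% CI covers 0
        # in >= 90% of independently regenerated datasets
        covered = 0
        for seed in range(40):
            cfg = SimConfig(seed=1000 + seed, feeding_log_slope=0.0,
                            feeding_log_intercept=0.2, n_ringed_chicks=100)
            rec = simulate_feeding_observations(cfg)
            lo, hi = FeedingCountModel(rec).fit(seed=seed).conf_int()
            covered += lo <= 0 <= hi
        assert covered >= 36

    def test_equal_counts_give_zero_slope(self):
        rec = pd.DataFrame({
            "chick_id": [f"c{i}" for i in range(40)],
            "age_days": np.repeat([40, 50, 60, 70], 10).astype(float),
        })
        res = FeedingCountModel(rec).fit(seed=0)
        assert res.slope == pytest.approx(0.0, abs=1e-8)

    def test_single_age_class_rejected(self):
        rec = pd.DataFrame({"chick_id": ["a", "b"], "age_days": [40.0, 41.0]})
        with pytest.raises(ValueError):
            FeedingCountModel(rec).fit(seed=0)

    def test_distance_exact_linear_r2_one(self):
        rec = pd.DataFrame({"chick_id": list("abcdef"),
                            "age_days": [40, 50, 60, 70, 80, 90.0]})
        rec["distance_km"] = 1.0 + 0.1 * rec["age_days"]
        res = FeedingDistanceModel(rec).fit()
        assert res.rsquared == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.1)

    def test_distance_slope_recovery(self):
        cfg = SimConfig(seed=24, n_ringed_chicks=200)
        rec = simulate_feeding_observations(cfg)
        res = FeedingDistanceModel(rec).fit()
        lo, hi = res.conf_int()
        assert lo <= cfg.feeding_dist_slope_km_per_day <= hi

    def test_permuted_ages_r2_near_zero(self):
        cfg = SimConfig(seed=25, n_ringed_chicks=200)
        rec = simulate_feeding_observations(cfg)
        rng = np.random.default_rng(25)
        rec["age_days"] = rng.permutation(rec["age_days"].to_numpy())
        assert FeedingDistanceModel(rec).fit().rsquared < 0.02

    def test_nonneg_distance_required(self):
        rec = pd.DataFrame({"chick_id": list("abc"), "age_days": [40.0, 50, 60],
                            "distance_km": [1.0, -0.5, 2.0]})
        with pytest.raises(ValueError):
            FeedingDistanceModel(rec)


@pytest.fixture(scope="module")
def summaries():
    cfg = SimConfig(seed=31)
    return simulate_daily_contact_summaries(cfg, n_pairs=12, n_days=50, seed=31)


class TestContactModels:
    def test_negative_decay_gives_negative_age_effect(self, summaries):
        res = ContactModel(summaries, ModelSpec("p_contact", fixed=("age",))).fit()
        assert res.fe_params["age_std"] < 0
        slope_per_day, _ = res.age_slope_per_day()
        assert slope_per_day < 0

    def test_random_heterogeneity_estimated(self, summaries):
        # the stated world has per-chick slopes larger than nothing:
        # random-effect SDs come out positive and non-degenerate
        res = ContactModel(summaries, ModelSpec("p_contact", fixed=("age",))).fit()
        assert res.re_sd["sd_intercept"] > 0.1
        assert res.re_sd["sd_slope"] > 0.05

    def test_zero_contact_degenerate(self, summaries):
        df = summaries.copy()
        df["n_contact"] = 0
        with pytest.raises(ValueError, match="degenerate"):
            ContactModel(df, ModelSpec("p_contact", fixed=("age",))).fit()

    def test_pair_random_effect_option(self, summaries):
        res = ContactModel(summaries,
                           ModelSpec("p_contact", fixed=("age",), random="pair")).fit()
        assert np.isfinite(res.aicc)

    def test_candidate_set_structure(self, summaries):
        fits = candidate_contact_models(summaries, "p_contact")
        labels = {f.spec.label for f in fits}
        assert len(fits) == 8  # all subsets of {age, chick_sex, parent_sex}
        assert "year" in labels  # intercept-only candidate still has year
        assert all("year" in l for l in labels)
        tab = model_selection_table(fits)
        assert tab["dAICc"].iloc[0] == 0.0
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_gamma_nest_distance_model_runs(self, summaries):
        res = ContactModel(summaries,
                           ModelSpec("nest_distance_contact", fixed=("age",),
                                     family="gamma-log")).fit()
        assert np.isfinite(res.llf)
        assert res.k == 4 + 3 + 1  # + Gamma shape

    def test_interactions_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("p_contact", fixed=("age", "age:chick_sex"))
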