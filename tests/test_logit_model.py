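import numpy as np
import pandas as pd
import pytest

from painpro import logit_model, registry, simulate, scores, morphine
from painpro.model_base import ModelSpec

PLAIN = ModelSpec(outcome="opioid_use", factors=[], continuous=[],
                  offset_stratum=None)


def _two_group_data(n1, k1, n2, k2, g1="GA-o", g2="SA-o"):
    y = np.r_[np.ones(k1), np.zeros(n1 - k1), np.ones(k2), np.zeros(n2 - k2)]
    g = np.r_[[g1] * n1, [g2] * n2]
    return pd.DataFrame({"opioid_use": y.astype(bool), "subgroup": g})


class TestFitLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        # use rates 0.9 vs 0.8 -> OR = (0.8/0.2)/(0.9/0.1) = 4/9
        df = _two_group_data(1000, 900, 1000, 800)
        fit = logit_model.fit_logistic(df, PLAIN)
        ors = logit_model.odds_ratios(fit)
        assert fit.method == "logit-ml"
        assert ors.loc[0, "or"] == pytest.approx(4 / 9, rel=1e-6)

    def test_reference_level_recoding(self):
        df = _two_group_data(1000, 900, 1000, 800)
        fit = logit_model.fit_logistic(df, PLAIN, reference="SA-o")
        ors = logit_model.odds_ratios(fit)
        assert ors.loc[0, "term"] == "subgroup[T.GA-o]"
        assert ors.loc[0, "or"] == pytest.approx(9 / 4, rel=1e-6)

    def test_equal_rates_give_unit_or_with_ci_spanning_one(self):
        df = _two_group_data(500, 400, 500, 400)
        ors = logit_model.odds_ratios(logit_model.fit_logistic(df, PLAIN))
        assert ors.loc[0, "or"] == pytest.approx(1.0, rel=1e-6)
        assert ors.loc[0, "ci_low"] < 1.0 < ors.loc[0, "ci_high"]

    def test_all_identical_outcomes_trigger_penalized_path(self):
        df = _two_group_data(100, 100, 100, 100)  # everyone used opioids
        with pytest.warns(UserWarning, match="separation"):
            fit = logit_model.fit_logistic(df, PLAIN)
        assert fit.method == "logit-ridge"
        ors = logit_model.odds_ratios(fit)
        assert (ors["method"] == "logit-ridge").all()
        assert np.isfinite(ors[["or", "ci_low", "ci_high"]].to_numpy()).all()

    def test_single_saturated_group_triggers_penalized_path(self):
        df = _two_group_data(300, 300, 300, 250)
        with pytest.warns(UserWarning, match="separation"):
            fit = logit_model.fit_logistic(df, PLAIN)
        assert fit.method == "logit-ridge"

    def test_coefficient_recovery_on_synthetic_registry(self):
        cfg = simulate.default_paperlike_config(n=20_000, seed=29)
        records, admin, _ = simulate.generate(cfg)
        records["subgroup"] = registry.allocate_subgroup(records)
        records["opioid_use"] = morphine.opioid_use_flag(records, admin).to_numpy()
        fit = logit_model.fit_logistic(records, PLAIN)
        se = pd.Series(np.sqrt(np.diag(fit.cov)), index=fit.params.index)
        truth = dict(zip(registry.SUBGROUPS, cfg.opioid_use_probs))

        def lo(p):
            return np.log(p / (1 - p))
        for g in registry.SUBGROUPS[1:]:
            term = f"subgroup[T.{g}]"
            expected = lo(truth[g]) - lo(truth["GA-o"])
            assert abs(fit.params[term] - expected) < 3 * se[term], term


class TestRiskDifferences:
    def test_gcomp_equals_raw_proportions_without_covariates(self):
        df = _two_group_data(400, 350, 600, 480)
        fit = logit_model.fit_logistic(df, PLAIN)
        rd = logit_model.risk_difference_contrasts(fit, ci="delta")
        raw = 100 * (350 / 400 - 480 / 600)
        assert rd.loc[0, "estimate_pp"] == pytest.approx(raw, abs=1e-8)

    def test_contrast_cycle_sums_to_zero(self, scored):
        fit = logit_model.fit_logistic(scored)
        rd = logit_model.risk_difference_contrasts(fit, ci="delta")
        d = {(r.level_a, r.level_b): r.estimate_pp for r in rd.itertuples()}

        def diff(a, b):
            return d[(a, b)] if (a, b) in d else -d[(b, a)]
        a, b, c = registry.SUBGROUPS[:3]
        assert diff(a, b) + diff(b, c) + diff(c, a) == pytest.approx(0.0, abs=1e-10)

    def test_marginal_probs_inside_prediction_envelope(self, scored):
        from scipy.special import expit
        from painpro.model_base import grid_design
        fit = logit_model.fit_logistic(scored)
        probs = logit_model._marginal_probs(fit.params.to_numpy(), fit, fit.frame)
        for lv, p in zip(fit.factor_levels["subgroup"], probs):
            cf = fit.frame.copy()
            cf["subgroup"] = pd.Categorical([lv] * len(cf),
                                            categories=fit.factor_levels["subgroup"])
            pred = expit(grid_design(fit.design_info, cf) @ fit.params.to_numpy())
            assert pred.min() - 1e-12 <= p <= pred.max() + 1e-12

    def test_bootstrap_ci_brackets_estimate_and_is_seeded(self):
        df = _two_group_data(400, 300, 400, 240)
        fit = logit_model.fit_logistic(df, PLAIN)
        rd1 = logit_model.risk_difference_contrasts(fit, B=80, seed=5)
        rd2 = logit_model.risk_difference_contrasts(fit, B=80, seed=5)
        pd.testing.assert_frame_equal(rd1, rd2)
        assert rd1.loc[0, "ci_low"] < rd1.loc[0, "estimate_pp"] < rd1.loc[0, "ci_high"]
        assert "bootstrap" in rd1.loc[0, "method"]

    def test_bonferroni_inflates_p(self, scored):
        fit = logit_model.fit_logistic(scored)
        plain = logit_model.risk_difference_contrasts(fit, ci="delta")
        bonf = logit_model.risk_difference_contrasts(fit, ci="delta",
                                                     adjust="bonferroni")
        assert np.all(bonf["p"].to_numpy() >= plain["p"].to_numpy() - 1e-12)

    def test_adjusted_matches_unadjusted_when_covariates_independent(self):
        rng = np.random.default_rng(8)
        n = 6000
        g = rng.integers(0, 2, n)
        age = rng.normal(65, 8, n)  # independent of group
        from scipy.special import expit as sigmoid
        pr = sigmoid(1.0 + 0.8 * g + 0.02 * (age - 65))
        df = pd.DataFrame({"opioid_use": rng.random(n) < pr,
                           "subgroup": np.where(g == 1, "GA&PNBc", "GA-o"),
                           "age": age})
        spec = ModelSpec(outcome="opioid_use", factors=[], continuous=["age"],
                         offset_stratum=None)
        fit_adj = logit_model.fit_logistic(df, spec)
        fit_raw = logit_model.fit_logistic(df, PLAIN)
        rd_adj = logit_model.risk_difference_contrasts(fit_adj, ci="delta")
        rd_raw = logit_model.risk_difference_contrasts(fit_raw, ci="delta")
        assert rd_adj.loc[0, "estimate_pp"] == pytest.approx(
            rd_raw.loc[0, "estimate_pp"], abs=0.5)
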