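import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from painpro import beta_model, registry, scores, simulate
from painpro.errors import PainProError
from painpro.model_base import ModelSpec

GROUPS = registry.SUBGROUPS
PLAIN = ModelSpec(factors=[], continuous=[], offset_stratum=None)


def _group_frame(y, groups):
    return pd.DataFrame({"pcs": y, "subgroup": groups})


class TestFitBeta:
    def test_intercept_only_symmetric_outcome_has_zero_intercept(self):
        # outcomes symmetric around NRS 5 -> mean 0.5 -> logit 0
        y = np.tile([4.8, 5.2], 200)
        df = pd.DataFrame({"pcs": y, "g": ["a"] * 400})
        fit = beta_model.fit_beta(df, ModelSpec(group="g", factors=[], continuous=[],
                                                offset_stratum=None))
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_duplicating_rows_keeps_estimates_and_shrinks_se(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 2, 400)
        mu = expit(-0.5 + 0.3 * g)
        y = 10 * rng.beta(mu * 3, (1 - mu) * 3)
        df = _group_frame(y, np.where(g == 1, "GA&PNBc", "GA-o"))
        fit1 = beta_model.fit_beta(df, PLAIN, n_effective=400)
        fit2 = beta_model.fit_beta(pd.concat([df, df], ignore_index=True), PLAIN,
                                   n_effective=400)
        assert np.allclose(fit1.params, fit2.params, atol=1e-5)
        se1 = np.sqrt(np.diag(fit1.cov))
        se2 = np.sqrt(np.diag(fit2.cov))
        assert np.allclose(se2 * np.sqrt(2), se1, rtol=1e-2)

    def test_coefficient_recovery_on_large_synthetic_registry(self):
        cfg = simulate.default_paperlike_config(n=20_000, seed=13)
        records, _, _ = simulate.generate(cfg)
        records["subgroup"] = registry.allocate_subgroup(records)
        sc = scores.score_registry(records)
        fit = beta_model.fit_beta(sc)
        se = pd.Series(np.sqrt(np.diag(fit.cov)), index=fit.params.index)
        truth = dict(zip(GROUPS, cfg.pcs_group_effects))
        for g in GROUPS[1:]:
            term = f"subgroup[T.{g}]"
            expected = truth[g] - truth["GA-o"]
            assert abs(fit.params[term] - expected) < 3 * se[term], term
        oands_terms = [c for c in fit.params.index if c.startswith("oands_flag")]
        assert len(oands_terms) == 1
        assert abs(fit.params[oands_terms[0]] - cfg.oands_effect) \
            < 3 * se[oands_terms[0]]

    def test_degenerate_stratum_raises_with_name(self):
        df = _group_frame([2.0, 3.0, 4.0, 5.0], ["GA-o", "GA-o", "GA-o", "SA-o"])
        with pytest.raises(PainProError, match="SA-o"):
            beta_model.fit_beta(df, PLAIN)

    def test_log_likelihood_is_a_local_optimum(self):
        """MLE beats random perturbations and an independent optimizer agrees."""
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, 150)
        mu = expit(-0.6 + 0.2 * g)
        y = 10 * rng.beta(mu * 2.5, (1 - mu) * 2.5)
        df = _group_frame(y, np.array(["GA-o", "SA-o", "SA&PNBs"])[g])
        fit = beta_model.fit_beta(df, PLAIN)
        model = fit.sm_result.model
        full = np.r_[fit.params.to_numpy(), np.log(fit.phi)]
        ll_hat = model.loglike(full)
        for _ in range(1000):
            assert model.loglike(full + rng.normal(0, 0.05, full.shape)) <= ll_hat + 1e-9
        # independent optimizer from a remote start
        from scipy.optimize import minimize
        res = minimize(lambda p: -model.loglike(p), np.zeros_like(full),
                       method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        assert 2 * abs(ll_hat - (-res.fun)) < 1e-6

    def test_penalized_income_mode_shrinks_stratum_coefficient(self, scored):
        spec = ModelSpec()
        fixed = beta_model.fit_beta(scored, spec, income_mode="fixed")
        pen = beta_model.fit_beta(scored, spec, income_mode="penalized", penalty=50.0)
        term = [c for c in fixed.params.index if c.startswith("country_income")][0]
        assert abs(pen.params[term]) < abs(fixed.params[term])
        assert pen.method == "beta-ml-penalized-stratum"


class TestEmmeans:
    def _fit_small(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, n)
        sex = rng.integers(0, 2, n)
        age = rng.normal(65, 8, n)
        mu = expit(-0.6 + 0.25 * g - 0.1 * sex)
        y = 10 * rng.beta(mu * 3, (1 - mu) * 3)
        df = pd.DataFrame({"pcs": y,
                           "subgroup": np.array(["GA-o", "SA-o", "SA&PNBs"])[g],
                           "sex": np.where(sex == 1, "male", "female"),
                           "age": age})
        spec = ModelSpec(factors=["sex"], continuous=["age"], offset_stratum=None)
        return beta_model.fit_beta(df, spec)

    def test_matches_brute_force_prediction_averaging_oracle(self):
        fit = self._fit_small()
        mm = beta_model.emmeans(fit)
        # oracle: explicit per-combination design rows, averaged by hand
        from painpro.model_base import grid_design
        beta = fit.params.to_numpy()
        for _, row in mm.table.iterrows():
            etas = []
            for sex in fit.factor_levels["sex"]:
                g = pd.DataFrame({"subgroup": pd.Categorical(
                    [row["subgroup"]], categories=fit.factor_levels["subgroup"]),
                    "sex": pd.Categorical([sex], categories=fit.factor_levels["sex"]),
                    "age": [fit.cont_means["age"]]})
                etas.append(float((grid_design(fit.design_info, g) @ beta)[0]))
            assert row["eta"] == pytest.approx(np.mean(etas), abs=1e-10)

    def test_single_emm_is_inverse_link_of_intercept(self):
        y = np.tile([logit_inv_nrs(0.30), logit_inv_nrs(0.34)], 150)
        df = pd.DataFrame({"pcs": y, "g": ["a"] * 300})
        fit = beta_model.fit_beta(df, ModelSpec(group="g", factors=[], continuous=[],
                                                offset_stratum=None))
        mm = beta_model.emmeans(fit, "g")
        expected = scores.inverse_rescale(expit(fit.params["Intercept"]),
                                          fit.n_effective)
        assert mm.table["estimate"].iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_unknown_factor_rejected(self):
        fit = self._fit_small()
        with pytest.raises(PainProError, match="not in the fitted model"):
            beta_model.emmeans(fit, "enrolment_period")

    def test_relabelling_levels_permutes_but_preserves_estimates(self):
        fit = self._fit_small(seed=5)
        mm = beta_model.emmeans(fit)
        base = dict(zip(mm.table["subgroup"], mm.table["estimate"]))
        relabel = {"GA-o": "SA&PNBs", "SA-o": "GA-o", "SA&PNBs": "SA-o"}
        # rebuild the same data with renamed labels
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, 300)
        sex = rng.integers(0, 2, 300)
        age = rng.normal(65, 8, 300)
        mu = expit(-0.6 + 0.25 * g - 0.1 * sex)
        y = 10 * rng.beta(mu * 3, (1 - mu) * 3)
        names = np.array(["GA-o", "SA-o", "SA&PNBs"])[g]
        renamed = np.array([relabel[x] for x in names])
        df2 = pd.DataFrame({"pcs": y, "subgroup": renamed,
                            "sex": np.where(sex == 1, "male", "female"), "age": age})
        fit2 = beta_model.fit_beta(
            df2, ModelSpec(factors=["sex"], continuous=["age"], offset_stratum=None))
        mm2 = beta_model.emmeans(fit2)
        new = dict(zip(mm2.table["subgroup"], mm2.table["estimate"]))
        for old, newname in relabel.items():
            assert new[newname] == pytest.approx(base[old], abs=1e-4)


def logit_inv_nrs(mu):
    """NRS value whose rescaled mean is mu (ignoring compression)."""
    return 10 * mu


class TestContrasts:
    def test_six_levels_give_fifteen_contrasts(self, scored):
        fit = beta_model.fit_beta(scored)
        con = beta_model.pairwise_contrasts(beta_model.emmeans(fit))
        assert len(con) == 15
        assert (con["p"] <= 1).all() and (con["p"] >= 0).all()
        assert ((con["ci_low"] <= con["estimate"])
                & (con["estimate"] <= con["ci_high"])).all()

    def test_identical_duplicated_levels_contrast_zero(self):
        rng = np.random.default_rng(2)
        y = 10 * rng.beta(1.0, 2.0, 200)
        df = pd.DataFrame({"pcs": np.r_[y, y],
                           "subgroup": ["GA-o"] * 200 + ["SA-o"] * 200})
        fit = beta_model.fit_beta(df, PLAIN)
        con = beta_model.pairwise_contrasts(beta_model.emmeans(fit))
        assert con["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-4)
        assert con["p"].iloc[0] > 0.999

    def test_tukey_dominates_unadjusted(self):
        rng = np.random.default_rng(4)
        for rep in range(5):
            g = rng.integers(0, 4, 400)
            mu = expit(-0.5 + 0.1 * g)
            y = 10 * rng.beta(mu * 2, (1 - mu) * 2)
            df = pd.DataFrame({
                "pcs": y,
                "subgroup": np.array(["GA-o", "SA-o", "SA&PNBs", "GA&PNBc"])[g]})
            fit = beta_model.fit_beta(df, PLAIN)
            mm = beta_model.emmeans(fit)
            p_t = beta_model.pairwise_contrasts(mm, adjust="tukey")["p"]
            p_u = beta_model.pairwise_contrasts(mm, adjust="none")["p"]
            assert np.all(p_t.to_numpy() >= p_u.to_numpy() - 1e-12)


class TestOandsSplit:
    def test_twelve_emms_and_66_contrasts(self, scored):
        spec = ModelSpec().with_interaction("subgroup", "oands_flag")
        fit = beta_model.fit_beta(scored, spec)
        mm, con = beta_model.emmeans_by_oands(fit)
        assert len(mm) == 12
        assert len(con) == 66

    def test_interaction_required(self, scored):
        fit = beta_model.fit_beta(scored)
        with pytest.raises(PainProError, match="interaction"):
            beta_model.emmeans_by_oands(fit)

    def test_additive_oands_shift_gives_consistent_within_subgroup_contrasts(self):
        cfg = simulate.default_paperlike_config(n=12_000, seed=17)
        cfg.oands_prevalence = 0.30  # enough O&S cases in every subgroup
        records, _, _ = simulate.generate(cfg)
        records["subgroup"] = registry.allocate_subgroup(records)
        sc = scores.score_registry(records)
        spec = ModelSpec().with_interaction("subgroup", "oands_flag")
        fit = beta_model.fit_beta(sc, spec)
        mm, _ = beta_model.emmeans_by_oands(fit)
        tab = mm.table.set_index(["subgroup", "oands_flag"])
        shifts = [tab.loc[(g, "True"), "eta"] - tab.loc[(g, "False"), "eta"]
                  for g in registry.SUBGROUPS]
        assert all(s > 0 for s in shifts)  # O&S raises pain in every subgroup
        assert np.std(shifts) < 0.15       # and by a similar amount (no interaction)
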