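"""Likelihood evaluation, priors, Akaike score, and the fitting surface."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import socialrl as s
from socialrl.fitting import FitOptions


class TestNLL:
    def test_flat_policy_gives_log2_per_trial(self, vs2_dataset):
        params = s.ParameterSet(alpha_p=0.4, alpha_i=0.3, beta=0.0, kappa=0.0)
        n_priv = (vs2_dataset["trial_type"] == "private").sum()
        nll = s.dataset_nll(s.get_model("VS2"), params, vs2_dataset)
        assert nll == pytest.approx(n_priv * math.log(2), abs=1e-9)

    def test_single_informative_trial_closed_form(self):
        # alpha_p = 1 drives Q to (1, 0) after one win; the second choice of
        # the same option then has pi = 1/(1+e^-1), contributing 0.31326
        rows = []
        for t, (c, r) in enumerate([("ctx0_a", 1), ("ctx0_a", 1)]):
            rows.append(dict(subject_id="x", session=0, block=0, trial_index=t,
                             condition="P", context_id=0, trial_type="private",
                             option_a="ctx0_a", option_b="ctx0_b", p_win_a=0.7,
                             p_win_b=0.3, demonstration=None, choice=c, outcome=r))
        df = pd.DataFrame(rows)
        params = s.ParameterSet(alpha_p=1.0, beta=1.0, kappa=0.0)
        nll = s.dataset_nll(s.get_model("RW1"), params, df)
        expected = math.log(2) + -math.log(1 / (1 + math.exp(-1)))
        assert nll == pytest.approx(expected, abs=1e-9)
        assert nll - math.log(2) == pytest.approx(0.31326, abs=1e-5)

    def test_observational_trials_only_act_through_state(self, exp2_schedule):
        # a demonstration-blind model yields the same NLL whether or not the
        # observational trials are present in the dataset
        params = s.ParameterSet(alpha_p=0.4, beta=4.0, kappa=0.0)
        spec = s.get_model("RW2", match_updates_last_action=False)
        sim = s.simulate_agent(spec, params, exp2_schedule, 5)
        nll_full = s.dataset_nll(spec, params, sim)
        nll_priv = s.dataset_nll(spec, params, sim[sim["trial_type"] == "private"])
        assert nll_full == pytest.approx(nll_priv, abs=1e-9)

    def test_private_trial_without_choice_rejected(self, exp2_schedule):
        with pytest.raises(ValueError, match="choice"):
            s.encode_dataset(exp2_schedule)  # schedule has unfilled choices


class TestAkaike:
    def test_log_evidence_scale_formula(self):
        assert s.aic(100.0, 5) == -105.0
        assert s.aic(3.5, 0) == -3.5

    def test_decreasing_in_nll_and_complexity(self):
        assert s.aic(100.0, 3) > s.aic(100.0, 4)
        assert s.aic(100.0, 3) > s.aic(101.0, 3)


class TestLogPrior:
    def test_matches_scipy_densities(self):
        spec = s.get_model("VS2")
        params = s.ParameterSet(alpha_p=0.5, alpha_i=0.25, beta=4.0, kappa=1.0)
        expected = (
            stats.beta(1.1, 1.1).logpdf(0.5)
            + stats.beta(1.1, 1.1).logpdf(0.25)
            + stats.gamma(a=1.2, scale=5).logpdf(4.0)
        )  # kappa flat: contributes 0
        assert s.log_prior(params, spec) == pytest.approx(expected, abs=1e-9)

    def test_pure(self):
        spec = s.get_model("metaVS")
        params = s.ParameterSet(alpha_p=0.3, alpha_m=0.6, beta=2.0)
        assert s.log_prior(params, spec) == s.log_prior(params, spec)

    def test_out_of_bounds_rejected(self):
        spec = s.get_model("RW2")
        with pytest.raises(ValueError):
            s.log_prior(s.ParameterSet(alpha_p=1.5), spec)
        with pytest.raises(ValueError):
            s.log_prior(s.ParameterSet(alpha_p=0.5, beta=-1.0), spec)


class TestFitSubject:
    def test_reproducible_given_seed(self, vs2_dataset):
        a = s.fit_subject("VS2", vs2_dataset, FitOptions(seed=3, n_restarts=4))
        b = s.fit_subject("VS2", vs2_dataset, FitOptions(seed=3, n_restarts=4))
        assert a.nll == b.nll
        assert a.params.to_dict() == b.params.to_dict()

    def test_optimum_beats_generating_parameters(self, vs2_dataset):
        truth = s.ParameterSet(alpha_p=0.4, alpha_i=0.3, beta=5.0, kappa=0.3)
        fit = s.fit_subject("VS2", vs2_dataset, FitOptions(seed=0, n_restarts=8))
        assert fit.nll <= s.dataset_nll(s.get_model("VS2"), truth, vs2_dataset) + 1e-6
        assert fit.aic == pytest.approx(-fit.nll - fit.p)

    def test_mean_nll_per_trial_beats_chance(self, vs2_dataset):
        fit = s.fit_subject("VS2", vs2_dataset, FitOptions(seed=0, n_restarts=8))
        assert fit.nll / fit.n_trials_used < math.log(2)

    def test_lpp_objective_reported(self, vs2_dataset):
        fit = s.fit_subject("VS2", vs2_dataset,
                            FitOptions(objective="lpp", seed=0, n_restarts=4))
        assert fit.lpp == pytest.approx(
            -fit.nll + s.log_prior(fit.params, s.get_model("VS2")), abs=1e-9
        )

    def test_condition_filter_fits_subset(self, vs2_dataset):
        # per-condition fitting is a dataset filter, not a new objective
        sd_p = vs2_dataset[vs2_dataset["condition"].isin(["SD", "P"])]
        fit = s.fit_subject("VS2", sd_p.reset_index(drop=True),
                            FitOptions(seed=1, n_restarts=4))
        assert fit.n_trials_used == (sd_p["trial_type"] == "private").sum()

    def test_empty_dataset_rejected(self, vs2_dataset):
        with pytest.raises(ValueError):
            s.fit_subject("RW2", vs2_dataset.iloc[0:0], FitOptions(seed=0))


class TestModelResultsSurface:
    def test_fit_and_summary(self, vs2_dataset):
        mod = s.SocialLearningModel(vs2_dataset, "VS2")
        res = mod.fit(seed=0, n_restarts=4)
        text = res.summary()
        for token in ("VS2", "NLL", "AIC", "alpha_p", "alpha_i", "beta", "kappa"):
            assert token in text
        assert res.aic == pytest.approx(-res.nll - 4)

    def test_results_simulate_roundtrip(self, vs2_dataset):
        mod = s.SocialLearningModel(vs2_dataset, "VS2")
        res = mod.fit(seed=0, n_restarts=2)
        sim = res.simulate(seed=1)
        assert len(sim) == len(vs2_dataset)
        assert sim.loc[sim["trial_type"] == "private", "choice"].notna().all()

    def test_multi_subject_rejected(self, vs2_dataset):
        other = vs2_dataset.copy()
        other["subject_id"] = "s01"
        both = pd.concat([vs2_dataset, other])
        with pytest.raises(ValueError):
            s.SocialLearningModel(both, "RW2")

    def test_loglike_is_negated_nll(self, vs2_dataset):
        mod = s.SocialLearningModel(vs2_dataset, "RW2")
        p = {"alpha_p": 0.4, "beta": 3.0, "kappa": 0.1}
        assert mod.loglike(p) == -mod.nll(p)


class TestFitCohort:
    def test_one_row_per_subject_model(self, vs2_dataset):
        other = vs2_dataset.copy()
        other["subject_id"] = "s01"
        cohort = pd.concat([vs2_dataset, other], ignore_index=True)
        table = s.fit_cohort(cohort, ["RW2", "VS2"],
                             FitOptions(seed=0, n_restarts=2))
        assert len(table) == 4
        assert set(table["model"]) == {"RW2", "VS2"}
        assert (table["aic"] == -table["nll"] - table["n_params"]).all()
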