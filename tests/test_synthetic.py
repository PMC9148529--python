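"""Ground-truth properties of the synthetic two-cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from ecarm.balance import standardized_mean_difference
from ecarm.outcomes import classify_missingness
from ecarm.synthetic import (
    BASELINE_COVARIATES,
    CohortConfig,
    MissingnessSpec,
    generate_latent,
    generate_study,
    impose_missingness,
    true_marginal_log_or,
)


def _empirical_log_or(trial_truth, obs_truth, vm):
    pt = trial_truth.loc[trial_truth["visit_month"] == vm, "remission_latent"].mean()
    po = obs_truth.loc[obs_truth["visit_month"] == vm, "remission_latent"].mean()
    return logit(pt) - logit(po)


class TestLatentGeneration:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_subjects=40, cohort_id="trial", seed=5)
        a, b = generate_latent(cfg), generate_latent(cfg)
        pd.testing.assert_frame_equal(a.baseline, b.baseline)
        pd.testing.assert_frame_equal(a.visits, b.visits)

    def test_null_effect_gives_zero_log_or(self):
        zero = {6: 0.0, 12: 0.0, 24: 0.0}
        t = generate_latent(
            CohortConfig(n_subjects=20000, cohort_id="trial", seed=1, strategy_log_or=zero)
        )
        o = generate_latent(
            CohortConfig(n_subjects=20000, cohort_id="observational", seed=2, strategy_log_or=zero)
        )
        truth = true_marginal_log_or(pd.concat([t.truth, o.truth]))
        assert all(v == 0.0 for v in truth.values())
        for vm in (6, 12, 24):
            assert abs(_empirical_log_or(t.truth, o.truth, vm)) < 0.08

    def test_no_shift_gives_zero_smds(self):
        t = generate_latent(CohortConfig(n_subjects=20000, cohort_id="trial", seed=3))
        o = generate_latent(CohortConfig(n_subjects=20000, cohort_id="observational", seed=4))
        base = pd.concat([t.baseline, o.baseline], ignore_index=True)
        for c in BASELINE_COVARIATES:
            smd = standardized_mean_difference(base[c], base["cohort"])
            assert abs(smd) < 0.05, c

    def test_recovers_configured_log_or(self):
        eff = {6: 0.70, 12: 0.70, 24: 0.70}
        t = generate_latent(
            CohortConfig(n_subjects=50000, cohort_id="trial", seed=8, strategy_log_or=eff)
        )
        o = generate_latent(
            CohortConfig(n_subjects=50000, cohort_id="observational", seed=9, strategy_log_or=eff)
        )
        emp = _empirical_log_or(t.truth, o.truth, 12)
        assert emp == pytest.approx(0.70, abs=0.05)
        # and the recorded marginal truth matches the realized data closely
        truth = true_marginal_log_or(pd.concat([t.truth, o.truth]))
        assert emp == pytest.approx(truth[12], abs=0.04)

    def test_component_ranges_and_exact_remission(self):
        p = generate_latent(CohortConfig(n_subjects=2000, cohort_id="trial", seed=6))
        v = p.visits
        assert v["tjc28"].between(0, 28).all() and (v["tjc28"] % 1 == 0).all()
        assert v["sjc28"].between(0, 28).all() and (v["sjc28"] % 1 == 0).all()
        assert (v["esr"] > 0).all() and v["pga"].between(0, 100).all()
        assert not v[["tjc28", "sjc28", "esr", "pga"]].isna().any().any()

    def test_invalid_configs_raise(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1, cohort_id="trial", seed=0)
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=5, cohort_id="registry", seed=0)
        with pytest.raises(ValueError):
            CohortConfig(
                n_subjects=5, cohort_id="trial", seed=0,
                strategy_log_or={6: np.inf, 12: 0, 24: 0},
            )


class TestImposeMissingness:
    def test_zero_probabilities_identity(self):
        p = generate_latent(CohortConfig(n_subjects=50, cohort_id="trial", seed=2))
        obs, labels = impose_missingness(p, MissingnessSpec(), seed=3)
        pd.testing.assert_frame_equal(obs.visits, p.visits)
        assert (labels["label"] == "observed").all()

    def test_reproducible(self):
        p = generate_latent(CohortConfig(n_subjects=200, cohort_id="observational", seed=2))
        spec = MissingnessSpec(
            dropout_hazard={6: 0.05, 12: 0.1, 24: 0.2},
            intermittent_prob={6: 0.05, 12: 0.1},
            component_missing_prob={6: 0.05, 12: 0.05, 24: 0.05},
        )
        a = impose_missingness(p, spec, seed=9)
        b = impose_missingness(p, spec, seed=9)
        pd.testing.assert_frame_equal(a[0].visits, b[0].visits)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_trial_like_dropout_rates(self):
        p = generate_latent(CohortConfig(n_subjects=100000, cohort_id="trial", seed=13))
        spec = MissingnessSpec(dropout_hazard={6: 0.016, 12: 0.049, 24: 0.040})
        _, labels = impose_missingness(p, spec, seed=14)
        cum = labels[labels["label"] == "dropout"].groupby("visit_month").size() / 100000
        assert cum[6] == pytest.approx(0.016, abs=0.005)
        assert cum[12] == pytest.approx(0.064, abs=0.005)
        assert cum[24] == pytest.approx(0.101, abs=0.005)

    def test_mcar_component_missing_rate(self):
        p = generate_latent(CohortConfig(n_subjects=100000, cohort_id="observational", seed=15))
        spec = MissingnessSpec(component_missing_prob={6: 0.04, 12: 0.0, 24: 0.0})
        _, labels = impose_missingness(p, spec, seed=16)
        at6 = labels[labels["visit_month"] == 6]
        frac = (at6["label"] == "missing_at_visit").mean()
        assert frac == pytest.approx(0.04, abs=0.003)

    def test_intermittent_at_final_visit_rejected(self):
        with pytest.raises(ValueError, match="final visit"):
            MissingnessSpec(intermittent_prob={6: 0.0, 12: 0.0, 24: 0.1})

    def test_mechanism_validation(self):
        with pytest.raises(ValueError):
            MissingnessSpec(mechanism="MCAR", mar_dropout={"age": 0.1})
        with pytest.raises(ValueError):
            MissingnessSpec(mechanism="MAR", mnar_delta=0.5)
        with pytest.raises(ValueError):
            MissingnessSpec(dropout_hazard={6: 1.2, 12: 0.0, 24: 0.0})


class TestMechanisms:
    def test_mcar_independent_of_covariates(self):
        import statsmodels.api as sm

        p = generate_latent(CohortConfig(n_subjects=50000, cohort_id="trial", seed=21))
        spec = MissingnessSpec(dropout_hazard={6: 0.15, 12: 0.0, 24: 0.0})
        _, labels = impose_missingness(p, spec, seed=22)
        drop6 = (
            labels[labels["visit_month"] == 6].set_index("subject_id")["label"] == "dropout"
        )
        x = p.baseline.set_index("subject_id")["baseline_das28"].loc[drop6.index]
        res = sm.Logit(
            drop6.to_numpy(float), sm.add_constant(x.to_numpy(float))
        ).fit(disp=0)
        assert abs(res.params[1]) < 0.05

    def test_mar_coefficient_recovered(self):
        import statsmodels.api as sm

        p = generate_latent(CohortConfig(n_subjects=50000, cohort_id="trial", seed=23))
        spec = MissingnessSpec(
            dropout_hazard={6: 0.15, 12: 0.0, 24: 0.0},
            mechanism="MAR",
            mar_dropout={"baseline_das28": 0.8},
        )
        _, labels = impose_missingness(p, spec, seed=24)
        drop6 = (
            labels[labels["visit_month"] == 6].set_index("subject_id")["label"] == "dropout"
        )
        x = p.baseline.set_index("subject_id")["baseline_das28"].loc[drop6.index]
        res = sm.Logit(
            drop6.to_numpy(float), sm.add_constant(x.to_numpy(float))
        ).fit(disp=0)
        assert res.params[1] == pytest.approx(0.8, abs=0.1)
        # calibration keeps the marginal rate at the specified hazard
        assert drop6.mean() == pytest.approx(0.15, abs=0.01)


class TestLabelRoundTrip:
    @pytest.mark.parametrize("seed", range(12))
    def test_classifier_reproduces_ground_truth(self, seed):
        rng = np.random.default_rng(seed)
        p = generate_latent(
            CohortConfig(n_subjects=60, cohort_id="observational", seed=seed + 100)
        )
        spec = MissingnessSpec(
            dropout_hazard={vm: rng.uniform(0, 0.3) for vm in (6, 12, 24)},
            intermittent_prob={vm: rng.uniform(0, 0.3) for vm in (6, 12)},
            component_missing_prob={vm: rng.uniform(0, 0.3) for vm in (6, 12, 24)},
        )
        obs, truth_labels = impose_missingness(p, spec, seed=seed)
        relabeled = classify_missingness(obs.visits)
        merged = truth_labels.merge(
            relabeled, on=["subject_id", "visit_month"], suffixes=("_truth", "_cls")
        )
        assert (merged["label_truth"] == merged["label_cls"]).all()


def test_study_determinism():
    a = generate_study(seed=3, n_trial=50, n_observational=60)
    b = generate_study(seed=3, n_trial=50, n_observational=60)
    pd.testing.assert_frame_equal(a.panel.visits, b.panel.visits)
    pd.testing.assert_frame_equal(a.labels, b.labels)
    assert a.true_marginal_log_or == b.true_marginal_log_or
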