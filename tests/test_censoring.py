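"""Artificial censoring and inverse-probability-of-censoring weights."""

import numpy as np
import pandas as pd
import pytest

from conftest import blank_cells, make_manual_panel
from ecarm.censoring import (
    CensoredPanel,
    artificial_censor,
    assert_monotone,
    fit_censoring_models,
    ipcw_weights,
)
from ecarm.outcomes import COMPONENTS, classify_missingness
from ecarm.synthetic import CohortConfig, MissingnessSpec, generate_latent, impose_missingness


def _labeled_panel(blanks):
    """Ten-subject panel with cells blanked per {sid: (months, components)}."""
    panel = make_manual_panel(
        {f"tri{i}": [True, i % 2 == 0, True] for i in range(10)}
    )
    for sid, (months, comps) in blanks.items():
        blank_cells(panel, sid, months, comps)
    labels = classify_missingness(panel.visits)
    return panel, labels


class TestArtificialCensor:
    def test_strict_censors_at_first_partial_visit(self):
        panel, labels = _labeled_panel({"tri0": ([12], ["esr"])})
        cens = artificial_censor(panel.visits, labels, rule="strict")
        assert cens.censor_visit["tri0"] == 12
        sub = cens.visits[cens.visits["subject_id"] == "tri0"]
        assert sub[sub["visit_month"] >= 12][list(COMPONENTS)].isna().all().all()
        assert sub[sub["visit_month"] == 6][list(COMPONENTS)].notna().all().all()

    def test_strict_censors_at_intermittent_visit(self):
        panel, labels = _labeled_panel({"tri1": ([6], COMPONENTS)})
        cens = artificial_censor(panel.visits, labels, rule="strict")
        assert cens.censor_visit["tri1"] == 6
        sub = cens.visits[cens.visits["subject_id"] == "tri1"]
        assert sub[list(COMPONENTS)].isna().all().all()

    def test_no_missingness_leaves_panel_unchanged(self):
        panel, labels = _labeled_panel({})
        cens = artificial_censor(panel.visits, labels, rule="strict")
        pd.testing.assert_frame_equal(cens.visits, panel.visits)
        assert cens.censor_visit.isna().all()

    def test_intermittent_only_ignores_partial_visits_and_fails_monotonicity(self):
        # a partial visit followed by observed data is not monotone, so the
        # intermittent-only rule (meant for post-MI panels) must fail loudly
        panel, labels = _labeled_panel({"tri0": ([12], ["esr"])})
        with pytest.raises(ValueError, match="monotone"):
            artificial_censor(panel.visits, labels, rule="intermittent_only")

    def test_unknown_rule(self):
        panel, labels = _labeled_panel({})
        with pytest.raises(ValueError, match="rule"):
            artificial_censor(panel.visits, labels, rule="everything")


def _intercept_only_panel(n=1000, censored_at_6=200):
    panel = make_manual_panel({f"tri{i}": [True, False, True] for i in range(n)})
    for i in range(censored_at_6):
        blank_cells(panel, f"tri{i}", [6, 12, 24])
    return panel


class TestCensoringModels:
    def test_no_censoring_gives_zero_hazards(self):
        panel = _intercept_only_panel(50, 0)
        cens = artificial_censor(panel.visits, classify_missingness(panel.visits))
        models = fit_censoring_models(cens, panel.baseline, covariates=[], timevarying=False)
        for vm in (6, 12, 24):
            assert models.marginal[vm] == 0.0
            assert (models.hazards[vm] == 0.0).all()

    def test_intercept_only_hazard_is_the_proportion(self):
        panel = _intercept_only_panel(1000, 200)
        cens = artificial_censor(panel.visits, classify_missingness(panel.visits))
        models = fit_censoring_models(cens, panel.baseline, covariates=[], timevarying=False)
        assert models.marginal[6] == pytest.approx(0.2)
        assert models.hazards[6].to_numpy() == pytest.approx(0.2, abs=1e-6)

    def test_small_at_risk_set_rejected(self):
        panel = _intercept_only_panel(10, 2)
        cens = artificial_censor(panel.visits, classify_missingness(panel.visits))
        with pytest.raises(ValueError, match="at-risk"):
            fit_censoring_models(
                cens, panel.baseline, covariates=[], timevarying=False, min_at_risk=50
            )

    def test_mar_hazard_coefficient_recovered(self):
        p = generate_latent(CohortConfig(n_subjects=50000, cohort_id="trial", seed=41))
        spec = MissingnessSpec(
            dropout_hazard={6: 0.2, 12: 0.0, 24: 0.0},
            mechanism="MAR",
            mar_dropout={"baseline_das28": 0.8},
        )
        obs, labels = impose_missingness(p, spec, seed=42)
        cens = artificial_censor(obs.visits, labels, rule="strict")
        models = fit_censoring_models(
            cens, p.baseline, covariates=["baseline_das28"], timevarying=False
        )
        assert models.params[6]["baseline_das28"] == pytest.approx(0.8, abs=0.1)


class TestIpcwWeights:
    def test_no_censoring_gives_unit_weights(self):
        panel = _intercept_only_panel(50, 0)
        cens = artificial_censor(panel.visits, classify_missingness(panel.visits))
        models = fit_censoring_models(cens, panel.baseline, covariates=[], timevarying=False)
        w = ipcw_weights(models, cens)
        assert np.allclose(w["ipcw"], 1.0)
        assert len(w) == 150

    def test_conservation_under_20pct_censoring(self):
        n = 1000
        panel = _intercept_only_panel(n, 200)
        cens = artificial_censor(panel.visits, classify_missingness(panel.visits))
        models = fit_censoring_models(cens, panel.baseline, covariates=[], timevarying=False)
        w = ipcw_weights(models, cens, stabilized=False)
        for vm in (6, 12, 24):
            wv = w[w["visit_month"] == vm]["ipcw"]
            assert wv.to_numpy() == pytest.approx(1.25, abs=1e-6)
            assert wv.sum() == pytest.approx(n, rel=0.01)

    def test_cumulative_product(self):
        # hazards 0.1 then 0.1 -> 24-month unstabilized weight 1/(0.9*0.9)
        panel = make_manual_panel({f"tri{i}": [True, False, True] for i in range(100)})
        for i in range(10):
            blank_cells(panel, f"tri{i}", [6, 12, 24])
        for i in range(10, 19):
            blank_cells(panel, f"tri{i}", [12, 24])
        cens = artificial_censor(panel.visits, classify_missingness(panel.visits))
        models = fit_censoring_models(cens, panel.baseline, covariates=[], timevarying=False)
        assert models.marginal[6] == pytest.approx(0.10)
        assert models.marginal[12] == pytest.approx(0.10)
        w = ipcw_weights(models, cens, stabilized=False)
        w24 = w[w["visit_month"] == 24]["ipcw"]
        assert w24.to_numpy() == pytest.approx(1.0 / 0.81, abs=1e-4)
        assert w24.to_numpy() == pytest.approx(1.2346, abs=1e-3)

    def test_stabilized_mean_near_one(self):
        panel = _intercept_only_panel(5000, 1000)
        cens = artificial_censor(panel.visits, classify_missingness(panel.visits))
        models = fit_censoring_models(cens, panel.baseline, covariates=[], timevarying=False)
        w = ipcw_weights(models, cens, stabilized=True)
        for vm in (6, 12, 24):
            assert w[w["visit_month"] == vm]["ipcw"].mean() == pytest.approx(1.0, abs=0.02)

    def test_monotone_precondition_enforced(self):
        panel = make_manual_panel({"tri0": [True, True, True]})
        blank_cells(panel, "tri0", [6])  # gap then observed data
        with pytest.raises(ValueError, match="monotone"):
            fit_censoring_models(
                CensoredPanel(panel.visits, pd.Series(dtype=float)),
                panel.baseline,
                covariates=[],
                timevarying=False,
            )


class TestIpcwUnbiasedness:
    def test_weighted_proportion_recovers_truth_where_complete_case_fails(self):
        p = generate_latent(CohortConfig(n_subjects=20000, cohort_id="observational", seed=51))
        spec = MissingnessSpec(
            dropout_hazard={6: 0.08, 12: 0.15, 24: 0.30},
            mechanism="MAR",
            mar_dropout={"baseline_das28": -1.5},
        )
        obs, labels = impose_missingness(p, spec, seed=52)
        truth24 = p.truth[p.truth["visit_month"] == 24]["remission_latent"].mean()

        cens = artificial_censor(obs.visits, labels, rule="strict")
        models = fit_censoring_models(
            cens, p.baseline, covariates=["baseline_das28"], timevarying=True
        )
        w = ipcw_weights(models, cens)
        from ecarm.outcomes import panel_das28, remission

        v24 = cens.visits[cens.visits["visit_month"] == 24].copy()
        v24["rem"] = remission(panel_das28(v24))
        v24 = v24[v24["rem"].notna()]
        wv = w[w["visit_month"] == 24].set_index("subject_id")["ipcw"]
        weighted = np.average(v24["rem"], weights=wv.loc[v24["subject_id"]])
        unweighted = v24["rem"].mean()
        assert abs(unweighted - truth24) > 0.03  # complete-case bias is real
        assert weighted == pytest.approx(truth24, abs=0.015)
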