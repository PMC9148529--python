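"""Synthetic two-cohort generator with known ground truth.

Emulates the data situation of a single-arm treat-to-target trial compared
against a prospective observational cohort used as an external control arm:
two cohorts of recently diagnosed RA patients with shifted baseline covariate
distributions, complete latent DAS28 component trajectories at the 6/12/24
month visits, a known strategy effect on remission, and missingness imposed on
top of the complete data by configurable mechanisms.

The generator produces three kinds of structure:

1. *Baseline covariates* drawn from simple parametric reference families
   (normal / lognormal / Bernoulli / binomial), optionally location/scale
   shifted per cohort.  The shifted families are chosen so that the true
   propensity of cohort membership is exactly logistic in the raw covariates.
2. *Latent outcomes*: the per-visit remission indicator follows a logistic
   model in the trial indicator (coefficient = the configured strategy log
   odds ratio) and standardized baseline covariates.  DAS28 component values
   (TJC28, SJC28, ESR, PGA) are then constructed to reproduce the drawn
   remission status exactly through the DAS28-ESR formula.
3. *Missingness*: per-visit drop-out hazards (monotone blanking), intermittent
   whole-visit gaps at 6/12 months, and component-level missingness at
   retained visits; each process may be MCAR, MAR (logistic in baseline and
   last-observed time-varying covariates) or MNAR (delta shift on the latent
   outcome entering the missingness model).

Every draw is governed by explicit integer seeds; identical configuration
yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .outcomes import (
    COMPONENTS,
    DAS28_ESR_COEF,
    DAS28_PGA_COEF,
    DAS28_SJC_COEF,
    DAS28_TJC_COEF,
    LABEL_DROPOUT,
    LABEL_INTERMITTENT,
    LABEL_MISSING_AT_VISIT,
    LABEL_OBSERVED,
    VISIT_MONTHS,
    das28,
)

BASELINE_COVARIATES = (
    "age",
    "female",
    "symptom_duration_months",
    "higher_education",
    "rf_positive",
    "accp_positive",
    "esr",
    "crp",
    "sjc28",
    "tjc28",
    "pga",
    "physician_global",
    "comorbidity",
    "current_smoking",
    "fatigue",
    "eq5d",
)

# (family, params) reference distributions; means sit in the ranges typical of
# early-RA inception cohorts.  Exact values are defaults, not claims.
_REFERENCE = {
    "age": ("normal", (55.0, 13.0, 18.0, 90.0)),
    "female": ("bernoulli", 0.66),
    "symptom_duration_months": ("lognormal", (1.95, 0.80, 0.5, 120.0)),
    "higher_education": ("bernoulli", 0.35),
    "rf_positive": ("bernoulli", 0.62),
    "accp_positive": ("bernoulli", 0.60),
    "esr": ("lognormal", (3.05, 0.60, 1.0, 140.0)),
    "crp": ("lognormal", (2.30, 0.90, 0.1, 200.0)),
    "sjc28": ("binomial", 0.25),
    "tjc28": ("binomial", 0.30),
    "pga": ("normal", (55.0, 22.0, 0.0, 100.0)),
    "physician_global": ("normal", (45.0, 20.0, 0.0, 100.0)),
    "comorbidity": ("bernoulli", 0.38),
    "current_smoking": ("bernoulli", 0.24),
    "fatigue": ("normal", (48.0, 25.0, 0.0, 100.0)),
    "eq5d": ("normal", (0.62, 0.22, -0.5, 1.0)),
}

# loadings of the latent baseline severity factor s ~ N(0,1) on the disease
# activity measures (logit scale for joint-count propensities, log scale for
# acute-phase reactants, raw mm for the VAS scales); these correlate the
# components so the composite DAS28 has realistic dispersion
_SEVERITY_LOADING = {
    "sjc28": 0.50,
    "tjc28": 0.50,
    "esr": 0.35,
    "crp": 0.40,
    "pga": 13.0,
    "physician_global": 11.0,
    "fatigue": 8.0,
}

# standardization constants for the outcome / trajectory models; the
# baseline-DAS28 pair is the mean/sd the reference families above imply
_Z_REF = {"baseline_das28": (5.24, 1.02), "age": (55.0, 13.0), "eq5d": (0.62, 0.22)}

# coefficients of the latent remission model on the z-scored covariates above
OUTCOME_COVARIATE_COEFS = {"baseline_das28": -0.40, "age": -0.10, "eq5d": 0.10}

# per-visit remission-model intercepts (control arm logit)
DEFAULT_ALPHA = {6: -0.85, 12: -0.71, 24: -0.08}
DEFAULT_STRATEGY_LOG_OR = {6: 0.42, 12: 0.77, 24: 0.40}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one generated cohort.

    ``strategy_log_or`` is the conditional log odds ratio on the trial
    indicator in the latent remission model and is shared between the two
    cohorts of a study; the cohort's own linear predictor uses the indicator
    implied by ``cohort_id``.
    """

    n_subjects: int
    cohort_id: str  # "trial" | "observational"
    seed: int
    covariate_shift: dict = field(default_factory=dict)
    strategy_log_or: dict = field(default_factory=lambda: dict(DEFAULT_STRATEGY_LOG_OR))
    alpha: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA))
    outcome_covariate_coefs: dict = field(
        default_factory=lambda: dict(OUTCOME_COVARIATE_COEFS)
    )

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.cohort_id not in ("trial", "observational"):
            raise ValueError(f"unknown cohort_id {self.cohort_id!r}")
        for d in (self.strategy_log_or, self.alpha):
            if not all(np.isfinite(list(d.values()))):
                raise ValueError("non-finite effect parameter")
        for v in self.covariate_shift.values():
            vals = v.values() if isinstance(v, dict) else [v]
            if not all(np.isfinite(list(vals))):
                raise ValueError("non-finite covariate shift")


@dataclass(frozen=True)
class MissingnessSpec:
    """Missingness mechanism for one cohort.

    Probabilities are per-visit and conditional: the drop-out hazard applies to
    subjects still in follow-up, the intermittent probability to non-dropped
    visits at 6/12 months (a later visit exists structurally), and the
    component-missing probability to retained visits.  MAR coefficient dicts
    map covariate names (any numeric baseline column, ``baseline_das28`` or
    ``prior_das28``) to log-odds slopes per raw unit.  Under MNAR the latent
    DAS28 at the visit being blanked enters each missingness model with slope
    ``mnar_delta``.
    """

    dropout_hazard: dict = field(default_factory=lambda: {6: 0.0, 12: 0.0, 24: 0.0})
    intermittent_prob: dict = field(default_factory=lambda: {6: 0.0, 12: 0.0})
    component_missing_prob: dict = field(
        default_factory=lambda: {6: 0.0, 12: 0.0, 24: 0.0}
    )
    mechanism: str = "MCAR"
    mar_dropout: dict = field(default_factory=dict)
    mar_intermittent: dict = field(default_factory=dict)
    mar_component: dict = field(default_factory=dict)
    mnar_delta: float = 0.0
    calibrate_marginal: bool = True

    def __post_init__(self):
        for name, probs in (
            ("dropout_hazard", self.dropout_hazard),
            ("intermittent_prob", self.intermittent_prob),
            ("component_missing_prob", self.component_missing_prob),
        ):
            for vm, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{vm}] = {p} outside [0, 1]")
        if self.intermittent_prob.get(VISIT_MONTHS[-1], 0.0) > 0:
            raise ValueError("intermittent probability at the final visit must be 0")
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        has_mar = any((self.mar_dropout, self.mar_intermittent, self.mar_component))
        if self.mechanism == "MCAR" and (has_mar or self.mnar_delta != 0.0):
            raise ValueError("MCAR spec must have no MAR coefficients and delta = 0")
        if self.mechanism == "MAR" and self.mnar_delta != 0.0:
            raise ValueError("MAR spec must have delta = 0")


@dataclass
class CohortPanel:
    """One cohort's data: a baseline table and a long per-visit table.

    ``truth`` (present for generated panels) carries the latent per-visit
    DAS28, the latent remission status, and the counterfactual remission
    probabilities under each strategy, from which the true marginal log OR of
    a two-cohort study is computed.
    """

    baseline: pd.DataFrame
    visits: pd.DataFrame
    truth: pd.DataFrame | None = None

    def copy(self) -> "CohortPanel":
        return CohortPanel(
            self.baseline.copy(),
            self.visits.copy(),
            None if self.truth is None else self.truth.copy(),
        )


def _zscore(name: str, values: np.ndarray) -> np.ndarray:
    mu, sd = _Z_REF[name]
    return (np.asarray(values, dtype=float) - mu) / sd


def _draw_baseline(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    severity = rng.standard_normal(n)  # shared baseline disease-activity factor
    cols = {}
    for name in BASELINE_COVARIATES:
        family, params = _REFERENCE[name]
        shift = cfg.covariate_shift.get(name, 0.0)
        loc = shift.get("loc", 0.0) if isinstance(shift, dict) else float(shift)
        scale = shift.get("scale", 1.0) if isinstance(shift, dict) else 1.0
        load = _SEVERITY_LOADING.get(name, 0.0)
        if family == "normal":
            mu, sd, lo, hi = params
            x = rng.normal(mu + loc + load * severity, sd * scale, n)
            cols[name] = np.clip(x, lo, hi)
        elif family == "lognormal":
            mu, sd, lo, hi = params
            x = np.exp(rng.normal(mu + loc + load * severity, sd * scale, n))
            cols[name] = np.clip(x, lo, hi)
        elif family == "bernoulli":
            p = float(np.clip(params + loc, 0.001, 0.999))
            cols[name] = rng.binomial(1, p, n).astype(float)
        elif family == "binomial":
            p0 = float(np.clip(params + loc / 28.0, 0.001, 0.999))
            p = expit(logit(p0) + load * severity)
            cols[name] = rng.binomial(28, p).astype(float)
    df = pd.DataFrame(cols)
    df.insert(0, "cohort", cfg.cohort_id)
    df.insert(
        0,
        "subject_id",
        [f"{cfg.cohort_id[:3]}_{i:06d}" for i in range(n)],
    )
    df["baseline_das28"] = das28(df["tjc28"], df["sjc28"], df["esr"], df["pga"])
    return df


def _components_from_das28(
    target: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Construct (TJC28, SJC28, ESR, PGA) whose DAS28 equals ``target`` exactly.

    Integer joint counts and lognormal-ish ESR are drawn at a severity
    commensurate with the target score; PGA is then solved exactly, with ESR
    re-solved (and joint counts adjusted in rare infeasible cases) so the
    recomputed score always matches the target to machine precision.
    """
    n = len(target)
    frac = np.clip(target / 9.4, 0.0, 1.0)
    p_joint = np.clip(frac**1.4, 0.0, 0.85)
    tjc = rng.binomial(28, np.clip(p_joint * 1.05, 0, 0.9)).astype(float)
    sjc = rng.binomial(28, np.clip(p_joint * 0.90, 0, 0.9)).astype(float)
    esr = np.exp(rng.normal(0.9 + 0.55 * target, 0.35, n))
    esr = np.clip(esr, 1.0, 140.0)

    def joint_term(t, s):
        return DAS28_TJC_COEF * np.sqrt(t) + DAS28_SJC_COEF * np.sqrt(s)

    jt = joint_term(tjc, sjc)
    pga = (target - jt - DAS28_ESR_COEF * np.log(esr)) / DAS28_PGA_COEF
    bad = (pga < 0) | (pga > 100)
    pga = np.clip(pga, 0.0, 100.0)
    if np.any(bad):
        esr_new = np.exp((target - jt - DAS28_PGA_COEF * pga) / DAS28_ESR_COEF)
        esr = np.where(bad, esr_new, esr)
        infeasible = np.flatnonzero(bad & ((esr < 1.0) | (esr > 150.0)))
        for i in infeasible:
            t_i, s_i = tjc[i], sjc[i]
            for _ in range(120):
                e_i = np.exp(
                    (target[i] - joint_term(t_i, s_i) - DAS28_PGA_COEF * pga[i])
                    / DAS28_ESR_COEF
                )
                if 1.0 <= e_i <= 150.0:
                    break
                if e_i > 150.0:  # score too high for current joints
                    t_i = min(t_i + 1, 28)
                    s_i = min(s_i + 1, 28)
                    pga[i] = 100.0
                else:  # score too low
                    if t_i > 0 or s_i > 0:
                        t_i = max(t_i - 1, 0)
                        s_i = max(s_i - 1, 0)
                    pga[i] = 0.0
            tjc[i], sjc[i], esr[i] = t_i, s_i, np.clip(e_i, 1.0, 150.0)
    return tjc, sjc, esr, pga


def generate_latent(config: CohortConfig) -> CohortPanel:
    """Generate one cohort's complete latent panel.

    Baseline covariates come from the (shifted) reference families; per-visit
    remission follows the configured logistic model; component values are
    constructed to reproduce the drawn remission status exactly.  The returned
    panel's ``truth`` table records the latent DAS28, the latent remission
    indicator and both counterfactual remission probabilities per
    subject-visit.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    baseline = _draw_baseline(config, rng)
    n = config.n_subjects
    arm = 1.0 if config.cohort_id == "trial" else 0.0

    zs = {
        "baseline_das28": _zscore("baseline_das28", baseline["baseline_das28"]),
        "age": _zscore("age", baseline["age"]),
        "eq5d": _zscore("eq5d", baseline["eq5d"]),
    }
    lin_cov = np.zeros(n)
    for name, coef in config.outcome_covariate_coefs.items():
        lin_cov += coef * zs[name]

    u = rng.normal(0.0, 0.35, n)  # subject random effect on disease trajectory
    visit_rows, truth_rows = [], []
    for vm in VISIT_MONTHS:
        a = config.alpha[vm]
        b = config.strategy_log_or[vm]
        p1 = expit(a + b + lin_cov)
        p0 = expit(a + lin_cov)
        p = p1 if arm == 1.0 else p0
        rem = rng.random(n) < p
        eta = -0.15 + 0.35 * zs["baseline_das28"] + u + rng.normal(0.0, 0.6, n)
        d_rem = np.clip(2.6 * expit(eta), 0.05, 2.58)
        d_non = np.clip(2.6 + 4.3 * expit(eta), 2.62, 8.6)
        target = np.where(rem, d_rem, d_non)
        tjc, sjc, esr, pga = _components_from_das28(target, rng)
        score = das28(tjc, sjc, esr, pga)
        # construction is exact: the realized score sits on the drawn side of 2.6
        assert np.array_equal(score < 2.6, rem)
        visit_rows.append(
            pd.DataFrame(
                {
                    "subject_id": baseline["subject_id"],
                    "cohort": config.cohort_id,
                    "visit_month": vm,
                    "tjc28": tjc,
                    "sjc28": sjc,
                    "esr": esr,
                    "pga": pga,
                }
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "subject_id": baseline["subject_id"],
                    "visit_month": vm,
                    "das28_latent": score,
                    "remission_latent": rem.astype(float),
                    "p_trial": p1,
                    "p_control": p0,
                }
            )
        )
    visits = pd.concat(visit_rows, ignore_index=True)
    visits = visits.sort_values(["subject_id", "visit_month"], ignore_index=True)
    truth = pd.concat(truth_rows, ignore_index=True)
    truth = truth.sort_values(["subject_id", "visit_month"], ignore_index=True)
    return CohortPanel(baseline=baseline, visits=visits, truth=truth)


def true_marginal_log_or(truth: pd.DataFrame) -> dict[int, float]:
    """True marginal (covariate-standardized) log OR per visit.

    Averages the counterfactual remission probabilities over the pooled
    covariate distribution of all subjects in ``truth`` (the ATE
    standardization the IPTW analyses target) and contrasts the two strategies
    on the log-odds scale.
    """
    out = {}
    for vm, grp in truth.groupby("visit_month"):
        out[int(vm)] = float(logit(grp["p_trial"].mean()) - logit(grp["p_control"].mean()))
    return out


def _mar_design(
    spec_coefs: dict,
    baseline: pd.DataFrame,
    prior_das28: np.ndarray,
) -> np.ndarray:
    lin = np.zeros(len(baseline))
    for name, coef in spec_coefs.items():
        if name == "prior_das28":
            x = prior_das28
        else:
            x = baseline[name].to_numpy(dtype=float)
        mu = _Z_REF.get(name, (float(np.mean(x)), 1.0))[0]
        lin += coef * (x - mu)
    return lin


def _solve_intercept(lin: np.ndarray, p_target: float) -> float:
    """Intercept a with mean(expit(a + lin)) == p_target over the given rows."""
    if p_target <= 0.0:
        return -np.inf
    if p_target >= 1.0:
        return np.inf
    if np.allclose(lin, 0.0):
        return float(logit(p_target))
    return float(brentq(lambda a: expit(a + lin).mean() - p_target, -30.0, 30.0))


# the 14 nonempty proper subsets of the four components
_COMPONENT_SUBSETS = [
    [c for j, c in enumerate(COMPONENTS) if (m >> j) & 1]
    for m in range(1, 2 ** len(COMPONENTS) - 1)
]


def impose_missingness(
    panel: CohortPanel, spec: MissingnessSpec, seed: int
) -> tuple[CohortPanel, pd.DataFrame]:
    """Blank cells of a complete panel according to the missingness spec.

    Drop-out is evaluated first, visit by visit; once triggered it blanks the
    visit and every later one.  Intermittent gaps and component-level blanking
    apply only to visits not already removed by drop-out.  MAR models use only
    values observed before the blanking time (baseline covariates and the
    last fully observed DAS28); MNAR additionally lets the latent DAS28 of the
    visit being blanked enter with slope ``mnar_delta``.  Returns the observed
    panel and the exact record of which rule fired per subject-visit; interior
    gaps left without any later observed visit by subsequent drop-out are
    reported as drop-out, so the label table is consistent with the final
    data.
    """
    if panel.truth is None:
        raise ValueError("impose_missingness needs a generated panel with truth")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    baseline = panel.baseline
    n = len(baseline)
    sid = baseline["subject_id"].to_numpy()
    latent = panel.truth.pivot(index="subject_id", columns="visit_month", values="das28_latent")
    latent = latent.loc[sid]

    prior_das28 = baseline["baseline_das28"].to_numpy(dtype=float).copy()
    dropped = np.zeros(n, dtype=bool)
    blank_visit = {vm: np.zeros(n, dtype=bool) for vm in VISIT_MONTHS}
    comp_blank = {vm: np.zeros((n, len(COMPONENTS)), dtype=bool) for vm in VISIT_MONTHS}

    for vm in VISIT_MONTHS:
        das_here = latent[vm].to_numpy(dtype=float)
        mnar = (
            spec.mnar_delta * (das_here - _Z_REF["baseline_das28"][0])
            if spec.mechanism == "MNAR"
            else 0.0
        )

        # drop-out among subjects still in follow-up
        h = spec.dropout_hazard.get(vm, 0.0)
        at_risk = ~dropped
        if h > 0 and at_risk.any():
            lin = _mar_design(spec.mar_dropout, baseline, prior_das28) + mnar
            a = (
                _solve_intercept(lin[at_risk], h)
                if spec.calibrate_marginal
                else float(logit(h)) if 0 < h < 1 else (np.inf if h >= 1 else -np.inf)
            )
            fire = rng.random(n) < expit(a + lin)
            dropped |= at_risk & fire
        blank_visit[vm] |= dropped

        # intermittent whole-visit gap (6/12 months only)
        p_int = spec.intermittent_prob.get(vm, 0.0)
        alive = ~dropped
        if p_int > 0 and alive.any():
            lin = _mar_design(spec.mar_intermittent, baseline, prior_das28) + mnar
            a = _solve_intercept(lin[alive], p_int) if spec.calibrate_marginal else float(logit(p_int))
            fire = rng.random(n) < expit(a + lin)
            blank_visit[vm] |= alive & fire

        # component-level blanking at retained visits
        p_cmp = spec.component_missing_prob.get(vm, 0.0)
        retained = ~blank_visit[vm]
        if p_cmp > 0 and retained.any():
            lin = _mar_design(spec.mar_component, baseline, prior_das28) + mnar
            a = _solve_intercept(lin[retained], p_cmp) if spec.calibrate_marginal else float(logit(p_cmp))
            fire = (rng.random(n) < expit(a + lin)) & retained
            subset_idx = rng.integers(0, len(_COMPONENT_SUBSETS), n)
            for i in np.flatnonzero(fire):
                for c in _COMPONENT_SUBSETS[subset_idx[i]]:
                    comp_blank[vm][i, COMPONENTS.index(c)] = True

        # update last observed DAS28 (fully observed visits only)
        fully_obs = ~blank_visit[vm] & ~comp_blank[vm].any(axis=1)
        prior_das28 = np.where(fully_obs, das_here, prior_das28)

    visits = panel.visits.copy()
    idx_map = pd.Series(np.arange(n), index=sid)
    for vm in VISIT_MONTHS:
        rows = visits["visit_month"] == vm
        pos = idx_map[visits.loc[rows, "subject_id"]].to_numpy()
        fully = blank_visit[vm][pos]
        for k, c in enumerate(COMPONENTS):
            col = visits.loc[rows, c].to_numpy(dtype=float)
            col[fully | comp_blank[vm][pos, k]] = np.nan
            visits.loc[rows, c] = col

    # canonical ground-truth labels consistent with the final data
    label_rows = []
    for i in range(n):
        states = []
        for vm in VISIT_MONTHS:
            if blank_visit[vm][i]:
                states.append("blank")
            elif comp_blank[vm][i].any():
                states.append("partial")
            else:
                states.append("observed")
        for j, vm in enumerate(VISIT_MONTHS):
            st = states[j]
            if st == "observed":
                lab = LABEL_OBSERVED
            elif st == "partial":
                lab = LABEL_MISSING_AT_VISIT
            elif any(s != "blank" for s in states[j + 1 :]):
                lab = LABEL_INTERMITTENT
            else:
                lab = LABEL_DROPOUT
            label_rows.append({"subject_id": sid[i], "visit_month": vm, "label": lab})
    labels = pd.DataFrame(label_rows, columns=["subject_id", "visit_month", "label"])
    observed = CohortPanel(baseline=baseline.copy(), visits=visits, truth=panel.truth.copy())
    return observed, labels


# ---------------------------------------------------------------------------
# presets reproducing the study's reported missingness conditions
# ---------------------------------------------------------------------------

#: trial-arm drop-out hazards giving cumulative drop-out 1.6/6.4/10.1%
TRIAL_DROPOUT_HAZARDS = {6: 0.016, 12: 0.049, 24: 0.040}
#: observational-arm hazards giving cumulative drop-out 2.4/9.2/35.1%
OBSERVATIONAL_DROPOUT_HAZARDS = {6: 0.024, 12: 0.0697, 24: 0.2852}
#: conditional intermittent rates giving marginal 7.3% (6m) and 11.3% (12m)
OBSERVATIONAL_INTERMITTENT = {6: 0.0748, 12: 0.1244}
#: conditional component-missing rates giving marginal 4.0/4.6/8.5%
OBSERVATIONAL_COMPONENT_MISSING = {6: 0.0443, 12: 0.0579, 24: 0.1310}

#: default cohort shift of the trial arm relative to the observational
#: reference: slightly younger, slightly higher baseline joint activity.
TRIAL_COVARIATE_SHIFT = {
    "age": -2.0,
    "sjc28": 1.0,
    "tjc28": 1.0,
    "pga": 3.0,
    "higher_education": 0.03,
    "current_smoking": 0.02,
}


def trial_preset(n: int = 188, seed: int = 0) -> tuple[CohortConfig, MissingnessSpec]:
    """Trial-like cohort: monotone drop-out only, sicker patients drop out."""
    cfg = CohortConfig(
        n_subjects=n,
        cohort_id="trial",
        seed=seed,
        covariate_shift=dict(TRIAL_COVARIATE_SHIFT),
    )
    spec = MissingnessSpec(
        dropout_hazard=dict(TRIAL_DROPOUT_HAZARDS),
        mechanism="MAR",
        mar_dropout={"baseline_das28": 0.30},
    )
    return cfg, spec


def observational_preset(
    n: int = 328, seed: int = 1
) -> tuple[CohortConfig, MissingnessSpec]:
    """Observational cohort: all three missingness types at the reported rates.

    Patients doing well attend less often, so drop-out and intermittent gaps
    load negatively on baseline DAS28.
    """
    cfg = CohortConfig(n_subjects=n, cohort_id="observational", seed=seed)
    spec = MissingnessSpec(
        dropout_hazard=dict(OBSERVATIONAL_DROPOUT_HAZARDS),
        intermittent_prob=dict(OBSERVATIONAL_INTERMITTENT),
        component_missing_prob=dict(OBSERVATIONAL_COMPONENT_MISSING),
        mechanism="MAR",
        mar_dropout={"baseline_das28": -0.30},
        mar_intermittent={"baseline_das28": -0.20},
    )
    return cfg, spec


@dataclass
class StudyData:
    """A combined two-cohort study: observed data, labels and ground truth."""

    panel: CohortPanel
    labels: pd.DataFrame
    true_marginal_log_or: dict[int, float]
    true_conditional_log_or: dict[int, float]


def generate_study(
    seed: int,
    n_trial: int = 188,
    n_observational: int = 328,
    trial_config: CohortConfig | None = None,
    trial_missingness: MissingnessSpec | None = None,
    observational_config: CohortConfig | None = None,
    observational_missingness: MissingnessSpec | None = None,
) -> StudyData:
    """Generate a full two-cohort study with one top-level seed.

    The seed is split into independent substreams (trial covariates/outcomes,
    observational covariates/outcomes, trial missingness, observational
    missingness) so individual stages can be reproduced independently.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]

    t_cfg, t_spec = trial_preset(n_trial, seed=sub[0])
    o_cfg, o_spec = observational_preset(n_observational, seed=sub[1])
    if trial_config is not None:
        t_cfg = replace(trial_config, seed=sub[0])
    if observational_config is not None:
        o_cfg = replace(observational_config, seed=sub[1])
    if trial_missingness is not None:
        t_spec = trial_missingness
    if observational_missingness is not None:
        o_spec = observational_missingness

    t_latent = generate_latent(t_cfg)
    o_latent = generate_latent(o_cfg)
    t_obs, t_labels = impose_missingness(t_latent, t_spec, seed=sub[2])
    o_obs, o_labels = impose_missingness(o_latent, o_spec, seed=sub[3])

    panel = CohortPanel(
        baseline=pd.concat([t_obs.baseline, o_obs.baseline], ignore_index=True),
        visits=pd.concat([t_obs.visits, o_obs.visits], ignore_index=True),
        truth=pd.concat([t_obs.truth, o_obs.truth], ignore_index=True),
    )
    labels = pd.concat([t_labels, o_labels], ignore_index=True)
    truth_or = true_marginal_log_or(panel.truth)
    cond = {vm: float(t_cfg.strategy_log_or[vm]) for vm in VISIT_MONTHS}
    return StudyData(
        panel=panel,
        labels=labels,
        true_marginal_log_or=truth_or,
        true_conditional_log_or=cond,
    )
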