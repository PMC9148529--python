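"""End-to-end dispatch of the five missing-data approaches.

Each approach handles the three missingness types differently and ends in the
same per-visit weighted logistic outcome model:

================== ===================== ==================== ==========
approach           missing at visit      intermittent visits  drop-out
================== ===================== ==================== ==========
complete_case      exclusion             exclusion            exclusion
strict_censor_ipcw censor (as drop-out)  censor (as drop-out) IPCW
mi_censor_ipcw     MI                    censor (as drop-out) IPCW
mi_ipcw            MI                    MI                   IPCW
mi_all             MI                    MI                   MI
================== ===================== ==================== ==========

IPTW for baseline balancing is estimated once on the complete baseline table
and enters every outcome model multiplicatively with the approach's IPCW.  In
MI-containing approaches the censoring/weight models are re-fitted within each
imputed dataset and Rubin's rules pool the final log odds ratios; arm
proportions are pooled on the logit scale.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .censoring import (
    CensoredPanel,
    artificial_censor,
    fit_censoring_models,
    ipcw_weights,
)
from .effects import (
    EffectEstimate,
    fit_outcome_model,
    or_ci,
    pool_proportions,
    remission_proportions,
)
from .imputation import MicePlan, mice_impute, rubins_pool
from .outcomes import (
    LABEL_OBSERVED,
    VISIT_MONTHS,
    classify_missingness,
    panel_das28,
    remission,
)
from .synthetic import CohortPanel

APPROACHES = (
    "complete_case",
    "strict_censor_ipcw",
    "mi_censor_ipcw",
    "mi_ipcw",
    "mi_all",
)


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the comparative analysis (MI, IPCW and variance options)."""

    m: int = 10
    n_iter: int = 10
    pmm_k: int = 5
    delta: float = 0.0
    seed: int = 0
    ipcw_covariates: tuple = ("baseline_das28", "age")
    ipcw_timevarying: bool = True
    ipcw_stabilized: bool = True
    ipcw_truncation: tuple | None = None
    ipcw_per_cohort: bool = True
    min_at_risk: int = 15
    robust: bool = True


@dataclass
class ApproachResult:
    approach: str
    effects: dict  # visit -> EffectEstimate
    proportions: dict  # visit -> {"trial": p, "observational": p}
    diagnostics: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """Failure inside one approach, annotated with approach and stage."""


@contextmanager
def _stage(approach: str, stage: str):
    try:
        yield
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"{approach}/{stage}: {exc}") from exc


def _mice_seed(config: AnalysisConfig) -> int:
    # one shared imputation stream for all MI approaches, so identical cells
    # receive identical draws and approaches that coincide structurally
    # coincide numerically
    return int(np.random.SeedSequence((config.seed, 101)).generate_state(1)[0] % (2**31 - 1))


def _visit_table(visits: pd.DataFrame, vm: int) -> pd.DataFrame:
    sub = visits[visits["visit_month"] == vm].copy()
    sub["das28"] = panel_das28(sub)
    sub = sub[sub["das28"].notna()]
    sub["remission"] = remission(sub["das28"].to_numpy()).astype(float)
    return sub[["subject_id", "cohort", "remission"]]


def _fit_visit(
    visits: pd.DataFrame,
    vm: int,
    iptw: pd.Series,
    ipcw: pd.DataFrame | None,
    config: AnalysisConfig,
) -> tuple[float, float, dict, int]:
    table = _visit_table(visits, vm)
    if table.empty:
        raise ValueError(f"empty analysis set at visit {vm}")
    w = iptw.loc[table["subject_id"]].to_numpy(dtype=float)
    if ipcw is not None:
        wv = ipcw[ipcw["visit_month"] == vm].set_index("subject_id")["ipcw"]
        w = w * wv.loc[table["subject_id"]].to_numpy(dtype=float)
    beta, se = fit_outcome_model(table, weights=w, robust=config.robust)
    props = remission_proportions(table, weights=w)
    return beta, se, props, len(table)


def _ipcw_all_cohorts(
    censored: CensoredPanel, baseline: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Fit censoring models and weights, separately per cohort by default."""
    if not config.ipcw_per_cohort:
        models = fit_censoring_models(
            censored,
            baseline,
            covariates=list(config.ipcw_covariates),
            timevarying=config.ipcw_timevarying,
            min_at_risk=config.min_at_risk,
        )
        return ipcw_weights(
            models,
            censored,
            stabilized=config.ipcw_stabilized,
            truncation=config.ipcw_truncation,
        )
    parts = []
    for name, base in baseline.groupby("cohort"):
        ids = set(base["subject_id"])
        sub = CensoredPanel(
            visits=censored.visits[censored.visits["subject_id"].isin(ids)],
            censor_visit=censored.censor_visit[censored.censor_visit.index.isin(ids)],
        )
        models = fit_censoring_models(
            sub,
            base,
            covariates=list(config.ipcw_covariates),
            timevarying=config.ipcw_timevarying,
            min_at_risk=config.min_at_risk,
        )
        parts.append(
            ipcw_weights(
                models,
                sub,
                stabilized=config.ipcw_stabilized,
                truncation=config.ipcw_truncation,
            )
        )
    return pd.concat(parts, ignore_index=True)


def _pooled_result(
    approach: str,
    per_visit_betas: dict,
    per_visit_vars: dict,
    per_visit_props: dict,
    diagnostics: dict,
) -> ApproachResult:
    effects, props = {}, {}
    for vm in VISIT_MONTHS:
        pooled = rubins_pool(per_visit_betas[vm], per_visit_vars[vm])
        effects[vm] = or_ci(pooled.qbar, pooled.se, df=pooled.df)
        props[vm] = pool_proportions(per_visit_props[vm])
    return ApproachResult(approach, effects, props, diagnostics)


def run_approach(
    approach: str,
    panel: CohortPanel,
    labels: pd.DataFrame,
    iptw: pd.Series,
    config: AnalysisConfig = AnalysisConfig(),
) -> ApproachResult:
    """Run one approach on a labeled two-cohort panel; see the module table."""
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    baseline = panel.baseline

    if approach == "complete_case":
        with _stage(approach, "exclusion"):
            complete = (
                labels.assign(obs=labels["label"] == LABEL_OBSERVED)
                .groupby("subject_id")["obs"]
                .all()
            )
            keep = complete.index[complete]
            visits = panel.visits[panel.visits["subject_id"].isin(keep)]
            if visits.empty:
                raise ValueError("no subjects with complete follow-up")
        effects, props, ns = {}, {}, {}
        with _stage(approach, "outcome_model"):
            for vm in VISIT_MONTHS:
                beta, se, p, n = _fit_visit(visits, vm, iptw, None, config)
                effects[vm] = or_ci(beta, se)
                props[vm] = p
                ns[vm] = n
        return ApproachResult(approach, effects, props, {"n_per_visit": ns})

    if approach == "strict_censor_ipcw":
        with _stage(approach, "artificial_censoring"):
            cens = artificial_censor(panel.visits, labels, rule="strict")
        with _stage(approach, "ipcw"):
            w = _ipcw_all_cohorts(cens, baseline, config)
        effects, props, ns = {}, {}, {}
        with _stage(approach, "outcome_model"):
            for vm in VISIT_MONTHS:
                beta, se, p, n = _fit_visit(cens.visits, vm, iptw, w, config)
                effects[vm] = or_ci(beta, se)
                props[vm] = p
                ns[vm] = n
        return ApproachResult(
            approach,
            effects,
            props,
            {"n_per_visit": ns, "ipcw_quantiles": _weight_quantiles(w)},
        )

    # MI-containing approaches
    scope = {
        "mi_censor_ipcw": "missing_at_visit",
        "mi_ipcw": "missing_at_visit+intermittent",
        "mi_all": "all",
    }[approach]
    plan = MicePlan(
        scope=scope,
        m=config.m,
        n_iter=config.n_iter,
        pmm_k=config.pmm_k,
        seed=_mice_seed(config),
        delta=config.delta,
    )
    with _stage(approach, "mice"):
        imputed = mice_impute(panel, labels, plan)

    betas = {vm: [] for vm in VISIT_MONTHS}
    variances = {vm: [] for vm in VISIT_MONTHS}
    props = {vm: [] for vm in VISIT_MONTHS}
    for imp in imputed.panels:
        if approach == "mi_all":
            visits = imp.visits
            w = None
        else:
            with _stage(approach, "post_mi_censoring"):
                # mi_censor_ipcw: remaining intermittent gaps become drop-outs;
                # mi_ipcw: intermittent gaps were imputed, so this is a no-op
                # monotonicity check and only natural drop-out remains
                imp_labels = classify_missingness(imp.visits)
                cens = artificial_censor(imp.visits, imp_labels, rule="intermittent_only")
            with _stage(approach, "ipcw"):
                w = _ipcw_all_cohorts(cens, baseline, config)
            visits = cens.visits
        with _stage(approach, "outcome_model"):
            for vm in VISIT_MONTHS:
                beta, se, p, _ = _fit_visit(visits, vm, iptw, w, config)
                betas[vm].append(beta)
                variances[vm].append(se**2)
                props[vm].append(p)
    with _stage(approach, "pooling"):
        return _pooled_result(
            approach, betas, variances, props, {"m": config.m, "scope": scope}
        )


def _weight_quantiles(w: pd.DataFrame) -> dict:
    qs = np.quantile(w["ipcw"], [0.0, 0.25, 0.5, 0.75, 1.0])
    return dict(zip(["min", "q25", "median", "q75", "max"], map(float, qs)))


def compare_approaches(
    panel: CohortPanel,
    labels: pd.DataFrame,
    iptw: pd.Series,
    config: AnalysisConfig = AnalysisConfig(),
    approaches=APPROACHES,
) -> dict[str, ApproachResult]:
    """Run the requested approaches and return their results keyed by name."""
    return {a: run_approach(a, panel, labels, iptw, config) for a in approaches}


def results_table(results: dict[str, ApproachResult]) -> pd.DataFrame:
    """Tidy per-approach, per-visit effect table (log OR, SE, OR, CI, p)."""
    rows = []
    for name, res in results.items():
        for vm, eff in res.effects.items():
            rows.append(
                {
                    "approach": name,
                    "visit_month": vm,
                    "estimate": eff.beta,
                    "se": eff.se,
                    "odds_ratio": eff.or_,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "p_value": eff.p,
                }
            )
    return pd.DataFrame(rows)


def proportions_table(results: dict[str, ApproachResult]) -> pd.DataFrame:
    """Tidy per-approach, per-arm, per-visit estimated remission proportions."""
    rows = []
    for name, res in results.items():
        for vm, d in res.proportions.items():
            for arm, p in d.items():
                rows.append(
                    {"approach": name, "arm": arm, "visit_month": vm, "proportion": p}
                )
    return pd.DataFrame(rows)
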