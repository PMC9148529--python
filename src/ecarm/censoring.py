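"""Artificial censoring and inverse probability of censoring weighting.

Non-monotone missingness (intermittent gaps, partially missing visits) is
monotonized by setting subjects as drop-outs at their first qualifying missing
visit; the resulting drop-out process (created or naturally occurring) is then
modeled with sequential per-visit logistic hazards, and uncensored subjects
receive cumulative inverse-probability weights

    W_i(k) = prod_{j <= k} 1 / (1 - h_i(j)),

optionally stabilized by the marginal survival prod (1 - hbar(j)).  Hazard
models condition on baseline covariates and the last fully observed DAS28, so
no information after the at-risk time enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .balance import SeparationError, _check_separation
from .outcomes import (
    COMPONENTS,
    LABEL_INTERMITTENT,
    LABEL_MISSING_AT_VISIT,
    VISIT_MONTHS,
    panel_das28,
)

CENSOR_RULES = ("strict", "intermittent_only")


@dataclass
class CensoredPanel:
    """Monotonized visit table plus the per-subject monotonizing visit.

    ``censor_visit`` records the first visit at which the artificial rule
    fired (NaN when it never did); natural drop-out tails are left in place
    and are picked up by the hazard models together with the created ones.
    """

    visits: pd.DataFrame
    censor_visit: pd.Series


@dataclass
class CensoringModelSet:
    """Per-visit fitted censoring hazards on a monotone panel."""

    hazards: dict = field(default_factory=dict)  # visit -> Series (at-risk subjects)
    marginal: dict = field(default_factory=dict)  # visit -> float
    params: dict = field(default_factory=dict)


def _fully_observed(visits: pd.DataFrame) -> pd.DataFrame:
    """Wide boolean frame: subject x visit, True when all components present."""
    ok = visits[list(COMPONENTS)].notna().all(axis=1)
    return (
        visits.assign(_ok=ok)
        .pivot(index="subject_id", columns="visit_month", values="_ok")
        .astype(bool)
    )


def assert_monotone(visits: pd.DataFrame) -> None:
    """Fail loudly unless missingness is monotone (observed prefix, blank tail)."""
    wide = _fully_observed(visits)
    arr = wide[list(VISIT_MONTHS)].to_numpy()
    resumed = (~arr[:, :-1]) & arr[:, 1:]
    if resumed.any():
        bad = wide.index[resumed.any(axis=1)][:5].tolist()
        raise ValueError(f"missingness is not monotone (e.g. subjects {bad})")


def artificial_censor(
    visits: pd.DataFrame, labels: pd.DataFrame, rule: str = "strict"
) -> CensoredPanel:
    """Monotonize a panel by censoring at the first qualifying missing visit.

    ``strict`` censors at the first visit labeled missing-at-visit *or*
    intermittent, whichever occurs first; ``intermittent_only`` censors at the
    first intermittent visit (used after MI has filled partially missing
    visits).  All data at and after the censoring visit are blanked; the
    output is checked to be monotone.
    """
    if rule not in CENSOR_RULES:
        raise ValueError(f"unknown censoring rule {rule!r}")
    trigger = [LABEL_INTERMITTENT]
    if rule == "strict":
        trigger.append(LABEL_MISSING_AT_VISIT)
    lab = labels[labels["label"].isin(trigger)]
    censor_visit = lab.groupby("subject_id")["visit_month"].min()

    out = visits.copy()
    cv = censor_visit.reindex(out["subject_id"]).to_numpy()
    blank = out["visit_month"].to_numpy() >= np.where(np.isnan(cv), np.inf, cv)
    out.loc[blank, list(COMPONENTS)] = np.nan
    all_subjects = visits["subject_id"].unique()
    censor_visit = censor_visit.reindex(all_subjects)
    assert_monotone(out)
    return CensoredPanel(visits=out, censor_visit=censor_visit)


def _prior_das28(visits: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """Wide frame of the last fully observed DAS28 strictly before each visit."""
    scores = (
        visits.assign(_das=panel_das28(visits))
        .pivot(index="subject_id", columns="visit_month", values="_das")
    )
    base = baseline.set_index("subject_id")["baseline_das28"]
    prior = pd.DataFrame(index=scores.index)
    last = base.reindex(scores.index)
    for vm in VISIT_MONTHS:
        prior[vm] = last
        last = scores[vm].where(scores[vm].notna(), last)
    return prior


def fit_censoring_models(
    censored: CensoredPanel,
    baseline: pd.DataFrame,
    covariates: list[str] = ("baseline_das28", "age"),
    timevarying: bool = True,
    min_at_risk: int = 15,
) -> CensoringModelSet:
    """Sequential logistic hazards of being censored at each visit.

    The model at visit k is fitted on subjects at risk at k (fully observed at
    all earlier visits) with event = no usable outcome at k, predictors =
    ``covariates`` from the baseline table plus, when ``timevarying``, the
    last fully observed DAS28 before k.  Visits with no events get hazard 0
    and no model.  Raises when the at-risk set is smaller than
    ``min_at_risk`` or on perfect separation (naming visit and covariate).
    """
    assert_monotone(censored.visits)
    wide_ok = _fully_observed(censored.visits)
    prior = _prior_das28(censored.visits, baseline) if timevarying else None
    base = baseline.set_index("subject_id").loc[wide_ok.index]

    models = CensoringModelSet()
    at_risk = pd.Series(True, index=wide_ok.index)
    for vm in VISIT_MONTHS:
        risk_idx = wide_ok.index[at_risk]
        if len(risk_idx) == 0:
            models.hazards[vm] = pd.Series(dtype=float)
            models.marginal[vm] = 0.0
            continue
        event = ~wide_ok.loc[risk_idx, vm]
        models.marginal[vm] = float(event.mean())
        if event.sum() == 0:
            models.hazards[vm] = pd.Series(0.0, index=risk_idx)
        else:
            if len(risk_idx) < min_at_risk:
                raise ValueError(
                    f"at-risk set at visit {vm} has {len(risk_idx)} subjects "
                    f"(< {min_at_risk})"
                )
            X = base.loc[risk_idx, list(covariates)].astype(float)
            if timevarying:
                X = X.assign(prior_das28=prior.loc[risk_idx, vm])
            y = event.to_numpy(dtype=float)
            try:
                _check_separation(X, y)
            except SeparationError as exc:
                raise SeparationError(f"visit {vm}: {exc}") from exc
            try:
                res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                    disp=0, maxiter=200
                )
                h = np.asarray(res.predict())
                models.params[vm] = res.params
            except SeparationError:
                raise
            except Exception:
                # rare non-convergence with very few events: fall back to the
                # marginal hazard rather than abort the whole analysis
                h = np.full(len(risk_idx), float(event.mean()))
            models.hazards[vm] = pd.Series(h, index=risk_idx)
        at_risk &= wide_ok[vm]
    return models


def ipcw_weights(
    models: CensoringModelSet,
    censored: CensoredPanel,
    stabilized: bool = True,
    truncation: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Cumulative IPCW per subject-visit for uncensored subjects.

    Returns a long table (subject_id, visit_month, ipcw) covering each subject
    at the visits where they are still observed.  Stabilization multiplies by
    the cumulative marginal survival; ``truncation`` clips weights at the
    given percentiles within each visit.
    """
    wide_ok = _fully_observed(censored.visits)
    rows = []
    cum = pd.Series(1.0, index=wide_ok.index)
    cum_marg = 1.0
    for vm in VISIT_MONTHS:
        h = models.hazards.get(vm)
        if h is None:
            h = pd.Series(dtype=float)
        avail = wide_ok.index[wide_ok[vm]]
        h_avail = h.reindex(avail).fillna(0.0)
        if np.any(h_avail >= 1.0):
            raise ValueError(f"fitted hazard 1 for an uncensored subject at visit {vm}")
        cum.loc[avail] = cum.loc[avail] / (1.0 - h_avail)
        cum_marg *= 1.0 - models.marginal.get(vm, 0.0)
        w = cum.loc[avail] * (cum_marg if stabilized else 1.0)
        if truncation is not None and len(w):
            lo, hi = np.quantile(w, truncation)
            w = w.clip(lo, hi)
        rows.append(
            pd.DataFrame(
                {"subject_id": avail, "visit_month": vm, "ipcw": w.to_numpy()}
            )
        )
    return pd.concat(rows, ignore_index=True)
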