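"""Baseline balancing: propensity scores, IPTW and balance diagnostics.

Baseline randomization between the trial strategy and the observational
(external-control) strategy is emulated by inverse probability of treatment
weighting.  The propensity e(X) = P(trial | X) is a maximum-likelihood
logistic fit of the cohort indicator on the baseline covariates; the default
estimand is the ATE with stabilized weights, with propensities clipped at
configurable percentiles before inversion.  Balance is diagnosed with
standardized mean differences before and after weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import BASELINE_COVARIATES


class SeparationError(RuntimeError):
    """Perfect separation in a logistic model, naming the offending covariate."""


@dataclass
class PropensityFit:
    coefficients: pd.Series
    propensity: pd.Series  # e(X), indexed by subject_id
    converged: bool
    covariates: list


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for c in X.columns:
        x = X[c].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        if x[y == 1].min() > x[y == 0].max() or x[y == 0].min() > x[y == 1].max():
            raise SeparationError(f"covariate {c!r} perfectly separates the cohorts")


def estimate_propensity(
    baseline: pd.DataFrame, covariates=BASELINE_COVARIATES
) -> PropensityFit:
    """Logistic propensity model of trial membership on baseline covariates.

    Requires complete baseline covariates (the synthetic path guarantees this;
    real data would need a prior imputation step).  Raises
    :class:`SeparationError` when a covariate perfectly separates the cohorts
    and ``ValueError`` on missing covariate values.
    """
    covariates = list(covariates)
    X = baseline[covariates].astype(float)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing baseline covariate values in {bad}")
    y = (baseline["cohort"] == "trial").to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("baseline table must contain both cohorts")
    _check_separation(X, y)
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises on hard separation
        raise SeparationError(str(exc)) from exc
    e = np.asarray(res.predict())
    if np.any(e <= 0) or np.any(e >= 1):
        raise SeparationError("fitted propensities at the 0/1 boundary")
    return PropensityFit(
        coefficients=res.params,
        propensity=pd.Series(e, index=baseline["subject_id"].to_numpy()),
        converged=bool(res.mle_retvals.get("converged", True)),
        covariates=covariates,
    )


def iptw_weights(
    fit: PropensityFit,
    assignment: pd.Series,
    estimand: str = "ATE",
    stabilized: bool = True,
    truncation: tuple[float, float] | None = (0.01, 0.99),
) -> pd.Series:
    """Per-subject IPTW from a propensity fit.

    ``assignment`` is a subject-indexed series of cohort labels.  ATE weights
    are 1/e(X) for trial subjects and 1/(1-e(X)) for controls; ATT weights are
    1 for trial subjects and e/(1-e) for controls.  Stabilization multiplies
    by the marginal assignment probability; ``truncation`` clips the
    propensity at the given percentiles before inversion.
    """
    e = fit.propensity.loc[assignment.index].to_numpy(dtype=float)
    z = (assignment == "trial").to_numpy(dtype=float)
    if truncation is not None:
        lo, hi = np.quantile(e, truncation)
        e = np.clip(e, lo, hi)
    if np.any(e <= 0) or np.any(e >= 1):
        raise ValueError("propensity at 0/1 after truncation")
    if estimand == "ATE":
        w = np.where(z == 1, 1.0 / e, 1.0 / (1.0 - e))
        if stabilized:
            w *= np.where(z == 1, z.mean(), 1.0 - z.mean())
    elif estimand == "ATT":
        w = np.where(z == 1, 1.0, e / (1.0 - e))
    else:
        raise ValueError(f"unknown estimand {estimand!r}")
    return pd.Series(w, index=assignment.index, name="iptw")


def standardized_mean_difference(x, group, weights=None) -> float:
    """SMD: (m1 - m2) / sqrt((s1^2 + s2^2) / 2), optionally weighted.

    Group means and variances use the supplied weights; the first group in
    sorted order of the labels is subtracted from the second ("trial" minus
    "observational" for the default labels).
    """
    x = np.asarray(x, dtype=float)
    group = np.asarray(group)
    weights = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    gs = sorted(set(group.tolist()), reverse=True)  # "trial" before "observational"
    if len(gs) != 2:
        raise ValueError("exactly two groups required")
    stats = []
    for g in gs:
        m = group == g
        if not m.any():
            raise ValueError(f"empty group {g!r}")
        w = weights[m]
        mu = np.average(x[m], weights=w)
        var = np.average((x[m] - mu) ** 2, weights=w)
        stats.append((mu, var))
    (m1, v1), (m2, v2) = stats
    pooled = (v1 + v2) / 2.0
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((m1 - m2) / np.sqrt(pooled))


def balance_table(
    baseline: pd.DataFrame,
    weights: pd.Series | None = None,
    covariates=BASELINE_COVARIATES,
) -> pd.DataFrame:
    """Balance report: unweighted and weighted SMD per covariate."""
    rows = []
    group = baseline["cohort"].to_numpy()
    w = None
    if weights is not None:
        w = weights.loc[baseline["subject_id"].to_numpy()].to_numpy(dtype=float)
    for c in covariates:
        x = baseline[c].to_numpy(dtype=float)
        rows.append(
            {
                "covariate": c,
                "smd_unweighted": standardized_mean_difference(x, group),
                "smd_weighted": (
                    standardized_mean_difference(x, group, w)
                    if w is not None
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
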