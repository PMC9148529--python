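"""Weighted outcome models, odds-ratio transformation and arm proportions.

The per-visit comparison is a weighted logistic regression of the binary
remission indicator on the strategy indicator (trial vs observational).  Since
the weights (IPTW, IPCW) are estimated, the default variance is the
probability-weight sandwich A^-1 B A^-1 with B built from the weighted score
contributions; with constant weights this coincides exactly with the classical
2x2 (Woolf) variance on the saturated model.  Wald intervals and p-values are
formed on the log-OR scale and exponentiated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit


@dataclass
class EffectEstimate:
    """Log OR of remission (trial vs observational), SE, OR, Wald CI, p-value."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    df: float = np.inf


def fit_outcome_model(
    table: pd.DataFrame, weights=None, robust: bool = True
) -> tuple[float, float]:
    """Weighted logistic fit of remission on the trial indicator.

    ``table`` needs columns ``remission`` (0/1, no missing) and ``cohort``.
    Returns (log OR, SE).  ``robust=False`` selects the model-based
    (inverse-information) variance, which equals the classical 2x2 standard
    error; the robust sandwich is the default because the weights are
    estimated.  Raises when the outcome is constant within an arm (the log OR
    would be infinite).
    """
    y = table["remission"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing remission values in the analysis table")
    z = (table["cohort"] == "trial").to_numpy(dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    for arm in (0.0, 1.0):
        ya = y[z == arm]
        if len(ya) == 0:
            raise ValueError("empty arm in the analysis table")
        if ya.min() == ya.max():
            raise ValueError(
                f"remission constant in arm {'trial' if arm else 'observational'}"
            )
    X = np.column_stack([np.ones_like(z), z])
    res = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
    beta = float(res.params[1])
    p = np.asarray(res.predict())
    a_mat = (X * (w * p * (1 - p))[:, None]).T @ X
    a_inv = np.linalg.inv(a_mat)
    if robust:
        score = X * (w * (y - p))[:, None]
        b_mat = score.T @ score
        cov = a_inv @ b_mat @ a_inv
    else:
        cov = a_inv
    return beta, float(np.sqrt(cov[1, 1]))


def or_ci(beta: float, se: float, level: float = 0.95, df: float = np.inf) -> EffectEstimate:
    """Wald OR and CI from a log-OR estimate and its standard error.

    The interval is formed on the log scale with the normal quantile (or t
    with the pooled degrees of freedom after multiple imputation) and
    exponentiated; the two-sided p-value uses the same reference.
    """
    if not np.isfinite(beta):
        raise ValueError("non-finite estimate")
    if se <= 0 or not np.isfinite(se):
        raise ValueError("standard error must be positive and finite")
    alpha = 1.0 - level
    if np.isfinite(df):
        q = stats.t.ppf(1 - alpha / 2, df)
        p = 2 * stats.t.sf(abs(beta) / se, df)
    else:
        q = stats.norm.ppf(1 - alpha / 2)
        p = 2 * stats.norm.sf(abs(beta) / se)
    return EffectEstimate(
        beta=float(beta),
        se=float(se),
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - q * se)),
        ci_high=float(np.exp(beta + q * se)),
        p=float(p),
        df=float(df),
    )


def remission_proportions(table: pd.DataFrame, weights=None) -> dict[str, float]:
    """Weighted remission proportion per arm."""
    y = table["remission"].to_numpy(dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    out = {}
    for arm in ("trial", "observational"):
        m = (table["cohort"] == arm).to_numpy()
        if not m.any():
            raise ValueError(f"empty arm {arm!r}")
        out[arm] = float(np.average(y[m], weights=w[m]))
    return out


def pool_proportions(per_imputation: list[dict[str, float]]) -> dict[str, float]:
    """Pool per-imputation arm proportions on the logit scale."""
    out = {}
    for arm in per_imputation[0]:
        p = np.clip([d[arm] for d in per_imputation], 1e-12, 1 - 1e-12)
        out[arm] = float(expit(np.mean(logit(p))))
    return out
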