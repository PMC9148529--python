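"""DAS28 outcome computation, visit alignment and missingness classification.

The analysis endpoint is clinical remission according to the Disease Activity
Score in 28 joints (DAS28-ESR), a composite of the tender joint count (TJC28),
swollen joint count (SJC28), erythrocyte sedimentation rate (ESR, mm/h) and the
patient's global assessment of disease (PGA, 0-100 mm VAS).  Remission is a
score strictly below 2.6.

Longitudinal missingness at the scheduled 6/12/24-month visits is classified
into three mutually exclusive types:

``missing_at_visit``
    the visit is recorded but at least one DAS28 component is absent;
``intermittent``
    the whole visit is missing but a later visit is observed;
``dropout``
    the visit and every later visit are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# DAS28-ESR composite; coefficients pinned here so a CRP variant could be
# swapped in one place.
DAS28_TJC_COEF = 0.56
DAS28_SJC_COEF = 0.28
DAS28_ESR_COEF = 0.70
DAS28_PGA_COEF = 0.014
REMISSION_CUTOFF = 2.6

VISIT_MONTHS = (6, 12, 24)
COMPONENTS = ("tjc28", "sjc28", "esr", "pga")

LABEL_OBSERVED = "observed"
LABEL_MISSING_AT_VISIT = "missing_at_visit"
LABEL_INTERMITTENT = "intermittent"
LABEL_DROPOUT = "dropout"


def das28(tjc28, sjc28, esr, pga):
    """DAS28-ESR score from its four components.

    Accepts scalars or array-likes; any missing component propagates to a
    missing score.  ESR values below 1 are floored to 1 before the log so the
    score stays finite.  Out-of-range components raise ``ValueError``.
    """
    t = np.asarray(tjc28, dtype=float)
    s = np.asarray(sjc28, dtype=float)
    e = np.asarray(esr, dtype=float)
    p = np.asarray(pga, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((t < 0) | (t > 28)) or np.any((s < 0) | (s > 28)):
            raise ValueError("joint counts must be in [0, 28]")
        if np.any(e <= 0):
            raise ValueError("ESR must be > 0")
        if np.any((p < 0) | (p > 100)):
            raise ValueError("PGA must be in [0, 100]")
    e = np.maximum(e, 1.0)
    score = (
        DAS28_TJC_COEF * np.sqrt(t)
        + DAS28_SJC_COEF * np.sqrt(s)
        + DAS28_ESR_COEF * np.log(e)
        + DAS28_PGA_COEF * p
    )
    if score.ndim == 0:
        return float(score)
    return score


def remission(score):
    """Remission indicator: DAS28 strictly below 2.6; missing stays missing."""
    sc = np.asarray(score, dtype=float)
    out = np.where(np.isnan(sc), np.nan, (sc < REMISSION_CUTOFF).astype(float))
    if out.ndim == 0:
        return float(out) if np.isnan(out) else bool(out)
    return out


def panel_das28(panel: pd.DataFrame) -> pd.Series:
    """Row-wise DAS28 for a long-format panel (NaN where any component is missing)."""
    return das28(panel["tjc28"], panel["sjc28"], panel["esr"], panel["pga"])


def map_visits(
    raw_visits: pd.DataFrame,
    window_spec: dict[int, tuple[float, float]],
    targets=VISIT_MONTHS,
) -> pd.DataFrame:
    """Align raw visits (arbitrary months) to the scheduled target months.

    ``window_spec`` maps each target month to an inclusive ``(lo, hi)`` window.
    Each target receives the raw visit nearest in time inside its window; a tie
    on distance resolves to the *later* visit (observational visits tend to run
    late rather than early).  Unmatched targets become fully blank visits and
    each raw visit is used at most once.  Windows must not overlap.
    """
    spans = sorted((window_spec[t], t) for t in targets)
    for (a, _), (b, _) in zip(spans, spans[1:]):
        if a[1] >= b[0]:
            raise ValueError(f"overlapping visit windows: {a} and {b}")

    rows = []
    for sid, grp in raw_visits.groupby("subject_id", sort=True):
        used: set[int] = set()
        for t in targets:
            lo, hi = window_spec[t]
            cand = grp[(grp["visit_month"] >= lo) & (grp["visit_month"] <= hi)]
            cand = cand[~cand.index.isin(used)]
            row = {"subject_id": sid, "visit_month": t}
            if len(cand):
                dist = (cand["visit_month"] - t).abs()
                best = dist[dist == dist.min()].index
                # tie on distance -> later raw visit
                pick = cand.loc[best, "visit_month"].idxmax()
                used.add(pick)
                for c in COMPONENTS:
                    row[c] = cand.at[pick, c]
            else:
                for c in COMPONENTS:
                    row[c] = np.nan
            rows.append(row)
    out = pd.DataFrame(rows, columns=["subject_id", "visit_month", *COMPONENTS])
    return out


def classify_missingness(panel: pd.DataFrame) -> pd.DataFrame:
    """Label each subject-visit of a schedule-aligned panel.

    A visit with all four components present is ``observed``; with some but not
    all components present ``missing_at_visit``; a fully blank visit is
    ``intermittent`` if any later visit is non-blank, otherwise ``dropout``
    (which then propagates to every later visit).
    """
    df = panel.copy()
    comp = df[list(COMPONENTS)]
    n_missing = comp.isna().sum(axis=1)
    df["_state"] = np.select(
        [n_missing == 0, n_missing == len(COMPONENTS)],
        ["observed", "blank"],
        default="partial",
    )
    labels = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("visit_month")
        states = grp["_state"].to_numpy()
        nonblank_later = np.zeros(len(states), dtype=bool)
        seen = False
        for i in range(len(states) - 1, -1, -1):
            nonblank_later[i] = seen
            if states[i] != "blank":
                seen = True
        for vm, st, later in zip(grp["visit_month"], states, nonblank_later):
            if st == "observed":
                lab = LABEL_OBSERVED
            elif st == "partial":
                lab = LABEL_MISSING_AT_VISIT
            elif later:
                lab = LABEL_INTERMITTENT
            else:
                lab = LABEL_DROPOUT
            labels.append({"subject_id": sid, "visit_month": vm, "label": lab})
    return pd.DataFrame(labels, columns=["subject_id", "visit_month", "label"])


def summarize_patterns(labels: pd.DataFrame) -> dict:
    """Per-visit label proportions, complete-follow-up fraction and monotone flag.

    A cohort's pattern is monotone iff all missingness is terminal drop-out,
    i.e. no subject has an intermittent or missing-at-visit label.
    """
    out: dict = {"per_visit": {}}
    for vm, grp in labels.groupby("visit_month"):
        props = grp["label"].value_counts(normalize=True).to_dict()
        out["per_visit"][int(vm)] = {
            lab: float(props.get(lab, 0.0))
            for lab in (
                LABEL_OBSERVED,
                LABEL_MISSING_AT_VISIT,
                LABEL_INTERMITTENT,
                LABEL_DROPOUT,
            )
        }
    complete = (
        labels.assign(obs=labels["label"] == LABEL_OBSERVED)
        .groupby("subject_id")["obs"]
        .all()
    )
    out["complete_followup_fraction"] = float(complete.mean())
    out["monotone"] = bool(
        ~labels["label"].isin([LABEL_INTERMITTENT, LABEL_MISSING_AT_VISIT]).any()
    )
    return out
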