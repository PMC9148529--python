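import numpy as np
import pandas as pd
import pytest

from ecarm.outcomes import COMPONENTS, VISIT_MONTHS
from ecarm.synthetic import (
    CohortConfig,
    CohortPanel,
    MissingnessSpec,
    generate_study,
)

# component quadruples on either side of the remission cutoff
REMIT = dict(tjc28=0.0, sjc28=0.0, esr=2.0, pga=10.0)  # DAS28 ~ 0.63
ACTIVE = dict(tjc28=10.0, sjc28=8.0, esr=40.0, pga=60.0)  # DAS28 ~ 5.99


def make_manual_panel(remission_by_subject: dict[str, list[bool]]) -> CohortPanel:
    """Hand-built two-cohort panel; subject ids starting 'tri'/'obs' set the arm.

    ``remission_by_subject`` maps subject_id -> remission status at 6/12/24.
    """
    visit_rows, base_rows = [], []
    for sid, pattern in remission_by_subject.items():
        cohort = "trial" if sid.startswith("tri") else "observational"
        base_rows.append(
            {"subject_id": sid, "cohort": cohort, "baseline_das28": 4.5, "age": 55.0}
        )
        for vm, rem in zip(VISIT_MONTHS, pattern):
            comp = REMIT if rem else ACTIVE
            visit_rows.append(
                {"subject_id": sid, "cohort": cohort, "visit_month": vm, **comp}
            )
    visits = pd.DataFrame(visit_rows)
    baseline = pd.DataFrame(base_rows)
    return CohortPanel(baseline=baseline, visits=visits)


def blank_cells(panel: CohortPanel, sid: str, months, components=COMPONENTS) -> None:
    """Blank the given components at the given visits of one subject, in place."""
    m = panel.visits["subject_id"].eq(sid) & panel.visits["visit_month"].isin(months)
    panel.visits.loc[m, list(components)] = np.nan


def unit_iptw(panel: CohortPanel) -> pd.Series:
    return pd.Series(1.0, index=panel.baseline["subject_id"].to_numpy())


@pytest.fixture(scope="session")
def nomiss_study():
    """Two-cohort study with zero missingness (n = 150 + 200)."""
    none = MissingnessSpec()
    return generate_study(
        seed=11,
        n_trial=150,
        n_observational=200,
        trial_missingness=none,
        observational_missingness=none,
    )


@pytest.fixture(scope="session")
def default_study():
    """Default preset study (paper-like missingness), modest size."""
    return generate_study(seed=7, n_trial=400, n_observational=600)
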