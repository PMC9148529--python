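"""Reproducible end-to-end runs: readers/writers, configuration, reports.

A run is fully specified by a :class:`RunConfig` (serializable to YAML); the
single global seed is split into per-stage substreams so re-running any stage
in isolation reproduces it.  ``run_end_to_end`` executes
simulate -> classify -> balance -> all approaches and writes a Table-2-style
effect report, a per-arm proportion report (the response-rate figure analog),
a balance table, pattern summaries and a manifest with the seed and a config
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .approaches import (
    APPROACHES,
    AnalysisConfig,
    compare_approaches,
    proportions_table,
    results_table,
)
from .balance import balance_table, estimate_propensity, iptw_weights
from .outcomes import COMPONENTS, VISIT_MONTHS, classify_missingness, summarize_patterns
from .synthetic import BASELINE_COVARIATES, CohortPanel, generate_study

log = logging.getLogger("ecarm")

VISIT_COLUMNS = ["subject_id", "cohort", "visit_month", *COMPONENTS]
BASELINE_COLUMNS = ["subject_id", "cohort", *BASELINE_COVARIATES, "baseline_das28"]
_FLOAT_FORMAT = "%.10g"


def write_panel(panel: CohortPanel, visits_path, baseline_path) -> None:
    """Write a panel as long-format visit CSV plus baseline CSV.

    Missing values are empty fields, never sentinel numbers.
    """
    panel.visits[VISIT_COLUMNS].to_csv(
        visits_path, index=False, float_format=_FLOAT_FORMAT
    )
    panel.baseline[BASELINE_COLUMNS].to_csv(
        baseline_path, index=False, float_format=_FLOAT_FORMAT
    )


def read_panel(visits_path, baseline_path) -> CohortPanel:
    """Read a panel written by :func:`write_panel`, validating the schema."""
    visits = pd.read_csv(visits_path)
    baseline = pd.read_csv(baseline_path)
    for name, df, want in (
        ("visits", visits, VISIT_COLUMNS),
        ("baseline", baseline, BASELINE_COLUMNS),
    ):
        missing = [c for c in want if c not in df.columns]
        extra = [c for c in df.columns if c not in want]
        if missing or extra:
            raise ValueError(
                f"{name} schema mismatch: missing columns {missing}, "
                f"unknown columns {extra}"
            )
    bad = set(visits["visit_month"]) - set(VISIT_MONTHS)
    if bad:
        raise ValueError(f"visit_month outside the schedule: {sorted(bad)}")
    return CohortPanel(baseline=baseline, visits=visits)


@dataclass
class RunConfig:
    """Everything needed to reproduce one comparative analysis run."""

    seed: int = 0
    n_trial: int = 188
    n_observational: int = 328
    approaches: tuple = APPROACHES
    m: int = 10
    n_iter: int = 10
    pmm_k: int = 5
    delta: float = 0.0
    iptw_stabilized: bool = True
    iptw_truncation: tuple | None = (0.01, 0.99)
    iptw_estimand: str = "ATE"
    ipcw_covariates: tuple = ("baseline_das28", "age")
    ipcw_stabilized: bool = True
    ipcw_truncation: tuple | None = None
    output_dir: str = "ecarm_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("approaches", "iptw_truncation", "ipcw_truncation", "ipcw_covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunBundle:
    """In-memory results of an end-to-end run."""

    panel: CohortPanel
    labels: pd.DataFrame
    balance: pd.DataFrame
    effects: pd.DataFrame
    proportions: pd.DataFrame
    patterns: dict
    truth: dict
    manifest: dict = field(default_factory=dict)


def run_end_to_end(config: RunConfig, output_dir=None) -> RunBundle:
    """Simulate, classify, balance and run all configured approaches.

    When ``output_dir`` (or ``config.output_dir``) exists or can be created,
    the report bundle is persisted there as CSV/JSON; the function always
    returns the in-memory bundle.
    """
    log.info("simulate: n_trial=%d n_observational=%d seed=%d",
             config.n_trial, config.n_observational, config.seed)
    study = generate_study(
        seed=config.seed,
        n_trial=config.n_trial,
        n_observational=config.n_observational,
    )
    panel, labels = study.panel, study.labels

    log.info("classify: %d subject-visits", len(labels))
    patterns = {
        cohort: summarize_patterns(
            labels[labels["subject_id"].isin(
                panel.baseline.loc[panel.baseline["cohort"] == cohort, "subject_id"]
            )]
        )
        for cohort in ("trial", "observational")
    }

    log.info("balance: IPTW (%s, stabilized=%s)", config.iptw_estimand,
             config.iptw_stabilized)
    fit = estimate_propensity(panel.baseline)
    assignment = panel.baseline.set_index("subject_id")["cohort"]
    iptw = iptw_weights(
        fit,
        assignment,
        estimand=config.iptw_estimand,
        stabilized=config.iptw_stabilized,
        truncation=config.iptw_truncation,
    )
    bal = balance_table(panel.baseline, weights=iptw)

    analysis = AnalysisConfig(
        m=config.m,
        n_iter=config.n_iter,
        pmm_k=config.pmm_k,
        delta=config.delta,
        seed=config.seed,
        ipcw_covariates=tuple(config.ipcw_covariates),
        ipcw_stabilized=config.ipcw_stabilized,
        ipcw_truncation=config.ipcw_truncation,
    )
    results = compare_approaches(
        panel, labels, iptw, analysis, approaches=config.approaches
    )
    effects = results_table(results)
    proportions = proportions_table(results)

    manifest = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_trial": config.n_trial,
        "n_observational": config.n_observational,
        "approaches": list(config.approaches),
        "m": config.m,
        "true_marginal_log_or": {str(k): v for k, v in study.true_marginal_log_or.items()},
    }
    bundle = RunBundle(
        panel=panel,
        labels=labels,
        balance=bal,
        effects=effects,
        proportions=proportions,
        patterns=patterns,
        truth=study.true_marginal_log_or,
        manifest=manifest,
    )

    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel(panel, out / "visits.csv", out / "baseline.csv")
    labels.to_csv(out / "labels.csv", index=False)
    bal.to_csv(out / "balance.csv", index=False, float_format=_FLOAT_FORMAT)
    effects.to_csv(out / "effects.csv", index=False, float_format=_FLOAT_FORMAT)
    proportions.to_csv(out / "proportions.csv", index=False, float_format=_FLOAT_FORMAT)
    (out / "patterns.json").write_text(json.dumps(patterns, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("report written to %s", out)
    return bundle


def render_effects(effects: pd.DataFrame) -> str:
    """Plain-text effect table rounded for display (3 dp estimates, 2 dp ORs)."""
    df = effects.copy()
    for c in ("estimate", "se"):
        df[c] = df[c].map(lambda v: f"{v:.3f}")
    for c in ("odds_ratio", "ci_low", "ci_high"):
        df[c] = df[c].map(lambda v: f"{v:.2f}")
    df["p_value"] = df["p_value"].map(
        lambda v: "< 0.001" if v < 0.001 else f"{v:.3f}"
    )
    df["95% CI"] = df["ci_low"] + "-" + df["ci_high"]
    df = df.drop(columns=["ci_low", "ci_high"])
    return df.to_string(index=False)
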