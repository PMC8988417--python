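"""File formats and the synthetic example-cohort generator.

Cohorts travel as plain CSV (comma separator, "." decimal, header row,
UTF-8, no index column) with at least ``subject_id``, a follow-up time
column and a {0,1} event column.  Model specifications and configs travel
as YAML.  The fixture generator produces a synthetic cohort emulating the
shape of a realistic validation dataset for a chronic-disease risk model:
four correlated continuous predictors, a low event fraction over a ~6-year
horizon, staggered-entry censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .simgen import inverse_exponential_time
from .survmodels import ModelSpec

__all__ = [
    "read_cohort",
    "write_cohort",
    "save_model",
    "load_model",
    "FixtureConfig",
    "generate_example_cohort",
]


class CohortSchemaError(ValueError):
    """A cohort table violates the expected schema."""


def validate_cohort(
    df: pd.DataFrame,
    duration_col: str = "observed_time",
    event_col: str = "event",
    id_col: str = "subject_id",
) -> pd.DataFrame:
    """Validate required columns, positivity of times, {0,1} events, no NA."""
    for col in (id_col, duration_col, event_col):
        if col not in df.columns:
            raise CohortSchemaError(f"missing required column {col!r}")
    na = df.isna()
    if na.to_numpy().any():
        col = na.any()[na.any()].index[0]
        row = int(na[col].idxmax())
        raise CohortSchemaError(f"missing value in column {col!r} (row {row})")
    times = pd.to_numeric(df[duration_col], errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax())
        raise CohortSchemaError(f"non-numeric {duration_col!r} (row {row})")
    bad = times <= 0
    if bad.any():
        row = int(bad.idxmax())
        raise CohortSchemaError(f"non-positive {duration_col!r} (row {row})")
    events = pd.to_numeric(df[event_col], errors="coerce")
    bad = ~events.isin([0, 1])
    if bad.any():
        row = int(bad.idxmax())
        raise CohortSchemaError(
            f"event column {event_col!r} must be 0/1 (row {row}, "
            f"value {df[event_col].iloc[row]!r})"
        )
    return df


def read_cohort(
    path,
    duration_col: str = "observed_time",
    event_col: str = "event",
    id_col: str = "subject_id",
) -> pd.DataFrame:
    """Read and validate a cohort CSV; extra columns are kept."""
    df = pd.read_csv(path)
    return validate_cohort(df, duration_col, event_col, id_col)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV at full float precision (round-trip safe)."""
    cohort.to_csv(path, index=False, float_format="%.17g")


def save_model(model: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def load_model(path) -> ModelSpec:
    with open(path) as fh:
        return ModelSpec.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# synthetic example cohort

DEFAULT_PREDICTORS = {
    # name: (mean, sd) — plausible values for an adult screening population
    "age": (44.0, 9.0),
    "bmi": (22.0, 3.2),
    "triglyceride": (0.9, 0.6),
    "fasting_glucose": (5.2, 0.4),
}

DEFAULT_LOG_HRS = {
    "age": 0.03,
    "bmi": 0.12,
    "triglyceride": 0.30,
    "fasting_glucose": 1.20,
}


@dataclass
class FixtureConfig:
    """Synthetic validation-cohort generator settings.

    Emulates a medical-examination cohort used to validate a diabetes-risk
    model: n subjects, four positively correlated continuous predictors,
    exponential proportional-hazards event times whose baseline hazard is
    solved so the expected number of observed events matches
    ``target_events``, staggered-entry (uniform) censoring capped
    administratively at ``admin_years``.
    """

    n_subjects: int = 15464
    target_events: int = 192
    admin_years: float = 6.0
    min_followup_years: float = 0.45
    correlation: float = 0.2
    predictor_means_sds: dict = field(
        default_factory=lambda: dict(DEFAULT_PREDICTORS)
    )
    log_hazard_ratios: dict = field(default_factory=lambda: dict(DEFAULT_LOG_HRS))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 < self.target_events <= self.n_subjects):
            raise ValueError("target_events must be in (0, n_subjects]")
        if set(self.predictor_means_sds) != set(self.log_hazard_ratios):
            raise ValueError("predictor names and hazard ratios must match")


def generate_example_cohort(config: FixtureConfig) -> pd.DataFrame:
    """Generate the synthetic example cohort.

    The baseline hazard is found by root-finding so that the expected event
    count over the realized censoring times equals ``target_events``; the
    realized count then varies binomially around the target.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.predictor_means_sds)
    k = len(names)
    corr = np.full((k, k), config.correlation)
    np.fill_diagonal(corr, 1.0)
    z = rng.multivariate_normal(np.zeros(k), corr, size=config.n_subjects)
    cols = {}
    for j, name in enumerate(names):
        mean, sd = config.predictor_means_sds[name]
        cols[name] = mean + sd * z[:, j]

    betas = np.array([config.log_hazard_ratios[n] for n in names])
    X = np.column_stack([cols[n] for n in names])
    lp = X @ betas
    lp = lp - lp.mean()  # keep the rate solve well-conditioned
    rel_hazard = np.exp(lp)

    # staggered entry: potential follow-up uniform up to the admin horizon
    followup = rng.uniform(
        config.min_followup_years, config.admin_years, size=config.n_subjects
    )

    def expected_events(lam0: float) -> float:
        return float(np.sum(1.0 - np.exp(-lam0 * rel_hazard * followup)))

    target = float(config.target_events)
    if expected_events(1e6) < target:
        raise ValueError("target event count unreachable for this cohort")
    lam0 = brentq(lambda v: expected_events(v) - target, 1e-12, 1e6)

    u = 1.0 - rng.random(config.n_subjects)
    t = -np.log(u) / (lam0 * rel_hazard)
    observed = np.minimum(t, followup)
    event = (t <= followup).astype(int)

    out = pd.DataFrame({"subject_id": np.arange(config.n_subjects), **cols})
    out["true_event_time"] = t
    out["observed_time"] = observed
    out["event"] = event
    return out
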