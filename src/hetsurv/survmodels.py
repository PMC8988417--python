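"""Proportional-hazards prediction models and baseline recalibration.

A model is summarized by a :class:`ModelSpec`: named log-hazard-ratio
coefficients, a baseline survival function S0 (either an exponential rate
or a right-continuous step function), and per-predictor centering offsets.
Predicted survival for a subject is ``S(t | x) = S0(t) ** exp(LP)`` with
linear predictor ``LP = sum_j beta_j * (x_j - offset_j)``.

Fitting is exposed both as sklearn-style estimators
(:class:`ExponentialPHModel`, :class:`CoxPHModel`) and as thin functional
wrappers returning a :class:`ModelSpec`.  The exponential model is fitted by
maximum likelihood through the exact Poisson-regression equivalence (event
indicator regressed on the predictors with log follow-up time as offset);
the Cox model through the partial likelihood (Efron ties) with a Breslow
baseline.  :func:`recalibrate_baseline` re-estimates the baseline on a new
cohort holding each subject's linear predictor fixed as an offset, the
standard "recalibration in the large" update.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from sklearn.base import BaseEstimator

__all__ = [
    "ModelSpec",
    "StepBaseline",
    "breslow_baseline",
    "ExponentialPHModel",
    "CoxPHModel",
    "fit_exponential_ph",
    "fit_cox",
    "predict_survival",
    "recalibrate_baseline",
]


@dataclass(frozen=True)
class StepBaseline:
    """Right-continuous non-increasing baseline survival step function.

    ``surv[k]`` is the value of S0 on ``[times[k], times[k+1])``; S0 = 1
    before the first step.  ``t_max`` is the largest follow-up time in the
    estimation data: evaluation beyond it is extrapolation.
    """

    times: np.ndarray
    surv: np.ndarray
    t_max: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.surv, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "surv", s)
        if t.shape != s.shape:
            raise ValueError("times and surv must have equal length")
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValueError("step times must be strictly increasing")
        if np.any(s < 0) or np.any(s > 1) or (s.size and np.any(np.diff(s) > 1e-12)):
            raise ValueError("baseline survival must be non-increasing within [0, 1]")

    def __call__(self, t, extrapolation: str = "fail"):
        t = np.asarray(t, dtype=float)
        if extrapolation == "fail" and np.any(t > self.t_max):
            raise ValueError(
                f"evaluation time beyond baseline support (t_max={self.t_max:g}); "
                "pass extrapolation='clamp' to hold the last value"
            )
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.surv[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


def breslow_baseline(times, events, offsets) -> StepBaseline:
    """Breslow estimator of the baseline survival given fixed linear predictors.

    ``H0(t) = sum_{event times t_j <= t} d_j / sum_{i at risk at t_j} exp(lp_i)``
    and ``S0(t) = exp(-H0(t))``.  With all offsets zero this reduces to the
    Nelson-Aalen-based estimate of marginal survival.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    lp = np.asarray(offsets, dtype=float)
    order = np.argsort(t, kind="stable")
    t, e, r = t[order], e[order], np.exp(lp[order])
    # at-risk weight totals for each index onward (subjects with time >= t_i)
    at_risk = np.cumsum(r[::-1])[::-1]
    uniq, first = np.unique(t, return_index=True)
    d = np.add.reduceat(e.astype(float), first)
    risk = at_risk[first]
    keep = d > 0
    dh = d[keep] / risk[keep]
    h0 = np.cumsum(dh)
    return StepBaseline(times=uniq[keep], surv=np.exp(-h0), t_max=float(t[-1]))


@dataclass(frozen=True)
class ModelSpec:
    """A proportional-hazards prediction model in portable form."""

    predictor_names: tuple[str, ...]
    coefficients: np.ndarray
    baseline_kind: str  # "exponential_rate" or "step_function"
    baseline: float | StepBaseline
    centering_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coefs)
        object.__setattr__(self, "predictor_names", tuple(self.predictor_names))
        if len(self.predictor_names) != coefs.size:
            raise ValueError("one coefficient per predictor name is required")
        if not np.all(np.isfinite(coefs)):
            raise ValueError("coefficients must be finite")
        offs = self.centering_offsets
        offs = np.zeros_like(coefs) if offs is None else np.asarray(offs, dtype=float)
        object.__setattr__(self, "centering_offsets", offs)
        if self.baseline_kind == "exponential_rate":
            if not (float(self.baseline) > 0):
                raise ValueError("exponential baseline rate must be positive")
        elif self.baseline_kind == "step_function":
            if not isinstance(self.baseline, StepBaseline):
                raise TypeError("step_function baseline must be a StepBaseline")
        else:
            raise ValueError(f"unknown baseline_kind {self.baseline_kind!r}")

    # -- prediction ---------------------------------------------------------

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictor_names if p not in data.columns]
        if missing:
            raise KeyError(f"missing predictor column(s): {missing}")
        X = data[list(self.predictor_names)].to_numpy(dtype=float)
        return (X - self.centering_offsets) @ self.coefficients

    def baseline_survival(self, t, extrapolation: str = "fail"):
        if self.baseline_kind == "exponential_rate":
            return np.exp(-float(self.baseline) * np.asarray(t, dtype=float))
        return self.baseline(t, extrapolation=extrapolation)

    def predict_survival(
        self, data: pd.DataFrame, horizon: float, extrapolation: str = "fail"
    ) -> np.ndarray:
        """Predicted survival probability at ``horizon`` for each row."""
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        lp = self.linear_predictor(data)
        s0 = self.baseline_survival(horizon, extrapolation=extrapolation)
        return np.asarray(s0) ** np.exp(lp)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "predictor_names": list(self.predictor_names),
            "coefficients": [float(c) for c in self.coefficients],
            "centering_offsets": [float(c) for c in self.centering_offsets],
            "baseline_kind": self.baseline_kind,
        }
        if self.baseline_kind == "exponential_rate":
            d["baseline"] = {"rate": float(self.baseline)}
        else:
            b = self.baseline
            d["baseline"] = {
                "times": [float(v) for v in b.times],
                "surv": [float(v) for v in b.surv],
                "t_max": float(b.t_max),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        kind = d["baseline_kind"]
        if kind == "exponential_rate":
            baseline = float(d["baseline"]["rate"])
        else:
            b = d["baseline"]
            baseline = StepBaseline(
                times=np.asarray(b["times"], dtype=float),
                surv=np.asarray(b["surv"], dtype=float),
                t_max=float(b["t_max"]),
            )
        return cls(
            predictor_names=tuple(d["predictor_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            baseline_kind=kind,
            baseline=baseline,
            centering_offsets=np.asarray(d["centering_offsets"], dtype=float),
        )


# ---------------------------------------------------------------------------
# fitting


def _check_fit_inputs(
    cohort: pd.DataFrame, predictors, duration_col: str, event_col: str
):
    predictors = list(predictors)
    missing = [p for p in predictors if p not in cohort.columns]
    if missing:
        raise KeyError(f"predictor column(s) not in cohort: {missing}")
    for col in (duration_col, event_col):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    events = cohort[event_col].to_numpy()
    if int(events.sum()) < 2:
        raise ValueError("at least 2 events are required to fit a survival model")
    for p in predictors:
        if np.ptp(cohort[p].to_numpy(dtype=float)) == 0:
            raise ValueError(f"predictor {p!r} has no variation")
    return predictors


def fit_exponential_ph(
    cohort: pd.DataFrame,
    predictors,
    duration_col: str = "observed_time",
    event_col: str = "event",
    center: bool = False,
) -> ModelSpec:
    """Maximum-likelihood exponential proportional-hazards fit.

    Uses the Poisson-likelihood equivalence: the exponential PH
    log-likelihood equals that of a Poisson regression of the event
    indicator on the predictors with log follow-up time as offset, so the
    GLM solution is the exact survival MLE.
    """
    predictors = _check_fit_inputs(cohort, predictors, duration_col, event_col)
    offsets = (
        cohort[predictors].to_numpy(dtype=float).mean(axis=0)
        if center
        else np.zeros(len(predictors))
    )
    X = cohort[predictors].to_numpy(dtype=float) - offsets
    exog = sm.add_constant(X, has_constant="add")
    time = cohort[duration_col].to_numpy(dtype=float)
    res = sm.GLM(
        cohort[event_col].to_numpy(dtype=float),
        exog,
        family=sm.families.Poisson(),
        offset=np.log(time),
    ).fit()
    if not res.converged:
        raise RuntimeError(f"exponential PH fit did not converge: {res.summary()}")
    params = np.asarray(res.params, dtype=float)
    return ModelSpec(
        predictor_names=tuple(predictors),
        coefficients=params[1:],
        baseline_kind="exponential_rate",
        baseline=float(np.exp(params[0])),
        centering_offsets=offsets,
    )


def fit_cox(
    cohort: pd.DataFrame,
    predictors,
    duration_col: str = "observed_time",
    event_col: str = "event",
    center: bool = False,
) -> ModelSpec:
    """Cox partial-likelihood fit (Efron ties) with a Breslow step baseline."""
    predictors = _check_fit_inputs(cohort, predictors, duration_col, event_col)
    cph = CoxPHFitter()
    cph.fit(
        cohort[predictors + [duration_col, event_col]],
        duration_col=duration_col,
        event_col=event_col,
    )
    coefs = cph.params_.loc[predictors].to_numpy(dtype=float)
    offsets = (
        cohort[predictors].to_numpy(dtype=float).mean(axis=0)
        if center
        else np.zeros(len(predictors))
    )
    lp = (cohort[predictors].to_numpy(dtype=float) - offsets) @ coefs
    baseline = breslow_baseline(
        cohort[duration_col].to_numpy(dtype=float),
        cohort[event_col].to_numpy(),
        lp,
    )
    return ModelSpec(
        predictor_names=tuple(predictors),
        coefficients=coefs,
        baseline_kind="step_function",
        baseline=baseline,
        centering_offsets=offsets,
    )


def predict_survival(
    model: ModelSpec,
    covariates: pd.DataFrame,
    horizon: float,
    extrapolation: str = "fail",
) -> pd.DataFrame:
    """Per-subject predicted survival at ``horizon`` as a tidy table."""
    s = model.predict_survival(covariates, horizon, extrapolation=extrapolation)
    ids = (
        covariates["subject_id"].to_numpy()
        if "subject_id" in covariates.columns
        else np.arange(len(covariates))
    )
    return pd.DataFrame(
        {"subject_id": ids, "predicted_survival": s, "horizon": horizon}
    )


def recalibrate_baseline(
    model: ModelSpec,
    cohort: pd.DataFrame,
    duration_col: str = "observed_time",
    event_col: str = "event",
) -> ModelSpec:
    """Re-estimate the baseline survival on ``cohort``, coefficients fixed.

    Each subject's linear predictor enters the Breslow estimator as a fixed
    offset, so the updated model is calibrated-in-the-large on ``cohort``
    while its hazard ratios are untouched.
    """
    if int(cohort[event_col].sum()) < 1:
        raise ValueError("cannot recalibrate a baseline on a cohort with no events")
    lp = model.linear_predictor(cohort)
    baseline = breslow_baseline(
        cohort[duration_col].to_numpy(dtype=float),
        cohort[event_col].to_numpy(),
        lp,
    )
    return replace(model, baseline_kind="step_function", baseline=baseline)


# ---------------------------------------------------------------------------
# sklearn-style estimators


def _unpack_y(y):
    """Accept (time, event) tuples or sksurv-style structured arrays."""
    if isinstance(y, tuple) and len(y) == 2:
        time, event = np.asarray(y[0], dtype=float), np.asarray(y[1])
    elif hasattr(y, "dtype") and y.dtype.names:
        names = y.dtype.names
        event_name = next(n for n in names if y[n].dtype == bool or "event" in n)
        time_name = next(n for n in names if n != event_name)
        time, event = np.asarray(y[time_name], dtype=float), np.asarray(y[event_name])
    else:
        raise TypeError("y must be a (time, event) tuple or a structured array")
    return time, event.astype(int)


class _BasePHEstimator(BaseEstimator):
    """Shared plumbing for the proportional-hazards estimators."""

    def __init__(self, center: bool = False):
        self.center = center

    def _fit_frame(self, X, y) -> tuple[pd.DataFrame, list[str]]:
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            frame = X.copy()
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            names = [f"x{j}" for j in range(X.shape[1])]
            frame = pd.DataFrame(X, columns=names)
        time, event = _unpack_y(y)
        if len(time) != len(frame):
            raise ValueError("X and y have inconsistent lengths")
        frame["observed_time"] = time
        frame["event"] = event
        return frame, names

    def _predict_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return pd.DataFrame(X, columns=list(self.feature_names_in_))

    def predict_survival(self, X, horizon: float, extrapolation: str = "fail"):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_spec_")
        return self.model_spec_.predict_survival(
            self._predict_frame(X), horizon, extrapolation=extrapolation
        )

    def predict(self, X):
        """Linear predictor (log relative hazard) per subject."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_spec_")
        return self.model_spec_.linear_predictor(self._predict_frame(X))

    def to_spec(self) -> ModelSpec:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_spec_")
        return self.model_spec_


class ExponentialPHModel(_BasePHEstimator):
    """Exponential (constant-baseline-hazard) proportional-hazards model."""

    def fit(self, X, y):
        frame, names = self._fit_frame(X, y)
        self.model_spec_ = fit_exponential_ph(frame, names, center=self.center)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.coef_ = self.model_spec_.coefficients.copy()
        self.rate_ = float(self.model_spec_.baseline)
        return self


class CoxPHModel(_BasePHEstimator):
    """Cox proportional-hazards model with a Breslow step baseline."""

    def fit(self, X, y):
        frame, names = self._fit_frame(X, y)
        self.model_spec_ = fit_cox(frame, names, center=self.center)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.coef_ = self.model_spec_.coefficients.copy()
        self.baseline_times_ = self.model_spec_.baseline.times.copy()
        self.baseline_survival_ = self.model_spec_.baseline.surv.copy()
        return self
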