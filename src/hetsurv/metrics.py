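"""Horizon-specific predictive-performance metrics for survival models.

The battery evaluated at a prediction horizon t comprises:

- O/E ratio (calibration-in-the-large): observed over expected event
  probability at t, with the observed part from a Kaplan-Meier curve.
- AUC(t): cumulative/dynamic time-dependent AUC.  Cases are subjects with
  an event by t, controls are subjects observed beyond t; censoring is
  handled by inverse-probability-of-censoring weights (IPCW) from the
  reverse Kaplan-Meier curve G — cases weighted 1/G(time-), controls
  1/G(t).  Without censoring this is the Mann-Whitney AUC of the binary
  outcome 1{T <= t}.
- Brier(t): IPCW-weighted mean squared error between the event-free
  indicator at t and predicted survival.
- IPA(t): 1 - Brier_model / Brier_null, the Brier score benchmarked
  against a null model that predicts the Kaplan-Meier marginal risk for
  everyone.  1 = perfect, 0 = uninformative, negative = harmful.

Percentile bootstrap confidence intervals resample subjects with
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "km_survival",
    "censoring_survival",
    "oe_ratio",
    "cd_auc",
    "brier",
    "ipa",
    "bootstrap_ci",
    "MetricsResult",
    "compute_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = ("oe_ratio", "auc", "brier", "ipa")


class _StepCurve:
    """Right-continuous step function dropping from 1 (a survival curve)."""

    __slots__ = ("times", "vals")

    def __init__(self, times: np.ndarray, vals: np.ndarray):
        self.times = times
        self.vals = vals

    def __call__(self, t, left: bool = False):
        side = "left" if left else "right"
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side=side) - 1
        out = np.where(idx >= 0, self.vals[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


def _fit_km(times, events) -> _StepCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty input")
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    v = sf.iloc[:, 0].to_numpy(dtype=float)
    # lifelines prepends t=0 with S=1; keep it, the step lookup handles it
    return _StepCurve(t, v)


def km_survival(times, events, t: float) -> float:
    """Kaplan-Meier (product-limit) estimate of S(t)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(_fit_km(times, events)(t))


def censoring_survival(times, events, t: float) -> float:
    """Reverse Kaplan-Meier estimate G(t) of the censoring-free probability."""
    events = np.asarray(events)
    return float(_fit_km(times, 1 - events)(t))


def _censoring_curve(times, events) -> _StepCurve:
    return _fit_km(times, 1 - np.asarray(events))


def oe_ratio(predicted_survival, times, events, t: float, form: str = "event") -> float:
    """Observed/expected ratio at horizon ``t``.

    ``form='event'`` (default): ratio of observed to mean predicted event
    probability, (1 - S_KM(t)) / (1 - mean S_pred(t)); values below 1 mean
    predicted risks are too high on average.  ``form='survival'`` instead
    returns S_KM(t) / mean S_pred(t).
    """
    s_pred = np.asarray(predicted_survival, dtype=float)
    if s_pred.size == 0:
        raise ValueError("empty predictions")
    s_km = km_survival(times, events, t)
    if form == "survival":
        if s_pred.mean() == 0:
            raise ZeroDivisionError("mean predicted survival is zero")
        return s_km / s_pred.mean()
    if form != "event":
        raise ValueError("form must be 'event' or 'survival'")
    expected = 1.0 - s_pred.mean()
    if expected == 0:
        raise ZeroDivisionError("mean predicted risk is zero")
    return (1.0 - s_km) / expected


def _ipcw(times, events, t, curve: _StepCurve | None = None):
    """Case/control masks and IPCW weights at horizon t."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    G = curve if curve is not None else _censoring_curve(times, events)
    g_t = G(t)
    if g_t <= 0:
        raise ValueError(
            f"censoring survival G({t:g}) = 0; choose a smaller horizon"
        )
    cases = (times <= t) & (events == 1)
    controls = times > t
    g_case = G(times[cases], left=True)
    if np.any(g_case <= 0):
        raise ValueError("censoring survival is zero at an event time before t")
    return cases, controls, 1.0 / g_case, 1.0 / g_t


def _cd_auc_weighted(marker, cases, controls, w_case, w_ctrl, t) -> float:
    if not cases.any() or not controls.any():
        raise ValueError(f"AUC({t:g}) undefined: need at least one case and one control")
    m_case = marker[cases]
    m_ctrl = np.sort(marker[controls])
    # constant control weight w_ctrl: cumulative weight = count * w_ctrl
    lo = np.searchsorted(m_ctrl, m_case, side="left")
    hi = np.searchsorted(m_ctrl, m_case, side="right")
    conc = w_ctrl * (lo + 0.5 * (hi - lo))
    num = float(np.sum(w_case * conc))
    den = float(np.sum(w_case)) * (w_ctrl * m_ctrl.size)
    return num / den


def cd_auc(marker, times, events, t: float) -> float:
    """Cumulative/dynamic AUC(t) with IPCW weights.

    Concordance P(marker_case > marker_control) over weighted case-control
    pairs; marker ties count 1/2.  Computed in O(n log n) via sorted
    cumulative control weights (identical to the pairwise double sum).
    """
    marker = np.asarray(marker, dtype=float)
    cases, controls, w_case, w_ctrl = _ipcw(times, events, t)
    return _cd_auc_weighted(marker, cases, controls, w_case, w_ctrl, t)


def _brier_weighted(s, cases, controls, w_case, w_ctrl) -> float:
    total = float(np.sum(s[cases] ** 2 * w_case))
    total += float(np.sum((1.0 - s[controls]) ** 2 * w_ctrl))
    return total / s.size


def brier(predicted_survival, times, events, t: float) -> float:
    """IPCW Brier score at horizon ``t``.

    Events by t contribute (0 - S)^2 / G(time-), subjects observed beyond t
    contribute (1 - S)^2 / G(t), subjects censored before t contribute 0;
    the divisor is the full sample size.
    """
    s = np.asarray(predicted_survival, dtype=float)
    times = np.asarray(times, dtype=float)
    if s.size != times.size:
        raise ValueError("predictions and times must have equal length")
    cases, controls, w_case, w_ctrl = _ipcw(times, events, t)
    return _brier_weighted(s, cases, controls, w_case, w_ctrl)


def ipa(predicted_survival, times, events, t: float) -> float:
    """Index of prediction accuracy: 1 - Brier_model(t) / Brier_null(t)."""
    b_model = brier(predicted_survival, times, events, t)
    s_km = km_survival(times, events, t)
    null_pred = np.full(np.asarray(predicted_survival).shape, s_km)
    b_null = brier(null_pred, times, events, t)
    if b_null == 0:
        raise ZeroDivisionError("null-model Brier score is zero (degenerate outcome)")
    return 1.0 - b_model / b_null


def bootstrap_ci(
    statistic,
    n: int,
    n_bootstrap: int = 500,
    level: float = 0.95,
    seed=None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``statistic`` over subject resamples.

    ``statistic`` is called with an integer index array of length ``n``
    (subjects resampled with replacement) and returns a float; resamples
    where it raises or returns NaN are dropped, erroring out if more than
    half fail.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = []
    failures = 0
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            v = float(statistic(idx))
        except (ValueError, ZeroDivisionError):
            v = np.nan
        if np.isnan(v):
            failures += 1
        else:
            values.append(v)
    if failures > n_bootstrap / 2:
        raise RuntimeError(
            f"statistic undefined in {failures}/{n_bootstrap} bootstrap resamples"
        )
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class MetricsResult:
    """Performance battery at one horizon, with optional bootstrap CIs."""

    horizon: float
    oe_ratio: float
    auc: float
    brier_model: float
    brier_null: float
    n_bootstrap: int = 0
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def ipa(self) -> float:
        return 1.0 - self.brier_model / self.brier_null

    @property
    def brier(self) -> float:
        return self.brier_model

    def value(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise KeyError(name)
        return getattr(self, name if name != "brier" else "brier_model")

    def to_dict(self) -> dict:
        d = {
            "horizon": self.horizon,
            "oe_ratio": self.oe_ratio,
            "auc": self.auc,
            "brier": self.brier_model,
            "brier_null": self.brier_null,
            "ipa": self.ipa,
            "n_bootstrap": self.n_bootstrap,
        }
        for name, (lo, hi) in self.ci.items():
            d[f"{name}_lo"], d[f"{name}_hi"] = lo, hi
        return d


def compute_metrics(
    predicted_survival,
    times,
    events,
    horizon: float,
    marker=None,
    oe_form: str = "event",
) -> MetricsResult:
    """Compute the full battery at one horizon.

    ``marker`` defaults to predicted risk (1 - predicted survival); AUC(t)
    is invariant to any strictly increasing transform of it.
    """
    s = np.asarray(predicted_survival, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if s.size != times.size:
        raise ValueError("predictions and times must have equal length")
    marker = 1.0 - s if marker is None else np.asarray(marker, dtype=float)
    s_km = float(_fit_km(times, events)(horizon))
    G = _censoring_curve(times, events)
    cases, controls, w_case, w_ctrl = _ipcw(times, events, horizon, curve=G)
    if oe_form == "event":
        expected = 1.0 - s.mean()
        if expected == 0:
            raise ZeroDivisionError("mean predicted risk is zero")
        oe = (1.0 - s_km) / expected
    elif oe_form == "survival":
        oe = s_km / s.mean()
    else:
        raise ValueError("oe_form must be 'event' or 'survival'")
    b_null = _brier_weighted(np.full(s.shape, s_km), cases, controls, w_case, w_ctrl)
    if b_null == 0:
        raise ZeroDivisionError("null-model Brier score is zero (degenerate outcome)")
    return MetricsResult(
        horizon=horizon,
        oe_ratio=oe,
        auc=_cd_auc_weighted(marker, cases, controls, w_case, w_ctrl, horizon),
        brier_model=_brier_weighted(s, cases, controls, w_case, w_ctrl),
        brier_null=b_null,
    )
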