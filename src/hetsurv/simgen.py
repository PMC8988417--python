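"""Cohort simulation from a Cox-exponential data-generating mechanism.

Event times follow a proportional-hazards model with an exponential
baseline: the hazard for a subject with predictor value ``x`` is
``lambda0 * exp(beta * x)``.  Times are drawn by inverting the cumulative
hazard (the Bender inverse-transform construction),

    T = -ln(U) / (lambda0 * exp(beta * x)),   U ~ Uniform(0, 1).

Three censoring regimes are supported: none, administrative censoring at a
fixed time, and random censoring whose times are drawn from the same
construction on an independent covariate Z (optionally combined with the
administrative cap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq

__all__ = [
    "DGMConfig",
    "draw_covariates",
    "inverse_exponential_time",
    "sample_event_times",
    "apply_censoring",
    "generate_cohort",
    "marginal_survival",
    "marginal_median",
    "admin_event_fraction",
    "random_censoring_event_fraction",
]

CENSORING_MODES = ("none", "administrative", "random")


@dataclass
class DGMConfig:
    """Parameters of the Cox-exponential data-generating mechanism.

    Defaults correspond to the simulation design used throughout this
    package: standard-normal predictor, baseline event hazard 0.1, hazard
    ratio 2 per unit of the predictor, administrative censoring at t = 15,
    and random censoring with baseline hazard 0.01 and hazard ratio 3 on an
    independent standard-normal covariate Z.
    """

    n: int = 1000
    baseline_hazard: float = 0.1
    log_hazard_ratio: float = math.log(2.0)
    censoring_mode: str = "none"
    admin_time: float = 15.0
    censor_baseline_hazard: float = 0.01
    censor_log_hazard_ratio: float = math.log(3.0)
    # random censoring co-applies the administrative cap by default
    admin_cap_under_random: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.admin_time <= 0:
            raise ValueError("admin_time must be positive")
        if self.censoring_mode not in CENSORING_MODES:
            raise ValueError(
                f"censoring_mode must be one of {CENSORING_MODES}, "
                f"got {self.censoring_mode!r}"
            )
        if self.censoring_mode == "random" and self.censor_baseline_hazard <= 0:
            raise ValueError(
                "censor_baseline_hazard must be positive under random censoring"
            )


def _substreams(seed: int | None) -> dict[str, np.random.Generator]:
    """Independent RNG substreams derived from one master seed.

    Covariates, event-time uniforms, the censoring covariate and
    censoring-time uniforms each get their own stream so that switching the
    censoring regime never perturbs the simulated event times.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4)
    names = ("x", "event_u", "z", "censor_u")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def draw_covariates(n: int, seed=None) -> np.ndarray:
    """Draw ``n`` iid standard-normal predictor values.

    ``seed`` may be an int, a SeedSequence, or a Generator.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.standard_normal(int(n))


def inverse_exponential_time(
    u, x, baseline_hazard: float, log_hr: float
) -> np.ndarray:
    """Invert the exponential cumulative hazard at uniform draws ``u``.

    Returns ``-ln(u) / (baseline_hazard * exp(log_hr * x))``, the
    proportional-hazards event time associated with survival quantile u.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    u = np.asarray(u, dtype=float)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate values must be finite")
    rate = baseline_hazard * np.exp(log_hr * x)
    return -np.log(u) / rate


def sample_event_times(
    x, baseline_hazard: float, log_hr: float, seed=None
) -> np.ndarray:
    """Sample event times conditional on covariates ``x``.

    Conditional on ``x_i`` the time is exponential with rate
    ``baseline_hazard * exp(log_hr * x_i)``.
    """
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # 1 - random() lies in (0, 1]; avoids log(0)
    u = 1.0 - rng.random(x.shape[0])
    return inverse_exponential_time(u, x, baseline_hazard, log_hr)


def apply_censoring(
    true_times, z, config: DGMConfig, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the configured censoring regime to latent event times.

    Returns ``(observed_time, event_indicator)``.  Under random censoring,
    censoring times are drawn by the same inverse-transform construction
    with rate ``censor_baseline_hazard * exp(censor_log_hr * z)`` and, by
    default, combined with the administrative cap.  Ties between event and
    censoring time are resolved as censored.
    """
    t = np.asarray(true_times, dtype=float)
    if config.censoring_mode == "none":
        return t.copy(), np.ones(t.shape[0], dtype=int)
    if config.censoring_mode == "administrative":
        observed = np.minimum(t, config.admin_time)
        event = (t <= config.admin_time).astype(int)
        return observed, event
    # random censoring
    if z is None:
        raise ValueError("censoring covariate z is required under random censoring")
    z = np.asarray(z, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = 1.0 - rng.random(t.shape[0])
    c = inverse_exponential_time(
        u, z, config.censor_baseline_hazard, config.censor_log_hazard_ratio
    )
    if config.admin_cap_under_random:
        c = np.minimum(c, config.admin_time)
    observed = np.minimum(t, c)
    event = (t < c).astype(int)
    return observed, event


def generate_cohort(config: DGMConfig) -> pd.DataFrame:
    """Simulate a full cohort table from the data-generating mechanism.

    Columns: ``subject_id``, ``x``, (``z`` under random censoring),
    ``true_event_time``, ``observed_time``, ``event``.
    """
    streams = _substreams(config.seed)
    x = draw_covariates(config.n, streams["x"])
    t = sample_event_times(
        x, config.baseline_hazard, config.log_hazard_ratio, streams["event_u"]
    )
    cols: dict[str, np.ndarray] = {"subject_id": np.arange(config.n), "x": x}
    if config.censoring_mode == "random":
        z = streams["z"].standard_normal(config.n)
        cols["z"] = z
    else:
        z = None
    observed, event = apply_censoring(t, z, config, streams["censor_u"])
    cols["true_event_time"] = t
    cols["observed_time"] = observed
    cols["event"] = event
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# analytic summaries of the marginal survival distribution


def marginal_survival(
    t, baseline_hazard: float = 0.1, log_hr: float = math.log(2.0), order: int = 100
):
    """Marginal survival S(t) = E_X[exp(-lambda0 * t * exp(beta X))], X ~ N(0,1).

    Computed by Gauss-Hermite quadrature.
    """
    nodes, weights = hermgauss(order)
    x = math.sqrt(2.0) * nodes  # change of variables to standard normal
    t = np.asarray(t, dtype=float)
    rates = baseline_hazard * np.exp(log_hr * x)
    vals = np.exp(-np.multiply.outer(t, rates)) @ weights / math.sqrt(math.pi)
    return vals if vals.shape else float(vals)


def marginal_median(
    baseline_hazard: float = 0.1, log_hr: float = math.log(2.0)
) -> float:
    """Median of the marginal event-time distribution (root of S(t) = 1/2)."""
    return float(
        brentq(lambda t: marginal_survival(t, baseline_hazard, log_hr) - 0.5, 1e-9, 1e4)
    )


def admin_event_fraction(
    admin_time: float = 15.0,
    baseline_hazard: float = 0.1,
    log_hr: float = math.log(2.0),
) -> float:
    """P(T <= admin_time) under the marginal event-time distribution."""
    return 1.0 - float(marginal_survival(admin_time, baseline_hazard, log_hr))


def random_censoring_event_fraction(config: DGMConfig | None = None, order: int = 80) -> float:
    """P(T < min(C, admin_time)) under the random-censoring regime.

    Double Gauss-Hermite quadrature over the independent covariates X and Z:
    given rates a = lambda_T(x) and b = lambda_C(z), competing exponentials
    give P(T < C, T < tau) = a/(a+b) * (1 - exp(-(a+b) tau)).
    """
    cfg = config if config is not None else DGMConfig(n=1, censoring_mode="random")
    nodes, weights = hermgauss(order)
    g = math.sqrt(2.0) * nodes
    wn = weights / math.sqrt(math.pi)
    a = cfg.baseline_hazard * np.exp(cfg.log_hazard_ratio * g)
    b = cfg.censor_baseline_hazard * np.exp(cfg.censor_log_hazard_ratio * g)
    A, B = a[:, None], b[None, :]
    W2 = np.outer(wn, wn)
    tau = cfg.admin_time if cfg.admin_cap_under_random else np.inf
    inner = A / (A + B)
    if np.isfinite(tau):
        inner = inner * (1.0 - np.exp(-(A + B) * tau))
    return float(np.sum(W2 * inner))
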