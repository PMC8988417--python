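"""Measurement-heterogeneity model linking two measurement procedures.

A predictor measured as X in the validation setting is assumed to be
measured as

    W = psi + theta * X + eps,    eps ~ N(0, sigma_eps^2)

in the implementation setting: ``psi`` is an additive systematic shift,
``theta`` a multiplicative systematic association, and ``sigma_eps`` the
standard deviation of additional random measurement variation.
Scenario grids enumerate finite collections of (psi, theta, sigma_eps)
triples for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "HetParams",
    "ScenarioGrid",
    "apply_heterogeneity",
    "build_grid",
    "MeasurementHeterogeneity",
    "HOMOGENEITY",
]


@dataclass(frozen=True)
class HetParams:
    """One measurement-heterogeneity scenario (psi, theta, sigma_eps)."""

    psi: float = 0.0
    theta: float = 1.0
    sigma_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be non-negative")
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def is_homogeneous(self) -> bool:
        return self.psi == 0.0 and self.theta == 1.0 and self.sigma_eps == 0.0


HOMOGENEITY = HetParams(0.0, 1.0, 0.0)


def apply_heterogeneity(x, params: HetParams, seed=None) -> np.ndarray:
    """Transform validation measurements into implementation measurements.

    Returns ``w_i = psi + theta * x_i + eps_i`` with fresh
    ``eps_i ~ N(0, sigma_eps^2)`` drawn from ``seed`` on every call.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    w = params.psi + params.theta * x
    if params.sigma_eps > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        w = w + rng.normal(0.0, params.sigma_eps, size=x.shape)
    return w


@dataclass
class ScenarioGrid:
    """Ordered, duplicate-free collection of heterogeneity scenarios."""

    scenarios: list[HetParams]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.scenarios) == 0:
            raise ValueError("scenario grid must be non-empty")
        triples = [(s.psi, s.theta, s.sigma_eps) for s in self.scenarios]
        if len(set(triples)) != len(triples):
            raise ValueError("scenario grid contains duplicate (psi, theta, sigma_eps)")
        if self.labels is None:
            self.labels = [
                f"psi={s.psi:g}_theta={s.theta:g}_sigma={s.sigma_eps:g}"
                for s in self.scenarios
            ]
        elif len(self.labels) != len(self.scenarios):
            raise ValueError("labels length must match scenarios length")

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "psi": [s.psi for s in self.scenarios],
                "theta": [s.theta for s in self.scenarios],
                "sigma_eps": [s.sigma_eps for s in self.scenarios],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScenarioGrid":
        scenarios = [
            HetParams(float(r.psi), float(r.theta), float(r.sigma_eps))
            for r in frame.itertuples()
        ]
        labels = list(frame["label"]) if "label" in frame.columns else None
        return cls(scenarios=scenarios, labels=labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScenarioGrid":
        return cls.from_frame(pd.read_csv(path))


def _levels(low: float, high: float, k: int) -> np.ndarray:
    if low > high:
        raise ValueError(f"inverted interval [{low}, {high}]")
    if k < 1:
        raise ValueError("levels_per_param must be >= 1")
    if k == 1:
        return np.array([(low + high) / 2.0])
    return np.linspace(low, high, k)


def build_grid(
    psi_range: tuple[float, float] = (-0.3, 0.3),
    theta_range: tuple[float, float] = (0.5, 2.0),
    sigma_range: tuple[float, float] = (0.0, np.sqrt(2.0)),
    levels_per_param: int = 3,
) -> ScenarioGrid:
    """Full factorial grid of equally spaced heterogeneity levels.

    Levels include both interval endpoints; scenarios are ordered
    lexicographically with psi varying slowest and sigma_eps fastest.
    The defaults span the ranges explored in the simulation study
    (psi in [-0.3, 0.3], theta in [0.5, 2], sigma_eps in [0, sqrt 2]),
    giving the 3^3 = 27 scenario design.
    """
    psis = _levels(*psi_range, levels_per_param)
    thetas = _levels(*theta_range, levels_per_param)
    sigmas = _levels(*sigma_range, levels_per_param)
    scenarios = [
        HetParams(float(p), float(t), float(s))
        for p in psis
        for t in thetas
        for s in sigmas
    ]
    return ScenarioGrid(scenarios=scenarios)


class MeasurementHeterogeneity(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer applying the measurement model columnwise.

    Transforms every column of ``X`` as ``psi + theta * x + eps``; typically
    used on the single flagged predictor column.  ``fit`` is stateless and
    only records the input dimensionality.

    Parameters
    ----------
    psi : additive shift, in predictor units.
    theta : multiplicative association (dimensionless, > 0).
    sigma_eps : SD of the random deviation, in predictor units.
    random_state : seed for the noise draw in :meth:`transform`.
    """

    def __init__(self, psi=0.0, theta=1.0, sigma_eps=0.0, random_state=None):
        self.psi = psi
        self.theta = theta
        self.sigma_eps = sigma_eps
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        self.n_features_in_ = X.shape[1]
        # validates the parameter triple
        self.params_ = HetParams(self.psi, self.theta, self.sigma_eps)
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        rng = np.random.default_rng(self.random_state)
        W = np.column_stack(
            [apply_heterogeneity(X[:, j], self.params_, rng) for j in range(X.shape[1])]
        )
        return W[:, 0] if squeeze else W
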