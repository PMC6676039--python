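"""Fraction-versus-optical-property curve models.

Stroma and adipose volume fractions vary monotonically with each scattering
property and are fitted with a two-parameter logistic curve; epithelium peaks
at intermediate property values and is fitted with a three-parameter Gaussian.
Fits are bounded nonlinear least squares with a deterministic multi-start grid.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ModelFamily",
    "OpticalPropertyMap",
    "ScatterModel",
    "PredictionInterval",
    "logistic2",
    "gaussian3",
    "fit_model",
    "evaluate_fit",
    "prediction_interval",
]

PROPERTY_NAMES = ("mus_prime", "gamma", "b_power")
FRACTION_NAMES = ("epithelium", "stroma", "adipose")


class ModelFamily(str, enum.Enum):
    LOGISTIC2 = "LOGISTIC2"
    GAUSSIAN3 = "GAUSSIAN3"


#: Curve family used for each tissue fraction.
FAMILY_FOR_FRACTION = {
    "stroma": ModelFamily.LOGISTIC2,
    "adipose": ModelFamily.LOGISTIC2,
    "epithelium": ModelFamily.GAUSSIAN3,
}


@dataclass
class OpticalPropertyMap:
    """Per-pixel light-scattering properties with spatial scale.

    ``mus_prime`` is the reduced scattering coefficient in 1/mm; ``gamma`` the
    dimensionless phase-function parameter; ``b_power`` the scatter-power
    exponent of the wavelength dependence.
    """

    mus_prime: np.ndarray
    gamma: np.ndarray
    b_power: np.ndarray
    pixel_size: float
    amplitude_a: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.mus_prime = np.asarray(self.mus_prime, float)
        self.gamma = np.asarray(self.gamma, float)
        self.b_power = np.asarray(self.b_power, float)
        if not (self.mus_prime.shape == self.gamma.shape == self.b_power.shape):
            raise ValueError("property maps must share one grid")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.mus_prime.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if np.any(self.mus_prime[self.valid_mask] <= 0):
            raise ValueError("mus_prime must be positive where valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mus_prime.shape

    def property_array(self, name: str) -> np.ndarray:
        if name not in PROPERTY_NAMES:
            raise KeyError(f"unknown property {name!r}")
        return getattr(self, name)


def logistic2(x, c: float, w: float):
    """Two-parameter logistic curve 1 / (1 + exp((x - c) / w)).

    Decreasing for ``w > 0``, increasing for ``w < 0``; value 0.5 at ``x = c``.
    """
    if w == 0:
        raise ValueError("logistic width w must be nonzero")
    z = (np.asarray(x, float) - c) / w
    # evaluate in a numerically safe split to avoid overflow warnings
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = np.exp(-z[pos]) / (1.0 + np.exp(-z[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(z[~pos]))
    return out if out.ndim else float(out)


def gaussian3(x, a: float, c: float, w: float):
    """Three-parameter Gaussian curve a * exp(-(x - c)^2 / (2 w^2)).

    Peak height ``a`` at location ``c``; symmetric about ``c``.
    """
    if w <= 0:
        raise ValueError("gaussian width w must be positive")
    if a <= 0:
        raise ValueError("gaussian amplitude a must be positive")
    x = np.asarray(x, float)
    out = a * np.exp(-((x - c) ** 2) / (2.0 * w**2))
    return out if out.ndim else float(out)


class PredictionInterval(NamedTuple):
    lower: float
    upper: float
    extrapolated: bool


@dataclass
class ScatterModel:
    """One fitted fraction-versus-property curve with its fit diagnostics."""

    family: ModelFamily
    property_name: str
    fraction_name: str
    params: tuple[float, ...]
    param_cov: np.ndarray
    rmse: float
    r2_adj: float
    n_fit: int
    x_min: float = float("nan")
    x_max: float = float("nan")

    @property
    def n_params(self) -> int:
        return len(self.params)

    def predict(self, x):
        if self.family is ModelFamily.LOGISTIC2:
            return logistic2(x, *self.params)
        return gaussian3(x, *self.params)

    def gradient(self, x: float) -> np.ndarray:
        """Gradient of the curve with respect to its parameters at ``x``."""
        if self.family is ModelFamily.LOGISTIC2:
            c, w = self.params
            f = logistic2(x, c, w)
            u = (x - c) / w
            return np.array([f * (1 - f) / w, f * (1 - f) * u / w])
        a, c, w = self.params
        f = gaussian3(x, a, c, w)
        return np.array([f / a, f * (x - c) / w**2, f * (x - c) ** 2 / w**3])

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "property_name": self.property_name,
            "fraction_name": self.fraction_name,
            "params": list(self.params),
            "param_cov": np.asarray(self.param_cov).tolist(),
            "rmse": self.rmse,
            "r2_adj": self.r2_adj,
            "n_fit": self.n_fit,
            "x_min": self.x_min,
            "x_max": self.x_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScatterModel":
        return cls(
            family=ModelFamily(d["family"]),
            property_name=d["property_name"],
            fraction_name=d["fraction_name"],
            params=tuple(d["params"]),
            param_cov=np.asarray(d["param_cov"], float),
            rmse=float(d["rmse"]),
            r2_adj=float(d["r2_adj"]),
            n_fit=int(d["n_fit"]),
            x_min=float(d.get("x_min", float("nan"))),
            x_max=float(d.get("x_max", float("nan"))),
        )


class FitError(RuntimeError):
    """Raised when nonlinear least squares cannot produce a model."""


def _logistic_residual_jac(x: np.ndarray, y: np.ndarray):
    def residual(p):
        return logistic2(x, p[0], p[1]) - y

    def jac(p):
        c, w = p
        f = logistic2(x, c, w)
        u = (x - c) / w
        g = f * (1.0 - f)
        return np.column_stack([g / w, g * u / w])

    return residual, jac


def _gaussian_residual_jac(x: np.ndarray, y: np.ndarray):
    def residual(p):
        a, c, w = p
        return a * np.exp(-((x - c) ** 2) / (2.0 * w**2)) - y

    def jac(p):
        a, c, w = p
        e = np.exp(-((x - c) ** 2) / (2.0 * w**2))
        return np.column_stack(
            [e, a * e * (x - c) / w**2, a * e * (x - c) ** 2 / w**3]
        )

    return residual, jac


W_MIN = 1e-4  # smallest admissible |w|
A_MAX = 1.5  # largest admissible gaussian amplitude


def _multistart_problems(family: ModelFamily, x: np.ndarray):
    """Deterministic start/bound grid: c over 5 quantiles of x, |w| over
    {0.05, 0.2, 1} * range(x) (both signs for the logistic family), a over
    {0.25, 0.5, 1.0}."""
    x_range = float(np.ptp(x))
    c_starts = np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0])
    w_starts = np.array([0.05, 0.2, 1.0]) * x_range
    w_max = 10.0 * x_range
    c_lo, c_hi = float(x.min() - x_range), float(x.max() + x_range)

    problems = []
    if family is ModelFamily.LOGISTIC2:
        for sign in (1.0, -1.0):
            if sign > 0:
                bounds = ([c_lo, W_MIN], [c_hi, w_max])
            else:
                bounds = ([c_lo, -w_max], [c_hi, -W_MIN])
            for c0 in c_starts:
                for w0 in w_starts:
                    problems.append((np.array([c0, sign * max(w0, W_MIN)]), bounds))
    else:
        bounds = ([1e-6, c_lo, W_MIN], [A_MAX, c_hi, w_max])
        for a0 in (0.25, 0.5, 1.0):
            for c0 in c_starts:
                for w0 in w_starts:
                    problems.append((np.array([a0, c0, max(w0, W_MIN)]), bounds))
    return problems


def fit_model(
    x: Sequence[float],
    y: Sequence[float],
    family: ModelFamily | str,
    property_name: str = "",
    fraction_name: str = "",
    seed: int = 0,
) -> ScatterModel:
    """Fit one fraction-versus-property curve by multi-start least squares.

    Trust-region-reflective nonlinear least squares over a fixed grid of
    initializations; the start with the lowest sum of squared residuals wins
    (ties broken by grid order, so the fit is deterministic). ``seed`` is
    accepted for interface stability; the grid itself is deterministic.

    Returns the fitted :class:`ScatterModel` with rmse = sqrt(SSE/n),
    degree-of-freedom-adjusted R^2, and the linearized parameter covariance
    (J^T J)^{-1} * SSE / (n - p).
    """
    family = ModelFamily(family)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("x and y must be finite")
    n = x.size
    p = 2 if family is ModelFamily.LOGISTIC2 else 3
    if n <= p:
        raise FitError(f"need more than {p} points to fit {family.value}")
    if np.ptp(y) == 0:
        raise FitError("no curvature: y is constant")
    if np.ptp(x) == 0:
        raise FitError("fit failed: x has no spread")

    make = (
        _logistic_residual_jac if family is ModelFamily.LOGISTIC2 else _gaussian_residual_jac
    )
    residual, jac = make(x, y)

    best: optimize.OptimizeResult | None = None
    best_sse = np.inf
    for start, bounds in _multistart_problems(family, x):
        try:
            res = optimize.least_squares(
                residual,
                start,
                jac=jac,
                bounds=bounds,
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=150,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if res.success and sse < best_sse:
            best_sse = sse
            best = res
            if best_sse <= n * 1e-18:  # perfect fit: later starts cannot win
                break
    if best is None:
        raise FitError("fit failed: no start converged")

    params = tuple(float(v) for v in best.x)
    sse = best_sse
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / n))
    r2_adj = 1.0 - (sse / (n - p)) / (sst / (n - 1))
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * (sse / (n - p))
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * (sse / (n - p))
    return ScatterModel(
        family=family,
        property_name=property_name,
        fraction_name=fraction_name,
        params=params,
        param_cov=cov,
        rmse=rmse,
        r2_adj=r2_adj,
        n_fit=n,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def evaluate_fit(
    model: ScatterModel, x: Sequence[float], y: Sequence[float], n_params: int | None = None
) -> tuple[float, float]:
    """Recompute (rmse, adjusted R^2) of a model on data.

    ``n_params`` overrides the penalty's parameter count (useful for
    evaluating fixed reference curves with p = 0).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    p = model.n_params if n_params is None else n_params
    n = x.size
    if n <= p:
        raise ValueError("need more points than parameters")
    resid = y - model.predict(x)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / n))
    if sst == 0:
        r2_adj = 1.0 if sse == 0 else -np.inf
    elif n == p:
        r2_adj = float("nan")
    else:
        r2_adj = 1.0 - (sse / (n - p)) / (sst / (n - 1))
    return rmse, r2_adj


def prediction_interval(
    model: ScatterModel, x: float, level: float = 0.95
) -> PredictionInterval:
    """Pointwise linearized prediction interval for a new observation at ``x``.

    f(x) +/- t_{n-p,(1+level)/2} * sqrt(s^2 + g' cov g) with s^2 the residual
    variance SSE/(n-p) and g the parameter gradient of f at x; endpoints are
    clipped to [0, 1]. Points outside the fitted support are flagged as
    extrapolation but still receive an interval.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    n, p = model.n_fit, model.n_params
    fx = float(model.predict(x))
    g = model.gradient(x)
    s2 = model.rmse**2 * n / (n - p)  # == SSE/(n-p)
    var = s2 + float(g @ np.asarray(model.param_cov) @ g)
    tq = float(stats.t.ppf((1.0 + level) / 2.0, df=n - p))
    half = tq * np.sqrt(max(var, 0.0))
    lower = float(np.clip(fx - half, 0.0, 1.0))
    upper = float(np.clip(fx + half, 0.0, 1.0))
    extrapolated = bool(x < model.x_min or x > model.x_max)
    return PredictionInterval(lower, upper, extrapolated)


def save_models(models: Sequence[ScatterModel], path) -> None:
    """Serialize a collection of fitted models to JSON."""
    payload = [m.to_dict() for m in models]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_models(path) -> list[ScatterModel]:
    with open(path) as fh:
        payload = json.load(fh)
    return [ScatterModel.from_dict(d) for d in payload]
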