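"""Primary growth models for predictive microbiology.

Four sigmoidal kinetic curves describe how the log bacterial count
N(t) (or a monotone surrogate such as a gas/taste sensor response)
moves from an initial level ``n0`` to an asymptotic level ``nmax``
after a lag of ``lag`` hours, at maximum specific rate ``mu_max``:

* Modified Gompertz (Zwietering parameterisation)
* Logistic (four-parameter, inflection at ``t = lag``)
* Huang (explicit form with a smooth four-parameter lag transfer)
* Baranyi–Roberts (explicit adjustment-function form)

All four are supported in both directions: ``nmax > n0`` gives the
classical increasing growth curve, ``nmax < n0`` a decreasing curve
(declining sensor responses).  Exponentials are evaluated in log
space wherever ``mu_max * t`` products can exceed the double range.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ModelKind",
    "GrowthParams",
    "CurveSeries",
    "evaluate_curve",
    "shelf_life_time",
]


class ModelKind(str, Enum):
    """Closed enumeration of the supported primary models."""

    MODIFIED_GOMPERTZ = "modified_gompertz"
    LOGISTIC = "logistic"
    HUANG = "huang"
    BARANYI = "baranyi"

    @classmethod
    def coerce(cls, value: "ModelKind | str") -> "ModelKind":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        aliases = {"gompertz": "modified_gompertz", "baranyi-roberts": "baranyi"}
        return cls(aliases.get(key, key))


# report/table ordering of the four models
MODEL_ORDER: tuple[ModelKind, ...] = (
    ModelKind.MODIFIED_GOMPERTZ,
    ModelKind.LOGISTIC,
    ModelKind.HUANG,
    ModelKind.BARANYI,
)


@dataclass(frozen=True)
class GrowthParams:
    """Kinetic parameters of one primary growth model.

    Parameters
    ----------
    n0 : float
        Initial level (Log CFU/mL for plate counts, instrument units
        for sensor channels).
    nmax : float
        Asymptotic level, same units as ``n0``.  ``nmax < n0`` is
        legal and describes a decreasing curve.
    mu_max : float
        Maximum specific rate in 1/h; must be positive.
    lag : float
        Lag time λ in hours; must be non-negative.
    """

    n0: float
    nmax: float
    mu_max: float
    lag: float

    def __post_init__(self) -> None:
        vals = (self.n0, self.nmax, self.mu_max, self.lag)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"growth parameters must be finite, got {vals}")
        if self.mu_max <= 0:
            raise ValueError(f"mu_max must be > 0, got {self.mu_max}")
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")
        if self.nmax == self.n0:
            raise ValueError("nmax must differ from n0")

    @property
    def increasing(self) -> bool:
        return self.nmax > self.n0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.n0, self.nmax, self.mu_max, self.lag)


@dataclass(frozen=True)
class CurveSeries:
    """A model (or observed) level series on a time grid in hours."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1-d of equal length")
        if not np.all(np.isfinite(t)):
            raise ValueError("times must be finite")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


def _validate_times(times: Sequence[float]) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t


def _gompertz(t: np.ndarray, n0: float, nmax: float, mu: float, lag: float) -> np.ndarray:
    # Zwietering form; |nmax-n0| in the slope factor keeps the curve
    # running n0 -> nmax in either direction (the signed form would
    # time-reverse a decreasing curve).
    dn = nmax - n0
    with np.errstate(over="ignore"):
        inner = np.exp(mu * np.e / abs(dn) * (lag - t) + 1.0)
        return n0 + dn * np.exp(-inner)


def _logistic(t: np.ndarray, n0: float, nmax: float, mu: float, lag: float) -> np.ndarray:
    z = np.clip(mu * (lag - t), -700.0, 700.0)
    return n0 + (nmax - n0) / (1.0 + np.exp(z))


def _huang(t: np.ndarray, n0: float, nmax: float, mu: float, lag: float) -> np.ndarray:
    # B(t) = t + (1/4) ln[(1 + e^{-4(t-lag)}) / (1 + e^{4 lag})]
    b = t + 0.25 * (np.logaddexp(0.0, -4.0 * (t - lag)) - np.logaddexp(0.0, 4.0 * lag))
    dn = nmax - n0
    # N = nmax - ln(1 + expm1(dn) e^{-mu B}); B >= 0 for t >= 0
    return nmax - np.log1p(np.expm1(dn) * np.exp(-np.minimum(mu * b, 700.0)))


def _log_exp_plus(x: np.ndarray, c: float) -> np.ndarray:
    """log(e^x + c) for x >= 0, c > -1, overflow-safe."""
    x = np.asarray(x, dtype=float)
    small = np.log(np.exp(np.minimum(x, 30.0)) + c)
    large = x + np.log1p(c * np.exp(-np.maximum(x, 1.0)))
    return np.where(x > 30.0, large, small)


def _baranyi(t: np.ndarray, n0: float, nmax: float, mu: float, lag: float) -> np.ndarray:
    # A(t) = t + (1/mu) ln(e^{-mu t}(1 - e^{-h0}) + e^{-h0}), h0 = mu*lag
    h0 = mu * lag
    if h0 > 0:
        with np.errstate(divide="ignore"):  # log1p(-1) -> -inf is the h0->0 limit
            log_one_minus = np.log1p(-np.exp(-h0))
        a = t + np.logaddexp(-mu * t + log_one_minus, -h0) / mu
    else:
        a = np.asarray(t, dtype=float)
    x = mu * a
    dn = nmax - n0
    # N = n0 + x - ln(1 + (e^x - 1) e^{-dn}) = n0 + x + dn - ln(e^x + expm1(dn))
    return n0 + x + dn - _log_exp_plus(x, np.expm1(dn))


_MODEL_FUNCS = {
    ModelKind.MODIFIED_GOMPERTZ: _gompertz,
    ModelKind.LOGISTIC: _logistic,
    ModelKind.HUANG: _huang,
    ModelKind.BARANYI: _baranyi,
}


def model_function(kind: ModelKind | str):
    """Return the raw ``f(t, n0, nmax, mu_max, lag)`` callable for ``kind``."""
    return _MODEL_FUNCS[ModelKind.coerce(kind)]


def evaluate_curve(
    kind: ModelKind | str,
    params: GrowthParams,
    times: Sequence[float],
) -> CurveSeries:
    """Evaluate one primary growth model on a time grid.

    The returned values start at ``params.n0`` (exactly for Huang and
    Baranyi, within the model's lag behaviour for Modified Gompertz
    and Logistic), approach ``params.nmax`` as ``t`` grows, and are
    monotone in between.
    """
    t = _validate_times(times)
    f = model_function(kind)
    return CurveSeries(times=t, values=f(t, *params.as_tuple()))


def shelf_life_time(
    kind: ModelKind | str,
    params: GrowthParams,
    threshold: float,
    *,
    tol: float = 1e-9,
) -> float | None:
    """Earliest time at which the curve reaches ``threshold``.

    For a spoilage threshold (e.g. 5 Log CFU/mL for freshly squeezed
    juice) this is the predicted shelf life.  Returns ``None`` when
    the threshold lies outside the open band swept by the curve
    (strictly beyond ``nmax``, or strictly behind the starting
    level).  A threshold already met at ``t = 0`` returns ``0.0``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    f = model_function(kind)
    n0, nmax, mu, lag = params.as_tuple()
    sign = 1.0 if nmax > n0 else -1.0
    v0 = float(f(np.array([0.0]), n0, nmax, mu, lag)[0])

    # already at/behind the threshold when storage starts
    if sign * (v0 - threshold) >= -tol:
        return 0.0 if sign * (threshold - n0) >= -tol else None
    # asymptote never reached
    if sign * (nmax - threshold) <= tol:
        return None

    hi = max(2.0 * lag, 1.0 / mu, 1.0)
    while sign * (float(f(np.array([hi]), n0, nmax, mu, lag)[0]) - threshold) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid params
            return None

    from scipy.optimize import brentq

    root = brentq(
        lambda t: float(f(np.array([t]), n0, nmax, mu, lag)[0]) - threshold,
        0.0,
        hi,
        xtol=1e-10,
        rtol=1e-14,
    )
    return float(root)
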