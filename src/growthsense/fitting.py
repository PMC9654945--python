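"""Nonlinear least-squares fitting of the primary growth models.

The central object is :class:`GrowthCurveFitter`, a scikit-learn style
regressor: ``X`` is the sampling time in hours (shape ``(n, 1)`` or
``(n,)``), ``y`` the observed level.  Fitting minimises the residual
sum of squares over the four kinetic parameters with a bounded
multi-start trust-region search, deterministic for a given seed.

Goodness of fit uses the degrees-of-freedom adjusted statistics

    RMSE = sqrt( SSE / (n - p) )
    R²   = 1 - (n - 1)/(n - p) · SSE / SST

with ``p`` the number of fitted parameters (4 for all four models).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import (
    MODEL_ORDER,
    CurveSeries,
    GrowthParams,
    ModelKind,
    model_function,
)
from .panel import ReplicatePanel

__all__ = [
    "FitMetrics",
    "FitOptions",
    "FitResult",
    "GrowthCurveFitter",
    "fit_metrics",
    "fit_growth",
    "fit_all",
    "fit_with_validation",
    "curve_correlation",
    "ConvergenceError",
    "DegenerateDataError",
]

N_PARAMS = 4


class ConvergenceError(RuntimeError):
    """Raised when every restart of the optimiser fails."""


class DegenerateDataError(ValueError):
    """Raised for inputs with no usable variation."""


@dataclass(frozen=True)
class FitMetrics:
    """Adjusted R² and RMSE for one evaluation of a fitted curve."""

    r2: float
    rmse: float
    n: int
    p: int


@dataclass(frozen=True)
class FitOptions:
    """Optimiser settings for :class:`GrowthCurveFitter`.

    ``bound_widen`` is the fraction of the observed range by which the
    level bounds extend beyond the data; ``mu_bounds`` and the lag
    bound ``[0, max(t)]`` keep every exponential finite.
    """

    n_restarts: int = 32
    seed: int = 0
    bound_widen: float = 0.5
    mu_bounds: tuple[float, float] = (1e-4, 1.0)
    tolerance: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """One fitted model with its training (and optional testing) metrics."""

    kind: ModelKind
    params: GrowthParams
    train: FitMetrics
    test: FitMetrics | None = None
    r: float | None = None
    converged: bool = True
    restarts_used: int = 0
    sse: float = float("nan")

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind.value,
            "params": asdict(self.params),
            "train": asdict(self.train),
            "test": asdict(self.test) if self.test is not None else None,
            "r": self.r,
            "converged": self.converged,
            "restarts_used": self.restarts_used,
            "sse": self.sse,
        }
        return d


def fit_metrics(
    observed: Sequence[float],
    predicted: Sequence[float],
    p: int,
) -> FitMetrics:
    """Adjusted R² and RMSE of ``predicted`` against ``observed``.

    Raises
    ------
    ValueError
        If fewer observations than ``p + 1`` are supplied.
    DegenerateDataError
        If the observed series has zero variance.
    """
    y = np.asarray(observed, dtype=float)
    yp = np.asarray(predicted, dtype=float)
    if y.shape != yp.shape or y.ndim != 1:
        raise ValueError("observed and predicted must be 1-d of equal length")
    n = len(y)
    if n <= p:
        raise ValueError(f"need n > p observations (n={n}, p={p})")
    sse = float(np.sum((y - yp) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DegenerateDataError("observed series has zero variance")
    r2 = 1.0 - (n - 1) / (n - p) * sse / sst
    rmse = float(np.sqrt(sse / (n - p)))
    return FitMetrics(r2=float(r2), rmse=rmse, n=n, p=p)


def curve_correlation(fitted: Sequence[float], reference: Sequence[float]) -> float:
    """Pearson correlation between a fitted curve and a reference series."""
    a = np.asarray(fitted, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateDataError("a series has zero variance")
    return float(stats.pearsonr(a, b).statistic)


class GrowthCurveFitter(RegressorMixin, BaseEstimator):
    """Bounded multi-start least-squares fitter for one primary model.

    Parameters
    ----------
    kind : str or ModelKind, default "baranyi"
        Which primary model to fit.
    n_restarts : int, default 32
        Number of optimiser starts: one data-driven initial guess,
        the rest Latin-hypercube samples over the bounds.
    seed : int, default 0
        Seed for the restart design; fits are bit-reproducible.
    bound_widen : float, default 0.5
        Fraction of the observed range added on each side of the
        ``n0``/``nmax`` bounds.

    Attributes
    ----------
    params_ : GrowthParams
        Best-fit kinetic parameters.
    sse_ : float
        Residual sum of squares at the optimum.
    train_metrics_ : FitMetrics
        Adjusted R²/RMSE on the training series with ``p = 4``.
    converged_ : bool
    restarts_used_ : int
    """

    def __init__(
        self,
        kind: str | ModelKind = "baranyi",
        n_restarts: int = 32,
        seed: int = 0,
        bound_widen: float = 0.5,
        mu_bounds: tuple[float, float] = (1e-4, 1.0),
        tolerance: float = 1e-12,
    ):
        self.kind = kind
        self.n_restarts = n_restarts
        self.seed = seed
        self.bound_widen = bound_widen
        self.mu_bounds = mu_bounds
        self.tolerance = tolerance

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _as_time(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be a single time column")
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-d times or an (n, 1) column")
        if not np.all(np.isfinite(t)):
            raise ValueError("times must be finite")
        return t

    def _bounds(self, t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rng = float(y.max() - y.min())
        lo = np.array([y.min() - self.bound_widen * rng,
                       y.min() - self.bound_widen * rng,
                       self.mu_bounds[0], 0.0])
        hi = np.array([y.max() + self.bound_widen * rng,
                       y.max() + self.bound_widen * rng,
                       self.mu_bounds[1], float(t.max())])
        return lo, hi

    def _starts(self, t, y, lo, hi) -> list[np.ndarray]:
        slopes = np.diff(y) / np.diff(t)
        i = int(np.argmax(np.abs(slopes)))
        span = max(abs(y[-1] - y[0]), 1e-9)
        mu0 = float(np.clip(abs(slopes[i]) / span, lo[2], hi[2]))
        smart = np.clip([y[0], y[-1], mu0, max(t[i] - 1.0 / mu0, 0.0)], lo, hi)
        starts = [smart]
        if self.n_restarts > 1:
            sampler = qmc.LatinHypercube(d=N_PARAMS, seed=self.seed)
            for row in sampler.random(self.n_restarts - 1):
                starts.append(lo + row * (hi - lo))
        return starts

    def fit(self, X, y):
        t = self._as_time(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("X and y must have equal length")
        if len(t) < N_PARAMS + 1:
            raise ValueError(f"need at least {N_PARAMS + 1} time points")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        if float(np.std(y)) == 0.0:
            raise DegenerateDataError("series has zero variance; nothing to fit")

        kind = ModelKind.coerce(self.kind)
        f = model_function(kind)
        order = np.argsort(t)
        ts, ys = t[order], y[order]
        lo, hi = self._bounds(ts, ys)

        def residual(theta):
            # keep nmax != n0 for numerical safety inside the forms
            n0, nmax, mu, lag = theta
            if abs(nmax - n0) < 1e-12:
                nmax = n0 + (1e-12 if nmax >= n0 else -1e-12)
            return f(ts, n0, nmax, mu, lag) - ys

        best_sse, best_theta, used = np.inf, None, 0
        for x0 in self._starts(ts, ys, lo, hi):
            try:
                res = optimize.least_squares(
                    residual, x0, bounds=(lo, hi), method="trf",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=3000,
                )
            except Exception:
                continue
            used += 1
            sse = float(np.sum(res.fun ** 2))
            if np.isfinite(sse) and sse < best_sse:
                best_sse, best_theta = sse, res.x
        if best_theta is None:
            raise ConvergenceError(
                f"all {self.n_restarts} restarts failed for model {kind.value}"
            )

        n0, nmax, mu, lag = (float(v) for v in best_theta)
        if nmax == n0:  # boundary degeneracy; nudge by one ulp
            nmax = np.nextafter(nmax, np.inf)
        self.kind_ = kind
        self.params_ = GrowthParams(n0=n0, nmax=nmax, mu_max=mu, lag=lag)
        self.sse_ = best_sse
        self.restarts_used_ = used
        self.converged_ = True
        self.train_metrics_ = fit_metrics(ys, f(ts, *self.params_.as_tuple()), N_PARAMS)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        t = self._as_time(X)
        f = model_function(self.kind_)
        return f(t, *self.params_.as_tuple())

    def score(self, X, y) -> float:
        """Adjusted R² (p = 4) of the fitted curve on ``(X, y)``."""
        return fit_metrics(np.asarray(y, dtype=float), self.predict(X), N_PARAMS).r2


# -- functional wrappers ----------------------------------------------------

def _fitter(kind: ModelKind | str, options: FitOptions) -> GrowthCurveFitter:
    return GrowthCurveFitter(
        kind=kind,
        n_restarts=options.n_restarts,
        seed=options.seed,
        bound_widen=options.bound_widen,
        mu_bounds=options.mu_bounds,
        tolerance=options.tolerance,
    )


def fit_growth(
    series: CurveSeries,
    kind: ModelKind | str,
    options: FitOptions = FitOptions(),
    reference: Sequence[float] | None = None,
) -> FitResult:
    """Fit one model to a level series; optional curve correlation.

    ``reference`` is an observed series on the same grid (typically
    the plate-count log means); the fitted curve's Pearson r against
    it is recorded in the result.
    """
    est = _fitter(kind, options).fit(series.times, series.values)
    r = None
    if reference is not None:
        r = curve_correlation(est.predict(series.times), reference)
    return FitResult(
        kind=est.kind_,
        params=est.params_,
        train=est.train_metrics_,
        r=r,
        converged=est.converged_,
        restarts_used=est.restarts_used_,
        sse=est.sse_,
    )


def fit_all(
    series: CurveSeries,
    options: FitOptions = FitOptions(),
    reference: Sequence[float] | None = None,
) -> list[FitResult]:
    """Fit all four models; sorted by adjusted R² (ties: lower RMSE,
    then the conventional model order)."""
    results: list[FitResult] = []
    errors: list[str] = []
    for kind in MODEL_ORDER:
        try:
            results.append(fit_growth(series, kind, options, reference))
        except DegenerateDataError:
            raise  # no model can fit a constant series
        except (ConvergenceError, ValueError) as exc:  # report partial results
            errors.append(f"{kind.value}: {exc}")
    if not results:
        raise ConvergenceError("; ".join(errors))
    rank = {k: i for i, k in enumerate(MODEL_ORDER)}
    results.sort(key=lambda fr: (-fr.train.r2, fr.train.rmse, rank[fr.kind]))
    return results


def fit_with_validation(
    train_panel: ReplicatePanel,
    test_panel: ReplicatePanel,
    kind: ModelKind | str,
    options: FitOptions = FitOptions(),
    reference: Sequence[float] | None = None,
) -> FitResult:
    """Train/test evaluation of one model on a single-channel panel.

    The model is fitted to the per-time means of the training
    replicates; the trained curve (no refit) is then scored on the
    per-time means of the testing replicates.  Both metric sets use
    ``p = 4``, mirroring how calibration and prediction statistics
    are reported for sensor-based growth curves.
    """
    (ch_train,) = train_panel.channels
    (ch_test,) = test_panel.channels
    if ch_train != ch_test:
        raise ValueError("train and test panels must hold the same channel")
    t_train, y_train = train_panel.mean_series(ch_train)
    t_test, y_test = test_panel.mean_series(ch_test)
    if len(t_train) != len(t_test) or not np.allclose(t_train, t_test):
        raise ValueError("train and test panels must share the time grid")

    est = _fitter(kind, options).fit(t_train, y_train)
    test = fit_metrics(y_test, est.predict(t_test), N_PARAMS)
    r = None
    if reference is not None:
        r = curve_correlation(est.predict(t_train), reference)
    return FitResult(
        kind=est.kind_,
        params=est.params_,
        train=est.train_metrics_,
        test=test,
        r=r,
        converged=est.converged_,
        restarts_used=est.restarts_used_,
        sse=est.sse_,
    )
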