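"""Least-squares fitting, fit statistics and train/test evaluation."""

import numpy as np
import pytest

from growthsense import (
    CurveSeries,
    FitOptions,
    GrowthCurveFitter,
    GrowthParams,
    ModelKind,
    ReplicatePanel,
    curve_correlation,
    evaluate_curve,
    fit_all,
    fit_growth,
    fit_metrics,
    fit_with_validation,
)
from growthsense.fitting import DegenerateDataError

GRID = np.arange(0.0, 169.0, 12.0)
FAST = FitOptions(n_restarts=8, seed=0)


class TestFitMetrics:
    def test_hand_computed_example(self):
        """SSE=0.11, SST=10, n=5, p=2 -> rmse=sqrt(0.11/3), adj R2=1-(4/3)(0.011)."""
        m = fit_metrics([1, 2, 3, 4, 5], [1.1, 1.9, 3.2, 3.8, 5.1], p=2)
        assert m.rmse == pytest.approx(np.sqrt(0.11 / 3), abs=1e-12)
        assert m.rmse == pytest.approx(0.19149, abs=1e-5)
        assert m.r2 == pytest.approx(1 - (4 / 3) * 0.011, abs=1e-12)
        assert m.r2 == pytest.approx(0.98533, abs=1e-5)

    def test_perfect_prediction(self):
        m = fit_metrics([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], p=4)
        assert m.r2 == 1.0 and m.rmse == 0.0

    def test_adjustment_factor_at_study_size(self):
        """n=15, p=4 applies the (n-1)/(n-p) = 14/11 penalty."""
        y = np.linspace(0, 1, 15)
        yp = y + 0.1
        m = fit_metrics(y, yp, p=4)
        sse = 15 * 0.01
        sst = float(np.sum((y - y.mean()) ** 2))
        assert m.r2 == pytest.approx(1 - (14 / 11) * sse / sst, rel=1e-12)

    def test_adjusted_below_unadjusted_when_sse_positive(self):
        y = np.array([1.0, 2.2, 2.9, 4.1, 5.0, 6.2, 6.8])
        yp = np.array([1.1, 2.0, 3.0, 4.0, 5.2, 6.0, 7.0])
        adj = fit_metrics(y, yp, p=4).r2
        sse = np.sum((y - yp) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert adj < 1 - sse / sst

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_metrics([1, 2, 3], [1, 2, 3], p=4)
        with pytest.raises(DegenerateDataError):
            fit_metrics([2, 2, 2, 2, 2], [1, 2, 3, 4, 5], p=2)


class TestCurveCorrelation:
    def test_self_and_negation(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert curve_correlation(y, y) == pytest.approx(1.0)
        assert curve_correlation(y, -y) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert curve_correlation([1, 2, 3], [2, 4, 5]) == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance(self):
        with pytest.raises(DegenerateDataError):
            curve_correlation([1.0, 1.0, 1.0], [1, 2, 3])


@pytest.mark.parametrize("kind", list(ModelKind))
def test_noiseless_recovery_is_exact(kind):
    """On noiseless model data the fitter recovers the generating parameters."""
    true = GrowthParams(4.0, 6.0, 0.06, 50.0)
    series = evaluate_curve(kind, true, GRID)
    fr = fit_growth(series, kind, FitOptions(n_restarts=16, seed=0))
    assert fr.train.r2 == pytest.approx(1.0, abs=1e-9)
    for got, want in zip(fr.params.as_tuple(), true.as_tuple()):
        assert got == pytest.approx(want, rel=1e-5)


def test_optimizer_beats_exhaustive_grid():
    """Fitted SSE never exceeds the best point of a dense 20^4 parameter lattice."""
    t = np.linspace(0.0, 140.0, 8)
    rng = np.random.default_rng(5)
    true = GrowthParams(4.0, 6.0, 0.05, 40.0)

    def logistic(tt, n0, nmax, mu, lag):  # independent oracle form
        return n0 + (nmax - n0) / (1.0 + np.exp(mu * (lag - tt)))

    y = logistic(t, *true.as_tuple()) + rng.normal(0, 0.15, len(t))
    fr = fit_growth(CurveSeries(t, y), "logistic", FitOptions(n_restarts=16, seed=1))

    r = y.max() - y.min()
    axes = [
        np.linspace(y.min() - 0.5 * r, y.max() + 0.5 * r, 20),
        np.linspace(y.min() - 0.5 * r, y.max() + 0.5 * r, 20),
        np.linspace(1e-4, 1.0, 20),
        np.linspace(0.0, t.max(), 20),
    ]
    N0, NM, MU, LG = np.meshgrid(*axes, indexing="ij")
    pred = logistic(t[:, None], N0.ravel()[None, :], NM.ravel()[None, :],
                    MU.ravel()[None, :], LG.ravel()[None, :])
    grid_best = float(np.min(np.sum((pred - y[:, None]) ** 2, axis=0)))
    assert fr.sse <= grid_best + 1e-9


def test_optimizer_dominates_true_parameters():
    """SSE of the fit is at most the SSE at the generating parameters."""
    true = GrowthParams(3.996, 5.337, 0.064, 97.85)
    rng = np.random.default_rng(11)
    for i in range(5):
        y = evaluate_curve("baranyi", true, GRID).values + rng.normal(0, 0.1, len(GRID))
        fr = fit_growth(CurveSeries(GRID, y), "baranyi", FitOptions(n_restarts=8, seed=i))
        sse_true = float(np.sum((evaluate_curve("baranyi", true, GRID).values - y) ** 2))
        assert fr.sse <= sse_true + 1e-9


def test_fit_determinism():
    rng = np.random.default_rng(3)
    y = evaluate_curve("huang", GrowthParams(4, 6, 0.05, 30), GRID).values
    y = y + rng.normal(0, 0.1, len(GRID))
    a = fit_growth(CurveSeries(GRID, y), "huang", FitOptions(seed=42))
    b = fit_growth(CurveSeries(GRID, y), "huang", FitOptions(seed=42))
    assert a.to_dict() == b.to_dict()


class TestFitAll:
    def test_generating_model_wins_on_noiseless_data(self):
        true = GrowthParams(4.0, 6.0, 0.06, 50.0)
        series = evaluate_curve("baranyi", true, GRID)
        results = fit_all(series, FitOptions(n_restarts=12, seed=0))
        assert results[0].kind == ModelKind.BARANYI
        assert results[0].train.r2 == pytest.approx(1.0, abs=1e-9)
        assert all(results[0].sse <= fr.sse for fr in results[1:])
        r2s = [fr.train.r2 for fr in results]
        assert r2s == sorted(r2s, reverse=True)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_all(CurveSeries(GRID, np.full_like(GRID, 2.0)), FAST)

    def test_reference_correlation_recorded(self):
        series = evaluate_curve("logistic", GrowthParams(4, 6, 0.06, 50), GRID)
        ref = series.values + 0.01
        results = fit_all(series, FAST, reference=ref)
        assert all(fr.r is not None and fr.r > 0.99 for fr in results)


class TestFitWithValidation:
    def _panel(self, values):
        return ReplicatePanel.from_arrays(GRID, values, "S7")

    def test_identical_test_panel_gives_equal_metrics(self):
        rng = np.random.default_rng(0)
        base = evaluate_curve("baranyi", GrowthParams(10.7, 5.7, 0.03, 3), GRID).values
        vals = base[:, None] + rng.normal(0, 0.3, (len(GRID), 6))
        fr = fit_with_validation(self._panel(vals), self._panel(vals), "baranyi", FAST)
        assert fr.test is not None
        assert fr.test.r2 == pytest.approx(fr.train.r2, abs=1e-12)
        assert fr.test.rmse == pytest.approx(fr.train.rmse, abs=1e-12)

    def test_fixture_split_generalizes(self, fixture1):
        """Homogeneous generator noise keeps train and test R2 close."""
        ch = fixture1.sensors.channel("S7")
        train = ch.select_replicates(fixture1.train_ids)
        test = ch.select_replicates(fixture1.test_ids)
        fr = fit_with_validation(train, test, "baranyi", FAST)
        assert abs(fr.train.r2 - fr.test.r2) < 0.1

    def test_mismatched_grid_rejected(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(len(GRID), 4))
        other = ReplicatePanel.from_arrays(GRID[:-1] + 1.0, vals[:-1], "S7")
        with pytest.raises(ValueError):
            fit_with_validation(self._panel(vals), other, "baranyi", FAST)
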