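"""Saturating-exponential ablation dynamics and side-asymmetry fitting.

Cumulative ablated-pixel counts during a LITT ablation rise sharply and
plateau within a few minutes, which first-order thermal arguments model as

    N(t) = C · (1 − exp(−(t − t_shift)/τ))

with time constant τ (s), plateau count C (pixels) and onset delay t_shift
(s).  The inverse time constant τ⁻¹ is the ablation *rate* used in
regressions against per-subject covariates.

Side asymmetry (mesial − lateral, or superior − inferior, counts) is
summarized by independent ordinary-least-squares lines fitted to the early
(< 60 s) and late (≥ 60 s) phases of the difference series, and by a paired
bootstrap comparison of the two side series across subjects at each time
point.

The two model fits are scikit-learn-style estimators
(:class:`SaturatingExponential`, :class:`PiecewiseLinearPhases`); the
module-level operations wrap them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .video import AblationSeries

__all__ = [
    "ExpFit",
    "AsymmetryFit",
    "DifferenceSeries",
    "SaturatingExponential",
    "PiecewiseLinearPhases",
    "fit_exponential",
    "difference_series",
    "fit_piecewise_linear",
    "pointwise_side_comparison",
    "NoSignalError",
]


class NoSignalError(ValueError):
    """Raised when a series contains no ablated pixels to fit."""


@dataclass
class ExpFit:
    """Fitted saturating-exponential parameters for one count series."""

    tau: float
    C: float
    t_shift: float
    inv_tau: float
    r_squared: float
    converged: bool
    message: str = ""


@dataclass
class AsymmetryFit:
    """Early/late phase lines of a side-difference series (split at 60 s)."""

    m_early: float
    b_early: float
    m_late: float
    b_late: float
    split: float = 60.0
    axis: str = "ML"


@dataclass
class DifferenceSeries:
    """Signed per-frame difference of two side series (first minus second)."""

    times: np.ndarray
    diff: np.ndarray
    label: str = "mesial-lateral"


def _model(t: np.ndarray, C: float, tau: float, t_shift: float) -> np.ndarray:
    return C * (1.0 - np.exp(-np.clip(t - t_shift, 0.0, None) / tau))


class SaturatingExponential(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fit of ``C·(1 − exp(−(t − t_shift)/τ))``.

    Parameters
    ----------
    max_nfev : int
        Function-evaluation budget for the trust-region solver.
    rate_parameterization : bool
        Fit with τ⁻¹ as the free parameter instead of τ (the two give the
        same curve; exposed for consistency checks).

    Attributes
    ----------
    tau_, C_, t_shift_, inv_tau_ : float
        Fitted parameters.
    r_squared_ : float
        1 − SS_res/SS_tot about the series mean, over all frames.
    converged_ : bool
        False when the solver failed; the best available parameters and a
        diagnostic message are still recorded (no exception), so cohort
        loops complete.
    """

    def __init__(self, max_nfev: int = 10_000, rate_parameterization: bool = False):
        self.max_nfev = max_nfev
        self.rate_parameterization = rate_parameterization

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("times and counts must have equal length")
        if t.size < 5:
            raise ValueError("need at least 5 frames to fit")
        if np.all(y == 0):
            raise NoSignalError("series is identically zero")

        # initialization from the series shape
        C0 = float(y.max())
        zeros = t[y == 0]
        ts0 = float(zeros.max()) if zeros.size else 0.0
        knee = y >= (1 - 1 / np.e) * C0
        t_knee = float(t[knee][0]) if knee.any() else float(t[-1])
        tau0 = max(t_knee - ts0, np.diff(t).min() if t.size > 1 else 1.0)

        tiny = 1e-9
        if self.rate_parameterization:
            def f(tt, C, rate, tsh):
                return _model(tt, C, 1.0 / rate, tsh)
            p0 = [C0 if C0 > 0 else 1.0, 1.0 / tau0, ts0]
            bounds = ([tiny, tiny, -np.inf], [np.inf, np.inf, np.inf])
        else:
            f = _model
            p0 = [C0 if C0 > 0 else 1.0, tau0, ts0]
            bounds = ([tiny, tiny, -np.inf], [np.inf, np.inf, np.inf])

        converged = True
        message = ""
        try:
            popt, _ = curve_fit(f, t, y, p0=p0, bounds=bounds,
                                max_nfev=self.max_nfev)
        except RuntimeError as exc:  # no convergence: keep the initial guess
            popt = p0
            converged = False
            message = str(exc)

        C, second, tsh = (float(v) for v in popt)
        tau = 1.0 / second if self.rate_parameterization else second
        self.C_, self.tau_, self.t_shift_ = C, tau, tsh
        self.inv_tau_ = 1.0 / tau
        resid = y - _model(t, C, tau, tsh)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
        self.converged_ = converged
        self.message_ = message
        return self

    def predict(self, X):
        check_is_fitted(self, "tau_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return _model(t, self.C_, self.tau_, self.t_shift_)

    def to_result(self) -> ExpFit:
        check_is_fitted(self, "tau_")
        return ExpFit(tau=self.tau_, C=self.C_, t_shift=self.t_shift_,
                      inv_tau=self.inv_tau_, r_squared=self.r_squared_,
                      converged=self.converged_, message=self.message_)


def fit_exponential(series: AblationSeries, **kwargs) -> ExpFit:
    """Fit the saturating-exponential count law to one series."""
    est = SaturatingExponential(**kwargs)
    est.fit(series.times, series.counts)
    return est.to_result()


def difference_series(a: AblationSeries, b: AblationSeries,
                      label: str | None = None) -> DifferenceSeries:
    """Signed difference of two side series sharing one time grid."""
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("time vectors differ")
    if label is None:
        label = f"{a.roi_label}-{b.roi_label}"
    return DifferenceSeries(times=a.times.copy(),
                            diff=np.asarray(a.counts, dtype=float) - b.counts,
                            label=label)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS (slope, intercept)."""
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx == 0:
        raise ValueError("degenerate time vector in phase")
    m = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    return m, float(ybar - m * tbar)


class PiecewiseLinearPhases(BaseEstimator, RegressorMixin):
    """Independent OLS lines on the early (< split) and late (>= split) phases.

    The boundary point t = split is assigned to the late phase.
    """

    def __init__(self, split: float = 60.0):
        self.split = split

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        early = t < self.split
        late = ~early
        if early.sum() < 2 or late.sum() < 2:
            raise ValueError("need >= 2 points in each phase")
        self.m_early_, self.b_early_ = _ols_line(t[early], y[early])
        self.m_late_, self.b_late_ = _ols_line(t[late], y[late])
        return self

    def predict(self, X):
        check_is_fitted(self, "m_early_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return np.where(t < self.split,
                        self.m_early_ * t + self.b_early_,
                        self.m_late_ * t + self.b_late_)


def fit_piecewise_linear(d: DifferenceSeries, split: float = 60.0,
                         axis: str = "ML") -> AsymmetryFit:
    """Early/late linear fits of a side-difference series."""
    est = PiecewiseLinearPhases(split=split).fit(d.times, d.diff)
    return AsymmetryFit(m_early=est.m_early_, b_early=est.b_early_,
                        m_late=est.m_late_, b_late=est.b_late_,
                        split=split, axis=axis)


def _interp_onto(series: AblationSeries, grid: np.ndarray) -> np.ndarray:
    return np.interp(grid, series.times, series.counts)


def pointwise_side_comparison(
    pairs: list[tuple[AblationSeries, AblationSeries]],
    n_boot: int = 1000,
    seed: int | None = 0,
    grid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> dict:
    """Per-time-point paired bootstrap comparison of two side series.

    Each subject contributes one (side1, side2) pair; the pairs are linearly
    interpolated onto a common time grid and, at each grid time, subjects are
    resampled with replacement ``n_boot`` times to obtain a two-sided
    percentile p-value for the mean side1 − side2 difference (floored at
    1/n_boot).

    Returns a dict with ``times``, ``mean_diff``, ``p`` and ``significant``
    (p <= alpha), plus the run lengths of consecutive significant points.
    """
    if len(pairs) < 5:
        raise ValueError("need at least 5 subjects")
    if grid is None:
        t_max = min(p[0].times.max() for p in pairs)
        dt = np.median(np.diff(pairs[0][0].times))
        grid = np.arange(0.0, t_max + dt / 2, dt)
    grid = np.asarray(grid, dtype=float)

    diffs = np.stack([
        _interp_onto(a, grid) - _interp_onto(b, grid) for a, b in pairs
    ])  # (n_subj, n_times)
    n_subj = diffs.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_subj, size=(n_boot, n_subj))
    boot_means = diffs[idx].mean(axis=1)  # (n_boot, n_times)
    p_lo = (boot_means <= 0).mean(axis=0)
    p_hi = (boot_means >= 0).mean(axis=0)
    p = np.clip(2 * np.minimum(p_lo, p_hi), 1.0 / n_boot, 1.0)

    sig = p <= alpha
    runs, length = [], 0
    for flag in sig:
        if flag:
            length += 1
        elif length:
            runs.append(length)
            length = 0
    if length:
        runs.append(length)
    return {"times": grid, "mean_diff": diffs.mean(axis=0), "p": p,
            "significant": sig, "run_lengths": runs}
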