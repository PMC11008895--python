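"""GM(1,1) grey forecasting, posterior-variance diagnostics, BP-network
residual correction, and the coupled grey-neural forecaster.

GM(1,1) fits the accumulated series x1 (running sum of the positive series
x0) with the grey differential equation dx1/dt + a*x1 = u. Least squares on
the averaged background value z(t) = (x1(t-1) + x1(t))/2 gives the discrete
development coefficient; because the discrete average is a trapezoidal
approximation of the continuous model, the raw least-squares coefficient
a_ls equals 2*tanh(a/2) rather than a itself. fit_gm11 therefore maps it
back to the continuous-time parameter, a = ln((2 + a_ls)/(2 - a_ls)),
which makes the time response

    x1_hat(t) = (x0(1) - u/a) * exp(-a (t-1)) + u/a

reproduce any geometric series exactly (the fitted ratio e^{-a} equals the
series ratio to machine precision) instead of carrying an O(a^3) bias. The
textbook plug-in estimator is available with ``bias_correction=False``.

Model adequacy is graded from the posterior variance ratio C = s2/s1
(residual deviation over data deviation) and the small-error probability
P = share of residual deviations within 0.6745*s1:

    C < 0.35 and P > 0.95  ->  grade 1, Good
    C < 0.50 and P > 0.80  ->  grade 2, Qualified
    C < 0.65 and P > 0.70  ->  grade 3, Barely qualified
    otherwise              ->  grade 4, Unqualified
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, DegenerateInputError, DomainError

logger = logging.getLogger("ecoeff.grey")

__all__ = [
    "GreyModel",
    "GreyDiagnostics",
    "BPNetConfig",
    "BPNet",
    "HybridForecast",
    "ago",
    "iago",
    "fit_gm11",
    "relative_errors",
    "mean_absolute_error_pct",
    "posterior_diagnostics",
    "grade_from_cp",
    "train_bp",
    "grey_bp_hybrid",
    "forecast",
]


def ago(x0: np.ndarray) -> np.ndarray:
    """Accumulated generating operation: running sum."""
    return np.cumsum(np.asarray(x0, dtype=float))


def iago(x1: np.ndarray) -> np.ndarray:
    """Inverse AGO: first difference with the first value kept."""
    x1 = np.asarray(x1, dtype=float)
    return np.concatenate([[x1[0]], np.diff(x1)])


@dataclass
class GreyModel:
    a: float                 # development coefficient (continuous-time)
    u: float                 # grey input
    x1: float                # base value x0(1)
    values: np.ndarray       # original series
    fitted: np.ndarray       # restored values, fitted[0] = values[0]
    residuals: np.ndarray    # values - fitted
    relative_errors_pct: np.ndarray
    a_ls: float = np.nan     # raw least-squares coefficient
    u_ls: float = np.nan
    degenerate: bool = False  # constant-series branch

    @property
    def n(self) -> int:
        return len(self.values)

    def extrapolate(self, t: np.ndarray) -> np.ndarray:
        """Restored value at 1-based period index t >= 2."""
        t = np.asarray(t, dtype=float)
        if self.degenerate or abs(self.a) < 1e-12:
            return np.full(t.shape, self.u)
        k = self.x1 - self.u / self.a
        return k * np.exp(-self.a * (t - 1.0)) * (1.0 - np.exp(self.a))


def fit_gm11(values, bias_correction: bool = True) -> GreyModel:
    """Fit GM(1,1) to a positive series of length >= 4.

    A numerically flat series (|a_ls| < 1e-12) falls back to a constant
    model fitted at the mean of x0(2..N), with a warning.
    """
    x0 = np.asarray(values, dtype=float)
    if x0.ndim != 1 or len(x0) < 4:
        raise DomainError("GM(1,1) needs a 1-d series of length >= 4")
    if (x0 <= 0).any():
        raise DomainError("GM(1,1) requires strictly positive values")
    x1 = ago(x0)
    z = 0.5 * (x1[:-1] + x1[1:])          # background values, t = 2..N
    B = np.column_stack([-z, np.ones(len(z))])
    y = x0[1:]
    (a_ls, u_ls), *_ = np.linalg.lstsq(B, y, rcond=None)

    if abs(a_ls) < 1e-12:
        logger.warning("flat series: GM(1,1) degenerates to the mean of x0(2..N)")
        mean = float(y.mean())
        fitted = np.concatenate([[x0[0]], np.full(len(y), mean)])
        resid = x0 - fitted
        return GreyModel(a=0.0, u=mean, x1=float(x0[0]), values=x0, fitted=fitted,
                         residuals=resid,
                         relative_errors_pct=resid / x0 * 100.0,
                         a_ls=float(a_ls), u_ls=float(u_ls), degenerate=True)

    if bias_correction:
        if abs(a_ls) >= 2.0:
            raise DomainError(
                f"|a_ls| = {abs(a_ls):.3f} >= 2: series decays/grows too fast for "
                "the continuous-time GM(1,1) correction"
            )
        a = float(np.log((2.0 + a_ls) / (2.0 - a_ls)))
        u = float(a * (u_ls / a_ls))
    else:
        a, u = float(a_ls), float(u_ls)

    model = GreyModel(a=a, u=u, x1=float(x0[0]), values=x0,
                      fitted=np.empty(0), residuals=np.empty(0),
                      relative_errors_pct=np.empty(0),
                      a_ls=float(a_ls), u_ls=float(u_ls))
    fitted = np.concatenate([[x0[0]], model.extrapolate(np.arange(2, len(x0) + 1))])
    model.fitted = fitted
    model.residuals = x0 - fitted
    model.relative_errors_pct = model.residuals / x0 * 100.0
    return model


def relative_errors(actual, simulated) -> tuple:
    """Per-period errors e(t) = (actual - simulated)/actual * 100, rounded
    to 2 decimals for reporting, and their mean absolute value over t >= 2
    (the base year is zero by construction and excluded)."""
    a = np.asarray(actual, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if a.shape != s.shape:
        raise DomainError("actual and simulated series differ in length")
    if (a == 0).any():
        raise DomainError("zero actual value: relative error undefined")
    e = np.round((a - s) / a * 100.0, 2)
    return e, mean_absolute_error_pct(e)


def mean_absolute_error_pct(errors_pct) -> float:
    """Mean absolute percent error over t >= 2 (base year excluded)."""
    e = np.asarray(errors_pct, dtype=float)
    return float(np.round(np.mean(np.abs(e[1:])), 2))


#: (C strict upper bound, P strict lower bound, label, grade)
_GRADE_BANDS = [
    (0.35, 0.95, "Good", 1),
    (0.50, 0.80, "Qualified", 2),
    (0.65, 0.70, "Barely qualified", 3),
]


@dataclass
class GreyDiagnostics:
    s1: float
    s2: float
    C: float
    P: float
    grade: int
    label: str


def grade_from_cp(C: float, P: float) -> tuple:
    """Map a (C, P) pair to its adequacy grade: the best band whose C bound
    (strict less) and P bound (strict greater) both hold, else grade 4.
    Total: every pair maps to exactly one grade."""
    if C < 0:
        raise DomainError("C must be nonnegative")
    for c_hi, p_lo, label, grade in _GRADE_BANDS:
        if C < c_hi and P > p_lo:
            return grade, label
    return 4, "Unqualified"


def posterior_diagnostics(model: GreyModel) -> GreyDiagnostics:
    """Posterior-variance adequacy check of a fitted GM(1,1).

    s1 is the (population) s.d. of the data about its mean, s2 the s.d. of
    the t >= 2 residuals about theirs; C = s2/s1 and P is the share of
    residual deviations smaller than 0.6745*s1. The grade is the best band
    whose C bound (strict less) and P bound (strict greater) both hold.
    """
    x0 = model.values
    q = model.residuals[1:]  # base-year residual is zero by convention
    if len(q) < 3:
        raise DomainError("need at least 3 residuals for diagnostics")
    s1 = float(np.sqrt(np.mean((x0 - x0.mean()) ** 2)))
    if s1 == 0:
        raise DegenerateInputError("constant series: s1 = 0")
    s2 = float(np.sqrt(np.mean((q - q.mean()) ** 2)))
    C = s2 / s1
    P = float(np.mean(np.abs(q - q.mean()) < 0.6745 * s1))
    grade, label = grade_from_cp(C, P)
    return GreyDiagnostics(s1=s1, s2=s2, C=C, P=P, grade=grade, label=label)


# ---------------------------------------------------------------------------
# BP neural network (single hidden layer, sigmoid/linear, full-batch GD)

@dataclass
class BPNetConfig:
    n_hidden: int = 5
    learning_rate: float = 0.05
    max_epochs: int = 10_000
    target_mse: float = 1e-5
    seed: int = 0


@dataclass
class BPNet:
    config: BPNetConfig
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    in_min: np.ndarray
    in_max: np.ndarray
    out_min: np.ndarray
    out_max: np.ndarray
    epochs_run: int = 0
    final_mse: float = np.nan

    def _norm_in(self, X):
        return 2.0 * (X - self.in_min) / (self.in_max - self.in_min) - 1.0

    def _denorm_out(self, Y):
        return (Y + 1.0) / 2.0 * (self.out_max - self.out_min) + self.out_min

    def _forward(self, Xn):
        with np.errstate(over="ignore"):  # saturated sigmoids are fine
            H = 1.0 / (1.0 + np.exp(-(Xn @ self.W1.T + self.b1)))
        return H, H @ self.W2.T + self.b2

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, Yn = self._forward(self._norm_in(X))
        return self._denorm_out(Yn)


def train_bp(inputs, targets, config: BPNetConfig | None = None) -> BPNet:
    """Train the network by full-batch gradient descent on the MSE of the
    min-max normalized data (features and targets both mapped to [-1, 1],
    as with MATLAB's premnmx). Weights start uniform(-0.5, 0.5), seeded."""
    config = config or BPNetConfig()
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.reshape(X.shape[0], -1)
    if X.shape[0] < 2:
        raise DomainError("need at least 2 training samples")
    in_min, in_max = X.min(axis=0), X.max(axis=0)
    out_min, out_max = Y.min(axis=0), Y.max(axis=0)
    if np.any(in_max - in_min == 0):
        raise DegenerateInputError("constant feature: min-max normalization undefined")
    if np.any(out_max - out_min == 0):
        raise DegenerateInputError("constant target: min-max normalization undefined")

    rng = np.random.default_rng(config.seed)
    h, p, q = config.n_hidden, X.shape[1], Y.shape[1]
    net = BPNet(
        config=config,
        W1=rng.uniform(-0.5, 0.5, (h, p)),
        b1=rng.uniform(-0.5, 0.5, h),
        W2=rng.uniform(-0.5, 0.5, (q, h)),
        b2=rng.uniform(-0.5, 0.5, q),
        in_min=in_min, in_max=in_max, out_min=out_min, out_max=out_max,
    )
    Xn = net._norm_in(X)
    Yn = 2.0 * (Y - out_min) / (out_max - out_min) - 1.0
    n = X.shape[0]
    lr = config.learning_rate
    mse = np.inf
    for epoch in range(1, config.max_epochs + 1):
        H, Out = net._forward(Xn)
        err = Out - Yn
        with np.errstate(over="ignore", invalid="ignore"):
            mse = float(np.mean(err**2))
        if not np.isfinite(mse):
            raise ConvergenceError(f"BP training diverged (NaN loss at epoch {epoch})")
        if mse < config.target_mse:
            net.epochs_run = epoch
            break
        gOut = 2.0 * err / n  # gradient of the per-sample mean squared error
        gW2 = gOut.T @ H
        gb2 = gOut.sum(axis=0)
        gH = gOut @ net.W2
        gZ = gH * H * (1.0 - H)
        gW1 = gZ.T @ Xn
        gb1 = gZ.sum(axis=0)
        net.W2 -= lr * gW2
        net.b2 -= lr * gb2
        net.W1 -= lr * gW1
        net.b1 -= lr * gb1
        net.epochs_run = epoch
    net.final_mse = mse
    return net


# ---------------------------------------------------------------------------
# Hybrid grey-neural model

@dataclass
class HybridForecast:
    gm: GreyModel
    bp: BPNet | None
    window: int
    corrections: np.ndarray       # in-sample residual predictions (0 where none)
    combined: np.ndarray          # gm fitted + corrections
    relative_errors_pct: np.ndarray = field(default_factory=lambda: np.empty(0))


def grey_bp_hybrid(values, bp_config: BPNetConfig | None = None,
                   window: int = 3) -> HybridForecast:
    """GM(1,1) plus a BP network trained on sliding windows of past GM
    residuals to predict the next residual; the combined value is the GM
    value plus the predicted residual.

    A noiseless grey series leaves nothing to correct: when the GM
    residuals are numerically zero the BP stage is skipped and the hybrid
    coincides with the plain GM(1,1) model.
    """
    gm = fit_gm11(values)
    x0 = gm.values
    n = len(x0)
    if window < 1:
        raise DomainError("window must be >= 1")
    q = gm.residuals[1:]  # residuals at t = 2..n
    n_samples = len(q) - window
    if n_samples < 2:
        raise DomainError(
            f"window {window} too large for series of length {n} "
            f"(need >= {window + 3})"
        )
    corrections = np.zeros(n)
    scale = np.max(np.abs(q)) if len(q) else 0.0
    bp = None
    if scale > 1e-10 * max(1.0, np.max(np.abs(x0))):
        Xw = np.array([q[i:i + window] for i in range(n_samples)])
        Yw = q[window:]
        try:
            bp = train_bp(Xw, Yw, bp_config)
            preds = bp.predict(Xw)[:, 0]
            # windows ending at residual index window+i predict x0 period
            # t = 2 + window + i  (0-based array index 1 + window + i)
            corrections[1 + window:] = preds
        except DegenerateInputError:
            bp = None
    combined = gm.fitted + corrections
    rel = (x0 - combined) / x0 * 100.0
    return HybridForecast(gm=gm, bp=bp, window=window, corrections=corrections,
                          combined=combined, relative_errors_pct=rel)


def forecast(model, horizon: int):
    """Extrapolate a GreyModel or HybridForecast ``horizon`` periods past
    the end of the series. Returns (periods, gm_component, correction,
    combined) arrays; for a plain GreyModel the correction is zero."""
    if horizon <= 0:
        raise DomainError("horizon must be a positive number of periods")
    if isinstance(model, GreyModel):
        gm, bp, window = model, None, 0
        hist_resid = None
    elif isinstance(model, HybridForecast):
        gm, bp, window = model.gm, model.bp, model.window
        hist_resid = list(gm.residuals[1:])
    else:
        raise DomainError(f"cannot forecast from {type(model).__name__}")
    n = gm.n
    periods = np.arange(n + 1, n + horizon + 1)
    gm_part = gm.extrapolate(periods)
    corr = np.zeros(horizon)
    if bp is not None:
        resid = list(hist_resid)
        for h in range(horizon):
            qhat = float(bp.predict(np.array(resid[-window:]))[0, 0])
            corr[h] = qhat
            resid.append(qhat)
    return periods, gm_part, corr, gm_part + corr
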