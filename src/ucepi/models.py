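"""Parametric diversity-versus-distance curves.

Diversity around a conserved core is depressed at position 0 and recovers
to a plateau in the flanks; the plateau is the estimate of the
population-scaled mutation rate theta. The primary model is the Gompertz
sigmoid

    f(i) = theta * exp(-beta * exp(-gamma * |i|))

with asymptote theta, core-depression depth beta and per-bp recovery rate
gamma. Under a background-selection reading (Hudson-Kaplan: a focal site
under purifying selection with coefficient s, deleterious mutation rate u
and recombination rate r per bp), beta ~ u/(4s) and gamma ~ r/s, and the
Gompertz curve approximates the Hudson-Kaplan reduction

    f(x) = theta * exp(-u*s / (2s + r*x)^2)

for distances small relative to s/r.

Two comparison curves are provided: a six-parameter Richards generalized
logistic (GLF) and a piecewise linear profile (PLF: flat core, linear ramp,
flat asymptote). All curves are symmetric in position and non-decreasing in
|i| for valid parameters.

Each curve is also exposed as a scikit-learn regressor fitting its
parameters to (position, diversity) data by bounded weighted least squares.
Because every curve depends on position only through |i|, the weighted
objective collapses exactly onto per-distance sufficient statistics
(sum of w, of w*y and of w*y^2 at each distinct distance), so the fit cost
is independent of how many loci contributed observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import NotFittedError

from .errors import ParameterError

#: Shared optimizer settings: trust-region constrained minimization.
OPTIMIZER_OPTIONS = {"gtol": 1e-14, "xtol": 1e-14, "barrier_tol": 1e-14, "maxiter": 10_000}


# ---------------------------------------------------------------------------
# parameter containers and plain evaluation functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GompertzParams:
    theta: float  # asymptotic diversity (the theta estimate)
    beta: float  # core depression depth, ~ u/4s
    gamma: float  # recovery rate per bp, ~ r/s


@dataclass(frozen=True)
class HKParams:
    """Hudson-Kaplan background-selection parameters (u, r << s assumed)."""

    theta: float
    u: float  # deleterious mutation rate per bp
    s: float  # selection coefficient
    r: float  # recombination rate per bp


@dataclass(frozen=True)
class GLFParams:
    """Richards generalized logistic in |i| (six parameters)."""

    A: float  # lower asymptote
    K: float  # upper asymptote (the theta estimate)
    B: float  # growth rate
    Q: float  # shift
    nu: float  # asymmetry
    M: float  # location


@dataclass(frozen=True)
class PLFParams:
    """Flat core, linear ramp on (c, d), flat asymptote beyond d."""

    core_level: float
    asymptote: float  # the theta estimate
    core_halfwidth: float  # c
    ramp_end: float  # d > c


def gompertz_eval(i, p: GompertzParams):
    """theta * exp(-beta * exp(-gamma |i|)); symmetric in i."""
    d = np.abs(np.asarray(i, dtype=float))
    out = p.theta * np.exp(-p.beta * np.exp(-p.gamma * d))
    return out if out.ndim else float(out)


def hk_eval(x, p: HKParams):
    """theta * exp(-u*s / (2s + r*x)^2) at distance x >= 0.

    Algebraically equal to theta * exp(-(u/4s) * (1 + r*x/2s)^-2).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ParameterError("distance x must be >= 0")
    out = p.theta * np.exp(-p.u * p.s / (2 * p.s + p.r * x) ** 2)
    return out if out.ndim else float(out)


def glf_eval(i, p: GLFParams):
    """A + (K - A) / (1 + Q exp(-B(|i| - M)))^(1/nu); symmetric in i."""
    if p.nu <= 0:
        raise ParameterError(f"GLF asymmetry nu must be > 0, got {p.nu}")
    d = np.abs(np.asarray(i, dtype=float))
    out = p.A + (p.K - p.A) / (1.0 + p.Q * np.exp(-p.B * (d - p.M))) ** (1.0 / p.nu)
    return out if out.ndim else float(out)


def plf_eval(i, p: PLFParams):
    """Piecewise linear: core_level up to c, ramp on (c, d), asymptote beyond."""
    if p.ramp_end <= p.core_halfwidth:
        raise ParameterError(
            f"PLF ramp_end ({p.ramp_end}) must exceed core_halfwidth ({p.core_halfwidth})"
        )
    d = np.abs(np.asarray(i, dtype=float))
    frac = np.clip((d - p.core_halfwidth) / (p.ramp_end - p.core_halfwidth), 0.0, 1.0)
    out = p.core_level + (p.asymptote - p.core_level) * frac
    out = np.where(frac >= 1.0, p.asymptote, out)  # exact on the flat segment
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# scikit-learn regressors
# ---------------------------------------------------------------------------


def _as_distances(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be 1-D positions or a single-column 2-D array")
    return np.abs(X)


class SymmetricCurveRegressor(RegressorMixin, BaseEstimator):
    """Base: weighted least-squares fit of a symmetric curve f(|i|; params).

    Subclasses define the parameter names, defaults and the curve (plus an
    analytic parameter gradient where available). ``fit`` minimizes

        sum_m w_m (f(|x_m|) - y_m)^2

    with a bounded trust-region optimizer, after exact reduction to
    per-distance sufficient statistics. Parameters may be pinned with
    ``fixed`` (name -> value), e.g. the reduced PLF variant.
    """

    _names: tuple[str, ...] = ()
    _theta_name: str = "theta"
    _params_cls = None

    def __init__(self, x0=None, bounds=None, fixed=None):
        self.x0 = x0
        self.bounds = bounds
        self.fixed = fixed

    # subclass API ---------------------------------------------------------
    def _default_x0(self) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _default_bounds(self) -> tuple[np.ndarray, np.ndarray]:  # pragma: no cover
        raise NotImplementedError

    def _curve(self, d: np.ndarray, p: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _curve_grad(self, d: np.ndarray, p: np.ndarray):
        """(n_params, n_distances) analytic gradient, or None for 2-point."""
        return None

    def _param_scale(self) -> np.ndarray:
        """Characteristic magnitude per parameter; the optimizer works on
        parameters divided by this, so its stopping tolerances are
        comparable across parameters of very different size."""
        return np.ones(len(self._names))

    # ----------------------------------------------------------------------
    def fit(self, X, y, sample_weight=None):
        """Fit curve parameters to positions ``X`` and diversities ``y``."""
        d = _as_distances(X)
        y = np.asarray(y, dtype=float)
        if y.shape != d.shape:
            raise ValueError("X and y have mismatched lengths")
        if sample_weight is None:
            w = np.ones_like(y)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if w.shape != y.shape or np.any(w < 0):
                raise ValueError("sample_weight must be non-negative, same length as y")
        ud, inv = np.unique(d, return_inverse=True)
        A = np.bincount(inv, weights=w)
        B = np.bincount(inv, weights=w * y)
        C = np.bincount(inv, weights=w * y * y)
        keep = A > 0
        ud, A, B, C = ud[keep], A[keep], B[keep], C[keep]
        if len(ud) == 0:
            raise ValueError("all observations have zero weight")
        # optimize on a total-weight-normalized scale so the stopping
        # tolerances mean the same thing whatever the data size; the argmin
        # is unchanged and the reported objective is rescaled back
        scale = float(A.sum())
        A, B, C = A / scale, B / scale, C / scale

        x0_full = np.asarray(self.x0 if self.x0 is not None else self._default_x0(), float)
        lo_full, hi_full = (
            (np.asarray(b, float) for b in self.bounds)
            if self.bounds is not None
            else self._default_bounds()
        )
        lo_full, hi_full = np.asarray(lo_full, float), np.asarray(hi_full, float)

        fixed = dict(self.fixed or {})
        unknown = set(fixed) - set(self._names)
        if unknown:
            raise ParameterError(f"unknown fixed parameter(s): {sorted(unknown)}")
        free = np.array([name not in fixed for name in self._names])
        full = x0_full.copy()
        for name, val in fixed.items():
            full[self._names.index(name)] = val

        pscale = self._param_scale()

        def expand(z_free: np.ndarray) -> np.ndarray:
            v = full.copy()
            v[free] = z_free * pscale[free]
            return v

        def objective(z_free: np.ndarray) -> float:
            f = self._curve(ud, expand(z_free))
            return float(np.sum(A * f * f - 2.0 * B * f + C))

        grad_available = self._curve_grad(ud, x0_full) is not None

        def gradient(z_free: np.ndarray) -> np.ndarray:
            p = expand(z_free)
            f = self._curve(ud, p)
            g = self._curve_grad(ud, p)
            return (2.0 * (A * f - B) * g).sum(axis=1)[free] * pscale[free]

        with warnings.catch_warnings():
            # benign quasi-Newton bookkeeping notice on flat objective regions
            warnings.filterwarnings("ignore", message="delta_grad == 0.0")
            res = minimize(
                objective,
                x0_full[free] / pscale[free],
                jac=gradient if grad_available else "2-point",
                method="trust-constr",
                bounds=Bounds(lo_full[free] / pscale[free], hi_full[free] / pscale[free]),
                options=OPTIMIZER_OPTIONS,
            )
        p_hat = expand(res.x)
        self.coef_ = dict(zip(self._names, p_hat.tolist()))
        self.params_ = self._params_cls(**self.coef_)
        self.theta_ = float(self.coef_[self._theta_name])
        self.objective_ = float(res.fun) * scale
        self.initial_objective_ = objective(x0_full[free] / pscale[free]) * scale
        self.converged_ = bool(res.status in (1, 2))
        self.n_iter_ = int(res.niter)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Evaluate the fitted curve at positions ``X``."""
        if not hasattr(self, "params_"):
            raise NotFittedError(f"{type(self).__name__} is not fitted")
        d = _as_distances(X)
        return self._curve(d, np.array([self.coef_[n] for n in self._names]))


class GompertzRegressor(SymmetricCurveRegressor):
    """Gompertz diversity curve theta * exp(-beta exp(-gamma |i|)).

    Defaults follow the standard settings for diversity near conserved
    elements: initials (0.001, 10, 0.009) and bounds theta in [0, 0.05],
    beta in [0.1, 30], gamma in [0.004, 0.03] per bp — theta within a
    population is generally small (often < 0.01), and the beta/gamma ranges
    keep the curve transitioning smoothly within realistic flank lengths.
    """

    _names = ("theta", "beta", "gamma")
    _theta_name = "theta"
    _params_cls = GompertzParams

    def _default_x0(self):
        return np.array([0.001, 10.0, 0.009])

    def _default_bounds(self):
        return np.array([0.0, 0.1, 0.004]), np.array([0.05, 30.0, 0.03])

    def _param_scale(self):
        return np.array([0.01, 10.0, 0.01])

    def _curve(self, d, p):
        theta, beta, gamma = p
        return theta * np.exp(-beta * np.exp(-gamma * d))

    def _curve_grad(self, d, p):
        theta, beta, gamma = p
        e = np.exp(-gamma * d)
        base = np.exp(-beta * e)
        f = theta * base
        return np.stack([base, -f * e, f * beta * d * e])


class HKRegressor(SymmetricCurveRegressor):
    """Hudson-Kaplan curve fit in its identifiable (theta, beta, gamma) form.

    f(|i|) = theta * exp(-beta * (1 + gamma |i| / 2)^-2) with beta = u/4s
    and gamma = r/s; u, s and r are not separately identifiable from the
    curve shape. Shares the Gompertz initials and bounds, since beta and
    gamma carry the same interpretation.
    """

    _names = ("theta", "beta", "gamma")
    _theta_name = "theta"
    _params_cls = GompertzParams

    def _default_x0(self):
        return np.array([0.001, 10.0, 0.009])

    def _default_bounds(self):
        return np.array([0.0, 0.1, 0.004]), np.array([0.05, 30.0, 0.03])

    def _param_scale(self):
        return np.array([0.01, 10.0, 0.01])

    def _curve(self, d, p):
        theta, beta, gamma = p
        return theta * np.exp(-beta / (1.0 + gamma * d / 2.0) ** 2)

    def _curve_grad(self, d, p):
        theta, beta, gamma = p
        P = 1.0 + gamma * d / 2.0
        base = np.exp(-beta / P**2)
        f = theta * base
        return np.stack([base, -f / P**2, f * beta * d / P**3])


class GeneralizedLogisticRegressor(SymmetricCurveRegressor):
    """Six-parameter Richards generalized logistic comparison model.

    More flexible than Gompertz but harder to fit: with limited flanks its
    six parameters are weakly identified and estimates can be erratic.
    Initials and bounds are package defaults (A=0, K=0.001, B=0.009, Q=1,
    nu=1, M=100; asymptotes bounded like theta, rate like gamma).
    """

    _names = ("A", "K", "B", "Q", "nu", "M")
    _theta_name = "K"
    _params_cls = GLFParams

    def _default_x0(self):
        return np.array([0.0, 0.001, 0.009, 1.0, 1.0, 100.0])

    def _default_bounds(self):
        return (
            np.array([0.0, 0.0, 1e-3, 1e-2, 0.05, 0.0]),
            np.array([0.05, 0.05, 0.1, 100.0, 20.0, 2000.0]),
        )

    def _param_scale(self):
        return np.array([0.01, 0.01, 0.01, 1.0, 1.0, 100.0])

    def _curve(self, d, p):
        A, K, B, Q, nu, M = p
        return A + (K - A) / (1.0 + Q * np.exp(-B * (d - M))) ** (1.0 / nu)


class PiecewiseLinearRegressor(SymmetricCurveRegressor):
    """Piecewise linear comparison model (flat core, ramp, flat asymptote).

    Fit parameters: core_level, asymptote, core halfwidth c and ramp width
    (ramp ends at c + width, guaranteeing d > c). The reported theta is the
    asymptote. A reduced variant pins the core at zero, e.g.::

        PiecewiseLinearRegressor(fixed={"core_level": 0.0, "core_halfwidth": 60.0})
    """

    _names = ("core_level", "asymptote", "core_halfwidth", "ramp_width")
    _theta_name = "asymptote"

    @staticmethod
    def _params_cls(core_level, asymptote, core_halfwidth, ramp_width):
        return PLFParams(core_level, asymptote, core_halfwidth, core_halfwidth + ramp_width)

    def _default_x0(self):
        return np.array([0.0, 0.001, 50.0, 400.0])

    def _default_bounds(self):
        return np.array([0.0, 0.0, 0.0, 1.0]), np.array([0.05, 0.05, 1500.0, 2000.0])

    def _param_scale(self):
        return np.array([0.01, 0.01, 100.0, 100.0])

    def _curve(self, d, p):
        h, t, c, width = p
        frac = np.clip((d - c) / width, 0.0, 1.0)
        return h + (t - h) * frac

    def _curve_grad(self, d, p):
        h, t, c, width = p
        raw = (d - c) / width
        frac = np.clip(raw, 0.0, 1.0)
        on_ramp = (raw > 0.0) & (raw < 1.0)
        return np.stack(
            [
                1.0 - frac,
                frac,
                np.where(on_ramp, -(t - h) / width, 0.0),
                np.where(on_ramp, -(t - h) * raw / width, 0.0),
            ]
        )


MODEL_REGISTRY = {
    "gompertz": GompertzRegressor,
    "glf": GeneralizedLogisticRegressor,
    "plf": PiecewiseLinearRegressor,
    "hk": HKRegressor,
}


def make_regressor(model: str, **kwargs) -> SymmetricCurveRegressor:
    """Instantiate a curve regressor by selector string (gompertz|glf|plf|hk)."""
    try:
        cls = MODEL_REGISTRY[model]
    except KeyError:
        raise ParameterError(
            f"unknown model {model!r}; choose from {sorted(MODEL_REGISTRY)}"
        ) from None
    return cls(**kwargs)
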