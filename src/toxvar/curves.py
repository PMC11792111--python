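"""Dose–response curves: the Hill equation, low-dimensional penalized smooths,
and the critical-consumption threshold model.

All curves are evaluated on a declared *link* scale (identity for relative
growth rate, logit for proportion herbivory). The central object is
:class:`DoseResponseCurve`, a thin tagged union over the supported functional
forms; everything downstream (Jensen effects, the variance-effect
decomposition) only needs ``evaluate_curve`` and ``jensen_potential``.

The smooth form is a natural cubic regression spline on log dose with at most
four basis functions plus an intercept (knots at quantiles of the log-dose
design), ridge-penalized on integrated squared curvature with the penalty
weight chosen by generalized cross-validation. Linear functions of log dose
lie in the penalty null space, so data that are exactly linear on that scale
are reproduced exactly. Uncertainty is carried as a Gaussian approximation at
the penalized optimum (mean = coefficients, covariance =
sigma^2 (X'X + lambda*P)^-1), from which reproducible curve realizations are
drawn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

from ._exceptions import (
    DomainError,
    ExtrapolationWarning,
    FitError,
    NonDifferentiableCurveError,
)

__all__ = [
    "HillParams",
    "SmoothCurveFit",
    "DoseResponseCurve",
    "CriticalThresholdModel",
    "evaluate_curve",
    "jensen_potential",
    "fit_smooth_curve",
    "sample_curve_draws",
    "critical_consumption",
]


@dataclass(frozen=True)
class HillParams:
    """Parameters of the Hill equation f(x) = e0 + (emax - e0) x^n / (x^n + ec50^n).

    ``e0`` and ``emax`` are the zero-dose and saturating responses on the link
    scale; ``ec50`` (nmol/mg) is the half-maximal dose; ``n`` is the Hill
    coefficient controlling steepness.
    """

    e0: float
    emax: float
    ec50: float
    n: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.e0) and np.isfinite(self.emax)):
            raise DomainError("e0 and emax must be finite")
        if not (self.ec50 > 0 and np.isfinite(self.ec50)):
            raise DomainError(f"ec50 must be a positive real, got {self.ec50}")
        if not (self.n > 0 and np.isfinite(self.n)):
            raise DomainError(f"Hill coefficient n must be positive, got {self.n}")


@dataclass(frozen=True)
class CriticalThresholdModel:
    """Critical toxin accumulation k_crit (nmol) beyond which the herbivore is
    poisoned; consumption is measured in mg leaf fresh weight."""

    k_crit: float

    def __post_init__(self) -> None:
        if not (self.k_crit > 0 and np.isfinite(self.k_crit)):
            raise DomainError(f"k_crit must be positive, got {self.k_crit}")


class LogDoseSplineBasis:
    """Natural cubic regression spline basis on natural-log dose.

    The classic "cr"-type construction: with K knots the basis has K columns
    — intercept, the linear term, and K-2 curvature functions built from
    truncated cubes with the natural (linear-beyond-boundary) constraints —
    so ``n_basis = K - 1`` non-intercept degrees of freedom. Knots default to
    equally spaced quantiles of the fitted log doses. Beyond the boundary
    knots the spline continues linearly, which also defines the extrapolation
    behaviour outside the fitted dose range. The curvature penalty matrix
    integrates products of second derivatives over the knot span; its null
    space is exactly {constant, linear in log dose}.
    """

    def __init__(self, dose_range: tuple[float, float], n_basis: int = 4,
                 knots: Sequence[float] | None = None):
        lo, hi = float(dose_range[0]), float(dose_range[1])
        if not (0 < lo < hi):
            raise DomainError("dose_range must satisfy 0 < lo < hi")
        self.dose_range = (lo, hi)
        if knots is None:
            if n_basis < 1:
                raise FitError("n_basis must be >= 1")
            self.knots = np.linspace(np.log(lo), np.log(hi), int(n_basis) + 1)
        else:
            self.knots = np.sort(np.asarray(knots, dtype=float))
            if self.knots.size < 2 or np.unique(self.knots).size != self.knots.size:
                raise FitError("need >= 2 distinct knots")
        self.n_cols = self.knots.size

    @classmethod
    def from_doses(cls, doses: np.ndarray, n_basis: int = 4) -> "LogDoseSplineBasis":
        """Knots at equally spaced quantiles of the observed log doses."""
        z = np.log(np.asarray(doses, dtype=float))
        q = np.quantile(z, np.linspace(0.0, 1.0, int(n_basis) + 1))
        q = np.unique(q)
        return cls((float(np.exp(z.min())), float(np.exp(z.max()))), knots=q)

    def _d(self, k: int, z: np.ndarray, nu: int = 0) -> np.ndarray:
        # d_k(z) = [(z - xi_k)_+^3 - (z - xi_K)_+^3] / (xi_K - xi_k), or its
        # nu-th derivative; building block of the natural-spline basis
        xiK = self.knots[-1]
        xik = self.knots[k]
        a = np.maximum(z - xik, 0.0)
        b = np.maximum(z - xiK, 0.0)
        if nu == 0:
            num = a**3 - b**3
        elif nu == 1:
            num = 3.0 * (a**2 - b**2)
        elif nu == 2:
            num = 6.0 * (a - b)
        else:
            raise DomainError(f"unsupported derivative order {nu}")
        return num / (xiK - xik)

    def _design_z(self, z: np.ndarray, nu: int = 0) -> np.ndarray:
        K = self.n_cols
        if nu == 0:
            cols = [np.ones_like(z), z]
        elif nu == 1:
            cols = [np.zeros_like(z), np.ones_like(z)]
        else:
            cols = [np.zeros_like(z), np.zeros_like(z)]
        for k in range(K - 2):
            cols.append(self._d(k, z, nu) - self._d(K - 2, z, nu))
        return np.column_stack(cols)

    def design(self, dose: np.ndarray) -> np.ndarray:
        """Basis design matrix at raw doses (natural linear extension beyond
        the boundary knots)."""
        z = np.log(np.asarray(dose, dtype=float))
        return self._design_z(z)

    def curvature_penalty(self) -> np.ndarray:
        """Gram matrix of second derivatives, exact by Gauss–Legendre per
        knot interval (second derivatives are piecewise linear)."""
        nodes, wts = leggauss(3)
        P = np.zeros((self.n_cols, self.n_cols))
        for a, b in zip(self.knots[:-1], self.knots[1:]):
            zm, zr = (a + b) / 2.0, (b - a) / 2.0
            zz = zm + zr * nodes
            D2 = self._design_z(zz, nu=2)
            P += zr * (D2.T * wts) @ D2
        return P

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, LogDoseSplineBasis)
                and np.array_equal(self.knots, other.knots))

    def __hash__(self) -> int:
        return hash(self.knots.tobytes())


@dataclass
class SmoothCurveFit:
    """A penalized-smooth fit on log dose with its Gaussian uncertainty."""

    basis: LogDoseSplineBasis
    coefficients: np.ndarray
    coefficient_covariance: np.ndarray
    link: str
    dose_range: tuple[float, float]
    penalty: float = 0.0
    sigma2: float = float("nan")
    edf: float = float("nan")
    fd_step_frac: float = 1e-4

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        C = np.asarray(self.coefficient_covariance, dtype=float)
        if C.shape != (self.coefficients.size, self.coefficients.size):
            raise DomainError("covariance shape does not match coefficients")
        if not np.allclose(C, C.T, atol=1e-10):
            raise DomainError("coefficient covariance must be symmetric")
        self.coefficient_covariance = (C + C.T) / 2.0


@dataclass
class DoseResponseCurve:
    """Tagged union over curve forms: ``hill``, ``smooth``, ``linear``,
    ``tabulated``. ``linear`` parameters are ``(intercept, slope)`` on raw
    dose; ``tabulated`` is ``(x, y)`` with linear interpolation."""

    form: str
    parameters: object
    link: str = "identity"

    @classmethod
    def hill(cls, e0: float, emax: float, ec50: float, n: float,
             link: str = "identity") -> "DoseResponseCurve":
        return cls("hill", HillParams(e0, emax, ec50, n), link)

    @classmethod
    def linear(cls, intercept: float, slope: float,
               link: str = "identity") -> "DoseResponseCurve":
        return cls("linear", (float(intercept), float(slope)), link)

    @classmethod
    def from_smooth_fit(cls, fit: SmoothCurveFit,
                        coefficients: np.ndarray | None = None) -> "DoseResponseCurve":
        if coefficients is not None:
            fit = SmoothCurveFit(fit.basis, np.asarray(coefficients, float),
                                 np.zeros((fit.basis.n_cols, fit.basis.n_cols)),
                                 fit.link, fit.dose_range,
                                 penalty=fit.penalty, fd_step_frac=fit.fd_step_frac)
        return cls("smooth", fit, fit.link)

    @classmethod
    def tabulated(cls, x: Sequence[float], y: Sequence[float],
                  link: str = "identity") -> "DoseResponseCurve":
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.ndim != 1 or x.shape != y.shape or np.any(np.diff(x) <= 0):
            raise DomainError("tabulated curve needs strictly increasing x")
        return cls("tabulated", (x, y), link)

    @property
    def dose_range(self) -> tuple[float, float] | None:
        if self.form == "smooth":
            return self.parameters.dose_range
        if self.form == "tabulated":
            x, _ = self.parameters
            return (float(x[0]), float(x[-1]))
        return None

    def __call__(self, x, **kwargs):
        return evaluate_curve(self, x, **kwargs)


def _hill_value(p: HillParams, x: np.ndarray) -> np.ndarray:
    # (x/ec50)^n parameterization is overflow-safe for large doses
    with np.errstate(divide="ignore"):
        r = np.power(x / p.ec50, p.n)
    g = r / (1.0 + r)
    g = np.where(np.isinf(r), 1.0, g)
    return p.e0 + (p.emax - p.e0) * g


def _hill_d2(p: HillParams, x: np.ndarray) -> np.ndarray:
    """Analytic second derivative of the Hill form.

    f''(x) = (emax-e0) * c^n * n * x^(n-2) * ((n-1)(x^n + c^n) - 2 n x^n)
             / (x^n + c^n)^3, written in the overflow-safe ratio r = (x/c)^n.
    """
    x = np.asarray(x, dtype=float)
    c, n = p.ec50, p.n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.power(x / c, n)
        num = n * np.power(x, n - 2.0) / c**2 * ((n - 1.0) * (1.0 + r) - 2.0 * n * r)
        d2 = (p.emax - p.e0) * num / (c ** (n - 2.0) * (1.0 + r) ** 3)
    # x -> 0 limits: the leading term is dl*n*(n-1)*x^(n-2)/c^n (dl = emax-e0),
    # which vanishes for n > 2, is finite for n = 2, and diverges for n in
    # (1, 2) u (0, 1); at n = 1 that term is zero and the next order gives
    # -2*dl/c^2.
    if np.any(x == 0):
        dl = p.emax - p.e0
        if n > 2:
            at0 = 0.0
        elif n == 2:
            at0 = 2.0 * dl / c**2
        elif n == 1:
            at0 = -2.0 * dl / c**2
        else:
            at0 = np.inf * np.sign(dl * (n - 1.0)) if dl != 0 else 0.0
        d2 = np.where(x == 0, at0, d2)
    d2 = np.where(np.isinf(r), 0.0, d2)
    return d2


def evaluate_curve(curve: DoseResponseCurve, x, *, warn_extrapolation: bool = True):
    """Evaluate f(x) on the curve's link scale.

    Doses must be nonnegative. Smooth and tabulated curves evaluated beyond
    their fitted dose range return the boundary extension and emit an
    :class:`ExtrapolationWarning` (once per call).
    """
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    if np.any(x_arr < 0) or np.any(~np.isfinite(x_arr)):
        raise DomainError("doses must be finite and nonnegative")

    if curve.form == "hill":
        y = _hill_value(curve.parameters, x_arr)
    elif curve.form == "linear":
        b0, b1 = curve.parameters
        y = b0 + b1 * x_arr
    elif curve.form == "smooth":
        fit: SmoothCurveFit = curve.parameters
        lo, hi = fit.dose_range
        if warn_extrapolation and np.any((x_arr < lo) | (x_arr > hi)):
            warnings.warn(
                f"evaluating smooth curve outside fitted dose range [{lo:g}, {hi:g}]",
                ExtrapolationWarning, stacklevel=2)
        if np.any(x_arr == 0):
            raise DomainError("smooth curves on log dose are undefined at dose 0")
        y = fit.basis.design(x_arr) @ fit.coefficients
    elif curve.form == "tabulated":
        xs, ys = curve.parameters
        if warn_extrapolation and np.any((x_arr < xs[0]) | (x_arr > xs[-1])):
            warnings.warn("evaluating tabulated curve outside its support",
                          ExtrapolationWarning, stacklevel=2)
        y = np.interp(x_arr, xs, ys)
    else:
        raise DomainError(f"unknown curve form {curve.form!r}")
    return float(y[0]) if scalar else y


def jensen_potential(curve: DoseResponseCurve, x, *, fd_step: float | None = None):
    """Second derivative f''(x) — the local Jensen's-effect potential.

    Positive where the curve is convex (variability raises the mean response),
    negative where concave. Analytic for Hill and linear forms; central finite
    differences for smooths, with step ``fd_step`` (default: the fit's
    ``fd_step_frac`` times the dose-range width).
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    scalar = np.ndim(x) == 0
    if curve.form == "hill":
        y = _hill_d2(curve.parameters, x_arr)
    elif curve.form == "linear":
        y = np.zeros_like(x_arr)
    elif curve.form == "smooth":
        fit: SmoothCurveFit = curve.parameters
        lo, hi = fit.dose_range
        h = fd_step if fd_step is not None else fit.fd_step_frac * (hi - lo)
        f = lambda t: evaluate_curve(curve, t, warn_extrapolation=False)
        y = (f(x_arr + h) - 2.0 * f(x_arr) + f(np.maximum(x_arr - h, 1e-300))) / h**2
    else:
        raise NonDifferentiableCurveError(
            f"no second derivative for curve form {curve.form!r}")
    return float(y[0]) if scalar else y


def fit_smooth_curve(doses, responses, max_basis: int = 4, link: str = "identity",
                     penalty: float | None = None,
                     fd_step_frac: float = 1e-4) -> SmoothCurveFit:
    """Fit a curvature-penalized B-spline to link-scale responses on log dose.

    Parameters
    ----------
    doses, responses
        Strictly positive doses (nmol/mg) and responses already on the link
        scale. At least ``max_basis + 2`` observations are required.
    max_basis
        Maximum number of basis functions beyond the intercept (default 4,
        guarding against overfit second derivatives).
    penalty
        Curvature-penalty weight lambda. ``None`` (default) selects it by
        generalized cross-validation on a fixed log-spaced grid, which keeps
        the fit deterministic for identical inputs.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise FitError("doses and responses must be 1-d and equal length")
    if np.any(x <= 0):
        raise DomainError("doses must be strictly positive for log-dose smoothing")
    if not np.all(np.isfinite(y)):
        raise FitError("responses must be finite")
    if x.size < max_basis + 2:
        raise FitError(f"need at least {max_basis + 2} points, got {x.size}")
    if np.unique(x).size < 2:
        raise FitError("all doses identical: design is rank deficient")

    basis = LogDoseSplineBasis.from_doses(x, n_basis=max_basis)
    B = basis.design(x)
    P = basis.curvature_penalty()
    BtB = B.T @ B
    Bty = B.T @ y
    n = x.size

    if penalty is None:
        # normalize the grid so lambda is comparable across data scales
        scale = np.trace(BtB) / max(np.trace(P), 1e-300)
        grid = scale * np.logspace(-8.0, 4.0, 49)
        best = (np.inf, grid[0])
        for lam in grid:
            A = BtB + lam * P
            try:
                coef = np.linalg.solve(A, Bty)
            except np.linalg.LinAlgError:
                continue
            fitted = B @ coef
            rss = float(np.sum((y - fitted) ** 2))
            edf = float(np.trace(np.linalg.solve(A, BtB)))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if gcv < best[0] - 1e-12 * abs(best[0]):
                best = (gcv, lam)
        lam = best[1]
    else:
        lam = float(penalty)

    A = BtB + lam * P
    coef = np.linalg.solve(A, Bty)
    fitted = B @ coef
    rss = float(np.sum((y - fitted) ** 2))
    edf = float(np.trace(np.linalg.solve(A, BtB)))
    sigma2 = rss / max(n - edf, 1.0)
    Ainv = np.linalg.inv(A)
    cov = sigma2 * (Ainv + Ainv.T) / 2.0
    return SmoothCurveFit(basis=basis, coefficients=coef,
                          coefficient_covariance=cov, link=link,
                          dose_range=(float(x.min()), float(x.max())),
                          penalty=lam, sigma2=sigma2, edf=edf,
                          fd_step_frac=fd_step_frac)


def sample_curve_draws(fit: SmoothCurveFit, n_draws: int,
                       seed: int | np.random.Generator) -> list[DoseResponseCurve]:
    """Draw curve realizations from the Gaussian approximation at the optimum.

    Returns ``n_draws`` smooth curves sharing the fit's basis, with
    coefficient vectors sampled from N(coefficients, coefficient_covariance).
    Reproducible for a given integer seed.
    """
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    C = fit.coefficient_covariance
    eig = np.linalg.eigvalsh(C)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise DomainError("coefficient covariance is not positive semi-definite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.coefficients, C, size=n_draws, method="svd")
    return [DoseResponseCurve.from_smooth_fit(fit, coefficients=d) for d in draws]


def critical_consumption(model: CriticalThresholdModel, x):
    """Critical leaf consumption m*(x) = k_crit / x (mg fresh weight).

    The leaf mass at which cumulative toxin intake at concentration ``x``
    reaches the poisoning threshold; strictly decreasing in dose, so marginal
    sensitivity |dm*/dx| = k_crit/x^2 shrinks as the mean dose rises.
    """
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr <= 0):
        raise DomainError("dose must be strictly positive")
    out = model.k_crit / x_arr
    return float(out[0]) if np.ndim(x) == 0 else out
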