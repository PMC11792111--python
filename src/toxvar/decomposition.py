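"""Counterfactual variance-effect decomposition.

Given a dose–response function f on a link scale, an observed dietary dose
distribution X_o (with selective feeding) and a counterfactual reference
distribution X_r (selectivity removed), the marginal effect of dose
variability splits into

    Jr := E[f(X_r)] - f(E[X_r])        nonlinear averaging (Jensen) effect
    S  := f(E[X_o]) - f(E[X_r])        selective feeding (mean-shift) effect
    JS := E[f(X_o)] - f(E[X_o]) - Jr   their interaction
    T^ := Jr + S + JS = E[f(X_o)] - f(E[X_r])   predicted total effect

and the residual eps := T_o - T^, where T_o is the observed total effect of
the variability treatment (standardized arm difference). Uncertainty in f and
in the preference weights is propagated by a full Cartesian cross of curve
draws and preference draws (default 500 x 500 = 250,000
simulations) and summarized by means and equal-tailed 89% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._exceptions import DataError, DomainError, ExtrapolationError
from .curves import DoseResponseCurve, evaluate_curve
from .dietary import DiscreteDoseDistribution, build_reference_distribution
from .preference import PreferenceEstimate, _logit, _shrink

__all__ = [
    "DecompositionTerms",
    "DecompositionResult",
    "ObservedTotalEffect",
    "expected_response",
    "jensen_effect",
    "decompose",
    "observed_total_effect",
    "monte_carlo_decompose",
    "standardize_result",
    "fraction_of_predicted",
    "link_transform",
]

QUANTITIES = ("jr", "s", "js", "t_hat", "t_obs", "eps")

#: link convention per response: RGR on identity, herbivory on log-odds
RESPONSE_LINKS = {"rgr": "identity", "herbivory": "logit"}
RESPONSE_COLUMNS = {"rgr": "rgr_per_h", "herbivory": "herbivory_prop"}


def _check_support(curve: DoseResponseCurve, d: DiscreteDoseDistribution,
                   allow_extrapolation: bool) -> None:
    rng = curve.dose_range
    if rng is None or allow_extrapolation:
        return
    lo, hi = rng
    if np.any((d.support < lo) | (d.support > hi)):
        raise ExtrapolationError(
            f"distribution support {d.support} outside fitted dose range "
            f"[{lo:g}, {hi:g}]; pass allow_extrapolation=True to override")


def expected_response(curve: DoseResponseCurve, d: DiscreteDoseDistribution,
                      *, allow_extrapolation: bool = False) -> float:
    """E[f(X)]: exact probability-weighted sum of the curve over the support."""
    _check_support(curve, d, allow_extrapolation)
    return float(d.probs @ evaluate_curve(curve, d.support,
                                          warn_extrapolation=False))


def jensen_effect(curve: DoseResponseCurve, d: DiscreteDoseDistribution,
                  *, allow_extrapolation: bool = False) -> float:
    """E[f(X)] - f(E[X]); zero for linear f, sign tracks local convexity."""
    _check_support(curve, d, allow_extrapolation)
    ef = expected_response(curve, d, allow_extrapolation=True)
    fe = evaluate_curve(curve, d.mean, warn_extrapolation=False)
    return ef - fe


class DecompositionTerms(NamedTuple):
    jr: float
    s: float
    js: float
    t_hat: float


def decompose(curve: DoseResponseCurve, xo: DiscreteDoseDistribution,
              xr: DiscreteDoseDistribution, *,
              allow_extrapolation: bool = False) -> DecompositionTerms:
    """Point decomposition (Jr, S, JS, T^) for a single curve and (X_o, X_r)."""
    _check_support(curve, xo, allow_extrapolation)
    _check_support(curve, xr, allow_extrapolation)
    f_exo = evaluate_curve(curve, xo.mean, warn_extrapolation=False)
    f_exr = evaluate_curve(curve, xr.mean, warn_extrapolation=False)
    jr = expected_response(curve, xr, allow_extrapolation=True) - f_exr
    s = f_exo - f_exr
    js = expected_response(curve, xo, allow_extrapolation=True) - f_exo - jr
    return DecompositionTerms(jr, s, js, jr + s + js)


@dataclass
class ObservedTotalEffect:
    """Observed total effect of the variability treatment, T_o.

    ``estimate`` is the variable-minus-constant arm difference of mean
    link-scale response divided by the pooled within-arm SD (``sd_link``);
    ``draws`` are cage-level bootstrap draws of the same standardized
    quantity (the SD is held at its point estimate so standardization is a
    fixed rescaling). ``estimate_link``/``draws_link`` are the unstandardized
    versions used when decomposition terms are still on the link scale.
    """

    estimate: float
    draws: np.ndarray
    sd_link: float
    response: str = ""
    mean_treatment: str = ""

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if not (self.sd_link > 0):
            raise DomainError("sd_link must be positive")

    @property
    def estimate_link(self) -> float:
        return self.estimate * self.sd_link

    @property
    def draws_link(self) -> np.ndarray:
        return self.draws * self.sd_link


def link_transform(values: np.ndarray, response: str) -> np.ndarray:
    """Map raw responses to their analysis link scale.

    RGR is already on the identity link; herbivory proportions are shrunk off
    the boundary by (p(n-1)+0.5)/n and logit-transformed.
    """
    v = np.asarray(values, dtype=float)
    link = RESPONSE_LINKS.get(response)
    if link is None:
        raise DataError(f"unknown response {response!r}; expected one of "
                        f"{sorted(RESPONSE_LINKS)}")
    if link == "identity":
        return v
    return _logit(_shrink(v, max(v.size, 2)))


def observed_total_effect(cages: pd.DataFrame, response: str,
                          mean_treatment: str, n_draws: int = 500,
                          seed: int = 0, variable_arm: str = "intra"
                          ) -> ObservedTotalEffect:
    """Standardized arm difference (variable minus constant) at one mean level.

    Link-scale responses are compared between the variation and constant
    treatment arms; uncertainty comes from an independent cage-level bootstrap
    within each arm.
    """
    col = RESPONSE_COLUMNS.get(response)
    if col is None or col not in cages.columns:
        raise DataError(f"cage table lacks response column for {response!r}")
    sub = cages.loc[cages["mean_treatment"] == mean_treatment]
    arms = {}
    for arm in ("constant", variable_arm):
        vals = sub.loc[sub["variation_treatment"] == arm, col] \
            .dropna().to_numpy(dtype=float)
        if vals.size < 2:
            raise DataError(
                f"missing or underpowered arm {arm!r} at mean_treatment="
                f"{mean_treatment!r} (n={vals.size})")
        arms[arm] = link_transform(vals, response)
    c, v = arms["constant"], arms[variable_arm]
    n_c, n_v = c.size, v.size
    pooled_var = (((n_c - 1) * c.var(ddof=1) + (n_v - 1) * v.var(ddof=1))
                  / (n_c + n_v - 2))
    sd = float(np.sqrt(pooled_var))
    if sd <= 0:
        raise DataError("pooled link-scale SD is zero; cannot standardize")
    est = float((v.mean() - c.mean()) / sd)
    rng = np.random.default_rng(seed)
    idx_c = rng.integers(0, n_c, size=(n_draws, n_c))
    idx_v = rng.integers(0, n_v, size=(n_draws, n_v))
    draws = (v[idx_v].mean(axis=1) - c[idx_c].mean(axis=1)) / sd
    return ObservedTotalEffect(est, draws, sd, response, mean_treatment)


def _curve_eval_matrix(curves: Sequence[DoseResponseCurve],
                       xs: np.ndarray) -> np.ndarray:
    """Evaluate many curves at many doses -> (n_points, n_curves).

    Curves that share one smooth basis reduce to a single design-matrix
    product; anything else falls back to a per-curve vectorized evaluation.
    """
    first = curves[0]
    if first.form == "smooth":
        basis = first.parameters.basis
        if all(c.form == "smooth" and c.parameters.basis == basis for c in curves):
            C = np.stack([c.parameters.coefficients for c in curves], axis=1)
            return basis.design(np.asarray(xs, float)) @ C
    return np.stack(
        [evaluate_curve(c, xs, warn_extrapolation=False) for c in curves], axis=1)


@dataclass
class DecompositionResult:
    """Draw-level and summarized decomposition.

    ``draws`` has one row per (curve draw x preference draw) with columns
    ``jr, s, js, t_hat, t_obs, eps``; ``summaries`` holds mean and equal-
    tailed interval bounds per quantity at ``ci_level``.
    """

    draws: pd.DataFrame
    ci_level: float = 0.89
    sd_link: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def summaries(self) -> pd.DataFrame:
        a = (1.0 - self.ci_level) / 2.0
        rows = []
        for q in QUANTITIES:
            col = self.draws[q]
            if col.isna().all():
                continue
            rows.append({"quantity": q, "mean": col.mean(),
                         "lower": col.quantile(a), "upper": col.quantile(1 - a)})
        out = pd.DataFrame(rows)
        out.attrs["ci_level"] = self.ci_level
        return out

    def __getattr__(self, name: str):
        if name in QUANTITIES:
            return float(self.draws[name].mean())
        raise AttributeError(name)


def monte_carlo_decompose(curve_draws: Sequence[DoseResponseCurve],
                          pref_draws, mu: float, delta: float,
                          t_obs: ObservedTotalEffect | None = None,
                          ci_level: float = 0.89, *,
                          include_t_obs_uncertainty: bool = True,
                          allow_extrapolation: bool = False
                          ) -> DecompositionResult:
    """Cross curve draws with preference draws and decompose every pair.

    ``pref_draws`` is an (n, 2) array of (low, high) herbivory weights or a
    :class:`PreferenceEstimate` (its bootstrap draws are used). Rows are
    curve-major: for each curve realization the simulation is repeated over
    all preference draws, giving n_curve x n_pref rows (500 x 500 = 250,000
    at the default settings). ``t_obs`` draws are recycled across rows; pass
    ``include_t_obs_uncertainty=False`` to pin T_o at its point estimate.
    All quantities stay on the curve's link scale; standardize afterwards
    with :func:`standardize_result`.
    """
    curve_draws = list(curve_draws)
    if isinstance(pref_draws, PreferenceEstimate):
        pref_draws = pref_draws.draws
    W = np.asarray(pref_draws, dtype=float)
    if W.ndim == 1:
        W = W[None, :]
    if len(curve_draws) == 0 or W.shape[0] == 0:
        raise DomainError("curve and preference draw sequences must be non-empty")
    if W.shape[1] != 2 or np.any(W < 0) or np.any(W.sum(axis=1) <= 0):
        raise DomainError("preference draws must be nonnegative (n, 2) weights")

    xr = build_reference_distribution(mu, delta)
    for c in curve_draws:
        _check_support(c, xr, allow_extrapolation)

    n_curve, n_pref = len(curve_draws), W.shape[0]
    support = xr.support if xr.support.size == 2 else np.array([mu, mu])
    P = W / W.sum(axis=1, keepdims=True)          # (n_pref, 2)
    e_xo = P @ support                            # (n_pref,)

    F_sup = _curve_eval_matrix(curve_draws, support)        # (2, n_curve)
    f_mu = _curve_eval_matrix(curve_draws, np.array([mu]))[0]   # (n_curve,)
    F_exo = _curve_eval_matrix(curve_draws, e_xo)           # (n_pref, n_curve)

    jr = 0.5 * (F_sup[0] + F_sup[1]) - f_mu if delta > 0 else np.zeros(n_curve)
    ef_xo = P @ F_sup                                       # (n_pref, n_curve)
    s = F_exo - f_mu[None, :]
    js = ef_xo - F_exo - jr[None, :]
    t_hat = ef_xo - f_mu[None, :]  # = jr + s + js by construction

    # curve-major flattening: row = curve index slow, preference index fast
    def flat(m):
        return np.broadcast_to(m, (n_pref, n_curve)).T.reshape(-1)

    n_rows = n_curve * n_pref
    if t_obs is not None:
        if include_t_obs_uncertainty and t_obs.draws.size > 0:
            to_col = np.resize(t_obs.draws_link, n_rows)
        else:
            to_col = np.full(n_rows, t_obs.estimate_link)
    else:
        to_col = np.full(n_rows, np.nan)
    t_hat_col = flat(t_hat)
    draws = pd.DataFrame({
        "jr": flat(jr[None, :]), "s": flat(s), "js": flat(js),
        "t_hat": t_hat_col, "t_obs": to_col, "eps": to_col - t_hat_col,
    })
    meta = {"n_curve_draws": n_curve, "n_pref_draws": n_pref,
            "mu": mu, "delta": delta,
            "include_t_obs_uncertainty": include_t_obs_uncertainty}
    return DecompositionResult(draws=draws, ci_level=ci_level, meta=meta)


def standardize_result(result: DecompositionResult,
                       sd_link: float) -> DecompositionResult:
    """Rescale every quantity to standard-deviation units of the link response."""
    if not (sd_link > 0):
        raise DomainError("sd_link must be positive")
    draws = result.draws / sd_link
    meta = dict(result.meta)
    return DecompositionResult(draws=draws, ci_level=result.ci_level,
                               sd_link=sd_link, meta=meta)


def fraction_of_predicted(result: DecompositionResult,
                          tol: float = 1e-12) -> pd.DataFrame:
    """Per-mechanism share of the predicted total T^, in percent.

    Draws with |T^| below ``tol`` are excluded (their shares are undefined);
    the retained shares satisfy jr + s + js = 100 per draw. Shares are ratio
    statistics with heavy tails whenever some draws put T^ near zero, so the
    centre is the median, with equal-tailed quantile bounds. The returned
    frame carries the exclusion count in ``attrs["n_excluded"]``.
    """
    t = result.draws["t_hat"].to_numpy()
    keep = np.abs(t) >= tol
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise DataError("all draws have |t_hat| below tolerance; shares undefined")
    a = (1.0 - result.ci_level) / 2.0
    rows = []
    for q in ("jr", "s", "js"):
        share = 100.0 * result.draws[q].to_numpy()[keep] / t[keep]
        rows.append({"quantity": q, "median": float(np.median(share)),
                     "lower": np.quantile(share, a),
                     "upper": np.quantile(share, 1 - a)})
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["ci_level"] = result.ci_level
    return out
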