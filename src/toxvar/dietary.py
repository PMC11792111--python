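"""Discrete dietary-dose distributions.

The experimental design exposes a caterpillar to two leaf dose levels,
mu - delta and mu + delta (nmol/mg). Without selective feeding the ingested
dose X_r puts equal weight on both levels; with selective feeding the
observed dietary distribution X_o reweights them by the herbivore's measured
per-dose herbivory. Both live here as finite distributions with exact
moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import DomainError

__all__ = [
    "DiscreteDoseDistribution",
    "build_reference_distribution",
    "build_observed_distribution",
    "distribution_moments",
]

_PROB_TOL = 1e-12


@dataclass(frozen=True)
class DiscreteDoseDistribution:
    """Finite support of dose values (nmol/mg) with probability weights."""

    support: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if s.ndim != 1 or s.shape != p.shape or s.size == 0:
            raise DomainError("support and probs must be equal-length 1-d arrays")
        if np.any(s < 0):
            raise DomainError("dose support must be nonnegative")
        if np.unique(s).size != s.size:
            raise DomainError("support values must be distinct")
        if np.any(p < 0):
            raise DomainError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > _PROB_TOL:
            raise DomainError(f"probabilities sum to {p.sum()!r}, not 1")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "probs", p)

    @property
    def mean(self) -> float:
        return float(self.probs @ self.support)

    @property
    def variance(self) -> float:
        m = self.mean
        return float(self.probs @ (self.support - m) ** 2)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


def build_reference_distribution(mu: float, delta: float) -> DiscreteDoseDistribution:
    """The counterfactual no-selectivity distribution X_r.

    Two equally weighted dose levels mu +/- delta; mean exactly mu. With
    ``delta = 0`` the distribution degenerates to a point mass at mu.
    """
    if not (mu > delta >= 0):
        raise DomainError(
            f"need mu > delta >= 0 for positive doses, got mu={mu}, delta={delta}")
    if delta == 0 or mu - delta == mu + delta:  # offset below float resolution
        return DiscreteDoseDistribution(np.array([float(mu)]), np.array([1.0]))
    return DiscreteDoseDistribution(
        np.array([mu - delta, mu + delta], dtype=float), np.array([0.5, 0.5]))


def build_observed_distribution(mu: float, delta: float,
                                pref) -> DiscreteDoseDistribution:
    """The observed (selectivity-weighted) dietary distribution X_o.

    ``pref`` is either a :class:`~toxvar.preference.PreferenceEstimate` or a
    ``(weight_low_dose, weight_high_dose)`` pair of nonnegative herbivory
    weights; they are normalized here. Equal weights reproduce
    :func:`build_reference_distribution` exactly.
    """
    if not (mu > delta >= 0):
        raise DomainError(
            f"need mu > delta >= 0 for positive doses, got mu={mu}, delta={delta}")
    if hasattr(pref, "weight_low_dose"):
        w = np.array([pref.weight_low_dose, pref.weight_high_dose], dtype=float)
    else:
        w = np.asarray(pref, dtype=float)
    if w.shape != (2,) or np.any(w < 0):
        raise DomainError("preference weights must be two nonnegative numbers")
    tot = w.sum()
    if tot == 0:
        raise DomainError("both preference weights are zero")
    if delta == 0 or mu - delta == mu + delta:
        return DiscreteDoseDistribution(np.array([float(mu)]), np.array([1.0]))
    if w[0] == w[1]:
        probs = np.array([0.5, 0.5])
    else:
        probs = w / tot
    return DiscreteDoseDistribution(
        np.array([mu - delta, mu + delta], dtype=float), probs)


def distribution_moments(d: DiscreteDoseDistribution) -> tuple[float, float, float]:
    """Exact (mean, variance, sd) of a discrete dose distribution."""
    return d.mean, d.variance, d.sd
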