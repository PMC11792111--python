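"""Herbivore selective-feeding estimation from leaf-level herbivory tables.

In the within-plant variation treatment every plant carries leaves painted at
two dose levels (mu - delta and mu + delta). The herbivore's preference is
summarized as the mean proportion herbivory per dose level; these two weights
later reweight the dietary dose distribution X_o. Uncertainty comes from a
cluster (plant-level) nonparametric bootstrap, which respects the dependence
of leaves within a plant.

Point weights default to back-transformed means of logit herbivory
("logit-mean"); raw arithmetic means are available via ``method="raw"``.
Boundary proportions are shrunk by (p*(n-1) + 0.5)/n before the logit, with n
the number of leaves in the dose-level group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._exceptions import DataError, DegenerateDataWarning, DomainError

__all__ = [
    "PreferenceEstimate",
    "RatioEstimate",
    "estimate_preference",
    "preference_ratio",
    "LEAF_COLUMNS",
]

#: required columns of a leaf-level herbivory table
LEAF_COLUMNS = ("plant_id", "cage_id", "mean_treatment", "leaf_dose_level",
                "dose_nmol_mg", "herbivory_prop")

_LEVELS = ("low_dose", "high_dose")


@dataclass
class PreferenceEstimate:
    """Per-dose-level mean herbivory weights with bootstrap draws.

    Weights are unnormalized (they stay on the interpretable proportion-
    herbivory scale); the dietary module normalizes them into probabilities.
    ``draws`` has shape (n_draws, 2) in (low_dose, high_dose) order.
    """

    mean_treatment: str
    weight_low_dose: float
    weight_high_dose: float
    draws: np.ndarray
    n_plants: int
    method: str = "logit-mean"

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != 2:
            raise DomainError("draws must have shape (n_draws, 2)")
        if self.weight_low_dose < 0 or self.weight_high_dose < 0 or np.any(self.draws < 0):
            raise DomainError("preference weights must be nonnegative")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.weight_low_dose, self.weight_high_dose])


class RatioEstimate(NamedTuple):
    value: float
    draws: np.ndarray


def _shrink(p: np.ndarray, n: int) -> np.ndarray:
    # pulls exact 0/1 proportions off the boundary before the logit
    return (p * (n - 1) + 0.5) / n


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _validate_leaves(leaves: pd.DataFrame) -> None:
    missing = [c for c in LEAF_COLUMNS if c not in leaves.columns]
    if missing:
        raise DataError(f"leaf table is missing columns: {missing}")
    p = leaves["herbivory_prop"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DataError("herbivory_prop must lie in [0, 1]")
    if np.any(leaves["dose_nmol_mg"].to_numpy(dtype=float) <= 0):
        raise DataError("dose_nmol_mg must be positive")


def estimate_preference(leaves: pd.DataFrame, mean_treatment: str,
                        n_draws: int = 500, seed: int = 0,
                        method: str = "logit-mean") -> PreferenceEstimate:
    """Estimate per-dose-level herbivory weights for one mean-dose treatment.

    Parameters
    ----------
    leaves
        Leaf-level table with columns ``LEAF_COLUMNS``; only rows matching
        ``mean_treatment`` are used. Every plant must carry both dose levels.
    n_draws
        Number of plant-cluster bootstrap draws (default 500).
    method
        ``"logit-mean"`` (default): mean of shrunk-logit herbivory per dose
        level, back-transformed. ``"raw"``: plain mean proportion herbivory.
    """
    if method not in ("logit-mean", "raw"):
        raise DomainError(f"unknown method {method!r}")
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    _validate_leaves(leaves)
    sub = leaves.loc[leaves["mean_treatment"] == mean_treatment]
    if sub.empty:
        raise DataError(f"no leaves for mean_treatment={mean_treatment!r}")
    levels = set(sub["leaf_dose_level"].unique())
    if not set(_LEVELS) <= levels:
        raise DataError(f"both dose levels {_LEVELS} required, found {sorted(levels)}")
    plants = sub["plant_id"].unique()
    n_plants = plants.size
    if n_plants < 2:
        raise DataError("need >= 2 plants for cluster bootstrap uncertainty")

    p_all = sub["herbivory_prop"].to_numpy(dtype=float)
    if np.all(p_all == 0):
        warnings.warn("all-zero herbivory on both dose levels; "
                      "falling back to equal weights", DegenerateDataWarning)
        draws = np.full((n_draws, 2), 0.5)
        return PreferenceEstimate(mean_treatment, 0.5, 0.5, draws, n_plants, method)

    # Per-plant, per-level sufficient statistics so the bootstrap is a
    # vectorized multinomial reweighting of plants. The shrink denominator n
    # is frozen at the observed group size so resampling stays exact.
    plant_idx = pd.Categorical(sub["plant_id"], categories=plants).codes
    stat_sum = np.zeros((n_plants, 2))
    stat_cnt = np.zeros((n_plants, 2))
    for j, level in enumerate(_LEVELS):
        mask = (sub["leaf_dose_level"] == level).to_numpy()
        p = sub.loc[mask, "herbivory_prop"].to_numpy(dtype=float)
        n_group = int(mask.sum())
        vals = _logit(_shrink(p, n_group)) if method == "logit-mean" else p
        np.add.at(stat_sum[:, j], plant_idx[mask], vals)
        np.add.at(stat_cnt[:, j], plant_idx[mask], 1.0)
    if np.any(stat_cnt == 0):
        bad = plants[np.any(stat_cnt == 0, axis=1)]
        raise DataError(f"plants missing a dose level: {list(bad[:5])}")

    def weights_from_counts(m: np.ndarray) -> np.ndarray:
        # m: (n_reps, n_plants) multiplicity of each plant in a resample
        mean_stat = (m @ stat_sum) / (m @ stat_cnt)
        return _inv_logit(mean_stat) if method == "logit-mean" else mean_stat

    point = weights_from_counts(np.ones((1, n_plants)))[0]
    rng = np.random.default_rng(seed)
    mult = rng.multinomial(n_plants, np.full(n_plants, 1.0 / n_plants),
                           size=n_draws)
    draws = weights_from_counts(mult.astype(float))
    return PreferenceEstimate(mean_treatment, float(point[0]), float(point[1]),
                              draws, int(n_plants), method)


def preference_ratio(est: PreferenceEstimate) -> RatioEstimate:
    """Relative preference for the low-dose leaf, in percent.

    100 * (w_low - w_high) / w_high: 0 means no selectivity, 100 means the
    herbivore ate twice as much of the low-dose leaf. The draws are mapped
    elementwise so intervals can be read off directly.
    """
    if est.weight_high_dose <= 0:
        raise DomainError("high-dose weight must be positive for a ratio")
    if np.any(est.draws[:, 1] <= 0):
        raise DomainError("a bootstrap draw has zero high-dose weight")
    value = 100.0 * (est.weight_low_dose - est.weight_high_dose) / est.weight_high_dose
    draws = 100.0 * (est.draws[:, 0] - est.draws[:, 1]) / est.draws[:, 1]
    return RatioEstimate(float(value), draws)
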