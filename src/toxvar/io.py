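"""Plain-text serialization: curves and preferences to JSON, results to CSV,
and run manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import DataError
from .curves import DoseResponseCurve, HillParams, LogDoseSplineBasis, SmoothCurveFit
from .decomposition import DecompositionResult
from .preference import PreferenceEstimate

__all__ = [
    "curve_to_dict", "curve_from_dict", "save_curve", "load_curve",
    "preference_to_dict", "preference_from_dict",
    "save_preference", "load_preference",
    "summary_table", "write_summary", "write_manifest",
]


def curve_to_dict(obj) -> dict:
    """Serialize a DoseResponseCurve or SmoothCurveFit to plain JSON types."""
    if isinstance(obj, DoseResponseCurve):
        if obj.form == "hill":
            p: HillParams = obj.parameters
            return {"form": "hill", "link": obj.link,
                    "parameters": {"e0": p.e0, "emax": p.emax,
                                   "ec50": p.ec50, "n": p.n}}
        if obj.form == "linear":
            b0, b1 = obj.parameters
            return {"form": "linear", "link": obj.link,
                    "parameters": {"intercept": b0, "slope": b1}}
        if obj.form == "smooth":
            return curve_to_dict(obj.parameters)
        raise DataError(f"cannot serialize curve form {obj.form!r}")
    if isinstance(obj, SmoothCurveFit):
        return {
            "form": "smooth", "link": obj.link,
            "dose_range": list(obj.dose_range),
            "basis": {"type": "natural-cubic-log-dose",
                      "knots": obj.basis.knots.tolist()},
            "coefficients": obj.coefficients.tolist(),
            "covariance": obj.coefficient_covariance.tolist(),
            "penalty": obj.penalty, "sigma2": obj.sigma2, "edf": obj.edf,
            "fd_step_frac": obj.fd_step_frac,
        }
    raise DataError(f"cannot serialize {type(obj).__name__}")


def curve_from_dict(d: dict) -> DoseResponseCurve:
    form = d.get("form")
    link = d.get("link", "identity")
    if form == "hill":
        p = d["parameters"]
        return DoseResponseCurve.hill(p["e0"], p["emax"], p["ec50"], p["n"], link)
    if form == "linear":
        p = d["parameters"]
        return DoseResponseCurve.linear(p["intercept"], p["slope"], link)
    if form == "smooth":
        lo, hi = d["dose_range"]
        knots = np.asarray(d["basis"]["knots"], float)
        basis = LogDoseSplineBasis((float(lo), float(hi)), knots=knots)
        fit = SmoothCurveFit(
            basis=basis, coefficients=np.asarray(d["coefficients"], float),
            coefficient_covariance=np.asarray(d["covariance"], float),
            link=link, dose_range=(float(lo), float(hi)),
            penalty=float(d.get("penalty", 0.0)),
            sigma2=float(d.get("sigma2", float("nan"))),
            edf=float(d.get("edf", float("nan"))),
            fd_step_frac=float(d.get("fd_step_frac", 1e-4)))
        return DoseResponseCurve.from_smooth_fit(fit)
    raise DataError(f"unknown serialized curve form {form!r}")


def save_curve(obj, path) -> None:
    Path(path).write_text(json.dumps(curve_to_dict(obj), indent=1))


def load_curve(path) -> DoseResponseCurve:
    return curve_from_dict(json.loads(Path(path).read_text()))


def preference_to_dict(est: PreferenceEstimate, seed: int | None = None) -> dict:
    return {"mean_treatment": est.mean_treatment,
            "weight_low_dose": est.weight_low_dose,
            "weight_high_dose": est.weight_high_dose,
            "draws": est.draws.tolist(), "n_plants": est.n_plants,
            "method": est.method, "seed": seed}


def preference_from_dict(d: dict) -> PreferenceEstimate:
    return PreferenceEstimate(d["mean_treatment"], d["weight_low_dose"],
                              d["weight_high_dose"],
                              np.asarray(d["draws"], float),
                              int(d["n_plants"]), d.get("method", "logit-mean"))


def save_preference(est: PreferenceEstimate, path, seed: int | None = None) -> None:
    Path(path).write_text(json.dumps(preference_to_dict(est, seed)))


def load_preference(path) -> PreferenceEstimate:
    return preference_from_dict(json.loads(Path(path).read_text()))


def summary_table(result: DecompositionResult) -> pd.DataFrame:
    """Tidy summary: quantity, mean, lower, upper, ci_level, n_draws."""
    out = result.summaries.copy()
    out["ci_level"] = result.ci_level
    out["n_draws"] = len(result.draws)
    for key in ("response", "mean_treatment"):
        if key in result.meta:
            out[key] = result.meta[key]
    return out


def write_summary(result: DecompositionResult, path) -> None:
    summary_table(result).to_csv(path, index=False)


def write_manifest(out_dir, subcommand: str, seed: int | None,
                   config: dict | str | None = None,
                   inputs: dict | None = None,
                   outputs: list | None = None) -> Path:
    """Record enough to re-run a CLI command: subcommand, config, paths,
    seed, package version, timestamp."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config": config,
        "inputs": {k: str(v) for k, v in (inputs or {}).items()},
        "outputs": [str(p) for p in (outputs or [])],
        "seed": seed,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
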