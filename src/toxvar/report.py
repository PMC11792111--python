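"""Human-readable reporting of decomposition summaries.

Renders the summary tables as dot-and-interval text panels: one line per
quantity with its mean and equal-tailed interval, an asterisk where the
interval excludes zero and "ns" otherwise, plus each mechanism's share of
the predicted total T^ when draw-level shares are available.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._exceptions import DataError

_LABELS = {
    "jr": "Jr  (nonlinear averaging)",
    "s": "S   (selective feeding)",
    "js": "JS  (interaction)",
    "t_hat": "T^  (predicted total)",
    "t_obs": "To  (observed total)",
    "eps": "eps (residual mechanisms)",
}


def _flag(lower: float, upper: float) -> str:
    return "*" if (lower > 0 or upper < 0) else "ns"


def render_summary_panel(summary: pd.DataFrame, title: str = "") -> str:
    """One text panel for one summary table (one response x mean level)."""
    required = {"quantity", "mean", "lower", "upper"}
    if not required <= set(summary.columns):
        raise DataError(f"summary table needs columns {sorted(required)}")
    ci = summary["ci_level"].iloc[0] if "ci_level" in summary.columns else 0.89
    lines = []
    head = title or ", ".join(
        str(summary[c].iloc[0]) for c in ("response", "mean_treatment")
        if c in summary.columns)
    lines.append(f"== {head or 'decomposition'} ==")
    lines.append(f"   effect (SD units), {100 * ci:.0f}% interval")
    for _, row in summary.iterrows():
        label = _LABELS.get(row["quantity"], row["quantity"])
        lines.append(
            f"  {label:<28s} {row['mean']:+10.4g}  "
            f"[{row['lower']:+10.4g}, {row['upper']:+10.4g}]  "
            f"{_flag(row['lower'], row['upper'])}")
    return "\n".join(lines)


def render_shares_panel(shares: pd.DataFrame) -> str:
    lines = ["  -- share of predicted total T^ (%, median) --"]
    for _, row in shares.iterrows():
        label = _LABELS.get(row["quantity"], row["quantity"])
        lines.append(
            f"  {label:<28s} {row['median']:7.1f}%  "
            f"[{row['lower']:7.1f}%, {row['upper']:7.1f}%]")
    n_excl = shares.attrs.get("n_excluded")
    if n_excl:
        lines.append(f"  ({n_excl} draws with near-zero T^ excluded)")
    return "\n".join(lines)


def render_report(summaries: list[pd.DataFrame],
                  shares: list[pd.DataFrame] | None = None) -> str:
    """Assemble panels for any number of summary tables into one report."""
    if not summaries:
        raise DataError("no summary tables to report")
    parts = []
    for i, summary in enumerate(summaries):
        parts.append(render_summary_panel(summary))
        if shares is not None and i < len(shares) and shares[i] is not None:
            parts.append(render_shares_panel(shares[i]))
    return "\n\n".join(parts) + "\n"


def report_from_files(paths: list) -> str:
    if not paths:
        raise DataError("no summary files given")
    return render_report([pd.read_csv(Path(p)) for p in paths])
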