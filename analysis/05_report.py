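#!/usr/bin/env python
"""Render the decomposition summaries as dot-and-interval text panels with
per-mechanism shares of the predicted total, writing results/report.txt."""

from pathlib import Path

import pandas as pd

from toxvar.report import render_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    summaries, shares = [], []
    for response in ("rgr", "herbivory"):
        for level in ("low", "high"):
            summaries.append(pd.read_csv(ROOT / f"summary_{response}_{level}.csv"))
            shares.append(pd.read_csv(ROOT / f"shares_{response}_{level}.csv"))
    text = render_report(summaries, shares)
    (ROOT / "report.txt").write_text(text)
    print(text)


if __name__ == "__main__":
    main()
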