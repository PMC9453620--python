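#!/usr/bin/env python
"""Chronotype-stratified phenotype summary (the cohort-characteristics table).

Means with SDs per chronotype stratum (circular statistics for clock times,
with spread in minutes), and morning-vs-intermediate significance flags from
Student's t or chi-squared tests at p < 0.05.
"""

from pathlib import Path

import pandas as pd

from circphen import pipeline as pl

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    table = pd.read_csv(OUT / "phenotypes.csv")
    summary = pl.build_phenotype_summary(table)
    summary.to_csv(OUT / "summary.csv", index=False)

    cols = [c for c in ("variable", "overall_mean", "overall_spread",
                        "morning_mean", "intermediate_mean", "p_value",
                        "significant") if c in summary.columns]
    with pd.option_context("display.width", 120, "display.precision", 2):
        print(summary[cols].to_string(index=False))
    print(f"summary -> {OUT / 'summary.csv'}")


if __name__ == "__main__":
    main()
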