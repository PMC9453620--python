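#!/usr/bin/env python
"""Agreement between the transcriptomic angle and the other phase measures.

Pearson and age/sex-adjusted partial correlations of the angle with every
phenotype, plus z-scored Bland-Altman limits of agreement (clock-time
markers negated first so all measures point "positive = advanced"). The
hypothesized pattern: negative correlations with waketime, bedtime, M10 and
DLMO; positive with MEQ; none with amplitude, fragmentation or sleep quality.
"""

from pathlib import Path

import pandas as pd

from circphen import pipeline as pl

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    table = pd.read_csv(OUT / "phenotypes.csv")
    corr, ba = pl.agreement_analyses(table, covariates=("age", "sex"))
    corr.to_csv(OUT / "correlations.csv", index=False)
    ba.to_csv(OUT / "bland_altman.csv", index=False)

    print("partial correlations with transcriptomic angle (adjusted for age, sex):")
    for row in corr.itertuples(index=False):
        flag = "*" if row.partial_p < 0.05 else " "
        print(f"  {row.variable:24s} r = {row.partial_r:+.3f}  p = {row.partial_p:.4f} {flag}")
    print(f"tables -> {OUT / 'correlations.csv'}, {OUT / 'bland_altman.csv'}")


if __name__ == "__main__":
    main()
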