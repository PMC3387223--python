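#!/usr/bin/env python
"""Does promoter methylation track gene expression?

Correlates every differentially methylated CpG with its gene's median
expression and attaches a permutation p-value (1,000 joint sample-label
permutations), then reports the inverse-correlation census for both the
tumor-vs-normal and the SCC-vs-AC differential sets.
"""

from pathlib import Path

import pandas as pd

from lungmeth import dataio
from lungmeth.integration import correlation_screen, inverse_fraction, strongest_per_gene

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"
N_PERM = 1000
SEED = 1


def main() -> None:
    qn = dataio.read_beta(RES / "beta.qn.tsv", allow_missing=False)
    expr = dataio.read_expression(RES / "sim" / "expression.tsv")

    for contrast in ("tumor_vs_normal", "scc_vs_ac"):
        records = pd.read_csv(RES / f"diff_{contrast}.tsv", sep="\t", index_col=0)
        corr = correlation_screen(records, qn, expr, n_perm=N_PERM, seed=SEED)
        corr.to_csv(RES / f"correlation_{contrast}.tsv", sep="\t",
                    float_format=dataio.FLOAT_FORMAT)
        census = inverse_fraction(corr)
        print(f"{contrast}: {census['n_inverse']} of {census['n_total']} "
              f"differential CpGs inversely correlated ({census['percent']}%)")
        best = strongest_per_gene(corr[corr["inverse"]])
        top = best.nsmallest(3, "pearson_r")
        for cpg, row in top.iterrows():
            print(f"  strongest: {row['gene']} ({cpg}) r = {row['pearson_r']:.2f}, "
                  f"perm p = {row['perm_p']:.4f}")


if __name__ == "__main__":
    main()
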