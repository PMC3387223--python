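#!/usr/bin/env python
"""Prognostic-marker screens.

After excluding patients who survived no more than one month post-surgery,
runs (1) the per-CpG Kaplan-Meier / log-rank screen over low/medium/high
methylation groups (all non-empty groups must exceed five patients; BH FDR)
and (2) the Cox + Wilcoxon screen contrasting 1-24-month decedents against
>= 60-month survivors with the 0.136 delta-beta cutoff. Exports the KM step
curves of the best log-rank CpG.
"""

from pathlib import Path

from lungmeth import dataio, survival

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"


def main() -> None:
    qn = dataio.read_beta(RES / "beta.qn.tsv", allow_missing=False)
    sheet = dataio.read_sample_sheet(RES / "sim" / "samples.tsv")
    sheet = dataio.drop_duplicate_replicates(sheet).loc[list(qn.columns)]
    sheet, n_removed = survival.exclude_early_deaths(sheet)
    print(f"excluded {n_removed} patients with <= 1 month survival")

    km = survival.km_screen(qn, sheet)
    km.to_csv(RES / "km_screen.tsv", sep="\t", float_format=dataio.FLOAT_FORMAT)
    n_sig = int(km["significant"].sum())
    print(f"KM screen: {len(km)} CpGs passed the >5-per-group rule; "
          f"{n_sig} significant after FDR")
    if len(km):
        best = km["logrank_p"].idxmin()
        print(f"  best log-rank CpG: {best} "
              f"(chi2 = {km.loc[best, 'logrank_chi2']:.2f}, "
              f"p = {km.loc[best, 'logrank_p']:.2e}, "
              f"q = {km.loc[best, 'logrank_q']:.3f})")
        curves = survival.km_curves(qn.loc[best], sheet)
        curves.to_csv(RES / "km_curves_best.tsv", sep="\t", index=False,
                      float_format=dataio.FLOAT_FORMAT)

    cw = survival.cox_wilcoxon_screen(qn, sheet)
    cw.to_csv(RES / "coxwilcoxon_screen.tsv", sep="\t",
              float_format=dataio.FLOAT_FORMAT)
    called = cw[cw["combined_call"]]
    print(f"Cox+Wilcoxon screen ({cw['n_short'].iloc[0]} short vs "
          f"{cw['n_long'].iloc[0]} long survivors): {len(called)} CpGs called")
    for cpg, row in called.iterrows():
        print(f"  {cpg}: delta = {row['delta_short_long']:+.3f} "
              f"({row['direction']} in poor survival), cox p = {row['cox_p']:.3g}, "
              f"wilcoxon p = {row['wilcoxon_p']:.3g}")


if __name__ == "__main__":
    main()
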