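#!/usr/bin/env python
"""Differential methylation screens.

Three moderated-t contrasts — tumor vs normal, SCC vs AC (within tumors),
smoker vs non-smoker — plus a per-CpG linear regression of methylation on
pack-years. Calls use FDR q < 0.05 with the |delta-beta| >= 0.136 cutoff.
Writes diff_<contrast>.tsv under results/ and prints CpG/gene counts.
"""

from pathlib import Path

import numpy as np

from lungmeth import dataio, differential

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"


def main() -> None:
    qn = dataio.read_beta(RES / "beta.qn.tsv", allow_missing=False)
    sheet = dataio.read_sample_sheet(RES / "sim" / "samples.tsv")
    sheet = dataio.drop_duplicate_replicates(sheet).loc[list(qn.columns)]
    manifest = dataio.read_manifest(RES / "sim" / "manifest.tsv")

    contrasts = {
        "tumor_vs_normal": (sheet["tissue"], "tumor", "normal"),
        "scc_vs_ac": (sheet["histology"], "SCC", "AC"),
        "smoker_vs_nonsmoker": (
            sheet["smoker"].map(
                lambda v: None if v is None or (isinstance(v, float) and np.isnan(v))
                else ("smoker" if v else "nonsmoker")
            ),
            "smoker",
            "nonsmoker",
        ),
    }
    for name, (labels, a, b) in contrasts.items():
        stats = differential.moderated_t_test(qn, labels, a, b)
        rec = differential.call_differential(stats, manifest=manifest)
        rec.to_csv(RES / f"diff_{name}.tsv", sep="\t",
                   float_format=dataio.FLOAT_FORMAT)
        c = differential.count_cpgs_and_genes(rec)
        print(f"{name}: {c['n_hyper_cpgs']} hyper CpGs in {c['n_hyper_genes']} genes; "
              f"{c['n_hypo_cpgs']} hypo CpGs in {c['n_hypo_genes']} genes"
              + (f"; both-direction genes: {', '.join(c['overlap_genes'])}"
                 if c["overlap_genes"] else ""))

    # pack-years as a continuous exposure within tumors
    tumors = sheet[sheet["tissue"] == "tumor"]
    res = differential.covariate_regression(qn[list(tumors.index)],
                                            tumors["pack_years"])
    res.to_csv(RES / "packyears_regression.tsv", sep="\t",
               float_format=dataio.FLOAT_FORMAT)
    n_sig = int((res["q"] < 0.05).sum())
    print(f"pack-years regression: {n_sig} CpGs at q < 0.05 "
          f"({len(tumors) - int(tumors['pack_years'].notna().sum())} patient(s) "
          f"without smoking data excluded)")


if __name__ == "__main__":
    main()
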