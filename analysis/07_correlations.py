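"""Correlation analyses: cross-omics pairs and the radiation-dose check.

Correlates the strongest differential proteins against the strongest
differential metabolites (pairwise-complete Pearson, BH-adjusted,
|r|>0.8 screen), then correlates the top panel biomarkers with RT dose
overall and within each response group — the stratified comparison that
separates a real dose effect from group confounding.  Outputs under
results/correlations/.
"""

from _common import COHORT_SEED, load_cohort, outdir, transformed

import pandas as pd

from rtomics.associate import correlation_matrix, dose_association
from rtomics.classify import mccv_panels, panel_report
from rtomics.differential import call_differential


def main() -> None:
    out = outdir("correlations")
    _, proteome, metabolome, metadata, _ = load_cohort()
    tp, tm = transformed(proteome), transformed(metabolome)

    def top_sig(table, n=50):
        records, _ = call_differential(table, metadata)
        sig = records[records["significant_raw"].fillna(False)].sort_values("p_value")
        return list(sig.index[:n])

    prot_ids = [f for f in top_sig(proteome) if f in tp.values.index]
    met_ids = [f for f in top_sig(metabolome) if f in tm.values.index]
    full, strong = correlation_matrix(tp.subset_features(prot_ids),
                                      tm.subset_features(met_ids))
    full.to_csv(out / "cross_omics_correlations.tsv", sep="\t", index=False)
    strong.to_csv(out / "cross_omics_strong.tsv", sep="\t", index=False)
    print(f"cross-omics: {len(full)} pairs tested, {len(strong)} with |r|>0.8 and p<0.05")

    frames = []
    for name, t in (("proteome", tp), ("metabolome", tm)):
        res = mccv_panels(t, metadata, sizes=(10,), seed=COHORT_SEED)
        _, top = panel_report(res, n_features=10)
        frames.append(dose_association(t, metadata, list(top.index)))
    dose = pd.concat(frames, ignore_index=True)
    dose.to_csv(out / "dose_associations.tsv", sep="\t", index=False)
    within = dose[dose["stratum"] != "all"]
    n_sig = int((within["p_value"] < 0.05).sum())
    print(f"dose check: {len(within)} within-group correlations, {n_sig} at p<0.05 "
          "(dose is generated independent of abundance, so ~chance)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
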