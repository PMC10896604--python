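"""Generate the study cohort: 24 samples, 2741 proteins, 119 metabolites.

Writes the TIC-normalized feature tables, the Table-1-like clinical
metadata, and the planted ground truth under results/cohort/.
"""

from _common import load_cohort, outdir

from rtomics import write_feature_table, write_metadata


def main() -> None:
    cfg, proteome, metabolome, metadata, truth = load_cohort()
    out = outdir("cohort")
    write_feature_table(proteome, out / "proteome.tsv")
    write_feature_table(metabolome, out / "metabolome.tsv")
    write_metadata(metadata, out / "metadata.tsv")
    truth.to_json(out / "ground_truth.json")
    n_excl = len(truth.exclusive_feature_ids)
    print(f"cohort: {proteome.n_samples} samples, "
          f"{proteome.n_features} proteins + {metabolome.n_features} metabolites")
    print(f"planted: {len(truth.differential_feature_ids)} differential features "
          f"(g={cfg.effect_size}), {n_excl} group-exclusive")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
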