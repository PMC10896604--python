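"""Pathway enrichment: ORA per layer, permutation QEA, joint analysis.

Uses the bundled toy pathway collection (fictional pathways over the
synthetic feature ids).  Hits are the q<0.05 differential features of each
layer.  Outputs under results/enrichment/.
"""

from importlib import resources

from _common import COHORT_SEED, load_cohort, outdir, transformed

from rtomics.differential import call_differential
from rtomics.enrichment import joint_pathway, ora, qea, read_gmt, records_frame


def main() -> None:
    out = outdir("enrichment")
    _, proteome, metabolome, metadata, _ = load_cohort()
    with resources.as_file(resources.files("rtomics.data") / "toy_pathways.gmt") as p:
        pathways = read_gmt(p)
    print(f"{len(pathways)} pathways loaded")

    hits, universe = {}, {}
    for name, table in (("proteome", proteome), ("metabolome", metabolome)):
        records, _ = call_differential(table, metadata)
        tested = records[records["p_value"].notna()]
        hits[name] = set(tested.index[tested["p_adjusted"] < 0.05])
        universe[name] = set(tested.index)
        rec = ora(hits[name], universe[name], pathways)
        records_frame(rec).to_csv(out / f"{name}_ora.tsv", sep="\t")
        n_sig = sum(r.q_value < 0.05 for r in rec)
        print(f"{name} ORA: {len(hits[name])} hits / {len(universe[name])} universe, "
              f"{n_sig} pathways at q<0.05")

    rec = qea(transformed(metabolome), metadata, pathways,
              n_permutations=1000, seed=COHORT_SEED)
    records_frame(rec).to_csv(out / "metabolome_qea.tsv", sep="\t")
    print(f"QEA: {sum(r.q_value < 0.05 for r in rec)} of {len(rec)} measured pathways at q<0.05")

    rec = joint_pathway(hits["proteome"], hits["metabolome"],
                        universe["proteome"], universe["metabolome"], pathways)
    records_frame(rec).to_csv(out / "joint_pathway.tsv", sep="\t")
    top = min(rec, key=lambda r: r.p_value)
    print(f"joint: top pathway {top.pathway_id} "
          f"(p={top.p_value:.2e}, impact={top.impact:.2f}, "
          f"{top.n_hits_gene} protein + {top.n_hits_metabolite} metabolite hits)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
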