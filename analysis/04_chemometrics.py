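"""Unsupervised sample structure: PCA and Ward/Euclidean HCA per layer.

Scores, loadings and Newick dendrograms go to results/chemometrics/;
prints the explained variance of the leading components and how well a
2-cluster cut of the dendrogram agrees with the GR/PR labels.
"""

from _common import load_cohort, outdir, transformed

from rtomics.chemometrics import cluster_agreement, hca, pca


def main() -> None:
    out = outdir("chemometrics")
    _, proteome, metabolome, metadata, _ = load_cohort()
    for name, table in (("proteome", proteome), ("metabolome", metabolome)):
        t = transformed(table)
        res = pca(t, n_components=5)
        res.scores.to_csv(out / f"{name}_pca_scores.tsv", sep="\t")
        res.loadings.to_csv(out / f"{name}_pca_loadings.tsv", sep="\t")
        tree = hca(t)
        (out / f"{name}_hca.nwk").write_text(tree.to_newick() + "\n")
        agree = cluster_agreement(tree.cut(2), metadata.groups)
        evr = ", ".join(f"{v:.1%}" for v in res.explained_variance_fraction[:3])
        print(f"{name}: PC1-3 explain {evr}; 2-cluster GR/PR agreement {agree:.2f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
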