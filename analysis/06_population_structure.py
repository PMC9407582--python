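#!/usr/bin/env python
"""Population structure of the genotyped panel: PCA of the 0/1/2 dose
matrix and Euclidean complete-linkage clustering for heatmap ordering, at
both the individual and the breed-pool level.

Reads results/pipeline/ and writes the PCA/cluster tables plus (when
matplotlib is available) a PC1/PC2 scatter colored by breed.
"""

from pathlib import Path

import pandas as pd

from ripscan.cli import run_structure
from ripscan.io_formats import read_genotype_table
from ripscan.structure_analysis import encode_matrix, pca

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def main() -> None:
    run_structure(OUTDIR)
    variance = pd.read_csv(OUTDIR / "pca_variance.tsv", sep="\t")
    print("PCA variance explained:")
    print(variance.to_string(index=False))
    order = pd.read_csv(OUTDIR / "cluster_rows.tsv", sep="\t")
    print(f"clustering leaf order over {len(order)} individuals -> cluster_rows.tsv")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib unavailable; skipping the PCA figure")
        return

    table = read_genotype_table(OUTDIR / "genotype_calls.tsv")
    scores = pca(encode_matrix(table), k=2).scores
    breed_of = dict(table[["individual_id", "breed"]].drop_duplicates().itertuples(index=False))
    fig, ax = plt.subplots(figsize=(6, 5))
    for breed in sorted(set(breed_of.values())):
        ids = [i for i in scores.index if breed_of[i] == breed]
        ax.scatter(scores.loc[ids, "PC1"], scores.loc[ids, "PC2"], s=12, label=breed, alpha=0.7)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUTDIR.parent / "pca_breeds.png", dpi=120)
    print(f"PCA scatter -> {OUTDIR.parent / 'pca_breeds.png'}")


if __name__ == "__main__":
    main()
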