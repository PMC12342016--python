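#!/usr/bin/env python
"""Extract archetype-defining genes and their cross-archetype sharing.

Back-projects each archetype to gene space (centered reconstruction),
applies the 45-degree elbow rule separately to the positive and negative
coefficient tails, and summarizes how many defining genes are shared
between archetypes (with a ribbon table for circular-plot tools).

Writes results/genes/archetype<i>_genes.tsv, overlap.tsv, ribbons.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import paretoscope as ps
from paretoscope.pca import PCAModel
from paretoscope.simplex import SimplexFit

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    with open(ROOT / "fit.json") as fh:
        data = json.load(fh)
    pca = PCAModel(
        means=np.asarray(data["pca"]["means"]),
        loadings=np.asarray(data["pca"]["loadings"]),
        scores=np.zeros((0, 8)),
        eigenvalues=np.zeros(8),
        explained_fraction=np.asarray(data["pca"]["explained_fraction"]),
        gene_ids=data["pca"]["gene_ids"],
    )
    fit = SimplexFit(k=data["k"], archetypes_pc=np.asarray(data["archetypes_pc"]),
                     vertex_sample_indices=None,
                     weights=np.asarray(data["weights"]), esv=data["esv"])

    profiles = ps.archetype_gene_coefficients(fit, pca)
    lists = ps.select_defining_genes(profiles)
    summary = ps.overlap_summary(lists)

    outdir = ROOT / "genes"
    outdir.mkdir(parents=True, exist_ok=True)
    for prof in profiles:
        a = prof.archetype_index
        cmap = dict(zip(prof.gene_ids, prof.coefficients))
        rows = [{"gene": g, "coefficient": cmap[g], "sign": "+"}
                for g in lists.positive_genes[a]]
        rows += [{"gene": g, "coefficient": cmap[g], "sign": "-"}
                 for g in lists.negative_genes[a]]
        pd.DataFrame(rows).to_csv(outdir / f"archetype{a + 1}_genes.tsv",
                                  sep="\t", index=False)
        print(f"archetype {a + 1}: {len(lists.positive_genes[a])} positive "
              f"(cutoff {lists.positive_cutoffs[a]:.2f}), "
              f"{len(lists.negative_genes[a])} negative "
              f"(cutoff {lists.negative_cutoffs[a]:.2f}) defining genes")

    pd.DataFrame(summary.pairwise_counts,
                 columns=[f"archetype{j + 1}" for j in range(lists.k)]).to_csv(
        outdir / "overlap.tsv", sep="\t", index=False)
    summary.ribbon_table.to_csv(outdir / "ribbons.tsv", sep="\t", index=False)
    print(f"{summary.n_unique_genes} unique defining genes; "
          f"{summary.n_shared_genes} ({100 * summary.shared_fraction:.0f}%) "
          f"shared between >=2 archetypes")
    print(f"wrote per-archetype lists, overlap.tsv and ribbons.tsv to {outdir}")


if __name__ == "__main__":
    main()
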