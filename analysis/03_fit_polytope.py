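#!/usr/bin/env python
"""Fit the best data-constrained polytope and test its significance.

PCA to 8 dimensions, elbow selection of the archetype number K from the
explained-sample-variance curve, maximum-volume simplex fit with vertices on
data points, t-ratio randomization test (PC-column shuffling null), and a
1000-replicate bootstrap of archetype positions.

Writes results/fit.json (fit + PCA basis for downstream steps) and
results/esv_curve.tsv.
"""

import json
from pathlib import Path

import paretoscope as ps
from paretoscope.pipeline import stage_seed

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 21


def main() -> None:
    x = ps.read_expression_matrix(ROOT / "data" / "expression.tsv")
    filt = ps.filter_informative_genes(x)
    pca = ps.fit_pca(filt, 8)

    k, curve = ps.select_k_elbow(pca.scores, 2, 8, seed=stage_seed(SEED, "select_k"),
                                 return_curve=True)
    print("ESV by K:", {kk: round(v, 3) for kk, v in curve.items()})
    print(f"elbow selects K = {k} archetypes")

    fit = ps.fit_simplex(pca.scores, k, seed=stage_seed(SEED, "fit"))
    print(f"fit: ESV = {fit.esv:.4f}, vertex samples = "
          f"{[filt.sample_ids[i] for i in fit.vertex_sample_indices]}")

    tres = ps.t_ratio_test(pca.scores, k=k, n_rand=10_000,
                           scheme="shuffle_pc_columns",
                           seed=stage_seed(SEED, "t_ratio"), n_restarts=4)
    print(f"t-ratio = {tres.t_observed:.4f} (max null {tres.t_null.max():.4f}); "
          f"p = {tres.p_value:.3g} ({tres.n_randomizations} randomizations)")

    boot = ps.bootstrap_archetypes(pca.scores, k, n_boot=1000,
                                   seed=stage_seed(SEED, "bootstrap"), reference=fit)
    areas = boot.ellipse_areas[(0, 1)]
    print(f"bootstrap ({boot.n_boot} replicates, {boot.n_dropped} dropped): "
          f"95% ellipse areas in PC1-PC2 = {[round(float(a), 1) for a in areas]}")

    with open(ROOT / "fit.json", "w") as fh:
        json.dump({
            "k": fit.k,
            "esv": fit.esv,
            "algorithm": fit.algorithm,
            "esv_curve": curve,
            "archetypes_pc": fit.archetypes_pc.tolist(),
            "vertex_sample_ids": [filt.sample_ids[i] for i in fit.vertex_sample_indices],
            "weights": fit.weights.tolist(),
            "t_ratio": {
                "t_observed": tres.t_observed,
                "p_value": tres.p_value,
                "p_uncorrected": tres.p_uncorrected,
                "n_randomizations": tres.n_randomizations,
                "scheme": tres.randomization_scheme,
            },
            "bootstrap_ellipse_areas": {
                f"PC{a + 1}-PC{b + 1}": v.tolist()
                for (a, b), v in boot.ellipse_areas.items()
            },
            "pca": {
                "means": pca.means.tolist(),
                "loadings": pca.loadings.tolist(),
                "explained_fraction": pca.explained_fraction.tolist(),
                "gene_ids": pca.gene_ids,
            },
            "seed": SEED,
        }, fh)
    with open(ROOT / "esv_curve.tsv", "w") as fh:
        fh.write("k\tesv\n")
        for kk, v in curve.items():
            fh.write(f"{kk}\t{v}\n")
    print(f"wrote {ROOT}/fit.json and esv_curve.tsv")


if __name__ == "__main__":
    main()
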