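#!/usr/bin/env python
"""Simulate the study cohort: 300 samples mixing four archetype expression
programs over 1000 genes (TPM scale, 10:1 signal-to-noise), with planted
defining genes, a discrete label enriched near archetype 1, and a continuous
covariate that grows with proximity to it.

Writes expression.tsv, attributes.tsv, planted.gmt and truth.json under
results/data/.
"""

import dataclasses
import json
from pathlib import Path

import paretoscope as ps
from paretoscope.io import GeneSetCollection, write_expression_matrix, write_gmt
from paretoscope.pipeline import _jsonify

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ps.SyntheticConfig(seed=SEED)
    truth = ps.generate(cfg)

    write_expression_matrix(truth.expression, OUT / "expression.tsv")
    with open(OUT / "attributes.tsv", "w") as fh:
        fh.write("sample_id\tlabel\tcovariate\n")
        for s in truth.expression.sample_ids:
            fh.write(f"{s}\t{truth.discrete_labels[s]}\t{truth.continuous_covariate[s]}\n")
    sets = {}
    for a, d in enumerate(truth.defining_genes):
        for sign in ("positive", "negative"):
            if d[sign]:
                sets[f"archetype{a + 1}_{sign}"] = (f"planted {sign} genes", d[sign])
    write_gmt(GeneSetCollection(sets=sets), OUT / "planted.gmt")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(
            {
                "config": _jsonify(dataclasses.asdict(cfg)),
                "weights": truth.weights.tolist(),
                "archetype_profiles": truth.archetype_profiles.tolist(),
                "defining_genes": truth.defining_genes,
            },
            fh,
        )

    n_planted = len({g for d in truth.defining_genes for s in ("positive", "negative") for g in d[s]})
    print(f"cohort: {cfg.n_samples} samples x {cfg.n_genes} genes, "
          f"k={cfg.k_archetypes} archetypes, noise sd {cfg.noise_sd} TPM")
    print(f"planted defining genes: {n_planted} unique "
          f"({cfg.n_defining_per_archetype} slots per archetype, "
          f"shared fraction {cfg.shared_fraction})")
    print(f"wrote {OUT}/expression.tsv, attributes.tsv, planted.gmt, truth.json")


if __name__ == "__main__":
    main()
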