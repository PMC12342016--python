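#!/usr/bin/env python
"""Characterize the archetypes functionally and clinically.

Tests each archetype's defining-gene lists for hypergeometric enrichment in
the planted gene sets (universe = filtered genes, BH-FDR across sets), and
tests archetype proximity (top decile of mixture weight) against the
discrete label (hypergeometric per category) and the continuous covariate
(Mann-Whitney), BH-adjusted across the archetype x attribute family.

Writes results/enrichment.tsv and results/attribute_associations.tsv.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

import paretoscope as ps
from paretoscope.simplex import SimplexFit

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    x = ps.read_expression_matrix(ROOT / "data" / "expression.tsv")
    filt = ps.filter_informative_genes(x)
    sets = ps.read_gmt(ROOT / "data" / "planted.gmt")
    attrs = ps.read_attributes(ROOT / "data" / "attributes.tsv",
                               known_samples=filt.sample_ids)
    with open(ROOT / "fit.json") as fh:
        data = json.load(fh)
    fit = SimplexFit(k=data["k"], archetypes_pc=np.asarray(data["archetypes_pc"]),
                     vertex_sample_indices=None,
                     weights=np.asarray(data["weights"]), esv=data["esv"])

    rows = []
    for a in range(fit.k):
        df = pd.read_csv(ROOT / "genes" / f"archetype{a + 1}_genes.tsv", sep="\t")
        for sign in ("+", "-"):
            genes = list(df[df["sign"] == sign]["gene"])
            for r in ps.hypergeometric_enrichment(genes, sets, filt.gene_ids):
                rows.append({"archetype": a + 1, "list_sign": sign,
                             **dataclasses.asdict(r)})
    enr = pd.DataFrame(rows)
    enr.to_csv(ROOT / "enrichment.tsv", sep="\t", index=False)
    sig = enr[enr.q_bh < 0.05]
    print(f"enrichment: {len(sig)}/{len(enr)} list-set pairs significant at "
          f"FDR 0.05; smallest q = {enr.q_bh.min():.3g} "
          f"({enr.loc[enr.q_bh.idxmin(), 'set_name']} in archetype "
          f"{enr.loc[enr.q_bh.idxmin(), 'archetype']}"
          f"{enr.loc[enr.q_bh.idxmin(), 'list_sign']})")

    assoc = ps.test_attributes(fit, attrs, filt.sample_ids, bin_fraction=0.1)
    adf = pd.DataFrame([dataclasses.asdict(r) for r in assoc])
    adf.to_csv(ROOT / "attribute_associations.tsv", sep="\t", index=False)
    disc = adf[(adf.kind == "discrete")].sort_values("q_bh")
    cont = adf[(adf.kind == "continuous")].sort_values("q_bh")
    d0, c0 = disc.iloc[0], cont.iloc[0]
    print(f"label: category {d0.category!r} enriched {d0.effect:.1f}x near "
          f"archetype {d0.archetype_index + 1} (q = {d0.q_bh:.3g})")
    print(f"covariate: median difference {c0.effect:+.2f} near archetype "
          f"{c0.archetype_index + 1} (Mann-Whitney q = {c0.q_bh:.3g})")
    print(f"wrote {ROOT}/enrichment.tsv and attribute_associations.tsv")


if __name__ == "__main__":
    main()
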