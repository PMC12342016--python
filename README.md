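# paretoscope

Pareto task inference for bulk transcriptomes.

When cells face trade-offs between tasks (energy production, protein
synthesis, immune interaction, ...), theory predicts that their expression
profiles fill a **polytope** in trait space whose vertices — **archetypes** —
are the phenotypes maximally specialized for single tasks.  `paretoscope`
implements the full inference chain for a non-negative TPM expression matrix
(samples × genes), of the kind distributed by GDC for tumor cohorts:

1. **Informative-gene filter** — keep genes with across-sample standard
   deviation *and* variance ≥ 1 TPM; no other preprocessing is applied.
2. **PCA permutation validation** — sphericity statistics on the
   correlation-matrix eigenvalues λ,

   Ψ = Σᵢ (λᵢ − 1)²,  ϕ = √(Ψ / (p(p − 1))),

   tested against a null built by independently shuffling every gene column
   (p-values carry the (b+1)/(B+1) correction), plus the count of
   significant PCs and per-PC counts of genes whose bootstrap
   gene–score-correlation CI excludes 0.
3. **Simplex fit** — the best K-vertex simplex with vertices **on data
   points** in the leading K−1 PCs, found by restart-randomized greedy
   volume maximization with single-vertex swap refinement; per-sample
   mixture weights solve min ‖x − wᵀA‖ s.t. w ≥ 0, Σw = 1; K is chosen at
   the elbow of the explained-sample-variance (ESV) curve.
4. **t-ratio test** — t = volume(fitted simplex) / volume(convex hull),
   with an empirical null from refitting after randomization (shuffle raw
   gene columns and redo PCA, or shuffle PC columns), and a 1000-replicate
   bootstrap of archetype-position uncertainty (95% covariance-ellipse
   areas per PC plane).
5. **Archetype-defining genes** — each archetype is back-projected to gene
   space as a centered reconstruction (loadings · coordinates); a
   45°-line elbow rule applied to the ordered coefficient tails yields
   positive and negative defining-gene lists, plus a cross-archetype
   sharing summary and ribbon tables for circular plots.
6. **Characterization** — hypergeometric (Fisher) over-representation of
   the lists in user-supplied GMT gene sets with BH-FDR, and association of
   archetype proximity (top decile of mixture weight) with discrete
   (hypergeometric) and continuous (Mann-Whitney) sample attributes.

A synthetic-data generator (`paretoscope.synthetic`) produces cohorts as
Dirichlet convex mixtures of K archetype profiles with planted defining
genes, a label gradient and a continuous covariate, so every stage can be
scored against exact ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort (300 samples × 1000 genes, four archetypes, signal 10× noise):

```sh
python analysis/01_simulate.py
python analysis/02_pca_validation.py
python analysis/03_fit_polytope.py
python analysis/04_archetype_genes.py
python analysis/05_characterize.py
```

which prints, among other things:

```
Psi = 5065.2 (max null 3356.5) -> p = 0.009901
significant PCs: 4; genes with significant correlations per PC: [137, 134, 128, 222]
ESV by K: {2: -0.317, 3: 0.443, 4: 0.953, 5: 0.95, 6: 0.953, 7: 0.954, 8: 0.962}
elbow selects K = 4 archetypes
t-ratio = 0.7764 (max null 0.3296); p = 0.0001 (10000 randomizations)
bootstrap (1000 replicates, 0 dropped): 95% ellipse areas in PC1-PC2 = [43.8, 29.3, 27.8, 82.9]
archetype 1: 32 positive (cutoff 3.59), 16 negative (cutoff -13.84) defining genes
label: category 'A' enriched 2.1x near archetype 2 (q = 1.15e-05)
covariate: median difference +5.89 near archetype 2 (Mann-Whitney q = 8.46e-18)
```

Read: the permutation test rejects sphericity at the smallest attainable
p (100 permutations), the ESV curve has its elbow at the planted K = 4, the
observed t-ratio 0.78 is far outside the randomization null (largest null
value 0.33), and the planted label/covariate gradients are recovered at the
archetype they were planted on (archetype numbering is arbitrary).

The same steps are available as a CLI (`paretoscope simulate | filter |
pca-test | fit | t-test | genes | enrich | attrs | run`) for use on real
matrices; `paretoscope run --config cfg.yaml` executes the whole pipeline
with per-stage seeds derived from one master seed and writes a JSON report.

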