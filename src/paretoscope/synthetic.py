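"""Synthetic expression cohorts with known simplex (Pareto) structure.

Samples are convex mixtures of ``k`` archetype expression profiles plus
truncated Gaussian noise, so the population lies in a (k-1)-simplex in gene
space — the geometry Pareto task inference is designed to detect.  The
generator plants archetype-defining genes with a configurable shared/unique
structure, a discrete label enriched near one archetype, and a continuous
covariate that grows with proximity to that archetype.  Every downstream
stage of the pipeline can therefore be scored against exact ground truth.

A note on "defining" genes in mixture models: archetype coefficients are
deviations from the cohort mean, and those deviations are zero-sum across
archetypes (weighted by mean mixture weights).  A gene elevated at exactly
one archetype therefore shows genuine opposite-sign deviations of magnitude
``signal/(k-1)`` at every other archetype ("echoes").  Shared planted genes
are built as opposite-sign pairs (+signal at one archetype, -signal at
another, baseline elsewhere), which are echo-free trade-off genes; unique
planted genes are single-archetype deviations whose echoes are real but not
part of the nominal truth lists.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import ExpressionMatrix

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "recovery_error"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the standing study conditions used throughout the
    test-bench: a 300-sample, 1000-gene cohort mixing four archetypes with
    vertex-concentrated Dirichlet weights and a 10:1 signal-to-noise ratio
    on TPM-scale values.
    """

    n_samples: int = 300
    n_genes: int = 1000
    k_archetypes: int = 4
    latent_dim: int = 8
    noise_sd: float = 2.0
    dirichlet_alpha: tuple[float, ...] | float = 0.35
    n_defining_per_archetype: int = 30
    shared_fraction: float = 0.5
    attribute_archetype: int | None = 0
    seed: int = 0
    # expression scale: baseline TPM range for ordinary genes, elevated
    # baseline for planted genes so depressed levels stay non-negative
    baseline_low: float = 2.0
    baseline_high: float = 6.0
    signal: float = 20.0

    def __post_init__(self) -> None:
        if self.k_archetypes < 2:
            raise ValueError("need at least 2 archetypes")
        if self.latent_dim < self.k_archetypes - 1:
            raise ValueError("latent_dim must be >= k_archetypes - 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if np.isscalar(self.dirichlet_alpha):
            self.dirichlet_alpha = (float(self.dirichlet_alpha),) * self.k_archetypes
        else:
            self.dirichlet_alpha = tuple(float(a) for a in self.dirichlet_alpha)
        if len(self.dirichlet_alpha) != self.k_archetypes:
            raise ValueError("dirichlet_alpha length must equal k_archetypes")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        if self.k_archetypes > self.n_samples:
            raise ValueError("k_archetypes cannot exceed n_samples")
        if self.n_defining_per_archetype * self.k_archetypes > self.n_genes:
            raise ValueError("too many defining genes for n_genes")
        if self.attribute_archetype is not None and not (
            0 <= self.attribute_archetype < self.k_archetypes
        ):
            raise ValueError("attribute_archetype out of range")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    config: SyntheticConfig
    archetype_profiles: np.ndarray          # k x n_genes, non-negative
    weights: np.ndarray                     # n_samples x k, rows on the simplex
    defining_genes: list[dict[str, list[str]]]  # per archetype: {"positive", "negative"}
    discrete_labels: dict[str, str] = field(default_factory=dict)
    continuous_covariate: dict[str, float] = field(default_factory=dict)
    expression: ExpressionMatrix | None = None


def _plan_defining_genes(
    k: int, n_def: int, shared_fraction: float, rng: np.random.Generator
) -> tuple[list[list[tuple[int, int]]], int]:
    """Plan planted genes as per-gene lists of (archetype, sign) assignments.

    Shared genes occupy one slot in two archetypes (opposite signs); unique
    genes occupy a single slot.  The number of shared genes solves
    ``|S| = f * k * n_def / (1 + f)`` (rounded) so that the fraction of
    unique planted genes appearing in >=2 lists is ~``shared_fraction``.
    """
    total_slots = k * n_def
    n_shared = int(round(shared_fraction * total_slots / (1.0 + shared_fraction)))
    # distribute shared genes round-robin over archetype pairs, keeping per-
    # archetype slot usage as even as possible
    pairs = list(itertools.combinations(range(k), 2))
    slots_used = [0] * k
    genes: list[list[tuple[int, int]]] = []
    order = rng.permutation(len(pairs))
    i = 0
    placed = 0
    while placed < n_shared:
        a, b = pairs[order[i % len(pairs)]]
        i += 1
        if slots_used[a] >= n_def or slots_used[b] >= n_def:
            continue
        sign = 1 if rng.random() < 0.5 else -1
        genes.append([(a, sign), (b, -sign)])
        slots_used[a] += 1
        slots_used[b] += 1
        placed += 1
    for a in range(k):
        for _ in range(n_def - slots_used[a]):
            sign = 1 if rng.random() < 0.5 else -1
            genes.append([(a, sign)])
    return genes, n_shared


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Generate a cohort with known archetypes; deterministic given the seed."""
    cfg = config
    k, g, n = cfg.k_archetypes, cfg.n_genes, cfg.n_samples
    rng = np.random.default_rng(cfg.seed)

    plan, _ = _plan_defining_genes(k, cfg.n_defining_per_archetype, cfg.shared_fraction, rng)
    n_planted = len(plan)
    gene_ids = [f"gene{j:04d}" for j in range(g)]
    planted_idx = rng.choice(g, size=n_planted, replace=False)

    baseline = rng.uniform(cfg.baseline_low, cfg.baseline_high, size=g)
    # planted genes sit on a high-expressed baseline so a -signal deviation
    # stays non-negative
    baseline[planted_idx] += cfg.signal

    profiles = np.tile(baseline, (k, 1))
    defining: list[dict[str, list[str]]] = [
        {"positive": [], "negative": []} for _ in range(k)
    ]
    for gene_pos, assignments in zip(planted_idx, plan):
        for archetype, sign in assignments:
            profiles[archetype, gene_pos] = baseline[gene_pos] + sign * cfg.signal
            key = "positive" if sign > 0 else "negative"
            defining[archetype][key].append(gene_ids[gene_pos])
    np.clip(profiles, 0.0, None, out=profiles)

    weights = rng.dirichlet(cfg.dirichlet_alpha, size=n)
    expr = weights @ profiles
    if cfg.noise_sd > 0:
        expr = expr + rng.normal(0.0, cfg.noise_sd, size=expr.shape)
    np.clip(expr, 0.0, None, out=expr)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    expression = ExpressionMatrix(values=expr, sample_ids=sample_ids, gene_ids=gene_ids)

    labels: dict[str, str] = {}
    covariate: dict[str, float] = {}
    if cfg.attribute_archetype is not None:
        w_target = weights[:, cfg.attribute_archetype]
        p_target = np.clip(0.2 + 0.7 * w_target, 0.0, 1.0)
        draw = rng.random(n)
        other = rng.random(n)
        for i, s in enumerate(sample_ids):
            if draw[i] < p_target[i]:
                labels[s] = "A"
            else:
                labels[s] = "B" if other[i] < 0.5 else "C"
        cov = 2.0 + 8.0 * w_target + rng.normal(0.0, 1.0, size=n)
        covariate = {s: float(c) for s, c in zip(sample_ids, cov)}

    return SyntheticTruth(
        config=cfg,
        archetype_profiles=profiles,
        weights=weights,
        defining_genes=defining,
        discrete_labels=labels,
        continuous_covariate=covariate,
        expression=expression,
    )


def recovery_error(
    truth: SyntheticTruth, fitted_archetypes: np.ndarray, pca=None
) -> float:
    """Mean gene-space distance between true and fitted archetypes after
    optimal one-to-one (Hungarian) matching.

    ``fitted_archetypes`` may be given in gene space (k x n_genes) or in PC
    space (k x d) together with the ``pca`` model used, in which case they
    are back-projected via ``means + coords @ loadings.T``.
    """
    true = np.asarray(truth.archetype_profiles, dtype=float)
    fitted = np.asarray(fitted_archetypes, dtype=float)
    if fitted.shape[0] != true.shape[0]:
        raise ValueError(
            f"expected {true.shape[0]} fitted archetypes, got {fitted.shape[0]}"
        )
    if fitted.shape[1] != true.shape[1]:
        if pca is None:
            raise ValueError(
                f"fitted archetypes have dimension {fitted.shape[1]} but gene space "
                f"has {true.shape[1]}; pass the PCA model to back-project"
            )
        d = fitted.shape[1]
        if d > pca.loadings.shape[1]:
            raise ValueError("fitted dimension exceeds PCA dimension")
        fitted = pca.means + fitted @ pca.loadings[:, :d].T
    dist = np.linalg.norm(true[:, None, :] - fitted[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(dist)
    return float(dist[rows, cols].mean())
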