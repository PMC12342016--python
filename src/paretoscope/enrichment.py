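"""Gene-set enrichment and archetype-attribute association tests.

Enrichment of a defining-gene list in annotated sets uses the one-sided
hypergeometric (Fisher) over-representation test against the universe of
genes that survived the informative-gene filter, with Benjamini-Hochberg
FDR adjustment across sets.  Archetype-attribute association compares the
samples closest to an archetype (the top ``bin_fraction`` by mixture
weight) with the rest: hypergeometric over-representation per category for
discrete attributes, two-sided Mann-Whitney for continuous ones, BH across
the archetype x attribute family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import AttributeTable, GeneSetCollection
from .simplex import SimplexFit

__all__ = [
    "EnrichmentResult",
    "AttributeAssociation",
    "hypergeometric_enrichment",
    "bh_adjust",
    "bin_samples_by_archetype",
    "attribute_discrete",
    "attribute_continuous",
    "test_attributes",
]


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    list_size: int
    set_size: int
    universe_size: int
    p_raw: float
    q_bh: float


@dataclass
class AttributeAssociation:
    archetype_index: int
    attribute: str
    kind: str                 # "discrete" | "continuous"
    category: str | None
    effect: float             # fold-enrichment or median difference
    p_raw: float
    q_bh: float
    n_bin: int
    n_rest: int


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def hypergeometric_enrichment(
    gene_list, gene_sets: GeneSetCollection, universe
) -> list[EnrichmentResult]:
    """One-sided over-representation of ``gene_list`` in each gene set.

    P = P(X >= overlap) with X ~ Hypergeometric(N=|universe|,
    K=|set & universe|, n=|list|); sets are intersected with the universe
    before testing, and BH adjustment runs across all sets tested.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uset = set(universe)
    glist = set(gene_list)
    if not glist <= uset:
        raise ValueError("gene list contains genes outside the universe")
    N, n = len(uset), len(glist)
    results = []
    for name, (_, members) in gene_sets.sets.items():
        inset = set(members) & uset
        K = len(inset)
        overlap = len(glist & inset)
        if n == 0 or K == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=overlap,
                list_size=n,
                set_size=K,
                universe_size=N,
                p_raw=min(p, 1.0),
                q_bh=math.nan,
            )
        )
    if results:
        q = bh_adjust([max(r.p_raw, 1e-300) for r in results])
        for r, qv in zip(results, q):
            r.q_bh = float(qv)
    return results


def bin_samples_by_archetype(
    fit: SimplexFit, archetype_index: int, sample_ids: list[str], bin_fraction: float = 0.1
) -> tuple[list[str], list[str]]:
    """Split samples into the ceil(bin_fraction * n) with highest weight on
    the archetype versus the rest; ties break by sample id."""
    if not 0 < bin_fraction <= 1:
        raise ValueError("bin_fraction must lie in (0, 1]")
    w = fit.weights[:, archetype_index]
    n = len(sample_ids)
    n_bin = math.ceil(bin_fraction * n)
    order = sorted(range(n), key=lambda i: (-w[i], sample_ids[i]))
    bin_ids = sorted(sample_ids[i] for i in order[:n_bin])
    rest_ids = sorted(sample_ids[i] for i in order[n_bin:])
    return bin_ids, rest_ids


def _mannwhitney_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p by enumeration (tie-safe).

    Enumerates every assignment of the pooled values into the two groups and
    counts assignments whose U deviates from its mean at least as much as
    observed.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    const = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - const
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - const
        if abs(u - mu) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney p: exact enumeration for combined n <= 20,
    normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) + len(y) <= 20:
        return _mannwhitney_exact_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def attribute_discrete(
    fit: SimplexFit,
    labels: dict[str, str],
    archetype_index: int,
    sample_ids: list[str],
    bin_fraction: float = 0.1,
    attribute: str = "label",
) -> list[AttributeAssociation]:
    """Per-category hypergeometric over-representation inside the archetype bin.

    Samples without a label are excluded test-wise.  The returned q-values
    are BH-adjusted across this call's categories; family-wide adjustment
    across archetypes is applied by :func:`test_attributes`.
    """
    labelled = [s for s in sample_ids if s in labels]
    bin_ids, _ = bin_samples_by_archetype(fit, archetype_index, sample_ids, bin_fraction)
    bin_lab = [s for s in bin_ids if s in labels]
    N, n = len(labelled), len(bin_lab)
    results = []
    for cat in sorted(set(labels[s] for s in labelled)):
        K = sum(1 for s in labelled if labels[s] == cat)
        x = sum(1 for s in bin_lab if labels[s] == cat)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if n and K else 1.0
        cohort_prev = K / N
        bin_prev = x / n if n else 0.0
        results.append(
            AttributeAssociation(
                archetype_index=archetype_index,
                attribute=attribute,
                kind="discrete",
                category=cat,
                effect=(bin_prev / cohort_prev) if cohort_prev > 0 else math.nan,
                p_raw=min(p, 1.0),
                q_bh=math.nan,
                n_bin=n,
                n_rest=N - n,
            )
        )
    if results:
        q = bh_adjust([max(r.p_raw, 1e-300) for r in results])
        for r, qv in zip(results, q):
            r.q_bh = float(qv)
    return results


def attribute_continuous(
    fit: SimplexFit,
    values: dict[str, float],
    archetype_index: int,
    sample_ids: list[str],
    bin_fraction: float = 0.1,
    attribute: str = "covariate",
) -> AttributeAssociation:
    """Mann-Whitney comparison of a continuous attribute, bin vs rest.

    Effect is median(bin) - median(rest) in the attribute's units; samples
    with missing values are dropped test-wise.
    """
    bin_ids, rest_ids = bin_samples_by_archetype(fit, archetype_index, sample_ids, bin_fraction)
    x = np.array([values[s] for s in bin_ids if s in values])
    y = np.array([values[s] for s in rest_ids if s in values])
    p = mannwhitney_p(x, y)
    return AttributeAssociation(
        archetype_index=archetype_index,
        attribute=attribute,
        kind="continuous",
        category=None,
        effect=float(np.median(x) - np.median(y)),
        p_raw=p,
        q_bh=math.nan,
        n_bin=len(x),
        n_rest=len(y),
    )


def test_attributes(
    fit: SimplexFit,
    attributes: AttributeTable,
    sample_ids: list[str],
    bin_fraction: float = 0.1,
) -> list[AttributeAssociation]:
    """All archetypes x all attributes, with BH across the whole family
    (separately for discrete categories and continuous attributes)."""
    discrete: list[AttributeAssociation] = []
    continuous: list[AttributeAssociation] = []
    for a in range(fit.k):
        for col, labels in attributes.discrete.items():
            discrete.extend(
                attribute_discrete(fit, labels, a, sample_ids, bin_fraction, attribute=col)
            )
        for col, values in attributes.continuous.items():
            continuous.append(
                attribute_continuous(fit, values, a, sample_ids, bin_fraction, attribute=col)
            )
    for group in (discrete, continuous):
        if group:
            q = bh_adjust([max(r.p_raw, 1e-300) for r in group])
            for r, qv in zip(group, q):
                r.q_bh = float(qv)
    return discrete + continuous
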