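"""Archetype-defining genes: back-projection, elbow cutoffs, and sharing.

Each archetype's PC-space position is back-projected to gene space as a
*centered* reconstruction (``loadings @ coords``), so a coefficient is the
gene's deviation at the archetype from the cohort average; positive means
over-expressed there, negative under-expressed.  Ordered coefficient curves
are cliff-shaped — most genes near zero, a few extreme — and the
45-degree-line elbow rule picks the cutoffs for the positive and negative
defining-gene lists, separately per tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._chord import chord_knee
from .pca import PCAModel
from .simplex import SimplexFit

logger = logging.getLogger(__name__)

__all__ = [
    "ArchetypeProfile",
    "ArchetypeGeneLists",
    "OverlapSummary",
    "archetype_gene_coefficients",
    "find_elbow_cutoff",
    "select_defining_genes",
    "overlap_summary",
]


@dataclass
class ArchetypeProfile:
    archetype_index: int
    gene_ids: list[str]
    coefficients: np.ndarray  # per-gene centered reconstruction at the archetype

    @property
    def order(self) -> np.ndarray:
        """Gene indices sorted by coefficient, descending."""
        return np.argsort(-self.coefficients, kind="stable")


@dataclass
class ArchetypeGeneLists:
    positive_genes: list[list[str]]
    negative_genes: list[list[str]]
    positive_cutoffs: list[float | None]
    negative_cutoffs: list[float | None]

    @property
    def k(self) -> int:
        return len(self.positive_genes)

    def genes_of(self, archetype: int) -> set[str]:
        return set(self.positive_genes[archetype]) | set(self.negative_genes[archetype])


@dataclass
class OverlapSummary:
    n_unique_genes: int
    n_shared_genes: int
    shared_fraction: float
    pairwise_counts: np.ndarray
    ribbon_table: pd.DataFrame = field(repr=False, default=None)


def archetype_gene_coefficients(fit: SimplexFit, pca: PCAModel) -> list[ArchetypeProfile]:
    """Centered gene-space coefficients of each archetype.

    ``coefficients = loadings[:, :d] @ archetype_pc``; adding the PCA means
    recovers the archetype's reconstructed expression-space position.
    """
    d = fit.archetypes_pc.shape[1]
    if d > pca.d:
        raise ValueError(f"fit uses {d} dimensions but PCA provides {pca.d}")
    gene_ids = getattr(pca, "gene_ids", None) or [f"g{i}" for i in range(pca.loadings.shape[0])]
    profiles = []
    for a in range(fit.k):
        coeff = pca.loadings[:, :d] @ fit.archetypes_pc[a]
        profiles.append(
            ArchetypeProfile(archetype_index=a, gene_ids=list(gene_ids), coefficients=coeff)
        )
    return profiles


def find_elbow_cutoff(sorted_values: np.ndarray) -> int:
    """Elbow index of a non-increasing curve by the normalized 45-degree rule.

    Both axes are scaled to [0, 1]; the elbow is where a slope -1 line
    touches the curve (maximum perpendicular distance from the first-last
    chord, on the side the curve bends).  The returned index is the last
    point *included* before the break; ties resolve to the earliest index.
    Constant input raises; an essentially straight curve logs a
    low-curvature warning.
    """
    v = np.asarray(sorted_values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values")
    if np.any(np.diff(v) > 1e-12 * max(1.0, float(np.abs(v).max()))):
        raise ValueError("values must be non-increasing")
    idx, strength = chord_knee(v)
    if strength < 1e-9:
        logger.warning("curve is essentially straight; elbow index %d is arbitrary", idx)
    return idx


def _select_tail(values: np.ndarray, gene_ids: list[str]) -> tuple[list[str], float | None]:
    """Apply the elbow to one tail of |coefficients| sorted descending."""
    if values.size == 0:
        return [], None
    order = np.argsort(-values, kind="stable")
    sorted_vals = values[order]
    if sorted_vals.size < 3 or sorted_vals[0] - sorted_vals[-1] <= 1e-12 * max(1.0, sorted_vals[0]):
        # too few genes in the tail for an elbow: keep them all
        idx = sorted_vals.size - 1
    else:
        idx = find_elbow_cutoff(sorted_vals)
    cutoff = float(sorted_vals[idx])
    selected = [gene_ids[order[i]] for i in range(idx + 1)]
    return selected, cutoff


def select_defining_genes(profiles: list[ArchetypeProfile] | ArchetypeProfile) -> ArchetypeGeneLists:
    """Positive and negative defining-gene lists per archetype.

    The elbow rule runs separately on the descending positive coefficients
    and on the magnitudes of the negative coefficients; genes at or beyond
    each cutoff form the lists.  An empty tail yields an empty list.
    """
    if isinstance(profiles, ArchetypeProfile):
        profiles = [profiles]
    pos_lists, neg_lists, pos_cuts, neg_cuts = [], [], [], []
    for prof in profiles:
        c = prof.coefficients
        gene_ids = prof.gene_ids
        pos_mask = c > 0
        neg_mask = c < 0
        pos, pos_cut = _select_tail(c[pos_mask], [g for g, m in zip(gene_ids, pos_mask) if m])
        neg, neg_cut = _select_tail(-c[neg_mask], [g for g, m in zip(gene_ids, neg_mask) if m])
        if not pos:
            logger.info("archetype %d has no positive defining genes", prof.archetype_index)
        if not neg:
            logger.info("archetype %d has no negative defining genes", prof.archetype_index)
        pos_lists.append(pos)
        neg_lists.append(neg)
        pos_cuts.append(pos_cut)
        neg_cuts.append(None if neg_cut is None else -neg_cut)
    return ArchetypeGeneLists(
        positive_genes=pos_lists,
        negative_genes=neg_lists,
        positive_cutoffs=pos_cuts,
        negative_cutoffs=neg_cuts,
    )


def overlap_summary(lists: ArchetypeGeneLists) -> OverlapSummary:
    """Cross-archetype gene sharing.

    A gene is shared when it appears (either sign) in the lists of at least
    two archetypes.  The ribbon table enumerates each shared
    (archetype pair, gene) with the gene's sign in each archetype, suitable
    for circular-plot tools.
    """
    k = lists.k
    membership: dict[str, dict[int, str]] = {}
    for a in range(k):
        for g in lists.positive_genes[a]:
            membership.setdefault(g, {})[a] = "+"
        for g in lists.negative_genes[a]:
            # a gene cannot be both + and - within one archetype by construction
            membership.setdefault(g, {})[a] = "-"
    n_unique = len(membership)
    shared = {g: m for g, m in membership.items() if len(m) >= 2}
    pairwise = np.zeros((k, k), dtype=int)
    rows = []
    for g in sorted(shared):
        m = shared[g]
        archs = sorted(m)
        for i, a in enumerate(archs):
            for b in archs[i + 1 :]:
                pairwise[a, b] += 1
                pairwise[b, a] += 1
                rows.append(
                    {"archetype_a": a, "archetype_b": b, "gene": g, "sign_a": m[a], "sign_b": m[b]}
                )
    for a in range(k):
        pairwise[a, a] = len(lists.genes_of(a))
    ribbon = pd.DataFrame(rows, columns=["archetype_a", "archetype_b", "gene", "sign_a", "sign_b"])
    return OverlapSummary(
        n_unique_genes=n_unique,
        n_shared_genes=len(shared),
        shared_fraction=(len(shared) / n_unique) if n_unique else 0.0,
        pairwise_counts=pairwise,
        ribbon_table=ribbon,
    )
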