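"""The t-ratio statistic and its randomization test.

The t-ratio is the volume of the best-fitting data-constrained simplex
divided by the volume of the convex hull of the data in the leading K-1 PC
coordinates; since the simplex's vertices are data points it is contained in
the hull and t lies in (0, 1].  Values near 1 mean the data essentially fill
a simplex.  Significance comes from refitting after randomizations that
destroy inter-gene structure: either shuffling raw gene columns and redoing
PCA (faithful, slow) or shuffling the PC coordinate columns directly (fast).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .io import ExpressionMatrix
from .pca import fit_pca
from .simplex import DegenerateGeometryError, fit_simplex, max_volume_simplex

logger = logging.getLogger(__name__)

__all__ = ["TRatioTestResult", "simplex_volume", "hull_volume", "t_ratio_test"]

SCHEMES = ("shuffle_genes_then_pca", "shuffle_pc_columns")


@dataclass
class TRatioTestResult:
    t_observed: float
    t_null: np.ndarray
    p_value: float                  # (1 + #{null >= obs}) / (1 + n_rand)
    p_uncorrected: float            # #{null >= obs} / n_rand
    n_randomizations: int
    randomization_scheme: str
    seed: int


def simplex_volume(vertices: np.ndarray) -> float:
    """Volume of the simplex with k vertices in k-1 dimensions:
    |det([v2-v1; ...; vk-v1])| / (k-1)!."""
    V = np.asarray(vertices, dtype=float)
    k, d = V.shape
    if d != k - 1:
        raise ValueError(f"expected k x (k-1) vertex matrix, got {V.shape}")
    M = V[1:] - V[0]
    return abs(float(np.linalg.det(M))) / math.factorial(k - 1)


def hull_volume(points: np.ndarray) -> float:
    """Convex-hull volume of a full-dimensional point cloud."""
    P = np.asarray(points, dtype=float)
    if P.ndim == 2 and P.shape[1] == 1:
        length = float(P.max() - P.min())
        if length <= 0.0:
            raise DegenerateGeometryError("all points identical; hull has zero length")
        return length
    try:
        return float(ConvexHull(P).volume)
    except QhullError as exc:
        raise DegenerateGeometryError(
            "convex hull is degenerate (rank-deficient point cloud); "
            "reduce to the spanned dimensions first"
        ) from exc


def _t_for_points(P: np.ndarray, k: int, n_restarts: int, rng: np.random.Generator) -> float:
    verts, vol = max_volume_simplex(P, k, n_restarts, rng)
    return vol / hull_volume(P)


def t_ratio_test(
    x,
    k: int,
    n_rand: int,
    scheme: str = "shuffle_genes_then_pca",
    seed: int = 0,
    n_restarts: int = 10,
    max_redraws: int = 100,
) -> TRatioTestResult:
    """One-sided randomization test of the t-ratio (large t = simplex-like).

    Parameters
    ----------
    x : ExpressionMatrix or ndarray
        Raw expression (required for ``shuffle_genes_then_pca``) or a
        points matrix whose leading k-1 columns are PC coordinates.
    k : int
        Number of simplex vertices.
    scheme : {"shuffle_genes_then_pca", "shuffle_pc_columns"}
        Null model: independently permute raw gene columns across samples
        and recompute PCA per replicate, or permute the PC coordinate
        columns directly.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    m = k - 1
    rng = np.random.default_rng(seed)

    if isinstance(x, ExpressionMatrix) or (scheme == "shuffle_genes_then_pca"):
        if not isinstance(x, ExpressionMatrix):
            raise ValueError("shuffle_genes_then_pca requires an ExpressionMatrix input")
        raw = x.values
        P_obs = fit_pca(x, m).scores
    else:
        raw = None
        P_obs = np.asarray(x, dtype=float)[:, :m]

    fit = fit_simplex(P_obs, k, n_restarts=n_restarts, seed=int(rng.integers(2**31)))
    t_obs = simplex_volume(fit.archetypes_pc[:, :m]) / hull_volume(P_obs)

    t_null = np.empty(n_rand)
    redraws = 0
    b = 0
    while b < n_rand:
        try:
            if scheme == "shuffle_genes_then_pca":
                shuffled = rng.permuted(raw, axis=0)
                P = fit_pca(shuffled, m).scores
            else:
                P = rng.permuted(P_obs, axis=0)
            t_null[b] = _t_for_points(P, k, n_restarts, rng)
        except DegenerateGeometryError:
            redraws += 1
            if redraws > max_redraws:
                raise
            continue
        b += 1
    if redraws:
        logger.warning("redrew %d degenerate randomization replicates", redraws)

    exceed = int(np.sum(t_null >= t_obs))
    return TRatioTestResult(
        t_observed=float(t_obs),
        t_null=t_null,
        p_value=(1.0 + exceed) / (1.0 + n_rand),
        p_uncorrected=exceed / n_rand,
        n_randomizations=n_rand,
        randomization_scheme=scheme,
        seed=seed,
    )
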