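"""Best-fitting data-constrained simplex in PC space.

The fitter places the K vertices *on data points* (strict data constraint)
and maximizes the volume of the (K-1)-simplex they span in the leading K-1
PC coordinates: greedy successive volume maximization from randomized
starts, refined by single-vertex swap hill-climbing to a local optimum.
Per-sample mixture weights solve a simplex-constrained least-squares
problem, and the explained sample variance (ESV)

    ESV = 1 - sum ||x_i - w_i A||^2 / sum ||x_i - mean||^2

drives the elbow choice of K.  Archetype-position uncertainty comes from a
sample bootstrap with assignment-matched vertices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from scipy.stats import chi2

from ._chord import chord_knee
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimplexFit",
    "BootstrapResult",
    "fit_simplex",
    "decompose_weights",
    "explained_sample_variance",
    "select_k_elbow",
    "bootstrap_archetypes",
]

ALGORITHM_ID = "greedy-volume-swap"


class DegenerateGeometryError(ValueError):
    """Raised when the point cloud cannot support a non-degenerate simplex."""


@dataclass
class SimplexFit:
    k: int
    archetypes_pc: np.ndarray           # k x d vertex coordinates (PC space)
    vertex_sample_indices: np.ndarray | None
    weights: np.ndarray                 # n x k, rows on the probability simplex
    esv: float
    algorithm: str = ALGORITHM_ID
    seed: int = 0


@dataclass
class BootstrapResult:
    replicate_archetypes: list[np.ndarray]
    ellipse_areas: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    n_boot: int = 0
    n_dropped: int = 0
    seed: int = 0


def _as_points(x) -> np.ndarray:
    if isinstance(x, ExpressionMatrix):
        return x.values
    return np.asarray(x, dtype=float)


def _greedy_vertices(P: np.ndarray, k: int, start: int) -> tuple[list[int], float]:
    """Greedy successive volume maximization from a start vertex.

    Each step adds the point farthest from the affine span of the current
    vertex set (equivalently, the point maximizing the grown simplex
    volume).  Returns vertex indices and the simplex volume.
    """
    n, m = P.shape
    chosen = [start]
    R = P - P[start]
    log_prod = 0.0
    for j in range(k - 1):
        d2 = np.einsum("ij,ij->i", R, R)
        i = int(np.argmax(d2))
        dist = math.sqrt(d2[i])
        if dist <= 0.0:
            return chosen, 0.0
        u = R[i] / dist
        R = R - np.outer(R @ u, u)
        chosen.append(i)
        log_prod += math.log(dist)
    return chosen, math.exp(log_prod) / math.factorial(k - 1)


def _residual_distances(P: np.ndarray, base_points: np.ndarray) -> np.ndarray:
    """Distance of every point from the affine span of ``base_points``."""
    origin = base_points[0]
    B = base_points[1:] - origin
    q, _ = np.linalg.qr(B.T)  # m x (k-2) orthonormal basis
    R = P - origin
    proj = R @ q
    return np.sqrt(np.maximum(np.einsum("ij,ij->i", R, R) - np.einsum("ij,ij->i", proj, proj), 0.0))


def _swap_refine(P: np.ndarray, vertices: list[int], max_passes: int = 50) -> list[int]:
    """Single-vertex swap hill-climbing; ties keep the incumbent / lowest index."""
    k = len(vertices)
    verts = list(vertices)
    for _ in range(max_passes):
        improved = False
        for pos in range(k):
            others = [verts[i] for i in range(k) if i != pos]
            r = _residual_distances(P, P[others])
            best = int(np.argmax(r))
            if r[best] > r[verts[pos]] * (1.0 + 1e-12) and best not in others:
                verts[pos] = best
                improved = True
        if not improved:
            return verts
    return verts


def max_volume_simplex(
    P: np.ndarray, k: int, n_restarts: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Best (k-1)-simplex with vertices on data points of ``P`` (n x (k-1)).

    Restart 0 starts greedily from the point farthest from the centroid;
    remaining restarts start from random points.  Returns sorted vertex
    indices and the simplex volume.
    """
    n = P.shape[0]
    far = int(np.argmax(np.einsum("ij,ij->i", P - P.mean(axis=0), P - P.mean(axis=0))))
    starts = [far] + list(rng.integers(0, n, size=max(n_restarts - 1, 0)))
    best_idx: tuple[int, ...] | None = None
    best_vol = -1.0
    for start in starts:
        verts, vol = _greedy_vertices(P, k, int(start))
        if vol <= 0.0:
            continue
        verts = _swap_refine(P, verts)
        vol = _simplex_volume_from_indices(P, verts)
        cand = tuple(sorted(verts))
        if vol > best_vol * (1.0 + 1e-12) or (
            abs(vol - best_vol) <= 1e-12 * max(vol, best_vol) and (best_idx is None or cand < best_idx)
        ):
            best_vol = vol
            best_idx = cand
    if best_idx is None:
        raise DegenerateGeometryError("all points identical or rank-deficient; no simplex fits")
    return np.asarray(best_idx, dtype=int), best_vol


def _coverage_vertices(
    P: np.ndarray, k: int, n_restarts: int, rng: np.random.Generator
) -> np.ndarray:
    """Vertex selection when k exceeds the embedding dimension plus one.

    The first d+1 vertices maximize simplex volume as usual; further
    vertices greedily add the data point worst represented by the current
    archetype set (largest simplex-constrained residual), which is the
    natural coverage criterion once volume is saturated.
    """
    d = P.shape[1]
    base, _ = max_volume_simplex(P, d + 1, n_restarts, rng)
    verts = list(base)
    while len(verts) < k:
        A = P[verts]
        W = decompose_weights(P, A)
        resid = np.linalg.norm(P - W @ A, axis=1)
        resid[verts] = -1.0
        nxt = int(np.argmax(resid))
        if resid[nxt] <= 0.0 or nxt in verts:
            nxt = next(i for i in range(P.shape[0]) if i not in verts)
        verts.append(nxt)
    return np.asarray(sorted(verts), dtype=int)


def _simplex_volume_from_indices(P: np.ndarray, verts: list[int] | tuple[int, ...]) -> float:
    V = P[list(verts)]
    M = V[1:] - V[0]
    return abs(float(np.linalg.det(M))) / math.factorial(len(verts) - 1)


def fit_simplex(
    points, k: int, n_restarts: int = 10, seed: int = 0, trim_fraction: float = 0.0
) -> SimplexFit:
    """Fit the K-vertex data-constrained simplex.

    Vertices are chosen in the leading K-1 coordinates of ``points``; mixture
    weights and ESV use all supplied coordinates.  The computation runs on a
    canonical lexicographic row ordering, so the vertex *set* does not
    depend on input row order; returned indices refer to the input order.
    ``trim_fraction`` optionally excludes the most outlying points (by
    distance from the centroid) from vertex candidacy.
    """
    X = _as_points(points)
    n, d = X.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points n={n}")
    order = np.lexsort(X.T[::-1])  # canonical row order (first column primary)
    Xc = X[order]
    P = Xc[:, : min(k - 1, d)]
    if np.allclose(P, P[0]):
        raise DegenerateGeometryError("all points identical in the fitting coordinates")
    candidates = np.arange(n)
    if trim_fraction > 0.0:
        r = np.linalg.norm(P - P.mean(axis=0), axis=1)
        n_keep = max(k, int(math.ceil((1.0 - trim_fraction) * n)))
        candidates = np.sort(np.argsort(r)[:n_keep])
    rng = np.random.default_rng(seed)
    if d >= k - 1:
        local_idx, _ = max_volume_simplex(P[candidates], k, n_restarts, rng)
    else:
        local_idx = _coverage_vertices(P[candidates], k, n_restarts, rng)
    canon_idx = candidates[local_idx]
    orig_idx = np.sort(order[canon_idx])
    archetypes = X[orig_idx]
    weights = decompose_weights(X, archetypes)
    esv = explained_sample_variance(X, archetypes, weights)
    return SimplexFit(
        k=k,
        archetypes_pc=archetypes,
        vertex_sample_indices=orig_idx,
        weights=weights,
        esv=esv,
        algorithm=ALGORITHM_ID,
        seed=seed,
    )


def decompose_weights(points, archetypes: np.ndarray) -> np.ndarray:
    """Simplex-constrained least squares: min ||x - w A||, w >= 0, sum w = 1.

    Solved per sample by non-negative least squares on a system augmented
    with a heavily weighted sum-to-one row.
    """
    X = _as_points(points)
    A = np.asarray(archetypes, dtype=float)
    k = A.shape[0]
    scale = max(1.0, float(np.abs(A).max()))
    M = 1e4 * scale
    system = np.vstack([A.T, np.full((1, k), M)])
    W = np.empty((X.shape[0], k))
    for i, x in enumerate(X):
        target = np.concatenate([x, [M]])
        w, _ = nnls(system, target)
        s = w.sum()
        W[i] = w / s if s > 0 else np.full(k, 1.0 / k)
    return W


def explained_sample_variance(points, fit, weights: np.ndarray | None = None) -> float:
    """ESV = 1 - residual / total variance of points around their mean."""
    X = _as_points(points)
    if isinstance(fit, SimplexFit):
        A, W = fit.archetypes_pc, fit.weights
    else:
        A = np.asarray(fit, dtype=float)
        W = weights if weights is not None else decompose_weights(X, A)
    total = float(((X - X.mean(axis=0)) ** 2).sum())
    if total <= 0.0:
        raise DegenerateGeometryError("zero total variance; ESV undefined")
    resid = float(((X - W @ A) ** 2).sum())
    return 1.0 - resid / total


def select_k_elbow(
    points,
    k_min: int = 2,
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 10,
    return_curve: bool = False,
):
    """Choose K at the elbow of the ESV-vs-K curve.

    Fits every K in [k_min, k_max] with shared restart settings, checks that
    ESV is non-decreasing within a small tolerance (a violation indicates a
    fit failure), and locates the elbow of the normalized curve by the
    45-degree chord construction.  A near-straight curve triggers a
    low-curvature warning but still returns the maximum-distance point.
    """
    X = _as_points(points)
    if k_max > X.shape[0]:
        raise ValueError("k_max exceeds number of points")
    if k_max - k_min < 2:
        raise ValueError("need at least 3 candidate values of k for an elbow")
    ks = list(range(k_min, k_max + 1))
    esv = []
    for k in ks:
        fit = fit_simplex(X, k, n_restarts=n_restarts, seed=seed)
        esv.append(fit.esv)
    esv = np.asarray(esv)
    drops = np.diff(esv)
    if (drops < -0.05).any():
        raise RuntimeError(f"ESV decreased by more than tolerance along k: {esv}")
    idx, strength = chord_knee(esv[::-1])  # reversed curve is non-increasing
    k_elbow = ks[len(ks) - 1 - idx]
    if strength < 0.05:
        logger.warning(
            "ESV-vs-k curve has low curvature (knee strength %.3f); "
            "elbow at k=%d is weakly determined",
            strength,
            k_elbow,
        )
    if return_curve:
        return k_elbow, dict(zip(ks, esv.tolist()))
    return k_elbow


def align_to_reference(candidate: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Reorder candidate vertices to minimize total distance to reference."""
    dist = np.linalg.norm(reference[:, None, :] - candidate[None, :, :], axis=2)
    _, cols = linear_sum_assignment(dist)
    return candidate[cols]


def bootstrap_archetypes(
    points,
    k: int,
    n_boot: int = 1000,
    seed: int = 0,
    n_restarts: int = 10,
    reference: SimplexFit | None = None,
) -> BootstrapResult:
    """Bootstrap uncertainty of archetype positions.

    Samples are resampled with replacement, the simplex is refit, and each
    replicate's vertices are aligned to the reference fit by minimal-distance
    assignment.  Per archetype and per PC plane, the area of the 95%
    covariance ellipse of replicate positions is reported.  Degenerate
    replicate fits are dropped and counted.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = _as_points(points)
    n, d = X.shape
    if reference is None:
        reference = fit_simplex(X, k, n_restarts=n_restarts, seed=seed)
    ref = reference.archetypes_pc
    rng = np.random.default_rng(seed)
    reps: list[np.ndarray] = []
    dropped = 0
    m = k - 1
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        B = X[idx]
        try:
            verts, vol = max_volume_simplex(B[:, :m], k, n_restarts, rng)
        except DegenerateGeometryError:
            dropped += 1
            continue
        if vol <= 0.0:
            dropped += 1
            continue
        reps.append(align_to_reference(B[verts], ref))
    if dropped:
        logger.warning("dropped %d degenerate bootstrap replicates", dropped)
    if not reps:
        raise DegenerateGeometryError("every bootstrap replicate was degenerate")
    stack = np.stack(reps)  # r x k x d
    planes = [(0, 1)]
    if d >= 3:
        planes += [(0, 2), (1, 2)]
    scale = chi2.ppf(0.95, df=2)
    areas: dict[tuple[int, int], np.ndarray] = {}
    for a, b in planes:
        vals = np.empty(k)
        for j in range(k):
            cov = np.cov(stack[:, j, a], stack[:, j, b])
            vals[j] = math.pi * scale * math.sqrt(max(float(np.linalg.det(cov)), 0.0))
        areas[(a, b)] = vals
    return BootstrapResult(
        replicate_archetypes=reps,
        ellipse_areas=areas,
        n_boot=n_boot,
        n_dropped=dropped,
        seed=seed,
    )
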