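"""PCA and its permutation validation.

Two distinct PCA variants are used deliberately.  Simplex fitting downstream
works on covariance PCA of the raw TPM matrix (column-centered, unscaled),
computed by :func:`fit_pca`.  The permutation validation, by contrast,
follows the eigenvalue-based sphericity statistics of permutation-PCA
testing: Psi and Phi are computed from the eigenvalues of the *correlation*
matrix (standardized variables),

    Psi = sum_i (lambda_i - 1)^2        Phi = sqrt(Psi / (p (p - 1)))

where p is the number of variables.  Under no inter-gene correlation all
eigenvalues are 1 and both statistics vanish; a permutation null is built by
independently shuffling each gene column across samples, which destroys
correlation while preserving marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "PCAModel",
    "PCAValidationResult",
    "fit_pca",
    "psi_statistic",
    "phi_statistic",
    "correlation_eigenvalues",
    "pca_permutation_test",
]


@dataclass
class PCAModel:
    """Column-centered covariance PCA of a samples x genes matrix."""

    means: np.ndarray               # per-gene means
    loadings: np.ndarray            # genes x d, orthonormal columns
    scores: np.ndarray              # samples x d
    eigenvalues: np.ndarray         # d, non-increasing
    explained_fraction: np.ndarray  # d, fractions of total variance
    gene_ids: list[str] | None = None

    @property
    def d(self) -> int:
        return self.loadings.shape[1]

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.means) @ self.loadings

    def inverse_transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        d = coords.shape[-1]
        return self.means + coords @ self.loadings[:, :d].T


@dataclass
class PCAValidationResult:
    psi_observed: float
    phi_observed: float
    psi_null: np.ndarray
    phi_null: np.ndarray
    p_psi: float
    p_phi: float
    p_psi_uncorrected: float
    n_significant_pcs: int
    genes_significant_per_pc: np.ndarray
    n_permutations: int
    seed: int


def fit_pca(x: ExpressionMatrix | np.ndarray, d: int) -> PCAModel:
    """SVD-based PCA on column-centered (unscaled) data.

    Sign convention: the largest-magnitude entry of each loading column is
    made positive, so the decomposition is deterministic.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    n, g = values.shape
    if d > min(n - 1, g):
        raise ValueError(f"d={d} exceeds min(n_samples - 1, n_genes) = {min(n - 1, g)}")
    means = values.mean(axis=0)
    centered = values - means
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    loadings = vt[:d].T
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = centered @ loadings
    eigenvalues = (s[:d] ** 2) / (n - 1)
    total_var = float((centered**2).sum()) / (n - 1)
    explained = eigenvalues / total_var if total_var > 0 else np.zeros(d)
    return PCAModel(
        means=means,
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        explained_fraction=explained,
        gene_ids=list(x.gene_ids) if isinstance(x, ExpressionMatrix) else None,
    )


def correlation_eigenvalues(values: np.ndarray) -> np.ndarray:
    """Eigenvalues of the correlation matrix via SVD of standardized columns.

    Zero-variance columns (possible in permutation replicates of constant
    genes) are treated as uncorrelated: they contribute an eigenvalue slot
    but no correlation, i.e. they are standardized to zero.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    centered = values - values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    std = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    s = np.linalg.svd(std, compute_uv=False)
    lam = np.zeros(p)
    lam[: len(s)] = s**2 / (n - 1)
    return lam


def psi_statistic(eigenvalues_corr: np.ndarray) -> float:
    """Psi = sum (lambda - 1)^2 over correlation-matrix eigenvalues."""
    lam = np.asarray(eigenvalues_corr, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    return float(np.sum((lam - 1.0) ** 2))


def phi_statistic(eigenvalues_corr: np.ndarray, p: int | None = None) -> float:
    """Phi = sqrt(Psi / (p (p - 1)))."""
    lam = np.asarray(eigenvalues_corr, dtype=float)
    if p is None:
        p = lam.size
    if p < 2:
        raise ValueError("need p >= 2 variables")
    return float(np.sqrt(psi_statistic(lam) / (p * (p - 1))))


def _permute_columns(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return rng.permuted(values, axis=0)


def pca_permutation_test(
    x: ExpressionMatrix | np.ndarray,
    n_perm: int,
    seed: int,
    alpha: float = 0.05,
    n_boot: int | None = None,
    max_pcs: int | None = None,
) -> PCAValidationResult:
    """Permutation validation of PCA (Psi/Phi, significant PCs, gene counts).

    Each permutation replicate shuffles every gene column independently
    across samples.  P-values carry the (b+1)/(B+1) correction and can never
    be exactly zero; the uncorrected exceedance fraction for Psi is reported
    alongside.  A PC is significant when its observed correlation-matrix
    eigenvalue exceeds the (1 - alpha) quantile of the permutation null of
    the same-rank eigenvalue.  Per-PC significant gene counts use bootstrap
    percentile confidence intervals on gene-score correlations excluding 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    n, p = values.shape
    if n_boot is None:
        n_boot = n_perm
    rng = np.random.default_rng(seed)

    lam_obs = correlation_eigenvalues(values)
    psi_obs = psi_statistic(lam_obs)
    phi_obs = phi_statistic(lam_obs)

    psi_null = np.empty(n_perm)
    phi_null = np.empty(n_perm)
    n_track = lam_obs.size if max_pcs is None else min(max_pcs, lam_obs.size)
    lam_null = np.empty((n_perm, n_track))
    for b in range(n_perm):
        lam = correlation_eigenvalues(_permute_columns(values, rng))
        psi_null[b] = psi_statistic(lam)
        phi_null[b] = phi_statistic(lam)
        lam_null[b] = lam[:n_track]

    p_psi = (1.0 + np.sum(psi_null >= psi_obs)) / (1.0 + n_perm)
    p_phi = (1.0 + np.sum(phi_null >= phi_obs)) / (1.0 + n_perm)
    p_psi_unc = float(np.mean(psi_null >= psi_obs))

    thresh = np.quantile(lam_null, 1.0 - alpha, axis=0)
    sig = lam_obs[:n_track] > thresh
    # significant PCs are counted as the leading run; a late eigenvalue
    # exceeding its null after a non-significant one is noise
    n_sig = int(np.argmin(sig)) if not sig.all() else int(sig.size)

    genes_sig = _bootstrap_gene_counts(values, max(n_sig, 1) if n_sig else 0, n_boot, alpha, rng)

    return PCAValidationResult(
        psi_observed=psi_obs,
        phi_observed=phi_obs,
        psi_null=psi_null,
        phi_null=phi_null,
        p_psi=float(p_psi),
        p_phi=float(p_phi),
        p_psi_uncorrected=p_psi_unc,
        n_significant_pcs=n_sig,
        genes_significant_per_pc=genes_sig,
        n_permutations=n_perm,
        seed=seed,
    )


def _bootstrap_gene_counts(
    values: np.ndarray, n_pcs: int, n_boot: int, alpha: float, rng: np.random.Generator
) -> np.ndarray:
    """Count genes whose bootstrap CI of the gene-score correlation excludes 0.

    Bootstrap samples are projected onto the reference (full-data) loading
    directions; refitting PCA per replicate would let component signs and
    order jitter, which artificially widens the intervals.
    """
    if n_pcs == 0:
        return np.zeros(0, dtype=int)
    n = values.shape[0]
    ref = fit_pca(values, min(n_pcs, n - 1, values.shape[1]))
    n_pcs = ref.d
    corrs = np.empty((n_boot, values.shape[1], n_pcs))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = values[idx]
        scores = (boot - boot.mean(axis=0)) @ ref.loadings
        corrs[b] = _gene_score_correlations(boot, scores, n_pcs)
    lo = np.quantile(corrs, alpha / 2.0, axis=0)
    hi = np.quantile(corrs, 1.0 - alpha / 2.0, axis=0)
    return ((lo > 0) | (hi < 0)).sum(axis=0).astype(int)


def _gene_score_correlations(values: np.ndarray, scores: np.ndarray, n_pcs: int) -> np.ndarray:
    centered = values - values.mean(axis=0)
    sd_g = centered.std(axis=0, ddof=1)
    sc = scores[:, :n_pcs] - scores[:, :n_pcs].mean(axis=0)
    sd_s = sc.std(axis=0, ddof=1)
    num = centered.T @ sc / (values.shape[0] - 1)
    denom = np.outer(sd_g, sd_s)
    # genes with zero variance get correlation 0 by convention
    return np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
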