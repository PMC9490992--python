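"""Sample-by-sample relationship matrices.

Two constructions are provided:

* the VanRaden genomic relationship matrix
  ``G = Z Z' / (2 * sum_i p_i (1 - p_i))`` with ``Z`` the column-centered
  dosage matrix (``dosage - 2p``), the classical additive GRM; and
* the cosine kernel ``K(x_i, x_j) = <x_i, x_j> / (||x_i|| * ||x_j||)``
  applied to any per-sample feature rows — raw 0/1/2 SNP dosages for the
  genomic kernel G, raw FPKM profiles for the transcriptomic kernel T.

Cosine kernels receive an additive diagonal regularization ``K + C*I``
(default C = 0.05) so that the diagonal blocks inverted by the hybrid
single-step constructions are safely non-singular; the amount added is
recorded on the returned matrix.
"""

from __future__ import annotations

import numpy as np

from .containers import GenotypeMatrix, RelationshipMatrix

__all__ = [
    "allele_frequencies",
    "impute_mean_dosage",
    "vanraden_g",
    "cosine_kernel",
    "cosine_g",
    "cosine_t",
    "is_psd",
]

DEFAULT_JITTER_C = 0.05


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Per-marker allele frequency p_i = mean non-missing dosage / 2.

    Markers must be polymorphic; a fixed marker (p = 0 or 1) should have
    been removed by QC and raises here.
    """
    d = geno.dosages
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    fixed = np.flatnonzero(np.isnan(p) | (p <= 0.0) | (p >= 1.0))
    if fixed.size:
        bad = [geno.marker_ids[j] for j in fixed[:5]]
        raise ValueError(
            f"fixed or all-missing markers {bad}; run QC (MAF filter) first"
        )
    return p


def impute_mean_dosage(geno: GenotypeMatrix,
                       p: np.ndarray | None = None) -> np.ndarray:
    """Dosage matrix with missing entries replaced by the marker mean 2p."""
    if p is None:
        p = allele_frequencies(geno)
    d = geno.dosages.copy()
    miss = np.isnan(d)
    if miss.any():
        d[miss] = np.broadcast_to(2.0 * p, d.shape)[miss]
    return d


def vanraden_g(geno: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from additive dosages."""
    p = allele_frequencies(geno)
    d = impute_mean_dosage(geno, p)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("zero VanRaden denominator: all markers fixed")
    Z = d - 2.0 * p
    G = Z @ Z.T / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(list(geno.sample_ids), G, provenance="vanraden_G")


def cosine_kernel(features: np.ndarray,
                  sample_ids: list[str],
                  jitter_c: float = DEFAULT_JITTER_C,
                  provenance: str = "cosine") -> RelationshipMatrix:
    """Cosine-similarity kernel of per-sample feature rows, plus C*I.

    Pre-jitter the diagonal is exactly 1 and the matrix is the Gram matrix
    of unit vectors, hence positive semi-definite and scale-invariant in
    each sample's features.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(sample_ids):
        raise ValueError("features must be an n_samples x n_features matrix")
    if jitter_c < 0:
        raise ValueError("jitter_c must be >= 0")
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        bad = [sample_ids[i] for i in zero[:5]]
        raise ValueError(f"zero-norm feature rows for samples {bad}")
    U = X / norms[:, None]
    K = U @ U.T
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    if jitter_c:
        K = K + jitter_c * np.eye(K.shape[0])
    return RelationshipMatrix(list(sample_ids), K, provenance=provenance,
                              jitter_applied=float(jitter_c))


def cosine_g(geno: GenotypeMatrix,
             jitter_c: float = DEFAULT_JITTER_C) -> RelationshipMatrix:
    """Cosine genomic kernel from raw 0/1/2 dosages (missing mean-imputed)."""
    d = impute_mean_dosage(geno)
    return cosine_kernel(d, geno.sample_ids, jitter_c, provenance="cosine_G")


def cosine_t(expr, jitter_c: float = DEFAULT_JITTER_C,
             log1p: bool = False) -> RelationshipMatrix:
    """Cosine transcriptomic kernel from raw FPKM profiles.

    ``log1p`` optionally applies log(1 + FPKM) before kernelizing; off by
    default (the cosine form already normalizes per sample).
    """
    X = expr.abundances
    if log1p:
        X = np.log1p(X)
    return cosine_kernel(X, expr.sample_ids, jitter_c, provenance="cosine_T")


def is_psd(K: np.ndarray | RelationshipMatrix,
           tol: float = 1e-8) -> tuple[bool, float]:
    """Whether a symmetric matrix is PSD within ``tol``; also the min eigenvalue."""
    values = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("matrix must be square")
    if np.abs(values - values.T).max() > 1e-8:
        raise ValueError("matrix must be symmetric")
    min_eig = float(np.linalg.eigvalsh(values)[0])
    return min_eig >= -tol, min_eig
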