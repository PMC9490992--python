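"""Prediction-accuracy assessment and experiment drivers.

Accuracy is the Pearson correlation ``r(y*, GEBV)`` between adjusted
phenotypes and predicted genetic values of held-out animals. Two schemes
are provided: leave-one-out (each of the n animals predicted from the
other n-1, one correlation over all n held-out predictions) and
replicated k-fold (default five replicates of fivefold, one correlation
per validation fold, summarized as the mean of the k x replicates fold
correlations).

Variance components inside CV follow ``vc_policy``: ``fit-once`` (default)
estimates them a single time — on the full data for LOO, on each fold's
training set would be ``refit-per-fold`` — while ``refit-per-fold``
re-runs REML on every training set, which is what the brute-force oracle
in the test-suite mirrors.

On top sit three experiment drivers: the MBLUP blending-ratio sweep, the
wmssBLUP weight sweep, and the transcribed-proportion experiment that
grows the genotyped-only population around a fixed transcribed core.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import (
    AlignedBundle,
    CVResult,
    GridSearchResult,
    RelationshipMatrix,
    VarianceComponents,
)
from . import kernels as _kernels
from .mixedmodel import blend_m, blend_tw, build_hybrid, blup_predict, reml_fit

__all__ = [
    "pearson_accuracy",
    "loocv",
    "kfold_cv",
    "grid_search_ratio",
    "grid_search_w",
    "proportion_experiment",
]


def pearson_accuracy(y_star: np.ndarray, gebv: np.ndarray) -> float:
    """Sample Pearson correlation between adjusted phenotypes and GEBVs."""
    y = np.asarray(y_star, dtype=float)
    g = np.asarray(gebv, dtype=float)
    if y.size != g.size:
        raise ValueError("y* and GEBV vectors differ in length")
    if y.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(y) == 0 or np.ptp(g) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(y, g).statistic)


def _resolve_vc(y: np.ndarray, K: RelationshipMatrix, train_idx: np.ndarray,
                vc_policy: str, vc_full: VarianceComponents | None,
                ) -> VarianceComponents:
    if vc_policy == "fit-once":
        assert vc_full is not None
        return vc_full
    if vc_policy == "refit-per-fold":
        ids = [K.sample_ids[i] for i in train_idx]
        return reml_fit(y[train_idx], K.submatrix(ids))
    raise ValueError(f"unknown vc_policy {vc_policy!r}")


def loocv(y_star: np.ndarray, K: RelationshipMatrix,
          vc_policy: str = "fit-once") -> CVResult:
    """Leave-one-out accuracy: each animal predicted from all others.

    Returns one Pearson correlation computed over the n held-out
    predictions against y*.
    """
    y = np.asarray(y_star, dtype=float)
    n = K.n_samples
    if y.size != n:
        raise ValueError("y* must be aligned with K")
    if n < 10:
        raise ValueError("need at least 10 samples for LOO")
    vc_full = reml_fit(y, K) if vc_policy == "fit-once" else None
    preds = np.empty(n)
    ids = K.sample_ids
    for i in range(n):
        train_idx = np.delete(np.arange(n), i)
        try:
            vc = _resolve_vc(y, K, train_idx, vc_policy, vc_full)
            g = blup_predict(y, K, [ids[j] for j in train_idx], [ids[i]], vc)
        except Exception as e:
            raise RuntimeError(f"LOO fold {i} (sample {ids[i]!r}) failed: {e}") from e
        preds[i] = g.gebv[0]
    r = pearson_accuracy(y, preds)
    return CVResult(scheme="loo", k=n, n_replicates=1, seed=None,
                    fold_assignments=[np.arange(n)],
                    fold_accuracies=np.array([r]), predictions=preds)


def _make_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random k-partition as a fold-label array; sizes differ by at most 1."""
    labels = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


def kfold_cv(y_star: np.ndarray, K: RelationshipMatrix,
             k: int = 5, replicates: int = 5, seed: int = 0,
             vc_policy: str = "fit-once") -> CVResult:
    """Replicated k-fold CV; one Pearson r per validation fold.

    The summary accuracy is the mean of the ``k * replicates`` fold-level
    correlations. Identical seeds give bitwise-identical folds and
    accuracies.
    """
    y = np.asarray(y_star, dtype=float)
    n = K.n_samples
    if y.size != n:
        raise ValueError("y* must be aligned with K")
    if n < k:
        raise ValueError(f"need at least k={k} samples")
    rng = np.random.default_rng(seed)
    vc_full = reml_fit(y, K) if vc_policy == "fit-once" else None
    ids = K.sample_ids
    fold_assignments, accs = [], []
    for rep in range(replicates):
        labels = _make_folds(n, k, rng)
        fold_assignments.append(labels)
        for f in range(k):
            val = np.flatnonzero(labels == f)
            tr = np.flatnonzero(labels != f)
            vc = _resolve_vc(y, K, tr, vc_policy, vc_full)
            g = blup_predict(y, K, [ids[j] for j in tr], [ids[j] for j in val], vc)
            accs.append(pearson_accuracy(y[val], g.gebv))
    return CVResult(scheme="kfold", k=k, n_replicates=replicates, seed=seed,
                    fold_assignments=fold_assignments,
                    fold_accuracies=np.array(accs))


def _cv_accuracy(y: np.ndarray, K: RelationshipMatrix, scheme: str,
                 k: int, replicates: int, seed: int, vc_policy: str) -> float:
    if scheme == "loo":
        return loocv(y, K, vc_policy=vc_policy).mean_accuracy
    if scheme == "kfold":
        return kfold_cv(y, K, k=k, replicates=replicates, seed=seed,
                        vc_policy=vc_policy).mean_accuracy
    raise ValueError(f"unknown CV scheme {scheme!r}")


def _argmax_smallest(grid: np.ndarray, accs: np.ndarray) -> int:
    """Index of the maximum accuracy; ties resolved toward the smaller parameter."""
    return int(np.flatnonzero(accs == np.max(accs))[0])


def grid_search_ratio(G: RelationshipMatrix, T: RelationshipMatrix,
                      y_star: np.ndarray,
                      grid: np.ndarray | None = None,
                      scheme: str = "loo", k: int = 5, replicates: int = 5,
                      seed: int = 0, vc_policy: str = "fit-once",
                      ) -> GridSearchResult:
    """Sweep the MBLUP blend M = ratio*G + (1-ratio)*T over a ratio grid.

    The default grid is 0.01 to 0.99 in steps of 0.01 (99 points). Requires
    a fully transcribed population (G and T over the same samples).
    """
    if grid is None:
        grid = np.round(np.arange(0.01, 1.00, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(y_star, dtype=float)
    accs = np.empty(grid.size)
    for i, ratio in enumerate(grid):
        M = blend_m(G, T, float(ratio))
        accs[i] = _cv_accuracy(y, M, scheme, k, replicates, seed, vc_policy)
    best = _argmax_smallest(grid, accs)
    return GridSearchResult(parameter="ratio", grid=grid, accuracies=accs,
                            best_value=float(grid[best]),
                            best_accuracy=float(accs[best]))


def grid_search_w(bundle: AlignedBundle, y_star: np.ndarray,
                  grid: np.ndarray | None = None,
                  scheme: str = "kfold", k: int = 5, replicates: int = 5,
                  seed: int = 0, vc_policy: str = "fit-once",
                  jitter_c: float = _kernels.DEFAULT_JITTER_C,
                  expr_log1p: bool = False,
                  ) -> GridSearchResult:
    """Sweep the wmssBLUP weight w over a grid (default 0, 0.1, ..., 1).

    ``y_star`` must be aligned with the bundle's sample order. The w = 1
    entry reduces to GBLUP on the cosine genomic kernel under the same
    folds and seed.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.01, 0.1), 1)
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(y_star, dtype=float)
    G = _kernels.cosine_g(bundle.geno, jitter_c)
    t_ids = bundle.transcribed_ids
    T = _kernels.cosine_t(bundle.expr.subset_samples(t_ids), jitter_c,
                          log1p=expr_log1p)
    G22 = G.submatrix(t_ids)
    accs = np.empty(grid.size)
    for i, w in enumerate(grid):
        Tw = blend_tw(T, G22, float(w))
        Hmw = build_hybrid(G, Tw, bundle.transcribed_idx, w=float(w)).matrix
        accs[i] = _cv_accuracy(y, Hmw, scheme, k, replicates, seed, vc_policy)
    best = _argmax_smallest(grid, accs)
    return GridSearchResult(parameter="w", grid=grid, accuracies=accs,
                            best_value=float(grid[best]),
                            best_accuracy=float(accs[best]))


def proportion_experiment(bundle: AlignedBundle, y_star: np.ndarray,
                          sizes: list[int] | None = None,
                          w: float = 0.5, k: int = 5, replicates: int = 5,
                          seed: int = 0, vc_policy: str = "fit-once",
                          jitter_c: float = _kernels.DEFAULT_JITTER_C,
                          expr_log1p: bool = False,
                          ) -> list[dict]:
    """Grow the genotyped-only population around the fixed transcribed core.

    For each requested size, that many genotyped-only animals are drawn at
    random, combined with every transcribed animal, and both wmssBLUP (at
    the given w) and GBLUP (cosine genomic kernel) are scored by replicated
    k-fold CV on the combined set. Each row reports the paired accuracies
    plus the absolute and relative improvement of wmssBLUP over GBLUP.
    """
    y = np.asarray(y_star, dtype=float)
    pool = bundle.untranscribed_idx
    if sizes is None:
        sizes = _default_proportion_sizes(pool.size)
    rng = np.random.default_rng(seed)
    ids = bundle.sample_ids
    t_idx = bundle.transcribed_idx
    t_ids = bundle.transcribed_ids
    T = _kernels.cosine_t(bundle.expr.subset_samples(t_ids), jitter_c,
                          log1p=expr_log1p)
    rows = []
    for size in sizes:
        if size > pool.size:
            raise ValueError(f"size {size} exceeds the genotyped-only pool "
                             f"({pool.size})")
        chosen = np.sort(rng.choice(pool, size=size, replace=False))
        sel = np.concatenate([chosen, t_idx])  # transcribed block stays last
        sub_ids = [ids[i] for i in sel]
        sub_geno = bundle.geno.subset_samples(sub_ids)
        G = _kernels.cosine_g(sub_geno, jitter_c)
        block2 = np.arange(size, size + t_idx.size)
        Tw = blend_tw(T, G.submatrix(t_ids), w)
        Hmw = build_hybrid(G, Tw, block2, w=w).matrix
        y_sub = y[sel]
        cv_seed = int(rng.integers(0, 2**31 - 1))
        acc_w = kfold_cv(y_sub, Hmw, k=k, replicates=replicates, seed=cv_seed,
                         vc_policy=vc_policy).mean_accuracy
        acc_g = kfold_cv(y_sub, G, k=k, replicates=replicates, seed=cv_seed,
                         vc_policy=vc_policy).mean_accuracy
        rows.append({
            "size": int(size),
            "n_total": int(size + t_idx.size),
            "transcribed_fraction": t_idx.size / (size + t_idx.size),
            "accuracy_wmss": acc_w,
            "accuracy_gblup": acc_g,
            "improvement_abs": acc_w - acc_g,
            "improvement_pct": 100.0 * (acc_w - acc_g) / abs(acc_g)
            if acc_g != 0 else np.nan,
        })
    return rows


def _default_proportion_sizes(pool: int, n_points: int = 7) -> list[int]:
    """Seven evenly spaced genotyped-only subset sizes ending at the full pool."""
    return [int(round(pool * (i + 1) / n_points)) for i in range(n_points)]
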