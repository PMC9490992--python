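"""Phenotype adjustment, blended/hybrid relationship matrices, REML and BLUP.

The model family shares one animal model. Phenotypes are first adjusted
for fixed effects by OLS, ``y = X beta + y*``, and the residual ``y*`` is
modelled as ``y* = gamma + e`` with ``gamma ~ N(0, K sigma_g^2)`` and
``e ~ N(0, I sigma_e^2)``, where ``K`` is the model-specific relationship
matrix:

* GBLUP — VanRaden G or the cosine genomic kernel;
* TBLUP — cosine transcriptomic kernel T;
* MBLUP — the blend ``M = ratio * G + (1 - ratio) * T`` (all samples must
  have both omics layers);
* mssBLUP / wmssBLUP — a single-step style hybrid ``Hm`` that embeds T
  (or the blend ``Tw = (1 - w) T + w G22``) into the transcribed block of
  the genome-wide G, so animals without expression data borrow
  transcriptomic information through their genomic relationships.

Narrow-sense heritability is ``h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2)``.

The hybrid matrix uses the standard single-step correction

    Hm11 = G11 + G12 G22^-1 (T - G22) G22^-1 G21
    Hm12 = G12 G22^-1 T,   Hm21 = Hm12',   Hm22 = T

with block 2 = the transcribed animals. This is the unique block form
consistent with the closed-form inverse

    Hm^-1 = G^-1 + [[0, 0], [0, T^-1 - G22^-1]]

and with the sanity requirement that T = G22 collapses Hm to G.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .containers import (
    AdjustedPhenotypes,
    AlignedBundle,
    GEBVSet,
    HybridMatrix,
    PhenotypeTable,
    RelationshipMatrix,
    VarianceComponents,
)
from . import kernels as _kernels

__all__ = [
    "adjust_phenotypes",
    "blend_m",
    "blend_tw",
    "build_hybrid",
    "invert_hybrid",
    "reml_fit",
    "blup_predict",
    "build_model_kernel",
    "fit_model",
    "MODELS",
]

MODELS = ("GBLUP", "TBLUP", "MBLUP", "mssBLUP", "wmssBLUP")


# ---------------------------------------------------------------------------
# fixed-effect adjustment


def _build_design(pheno: PhenotypeTable, covariates: dict[str, str],
                  rows: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(rows))]
    names = ["intercept"]
    for name, kind in covariates.items():
        if kind == "continuous":
            cols.append(rows[name].to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(rows[name].astype(str).unique())
            for lev in levels[1:]:  # first level absorbed by the intercept
                cols.append((rows[name].astype(str) == lev).to_numpy(float))
                names.append(f"{name}[{lev}]")
    return np.column_stack(cols), names


def adjust_phenotypes(pheno: PhenotypeTable,
                      trait: str | None = None,
                      covariates: dict[str, str] | None = None,
                      ) -> AdjustedPhenotypes:
    """OLS fixed-effect adjustment: returns ``y* = y - X beta_hat``.

    Categorical covariates are expanded to indicator columns with the first
    level dropped; an intercept is always included, so ``y*`` has mean zero.
    Samples with a missing trait or covariate value are excluded from the
    fit and from the output (their count is recorded in ``n_dropped``).
    """
    trait = trait or pheno.trait
    covariates = dict(pheno.covariate_kinds if covariates is None else covariates)
    needed = [trait] + list(covariates)
    rows = pheno.data[needed].dropna()
    n_dropped = len(pheno.data) - len(rows)
    X, names = _build_design(pheno, covariates, rows)
    if len(rows) < X.shape[1] + 2:
        raise ValueError(
            f"need at least {X.shape[1] + 2} complete samples for "
            f"{X.shape[1]} design columns, have {len(rows)}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the dependent columns via pivoted QR
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        dep = [names[j] for j in piv[rank:]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dep}")
    y = rows[trait].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    y_star = y - X @ beta
    return AdjustedPhenotypes(
        sample_ids=[str(i) for i in rows.index],
        y_star=y_star,
        beta=beta,
        design_columns=names,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# blended and hybrid relationship matrices


def blend_m(G: RelationshipMatrix, T: RelationshipMatrix,
            ratio: float) -> RelationshipMatrix:
    """M = ratio * G + (1 - ratio) * T; equals G at ratio 1 and T at ratio 0."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    if G.sample_ids != T.sample_ids:
        raise ValueError("G and T must cover the same samples in the same order")
    M = ratio * G.values + (1.0 - ratio) * T.values
    return RelationshipMatrix(list(G.sample_ids), M, provenance="M",
                              jitter_applied=ratio * G.jitter_applied
                              + (1 - ratio) * T.jitter_applied)


def blend_tw(T: RelationshipMatrix, G22: RelationshipMatrix,
             w: float) -> RelationshipMatrix:
    """Tw = (1 - w) * T + w * G22 over the transcribed samples.

    ``w`` is the share of genetic relationships not captured by expression;
    w = 0 gives pure T, w = 1 recovers the genomic block G22.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    if T.n_samples != G22.n_samples:
        raise ValueError(
            f"T ({T.n_samples}) and G22 ({G22.n_samples}) dimension mismatch"
        )
    if T.sample_ids != G22.sample_ids:
        raise ValueError("T and G22 must cover the same samples in the same order")
    Tw = (1.0 - w) * T.values + w * G22.values
    return RelationshipMatrix(list(T.sample_ids), Tw, provenance="Tw",
                              jitter_applied=(1 - w) * T.jitter_applied
                              + w * G22.jitter_applied)


def _split_partition(G_full: RelationshipMatrix, T: RelationshipMatrix,
                     block2_idx: np.ndarray):
    b2 = np.asarray(block2_idx, dtype=int)
    n = G_full.n_samples
    if b2.size == 0 or b2.size > n:
        raise ValueError("block-2 (transcribed) index set is empty or too large")
    if len(set(b2.tolist())) != b2.size or b2.min() < 0 or b2.max() >= n:
        raise ValueError("block-2 indices must be unique positions in G")
    t_ids = [G_full.sample_ids[i] for i in b2]
    if T.sample_ids != t_ids:
        raise ValueError(
            "T sample IDs do not match the block-2 partition of G "
            f"(expected {t_ids[:3]}..., got {T.sample_ids[:3]}...)"
        )
    mask = np.ones(n, dtype=bool)
    mask[b2] = False
    b1 = np.flatnonzero(mask)
    return b1, b2


def build_hybrid(G_full: RelationshipMatrix, T_or_Tw: RelationshipMatrix,
                 block2_idx: np.ndarray,
                 w: float | None = None) -> HybridMatrix:
    """Embed the transcriptomic kernel into the genome-wide G single-step style.

    ``block2_idx`` gives the positions of the transcribed animals within
    ``G_full``; ``T_or_Tw`` must cover exactly those samples in that order.
    The result keeps ``G_full``'s sample order.
    """
    b1, b2 = _split_partition(G_full, T_or_Tw, block2_idx)
    G = G_full.values
    T = T_or_Tw.values
    G11 = G[np.ix_(b1, b1)]
    G12 = G[np.ix_(b1, b2)]
    G22 = G[np.ix_(b2, b2)]
    try:
        B = linalg.solve(G22, G12.T, assume_a="sym")  # G22^-1 G21
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "G22 is singular; rebuild the genomic kernel with diagonal jitter"
        ) from None
    Hm = np.empty_like(G)
    Hm[np.ix_(b2, b2)] = T
    Hm12 = B.T @ T  # G12 G22^-1 T
    Hm[np.ix_(b1, b2)] = Hm12
    Hm[np.ix_(b2, b1)] = Hm12.T
    Hm[np.ix_(b1, b1)] = G11 + B.T @ (T - G22) @ B
    Hm = (Hm + Hm.T) / 2.0
    provenance = "Hmw" if w is not None else "Hm"
    rel = RelationshipMatrix(list(G_full.sample_ids), Hm, provenance=provenance,
                             jitter_applied=G_full.jitter_applied)
    return HybridMatrix(matrix=rel, block1_idx=b1, block2_idx=b2, w=w,
                        g_provenance=G_full.provenance,
                        t_provenance=T_or_Tw.provenance)


def invert_hybrid(G_full: RelationshipMatrix, T_or_Tw: RelationshipMatrix,
                  block2_idx: np.ndarray) -> np.ndarray:
    """Closed-form inverse of the hybrid matrix:
    ``Hm^-1 = G^-1 + blockdiag(0, T^-1 - G22^-1)``.

    Equals the direct inverse of :func:`build_hybrid`'s output.
    """
    b1, b2 = _split_partition(G_full, T_or_Tw, block2_idx)
    G = G_full.values
    try:
        Ginv = linalg.inv(G)
        Tinv = linalg.inv(T_or_Tw.values)
        G22inv = linalg.inv(G[np.ix_(b2, b2)])
    except linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular G, G22 or T; rebuild kernels with diagonal jitter"
        ) from None
    Hinv = Ginv.copy()
    Hinv[np.ix_(b2, b2)] += Tinv - G22inv
    return (Hinv + Hinv.T) / 2.0


# ---------------------------------------------------------------------------
# REML


def _as_y(y, K: RelationshipMatrix) -> np.ndarray:
    if isinstance(y, AdjustedPhenotypes):
        return y.values_for(K.sample_ids)
    y = np.asarray(y, dtype=float)
    if y.size != K.n_samples:
        raise ValueError(f"y length {y.size} does not match K ({K.n_samples})")
    return y


def reml_fit(y, K: RelationshipMatrix,
             log10_delta_bounds: tuple[float, float] = (-8.0, 8.0),
             ) -> VarianceComponents:
    """REML variance components for ``y* = gamma + e``, gamma ~ N(0, K sg2).

    Works in the eigenbasis of K: with ``K = U diag(d) U'`` and
    ``u = U' y``, the restricted likelihood is profiled over
    ``sigma_g^2`` and maximized over ``delta = sigma_e^2 / sigma_g^2``
    by bounded scalar search on ``log10 delta``. Estimates on the
    boundary of the ``h2`` range are flagged, and their asymptotic
    standard errors (from the Fisher information of (sg2, se2)) are
    omitted.
    """
    yv = _as_y(y, K)
    n = yv.size
    if n < 10:
        raise ValueError("need at least 10 samples for REML")
    if not np.isfinite(yv).all():
        raise ValueError("y contains non-finite values")
    if np.ptp(yv) == 0:
        raise ValueError("y is constant; variance components are undefined")
    d, U = np.linalg.eigh(K.values)
    if np.ptp(d) <= 1e-8 * max(1.0, float(np.abs(d).max())):
        raise ValueError(
            "K is (proportional to) the identity: genetic and residual "
            "variance are not identifiable"
        )
    d = np.clip(d, 0.0, None)
    u2 = (U.T @ yv) ** 2

    def neg_profile_ll(log10_delta: float) -> float:
        delta = 10.0 ** log10_delta
        v = d + delta
        sg2 = float(np.mean(u2 / v))
        return 0.5 * (n * np.log(sg2) + float(np.sum(np.log(v))) + n)

    lo, hi = log10_delta_bounds
    # coarse log-spaced bracketing, then derivative-free refinement
    grid = np.linspace(lo, hi, 41)
    vals = [neg_profile_ll(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        neg_profile_ll,
        bounds=(max(lo, g0 - 1.0), min(hi, g0 + 1.0)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log10_delta = float(res.x)
    delta = 10.0 ** log10_delta
    v = d + delta
    sg2 = float(np.mean(u2 / v))
    se2 = sg2 * delta
    h2 = sg2 / (sg2 + se2)
    loglik = -neg_profile_ll(log10_delta) - 0.5 * n * np.log(2 * np.pi)
    at_boundary = bool(log10_delta <= lo + 1e-3 or log10_delta >= hi - 1e-3)

    se_sg2 = se_se2 = se_h2 = None
    if not at_boundary:
        vv = sg2 * d + se2
        info = 0.5 * np.array([
            [np.sum((d / vv) ** 2), np.sum(d / vv**2)],
            [np.sum(d / vv**2), np.sum(1.0 / vv**2)],
        ])
        try:
            cov = np.linalg.inv(info)
            se_sg2 = float(np.sqrt(max(cov[0, 0], 0.0)))
            se_se2 = float(np.sqrt(max(cov[1, 1], 0.0)))
            tot = sg2 + se2
            grad = np.array([se2, -sg2]) / tot**2
            se_h2 = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        except np.linalg.LinAlgError:
            pass

    return VarianceComponents(
        sigma_g2=sg2, sigma_e2=se2, h2=float(h2),
        se_sigma_g2=se_sg2, se_sigma_e2=se_se2, se_h2=se_h2,
        loglik=float(loglik), converged=bool(res.success),
        at_boundary=at_boundary,
    )


# ---------------------------------------------------------------------------
# BLUP prediction


def blup_predict(y_star, K: RelationshipMatrix,
                 train_ids: list[str], target_ids: list[str],
                 vc: VarianceComponents) -> GEBVSet:
    """BLUP conditional mean of the genetic values of ``target_ids``.

    ``gamma_hat = K[target, train] (K[train, train] + delta I)^-1 y*_train``
    with ``delta = sigma_e^2 / sigma_g^2``; one phenotype record per animal
    (identity incidence). Targets may overlap the training set.
    """
    pos = {s: i for i, s in enumerate(K.sample_ids)}
    try:
        tr = np.array([pos[str(s)] for s in train_ids], dtype=int)
        tg = np.array([pos[str(s)] for s in target_ids], dtype=int)
    except KeyError as e:
        raise KeyError(f"sample {e.args[0]!r} not in the relationship matrix") from None
    if isinstance(y_star, AdjustedPhenotypes):
        y_tr = y_star.values_for([str(s) for s in train_ids])
    else:
        y_star = np.asarray(y_star, dtype=float)
        if y_star.size != K.n_samples:
            raise ValueError("y_star must be aligned with K sample order")
        y_tr = y_star[tr]
    if not np.isfinite(y_tr).all():
        raise ValueError("training phenotypes must be complete")
    delta = vc.delta
    if not np.isfinite(delta):
        gebv = np.zeros(tg.size)  # sigma_g^2 = 0: complete shrinkage
    else:
        A = K.values[np.ix_(tr, tr)] + delta * np.eye(tr.size)
        try:
            c = linalg.cho_factor(A)
            alpha = linalg.cho_solve(c, y_tr)
        except linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular training system (delta ~ 0 with rank-deficient K); "
                "add diagonal jitter to the kernel"
            ) from None
        gebv = K.values[np.ix_(tg, tr)] @ alpha
    return GEBVSet(sample_ids=[str(s) for s in target_ids], gebv=gebv,
                   train_ids=[str(s) for s in train_ids], vc=vc)


# ---------------------------------------------------------------------------
# model dispatch


def _canonical_model(model: str) -> str:
    key = model.replace("-", "").replace("_", "").lower()
    table = {m.lower(): m for m in MODELS}
    if key not in table:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return table[key]


def build_model_kernel(bundle: AlignedBundle, model: str,
                       ratio: float = 0.5, w: float = 0.5,
                       genomic_kernel: str | None = None,
                       jitter_c: float = _kernels.DEFAULT_JITTER_C,
                       expr_log1p: bool = False,
                       ) -> RelationshipMatrix:
    """Construct the relationship matrix a given model runs on.

    ``genomic_kernel`` selects ``vanraden`` or ``cosine`` for the genomic
    side; the default is VanRaden for a standalone GBLUP and cosine
    everywhere a transcriptomic kernel is involved (MBLUP and the hybrid
    models blend/embed in cosine-kernel space).
    """
    model = _canonical_model(model)
    if model == "GBLUP":
        gk = genomic_kernel or "vanraden"
        if gk == "vanraden":
            return _kernels.vanraden_g(bundle.geno)
        if gk == "cosine":
            return _kernels.cosine_g(bundle.geno, jitter_c)
        raise ValueError(f"unknown genomic kernel {gk!r}")
    if model in ("TBLUP", "MBLUP"):
        if bundle.expr is None or not bundle.fully_transcribed:
            raise ValueError(
                f"{model} needs expression for every sample; for a partially "
                "transcribed population use mssBLUP or wmssBLUP"
            )
        order = bundle.transcribed_ids
        T = _kernels.cosine_t(bundle.expr.subset_samples(order), jitter_c,
                              log1p=expr_log1p)
        if model == "TBLUP":
            return T
        G = _kernels.cosine_g(bundle.geno.subset_samples(order), jitter_c)
        return blend_m(G, T, ratio)
    # hybrid models
    if bundle.expr is None or len(bundle.transcribed_idx) == 0:
        raise ValueError(f"{model} needs a transcribed subset with expression data")
    gk = genomic_kernel or "cosine"
    G = (_kernels.cosine_g(bundle.geno, jitter_c) if gk == "cosine"
         else _kernels.vanraden_g(bundle.geno))
    t_ids = bundle.transcribed_ids
    T = _kernels.cosine_t(bundle.expr.subset_samples(t_ids), jitter_c,
                          log1p=expr_log1p)
    if model == "wmssBLUP":
        G22 = G.submatrix(t_ids)
        T = blend_tw(T, G22, w)
    hyb = build_hybrid(G, T, bundle.transcribed_idx,
                       w=w if model == "wmssBLUP" else None)
    return hyb.matrix


def fit_model(bundle: AlignedBundle, model: str,
              trait: str | None = None,
              covariates: dict[str, str] | None = None,
              ratio: float = 0.5, w: float = 0.5,
              genomic_kernel: str | None = None,
              jitter_c: float = _kernels.DEFAULT_JITTER_C,
              ) -> tuple[RelationshipMatrix, VarianceComponents]:
    """Adjust the trait, build the model's kernel and fit REML components."""
    K = build_model_kernel(bundle, model, ratio=ratio, w=w,
                           genomic_kernel=genomic_kernel, jitter_c=jitter_c)
    adj = adjust_phenotypes(bundle.pheno, trait=trait, covariates=covariates)
    vc = reml_fit(adj, K)
    return K, vc
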