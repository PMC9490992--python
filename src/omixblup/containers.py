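"""Core in-memory containers shared across the toolkit.

All containers carry explicit sample identifiers so that multi-source
datasets (genotypes, expression, phenotypes) can be aligned safely; no
operation in the package matches samples by position alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "PhenotypeTable",
    "RelationshipMatrix",
    "AlignedBundle",
    "AdjustedPhenotypes",
    "VarianceComponents",
    "HybridMatrix",
    "GEBVSet",
    "QCReport",
    "CVResult",
    "GridSearchResult",
    "SimulationTruth",
]


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dup = set(), set()
        for i in ids:
            (dup if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what}: {sorted(dup)[:5]}")
    return ids


@dataclass
class GenotypeMatrix:
    """Additive SNP dosages for ``n`` samples by ``m`` markers.

    Dosages are stored as float64 with ``nan`` marking missing calls;
    every non-missing entry must be 0, 1 or 2 (count of one allele).
    Missingness is preserved here — imputation happens only at kernel
    construction time.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    marker_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ID")
        self.marker_ids = _check_unique(self.marker_ids, "marker ID")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad!r} is not 0/1/2/missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = _index_of(self.sample_ids, ids, "sample")
        return GenotypeMatrix(list(ids), list(self.marker_ids),
                              self.dosages[idx, :], self.marker_meta)

    def subset_markers(self, ids: list[str]) -> "GenotypeMatrix":
        idx = _index_of(self.marker_ids, ids, "marker")
        meta = None
        if self.marker_meta is not None:
            meta = self.marker_meta.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(list(self.sample_ids), list(ids),
                              self.dosages[:, idx], meta)


@dataclass
class ExpressionMatrix:
    """Gene-expression abundances (FPKM) for ``n`` samples by ``g`` genes."""

    sample_ids: list[str]
    gene_ids: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ID")
        self.gene_ids = _check_unique(self.gene_ids, "gene ID")
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"abundance shape {self.abundances.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.isfinite(self.abundances).all():
            raise ValueError("expression abundances must all be finite")
        if (self.abundances < 0).any():
            i, j = np.argwhere(self.abundances < 0)[0]
            raise ValueError(
                f"negative abundance for sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_samples(self, ids: list[str]) -> "ExpressionMatrix":
        idx = _index_of(self.sample_ids, ids, "sample")
        return ExpressionMatrix(list(ids), list(self.gene_ids),
                                self.abundances[idx, :])

    def subset_genes(self, ids: list[str]) -> "ExpressionMatrix":
        idx = _index_of(self.gene_ids, ids, "gene")
        return ExpressionMatrix(list(self.sample_ids), list(ids),
                                self.abundances[:, idx])


@dataclass
class PhenotypeTable:
    """Trait values plus fixed-effect covariates, one row per sample.

    ``covariate_kinds`` flags each covariate column ``categorical`` or
    ``continuous``; design-matrix expansion is deferred to
    :func:`omixblup.mixedmodel.adjust_phenotypes`.
    """

    data: pd.DataFrame  # indexed by sample ID
    trait: str
    covariate_kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = [str(i) for i in self.data.index]
        _check_unique(self.data.index, "sample ID")
        if self.trait not in self.data.columns:
            raise ValueError(f"trait column {self.trait!r} not in table")
        for c, kind in self.covariate_kinds.items():
            if c not in self.data.columns:
                raise ValueError(f"covariate column {c!r} not in table")
            if kind not in ("categorical", "continuous"):
                raise ValueError(f"covariate kind {kind!r} for {c!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_values(self) -> pd.Series:
        return self.data[self.trait]

    @property
    def missing_trait_ids(self) -> list[str]:
        return list(self.data.index[self.data[self.trait].isna()])

    def subset_samples(self, ids: list[str]) -> "PhenotypeTable":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"samples absent from phenotype table: {missing[:5]}")
        return PhenotypeTable(self.data.loc[list(ids)], self.trait,
                              dict(self.covariate_kinds))


@dataclass
class RelationshipMatrix:
    """Square symmetric sample-by-sample similarity matrix.

    ``provenance`` records how it was built (``vanraden_G``, ``cosine_G``,
    ``cosine_T``, ``M``, ``Tw``, ``Hm``, ``Hmw``); ``jitter_applied`` is the
    diagonal regularization that was added, if any.
    """

    sample_ids: list[str]
    values: np.ndarray
    provenance: str = "unknown"
    jitter_applied: float = 0.0

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample ID")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape}, expected ({n},{n})")
        if n and np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("relationship matrix is not symmetric (tol 1e-10)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        idx = _index_of(self.sample_ids, ids, "sample")
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                  self.provenance, self.jitter_applied)


@dataclass
class AlignedBundle:
    """Consistently ordered genotype/expression/phenotype views.

    Sample order follows the block-2 convention used by the hybrid
    relationship matrices: non-transcribed animals first, transcribed
    animals last, so that the transcriptome kernel occupies the trailing
    diagonal block.
    """

    geno: GenotypeMatrix
    pheno: PhenotypeTable
    expr: ExpressionMatrix | None = None
    transcribed_idx: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.geno.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.geno.n_samples

    @property
    def transcribed_ids(self) -> list[str]:
        return [self.geno.sample_ids[i] for i in self.transcribed_idx]

    @property
    def untranscribed_idx(self) -> np.ndarray:
        mask = np.ones(self.n_samples, dtype=bool)
        mask[self.transcribed_idx] = False
        return np.flatnonzero(mask)

    @property
    def fully_transcribed(self) -> bool:
        return len(self.transcribed_idx) == self.n_samples


@dataclass
class AdjustedPhenotypes:
    """OLS-adjusted phenotypes y* = y - X beta_hat and the fit that made them."""

    sample_ids: list[str]
    y_star: np.ndarray
    beta: np.ndarray
    design_columns: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.y_star = np.asarray(self.y_star, dtype=float)
        if len(self.sample_ids) != self.y_star.size:
            raise ValueError("y_star length does not match sample IDs")

    def values_for(self, ids: list[str]) -> np.ndarray:
        idx = _index_of(self.sample_ids, ids, "sample")
        return self.y_star[idx]


@dataclass
class VarianceComponents:
    """REML estimates for the one-random-effect animal model."""

    sigma_g2: float
    sigma_e2: float
    h2: float
    se_sigma_g2: float | None
    se_sigma_e2: float | None
    se_h2: float | None
    loglik: float
    converged: bool
    at_boundary: bool = False

    @property
    def delta(self) -> float:
        """Variance ratio sigma_e^2 / sigma_g^2 used by the BLUP equations."""
        if self.sigma_g2 <= 0:
            return np.inf
        return self.sigma_e2 / self.sigma_g2


@dataclass
class HybridMatrix:
    """Single-step style relationship matrix with its block partition."""

    matrix: RelationshipMatrix
    block1_idx: np.ndarray  # non-transcribed
    block2_idx: np.ndarray  # transcribed
    w: float | None = None
    g_provenance: str = ""
    t_provenance: str = ""

    @property
    def sample_ids(self) -> list[str]:
        return self.matrix.sample_ids

    @property
    def values(self) -> np.ndarray:
        return self.matrix.values


@dataclass
class GEBVSet:
    """Predicted genetic values for a set of target samples."""

    sample_ids: list[str]
    gebv: np.ndarray
    train_ids: list[str]
    vc: VarianceComponents | None = None

    def __post_init__(self) -> None:
        self.gebv = np.asarray(self.gebv, dtype=float)
        if len(self.sample_ids) != self.gebv.size:
            raise ValueError("GEBV length does not match target sample IDs")


@dataclass
class QCReport:
    """Bookkeeping for a filtering pass.

    ``n_removed_by_rule`` attributes each removed item to the first rule
    it failed (rules are applied in a fixed order), so the per-rule counts
    sum to the total number removed.
    """

    n_input: int
    n_output: int
    n_removed_by_rule: dict[str, int]
    removed_ids: dict[str, list[str]]

    def __post_init__(self) -> None:
        total = sum(self.n_removed_by_rule.values())
        if self.n_input - total != self.n_output:
            raise ValueError("QC accounting error: input - removed != output")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_removed_by_rule": dict(self.n_removed_by_rule),
            "removed_ids": {k: list(v) for k, v in self.removed_ids.items()},
        }


@dataclass
class CVResult:
    """Cross-validation accuracies (Pearson r between held-out GEBVs and y*)."""

    scheme: str  # "loo" or "kfold"
    k: int
    n_replicates: int
    seed: int | None
    fold_assignments: list[np.ndarray]  # one int array per replicate
    fold_accuracies: np.ndarray  # k * n_replicates entries (one for LOO)
    predictions: np.ndarray | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class GridSearchResult:
    """Accuracy curve over a blending-parameter grid."""

    parameter: str  # "ratio" or "w"
    grid: np.ndarray
    accuracies: np.ndarray
    best_value: float
    best_accuracy: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.accuracies = np.asarray(self.accuracies, dtype=float)


@dataclass
class SimulationTruth:
    """Ground truth stored alongside simulator output for scoring estimates."""

    seed: int
    h2: float | None = None
    mediation_share: float | None = None
    expr_h2: float | None = None
    marker_effects: np.ndarray | None = None
    causal_markers: np.ndarray | None = None
    cis_markers: list[np.ndarray] | None = None
    cis_effects: list[np.ndarray] | None = None
    genetic_expression: np.ndarray | None = None  # n x g genetic log-expression
    genetic_values: np.ndarray | None = None  # total genetic value per sample
    covariate_coefficients: dict[str, float] | None = None
    extras: dict = field(default_factory=dict)


def _index_of(universe: list[str], wanted, what: str) -> np.ndarray:
    pos = {s: i for i, s in enumerate(universe)}
    try:
        return np.array([pos[str(w)] for w in wanted], dtype=int)
    except KeyError as e:
        raise KeyError(f"unknown {what} ID {e.args[0]!r}") from None
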