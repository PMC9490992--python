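"""Marker- and gene-level quality-control filters.

SNP filters mirror PLINK semantics: individuals with a genotype missing
rate strictly above 10% are dropped first, then markers failing call rate
< 90%, minor allele frequency < 0.05 or a Hardy-Weinberg chi-square
p-value < 1e-6 are removed. Expression filtering discards genes whose
FPKM is below 0.1 in strictly more than 95% of samples. All thresholds
are strict inequalities, so boundary values survive.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, QCReport

__all__ = ["hwe_chisq_p", "filter_snps", "filter_genes"]


def hwe_chisq_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts are p^2, 2pq, q^2 at the observed allele
    frequency. A monomorphic marker is in trivial equilibrium and returns
    p = 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _marker_hwe_p(column: np.ndarray) -> float:
    obs = column[~np.isnan(column)]
    return hwe_chisq_p(int((obs == 2).sum()), int((obs == 1).sum()),
                       int((obs == 0).sum()))


def filter_snps(geno: GenotypeMatrix,
                maf_min: float = 0.05,
                call_rate_min: float = 0.90,
                hwe_p_min: float = 1e-6,
                sample_missing_max: float = 0.10,
                ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the sample-missingness, call-rate, MAF and HWE filters.

    Samples are filtered first; marker statistics are computed on the
    surviving samples. Each removed marker is attributed to the first rule
    it fails in the order call_rate, maf, hwe. Returns the filtered matrix
    and a :class:`QCReport` over markers (sample removals are reported
    under the ``sample_missing`` rule with sample IDs).
    """
    if geno.n_samples == 0 or geno.n_markers == 0:
        raise ValueError("empty genotype matrix")
    miss = geno.missing_mask
    sample_missing_rate = miss.mean(axis=1)
    bad_samples = sample_missing_rate > sample_missing_max
    kept_samples = [s for s, b in zip(geno.sample_ids, bad_samples) if not b]
    if not kept_samples:
        raise ValueError("all samples removed by the missing-rate filter; "
                         "review sample_missing_max")
    g = geno.subset_samples(kept_samples)

    removed: dict[str, list[str]] = {"sample_missing": [
        s for s, b in zip(geno.sample_ids, bad_samples) if b]}
    removed.update({"call_rate": [], "maf": [], "hwe": []})

    n = g.n_samples
    kept_markers = []
    for j, mid in enumerate(g.marker_ids):
        col = g.dosages[:, j]
        obs = col[~np.isnan(col)]
        call_rate = obs.size / n
        if call_rate < call_rate_min:
            removed["call_rate"].append(mid)
            continue
        if obs.size == 0:
            removed["call_rate"].append(mid)
            continue
        p = obs.mean() / 2.0
        maf = min(p, 1.0 - p)
        if maf < maf_min:
            removed["maf"].append(mid)
            continue
        if _marker_hwe_p(col) < hwe_p_min:
            removed["hwe"].append(mid)
            continue
        kept_markers.append(mid)

    if not kept_markers:
        raise ValueError("all markers removed by QC; review the thresholds")
    report = QCReport(
        n_input=geno.n_markers,
        n_output=len(kept_markers),
        n_removed_by_rule={r: len(ids) for r, ids in removed.items()
                           if r != "sample_missing"},
        removed_ids=removed,
    )
    return g.subset_markers(kept_markers), report


def filter_genes(expr: ExpressionMatrix,
                 min_fpkm: float = 0.1,
                 max_low_prop: float = 0.95,
                 ) -> tuple[ExpressionMatrix, QCReport]:
    """Drop genes expressed below ``min_fpkm`` in more than ``max_low_prop``
    of samples (strictly greater; a gene low in exactly that fraction stays).
    """
    if expr.n_samples == 0 or expr.n_genes == 0:
        raise ValueError("empty expression matrix")
    low_prop = (expr.abundances < min_fpkm).mean(axis=0)
    drop = low_prop > max_low_prop
    kept = [gid for gid, d in zip(expr.gene_ids, drop) if not d]
    removed = [gid for gid, d in zip(expr.gene_ids, drop) if d]
    report = QCReport(
        n_input=expr.n_genes,
        n_output=len(kept),
        n_removed_by_rule={"low_expression": len(removed)},
        removed_ids={"low_expression": removed},
    )
    return expr.subset_genes(kept), report
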