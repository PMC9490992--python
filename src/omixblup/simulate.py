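"""Synthetic population generator for the multi-omics prediction setting.

The generator emulates the study design the models target: a genotyped
resource population of which only a small subset is also transcribed,
gene expression partially under cis-genetic control, and a
low-heritability trait whose genetic signal acts partly through
expression. Markers are drawn in Hardy-Weinberg and linkage equilibrium
(no LD), expression noise is Gaussian on the log scale (so FPKM values
are skewed and non-negative), and every output is a pure function of
(parameters, seed). Ground truth — causal markers, cis architectures,
per-animal genetic values, covariate coefficients — is returned alongside
the data so downstream estimates can be scored against it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    AlignedBundle,
    ExpressionMatrix,
    GenotypeMatrix,
    PhenotypeTable,
    SimulationTruth,
)
from .io import align_samples

__all__ = [
    "simulate_genotypes",
    "simulate_expression",
    "simulate_phenotype",
    "make_study_bundle",
]


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_genotypes(n: int, m: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       seed: int = 0) -> GenotypeMatrix:
    """Draw an n-sample, m-marker dosage panel in HWE and linkage equilibrium.

    Each marker's allele frequency is uniform on ``maf_range`` and dosages
    are Binomial(2, p) i.i.d. across animals.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"invalid maf_range {maf_range}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(float)
    return GenotypeMatrix(_ids("S", n), _ids("M", m), dosages)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_expression(geno: GenotypeMatrix, g: int,
                        cis_per_gene: int = 3,
                        expr_h2: float = 0.5,
                        seed: int = 0,
                        log_sd: float = 0.4,
                        ) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate FPKM expression with a cis-genetic component.

    Each gene's log-expression is a baseline plus a cis signal (a linear
    combination of ``cis_per_gene`` marker dosages, scaled to contribute a
    fraction ``expr_h2`` of the across-animal log-scale variance) plus
    Gaussian noise; the output is exponentiated to the FPKM-like positive
    scale. ``log_sd`` is the total per-gene across-animal standard
    deviation on the log scale; the default 0.4 matches the sub-unit
    biological variation typical of bulk RNA-seq, while baselines spread
    over orders of magnitude across genes.
    """
    if not 0.0 <= expr_h2 <= 1.0:
        raise ValueError("expr_h2 must be in [0, 1]")
    if cis_per_gene < 1 or cis_per_gene > geno.n_markers:
        raise ValueError("cis_per_gene must be in [1, n_markers]")
    if log_sd <= 0:
        raise ValueError("log_sd must be > 0")
    rng = np.random.default_rng(seed)
    n, m = geno.n_samples, geno.n_markers
    dos = geno.dosages
    dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
    baselines = rng.normal(0.5, 1.0, size=g)
    genetic = np.zeros((n, g))
    cis_markers, cis_effects = [], []
    for j in range(g):
        cis = rng.choice(m, size=cis_per_gene, replace=False)
        eff = rng.normal(0.0, 1.0, size=cis_per_gene)
        cis_markers.append(cis)
        cis_effects.append(eff)
        if expr_h2 > 0:
            genetic[:, j] = np.sqrt(expr_h2) * _standardize(dos[:, cis] @ eff)
    noise = (rng.normal(0.0, np.sqrt(1.0 - expr_h2), size=(n, g))
             if expr_h2 < 1 else np.zeros((n, g)))
    log_expr = baselines + log_sd * (genetic + noise)
    expr = ExpressionMatrix(list(geno.sample_ids), _ids("G", g),
                            np.exp(log_expr))
    truth = SimulationTruth(
        seed=seed, expr_h2=expr_h2,
        cis_markers=cis_markers, cis_effects=cis_effects,
        genetic_expression=genetic,
        extras={"baselines": baselines, "log_noise": noise},
    )
    return expr, truth


def simulate_phenotype(geno: GenotypeMatrix,
                       expr_truth: SimulationTruth | None,
                       h2: float = 0.2,
                       mediation_share: float = 0.5,
                       seed: int = 0,
                       n_causal: int | None = None,
                       n_mediating_genes: int | None = None,
                       trait: str = "trait",
                       ) -> tuple[PhenotypeTable, SimulationTruth]:
    """Simulate a trait with direct-genomic and expression-mediated signal.

    The genetic value mixes a direct polygenic component (``n_causal``
    markers) and a mediated component (a linear combination of the
    genetically controlled parts of gene expression), in proportions
    ``1 - mediation_share`` and ``mediation_share`` of the genetic
    variance. Environmental noise scales the genetic fraction of the
    phenotypic variance to ``h2``. Four fixed-effect covariates with known
    coefficients (year of birth, birth weight, fattening duration,
    slaughter batch) are added on top so the adjustment step has real work
    to do.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    if not 0.0 <= mediation_share <= 1.0:
        raise ValueError("mediation_share must be in [0, 1]")
    if mediation_share > 0 and expr_truth is None:
        raise ValueError("mediated signal requested but no expression truth given")
    rng = np.random.default_rng(seed)
    n, m = geno.n_samples, geno.n_markers
    dos = geno.dosages
    dos = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)

    n_causal = min(m, 200) if n_causal is None else n_causal
    causal = rng.choice(m, size=n_causal, replace=False)
    beta = rng.normal(0.0, 1.0, size=n_causal)
    direct = _standardize(dos[:, causal] @ beta)

    if mediation_share > 0 and expr_truth.genetic_expression is not None:
        gx = expr_truth.genetic_expression
        n_med = min(gx.shape[1], 50) if n_mediating_genes is None else n_mediating_genes
        med_genes = rng.choice(gx.shape[1], size=n_med, replace=False)
        gene_w = rng.normal(0.0, 1.0, size=n_med)
        mediated = _standardize(gx[:, med_genes] @ gene_w)
    else:
        med_genes = np.array([], dtype=int)
        gene_w = np.array([])
        mediated = np.zeros(n)

    g_val = (np.sqrt(1.0 - mediation_share) * direct
             + np.sqrt(mediation_share) * mediated)
    g_val = _standardize(g_val) * np.sqrt(h2)
    e = _standardize(rng.normal(size=n)) * np.sqrt(1.0 - h2)
    y_base = g_val + e

    year = rng.choice(["2018", "2019", "2020"], size=n)
    year_eff = {"2018": 0.0, "2019": 0.5, "2020": 1.0}
    birth_weight = rng.normal(40.0, 4.0, size=n)
    fattening = rng.normal(300.0, 30.0, size=n)
    batch = rng.choice(["b1", "b2", "b3", "b4"], size=n)
    batch_eff = {"b1": 0.0, "b2": 0.3, "b3": 0.6, "b4": 0.9}
    coef_bw, coef_fat = 0.05, 0.01
    y = (y_base
         + np.array([year_eff[v] for v in year])
         + coef_bw * (birth_weight - 40.0)
         + coef_fat * (fattening - 300.0)
         + np.array([batch_eff[v] for v in batch]))

    data = pd.DataFrame({
        trait: y,
        "year_of_birth": year,
        "birth_weight": birth_weight,
        "fattening_duration": fattening,
        "slaughter_batch": batch,
    }, index=geno.sample_ids)
    pheno = PhenotypeTable(data, trait, {
        "year_of_birth": "categorical",
        "birth_weight": "continuous",
        "fattening_duration": "continuous",
        "slaughter_batch": "categorical",
    })
    truth = SimulationTruth(
        seed=seed, h2=h2, mediation_share=mediation_share,
        marker_effects=beta, causal_markers=causal,
        genetic_values=g_val,
        covariate_coefficients={
            "year_of_birth[2019]": 0.5, "year_of_birth[2020]": 1.0,
            "birth_weight": coef_bw, "fattening_duration": coef_fat,
            "slaughter_batch[b2]": 0.3, "slaughter_batch[b3]": 0.6,
            "slaughter_batch[b4]": 0.9,
        },
        extras={"environment": e, "sample_ids": list(geno.sample_ids)},
    )
    return pheno, truth


def make_study_bundle(n_total: int = 300, n_transcribed: int = 60,
                      m: int = 2000, g: int = 500,
                      h2: float = 0.2, mediation_share: float = 0.5,
                      expr_h2: float = 0.5, cis_per_gene: int = 3,
                      expr_log_sd: float = 0.4,
                      maf_range: tuple[float, float] = (0.05, 0.5),
                      seed: int = 0,
                      ) -> tuple[AlignedBundle, SimulationTruth]:
    """End-to-end miniature of the study population, ready for every model.

    ``n_total`` animals are genotyped; a random ``n_transcribed`` of them
    also get a measured expression matrix. The returned truth is reordered
    to the bundle's sample order (non-transcribed first, transcribed
    last).
    """
    if n_transcribed > n_total or n_transcribed < 0:
        raise ValueError("n_transcribed must be in [0, n_total]")
    children = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]
    geno = simulate_genotypes(n_total, m, maf_range, seed=seeds[0])
    expr_all, expr_truth = simulate_expression(geno, g, cis_per_gene,
                                               expr_h2, seed=seeds[1],
                                               log_sd=expr_log_sd)
    pheno, ph_truth = simulate_phenotype(geno, expr_truth, h2,
                                         mediation_share, seed=seeds[2])
    rng = np.random.default_rng(seeds[3])
    t_pos = np.sort(rng.choice(n_total, size=n_transcribed, replace=False))
    expr = expr_all.subset_samples([geno.sample_ids[i] for i in t_pos]) \
        if n_transcribed else None
    bundle = align_samples(geno, expr, pheno)

    # reorder per-animal truth to the bundle's block ordering
    order = [geno.sample_ids.index(s) for s in bundle.sample_ids]
    truth = SimulationTruth(
        seed=seed, h2=h2, mediation_share=mediation_share, expr_h2=expr_h2,
        marker_effects=ph_truth.marker_effects,
        causal_markers=ph_truth.causal_markers,
        cis_markers=expr_truth.cis_markers,
        cis_effects=expr_truth.cis_effects,
        genetic_expression=expr_truth.genetic_expression[order],
        genetic_values=ph_truth.genetic_values[order],
        covariate_coefficients=ph_truth.covariate_coefficients,
        extras={"sample_ids": list(bundle.sample_ids),
                "stage_seeds": seeds},
    )
    return bundle, truth
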