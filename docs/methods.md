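# Methods

## The model family

All five predictors share one animal model. Phenotypes are first adjusted
for fixed effects by ordinary least squares, `y = Xβ + y*`, where X
contains an intercept, continuous covariates as given, and categorical
covariates expanded to indicators with the first level absorbed by the
intercept. The residual `y*` is then modelled with a single random
genetic effect,

    y* = γ + e,   γ ~ N(0, K σg²),   e ~ N(0, I σe²),

with one record per animal (identity incidence). Narrow-sense
heritability is `h² = σg²/(σg²+σe²)`. The models differ only in the
relationship kernel K:

* **GBLUP** — the VanRaden genomic relationship matrix
  `G = ZZ′/(2Σpᵢ(1−pᵢ))`, Z the column-centered dosage matrix
  (`dosage − 2pᵢ`, `pᵢ` the allele frequency), or alternatively the
  cosine kernel of raw 0/1/2 dosage rows. VanRaden is the default for a
  standalone genomic fit; the cosine G is used wherever a transcriptomic
  kernel is blended in, so that the reductions below are exact.
* **TBLUP** — the cosine kernel of FPKM expression profiles,
  `K(xᵢ,xⱼ) = ⟨xᵢ,xⱼ⟩/(‖xᵢ‖‖xⱼ‖)`.
* **MBLUP** — `M = ratio·G + (1−ratio)·T` for populations where every
  animal has both omics layers; `ratio = 1` is (cosine) GBLUP and
  `ratio = 0` is TBLUP.
* **mssBLUP / wmssBLUP** — a single-step style hybrid for populations
  where only a subset is transcribed. With animals ordered
  non-transcribed first (block 1) and transcribed last (block 2),

      Hm22 = T          Hm12 = G12 G22⁻¹ T        Hm21 = Hm12′
      Hm11 = G11 + G12 G22⁻¹ (T − G22) G22⁻¹ G21

  and wmssBLUP replaces T by `Tw = (1−w)T + w·G22`, where w is the share
  of genetic relationships not captured by expression. The closed-form
  inverse is `Hm⁻¹ = G⁻¹ + blockdiag(0, T⁻¹ − G22⁻¹)`.

A note on the Hm11 block: the literature on single-step evaluation
occasionally prints the off-diagonal correction with a `+ G12G22⁻¹G21`
term in place of the subtracted one. That variant is inconsistent with
the closed-form inverse above and fails the basic sanity requirement that
embedding `T = G22` must leave `Hm = G`. The form implemented here
satisfies both, and the test-suite verifies the two constructions against
each other on random positive-definite instances.

## Kernels and regularization

Cosine kernels act on raw features by design — 0/1/2 dosages for the
genomic kernel (a term-frequency reading of the minor allele) and FPKM
for the transcriptomic one — because the kernel normalizes each sample's
profile internally. The kernel is the Gram matrix of unit vectors: unit
diagonal, positive semi-definite, invariant to per-sample scaling. A
diagonal regularization `K + C·I` with C = 0.05 (configurable, recorded
on the matrix) guarantees the invertibility of the G22 and Tw blocks that
the hybrid construction requires.

An optional `log1p` transform is exposed for expression kernels, off by
default. The evaluation drivers accept it because cosine similarity of
heavily right-skewed abundance profiles is dominated by the few
highest-expressed genes; on the log scale every gene contributes at a
comparable scale. The synthetic-data experiments below use it.

## REML and prediction

Variance components are estimated by restricted maximum likelihood in the
eigenbasis of K: with `K = U diag(d) U′` and `u = U′y*`, σg² is profiled
out analytically and the likelihood is maximized over
`δ = σe²/σg²` by bounded scalar search on log₁₀δ ∈ [−8, 8]
(coarse bracketing on 41 grid points, then derivative-free refinement to
1e−8). Because fixed effects are removed beforehand, the restricted
likelihood has no fixed-effect projection left; the two-stage procedure
(OLS adjustment, then the variance-component fit on residuals) is the
package's contract. It carries a small downward bias relative to a joint
fixed-plus-random REML because the adjustment absorbs a little genetic
variance; at the package's desk scales the bias is well inside the
sampling noise (the acceptance suite measures mean ĥ² within ±0.05 of
truth at n = 500).

Standard errors come from the inverse Fisher information of (σg², σe²),
with the h² error by the delta method. Estimates at the δ search
boundary (h² ≈ 0 or 1) are flagged `at_boundary` and reported without
standard errors rather than raised as errors. `K = I` is rejected
explicitly: genetic and residual variance are then not identifiable.

Prediction is the BLUP conditional mean
`γ̂ = K[target,train](K[train,train] + δI)⁻¹ y*_train` via Cholesky
factorization; a singular training system (δ ≈ 0 with rank-deficient K)
raises with a pointer to the diagonal jitter.

## Quality control

Filters reproduce PLINK-style semantics with strict inequalities, so
boundary values survive: samples with missing rate > 10% are removed
first; then markers with call rate < 90%, minor allele frequency < 0.05
(computed on non-missing calls after sample removal), or a one-df
chi-square Hardy–Weinberg p-value < 10⁻⁶ (expected counts p², 2pq, q² at
the observed allele frequency; monomorphic markers return p = 1 by
convention). The asymptotic chi-square is used rather than the exact
test; at a 10⁻⁶ threshold the distinction is immaterial for the panel
sizes involved. Genes are dropped when FPKM < 0.1 in strictly more than
95% of samples. Each removed item is attributed to the first rule it
fails (rule order: call rate, MAF, HWE), making the per-rule counts sum
to the total. Filters are idempotent. Raw storage keeps the missing-data
mask; missing dosages are mean-imputed (to 2p per marker) only at kernel
construction.

## Cross-validation and experiment drivers

Accuracy is the Pearson correlation between held-out GEBVs and adjusted
phenotypes. Leave-one-out predicts each animal from the other n−1 and
reports one correlation over the n held-out predictions. Replicated
k-fold (default five replicates of fivefold) reports one correlation per
validation fold and summarizes as the mean of the k·replicates fold
correlations — not the correlation of pooled predictions — so every fold
contributes equally. Fold partitions come from a seeded generator
(permutation + equal split, sizes differing by at most one); identical
seeds give bitwise-identical folds. Variance components are fitted once
per kernel by default (`fit-once`); `refit-per-fold` re-runs REML on each
training set and is the policy the brute-force oracle test uses.

One caveat worth knowing: with near-constant kernels (cosine kernels of
raw positive features have all off-diagonals close to 1) and mean-zero
y*, leave-one-out predictions acquire a negative coupling to the held-out
value (the training sum is minus the held-out value), which biases the
LOO correlation downward when signal is weak. The k-fold scheme does not
share this artifact, and the comparison drivers therefore use k-fold.

Grid searches sweep the MBLUP ratio (default 0.01–0.99, step 0.01, under
LOO) and the wmssBLUP weight w (default 0–1, step 0.1, under k-fold; the
step matches the granularity at which the weight is meaningfully
resolvable); ties break toward the smaller parameter for determinism.
The proportion experiment keeps the transcribed core fixed, draws
genotyped-only subsets of growing size (default seven evenly spaced
sizes up to the full pool), and scores wmssBLUP and GBLUP on shared folds,
reporting absolute and relative improvement.

## The synthetic-data generator

The simulator emulates the study design the models target: a genotyped
population (default 300 animals, 2000 markers) of which a small subset
(default 60) is transcribed; expression partially under cis-genetic
control; a low-heritability trait (default h² = 0.2) whose genetic signal
acts partly through expression (default mediation share 0.5).

* **Genotypes** — per-marker allele frequency uniform on [0.05, 0.5],
  dosages Binomial(2, p) i.i.d. across animals: Hardy–Weinberg and
  linkage equilibrium, no LD. LE markers exercise every formula; LD
  realism is out of scope, with the consequence noted below.
* **Expression** — per gene, log-expression = baseline + cis signal +
  Gaussian noise. Baselines are N(0.5, 1) across genes (FPKM spreads over
  orders of magnitude); the cis signal is a linear combination of 3
  marker dosages scaled so its share of the across-animal log variance is
  `expr_h2` (default 0.5); the total per-gene across-animal log SD is 0.4,
  the sub-unit variation typical of bulk RNA-seq. Values are
  exponentiated to the positive FPKM-like scale.
* **Phenotype** — genetic value = √(1−ms)·(direct polygenic score over
  200 causal markers) + √ms·(linear combination of the genetic components
  of 50 genes' expression), standardized so the genetic share of
  phenotypic variance is h² empirically. Four fixed-effect covariates
  with known coefficients (year of birth, birth weight, fattening
  duration, slaughter batch) are added on top, mirroring the covariates a
  slaughter-cohort analysis adjusts for.
* Every output is a pure function of (parameters, seed); per-animal
  genetic values, cis architectures and covariate coefficients are stored
  so downstream estimates can be scored against truth.

What the generator does **not** emulate: LD between markers (so the
effective number of independent genome segments equals the marker count,
and prediction accuracies at a given n are much lower than on real LD-rich
panels), trans-regulation and co-expression structure, environmental
covariance between expression and the trait (expression noise is
independent of phenotype noise), and count-level measurement models.
Passing tests therefore demonstrate the algebra, calibration and
qualitative behaviour of the methods, not field accuracy levels.

## The directional experiment and a known limitation

The acceptance experiment compares wmssBLUP (best w on the 0–1 grid)
against GBLUP on 20 simulated populations with a predominantly
transcriptome-mediated trait (n = 300 with 60 transcribed, 600 markers,
150 genes, h² = 0.2, mediation share 0.8, expression heritability 0.8,
log-scale expression kernel). The marker count keeps the ratio of
population size to independent genome segments near the regime of a
large LD-rich panel study; gene count is scaled to the transcribed
subset. wmssBLUP matches or exceeds GBLUP on average (the w = 1 grid
entry *is* GBLUP under the same folds, so the comparison is exact and
paired).

The companion claim — that the relative advantage of wmssBLUP shrinks
monotonically as the transcribed fraction is diluted by growing the
genotyped-only population — does **not** reproduce reliably at this
scale: in most seeds the improvement instead rises with population size.
The reason is a crossover: at the sweep's smaller sizes (total n ≈
94–200) both models are still noise-dominated (accuracy near zero), so
there is no stable advantage to dilute; the advantage only becomes
estimable near the top of the size range. The dilution regime requires
population sizes several times larger with stable baseline accuracies,
which is outside the desk scale this package targets; the experiment
driver reports both the per-size accuracies and the trend so the
behaviour is visible rather than hidden.

## Numerical choices and degenerate inputs

Relationship matrices are symmetrized after construction and validated to
1e−10; kernels record the jitter applied. Hybrid blocks are computed via
symmetric solves rather than explicit inverses except in the closed-form
inverse routine, which is itself cross-checked against direct inversion
in the tests (max |Hm·Hm⁻¹ − I| ≤ 1e−8 on random instances). Readers
never impute and flag, rather than drop, missing trait values; duplicate
IDs, non-numeric cells, negative abundances, asymmetric kernels and
rank-deficient designs raise errors that name the offending row, column
or sample. Grid-search ties break toward the smaller parameter; QC rule
attribution is first-failure in a fixed order; fold splitting is a seeded
permutation so every result is bit-reproducible from its seed.
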