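# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `frostgs`. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Mixed-model engine

Every analysis is a Gaussian linear mixed model
`y = Xb + Σ_k Z_k u_k + e`, `u_k ~ N(0, K_k σ²_k)`, `e ~ N(0, I σ²_r)`,
fitted by restricted maximum likelihood. Three evaluation strategies share
one likelihood definition (they are cross-checked against each other in the
tests):

- **Spectral profile (single random term).** After an eigendecomposition of
  `Z K Z'` the likelihood is a smooth one-dimensional function of the
  variance ratio `γ = σ²_g/σ²_r`; it is minimized by bounded scalar search
  on `log γ ∈ [−18, 18]` (absolute tolerance 1e−10), with the residual scale
  profiled out in closed form. This is the hot path for GBLUP, WBLUP,
  RR-BLUP and the GWAS null model.
- **Henderson determinant form (identity kernels).** For models whose
  kernels are all identity (line, block, row, column effects), the
  restricted likelihood is computed from the mixed-model-equation
  coefficient matrix, costing `O((p + Σq_k)³)` instead of `O(n³)` per
  evaluation.
- **Dense fallback** via Cholesky of `V` for anything else.

Multi-component models are optimized with Nelder–Mead over log variance
*ratios* (the residual scale is always profiled out analytically); the
boundary `σ² → 0` is handled by treating ratios below `e⁻³⁰` as zero and
flagging them, and a run that exhausts iterations with a numerically
collapsed simplex is accepted as converged. Noise-free responses (OLS
residual ~0) short-circuit to the boundary solution. Variance components
are constrained nonnegative by the log parameterization; AIC is
`−2·logRL + 2·(number of variance parameters)` and is only comparable
between fits with byte-identical fixed designs (enforced).

BLUEs, their covariance, and BLUPs are recovered at the optimum through the
GLS closed form, which equals the Henderson solution exactly; `solve_mme`
exposes that solution at user-supplied variance components.

## Phenotypic analysis

Stage 1 follows the two-pass scheme: the line effect is random in the first
pass (genetic variance σ²_G) and fixed in the second (BLUEs). The mean
variance of a difference, `MVD = mean_{i<j} var(BLUE_i − BLUE_j)`, comes
from the fixed-pass covariance matrix, and `h² = σ²_G/(σ²_G + ½MVD)`; in a
balanced complete-block design this reduces to `σ²_G/(σ²_G + σ²_r/r)`.
Field trials are screened over the candidate set {block}, {block+row},
{block+column}, {block+row+column} — random nuisance effects with i.i.d.
residuals — selected by AIC on the genotype-random fits. Trials with
h² ≤ 0.3 are flagged as too noisy for downstream use. Spatially correlated
residual structures (AR1⊗AR1) are intentionally out of scope; the random
row/column formulation preserves the model-selection workflow without a
specialized spatial REML, at some cost in fidelity for strongly
trend-affected trials. Stage 2 pools per-trial BLUEs with trial as a fixed
effect (sum-to-zero contrasts) and a single pooled residual that absorbs
trial-by-line interaction; with fixed genotypes this pass is ordinary least
squares.

A common error variance between replicated and unreplicated lines is
assumed throughout, matching routine practice for partially replicated
designs.

## Genotype pipeline

Markers are coded +1/0/−1 (homozygous major / heterozygous / homozygous
minor). QC removes markers with minor allele frequency `< 0.10` or
missingness `> 0.10` (strict inequalities, with a 1e−9 float guard so a
marker at exactly the threshold is kept). Imputation is a seeded,
deterministic chromosome-wise k-nearest-neighbour scheme (k = 5, 3 sweeps):
for each missing call the mode of the five nearest lines observed at that
marker is filled in, with distances computed over a local window of up to
10 map-adjacent markers on either side — the local haplotype context that
carries the linkage signal. Distances are missingness-aware on the first
sweep and use the completed matrix afterwards; zero-distance neighbours
(duplicated local haplotypes) take precedence. This replaces the
random-forest imputation used in comparable published pipelines with a
dependency-light deterministic analogue; its mask-and-recover error on
synthetic panels at the default marker density is ~10–13% (tested bound
< 15%), and a fidelity gap versus forest-based imputation on real data
should be assumed. Perfect-LD pruning drops one random (seeded) member of
every `r² = 1` clique after imputation; monomorphic markers are dropped as
`r²`-undefined.

The kinship matrix is the VanRaden genomic relationship
`K = WW'/(2Σ p_k(1−p_k))` with `W_ik = Z_ik + 1 − 2p_k`; the allele
frequencies are computed once on the analysis panel and frozen for
centering validation genotypes. `K` is symmetric PSD with rows summing to
zero. Note that the centered formulation makes `K` singular by
construction; all model fitting therefore works with `ZKZ'` and never
requires `K⁻¹`.

The *Fr-A2* haploblock combines two tag SNPs: +1 when both carry the
tolerance allele homozygously, −1 when both carry the susceptibility allele
homozygously, 0 otherwise. Heterozygous component calls map to 0; the
favorable allele of each component is an explicit input.

## Prediction and marker selection

GBLUP predicts validation lines jointly through the full-panel kinship
(`u_val = σ²_g K_{vt} V⁻¹(y − Xb̂)`), which is the exact mixed-model
solution with missing responses: an unrelated line predicts exactly zero
and a duplicated line reproduces its twin's BLUP. WBLUP adds the haploblock
as a fixed effect and refuses to run when the block is monomorphic in the
training set rather than silently degrading to GBLUP. RR-BLUP centers the
marker subset (training or frozen frequencies) and is the exact dual of
GBLUP when run on the full panel with matched scaling — an identity the
tests verify to 1e−6.

The association scan estimates the polygenic and residual variances once on
the null model and reuses them for every marker's Wald test (the standard
population-parameters-previously-determined approximation; a scan inside
100 cross-validation replicates would otherwise be prohibitive). Under a
polygenic null the p-values are uniform to a Kolmogorov–Smirnov test. A
marker carrying 20% of the genetic variance usually tops the scan, but in
roughly a quarter of simulated panels an unrelated marker wins by chance —
the correlation of markers with the realized polygenic draw is heavy-tailed
under family/LD structure — while the planted marker stays within the top
three in ~98% of panels. The tests assert that observed behaviour rather
than certain top-1 recovery.

ρ_G, the share of genetic variance attributed to a locus, is estimated as
`max(0, 1 − σ²_G(locus fixed)/σ²_G(base))` from two REML fits differing
only in the fixed locus term. This estimator is a deliberate design choice:
"explained genetic variance" with a fixed locus term has no unique
definition, and the variance-ratio form is the standard one.

Marker pre-selection is forward stepwise regression minimizing the OLS AIC
of training BLUEs on marker codes, implemented with an orthonormal basis
update (one `O(n)` sweep per candidate per step). The chromosome-wise route
takes up to 12 smallest-p markers per chromosome (ties broken by larger
|effect|, then map order), keeps 1–6 per chromosome, pools (21–126 markers
across 21 chromosomes) and reduces to ≤ 21 in a second stage; stage 2 may
stop below the cap when AIC stops improving. The genome-wide route selects
directly from the 126 most significant markers. All constants are
configurable; selection is a pure, audited function of its inputs.

## Selection index

Predicted winter-hardiness and frost-damage values of the candidate lines
are combined as `Index_i = X_w,i b_w + X_f,i b_f` with `b = G⁻¹a`, where `G`
is the 2×2 sample covariance of the predicted values across candidates. The
default desired-gains vector targets one standard deviation of predicted
performance per trait, `a = (σ_w, σ_f)`, which gives
`b ∝ (σ_f, σ_w)·(1−ρ)` — always positive. Gains proportional to the raw
variances (`a = diag G`) were considered and rejected: with a percent-scale
trait next to a 1–9 score the prediction covariance generically exceeds the
smaller variance, flipping that trait's weight negative and destroying the
index — incompatible with a desired gain of "one SD per trait". Explicit
`a` vectors are honored as given. Both traits are lower-is-better; a
mixed-direction declaration negates the second trait before `G` is formed.
The index's advantage depends on the balance of the two single-trait
accuracies: when one model is far weaker (e.g. cross-trait prediction from
a distant pool), the equal-SD index can land slightly below the better
single model while still reducing the replicate-to-replicate coefficient of
variation.

## Evaluation harness

Accuracy is `r(predicted, observed)/√h²` with the validation experiment's
entry-mean h²; it may exceed 1 at low h² and is not clipped. Within each
cross-validation replicate, disjoint training/validation sets of exact size
are drawn with a per-replicate child seed, and *everything* — GWAS, stepwise
selection, model fitting — reruns inside the training split; a test verifies
that perturbing validation phenotypes changes no prediction. Independent
validation samples the training set from one subpopulation's pool and the
validation set from a disjoint pool (fixed when the pool equals the
requested size), fits each model per training trait, and combines the two
trait predictions into the index using the validation candidates' predicted
values to estimate `G`.

## Synthetic-data generator

The generator emulates the structure of a commercial winter wheat program;
what passing tests show is that the estimators recover the parameters of
*this* generative model, not that they would behave identically on real
data.

- **Base population and LD.** A pool of founder haplotypes (default 16) is
  drawn with exact per-marker allele counts at frequencies uniform in the
  configured MAF range (default [0.10, 0.5]). Parents are segment mosaics
  of founders (Poisson(1) crossovers per chromosome), and each line is a
  doubled recombinant gamete of its cross's two parents (three further
  recombination rounds), with 2% residual heterozygosity. Shared founder
  segments give the panel its linkage disequilibrium and heterogeneous
  kinship; without a finite founder pool the panel has no LD and neither
  imputation nor marker tagging has anything to exploit.
- **Major locus.** A latent CNV allele travels on chromosome 5 haplotypes;
  copy number is 1, 2 or 3 (2 only through residual heterozygosity in this
  inbred material). Two tag SNPs are derived from the causal state per line
  with 0.95 per-haplotype concordance — modelling assays that read the CNV
  imperfectly — so the tag–CNV linkage does not erode through the simulated
  meioses. At the default 20% major-locus share the haploblock regression
  recaptures ~16–18% of TBV variance (the concordance loss), inside the
  0.12–0.28 band the recovery tests check.
- **Polygenic background and two traits.** 40 background QTL with
  equal-magnitude, random-sign effects (exchangeable minor loci; a
  heavy-tailed effect distribution would let single background QTL rival
  the planted major locus, which is not the architecture being emulated).
  True breeding values are built as
  `TBV_t = σ_G(√ρ·S + √(1−ρ)·P_t)` with `S` the standardized (negated)
  copy-number score and `P_t` standardized polygenic scores orthogonalized
  against `S`; the trait-trait polygenic correlation is constructed
  empirically exactly, so the realized genetic correlation equals the
  configured value (default 0.6 — a free parameter, not an empirically
  anchored one) and TBV variances equal σ²_G exactly.
- **Experiments.** Field trials are partially replicated two-block
  row-column layouts (30% of lines replicated by default); the residual
  variance solves the configured entry-mean h² under the realized
  replication; winter-hardiness liabilities are mapped to the 1–9 scale by
  rounding (1 = dense stand), which costs ~0.02–0.05 of recovered h² — the
  recovery tests use a ±0.08 band around the configured 0.65/0.71. The
  frost test is a complete-block design (4 replicates) on a 0–100% damage
  scale truncated at the bounds; at the configured h² = 0.98 recovery is
  within ±0.01–0.02. Block/row/column effect SDs default to 0.25/0.10/0.10
  on the liability scale.
- **Not modelled:** vernalization/photoperiod physiology, weather,
  epistasis, dominance, genotype×environment interaction beyond independent
  trial noise, and real LD-decay profiles.

## Problem sizes

The acceptance checks use: closed-form and dual-implementation oracles at
n ≤ 60, m ≤ 300; parameter recovery at the study sizes (180-line field
trials, 213-line 4-block frost test, full 21×67 marker panel) over 30
seeds; qualitative model-ordering experiments on 160-line populations with
21×20 markers, 130/30 splits and 100 replicates; and independent validation
on a 504-line program (181/213/110 subpopulations, 21×20 markers, 100
replicates). `scripts/acceptance.py` runs the same study at the full
21×67 = 1,407-marker density. These sizes are the package's default
experiment scale; all of them are configurable.

## Known limitations

- The spatial-model family is a simplification (no autoregressive
  residuals); h² from strongly trend-affected field data will differ from a
  full spatial analysis.
- kNN imputation is a deterministic stand-in for forest-based imputation;
  its error rate on real LD structure will differ.
- The P3D association scan slightly understates per-marker evidence when a
  marker carries a large share of the variance (the null σ²_g absorbs it).
- Under the generator's exchangeable subpopulations, same-trait training
  dominates cross-trait training in independent validation; in a real
  program the ordering also reflects genetic distance between
  subpopulations, which the generator does not model beyond random family
  assignment.
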