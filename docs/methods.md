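# Methods

This note records the models, estimators, numerical choices, and the design
decisions taken where the analysis recipe left them open.

## The phenotype: CASTER

The composite steroid-response score is built from five cross-sectional
clinical measures. Orientation fixes the sign convention (higher score =
better response): oral steroid courses, ED visits and bronchodilator response
are negated; FEV1 % predicted and the airway hyper-responsiveness scale
(a PC20 surrogate where higher = less reactive) enter as-is. Each oriented
feature is z-standardised; the score is the first principal component of the
5×5 covariance (eigendecomposition), sign-fixed to correlate positively with
oriented FEV1 so the convention is deterministic. Subjects with any missing
constituent are excluded from scoring. The cohort threshold is the arithmetic
mean of the scores; *good* responders are strictly above it, ties classify
poor. A `pls_distance` backend (negated Euclidean distance to the best
observed oriented profile in standardised space) is provided as an alternative
with the same output contract; it is a deliberately simple stand-in for a
supervised projection and is not used by default.

The airway hyper-responsiveness field is used only monotonically, so it
accepts raw PC20, log PC20, or a dose–response-slope surrogate without
changing the contract.

## miRNA counts

Filtering removes a miRNA iff the fraction of subjects with fewer than
`min_count` (5) reads is at least `min_frac` (0.5); the boundary is inclusive
(a row at exactly 50% is dropped), stated explicitly because the verbal rule
is ambiguous there.

Size factors are median-of-ratios: reference miRNAs are those with strictly
positive counts in every subject; `factor_j = exp(median_i(log c_ij - log
geomean_i))`. Factors are defined up to the geometric-mean convention, so only
factor *ratios* are contractual. Downstream association uses
`log2(count/factor + 1)`: per-unit odds ratios then refer to a doubling of
normalised abundance, the scale on which small per-unit effects
(OR ≈ 1.05–1.25) are naturally expressed. The transform is configurable
(`transform="none"`).

The guided-PCA batch statistic is `delta = var(X v_g) / var(X v_1)` on the
column-centred subject × miRNA matrix, where `v_g` is the leading right
singular vector of `Y'X` (`Y` the batch one-hot — the axis along which batch
means separate most) and `v_1` the unguided first principal axis; `delta` lies
in [0, 1] by construction. The p-value is the permutation tail probability
over random batch relabellings with the add-one correction, so it lives on
the (b+1)/(B+1) grid and is reproducible from the seed. Default 1000
permutations; no feature scaling beyond centring.

## Association, replication, prediction

Each miRNA is tested separately: logistic regression (IRLS via the GLM
machinery) of poor = 1 on its expression plus covariates; Wald z = β/se,
p = 2(1 − Φ(|z|)). Fits that do not converge, separate, or have constant
predictors are kept in the output with NaN statistics and a flag; they do not
enter the BH adjustment (m = converged tests). Categorical covariates expand
to indicator contrasts with the largest category as reference. Replication
requires discovery q < 0.10, replication p < 0.05 (two-sided), and sign
agreement.

The three prediction models are trained on the discovery cohort only and
applied to the replication cohort with frozen coefficients; complete cases
within each model's predictor set. AUC is the rank statistic with ties
counted one half; the CI is a percentile bootstrap over replication subjects.
Model comparison is the deviance-difference chi-square on the cohort where
both models were fit; the clinical-only vs miRNA-only pair is refused because
a deviance test between non-nested logistic models is undefined — each is
compared against the combined model instead.

## Paired DEX–sham differential expression

Per probe, the paired differences d_i give logfc = mean(d) and s² = var(d).
Variances are moderated toward a common prior: the prior degrees of freedom
d0 and prior variance s0² come from matching the mean and variance of log s²
to the moments of a scaled F distribution (digamma/trigamma identities; the
trigamma inverse is solved by Newton iteration). If the observed spread of
log s² does not exceed its sampling spread the prior dominates entirely
(d0 = ∞, normal reference distribution). Then s²_post = (d0·s0² + df·s²) /
(d0 + df) and t = logfc / √(s²_post/n) on df + d0 degrees of freedom. Probes
with all-zero differences produce t = 0 by convention. The d0 → 0 limit
reproduces the ordinary paired t exactly and is covered by a test.

Enrichment collapses duplicate probes per gene to the best q, takes the union
of the requested miRNAs' target genes restricted to the tested universe, and
computes the exact upper hypergeometric tail by integer summation. The
DEX-responsive threshold is BH q < 0.10, matching the prevailing FDR level of
the rest of the pipeline; it is configurable.

Gene-level miRNA association fits, per (miRNA, gene), a linear mixed model
with expression across both conditions as response, the subject's circulating
miRNA level plus age and sex as fixed effects, and a subject random intercept
absorbing the pairing; BH across all pairs. The eigengene version of this
model (below) is identical in structure. The response/predictor orientation
(expression as response) is a documented choice; the pipeline exposes the
levels so the transpose analysis is a one-liner.

## Paired-design co-expression network

**Paired correlation.** Pooling both conditions into one Pearson correlation
double-counts subjects and is inflated by any shared per-subject offset. Each
probe is split into pair means m_s = (x_DEX + x_sham)/2 and pair
half-differences d_s = (x_DEX − x_sham)/2; the reported correlation is the
degrees-of-freedom-weighted average of the between-component correlation
(corr of m) and the within-component correlation (corr of d) — equal weights
for balanced pairs. The within component is exactly free of subject offsets,
so the combined estimate is strictly closer to the generating correlation
than pooled Pearson whenever offsets are present (covered by a simulation
test), and it reduces to plain Pearson when each subject contributes one
sample. A naive variance-share weighting was considered and rejected: it
reconstructs the total covariance and is algebraically identical to pooled
Pearson. Components that are constant (e.g. no treatment variation) drop out
of the average with zero weight.

**Soft threshold.** Adjacency is |r|^β (unsigned, default) or ((1+r)/2)^β
(signed). β is the smallest integer in 1..20 whose connectivity distribution
fits the scale-free log-log regression with R² ≥ 0.8 and negative slope
(10 equal-width connectivity bins); if none qualifies the β maximising R² is
used with a warning.

**TOM and modules.** TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 −
a_ij), diagonal 1, clipped to [0,1]. Modules come from average-linkage
clustering of 1 − TOM with a static height cut (default 0.95), clusters below
`min_module_size` (default 30) falling to "grey". When an expression matrix
is supplied, a membership refinement pass follows (the PAM-like stage of
dynamic hybrid cutting): each probe joins the module whose eigengene it
correlates with most strongly, if |kME| ≥ 0.3, else grey; two passes, then
undersized modules dissolve. For paired designs the refinement uses the
within-pair difference matrix — the shared subject offset would otherwise
couple every probe to every eigengene and drag background probes into
modules. Exact dynamic-tree-cut is out of scope. Module labels follow the
WGCNA size-ranked colour vocabulary (turquoise, blue, ..., black, magenta,
...), so colour-named reporting is meaningful on synthetic runs.

**Eigengenes and association.** A module eigengene is the first left singular
vector of the probe-standardised module submatrix, unit variance, oriented to
correlate positively with the module's mean profile. Module–miRNA association
is the random-intercept LMM described above (10% FDR flag); module–trait uses
a 5% flag. exp(coef) is reported as a secondary presentation column next to
the linear coefficient, since effect sizes from a linear model are sometimes
displayed on the exponentiated scale.

## Statistical kernels

Logistic fits use the GLM/IRLS machinery of statsmodels behind a thin
contract layer (separation detected by coefficient blow-up or a perfect fit
and flagged). The random-intercept LMM is fit by profiling the (RE)ML over
the variance ratio λ = var_u/var_e: for fixed λ the GLS fixed effects and
both variances are closed-form (V_g⁻¹ = I − λ/(1+λn_g) J), so the optimum is
a bounded one-dimensional search on log λ with the λ = 0 boundary checked
explicitly. This is numerically robust where general-purpose mixed-model
optimisers can fail on near-degenerate responses, and it agrees with
statsmodels' MixedLM to ~1e-4 in the tests, which keep MixedLM as an
independent oracle. All-singleton grouping is unidentified and collapses to
OLS with zero intercept variance. The hypergeometric tail is exact integer
summation (no cancellation for small tails), cross-checked against scipy.
BH adjustment wraps the standard step-up and is verified against an O(m²)
oracle. p-values are kept at full precision; rounding happens only at
presentation.

## The synthetic cohorts

The generator's defaults are the study conditions. Two cohorts of 580 and
187 subjects; 317 and 257 miRNAs; 88 DEX–sham pairs of 2000 probes.

**Counts.** miRNA relative abundances are log-normal; subject library sizes
uniform in (2·10⁵, 10⁶); counts negative-binomial with common dispersion 0.3
around mean = abundance × library × subject-level biological variability.
The biological term is log-normal with σ = 1.5 (natural log), giving a log2
predictor spread of ≈ 2.3 — chosen so the per-unit Wald SE at n = 580 matches
the magnitude implied by the reference worked examples' z/β ratios; without it the per-unit
scale is several-fold off. An optional batch applies a 2^shift multiplicative
factor to a random half of the miRNAs for batch-2 subjects (a uniform
all-miRNA shift would be absorbed exactly by size factors and undetectable
after normalisation).

**Phenotype.** A chosen causal subset of miRNAs (default 20) shifts the
log-odds of true poor-responder status by a per-miRNA planted effect (mean
0.3 per log2 unit, SD 0.15, shared across cohorts when two are generated
together) plus a small age term; the intercept is calibrated to a 65% poor
rate. The five CASTER constituents are then drawn conditional on status with
the group means and SDs observed in real cohorts (poor responders: more
steroid courses and ED visits, lower FEV1, more reactive airways, higher
BDR). The mean-dichotomised composite recovers the true status at ≈ 78%, so
the *observed* per-unit ORs in the association stage land in the 1.05–1.25
range — the planted conditional effect is deliberately larger than the
marginal effect a reader of the association table would infer.

Because the composite is a noisy proxy, parameter-recovery checks estimate
the planted coefficients with the correctly specified model: all causal
miRNAs jointly plus age and sex, against the true status, on the generation
predictor scale log2(count/relative-library + 1) (recomputable from the truth
record's library sizes). Marginal per-miRNA fits on size-factor-normalised
data show the expected attenuation from omitted causal miRNAs and
normalisation noise (~80% CI coverage instead of 95%); this is a property of
marginal association, not an estimator defect.

**Paired expression.** Probe p of subject s under condition c is
mean_p + u_s + l_p f_{m(p),s,c} + shift_p·[c = DEX] + √(1−l_p²)·ε.
u_s is a shared subject offset (SD 0.7); module factors f are iid per
(module, sample); per-probe loadings l are uniform around √ρ (mean pairwise
within-module correlation = ρ, default 0.6), giving the hub/periphery
membership heterogeneity real co-expression data show — with homogeneous
loadings the degree distribution is degenerate and the scale-free criterion
cannot operate. The spread vanishes as ρ → 1 so the perfect-correlation
limit holds. Per-probe treatment shifts are N(0, 0.4). If a coupled module
is configured, its factor gains coupling_strength × standardised miRNA level
in both conditions, so its eigengene tracks the circulating miRNA. Truth
records carry the assignment, loadings, shifts and coupling so recovery is
computable without re-simulation.

**What the generator does not emulate:** miRNA–miRNA co-expression structure
(tests are independent given status, so the discovery-stage FDR behaves more
conservatively than in correlated real panels), sequence content,
probe-to-gene many-to-one annotation beyond a synthetic map, cohort
differences in covariate effects (the real discovery/replication pair showed
an age effect reversal), and array-level technical artefacts. Passing tests
therefore validate estimator correctness and pipeline wiring, not
field-realistic power.

## Problem sizes and defaults used in checks

Recovery and null simulations run at the sizes the claims refer to (n = 580
subjects for association recovery, 200 groups for variance components,
88 pairs for module recovery and coupling power) with miRNA panels and probe
counts reduced to tens/hundreds where the claim is per-unit rather than
per-panel; the end-to-end acceptance run uses the full 580/187 × 317/257 ×
88-pair scale. The pipeline caps gene-level LMM fits at the top 300 DE genes
by q (configurable), which keeps the full run in seconds while covering
every planted coupling.

## Known limitations

- The static-cut + kME refinement approximates dynamic hybrid cutting; very
  close or nested modules may merge.
- The PLS-distance CASTER backend is a geometric stand-in, not a trained
  projection.
- The moderated-t prior assumes a single variance population; strongly
  bimodal variance structure would call for robust estimation of d0.
- Replication sign consistency uses two-sided p < 0.05 plus sign agreement
  rather than a one-sided test; with very small replication cohorts this is
  slightly conservative.
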