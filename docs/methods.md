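# Methods

This note documents the models, numerical choices and known limitations of
`coexsurv`. It is written for users who want to understand what the
pipeline computes and what its synthetic-data validation does and does not
demonstrate.

## Network model

The co-expression network is the classic unsigned weighted network:
pairwise Pearson correlations between gene expression profiles, raised in
absolute value to a soft-threshold power β, so that
a₍ᵢⱼ₎ = |cor(xᵢ, xⱼ)|^β ∈ [0, 1] with a₍ᵢᵢ₎ = 1. The unsigned form treats
positively and negatively correlated genes alike; with the default even
power (β = 4) the distinction would vanish anyway. A signed variant is not
implemented.

β is selected by the scale-free topology criterion: for each β on a grid
(default 1…20) the connectivity kᵢ = Σ_{j≠i} a₍ᵢⱼ₎ is histogrammed into
`n_bins` equal-width bins (default 10), and log₁₀ of the bin frequency is
regressed on log₁₀ of the mean connectivity per occupied bin. The model R²
is reported when the slope is negative and 0 otherwise, so that positively
sloped (non-scale-free) fits can never be selected; the smallest β with
R² ≥ 0.80 wins, falling back to the β of maximal R² (logged) and to an
undefined selection when fewer than 3 occupied bins exist anywhere on the
grid (degenerate data such as a single perfect latent factor). The 0.80
cutoff and bin count are conventions, exposed as config keys; analyses that
already know their operating point can pass β directly (the pipeline
default is β = 4).

Topological overlap is computed vectorised as one matrix product,
TOM₍ᵢⱼ₎ = (ℓ₍ᵢⱼ₎ + a₍ᵢⱼ₎)/(min(kᵢ, kⱼ) + 1 − a₍ᵢⱼ₎) with
ℓ₍ᵢⱼ₎ = Σ_{u≠i,j} a₍ᵢᵤ₎a₍ᵤⱼ₎; the diagonal is fixed to 1 by definition
rather than computed. For any valid adjacency the off-diagonal values are
provably in [0, 1]; the test suite checks elementwise agreement with a
triple-loop reference to 1e-10. The dissimilarity clustered downstream is
1 − TOM.

## Module detection

Average-linkage (UPGMA) clustering runs on 1 − TOM via
`scipy.cluster.hierarchy`. The tree is cut by a three-stage hybrid
procedure with the two parameters that matter exposed directly
(`cut_height`, default 0.95; `min_size`, default 30):

1. static cut of the dendrogram at `cut_height`;
2. branches with ≥ `min_size` leaves become modules;
3. every remaining gene is adopted by the module with the smallest mean
   dissimilarity to its members, provided (a) that mean is smaller than
   the gene's mean dissimilarity to all genes outside that module and
   (b) that mean is within the clustering radius `cut_height`.

Stage 3 is a deliberate simplification of the published dynamic hybrid
tree cut, which carries additional under-determined parameters (deepSplit,
core scattering). Condition (b) mirrors that algorithm's maximum
PAM distance: without a radius, genes that are essentially equidistant
from everything (pure noise sits at dissimilarity ≈ 1 from all modules)
would be adopted on meaninglessly small differences. With the radius, the
procedure recovers planted partitions essentially exactly (adjusted Rand
index ≥ 0.99 in the acceptance checks) while leaving background genes
grey.

Modules are named by the conventional colour sequence in decreasing size
order (largest = "turquoise"); "grey" marks unassigned genes and is never
treated as a module. Colour identity is therefore stable across reruns of
the same data but carries no meaning across datasets.

Each module eigengene (ME) is the first right singular vector of the
module's row-standardized expression (zero mean, unit SD per gene, ddof 1),
i.e. the first principal component scores over samples. Because the rows
are centred, the ME has exactly zero mean. Its sign is oriented so the
mean kME (gene–ME Pearson correlation) of the module's members is
positive, making "increased module expression" interpretable. The variance
explained is s₁²/Σsₖ² of the standardized module matrix. Modules
containing a constant gene are a hard error, as standardization is
undefined.

For an independent validation cohort, modules are *not* re-detected:
memberships from the discovery data are intersected with the validation
genes and MEs are recomputed as first principal components of the
intersected member expression (`project_partition`). Modules reduced below
two shared genes are dropped with a log message.

## Survival association

Module covariates are the robustly scaled MEs: a piecewise-linear map
sending the 2.5%, 50% and 97.5% quantiles (linear-interpolation quantiles)
to −1, 0 and +1, with linear extrapolation beyond the outer anchors. This
puts all modules on a common scale so hazard ratios are comparable across
modules. A median-dichotomised covariate is available as a config option
(`covariate: dichotomised`) but the scaled continuous form is the primary
analysis. Scaling is computed on the full cohort and the covariate is then
subset per stratum, so subtype analyses use the same per-sample values as
the overall analysis.

The Cox proportional-hazards fit is a single-covariate Newton–Raphson
maximiser of the partial likelihood written in-package: Efron tie handling
by default (monthly follow-up data are heavily tied), Breslow as an
option, convergence at |Δβ| < 1e-9 within 100 iterations with
step-halving, and explicit errors for constant covariates and monotone
separation (|β| > 50). HR = exp(β), the 95% CI is exp(β ± 1.96·SE) with SE
from the observed information, and p is the two-sided Wald test. The fit
is cross-checked in the tests against `lifelines` (agreement to 1e-6) and
against a derivative-free golden-section maximisation of the partial
likelihood; its Wald test is calibrated to 5% ± 1.5% type-I error in the
acceptance simulations.

Gene-level associations use raw expression as the covariate; GS =
−log10(p). Benjamini–Hochberg FDR is applied within the family actually
tested: across the modules of one stratum for module associations, and
within one module's member genes for gene associations. Hub genes are the
members with within-module connectivity k.in ranked ≤ 10 (descending,
lexicographic tie-break) and GS > 2, i.e. p < 0.01.

Tumour stage is coded II → 2, III → 3 for the module–stage Pearson
correlation; the coding only affects the sign convention, not |r| or p.

Molecular subtypes follow the five-way MSI/CIMP/BRAF/KRAS rule table;
any missing or unrecognised marker yields "unclassified" (the function is
total). Subtype-stratified survival runs only in strata with at least
`min_stratum_n` samples (default 50), since hazard-ratio estimates in
strata of a few dozen samples are dominated by noise.

Kaplan–Meier curves group samples by tertiles of a covariate and use the
product-limit estimator (via `lifelines`), with a log-rank test across
groups. Both the tertile grouping and the continuous Cox fit are exposed;
neither is asserted to be "the" canonical analysis, as they answer
slightly different questions.

## Enrichment

Module enrichment is a plain hypergeometric upper tail
P(overlap ≥ k) against a user-supplied GMT collection and an explicit
background universe (set members outside the universe are ignored for
counting), with BH FDR across sets and −log10(p) scores. No GO DAG
propagation or EASE-style correction is applied; results therefore depend
entirely on the supplied collection, and the universe is a required input
because no canonical background gene list ships with the package.

## Synthetic data

`synthdata` generates the cohorts the test suite and the acceptance script
run on. Expression follows a spiked-covariance latent factor model: module
m has a standard normal factor f_m per sample, member gene g is
x_g = u_g·f_m + ε with loading u_g drawn uniformly from `loading_range`
(default (0.3, 0.9)) and ε ~ N(0, σ²) (default σ = 1.0); background genes
are pure noise. The implied within-module correlation
u_g·u_h/√((u_g²+σ²)(u_h²+σ²)) gives eigengene recovery an analytic ground
truth, checked empirically in the tests. Optional per-batch additive
shifts emulate uncorrected batch structure; the pipeline does not correct
them (it assumes pre-normalized, batch-corrected input).

Survival times are exponential with hazard λ·exp(Σ_m β_m·sME_m), where
sME_m is the *scaled eigengene recomputed from the generated matrix by the
pipeline's own code* — deliberately, so that the eigengene and scaling
steps sit inside the tested loop rather than beside it. The baseline rate
defaults to λ = 0.03/month, chosen so that realistic censoring fractions
(from ~17% administrative-only up to near-total) are all reachable;
requested censoring is achieved by bisecting the horizon of an independent
uniform censoring time, then administrative censoring at the 60-month RFS
cutoff is applied. The realised fraction lands within ±5% of the request
whenever it is attainable.

Subtype markers are drawn to be exactly consistent with the rule table
(unclassified samples get missing markers), so subtype assignment inverts
generation exactly — including the default 26/6/108/151/8-of-461
composition of a stage II/III colon-cancer cohort.

Recovery studies (module detection, eigengene fidelity, hazard-ratio
recovery) are simulated at loadings 0.5–0.9 with noise SD 0.5, i.e.
within-module correlations of roughly 0.5–0.77 — the regime of real,
well-formed co-expression module cores. At the generator's default noise
(σ = 1.0) within-module correlations drop to ~0.2–0.45, adjacencies at
β = 4 become uniformly small, and no branch of the TOM dendrogram falls
below the 0.95 cut height: the pipeline then correctly reports an all-grey
partition. Detection at the default cut therefore presumes modules at
least as coherent as the σ = 0.5 regime.

What passing these simulations does *not* show: robustness to
probe-level artefacts, residual normalization structure, outlier samples,
non-Gaussian expression, overlapping module membership, or
non-proportional hazards — none of which the generator emulates.

## Problem sizes

The default test suite and the acceptance script use reduced problem
sizes chosen to exercise every code path at full statistical fidelity:
planted-module recovery at 1000 genes × 200 samples over 10 seeds, Cox
calibration over 2000 null cohorts of n = 200, hazard-ratio recovery over
100 cohorts of n = 461, and one full-scale end-to-end run at 3600 genes ×
461 samples with 11 planted modules sized 35–866. In that full-scale run
the planted protective module (true HR 0.59) is recovered with zero grey
leakage and an HR estimate near the truth; its *single genes* typically
fall short of GS > 2 because a module-level effect of that size dilutes
across members — a reminder that the hub criterion rewards genes with
strong marginal association, not merely membership in a prognostic
module.

## Numerical notes

- Adjacency clips |r| into [0, 1] before powering to absorb rounding.
- TOM symmetrises its output (average with its transpose) to remove
  float asymmetry before downstream use; symmetry is enforced on input to
  clustering at 1e-10.
- All top-n filters break ties lexicographically by gene symbol; variance
  ranking uses the sample SD (ddof 1). The SD ranking keeps the *largest*
  values — the only reading of a "top varying genes" filter consistent
  with co-expression practice.
- Probe collapsing uses the MaxMean rule (the collapsing method of the
  standard tooling's default): per gene, keep the probe with the largest
  mean expression; ties break lexicographically by probe id.
- The connectivity pre-filter computes k.total at the same β as the final
  network (configurable), since the operating β is the scale on which
  "most connected" is defined.
- All simulation randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global RNG state is used anywhere.
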