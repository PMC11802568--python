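# Methods

This note documents the model, the numerical conventions, the synthetic
data generator, and the design choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The model

### 1.1 Dual-SVDD

Support Vector Data Description (SVDD) fits the smallest hypersphere in
kernel feature space that encloses a training cloud up to a tolerated
outlier fraction. We solve the canonical dual

    min_α  αᵀKα − Σᵢ αᵢ Kᵢᵢ    s.t.  Σᵢ αᵢ = 1,   0 ≤ αᵢ ≤ 1/(nν)

with the RBF kernel K. Because the RBF kernel has unit diagonal, this dual
coincides with the ν-one-class-SVM dual after rescaling α by 1/(nν); we
obtain α from that quadratic program (libsvm via scikit-learn,
tol = 1e-9) and compute the geometry ourselves:

* center norm  ‖a‖² = αᵀKα;
* squared distance of any point x from the center
  ‖φ(x) − a‖² = 1 − 2 Σⱼ αⱼ k(xⱼ, x) + αᵀKα;
* decision value f(x) = ‖φ(x) − a‖² − r², f ≤ 0 inside (boundary points
  count as inside).

**Radius convention.** Exact dual solutions place every unbounded support
vector (0 < αᵢ < 1/(nν)) exactly on the sphere, so r² is the common
center-distance of unbounded SVs. Under finite solver tolerance those
distances spread slightly; we take r² as their **maximum**, which keeps
every unbounded SV inside-or-on as the KKT conditions require. On
well-conditioned problems the choice is irrelevant (the spread is ~1e-9,
and fitted α, r² and decision values match an independent SLSQP solve of
the dual to 1e-6 — tested); in near-degenerate high-dimensional problems
the maximum preserves the training-side ν-property (outlier fraction
≤ ν + 1/n), which a mean- or median-type convention violates.

**Kernel width.** γ = 1/(d·σ²), with d the number of genes and σ² the
variance pooled over all matrix entries, recomputed per stage from that
stage's training matrix. Both γ values are logged and stored in the
pipeline manifest.

**Two stages.** Stage 1 trains on DMSO samples. X_NT is the set of
non-toxic drug-treated samples with f_DE > 0; X_T the toxic-treated
samples with f_DE > 0. Stage 2 trains on X_NT (a procedural error is
raised if |X_NT| < 5, advising a ν/γ adjustment); PT = members of X_T
with f_TE > 0. ν defaults to 0.1 in both stages and is exposed on the CLI.

**Small-cohort behaviour.** With the prescribed γ, pairwise RBF kernel
values on control-relative z-score data concentrate near e⁻²; when the
number of training samples is small relative to the data's effective
dimensionality, every training point becomes a support vector on the
sphere and any fresh point exceeds the boundary by roughly the 2/n
self-kernel gap. In that regime PT approximates X_T. A boundary that
generalises (fresh same-distribution points inside at ≈ the ν rate, PT a
genuinely extreme subset) requires training samples that cover the data
manifold — many samples, or data whose variation is effectively
low-dimensional. This is a property of the method, not of the
implementation; the test suite therefore checks the null behaviour
(toxic ≡ DMSO ⇒ |PT|/|toxic| ≤ ν + 2/n) on a cohort with 250 samples per
group and a low-rank covariance, where the premise holds.

### 1.2 Pathway toxicity spaces

For pathway p, the genes present in the expression matrix are intersected
with the pathway's gene set (genes missing from the matrix are dropped
with a warning; pathways with fewer than `min_genes` = 3 surviving genes
are skipped and excluded from their mechanism's sum — skipped pathways are
reported, and a mechanism with no surviving pathway is flagged missing
rather than silently zero). A kernel-PCA embedding with RBF kernel,
γ_p = 1/l_p (l_p = intersected gene count) and latent dimension
d = clamp(⌊0.1·l_p⌋, 1, 3) is fitted on the PT samples (scikit-learn
KernelPCA; components with eigenvalue ≤ 1e-10 are dropped, never below one
component — all-degenerate training raises an error). Out-of-sample
projection uses the training centering statistics, and the implementation
is cross-checked in tests against an explicit double-centered
eigendecomposition (sign-invariant, 1e-8).

All samples are embedded; the reference (μ_p, S_p) is the mean and sample
covariance (ddof = 1) of **all** embedded samples — PT and non-PT — with a
ridge ε·I, ε = 1e-6 × mean(diag S), guaranteeing positive definiteness
(on well-conditioned data the ridge changes distances by < 0.1%, tested).
The raw score is the squared Mahalanobis distance (no square root); the
subsequent min-max normalisation to [0, 1] is computed globally across the
cohort (per-subset normalisation would not change within-cohort ranks).
Constant inputs normalise to all-zeros.

### 1.3 F-null weights

The weight of pathway p for sample x scores how exceptional the sample's
normalised distance d_p(x) is against the non-PT samples' distances, which
we model with an F distribution whose degrees of freedom (d₁, d₂) are
fitted by maximum likelihood (location fixed at 0; zeros floored at 1e-9).

Two conventions are implemented:

* `survival` (default): w = −log(1 − F(d_p; d₁, d₂)) — minus the log
  upper-tail probability, i.e. −log p-value. This grows with
  dysregulation, matching the weight's role as *significance of
  dysregulation*.
* `cdf`: w = −log I_{d₁d/(d₁d+d₂)}(d₁/2, d₂/2) = −log F(d_p; d₁, d₂),
  the mirrored convention, which decreases with dysregulation. At
  d₁ = d₂ = 2 and d_p = 1 both give −ln ½ ≈ 0.6931.

Weights are clamped to [0, 700] (−log of the smallest positive double) so
tail underflow cannot produce infinities.

**Fitted scale.** By default the F fit also estimates a scale parameter
(location stays 0; `fit_scale=False` pins the scale at 1). The min-max
step maps the bulk of the null far below 1 whenever any sample is strongly
dysregulated, and a unit-scale F can only adjust the power-law exponent at
the origin — it cannot represent a null concentrated at, say, 0.05, so all
weights flatten toward −log ½ and the weighting stops discriminating. With
a fitted scale the weight behaves as a genuine significance. On true
F-distributed data the scale fits to ≈ 1 and (d₁, d₂) are recovered within
15% at n = 5000 (tested), so the two variants agree where the unit-scale
model is correct.

### 1.4 Mechanism aggregation and display

D_M(x) = Σ_{p∈M} w(p, x)·d_p(x) over the mechanism's scored pathways; the
sum is additive under any split of a mechanism (tested) and nonnegative.
`max_distance` is the maximum over the five mechanisms. Because D_M sums
as many terms as the mechanism has pathways, axes are not directly
comparable in raw units; the radar display therefore min-max normalises
each axis across the scored cohort ([0, 1] radial scale), while raw sums
are always written to the output files. SVG rendering is deterministic
(fixed hash salt, no timestamp metadata): identical profiles give
byte-identical files.

## 2. The synthetic cohort generator

The generator produces the study conditions used throughout the tests and
the acceptance script: three groups (DMSO vehicle, non-toxic drug-treated,
toxic drug-treated; 30 samples each by default), a 26-pathway annotation
in the five-mechanism layout (6 + 3 + 13 + 2 + 2), dose and time
annotations, and a ground-truth record.

* **Scale.** Profiles are control-relative z-scores: every gene's marginal
  background is N(0, 1) (noise_sd = 1), and effect sizes are z-shift
  units.
* **Gene universe.** 3000 genes; pathway sizes cycle through
  (25, 20, 16, 12, 10) — KEGG-like sizes, 432 pathway genes in total,
  disjoint by default with an optional overlap fraction.
* **Co-expression.** Backgrounds are not independent across genes: genes
  outside the annotated pathways share `latent_rank = 2` global factors
  (the dominant co-regulated programs of a cell line), and each pathway's
  genes share `pathway_factors = 2` factors of their own — pathways are
  treated as co-expression modules, and keeping their factors independent
  across pathways keeps mechanism attribution identifiable. The shared
  fraction of each gene's variance is `latent_var_fraction = 0.98`;
  per-gene marginals remain N(0, noise_sd²) exactly. Replicate-collapsed
  z-score profiles are strongly co-expressed in reality, and this
  low-effective-dimension structure is also what lets one-class boundaries
  trained on tens of samples generalise at all (section 1.1); with independent
  gene noise (`latent_rank = pathway_factors = 0`, available as an
  option) the two-stage selection degenerates to "everything outside".
* **Doses.** (0.1, 0.37, 1.11, 3.33, 10) µM — a ~3.3× dilution series;
  toxic (and non-toxic) samples are assigned drugs in blocks of one
  sample per dose, so every drug contributes one full dose series at a
  fixed cell line and time.
* **Toxic effect.** `effect_size` β = 3 z-units per decade of dose.
  Monotone model: shift s(dose) = β·log₁₀(dose/dose_min), zero at the
  lowest dose. Hormetic model: s(dose) = β·log₁₀(dose/d_mid)², a U-shape
  with its minimum at the middle dose. Each target gene g (the genes of
  the perturbed mechanism's pathways) carries a fixed response coefficient
  u_g, |u_g| ~ Uniform(0.15, 0.7) with random sign, and receives
  u_g·s(dose): within-pathway responses are heterogeneous in magnitude
  and direction, as in real signatures. Homogeneous full-magnitude shifts
  (the `gene_response=(1,1)`, unsigned option) drive the pathway kernel
  into saturation — exp(−γ_p‖Δ‖²) ≈ exp(−s²) underflows for s ≳ 2.5 — and
  the kernel stops ordering doses; the default keeps the top dose inside
  the kernel's sensitive range.
* **Non-toxic effect.** Each non-toxic sample shifts a random 20% subset
  of non-target genes by ±(0.6–1.0)·0.25β per gene (within a |shift| ≤
  0.25β cap) — a generic drug effect, strong enough that a realistic
  fraction of non-toxic samples carries a detectable drug effect
  (f_DE > 0), which stage 2 requires.
* **Determinism.** The random stream is split hierarchically (layout,
  DMSO, non-toxic, toxic), so enlarging one group never changes another
  group's draws; a fixed seed reproduces the cohort bitwise.

**What the generator does not emulate:** probe-level inference and
replicate collapsing; dose-dependent variance changes; batch or plate
effects; pathway crosstalk beyond optional gene overlap; real KEGG
topology (only gene membership is used, as in the method itself). Passing
tests on this generator show the pipeline recovers planted structure
under a plausible statistical shape of the data — not that it would reach
any particular accuracy on a real cohort.

## 3. Evaluation protocols

* **Dose–distance correlation.** Samples are grouped into series by
  (drug, cell line, time); series with fewer than 5 distinct doses are
  excluded and counted. Per series, Spearman's ρ between dose and
  distance (Pearson available); ties handled by average ranks. The
  positive ratio is the fraction of series with ρ > 0. Spearman is the
  default because the claim under test is monotonicity, and ρ is
  invariant to monotone transforms of the distance (tested). The scalar
  distance per sample defaults to the maximum over mechanism distances;
  any single mechanism is selectable.
* **Baselines.** Cosine, Euclidean and Mahalanobis distances of each
  sample's full gene vector to the DMSO centroid; the Mahalanobis
  covariance is Ledoit-Wolf-shrunk so it stays invertible when genes far
  outnumber samples. The same reference point is used for all three, for
  fairness. Externally computed distance tables in the same TSV schema
  can be plugged into the comparison.
* **Group comparison.** Two-sided Mann-Whitney U; exact p-value for group
  sizes ≤ 20 without ties, otherwise the normal approximation with tie
  correction; identical constant groups return p = 1.

## 4. Numerical conventions and degenerate inputs

* Boundary decision at exactly 0 counts as inside (both boundaries).
* SVDD with identical training points: degenerate sphere, all points
  inside (r² from the largest training distance when no unbounded SV
  exists).
* Kernel-PCA training on identical PT profiles raises a degenerate-space
  error; near-zero eigenvalues reduce the latent dimension instead.
* min-max of a constant vector is all-zeros; F-fit on all-zero distances
  raises rather than returning an arbitrary null.
* All randomised procedures take explicit seeds; the pipeline manifest
  records every effective parameter (γ per stage, ν, latent dimension per
  pathway, skipped pathways, weight mode) plus SHA-256 hashes of every
  output file.

## 5. Problem sizes

Defaults were chosen so the full pipeline on the default study (3000
genes × 90 samples, 26 pathways) completes in a few seconds: the SVDD
duals are 20–30-variable QPs, each pathway space is a ≤ 30-point kernel
PCA, and the dose-series study (190 samples) adds under half a minute.
The parameter-recovery and oracle checks use n = 5000 draws and ≤ 20-point
fixtures respectively.
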