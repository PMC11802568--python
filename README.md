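# mdtr — a multi-dimensional transcriptomic ruler for drug-induced liver injury

`mdtr` quantifies the degree of drug-induced hepatotoxicity in drug-treated
expression profiles. Its input is a genes × samples matrix of z-scores
relative to vehicle (DMSO) controls — the format of replicate-collapsed
differential-expression signatures such as LINCS L1000 Level 5 data —
together with per-sample treatment annotations (drug, dose, time, cell
line, toxicity label), KEGG-style gene sets in GMT format, and a mapping of
pathways to five hepatotoxicity mechanisms: oxidative stress, immunological
response, altered lipid metabolism, mitochondrial dysfunction, and bile
acids accumulation.

It is intended for computational toxicologists and bioinformaticians who
want a per-sample, mechanism-resolved toxicity readout rather than a single
binary classification.

## Method

The pipeline has three stages:

1. **Dual-SVDD outlier selection.** A one-class Support Vector Data
   Description with RBF kernel `k(u, v) = exp(−γ‖u−v‖²)`, γ = 1/(d·σ²)
   with d the gene count and σ² the pooled entry variance, is fitted on
   DMSO samples (the *drug-effect boundary*, decision function f_DE). A
   second SVDD is fitted on the non-toxic drug-treated samples with
   f_DE > 0 (the *toxic-effect boundary*, f_TE). Toxic-treated samples
   outside both boundaries form the *potentially toxic* (PT) set
   X_PT = {x ∈ X_T : f_TE(x) > 0}. The canonical dual

       min_α  αᵀKα − Σᵢ αᵢKᵢᵢ   s.t.  Σαᵢ = 1,  0 ≤ αᵢ ≤ 1/(nν)

   is solved, with ν bounding the training outlier fraction.

2. **Pathway-level distances.** For each pathway p with l_p genes present,
   a kernel-PCA embedding (RBF, γ_p = 1/l_p, latent dimension
   clamp(⌊0.1·l_p⌋, 1, 3)) is fitted on the PT samples restricted to those
   genes. All samples are embedded; the squared Mahalanobis distance
   d_p(x) = (z − μ_p)ᵀ S_p⁻¹ (z − μ_p) to the pooled embedded distribution
   is min-max normalised to [0, 1] across the cohort. A weight
   w(p, x) = −log(1 − F(d_p(x); d₁, d₂)) scores the significance of each
   sample's dysregulation against an F-distribution null fitted by maximum
   likelihood to the non-PT samples' normalised distances (the regularised
   incomplete beta function I evaluates the F CDF).

3. **Mechanism aggregation.** For each mechanism M the mechanism-level
   toxic distance is D_M(x) = Σ_{p∈M} w(p, x)·d_p(x); the five mechanism
   distances per sample are rendered as a radar chart (optionally min-max
   scaled per mechanism to [0, 1] for display; raw sums are always kept).

A synthetic-cohort generator with known ground truth (which pathways were
perturbed, per-sample shift magnitudes, monotone or hormetic dose response)
makes every stage testable without external data, and an evaluation module
reproduces the dose–distance correlation protocol (per-series Spearman ρ
over (drug, cell line, time) dose series, positive ratio) against
cosine/Euclidean/Mahalanobis baselines computed on all genes.

## Worked example

```python
from mdtr import (SynthConfig, generate_cohort, fit_dual_boundaries,
                  build_spaces, compute_mdtr)

expr, meta, pathways, mech_map, truth = generate_cohort(SynthConfig(seed=1))
boundary = fit_dual_boundaries(expr, meta, nu=0.1)
spaces = build_spaces(expr, pathways, boundary.pt_sample_ids)
profiles = compute_mdtr(expr, meta, spaces, mech_map,
                        pt_ids=set(boundary.pt_sample_ids))
```

On the default synthetic study (90 samples, 3000 genes, the
oxidative-stress mechanism perturbed in toxic samples at 3 z-units per
dose decade) this prints, via `examples/03_pathway_ruler.py`:

```
mechanism-level distance (group means):
  mechanism                       toxic     DMSO
  Oxidative stress                13.49     0.29
  Immunological response           2.02     1.54
  Altered lipid metabolism         9.98     6.72
  Mitochondrial dysfunction        1.64     1.03
  Bile acids accumulation          1.41     1.10
```

The perturbed mechanism (oxidative stress) shows by far the largest
toxic-group distance and the largest toxic/vehicle contrast (13.49 vs
0.29); unperturbed mechanisms stay near their vehicle baseline, with the
13-pathway lipid-metabolism axis carrying the largest baseline sum simply
because it sums more pathways. Of the 30 toxic samples, 19 are flagged PT,
concentrated at the two highest doses (see `examples/02_dual_svdd.py`).

The scripts in `examples/` each demonstrate one capability end to end:
cohort simulation, Dual-SVDD selection, ruler scoring with a radar chart,
and dose-response evaluation. A thin command-line interface wraps the same
functions (`mdtr simulate | fit-boundaries | build-spaces | score |
evaluate | compare-groups | pipeline`); `mdtr pipeline --config cfg.yaml`
runs everything from one YAML file and writes a manifest with output
hashes for reproducibility.

## Limitations

The synthetic generator emulates the statistical shape of control-relative
z-score profiles, not real biology; see `docs/methods.md` for what the
generator does and does not capture, the numerical conventions, and the
reasoning behind every tunable default.
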