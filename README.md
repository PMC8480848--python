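# otoshape

Otolith-shape morphometrics for fish ecotype discrimination, with a growth
model that quantifies how growth-rate and cohort variation can mask the
ecotype signal.

## The problem

Atlantic cod (*Gadus morhua*) around Iceland occurs as a coastal and a
frontal (migratory) ecotype, conventionally proxied by the pantophysin I
(*Pan* I) genotype: AA ↔ coastal, BB ↔ frontal, with the heterozygote AB
showing both behaviours. The outline shape of the sagittal otolith records
a fish's growth history and is widely used for stock discrimination — but
otolith shape is itself strongly driven by growth rate, so spatial and
temporal growth variation can confound ecotype classification. This package
implements the full analysis chain needed to study that confounding:

1. **Outline extraction** — binarize a backlit otolith photograph (global
   Otsu by default), keep the largest filled component, trace the boundary
   at sub-pixel resolution, mirror left otoliths, and measure the maximum
   Feret diameter (largest distance between any two boundary points;
   convex-hull accelerated, exactly equal to the brute-force maximum).
2. **Shape descriptors** — Normalized Elliptic Fourier descriptors
   (Kuhl–Giardina chain expansion; start point and rotation standardized on
   the first harmonic ellipse, size divided by the Feret diameter; 12
   harmonics → 4·12 − 3 = 45 descriptors) and Discrete Wavelet descriptors
   (a 1024-point centroid-radius profile, angle zero on the Feret axis,
   decomposed by a periodized orthonormal Daubechies filter bank over 10
   dyadic levels; the 64 coarsest coefficients are the descriptors). Each
   descriptor is detrended against fish length with a common within-group
   slope β from `descriptor ~ length + location`, subtracting β·length when
   the slope is significant at α = 0.05.
3. **Growth index** — the von Bertalanffy growth function in the Francis
   (1988) parameterization,

   E[L|t] = L₁ + (L₃ − L₁) · (1 − r^(2(t−t₁)/(t₃−t₁))) / (1 − r²),
   r = (L₃ − L₂)/(L₂ − L₁),

   fitted by nonlinear least squares with anchor ages (t₁, t₂, t₃) =
   (6, 10, 14); the growth index *G* of a fish is its length residual (cm)
   from the fitted curve, an age-independent relative growth measure.
4. **Discrimination** — stepwise discriminant analysis (greedy Wilks' Λ
   minimization, F-to-enter 3.84 / F-to-remove 2.71), canonical linear
   discriminant axes, classification by maximum posterior under the
   shared-covariance Gaussian model with group-size priors, leave-one-out
   cross-validation, and assignment of AB fish along the AA–BB axis.
5. **Variance partitioning** — genotype-proportion chi-squared tests,
   per-descriptor linear-model significance scans, a three-way Type III
   ANOVA of *G* on genotype, location and cohort with two-way interactions
   (empty-cell aware), and Tukey HSD post-hoc comparisons with compact
   letter displays.
6. **Synthetic data** — a generator that emulates the archive the analysis
   assumes (826 fish from three spawning grounds sampled in year-by-location
   batches over five decades, AB-dominant genotype mix varying by cohort,
   growth variance dominated by location and cohort, otolith shape driven by
   growth rate, cohort and — weakly — genotype, AB shapes an even mixture of
   the homozygote shape models), so every stage is testable without any
   archived material.

## Worked example

```python
import otoshape as ot
from otoshape.synthetic import SimConfig

res = ot.run_study(SimConfig(n_fish=826, seed=1), kind="fourier")
print(res.two_group.per_group_pct)     # AA 91.0, BB 79.5  (% correct, LOO)
print(res.three_group.overall_pct)     # 59.9
print(res.ab_assignment.summary_pct)   # AA 51.7, BB 48.3
print(res.anova.table.loc["genotype", "p"])   # 0.113
```

On this seeded synthetic study the two-group AA-vs-BB discriminant reaches
91% / 80% per-group success while the three-group analysis collapses to 60%
overall (nearly everything is classified as the numerous AB group) — the
heterozygote's shape variability, spread across the whole AA–BB range,
destroys the three-group classification. AB fish are assigned essentially
50/50 to the two homozygote shapes. The three-way Type III ANOVA finds
location (p = 0.008) and cohort (p < 0.001) significant for the growth index
while genotype is not (p = 0.11): growth-rate variance attributable to
ecotype is dwarfed by cohort- and location-related variance, which is
exactly the mechanism that masks ecotype signal in otolith shape.

A thin CLI mirrors step 4 for tabular inputs:

```sh
otoshape-discriminate --fish fish.csv --descriptors desc.csv \
    --groups AA,BB --add cohort --loo fixed --out-prefix dfa
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the whole pipeline from scratch on seeded synthetic data: the
growth-curve fit, both stepwise DFAs with leave-one-out confusion matrices,
the AB assignment split, the per-descriptor GLM scan, the genotype-by-decade
chi-squared test, the Tukey comparison of *G* across genotypes, the Type III
ANOVA, and the descriptor dimensionalities (45 Fourier / 64 wavelet), then
writes its JSON report to `--out`.
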