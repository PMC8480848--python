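# Methods

This note documents the models, numerical conventions and deliberate design
choices behind `otoshape`, in the spirit of a package reference manual. It
states no empirical result that the test suite or `scripts/acceptance.py` do
not themselves compute.

## Outline extraction

Backlit otolith photographs are solid dark silhouettes on a light
background. `binarize` thresholds at or below a global Otsu value (the
threshold is exposed because imaging protocols differ), keeps only the
largest connected component and fills interior holes — interior bright
spots on a silhouette are artefacts, not anatomy. `trace_outline` uses
sub-pixel marching-squares contouring at the 0.5 level, so the traced
boundary runs midway between foreground and background pixel centres;
a component touching the image border raises an error rather than being
silently cropped, because a truncated outline corrupts every descriptor
downstream. Images of left otoliths are mirrored before description so all
shapes share the right-otolith chirality.

Coordinates map image (row, col) to Cartesian (x, y) with the origin at the
lower-left and outlines stored counter-clockwise; this fixes the Fourier
phase conventions unambiguously. All geometry is in mm via `pixels_per_mm`;
microscope optics are metadata only.

The Feret diameter is computed over convex-hull vertices and is exactly the
brute-force maximum pairwise distance (the diameter of a point set is
attained on its hull). For very dense hulls the pairwise scan is chunked to
bound memory; the result is unchanged.

## Elliptic Fourier descriptors

The closed outline is expanded with the Kuhl–Giardina chain-sum formulas,
which integrate the piecewise-linear contour exactly under the constant-
speed (arc length) parameterization. Normalization standardizes the start
point and rotation on the first harmonic ellipse (start on the semi-major
axis, major axis rotated onto +x), resolves the residual 180° ambiguity by
a deterministic sign rule on the first decisive even-harmonic coefficient,
and divides by the Feret diameter (the field's usual otolith size measure;
`size_norm="a1"` gives first-semi-major normalization instead). The three
first-harmonic coefficients pinned by this standardization are dropped:
n harmonics yield 4n − 3 descriptors, 45 at the default n = 12. The
retained first-harmonic term is the aspect (minor/major) of the best-
fitting ellipse.

Two properties of the arc-length convention are worth knowing:

* An ellipse traversed at constant speed has genuine odd higher harmonics
  (≈7% of the first harmonic for a 2:1 ellipse) — only a circle is a pure
  first-harmonic shape. The tests therefore check the ellipse against a
  direct dense Fourier integral, not against zero.
* Synthesis followed by re-description is not the identity map: perturbing
  a curve in coefficient space also perturbs its own arc-length
  parameterization, so a planted coefficient delta is measured as that
  delta passed through a fixed first-order mixing across harmonics. The
  synthetic generator's guarantee is therefore *linearity* of the measured
  descriptor response (verified in the tests), not per-coefficient identity.

## Wavelet descriptors

The outline is resampled as a 1024-point centroid-radius profile at equally
spaced angles, with angle zero along the Feret axis (direction towards the
Feret endpoint farther from the centroid), making the profile independent
of where boundary tracing started. Radii are exact ray/segment
intersections; a ray crossing the boundary more than once (a non-star-shaped
outline) raises an error naming the offending angle, rather than silently
switching parameterization.

The transform is a periodized orthonormal Daubechies filter bank (default
`db4`, orders 1/2/4 available) implemented directly: circular convolution
with stride-2 decimation, inverted by the adjoint. For any even length the
wrapped even-shift autocorrelations of an orthonormal filter vanish, so the
periodized analysis stays exactly orthonormal at every level down to a
single coefficient — giving testable perfect reconstruction and energy
conservation (both held to 1e-8 in the acceptance tests). A 1024-point
profile yields a 10-level decomposition; the 64 coarsest coefficients (the
scaling coefficient plus detail bands of sizes 1, 2, 4, 8, 16, 32 — depths
10 down to 5) are the shape descriptors, each tagged with its level.
PyWavelets was not available in the target environment; the in-package
transform is deliberately minimal and fully tested.

## Length detrending

Each descriptor is regressed on fish length with location-specific
intercepts and a common slope β; if the slope's t-test is significant at
α = 0.05 the descriptor is replaced by `descriptor − β·(length − mean
length)`. Centering preserves the descriptor's scale; a `strict` mode
subtracts β·length verbatim, differing only by a constant per column, which
no downstream discriminant or ANOVA result can see (tested). No
multiple-testing correction is applied in this screen by design — the screen
is a preprocessing filter, not an inference.

## Growth model

The Francis parameterization anchors the von Bertalanffy curve at the
expected lengths L1, L2, L3 at ages 6, 10 and 14 (t2 must be midway, and
these defaults bracket the sampled age range 6–14). It is fitted by
Levenberg–Marquardt from a small multistart around the empirical mean
lengths at the anchor ages; the r → 1 degeneracy (uniform growth) is
handled by its analytic limit — linear interpolation through the anchors —
below |r − 1| < 1e-8, and intermediate iterates with r < 0 are kept finite
by a sign-symmetric continuation and flagged at the optimum. A single
pooled fit across locations/cohorts/genotypes is the default (per-group
fits are a caller-side loop). The growth index G is the per-fish residual;
fish outside the fitted age support get G flagged as extrapolated.

## Discrimination

Stepwise selection greedily minimizes Wilks' Λ = det(W)/det(T): at each
step the candidate with the largest partial F enters if F ≥ F_enter
(default 3.84), and entered features with partial F < F_remove (default
2.71) are removed; ties break by column order so runs are deterministic.
The thresholds are the classical stepwise-DFA defaults; the source
procedure names no values. Canonical axes come from the between/within
generalized eigenproblem (at most n_groups − 1), and classification is by
maximum posterior under a shared-covariance Gaussian with priors equal to
the group proportions of the training sample.

Leave-one-out cross-validation refits the discriminant without the held-out
fish. By default the feature selection is performed once on the full sample
and held fixed across folds — matching how classical stepwise-DFA software
reports "cross-validated" accuracy; a fully `nested` mode (selection re-run
inside each fold) exists for honest error estimation and is the right
choice when the selection itself is in question. Cohort enters the feature
set as a centered calendar year alongside G.

AB fish are scored on the AA-vs-BB model's discriminant axis and assigned
by maximum posterior; the split percentages and score distributions are the
basis for heterozygote-intermediacy analyses.

## Group statistics

Type III sums of squares follow their literal definition — the RSS increase
when a term's sum-to-zero-coded columns are removed from the otherwise full
design — computed on a full-rank basis obtained by sweep-order pivoting
(intercept, main effects, interactions, in that order), so empty-cell
redundancy is charged to the interactions. One departure is needed for
sparse archival designs: when an interaction is rank-deficient (empty
cells), the classic test of any term it contains degenerates, because the
interaction columns absorb that term's explanatory directions; such terms
are instead tested marginally, with the deficient interaction excluded from
both models, keeping full df and marginal power. On designs with fully
populated cells every test reduces to the plain full-vs-reduced RSS
difference (verified against an independent statsmodels oracle), and on
balanced designs Type III equals Type I term for term. A term whose own
columns add no rank is reported aliased, with no F or p — mirroring how
classical packages annotate inestimable interactions in archival data.

The "multivariate GLM" scan is implemented as per-descriptor univariate
F-tests within one shared design (G, location, cohort, genotype, G×cohort
by default); the reported quantity is the count of descriptors significant
per term at α = 0.05, uncorrected. Chi-squared tests of genotype
proportions drop empty rows/columns with a warning and warn when expected
counts fall below 5. Tukey HSD uses the pooled one-way MSE with the
Tukey–Kramer standard error for unequal group sizes and the studentized-
range distribution; compact letters are assigned from the maximal cliques
of the non-significance graph, which makes "groups share a letter iff not
significantly different" exact.

## Synthetic data: the stated world

The generator emulates the archival design the analysis assumes:

* **Sampling**: 14 year-by-location batches (three spawning grounds,
  1948–2000, batch sizes summing to 826). Batches — not independent draws
  of year and location — matter: they reproduce the location-by-cohort
  confounding of a real archive, which controls how many interaction df
  are estimable in the ANOVA. Ages are uniform on 6–14;
  cohort = sampling year − age.
* **Genotypes**: per-cohort (AA, AB, BB) proportions averaging about
  (0.24, 0.60, 0.16) with sinusoidal AA/AB inversions across cohorts.
* **Growth**: length = Francis curve (L1, L2, L3 = 55, 80, 95 cm) +
  true_G + observation noise (SD 2 cm). true_G adds location offsets
  (BRE −3.5, FAX +0.5, SW +2.0 cm), per-cohort offsets drawn once with
  SD 3.5 cm, genotype offsets (AA +0.2, AB 0, BB −0.2 cm) and an
  individual deviate (SD 5 cm). The genotype component is deliberately
  near-nil: in the source world the genotype effect on growth vanishes
  once location and cohort are accounted for, and the location spread is
  set to the magnitude implied by that world's variance partition.
* **Shape**: raw elliptic-Fourier coefficients = a cod-like base (an
  elongated lobed oval measured from a parametric curve) + genotype offsets
  of 1.6 noise SD on four mid harmonics + a growth-rate slope + a cohort
  trend + per-coefficient noise (SD 0.01 mm), reconstructed at 512 points;
  self-intersecting draws are retried up to 10 times with fresh noise. AB
  fish adopt the AA or BB offset with equal probability — a behavioural
  mixture — and left-side fish (25% by default) get mirrored outlines.
  The genotype effect size is calibrated once so that the two-group
  AA-vs-BB discriminant succeeds markedly better than the three-group one
  and the AB mixture assigns near-evenly despite group-size priors, the
  qualitative contrast the package exists to reproduce; it is not tuned to
  any published percentage.

What a green end-to-end test establishes: the pipeline's machinery
(descriptors, growth index, selection, LOO, ANOVA) reproduces the
qualitative masking phenomenon under the stated world. What it does not
establish: agreement with the source study's numeric classification rates,
which depend on an unpublished otolith archive; or realism of features the
generator does not model — no otolith annuli or sulcus, no broken-otolith
reconstruction, no ageing error, no gear selectivity, and shape noise that
is independent across coefficients rather than spatially structured.

## Numerical conventions

* Orientation: outlines canonical counter-clockwise; mirroring reverses
  point order to preserve orientation.
* EFD invariance tolerance 1e-6 (achieved at machine precision in tests);
  the residual 180° normalization ambiguity is resolved by a sign rule with
  a 1e-9 relative decisiveness threshold.
* Sweep pivoting and rank decisions use a 1e-8 relative tolerance with one
  re-orthogonalization pass.
* Stepwise F comparisons use a 1e-12 absolute tie window before falling
  back to column order.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the same seed gives byte-identical fish
  tables, outlines and rendered images.
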