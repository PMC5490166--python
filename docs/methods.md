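# Methods

This note documents the models, conventions and numerical choices behind
`cardiodense`, what the synthetic data do and do not emulate, and the
design decisions taken where more than one convention was defensible.

## Displacement encoding and decoding

A DENSE acquisition encodes in-plane tissue displacement into the phase of
two images (horizontal and vertical encoding).  We model the stored phase
at a tissue pixel as `wrap(2π k_e u) + ε`, with `ε ~ N(0, σ_φ)` independent
per pixel and per encoding direction, re-wrapped into `(−π, π]`; background
pixels carry uniform random phase.  The default encoding frequency is
`k_e = 0.1` cycles/mm, giving an unambiguous displacement range of
±`1/(2 k_e)` = ±5 mm.  Phase noise maps to displacement noise of SD
`σ_φ/(2π k_e)` (≈0.24 mm at σ_φ = 0.15 rad), which the test suite verifies
on a flat-field phantom.

**Unwrapping** is a quality-guided flood fill: pixel quality is the inverse
(1 + variance) of the wrapped phase differences to the 4-neighbourhood, and
each 4-connected component of the tissue mask grows from its highest-quality
pixel, always expanding the highest-quality frontier pixel next.  Off-mask
pixels never participate (their phase is noise by construction).  Within a
component the result equals the true phase up to one additive multiple of
2π, provided the true phase is spatially consistent (adjacent differences
inside `(−π, π]`).

**Anchoring.**  The per-component 2π ambiguity corresponds to a constant
displacement offset of `1/k_e` = 10 mm.  The default rule picks the integer
offset that minimises the median absolute displacement of the component,
separately per encoding direction; the rationale is that bulk cardiac
displacement between end-diastole and end-systole is small compared with
the 10-mm ambiguity step.  A user-supplied zero-displacement anchor pixel
overrides the rule for its component.  Because the offset is constant per
component it shifts the deformed mesh rigidly and cannot affect strain; it
only matters for absolute displacement read-outs.

## Mesh-deformation strain

The myocardial wall between an endocardial and an epicardial contour is
meshed as a structured strip: both contours are resampled by arc length,
intermediate layers are linear blends, and quads are split into triangles
(minimum element angle enforced at 15°).  Node displacements are bilinear
interpolations of the decoded field (matching the per-pixel provenance of
DENSE and avoiding overshoot); nodes within one pixel of the mask border
use nearest-valid filling and are counted in the result.

Per element, the affine map from the reference to the deformed triangle
gives the deformation gradient `F`; the strain measure is Green–Lagrange
`E = ½(FᵀF − I)`, which is exactly objective (rigid motions give `E = 0`
to machine precision — a test asserts `< 1e-10`).  Longitudinal strain is
the projection `E_LL = ℓᵀEℓ` onto the element's longitudinal direction
`ℓ`: the local wall-centreline tangent, oriented by the base→apex ordering
of the input contours.  The wall-tangent convention is our documented
choice; an engineering-strain column (`λ − 1 = √(1+2E_LL) − 1`) is provided
for comparability with speckle-tracking conventions.  Elements with
`det F ≤ 0` are excluded and counted; more than 20 % of them is a hard
error.  The free-wall summary is the unweighted mean of `E_LL` over
`rv_free_wall` elements (elements are near-uniform in size by the mesh
contract; an area-weighted option exists).  All labelled free-wall elements
are retained, including those near the insertion points.

The RV method is deliberately single-frame: strain is computed at the
end-systolic frame only, selected as the frame of minimum chamber area
(automated argmin with earliest-frame tie-breaking and a manual override),
with no temporal smoothing.  The cine LV path decodes each frame relative
to end-diastole, computes the same mesh strain over `lv_wall` elements,
takes the most negative point of the curve as peak strain, and averages
the two- and four-chamber views when both are present; it applies no
temporal smoothing either.

**Defaults.**  Image matrix 128×128 at 1.6 mm in-plane spacing (a typical
high-resolution pediatric four-chamber DENSE protocol); mesh target edge
length 3.0 mm (~2 pixels).  The edge length matters under noise: the
noise-induced bias of `E_LL` is quadratic in the displacement-gradient
noise, which scales inversely with element size; 3-mm elements keep the
bias below 0.01 absolute at σ_φ = 0.15 rad while still resolving the 6-mm
free wall with two element layers.

## The imaging phantom

One 2D four-chamber-like plane holds an annular LV wall (radii 10–18 mm)
and a crescent-shaped RV free wall (radii 24–30 mm, ±60° arc), placed
disjointly.  Ground-truth deformations are analytic maps with closed-form
strain: translations and rotations (objectivity tests), uniform axis
stretches, isotropic scaling (uniform strain on the closed LV ring), and
azimuthal scaling `(r, θ) → (r, λθ)` about the crescent centre, which
imposes exactly uniform longitudinal strain `E_LL = (λ²−1)/2` on every
free-wall element — the work-horse for ground-truth recovery.  Strain
tensors of every map are verified against numerical differentiation of the
displacement (to 1e-6).

The tissue mask includes a 1.5-pixel margin beyond the contours, emulating
a segmentation that keeps partial-volume boundary pixels; this guarantees
every contour node a fully valid bilinear stencil (without it,
nearest-valid filling at the wall edge biases recovered strain by ~0.005).
Through-plane motion, k-space/MRI physics, echo-suppression artifacts and
multi-frame phantoms beyond a linear ED→ES ramp are not simulated; passing
phantom tests therefore demonstrates correctness of the decoding and strain
chain, not robustness to acquisition artifacts (blurring, mis-registration)
that cause real-world exclusions.

## Volumetry, mass, classification

Ventricular volume is the slice-summation Simpson's rule: per-slice polygon
area (shoelace) times the effective slab height (slice thickness + gap),
summed over the stack.  Both ventricles use this method — including the LV,
where a dedicated 3D surface reconstruction would differ by a few percent
in absolute volume; this is a documented simplification.  Contours are
taken as provided (no papillary/trabecular convention enforced).
Myocardial mass is the epi−endo shell volume at end-diastole times
1.05 g/mL, computed strictly between the provided contours (whether septum
is included is determined by the contour convention, not by the code), and
indexed to height^2.7 — the allometric normalisation appropriate for
children.  Volumetry fixtures slice analytic nested ellipsoids/cylinders,
whose closed-form volumes bound the discretisation error (<0.1 % at 1-mm
slices for a 30-mm sphere).

LV remodeling classes combine LVMI and mass/volume ratio at the cutoffs
27.52 g/m^2.7 and 0.69 g/mL (taken as published, not re-derived).  Values
exactly at a cutoff classify to the lower category (strict inequality for
"above"); the cutoffs are configurable, the boundary convention is not.

## Cohort statistics

The statistical layer is implemented from first principles on tabular data;
least-squares fits solve the normal equations and are cross-checked against
an independent QR solution on every call (disagreement raises).  All tests
are two-sided with significance at p ≤ 0.05 (inclusive).  Missing values
are deleted listwise per analysis and counted.

- **Age-adjusted comparison (ANCOVA).**  `outcome ~ group + age`.  The
  reported difference, SE and p always come from this additive model.  A
  group×age interaction model is fitted alongside; its p-value tests slope
  equality, and the interaction-model contrast at the mean age is reported
  in separate fields for use when slopes differ.  We deliberately do *not*
  switch the primary estimate to the interaction model when the interaction
  is significant: that conditional selection measurably inflates the null
  rejection rate (~0.053 vs 0.048 in our calibration runs), whereas the
  unconditional report keeps the test at its nominal level.
- **t-test.**  Pooled-variance two-sample by default, Welch optional (the
  original analysis does not state which; pooled is the classical default).
- **Fisher's exact test.**  Two-sided by summation of hypergeometric
  probabilities not exceeding the observed table's.
- **ANOVA + Dunnett.**  One-way F-test across remodeling groups after
  pooling the two intermediate classes (concentric remodeling + eccentric
  hypertrophy; their observed sizes are small).  Adjusted p-values are
  `P(max_i |T_i| ≥ |t|)` under the equicorrelated-factor multivariate-t
  with `λ_i = √(n_i/(n_i+n_ref))`, computed by seeded Monte Carlo (default
  2×10⁵ draws) or deterministic Gauss–Hermite × quadrature integration.
  The adjusted p is floored at the unadjusted p so the dominance
  `p_adj ≥ p_unadj` holds despite Monte-Carlo noise.
- **Adjusted associations.**  Partial correlation: both variables are
  residualised on the covariates (sex, height by default; sex only for the
  BMI z-score, which already embeds height standardisation), and the
  residual Pearson r is reported with `t = r√((n−k−2)/(1−r²))`.  Whether
  the original "multivariable regression r" is a partial correlation or a
  standardised coefficient is not stated; partial correlation is our
  documented choice.
- **Reproducibility.**  The modified CoV is
  `Σ_i SD(x1_i, x2_i) / |Σ_i mean(x1_i, x2_i)|` (two-value SD =
  `|x1−x2|/√2`), flagged reproducible at ≤20 %.  Bland–Altman reports
  `mean(x2−x1)` with limits ±1.96·SD(differences, n−1).

## The synthetic cohort

Each weight group is a correlated multivariate Gaussian over the core
tabulated variables (demographics, pressures, circumferences, cardiac
indices, strains), with sex Bernoulli and a few columns derived
deterministically so internal identities hold exactly (BMI from weight and
height, waist/hip ratio, SV = EDV − ESV, EF = SV/EDV, RV mass from its
height-indexed value).  Group means and SDs default to the study
population's tables (34 obese/overweight vs 36 healthy), so the published
arithmetic (e.g. the 22 % RV mass-index difference) re-emerges from large
draws.  Within-group correlations encode the structure the analyses rely
on: height with weight and ventricular volumes, EDV with ESV (0.85, so the
derived EF has a realistic spread), RV strain with LV strain (0.34),
systolic pressure and hip circumference, and a positive correlation (0.20)
of the signed strain with age, reflecting the modest decline of strain
magnitude through adolescence consistent with parallel age–strain
regression lines in the two groups.  A few physically bounded variables
(BMI percentile, volumes, heights) are clipped to plausible ranges; the
bounds sit several SDs from the means, so the requested covariance is
preserved to within the 2 % the tests check.  The generator reproduces
marginal table structure, not a mechanistic heart: LV mass index and
mass/volume ratio are drawn, not derived from simulated LV geometry.

## Pipeline and reproducibility

The pipeline driver simulates a cohort, writes one DENSE phantom per
subject (HDF5, with `k_e`, pixel spacing and seed as required attributes),
re-reads and decodes each file, measures free-wall strain and — from
sliced-ellipsoid stacks matched to the subject's volumes — RV volumetry and
mass, classifies remodeling from the tabulated LV indices, and runs the
statistics, emitting a tidy results CSV, a human-readable report and a
machine-readable data dictionary (fixed units per column).  A subject whose
files fail to process is logged and skipped; the run completes with status
"partial".  All randomness flows from a single seed through named
generators, and outputs are byte-reproducible (HDF5 written without
timestamps).

Validation problem sizes: strain recovery uses 4 imposed strains noiseless
plus 50 noise seeds at −18 %; statistical calibration uses 1000 null
replicates for the ANCOVA and the Dunnett family (a calibrated 5 % test
falls inside the binomial band [0.036, 0.064] with 95 % probability, so an
occasional marginal excursion for a particular seed family is expected);
power uses 500 cohort draws at the study group sizes.

## Known limitations

- 2D single-plane phantoms; no through-plane motion, no acquisition
  physics, no image-quality failure modes.
- The anchor rule assumes bulk displacement well below 5 mm per component;
  fields whose median displacement approaches a half-wrap would anchor to
  the wrong offset (strain is unaffected).
- LV volumetry by slice stacks rather than 3D surface reconstruction.
- The cohort generator emulates marginal moments and selected correlations
  only; derived-variable SDs (e.g. BMI) follow from the identities rather
  than matching tabulated SDs exactly.
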