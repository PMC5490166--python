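# cardiodense

Quantification of right-ventricular (RV) contractile function from
displacement-encoded (DENSE) cardiac MRI, with the surrounding measurement
chain a pediatric cardiac-remodeling study needs: Simpson's-rule ventricular
volumetry, height-indexed myocardial mass, left-ventricular (LV) remodeling
classification, and the cohort statistics used to compare obese/overweight
and healthy-weight children.  Because clinical DENSE acquisitions are not
public, the package ships synthetic phantoms with exact ground truth for
every stage, so the whole chain is testable end to end.

## The measurement

DENSE stores tissue displacement in image phase: a pixel that moved `u` mm
along the encoded direction carries phase `φ = 2π k_e u`, wrapped into
`(−π, π]`, at encoding frequency `k_e` (0.1 cycles/mm here, i.e. an
unambiguous range of ±5 mm).  The pipeline:

1. **Unwrap** the horizontal/vertical phase pair over the myocardial mask
   (quality-guided flood fill, per connected tissue region).
2. **Decode** displacement `u = φ / (2π k_e)` and **anchor** the per-region
   `1/k_e`-mm offset ambiguity (minimum-median-|u| rule, or a user anchor
   pixel).
3. **Deform** a reference end-diastolic wall mesh by the decoded field and
   compute, per triangle, the deformation gradient `F` and Green–Lagrange
   strain `E = ½(FᵀF − I)`.
4. **Project** onto the local wall-tangent (base→apex) direction `ℓ`:
   longitudinal strain `E_LL = ℓᵀEℓ`, negative in systole; the RV summary is
   the mean over `rv_free_wall` elements at the end-systolic frame (minimum
   chamber area).

Companion modules compute volumes (`Σ slice-area × slab height`), mass
(shell volume × 1.05 g/mL, indexed to height^2.7), the four LV remodeling
classes (cutoffs: LVMI 27.52 g/m^2.7, mass/volume 0.69), and the
statistical layer (age-adjusted ANCOVA with a slope-equality check, pooled
t-tests, Fisher's exact test, ANOVA with Dunnett contrasts, sex/height
adjusted partial correlations, a modified inter-observer coefficient of
variation, Bland–Altman agreement).

## Worked example

```python
import numpy as np
import cardiodense as cd
from cardiodense.experiments import decode_chain

spec = cd.PhantomSpec(noise_sd_rad=0.1, seed=12)       # 128x128, 1.6 mm, k_e = 0.1
field = cd.imposed_strain_field(spec, -0.18)           # true E_LL = -18 %
phantom = cd.make_phantom_pair(spec, field)
print("wrapping expected:", phantom.pair.meta["wrapping_expected"])

disp = decode_chain(phantom)                           # unwrap -> decode -> anchor
err = np.abs(disp.u_x - phantom.truth_ux)[phantom.rv_mask].max()
print(f"max |u_x - truth| on the free wall: {err:.3f} mm")

result = cd.deform_and_strain(phantom.meshes["rv"], disp)
print(f"RV free-wall longitudinal strain: {result.summary_pct:.2f}%  "
      f"({result.n_retained} elements, {result.n_excluded} excluded)")
```

prints

```
wrapping expected: True
max |u_x - truth| on the free wall: 0.466 mm
RV free-wall longitudinal strain: -17.54%  (76 elements, 0 excluded)
```

The imposed deformation reaches ~6 mm of displacement, beyond the ±5 mm
unambiguous range, so the phase wraps and is recovered spatially; with
0.1 rad of phase noise the per-pixel displacement error is a few tenths of
a millimetre and the 76-element free-wall mean lands within half a
percentage point of the imposed −18 %.

The same chain is available from the shell:

```bash
cardiodense simulate --seed 3 --strain-pct -18 --noise-sd 0.1 --out demo.h5
cardiodense strain demo.h5
# RV free-wall longitudinal strain: -17.78% (76 elements, 0 excluded)
cardiodense run-all --seed 7 --out out/        # full phantom-cohort pipeline
```

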