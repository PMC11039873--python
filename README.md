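# canalssm

Statistical shape analysis of the **distal femoral medullary canal** — the
hollow cavity of the femoral shaft where osseointegrated stems and
intramedullary nails are implanted. The package is aimed at biomechanics and
implant-design researchers who want to quantify how canal geometry varies
across a population, and how that variability depends on the residual canal
length left after a transfemoral amputation.

## What it computes

Given a cohort of triangulated canal surfaces (STL/PLY), the pipeline:

1. **mirrors** right-side canals onto left-side geometry (rigid Procrustes
   residual against an intermediate-sized left reference, with and without
   reflection across the sagittal plane);
2. **cuts** sixteen nested distal segments from each canal, from 25% to 100%
   of the full region-of-interest length in 5% steps — each segment models a
   residual limb after amputation at that level;
3. **aligns** every segment rigidly to the corresponding segment of the
   reference canal with point-to-point ICP (stopping increments 0.01 mm in
   translation, 0.05° in rotation);
4. establishes dense **point-to-point correspondence** by elastically
   registering the reference mesh onto every subject with an iterated
   thin-plate-spline (RBF) deformation (stopping distance 0.001 mm, at most
   50 iterations), producing iso-topological geometries;
5. builds a **statistical shape model** per segment: a rigid-only
   generalized-Procrustes mean M̄ and a PCA of the stacked vertex
   coordinates, giving modes m_i and variances λ_i. The main anatomical
   variations are the mode shapes

       M_{i,±2σ} = M̄ ± m_i · 2√λ_i ;

6. **parametrizes** every shape by five geometric features, measured from
   10-mm cross-sections best-fitted with ellipses: longitudinal length La,
   radius of curvature Rc (least-squares circle through the slice centroids
   in their SVD best-fit plane), distal ellipticity ell (Axmax − Axmin),
   mean area-equivalent diameter davg, and conicity con (distal minus
   minimum diameter);
7. reports, per segment and per mode, the **percent variation** of each
   parameter between the ±2σ shapes,
   var% = |p₊ − p₋| / ((|p₊|+|p₋|)/2) × 100, flagging variations under 5% as
   negligible and highlighting, per parameter, the mode that carries it.

A first-class **synthetic cohort generator** produces tubular canal surfaces
with known ground truth for all five parameters (plus random rigid pose and
left/right side), so every stage is testable without any imaging data.

## Worked example

```python
import numpy as np
from canalssm import (CanalParams, PipelineConfig, PopulationSpec,
                      canal_features, generate_canal, run_pipeline)

# one synthetic canal with known geometry, and its extracted features
p = CanalParams(length_mm=180.0, curvature_radius_mm=900.0,
                diameter_distal_mm=18.0, diameter_min_mm=11.0,
                ellipticity_mm=2.5)
mesh = generate_canal(p, n_circumferential=48, n_longitudinal=91)
f = canal_features(mesh)
print(f"La   = {f.length_mm:.1f} mm")
print(f"Rc   = {f.curvature_radius_mm:.0f} mm")
print(f"ell  = {f.ellipticity_mm:.2f} mm")
print(f"davg = {f.mean_diameter_mm:.2f} mm")
print(f"con  = {f.conicity_mm:.2f} mm")

# a small cohort through the full pipeline at two segment lengths
spec = PopulationSpec(n_subjects=12, seed=0)
result = run_pipeline(PipelineConfig(population=spec, fractions=(0.40, 1.00)))
for frac, fr in sorted(result.fractions.items()):
    pcs = ", ".join(f"{100*v:.1f}%" for v in fr.variance_fractions[:4])
    print(f"{frac:.0%} L: PC variance [{pcs}], {fr.n_modes_90} mode(s) reach 90%")
vt = result.fractions[1.00].variation
print("highlighted PC per parameter:", vt.highlights)
```

prints

```
La   = 180.0 mm
Rc   = 900 mm
ell  = 2.50 mm
davg = 13.95 mm
con  = 6.99 mm
40% L: PC variance [90.3%, 9.2%, 0.4%, 0.1%], 1 mode(s) reach 90%
100% L: PC variance [98.0%, 1.7%, 0.2%, 0.0%], 1 mode(s) reach 90%
highlighted PC per parameter: {'La': 1, 'Rc': 3, 'ell': 4, 'davg': 2, 'con': 4}
```

The extracted features reproduce the generator's ground truth (La 180, Rc
900, ell 2.5, con 7 = 18 − 11). In the cohort run, PC1 carries almost all
variance because canal length dominates the default population spread, and
each geometric parameter is traced to the principal component that moves it
most.

The same pipeline runs from the shell on a directory of meshes or a
synthetic specification:

```sh
canal-ssm generate --n-subjects 20 --seed 1 --outdir cohort/
canal-ssm run --config run.yaml
```

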