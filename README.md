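# nervestereo

Vertical-section stereology for segmented serial-section EM stacks, built
around the question of how corneal stromal nerve bundles interact with the
epithelial basal lamina: slim bundles *penetrate* through lamina pores into
the epithelium, while swollen bundles terminate by *fusing* with basal
epithelial cells. The two phenotypes differ sharply in surface-to-volume
ratio, and this package provides the full measurement chain used to
quantify that difference — plus a synthetic phantom generator with
closed-form ground truth to validate every step.

For image analysts working with serial block-face SEM segmentations
(anisotropic label stacks: nanometre pixels, 100 nm z-steps) who need
unbiased surface density estimates from single randomly chosen sections.

## What it computes

The surface-to-volume ratio is estimated with a cycloid test grid cast on
vertical sections:

    Ŝ_V = 2·ΣI / ((l/p)·ΣP)

where **I** counts transversal intersections of the cycloid arcs with the
bundle boundary, **P** counts test points inside the bundle, and **l/p** is
the grid's test-line length per point (8·r_c for a full arc per point).
The arcs' minor axis is aligned with the tissue's vertical axis — the normal
of the per-section basal-lamina trace — which makes the sine-weighted
cycloid orientation distribution exactly compensate the anisotropy of
vertical sections. A restriction line across each lamina pore confines
counts to the stromal side.

Around the estimator: voxel-summation volumes, pore "maximum dimension"
(max Feret diameter over sections), bundle phenotype classification by 3D
connectivity (fusing axon ↔ epithelium through a pore), pooled two-tailed
Student's t (S/V groups), exact-enumeration Mann-Whitney U (pore sizes),
fusion frequency and volume fractions.

The phantom module generates calibrated cohorts: capsules tuned to the
penetrating-group mean S/V (3.32 μm⁻¹) and tube-with-bulb shapes tuned to
the fusing-group mean (1.39 μm⁻¹), rasterized into label stacks
(multi-page TIFF + JSON sidecar) with lamina, pores and epithelium.

## Worked example

```python
from nervestereo import generate_cohort
from nervestereo.pipeline import estimate_cohort

cohort = generate_cohort(n_pen=8, n_fus=6, cv=0.0, seed=42)   # calibrated phantoms
results = estimate_cohort(cohort, lp=0.7, casts=5, seed=43)   # grid estimation
```

`python examples/04_sv_recovery.py` (exactly this computation) prints:

```
 penetrating: n=8  mean Ŝ_V = 3.298 μm⁻¹ (target 3.32; per-bundle SEM 0.055)
fusing_mixed: n=6  mean Ŝ_V = 1.395 μm⁻¹ (target 1.39; per-bundle SEM 0.036)
```

i.e. the grid estimate recovers each phenotype's analytic surface-to-volume
ratio, and the penetrating mean is more than twice the fusing mean — the
morphological contrast between the two kinds of nerve-epithelium
interaction. The `examples/` directory has one short script per capability
(shapes & calibration, voxelization, a single grid cast with an audit
overlay, cohort recovery, and the full statistics pipeline).

A thin CLI wraps the same pipeline:

```
nervestereo run --seed 1 --out results_run        # simulate → estimate → compare
nervestereo count stacks/pen_000.tif --lp 0.7 --casts 5 --seed 1
```

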