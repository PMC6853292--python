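# Methods

`nervestereo` estimates the surface-to-volume ratio (S_V), volume, pore
geometry and phenotype of nerve bundles from segmented serial-section EM
stacks, and validates the whole chain on synthetic phantoms with closed-form
ground truth. This note documents the model, the sampling design, the
numerical choices and their limitations.

## The estimation problem

Corneal stromal nerve bundles approach the epithelial basal lamina and either
*penetrate* through a lamina pore into the epithelium (slim, high-S_V
bundles) or terminate in a *fusion* with a basal epithelial cell (swollen,
low-S_V bundles). Serial block-face SEM delivers registered label stacks
with strongly anisotropic voxels — in-plane pixels of 4–15 nm but z-steps of
100 nm — so the sections are *vertical sections*: they all contain the
tissue's vertical axis (the epithelial-surface normal). Surface density
cannot be estimated from such sections with isotropic line grids; the
classical remedy is a cycloid test system.

## Cycloid grids and the surface-to-volume estimator

A cycloid arc `(u, v) = r_c (t − sin t, 1 − cos t)`, `t ∈ [0, 2π]`, has
length `8 r_c` and tangent directions distributed ∝ sin θ, with θ measured
from the arc's minor axis. Casting such arcs on a vertical section with the
minor axis parallel to the vertical axis exactly compensates the orientation
bias of vertical sections, giving the unbiased estimator

    Ŝ_V = 2 ΣI / ((l/p) · ΣP)

where I counts transversal intersections of the arcs with the structure
boundary, P counts test points inside the structure, and l/p is the test-line
length per point (`l/p = 8 r_c` with one point per full arc, placed at the
arc-length midpoint, i.e. the apex). The repeating tile is
`2π r_c × 4 r_c` and holds the base arc plus its vertical mirror image
shifted by half a tile — a packing with 2-fold rotational symmetry.

**Grid orientation.** The per-section basal-lamina trace is fitted by total
least squares; the grid is cast with the arcs' *minor* axis along the lamina
*normal* — the tissue's vertical axis. (Equivalently: the grid card's
vertical arrow, which marks the arcs' major-axis direction, is kept parallel
to the lamina.) This is the orientation for which the cycloid weighting is
exact: for a cylinder along the epithelial normal, aligning the minor axis
*with* the lamina instead would underestimate S_V by a factor 2/π ≈ 0.64.
The design assumes rotational randomization about the vertical axis, which
the serial-section geometry supplies for structures that are approximately
axially symmetric about the epithelial normal — true by construction for the
phantoms, and approximately true for bundles imaged as they approach the
epithelium.

**Sampling design.** Per bundle, one section is drawn uniformly among the
sections in which the bundle is visible (the study's design). With
`casts > 1` the implementation uses systematic-uniform-random sampling
(SURS): a single random start, then every (n/casts)-th visible section, with
an independent uniform grid phase per cast. SURS is marginally uniform
(hence unbiased) and suppresses most of the profile-size variance of
independent draws. Counts are pooled across casts as a ratio of sums —
`2·ΣI / (l/p · ΣP)` — not a mean of per-cast ratios; the latter is badly
biased upward (for a capsule, E[1/width] exceeds 1/E[width] by ~23%).

**Restriction line.** Where a section shows a lamina pore, the chord joining
the two trace endpoints flanking the gap is the restriction line; only
intersections and points on the stromal side (the half-plane not containing
the epithelium-label centroid) are counted, excluding epithelial-side
profiles from the stromal tally.

**Grid constant.** Default `l/p = 0.7 μm`, i.e. `r_c ≈ 88 nm`, giving
roughly 50–100 points and intersections per cast on μm-scale bundles. The
counts matter because the ratio-of-sums estimator carries a small-sample
bias of order CV²(ΣP); at these counts and 5 casts it stays at the 1% level.

## Phantoms and the synthetic cohort

Phantom shapes carry exact surface areas and volumes:

| shape | role | S, V |
|---|---|---|
| sphere(r) | oracle | 4πr², 4πr³/3 |
| capsule(r, L) | penetrating bundle | 2πrL + 4πr², πr²L + 4πr³/3 |
| tube_with_bulb(r_s, L, R_b) | fusing bundle | exact union of capsule and sphere (cap subtraction at the junction; requires L ≥ √(R_b²−r_s²)) |

Radii are calibrated by inverting the closed-form S_V (bisection to 1e-10):
the penetrating capsule (L = 6 μm) to 3.32 μm⁻¹ (r ≈ 0.640 μm) and the
fusing bulb (0.3 μm shaft, L = 4 μm) to 1.39 μm⁻¹ (R_b ≈ 2.254 μm). Group
sizes default to 23 penetrating and 20 fusing bundles. Between-bundle
variability is lognormal on the calibrated radius (median-preserving,
configurable CV, default 0.1). Basal-lamina pores are elliptical
discontinuities whose major-axis diameter is drawn from a single lognormal
(median 1.8 μm, CV 0.25) *shared by both phenotypes*, reflecting that pore
sizes do not differ between them; the aspect ratio b/a is uniform on
[0.7, 1].

Each bundle lives in its own scene: epithelium slab on top (y < y_lam),
a 0.3 μm lamina slab below it, the nerve rising from the stroma along the
vertical (y) axis. The penetrating capsule's tip stops 50 nm below the
lamina; the fusing bulb protrudes 0.2 μm into the pore so its membrane meets
the epithelium (those protruding voxels are relabelled as pore by the
priority rule, which perturbs the measurable surface and volume by ≲0.5% —
the flat cut face nearly replaces the removed cap area).

**Voxelization** is by voxel-centre membership (no partial volume) at
default spacing 10 × 10 × 100 nm, with priority pore > lamina > phantoms
(list order) > epithelium > background; it is deterministic given
(scene, spacing), and stacks may be rendered lazily per section —
bit-identical to eager rendering — so sampling pipelines touch only the
sections they use.

What the phantoms do **not** emulate: grayscale EM appearance, segmentation
error (labels are geometrically exact), multi-axon bundle substructure,
Schwann cells, curved or branching trajectories, and tilted approach angles.
Passing recovery tests therefore demonstrates correctness of the estimator
chain on ideal segmentations, not robustness to tracing error or to bundles
violating the axial-symmetry assumption.

## Other estimators

* **Volume**: voxel count × voxel volume per label.
* **Pore diameter** ("maximum dimension"): per section, the maximal caliper
  (Feret) diameter of the pore region, computed from the convex hull of the
  sub-pixel iso-contour in physical units; maximized over sections. On the
  generator's 3D pore regions this includes the lamina-slab thickness
  (√(d² + 0.3²) ≈ d for μm-scale pores), identically for both phenotypes.
* **Phenotype**: a bundle is `fusing_mixed` if any fusing-axon voxel is
  26-connected to an epithelium voxel through pore regions (membrane
  continuity across a lamina discontinuity), else `penetrating`. The
  26-connectivity runs on the anisotropic grid as-is; the ≥2-voxel-thick
  lamina slab prevents spurious diagonal leakage across an intact lamina.

## Statistics

S_V groups are compared with a two-tailed Student's t-test (pooled variance,
df = n₁+n₂−2; Welch behind a flag; two identical constant groups report
t = 0, p = 1). Pore diameters are compared with a Mann-Whitney U test: for
combined n ≤ 20 the p-value is exact by full enumeration of all C(n, n₁)
assignments of the pooled midranks (valid under ties), two-sided as the
doubled smaller tail capped at 1; above that, the tie-corrected normal
approximation with continuity correction. Summary quantities: fusion
frequency (percent of fusing bundles, one decimal, round-half-away-from-zero)
and volume fractions. Significance threshold α = 0.05 throughout
(configurable).

## Numerical choices

* **Sub-pixel boundaries.** Crossing counts use the 0.5 iso-contour of the
  label indicator smoothed with a σ = 1 px Gaussian. On raw binary masks the
  marching-squares staircase generates spurious near-tangent double
  crossings that inflate I by several percent; the smoothed level set tracks
  the true boundary (a smoothed step edge keeps its 0.5-level on the edge;
  the curvature-induced shift ~σ²κ/2 is sub-nanometre here). Contours are
  assembled even-odd, so nested contours become holes.
* **Tangency tie-break.** I counts sign changes of the inside/outside
  indicator along 256-vertex arc polylines; tangential touches without a
  sign change count zero. At 256 vertices a 10⁴-sample oracle finds no
  missed crossings over hundreds of random configurations (at 128 it found
  ~0.3%).
* **Residual bias.** The discrete 100 nm z-step weights edge sections of a
  convex body slightly above their continuum share (midpoint-rule error on
  the √-shaped profile), inflating the cohort-mean Ŝ_V by ~1% for the
  default geometries. This is a property of serial sections at fixed step,
  not of the implementation, and sits well inside the 5% recovery envelope.
* **Degenerate inputs.** ΣP = 0 raises an undefined-estimate error; an
  absent label in a section counts I = P = 0 with a warning; a lamina trace
  of coincident points, a missing pore for a restricted cast, and
  insufficient group sizes raise typed errors.

## Problem sizes

Default validation runs use the full cohorts (23 + 20 bundles, 5 casts
each) at 10 nm pixels. The repeated power study (100 full simulate→test
replicates at cv = 0.1) runs at 15 nm in-plane pixels — inside the stated
acquisition range — after verifying that recovery is pixel-size independent;
a single replicate takes a few seconds, the study minutes.

## Known limitations

* The estimator's unbiasedness leans on approximate rotational symmetry of
  the structure about the epithelial normal; strongly oblique or curved
  bundles would need genuinely randomized vertical sections.
* One grid cast per selected section is the paper-faithful default; the
  recovery envelopes quoted here use 5 SURS casts per bundle.
* Phenotype classification requires the legend to distinguish fusing from
  penetrating axon labels, as the tracing protocol did; with a single
  undifferentiated nerve label every bundle reads as penetrating.
* The pipeline treats each bundle as an independent nerve; animal-level
  clustering (10 animals per group) is not modelled.
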