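"""Calibrated phantom cohorts emulating segmented SBF-SEM stacks.

Each "nerve bundle" is one phantom approaching an epithelial basal lamina
from the stromal side, in its own scene/stack:

* penetrating bundles are slim capsules whose radius is calibrated so the
  analytic surface-to-volume ratio hits the penetrating-group mean
  (3.32 μm⁻¹ by default), their tip arrested just under the lamina pore;
* fusing bundles are tube-with-bulb phantoms calibrated to the fusing-group
  mean (1.39 μm⁻¹ by default), the swollen bulb protruding slightly into
  the lamina pore so its membrane meets the epithelium.

Between-phantom biological variability is a lognormal perturbation of the
calibrated radius with a configurable coefficient of variation.  Basal
lamina pores are elliptical discontinuities whose major-axis diameter is
drawn from a single lognormal distribution shared by both phenotypes
(pore sizes did not differ between groups).  Everything is reproducible
bit-exactly from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .estimators import Phenotype
from .scene import (
    ROLE_FUSING,
    ROLE_PENETRATING,
    LaminaSpec,
    PoreSpec,
    ScenePhantom,
    SceneSpec,
)
from .shapes import (
    Pose,
    ShapeKind,
    calibrate_radius_for_sv,
    make_capsule,
    make_tube_with_bulb,
)
from .stack import DEFAULT_SPACING, LabelStack
from .voxelize import voxelize
from scipy.spatial.transform import Rotation

# Study conditions: group sizes and group-mean S/V targets.
N_PENETRATING = 23
N_FUSING = 20
SV_PENETRATING = 3.32  # μm⁻¹
SV_FUSING = 1.39  # μm⁻¹

# Geometry defaults (μm).
CAPSULE_LENGTH = 6.0  # penetrating shaft length within the imaged volume
SHAFT_RADIUS = 0.3  # fusing-bundle shaft radius
SHAFT_LENGTH = 4.0  # fusing-bundle shaft length
LAMINA_THICKNESS = 0.3
EPITHELIUM_THICKNESS = 0.8
TIP_GAP = 0.05  # penetrating tip clearance below the lamina
BULB_PROTRUSION = 0.2  # how far the fusing bulb reaches into the pore
MARGIN = 0.5  # empty margin around structures
PORE_MEDIAN_DIAMETER = 1.8  # μm, shared by both phenotypes
PORE_DIAMETER_CV = 0.25
PORE_MIN_ASPECT = 0.7  # b/a of the elliptical pore, drawn uniformly in [min, 1]

LABEL_NERVE = 1
LABEL_LAMINA = 3
LABEL_PORE = 4
LABEL_EPITHELIUM = 5

__all__ = [
    "BundleGroundTruth",
    "build_bundle_scene",
    "generate_cohort",
    "sample_pore_diameters",
    "N_PENETRATING",
    "N_FUSING",
    "SV_PENETRATING",
    "SV_FUSING",
]


@dataclass(frozen=True)
class BundleGroundTruth:
    """Analytic truth for one generated bundle."""

    bundle_id: str
    phenotype: Phenotype
    sv: float  # μm⁻¹
    surface: float  # μm²
    volume: float  # μm³
    radius: float  # the varied radius (capsule r or bulb R), μm
    pore_diameter: float  # μm (major axis of the lamina pore)
    seed: int


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal noise with median 1 and coefficient of variation cv."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def sample_pore_diameters(
    n: int,
    seed: int | np.random.Generator,
    median: float = PORE_MEDIAN_DIAMETER,
    cv: float = PORE_DIAMETER_CV,
) -> np.ndarray:
    """Draw pore major-axis diameters (μm) from the shared lognormal model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    return median * np.exp(rng.normal(0.0, sigma, size=int(n)))


def build_bundle_scene(
    phenotype: Phenotype,
    radius: float,
    pore_diameter: float,
    pore_aspect: float = 1.0,
    capsule_length: float = CAPSULE_LENGTH,
    shaft_radius: float = SHAFT_RADIUS,
    shaft_length: float = SHAFT_LENGTH,
    seed: int = 0,
) -> SceneSpec:
    """One-bundle scene: epithelium | lamina (with pore) | nerve below.

    ``radius`` is the capsule radius (penetrating) or the bulb radius
    (fusing).  The nerve axis is the tissue vertical axis (image y), so the
    phantom is rotationally symmetric about the axis perpendicular to the
    lamina — the geometry the vertical-section cycloid design samples
    without bias.
    """
    a = pore_diameter / 2.0
    b = a * pore_aspect
    y_lam = EPITHELIUM_THICKNESS
    lam = LaminaSpec(y0=y_lam, thickness=LAMINA_THICKNESS, label=LABEL_LAMINA)

    # Local phantoms run along +y from the bottom cap; rotate by π about x so
    # the tip points up (toward small y / the epithelium) in image coords.
    flip = Rotation.from_euler("x", 180, degrees=True)
    if phenotype is Phenotype.PENETRATING:
        body = make_capsule(radius, capsule_length)
        tip_local = np.array([0.0, capsule_length + radius, 0.0])
        tip_y = y_lam + LAMINA_THICKNESS + TIP_GAP
        half_width = radius
        role = ROLE_PENETRATING
        depth = capsule_length + 2.0 * radius
    elif phenotype is Phenotype.FUSING_MIXED:
        body = make_tube_with_bulb(shaft_radius, shaft_length, radius)
        tip_local = np.array([0.0, shaft_length + radius, 0.0])
        tip_y = y_lam + LAMINA_THICKNESS - BULB_PROTRUSION
        half_width = max(radius, shaft_radius)
        role = ROLE_FUSING
        depth = shaft_length + shaft_radius + 2.0 * radius
    else:
        raise InvalidParameterError(f"unknown phenotype {phenotype!r}")

    width = 2.0 * max(half_width, a) + 2.0 * MARGIN
    x0 = width / 2.0
    z_extent = 2.0 * max(half_width, b) + 2.0 * MARGIN
    z0 = z_extent / 2.0
    height = tip_y + depth + MARGIN

    translation = np.array([x0, tip_y, z0]) - flip.apply(tip_local)
    placed = replace(body, pose=Pose(rotation=flip, translation=tuple(translation)))

    return SceneSpec(
        phantoms=(ScenePhantom(phantom=placed, label=LABEL_NERVE, role=role),),
        bounds=((0.0, 0.0, 0.0), (width, height, z_extent)),
        basal_lamina=lam,
        pores=(PoreSpec(center=(x0, z0), a=a, b=b, label=LABEL_PORE),),
        epithelium_label=LABEL_EPITHELIUM,
        seed=seed,
    )


def generate_cohort(
    n_pen: int = N_PENETRATING,
    n_fus: int = N_FUSING,
    sv_pen: float = SV_PENETRATING,
    sv_fus: float = SV_FUSING,
    cv: float = 0.1,
    seed: int = 0,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    lazy: bool = True,
    capsule_length: float = CAPSULE_LENGTH,
    shaft_radius: float = SHAFT_RADIUS,
    shaft_length: float = SHAFT_LENGTH,
    pore_median: float = PORE_MEDIAN_DIAMETER,
    pore_cv: float = PORE_DIAMETER_CV,
) -> list[tuple[LabelStack, BundleGroundTruth]]:
    """Generate calibrated penetrating and fusing bundles with ground truth.

    The calibrated radii hit ``sv_pen`` / ``sv_fus`` exactly at cv = 0; with
    cv > 0 each phantom's radius carries lognormal variation and the ground
    truth records its actual analytic values.  Stacks are lazily rendered by
    default (bit-identical to eager rendering).
    """
    if n_pen < 0 or n_fus < 0 or n_pen + n_fus == 0:
        raise InvalidParameterError("need at least one phantom in the cohort")
    if cv < 0:
        raise InvalidParameterError(f"cv must be >= 0, got {cv}")
    r_pen = calibrate_radius_for_sv(
        sv_pen, ShapeKind.CAPSULE, {"L": capsule_length}
    )
    r_fus = calibrate_radius_for_sv(
        sv_fus,
        ShapeKind.TUBE_WITH_BULB,
        {"r_shaft": shaft_radius, "L": shaft_length},
    )
    ss = np.random.SeedSequence(seed)
    out: list[tuple[LabelStack, BundleGroundTruth]] = []
    plan = [(Phenotype.PENETRATING, r_pen)] * n_pen + [
        (Phenotype.FUSING_MIXED, r_fus)
    ] * n_fus
    for idx, ((phenotype, r_cal), child) in enumerate(zip(plan, ss.spawn(len(plan)))):
        rng = np.random.default_rng(child)
        bundle_seed = int(child.generate_state(1)[0] % (2**31))
        radius = r_cal * _lognormal_factor(rng, cv)
        pore_d = float(sample_pore_diameters(1, rng, pore_median, pore_cv)[0])
        aspect = float(rng.uniform(PORE_MIN_ASPECT, 1.0))
        scene = build_bundle_scene(
            phenotype,
            radius,
            pore_d,
            pore_aspect=aspect,
            capsule_length=capsule_length,
            shaft_radius=shaft_radius,
            shaft_length=shaft_length,
            seed=bundle_seed,
        )
        stack = voxelize(scene, spacing, lazy=lazy)
        phantom = scene.phantoms[0].phantom
        prefix = "pen" if phenotype is Phenotype.PENETRATING else "fus"
        truth = BundleGroundTruth(
            bundle_id=f"{prefix}_{idx:03d}",
            phenotype=phenotype,
            sv=phantom.sv,
            surface=phantom.analytic_surface,
            volume=phantom.analytic_volume,
            radius=radius,
            pore_diameter=pore_d,
            seed=bundle_seed,
        )
        out.append((stack, truth))
    return out
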