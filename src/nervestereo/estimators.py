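"""Morphometric estimators on tallies and label stacks.

Turns cycloid-grid tallies and segmented stacks into the quantities of
interest: the surface-to-volume ratio Ŝ_V = 2·ΣI / ((l/p)·ΣP), label volumes
by voxel summation, the basal-lamina pore diameter (maximum Feret diameter,
maximized over sections), and the bundle phenotype (penetrating vs
fusing/mixed) from 3D connectivity through lamina pores.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.measure import find_contours

from .errors import (
    InvalidParameterError,
    NotFoundError,
    UndefinedEstimateError,
)
from .grid import CountTally, SectionPlane, build_grid, count, lamina_orientation
from .scene import ROLE_EPITHELIUM, ROLE_FUSING, ROLE_LAMINA, ROLE_PENETRATING, ROLE_PORE
from .stack import LabelStack

__all__ = [
    "Phenotype",
    "MorphometryResult",
    "estimate_sv",
    "select_section",
    "volume_from_labels",
    "pore_diameter",
    "classify_bundle",
    "make_section_plane",
    "estimate_bundle_sv",
]


class Phenotype(str, Enum):
    PENETRATING = "penetrating"
    FUSING_MIXED = "fusing_mixed"


@dataclass
class MorphometryResult:
    """One nerve bundle's morphometry: the row type of the output table."""

    bundle_id: str
    phenotype: Phenotype | None
    sv_hat: float  # μm⁻¹
    sections_used: tuple[int, ...]
    volume_by_label: dict[int, float] = field(default_factory=dict)  # μm³
    pore_diameter: float | None = None  # μm
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# the stereology estimator


def estimate_sv(tallies: Iterable[CountTally], lp: float) -> float:
    """Surface-to-volume ratio from tallies: Ŝ_V = 2·ΣI / ((l/p)·ΣP).

    Aggregation across casts is ratio-of-sums (sum the intersection and
    point counts first, then divide), the standard low-variance pooling for
    stereological ratio estimators.
    """
    if not lp > 0:
        raise InvalidParameterError(f"l/p must be > 0, got {lp}")
    tallies = list(tallies)
    sum_i = sum(t.I for t in tallies)
    sum_p = sum(t.P for t in tallies)
    if sum_p == 0:
        raise UndefinedEstimateError(
            "no test point fell inside the target: Ŝ_V is undefined (ΣP = 0)"
        )
    return 2.0 * sum_i / (lp * sum_p)


def select_section(
    stack: LabelStack, target_label: int, seed: int | np.random.Generator
) -> int:
    """Uniform random draw over the sections in which ``target_label`` appears."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = stack.sections_with_label(target_label)
    if not candidates:
        raise NotFoundError(f"label {target_label} absent from every section")
    return int(candidates[rng.integers(len(candidates))])


def volume_from_labels(stack: LabelStack, label: int) -> float:
    """Volume of ``label`` as voxel count × voxel volume (μm³)."""
    return stack.count_label(label) * stack.voxel_volume


# ---------------------------------------------------------------------------
# pore diameter


def _section_feret(mask: np.ndarray, spacing: tuple[float, float]) -> float:
    """Max Feret diameter (μm) of a 2D region from its sub-pixel contour.

    The iso-0.5 contour of the padded mask tracks the region boundary to
    within half a pixel; the maximum caliper width is the largest pairwise
    distance between convex-hull vertices of the contour points.
    """
    dx, dy = spacing
    padded = np.pad(mask.astype(float), 1)
    pts: list[np.ndarray] = []
    for contour in find_contours(padded, 0.5):
        pts.append(
            np.column_stack(
                [(contour[:, 1] - 0.5) * dx, (contour[:, 0] - 0.5) * dy]
            )
        )
    if not pts:  # single-pixel region: fall back to the pixel footprint
        return float(math.hypot(dx, dy))
    allpts = np.concatenate(pts)
    if len(allpts) > 3:
        try:
            allpts = allpts[ConvexHull(allpts).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    diff = allpts[:, None, :] - allpts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def pore_diameter(stack: LabelStack, pore_label: int) -> float:
    """Maximum dimension of the pore across the stack (μm).

    Per section, the maximum point-to-point distance (max Feret diameter) of
    the pore region in physical in-plane units; the result is the maximum
    over all sections in which the pore appears.
    """
    dx, dy = stack.spacing[0], stack.spacing[1]
    best = 0.0
    seen = False
    for k in stack.sections_with_label(pore_label):
        mask = np.asarray(stack.sections[k]) == pore_label
        if not mask.any():
            continue
        seen = True
        best = max(best, _section_feret(mask, (dx, dy)))
    if not seen:
        raise NotFoundError(f"pore label {pore_label} absent from stack")
    return best


# ---------------------------------------------------------------------------
# phenotype classification


def classify_bundle(stack: LabelStack) -> Phenotype:
    """Phenotype of the bundle in ``stack``.

    ``fusing_mixed`` if any fusing-axon voxel is 26-connected to an
    epithelium voxel through pore regions (continuity of membranes across a
    lamina discontinuity); otherwise ``penetrating``.  The legend must
    distinguish fusing-axon from penetrating-axon labels.
    """
    fusing = stack.labels_by_role(ROLE_FUSING)
    penetrating = stack.labels_by_role(ROLE_PENETRATING)
    if not fusing and not penetrating:
        raise NotFoundError("stack legend contains no nerve labels")
    if not fusing:
        return Phenotype.PENETRATING
    epi = stack.labels_by_role(ROLE_EPITHELIUM)
    pores = stack.labels_by_role(ROLE_PORE)
    if not epi:
        return Phenotype.PENETRATING
    vol = stack.asarray()
    passable = np.isin(vol, fusing + pores + epi)
    labeled, n = ndimage.label(passable, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return Phenotype.PENETRATING
    fusing_comps = np.unique(labeled[np.isin(vol, fusing)])
    epi_comps = np.unique(labeled[np.isin(vol, epi)])
    if np.intersect1d(fusing_comps, epi_comps).size:
        return Phenotype.FUSING_MIXED
    return Phenotype.PENETRATING


# ---------------------------------------------------------------------------
# stack -> section plane, and the per-bundle estimation pipeline


def make_section_plane(stack: LabelStack, k: int) -> SectionPlane:
    """Build a :class:`SectionPlane` for section ``k`` from the stack legend.

    The lamina trace is the per-column mean y of lamina pixels; a pore in the
    section opens a gap in the trace, and the trace points flanking the gap
    become the pore endpoints.
    """
    img = np.asarray(stack.sections[k])
    dx, dy = stack.spacing[0], stack.spacing[1]
    lam_labels = stack.labels_by_role(ROLE_LAMINA)
    pore_labels = stack.labels_by_role(ROLE_PORE)
    epi_labels = stack.labels_by_role(ROLE_EPITHELIUM)

    trace = None
    pore_endpoints = None
    if lam_labels:
        lam_mask = np.isin(img, lam_labels)
        counts = lam_mask.sum(axis=0)
        cols = np.nonzero(counts)[0]
        if cols.size >= 2:
            row_idx = np.arange(img.shape[0], dtype=float)
            rows_mean = (lam_mask * row_idx[:, None]).sum(axis=0)[cols] / counts[cols]
            trace = np.column_stack([(cols + 0.5) * dx, (rows_mean + 0.5) * dy])
            if pore_labels and np.isin(img, pore_labels).any():
                gaps = np.nonzero(np.diff(cols) > 1)[0]
                if gaps.size:
                    g = gaps[int(np.argmax(np.diff(cols)[gaps]))]  # widest gap
                    pore_endpoints = (trace[g].copy(), trace[g + 1].copy())

    centroid = None
    if epi_labels:
        epi_mask = np.isin(img, epi_labels)
        if epi_mask.any():
            rr, cc = np.nonzero(epi_mask)
            centroid = np.array([(cc.mean() + 0.5) * dx, (rr.mean() + 0.5) * dy])

    return SectionPlane(
        image=img,
        spacing=(dx, dy),
        lamina_trace=trace,
        pore_endpoints=pore_endpoints,
        epithelium_centroid=centroid,
    )


def estimate_bundle_sv(
    stack: LabelStack,
    target_label: int,
    lp: float,
    casts: int = 1,
    seed: int | np.random.Generator = 0,
    restricted: bool | str = "auto",
) -> tuple[float, list[tuple[int, CountTally]]]:
    """Estimate one bundle's Ŝ_V from ``casts`` independent grid casts.

    Each cast draws a fresh random section (uniform over the sections in
    which the bundle is visible) and a fresh uniform random grid phase; the
    grid's minor axis is set along the tissue's vertical axis (the normal of
    the per-section lamina trace).  Tallies are pooled by ratio of sums.
    ``restricted='auto'`` applies the restriction-line rule whenever the
    section shows a pore.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    candidates = stack.sections_with_label(target_label)
    if not candidates:
        raise NotFoundError(f"label {target_label} absent from every section")
    if int(casts) > 1:
        # Systematic-uniform-random section sampling (SURS): one random start,
        # then every (n/casts)-th visible section.  Marginally uniform, hence
        # unbiased, with far less profile-size variance than independent draws
        # — the standard serial-section sampling design.
        period = len(candidates) / int(casts)
        start = rng.uniform(0.0, period)
        section_draws = [
            int(candidates[min(int(start + j * period), len(candidates) - 1)])
            for j in range(int(casts))
        ]
    else:
        section_draws = [select_section(stack, target_label, rng)]
    tallies: list[tuple[int, CountTally]] = []
    for k in section_draws:
        sp = make_section_plane(stack, k)
        if sp.lamina_trace is not None:
            vertical = (lamina_orientation(sp) + math.pi / 2.0) % math.pi
        else:
            vertical = math.pi / 2.0  # image y: the stroma->epithelium axis
        r_c = lp / 8.0
        phase = (
            rng.uniform(0.0, 2.0 * math.pi * r_c),
            rng.uniform(0.0, 4.0 * r_c),
        )
        grid = build_grid(lp, vertical, phase, sp.extent)
        use_restriction = (
            restricted is True
            or (restricted == "auto" and sp.pore_endpoints is not None)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty edge sections tally 0/0
            tally = count(grid, target_label, sp, restricted=use_restriction)
        tallies.append((k, tally))
    sv = estimate_sv([t for _, t in tallies], lp)
    return sv, tallies
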