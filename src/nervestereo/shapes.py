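"""Parametric solids with closed-form surface area and volume.

These phantoms stand in for segmented nerve bundles: a slim capsule models
the small-diameter, high surface-to-volume "penetrating" phenotype, while a
capsule shaft terminating in a large sphere (``tube_with_bulb``) models the
swollen, low surface-to-volume "fusing" phenotype.  Every shape carries its
exact surface area and volume so that stereological estimates can be checked
against analytic ground truth.

All lengths are in micrometres (μm), areas in μm², volumes in μm³ and
surface-to-volume ratios in μm⁻¹.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .errors import InvalidParameterError, NoSolutionError

__all__ = [
    "ShapeKind",
    "Pose",
    "Phantom",
    "make_sphere",
    "make_capsule",
    "make_finite_cylinder",
    "make_tube_with_bulb",
    "calibrate_radius_for_sv",
]


class ShapeKind(str, enum.Enum):
    SPHERE = "sphere"
    CAPSULE = "capsule"
    FINITE_CYLINDER = "finite_cylinder"
    TUBE_WITH_BULB = "tube_with_bulb"


def _identity_rotation() -> Rotation:
    return Rotation.identity()


@dataclass(frozen=True)
class Pose:
    """Rigid transform (rotation followed by translation), lengths in μm."""

    rotation: Rotation = field(default_factory=_identity_rotation)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def _matrix(self) -> np.ndarray:
        m = self.__dict__.get("_matrix_cache")
        if m is None:
            m = self.rotation.as_matrix()
            self.__dict__["_matrix_cache"] = m
        return m

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Map world-frame points (N, 3) into the shape's local frame."""
        p = np.asarray(points, dtype=float) - np.asarray(self.translation)
        return p @ self._matrix  # (R⁻¹ = Rᵀ) row-wise

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return self.rotation.apply(np.asarray(points, dtype=float)) + np.asarray(
            self.translation
        )

    def to_dict(self) -> dict:
        return {
            "quat_xyzw": [float(v) for v in self.rotation.as_quat()],
            "translation": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pose":
        return cls(
            rotation=Rotation.from_quat(d.get("quat_xyzw", [0, 0, 0, 1])),
            translation=tuple(d.get("translation", (0.0, 0.0, 0.0))),
        )


@dataclass(frozen=True)
class Phantom:
    """A parametric solid with analytic surface area and volume.

    The canonical (local) frame places elongated shapes with their axis along
    +y: a capsule runs from its bottom cap centre at the origin to its top cap
    centre at (0, L, 0); a tube-with-bulb has its bulb centred on the top axis
    endpoint.  ``pose`` maps the local frame into the world/stack frame.
    """

    shape_kind: ShapeKind
    params: dict
    pose: Pose = field(default_factory=Pose)
    analytic_surface: float = 0.0  # μm²
    analytic_volume: float = 0.0  # μm³

    @property
    def sv(self) -> float:
        """Analytic surface-to-volume ratio, μm⁻¹."""
        return self.analytic_surface / self.analytic_volume

    # -- membership ------------------------------------------------------
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership of world-frame points (N, 3)."""
        local = self.pose.to_local(np.atleast_2d(points))
        return self._contains_local(local)

    def _contains_local(self, p: np.ndarray) -> np.ndarray:
        k = self.shape_kind
        if k is ShapeKind.SPHERE:
            r = self.params["r"]
            return np.einsum("ij,ij->i", p, p) <= r * r
        if k is ShapeKind.CAPSULE:
            return _dist2_to_axis_segment(p, self.params["L"]) <= self.params["r"] ** 2
        if k is ShapeKind.FINITE_CYLINDER:
            r, L = self.params["r"], self.params["L"]
            radial2 = p[:, 0] ** 2 + p[:, 2] ** 2
            return (radial2 <= r * r) & (p[:, 1] >= 0.0) & (p[:, 1] <= L)
        if k is ShapeKind.TUBE_WITH_BULB:
            r_s, L, R_b = (
                self.params["r_shaft"],
                self.params["L"],
                self.params["R_bulb"],
            )
            in_shaft = _dist2_to_axis_segment(p, L) <= r_s * r_s
            d2_bulb = p[:, 0] ** 2 + (p[:, 1] - L) ** 2 + p[:, 2] ** 2
            return in_shaft | (d2_bulb <= R_b * R_b)
        raise InvalidParameterError(f"unknown shape kind {k!r}")

    # -- bounds ----------------------------------------------------------
    def local_aabb(self) -> tuple[np.ndarray, np.ndarray]:
        k = self.shape_kind
        if k is ShapeKind.SPHERE:
            r = self.params["r"]
            return np.array([-r, -r, -r]), np.array([r, r, r])
        if k is ShapeKind.CAPSULE:
            r, L = self.params["r"], self.params["L"]
            return np.array([-r, -r, -r]), np.array([r, L + r, r])
        if k is ShapeKind.FINITE_CYLINDER:
            r, L = self.params["r"], self.params["L"]
            return np.array([-r, 0.0, -r]), np.array([r, L, r])
        if k is ShapeKind.TUBE_WITH_BULB:
            r_s, L, R_b = (
                self.params["r_shaft"],
                self.params["L"],
                self.params["R_bulb"],
            )
            m = max(r_s, R_b)
            return np.array([-m, -r_s, -m]), np.array([m, L + R_b, m])
        raise InvalidParameterError(f"unknown shape kind {k!r}")

    def aabb(self) -> tuple[np.ndarray, np.ndarray]:
        """World-frame axis-aligned bounding box (conservative)."""
        lo, hi = self.local_aabb()
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
        )
        world = self.pose.to_world(corners)
        return world.min(axis=0), world.max(axis=0)

    def min_radius(self) -> float:
        """Smallest radius-like length, used for undersampling warnings."""
        k = self.shape_kind
        if k is ShapeKind.TUBE_WITH_BULB:
            return self.params["r_shaft"]
        return self.params["r"]

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "shape_kind": self.shape_kind.value,
            "params": {k: float(v) for k, v in self.params.items()},
            "pose": self.pose.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Phantom":
        kind = ShapeKind(d["shape_kind"])
        params = d["params"]
        pose = Pose.from_dict(d.get("pose", {}))
        maker = {
            ShapeKind.SPHERE: lambda: make_sphere(params["r"], pose=pose),
            ShapeKind.CAPSULE: lambda: make_capsule(params["r"], params["L"], pose=pose),
            ShapeKind.FINITE_CYLINDER: lambda: make_finite_cylinder(
                params["r"], params["L"], pose=pose
            ),
            ShapeKind.TUBE_WITH_BULB: lambda: make_tube_with_bulb(
                params["r_shaft"], params["L"], params["R_bulb"], pose=pose
            ),
        }[kind]
        return maker()


def _dist2_to_axis_segment(p: np.ndarray, L: float) -> np.ndarray:
    """Squared distance of points to the segment (0,0,0)-(0,L,0)."""
    t = np.clip(p[:, 1], 0.0, L)
    return p[:, 0] ** 2 + (p[:, 1] - t) ** 2 + p[:, 2] ** 2


# ---------------------------------------------------------------------------
# constructors


def make_sphere(r: float, pose: Pose | None = None) -> Phantom:
    """Sphere of radius ``r`` μm; S = 4πr², V = (4/3)πr³, S/V = 3/r."""
    if not r > 0:
        raise InvalidParameterError(f"sphere radius must be > 0, got {r}")
    return Phantom(
        shape_kind=ShapeKind.SPHERE,
        params={"r": float(r)},
        pose=pose or Pose(),
        analytic_surface=4.0 * math.pi * r * r,
        analytic_volume=(4.0 / 3.0) * math.pi * r**3,
    )


def make_capsule(r: float, L: float, pose: Pose | None = None) -> Phantom:
    """Capsule: cylinder of length ``L`` with hemispherical caps of radius ``r``.

    S = 2πrL + 4πr²,  V = πr²L + (4/3)πr³.  L = 0 degenerates to a sphere.
    """
    if not r > 0:
        raise InvalidParameterError(f"capsule radius must be > 0, got {r}")
    if L < 0:
        raise InvalidParameterError(f"capsule length must be >= 0, got {L}")
    return Phantom(
        shape_kind=ShapeKind.CAPSULE,
        params={"r": float(r), "L": float(L)},
        pose=pose or Pose(),
        analytic_surface=2.0 * math.pi * r * L + 4.0 * math.pi * r * r,
        analytic_volume=math.pi * r * r * L + (4.0 / 3.0) * math.pi * r**3,
    )


def make_finite_cylinder(r: float, L: float, pose: Pose | None = None) -> Phantom:
    """Right circular cylinder with flat end caps."""
    if not r > 0 or not L > 0:
        raise InvalidParameterError(f"cylinder needs r > 0 and L > 0, got r={r}, L={L}")
    return Phantom(
        shape_kind=ShapeKind.FINITE_CYLINDER,
        params={"r": float(r), "L": float(L)},
        pose=pose or Pose(),
        analytic_surface=2.0 * math.pi * r * L + 2.0 * math.pi * r * r,
        analytic_volume=math.pi * r * r * L,
    )


def make_tube_with_bulb(
    r_shaft: float, L: float, R_bulb: float, pose: Pose | None = None
) -> Phantom:
    """Capsule shaft terminating in a sphere (the swollen-bundle phantom).

    The solid is the union of a capsule (radius ``r_shaft``, cylinder length
    ``L``, bottom cap at the local origin) and a sphere of radius ``R_bulb``
    centred on the top axis endpoint (0, L, 0).  Exact union formulas follow
    from sphere-cap subtraction at the junction: the shaft pierces the bulb up
    to axial distance t* = sqrt(R_bulb² − r_shaft²) from the bulb centre, so
    the spherical cap beyond t* (height h = R_bulb − t*) lies inside the
    shaft and the shaft's own top cap lies inside the bulb.

    Requires R_bulb ≥ r_shaft and L ≥ t* (the bulb must not swallow the
    bottom cap, otherwise the union formulas do not apply).
    """
    if not r_shaft > 0:
        raise InvalidParameterError(f"shaft radius must be > 0, got {r_shaft}")
    if L < 0:
        raise InvalidParameterError(f"shaft length must be >= 0, got {L}")
    if R_bulb < r_shaft:
        raise InvalidParameterError(
            f"bulb radius {R_bulb} must be >= shaft radius {r_shaft}"
        )
    t_star = math.sqrt(R_bulb * R_bulb - r_shaft * r_shaft)
    if L < t_star:
        raise InvalidParameterError(
            f"shaft length {L} too short for bulb radius {R_bulb}: "
            f"requires L >= sqrt(R_bulb² − r_shaft²) = {t_star:.6g}"
        )
    h = R_bulb - t_star  # height of the bulb cap hidden inside the shaft
    sphere_s = 4.0 * math.pi * R_bulb * R_bulb
    cap_s = 2.0 * math.pi * R_bulb * h
    cap_v = math.pi * h * h * (R_bulb - h / 3.0)
    surface = (
        sphere_s
        - cap_s
        + 2.0 * math.pi * r_shaft * (L - t_star)  # exposed lateral shaft
        + 2.0 * math.pi * r_shaft * r_shaft  # bottom hemisphere
    )
    volume = (
        (4.0 / 3.0) * math.pi * R_bulb**3
        + math.pi * r_shaft * r_shaft * (L - t_star)
        - cap_v
        + (2.0 / 3.0) * math.pi * r_shaft**3
    )
    return Phantom(
        shape_kind=ShapeKind.TUBE_WITH_BULB,
        params={"r_shaft": float(r_shaft), "L": float(L), "R_bulb": float(R_bulb)},
        pose=pose or Pose(),
        analytic_surface=surface,
        analytic_volume=volume,
    )


# ---------------------------------------------------------------------------
# calibration


def calibrate_radius_for_sv(
    target_sv: float,
    shape_kind: ShapeKind | str,
    fixed_params: dict | None = None,
    rtol: float = 1e-10,
) -> float:
    """Find the free radius giving an analytic S/V equal to ``target_sv``.

    The free parameter is the sphere/capsule radius ``r`` or, for
    ``tube_with_bulb``, the bulb radius ``R_bulb`` (with ``r_shaft`` and ``L``
    fixed).  In every family S/V is strictly decreasing in the free radius,
    so the closed form is inverted by root bracketing.  Raises
    :class:`NoSolutionError` if the target lies outside the family's range.
    """
    if not target_sv > 0:
        raise InvalidParameterError(f"target S/V must be > 0, got {target_sv}")
    kind = ShapeKind(shape_kind)
    fixed = dict(fixed_params or {})

    if kind is ShapeKind.SPHERE:
        return 3.0 / target_sv

    if kind in (ShapeKind.CAPSULE, ShapeKind.FINITE_CYLINDER):
        L = float(fixed["L"])
        maker = make_capsule if kind is ShapeKind.CAPSULE else make_finite_cylinder

        def f(r: float) -> float:
            return maker(r, L).sv - target_sv

        lo, hi = 1e-9, 1.0
        while f(hi) > 0:
            hi *= 2.0
            if hi > 1e9:  # pragma: no cover - S/V -> 0 as r -> inf
                raise NoSolutionError(f"S/V {target_sv} unreachable for {kind.value}")
        root = brentq(f, lo, hi, xtol=1e-15, rtol=rtol)
        return float(root)

    if kind is ShapeKind.TUBE_WITH_BULB:
        r_s, L = float(fixed["r_shaft"]), float(fixed["L"])
        # Reachable bulb radii: [r_shaft, sqrt(L² + r_shaft²)] (geometry limit).
        r_max = math.sqrt(L * L + r_s * r_s) * (1.0 - 1e-12)

        def g(R: float) -> float:
            return make_tube_with_bulb(r_s, L, R).sv - target_sv

        sv_hi = make_tube_with_bulb(r_s, L, r_s).sv  # degenerate capsule limit
        sv_lo = make_tube_with_bulb(r_s, L, r_max).sv
        if not (sv_lo <= target_sv <= sv_hi):
            raise NoSolutionError(
                f"S/V {target_sv} unreachable for tube_with_bulb with "
                f"r_shaft={r_s}, L={L} (range [{sv_lo:.4g}, {sv_hi:.4g}])"
            )
        root = brentq(g, r_s, r_max, xtol=1e-15, rtol=rtol)
        return float(root)

    raise InvalidParameterError(f"unknown shape kind {kind!r}")
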