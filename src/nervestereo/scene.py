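"""Scene specifications: phantoms plus basal lamina, pores and epithelium.

A scene lives in a world box measured in μm.  The image/stack coordinate
convention is: x right, y down within each section image, z = section index.
The tissue's vertical axis is y: the epithelium occupies the slab above the
basal lamina (small y), the stroma lies below it (large y).  The lamina is a
slab of finite thickness normal to y, spanning the whole box in x and z,
perforated by elliptical pores (holes described in the x-z plane).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidParameterError
from .shapes import Phantom

SCHEMA_VERSION = 1

# Canonical legend roles.
ROLE_PENETRATING = "penetrating_axon"
ROLE_FUSING = "fusing_axon"
ROLE_LAMINA = "basal_lamina"
ROLE_PORE = "pore"
ROLE_EPITHELIUM = "epithelium"
ROLE_BACKGROUND = "background"

__all__ = [
    "SCHEMA_VERSION",
    "LaminaSpec",
    "PoreSpec",
    "ScenePhantom",
    "SceneSpec",
    "ROLE_PENETRATING",
    "ROLE_FUSING",
    "ROLE_LAMINA",
    "ROLE_PORE",
    "ROLE_EPITHELIUM",
    "ROLE_BACKGROUND",
]


@dataclass(frozen=True)
class LaminaSpec:
    """Basal-lamina slab: y ∈ [y0, y0 + thickness], all x, all z (μm)."""

    y0: float
    thickness: float
    label: int

    def __post_init__(self):
        if self.thickness <= 0:
            raise InvalidParameterError("lamina thickness must be > 0")


@dataclass(frozen=True)
class PoreSpec:
    """Elliptical hole through the lamina slab.

    ``center`` is (x, z) in μm; ``a`` and ``b`` are the semi-axes along x and
    z with a ≥ b.  The pore solid is the elliptical cylinder restricted to
    the lamina slab; its voxels carry ``label`` (they are not lamina).
    """

    center: tuple[float, float]
    a: float
    b: float
    label: int

    def __post_init__(self):
        if not (self.a >= self.b > 0):
            raise InvalidParameterError(f"pore semi-axes need a >= b > 0, got a={self.a}, b={self.b}")

    @property
    def max_dimension(self) -> float:
        """Ground-truth pore diameter (major axis), μm."""
        return 2.0 * self.a


@dataclass(frozen=True)
class ScenePhantom:
    phantom: Phantom
    label: int
    role: str = "phantom"


@dataclass(frozen=True)
class SceneSpec:
    """A voxelizable scene with unique positive labels per structure.

    Voxel labelling priority is pore > lamina > phantoms (list order) >
    epithelium > background(0).
    """

    phantoms: tuple[ScenePhantom, ...]
    bounds: tuple[tuple[float, float, float], tuple[float, float, float]]
    basal_lamina: LaminaSpec | None = None
    pores: tuple[PoreSpec, ...] = ()
    epithelium_label: int | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "phantoms", tuple(self.phantoms))
        object.__setattr__(self, "pores", tuple(self.pores))
        lo, hi = np.asarray(self.bounds[0], float), np.asarray(self.bounds[1], float)
        if not np.all(hi > lo):
            raise InvalidParameterError("scene bounds box must be nonempty")
        labels = [sp.label for sp in self.phantoms]
        labels += [p.label for p in self.pores]
        if self.basal_lamina is not None:
            labels.append(self.basal_lamina.label)
        if self.epithelium_label is not None:
            labels.append(self.epithelium_label)
        if any(l <= 0 for l in labels):
            raise InvalidParameterError("labels must be > 0 (0 is background)")
        if len(set(labels)) != len(labels):
            raise InvalidParameterError(f"labels must be unique, got {labels}")
        if self.pores and self.basal_lamina is None:
            raise InvalidParameterError("pores require a basal lamina")
        for sp in self.phantoms:
            alo, ahi = sp.phantom.aabb()
            if np.any(ahi < lo) or np.any(alo > hi):
                warnings.warn(
                    f"phantom label {sp.label} lies entirely outside the scene bounds",
                    stacklevel=2,
                )

    @property
    def legend(self) -> dict[int, str]:
        leg = {sp.label: sp.role for sp in self.phantoms}
        if self.basal_lamina is not None:
            leg[self.basal_lamina.label] = ROLE_LAMINA
        for p in self.pores:
            leg[p.label] = ROLE_PORE
        if self.epithelium_label is not None:
            leg[self.epithelium_label] = ROLE_EPITHELIUM
        return leg

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "schema_version": SCHEMA_VERSION,
            "bounds": [list(map(float, b)) for b in self.bounds],
            "seed": int(self.seed),
            "phantoms": [
                {"label": sp.label, "role": sp.role, **sp.phantom.to_dict()}
                for sp in self.phantoms
            ],
            "pores": [
                {
                    "center": list(map(float, p.center)),
                    "a": float(p.a),
                    "b": float(p.b),
                    "label": p.label,
                }
                for p in self.pores
            ],
        }
        if self.basal_lamina is not None:
            d["basal_lamina"] = {
                "y0": float(self.basal_lamina.y0),
                "thickness": float(self.basal_lamina.thickness),
                "label": self.basal_lamina.label,
            }
        if self.epithelium_label is not None:
            d["epithelium_label"] = int(self.epithelium_label)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise InvalidParameterError(f"unsupported scene schema version {version}")
        lam = d.get("basal_lamina")
        return cls(
            phantoms=tuple(
                ScenePhantom(
                    phantom=Phantom.from_dict(pd),
                    label=int(pd["label"]),
                    role=pd.get("role", "phantom"),
                )
                for pd in d.get("phantoms", [])
            ),
            bounds=(tuple(d["bounds"][0]), tuple(d["bounds"][1])),
            basal_lamina=LaminaSpec(lam["y0"], lam["thickness"], lam["label"]) if lam else None,
            pores=tuple(
                PoreSpec(tuple(pd["center"]), pd["a"], pd["b"], pd["label"])
                for pd in d.get("pores", [])
            ),
            epithelium_label=d.get("epithelium_label"),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SceneSpec":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
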