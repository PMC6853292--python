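"""LabelStack: serial 2D integer-label images with anisotropic voxel spacing.

The universal container for segmented serial-section EM data.  Section images
are indexed by section number (z); ``spacing`` is (dx, dy, dz) in μm with the
defaults matching serial block-face acquisition (10 nm in-plane pixels,
100 nm z-steps).  Sections may be a plain list of arrays or a lazily rendered
sequence (see :mod:`nervestereo.voxelize`); both behave identically.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_SPACING = (0.01, 0.01, 0.1)  # μm; within the stated SBF-SEM ranges

__all__ = ["LabelStack", "LazySections", "DEFAULT_SPACING"]


class LazySections(Sequence):
    """Sections rendered on demand by a deterministic per-index function."""

    def __init__(self, render: Callable[[int], np.ndarray], n: int):
        self._render = render
        self._n = int(n)
        self._cache: dict[int, np.ndarray] = {}

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, k):
        if isinstance(k, slice):
            return [self[i] for i in range(*k.indices(self._n))]
        if k < 0:
            k += self._n
        if not 0 <= k < self._n:
            raise IndexError(k)
        if k not in self._cache:
            self._cache[k] = self._render(k)
        return self._cache[k]


@dataclass
class LabelStack:
    """Ordered 2D label images + spacing + label legend.

    ``label_zranges`` optionally maps a label to the (start, stop) section
    range that can contain it; it is metadata carried by the generator so a
    lazy stack need not be scanned to find where a structure lives.
    """

    sections: Sequence
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    legend: dict[int, str] = field(default_factory=dict)
    label_zranges: dict[int, tuple[int, int]] | None = None
    seed: int | None = None

    def __post_init__(self):
        if len(self.sections) == 0:
            raise ValueError("a LabelStack needs at least one section")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def section_shape(self) -> tuple[int, int]:
        return tuple(self.sections[0].shape)

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def section(self, k: int) -> np.ndarray:
        return self.sections[k]

    def asarray(self) -> np.ndarray:
        """Materialize the full (nz, ny, nx) label volume."""
        return np.stack([np.asarray(s) for s in self.sections], axis=0)

    def materialize(self) -> "LabelStack":
        if isinstance(self.sections, list):
            return self
        return replace(self, sections=list(np.asarray(s) for s in self.sections))

    def labels_by_role(self, role: str) -> list[int]:
        return sorted(l for l, r in self.legend.items() if r == role)

    def sections_with_label(self, label: int) -> list[int]:
        """Section indices that contain ``label``.

        Uses the generator's z-range metadata when available (so lazy stacks
        are not fully rendered); otherwise scans every section.
        """
        if self.label_zranges is not None and label in self.label_zranges:
            lo, hi = self.label_zranges[label]
            return list(range(max(lo, 0), min(hi, self.n_sections)))
        found = []
        for k in range(self.n_sections):
            if bool(np.any(np.asarray(self.sections[k]) == label)):
                found.append(k)
        return found

    def count_label(self, label: int) -> int:
        ks = (
            self.sections_with_label(label)
            if self.label_zranges is not None
            else range(self.n_sections)
        )
        total = 0
        for k in ks:
            total += int(np.count_nonzero(np.asarray(self.sections[k]) == label))
        if total == 0:
            warnings.warn(f"label {label} absent from stack", stacklevel=2)
        return total
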