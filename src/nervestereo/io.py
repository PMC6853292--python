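"""Reading and writing label stacks (multi-page TIFF + JSON sidecar)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .stack import LabelStack

SIDECAR_KEYS = ("schema_version", "spacing", "legend")
SCHEMA_VERSION = 1

__all__ = ["read_stack", "write_stack", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(stack: LabelStack, path: str | Path, extra: dict | None = None) -> Path:
    """Write a stack as multi-page uint16 TIFF plus a JSON sidecar.

    The sidecar carries the physical metadata the pixels cannot: spacing
    (μm), the label legend, the generator seed and optional extra fields
    (e.g. a config hash).  Label semantics are never inferred from pixels.
    """
    path = Path(path)
    vol = stack.asarray().astype(np.uint16)
    tifffile.imwrite(path, vol, photometric="minisblack", compression="zlib")
    meta: dict = {
        "schema_version": SCHEMA_VERSION,
        "spacing": [float(s) for s in stack.spacing],
        "legend": {str(k): v for k, v in stack.legend.items()},
    }
    if stack.seed is not None:
        meta["seed"] = int(stack.seed)
    if stack.label_zranges is not None:
        meta["label_zranges"] = {str(k): list(v) for k, v in stack.label_zranges.items()}
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_stack(path: str | Path) -> LabelStack:
    """Read a multi-page TIFF + sidecar written by :func:`write_stack`."""
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar {side}: required keys are {', '.join(SIDECAR_KEYS)}"
        )
    meta = json.loads(side.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar {side} missing required keys: {missing}")
    vol = tifffile.imread(path)
    if vol.size == 0:
        raise ValueError(f"{path} contains no image data")
    if not np.issubdtype(vol.dtype, np.integer):
        raise ValueError(f"{path} has non-integer pixel type {vol.dtype}")
    if vol.ndim == 2:
        vol = vol[None, ...]
    zr = meta.get("label_zranges")
    return LabelStack(
        sections=[vol[k] for k in range(vol.shape[0])],
        spacing=tuple(meta["spacing"]),
        legend={int(k): v for k, v in meta["legend"].items()},
        label_zranges={int(k): tuple(v) for k, v in zr.items()} if zr else None,
        seed=meta.get("seed"),
    )
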