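"""End-to-end run: simulate → count → estimate → compare, reproducibly.

A :class:`RunConfig` fully determines a run (together with the code
version); every output file can be traced back to the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CAPSULE_LENGTH,
    N_FUSING,
    N_PENETRATING,
    SHAFT_LENGTH,
    SHAFT_RADIUS,
    SV_FUSING,
    SV_PENETRATING,
    generate_cohort,
)
from .estimators import (
    MorphometryResult,
    Phenotype,
    classify_bundle,
    estimate_bundle_sv,
    pore_diameter,
    volume_from_labels,
)
from .io import write_stack
from .stack import DEFAULT_SPACING
from .stats import compare_pores, compare_sv, fusion_frequency

logger = logging.getLogger("nervestereo")

CONFIG_SCHEMA_VERSION = 1

__all__ = ["RunConfig", "RunResult", "run_pipeline", "estimate_cohort", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a full simulate→compare run."""

    # cohort
    n_pen: int = N_PENETRATING
    n_fus: int = N_FUSING
    sv_pen: float = SV_PENETRATING
    sv_fus: float = SV_FUSING
    cv: float = 0.1
    capsule_length: float = CAPSULE_LENGTH
    shaft_radius: float = SHAFT_RADIUS
    shaft_length: float = SHAFT_LENGTH
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    # grid / estimator
    lp: float = 0.7  # μm of test line per point
    casts: int = 5
    restricted: bool | str = "auto"
    # extra measurements
    classify: bool = True
    measure_volumes: bool = True
    measure_pores: bool = True
    # stats
    alpha: float = 0.05
    welch: bool = False
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"
    write_stacks: bool = True
    overlays: bool = False
    schema_version: int = CONFIG_SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spacing"] = list(self.spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "spacing" in d:
            d["spacing"] = tuple(d["spacing"])
        version = d.get("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and other
        bookkeeping fields excluded, so runs to different directories match)."""
        d = self.to_dict()
        for key in ("out_dir", "write_stacks", "overlays"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    ground_truth: pd.DataFrame
    morphometry: pd.DataFrame
    comparisons: dict
    out_dir: Path


def estimate_cohort(
    cohort,
    lp: float,
    casts: int,
    seed: int,
    restricted: bool | str = "auto",
    classify: bool = False,
    measure_volumes: bool = False,
    measure_pores: bool = False,
    target_label: int = 1,
    pore_label: int = 4,
) -> list[MorphometryResult]:
    """Per-bundle morphometry for a generated cohort.

    Each bundle gets an independent estimation stream derived from ``seed``,
    so results do not depend on evaluation order.
    """
    ss = np.random.SeedSequence(seed)
    results: list[MorphometryResult] = []
    for (stack, truth), child in zip(cohort, ss.spawn(len(cohort))):
        rng = np.random.default_rng(child)
        sv, tallies = estimate_bundle_sv(
            stack, target_label, lp=lp, casts=casts, seed=rng, restricted=restricted
        )
        phenotype = classify_bundle(stack) if classify else truth.phenotype
        volumes = (
            {target_label: volume_from_labels(stack, target_label)}
            if measure_volumes
            else {}
        )
        pore_d = pore_diameter(stack, pore_label) if measure_pores else None
        results.append(
            MorphometryResult(
                bundle_id=truth.bundle_id,
                phenotype=phenotype,
                sv_hat=sv,
                sections_used=tuple(k for k, _ in tallies),
                volume_by_label=volumes,
                pore_diameter=pore_d,
                provenance={
                    "lp": lp,
                    "casts": casts,
                    "restricted": str(restricted),
                    "tallies": [(k, t.I, t.P) for k, t in tallies],
                },
            )
        )
    return results


def _morphometry_frame(results: list[MorphometryResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "bundle_id": r.bundle_id,
                "phenotype": r.phenotype.value if r.phenotype else None,
                "sv_hat_um^-1": r.sv_hat,
                "sections_used": ";".join(str(k) for k in r.sections_used),
                "nerve_volume_um^3": r.volume_by_label.get(1, np.nan),
                "pore_diameter_um": np.nan if r.pore_diameter is None else r.pore_diameter,
            }
        )
    return pd.DataFrame(rows)


def write_report(result: RunResult, path: Path) -> None:
    """Human-readable summary table of a run."""
    lines = [
        f"nervestereo {__version__}  config={result.config.config_hash}  seed={result.config.seed}",
        "",
    ]
    df = result.morphometry
    for pheno, sub in df.groupby("phenotype"):
        sv = sub["sv_hat_um^-1"]
        lines.append(
            f"{pheno:>12}: n={len(sub):3d}  S/V = {sv.mean():.3f} ± "
            f"{sv.std(ddof=1) / np.sqrt(len(sub)):.3f} μm⁻¹ (mean ± SEM)"
        )
    lines.append("")
    for name in ("sv", "pores"):
        comp = result.comparisons.get(name)
        if name not in result.comparisons:
            continue
        if comp is None:
            lines.append(f"{name}: skipped (one group empty or too small)")
            continue
        lines.append(
            f"{name}: {comp['statistic_name']} = {comp['statistic_value']:.4g}, "
            f"p = {comp['p_value']:.4g} "
            f"({'significant' if comp['significant'] else 'not significant'} at α={comp['alpha']})"
        )
    if "fusion_frequency_pct" in result.comparisons:
        lines.append(
            f"fusion frequency: {result.comparisons['fusion_frequency_pct']:.1f}% of bundles"
        )
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full workflow; writes outputs and a MANIFEST to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(log_handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": __version__,
        "completed_stages": [],
        "error": None,
    }
    config.to_yaml(out / "config.yaml")
    try:
        logger.info("stage simulate: %d penetrating + %d fusing phantoms", config.n_pen, config.n_fus)
        cohort = generate_cohort(
            n_pen=config.n_pen,
            n_fus=config.n_fus,
            sv_pen=config.sv_pen,
            sv_fus=config.sv_fus,
            cv=config.cv,
            seed=config.seed,
            spacing=config.spacing,
            capsule_length=config.capsule_length,
            shaft_radius=config.shaft_radius,
            shaft_length=config.shaft_length,
        )
        truth_df = pd.DataFrame(
            [
                {
                    "bundle_id": t.bundle_id,
                    "phenotype": t.phenotype.value,
                    "sv_um^-1": t.sv,
                    "surface_um^2": t.surface,
                    "volume_um^3": t.volume,
                    "radius_um": t.radius,
                    "pore_diameter_um": t.pore_diameter,
                    "seed": t.seed,
                }
                for _, t in cohort
            ]
        )
        truth_df.to_csv(out / "ground_truth.csv", index=False)
        if config.write_stacks:
            stack_dir = out / "stacks"
            stack_dir.mkdir(exist_ok=True)
            for stack, t in cohort:
                write_stack(
                    stack,
                    stack_dir / f"{t.bundle_id}.tif",
                    extra={"config_hash": config.config_hash},
                )
        manifest["completed_stages"].append("simulate")

        logger.info("stage estimate: lp=%.3g μm, casts=%d", config.lp, config.casts)
        results = estimate_cohort(
            cohort,
            lp=config.lp,
            casts=config.casts,
            seed=config.seed + 1,
            restricted=config.restricted,
            classify=config.classify,
            measure_volumes=config.measure_volumes,
            measure_pores=config.measure_pores,
        )
        morpho_df = _morphometry_frame(results)
        morpho_df.insert(0, "config_hash", config.config_hash)
        morpho_df.to_csv(out / "morphometry.csv", index=False, float_format="%.8g")
        if config.overlays:
            _write_overlays(cohort, config, out / "overlays")
        manifest["completed_stages"].append("estimate")

        logger.info("stage compare")
        comparisons: dict = {"config_hash": config.config_hash}
        pen_sv = morpho_df.loc[
            morpho_df.phenotype == Phenotype.PENETRATING.value, "sv_hat_um^-1"
        ].to_numpy()
        fus_sv = morpho_df.loc[
            morpho_df.phenotype == Phenotype.FUSING_MIXED.value, "sv_hat_um^-1"
        ].to_numpy()
        if len(pen_sv) >= 2 and len(fus_sv) >= 2:
            comparisons["sv"] = compare_sv(
                pen_sv, fus_sv, alpha=config.alpha, welch=config.welch
            ).to_dict()
        else:
            comparisons["sv"] = None
            logger.info(
                "comparison skipped: group sizes %d/%d are too small for a t-test",
                len(pen_sv),
                len(fus_sv),
            )
        if config.measure_pores:
            pen_d = morpho_df.loc[
                morpho_df.phenotype == Phenotype.PENETRATING.value, "pore_diameter_um"
            ].dropna().to_numpy()
            fus_d = morpho_df.loc[
                morpho_df.phenotype == Phenotype.FUSING_MIXED.value, "pore_diameter_um"
            ].dropna().to_numpy()
            if len(pen_d) >= 2 and len(fus_d) >= 2:
                comparisons["pores"] = compare_pores(pen_d, fus_d, alpha=config.alpha).to_dict()
            else:
                comparisons["pores"] = None
                logger.info("pore comparison skipped: group sizes %d/%d", len(pen_d), len(fus_d))
        comparisons["fusion_frequency_pct"] = fusion_frequency(
            [r.phenotype for r in results]
        )
        (out / "comparisons.json").write_text(json.dumps(comparisons, indent=2))
        manifest["completed_stages"].append("compare")

        result = RunResult(
            config=config,
            ground_truth=truth_df,
            morphometry=morpho_df,
            comparisons=comparisons,
            out_dir=out,
        )
        write_report(result, out / "report.txt")
        manifest["completed_stages"].append("report")
        return result
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        logger.exception("pipeline failed")
        raise
    finally:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        logger.removeHandler(log_handler)
        log_handler.close()


def _write_overlays(cohort, config: RunConfig, overlay_dir: Path) -> None:
    """One audit overlay (first cast) per bundle."""
    import math

    from .grid import build_grid, count, lamina_orientation
    from .estimators import make_section_plane, select_section
    from .overlay import save_overlay

    overlay_dir.mkdir(exist_ok=True)
    ss = np.random.SeedSequence(config.seed + 1)
    for (stack, truth), child in zip(cohort, ss.spawn(len(cohort))):
        rng = np.random.default_rng(child)
        k = select_section(stack, 1, rng)
        sp = make_section_plane(stack, k)
        vertical = (
            (lamina_orientation(sp) + math.pi / 2.0) % math.pi
            if sp.lamina_trace is not None
            else math.pi / 2.0
        )
        r_c = config.lp / 8.0
        phase = (rng.uniform(0, 2 * math.pi * r_c), rng.uniform(0, 4 * r_c))
        grid = build_grid(config.lp, vertical, phase, sp.extent)
        restricted = sp.pore_endpoints is not None and config.restricted in (True, "auto")
        tally = count(grid, 1, sp, restricted=restricted)
        save_overlay(sp, grid, 1, overlay_dir / f"{truth.bundle_id}.png", tally=tally)
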