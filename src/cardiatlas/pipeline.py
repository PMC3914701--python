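"""End-to-end phantom study orchestration.

``run_pipeline`` chains the stages of a desk-scale resolution study:

1. generate a pool of labeled phantom atlases (the synthetic stand-in for
   a manually labeled atlas set);
2. leave-one-out segmentation accuracy, 3D arm vs thick-slice 2D arm;
3. a test-retest cohort: per subject, two acquisitions of the same anatomy
   with pose jitter; wall-thickness maps at template-corresponded points
   for a high-resolution arm and a thick-slice arm;
4. per-point sample-size maps for both arms, the percentage reduction, and
   the voxelwise Wilcoxon significance map between arms.

Every stage is seeded from the single run seed; a manifest records
parameters, seeds, per-stage outputs and SHA-256 checksums so a rerun with
the same config is verifiably identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .core import write_landmarks, write_point_table, write_volume
from .metrics import leave_one_out_accuracy
from .phantom import (
    PhantomSpec,
    RetestJitter,
    ShapeVariation,
    generate_atlas_pool,
    generate_retest_pair,
)
from .power import (
    DifferenceField,
    percent_reduction,
    sample_size_map,
    wilcoxon_significance_map,
)
from .segmentation import FusionParams
from .surfaces import TemplateMapper

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameterisation of one pipeline run (YAML round-trippable)."""

    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(noise_sd=20.0))
    fusion: FusionParams = field(default_factory=FusionParams)
    variation: ShapeVariation = field(default_factory=ShapeVariation)
    jitter: RetestJitter = field(default_factory=RetestJitter)
    n_atlases: int = 10
    n_retest_subjects: int = 8
    spacing_3d: tuple[float, float, float] = (2.5, 2.5, 2.0)
    slice_thickness_mm: float = 8.0
    slice_gap_mm: float = 2.0
    delta_mm: float = 1.0
    alpha: float = 0.05
    power: float = 0.9
    seed: int = 0
    run_loo: bool = True
    run_retest: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        nested = {
            "phantom": PhantomSpec,
            "fusion": FusionParams,
            "variation": ShapeVariation,
            "jitter": RetestJitter,
        }
        for key, value in raw.items():
            if key in nested:
                if isinstance(value, dict):
                    for tup in ("endo_semiaxes", "rotation_rotvec", "translation", "thickness_harmonic"):
                        if tup in value and value[tup] is not None:
                            value[tup] = tuple(value[tup])
                    kwargs[key] = nested[key](**value)
                else:
                    raise ValueError(f"config section '{key}' must be a mapping")
            elif key == "spacing_3d":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)


def _plain(obj):
    """Recursively convert to YAML/JSON-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _plain(asdict(config)),
        "seed": config.seed,
        "stages": {},
    }
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(s) for name, s in zip(
        ("atlas_pool", "retest"), rng.integers(0, 2**31 - 1, 2)
    )}
    manifest["derived_seeds"] = seeds

    t0 = time.time()
    atlases = generate_atlas_pool(
        config.phantom,
        config.n_atlases,
        config.variation,
        rng_seed=seeds["atlas_pool"],
        spacing=config.spacing_3d,
    )
    atlas_dir = out / "atlases"
    atlas_dir.mkdir(exist_ok=True)
    files = []
    for a in atlases:
        d = atlas_dir / a.atlas_id
        d.mkdir(exist_ok=True)
        write_volume(a.intensity, d / "intensity.nii.gz")
        write_volume(a.labels, d / "labels.nii.gz")
        write_landmarks(a.landmarks, d / "landmarks.json")
        files += [d / "intensity.nii.gz", d / "labels.nii.gz", d / "landmarks.json"]
    manifest["stages"]["atlas_pool"] = {
        "n_atlases": len(atlases),
        "elapsed_s": round(time.time() - t0, 2),
        "checksums": {str(f.relative_to(out)): _sha256(f) for f in files},
    }

    if config.run_loo:
        t0 = time.time()
        loo = {}
        for arm, emulate in (("3d", False), ("2d", True)):
            reports = leave_one_out_accuracy(
                atlases,
                config.fusion,
                emulate_2d=emulate,
                slice_thickness_mm=config.slice_thickness_mm,
                gap_mm=config.slice_gap_mm,
            )
            loo[arm] = [
                {
                    "subject": r.subject_id,
                    "dice": {str(k): v for k, v in r.dice.items()},
                    "surface_mean_mm": r.surface_mean_mm,
                }
                for r in reports
            ]
        path = out / "leave_one_out.json"
        path.write_text(json.dumps(loo, indent=1))
        mean_myo = {
            arm: float(np.mean([r["dice"]["2"] for r in loo[arm]])) for arm in loo
        }
        manifest["stages"]["leave_one_out"] = {
            "mean_myocardium_dice": mean_myo,
            "elapsed_s": round(time.time() - t0, 2),
            "checksums": {path.name: _sha256(path)},
        }

    if config.run_retest:
        t0 = time.time()
        mapper = TemplateMapper().fit(atlases)
        arms: dict[str, list[list[np.ndarray]]] = {"3d": [], "2d": []}
        sub_rng = np.random.default_rng(seeds["retest"])
        from .core import resample_to_stack

        for i in range(config.n_retest_subjects):
            semi = np.asarray(config.phantom.endo_semiaxes) + sub_rng.normal(
                0, config.variation.semiaxes_sd, 3
            )
            thick = max(config.phantom.wall_thickness
                        + sub_rng.normal(0, config.variation.thickness_sd), 2.0)
            spec_i = replace(
                config.phantom,
                endo_semiaxes=tuple(np.maximum(semi, 5.0)),
                wall_thickness=float(thick),
            )
            pair_seed = int(sub_rng.integers(0, 2**31 - 1))
            acq1, acq2, _ = generate_retest_pair(
                spec_i, config.jitter, rng_seed=pair_seed, spacing=config.spacing_3d
            )
            maps_3d, maps_2d = [], []
            for k, (gray, labels, lms, gt) in enumerate((acq1, acq2)):
                tm3 = mapper.transform(labels, subject_id=f"s{i}", acquisition_id=f"a{k}")
                labels_2d = resample_to_stack(
                    labels, config.slice_thickness_mm, config.slice_gap_mm
                )
                tm2 = mapper.transform(labels_2d, subject_id=f"s{i}", acquisition_id=f"a{k}")
                maps_3d.append(tm3.values)
                maps_2d.append(tm2.values)
            arms["3d"].append(maps_3d)
            arms["2d"].append(maps_2d)

        results = {}
        maps = {}
        for arm in ("2d", "3d"):
            x = np.stack([m[0] for m in arms[arm]])
            y = np.stack([m[1] for m in arms[arm]])
            diff = DifferenceField.from_acquisitions(x, y, modality=arm.upper())
            ssm = sample_size_map(
                diff, config.delta_mm, config.alpha, config.power
            )
            maps[arm] = ssm
            write_point_table(ssm.n_required, out / f"sample_size_{arm}.csv")
            results[arm] = ssm.summary()
        reduction = percent_reduction(maps["2d"], maps["3d"])
        write_point_table(reduction, out / "percent_reduction.csv")
        wilcoxon_thr = None
        if config.n_retest_subjects >= 5:
            sig = wilcoxon_significance_map(
                np.stack([np.mean(m, axis=0) for m in arms["2d"]]),
                np.stack([np.mean(m, axis=0) for m in arms["3d"]]),
                alpha=config.alpha,
            )
            write_point_table(sig.minus_ln_p, out / "wilcoxon_minus_ln_p.csv")
            wilcoxon_thr = sig.threshold_minus_ln_p
        else:
            logger.info("fewer than 5 retest subjects: skipping the Wilcoxon map")
        manifest["stages"]["retest_power"] = {
            "n_subjects": config.n_retest_subjects,
            "template_points": mapper.n_points_,
            "sample_size_summary": results,
            "median_percent_reduction": float(np.nanmedian(reduction)),
            "wilcoxon_threshold": wilcoxon_thr,
            "elapsed_s": round(time.time() - t0, 2),
            "checksums": {
                f.name: _sha256(out / f.name)
                for f in out.glob("*.csv")
            },
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(_plain(manifest), indent=1))
    return manifest
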