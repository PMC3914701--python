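"""Segmentation accuracy and image-contrast metrics.

Dice overlap, point-to-surface distances and the blood/myocardium contrast
ratio used to compare segmentations against references and thick-slice 2D
imaging against high-resolution 3D imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import VALID_LABELS, SurfaceMesh, VolumeImage


@dataclass
class OverlapReport:
    """Per-structure overlap and surface-distance summary for one subject."""

    dice: dict[int, float]
    surface_mean_mm: dict[str, float] = field(default_factory=dict)
    surface_sd_mm: dict[str, float] = field(default_factory=dict)
    n_points: dict[str, int] = field(default_factory=dict)
    subject_id: str = ""


def dice_coefficient(
    labels_a: VolumeImage, labels_b: VolumeImage, label_code: int
) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)`` for one label code.

    0 means no overlap, 1 perfect agreement.  Defined as 1.0 when the label
    is absent from both volumes (vacuous agreement) and 0.0 when absent from
    exactly one.
    """
    if not labels_a.same_grid(labels_b):
        raise ValueError("label volumes must share the same grid")
    a = labels_a.data == label_code
    b = labels_b.data == label_code
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def dice_report(labels_a: VolumeImage, labels_b: VolumeImage) -> dict[int, float]:
    """Dice for every non-background label code."""
    return {
        code: dice_coefficient(labels_a, labels_b, code)
        for code in VALID_LABELS
        if code != 0
    }


def surface_distance(
    points: SurfaceMesh,
    reference: SurfaceMesh,
    corresponded: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Point-to-reference distances in mm: ``(mean, sd, per_point)``.

    In corresponded mode meshes must share the point count and distance k is
    ``||p_k - q_k||``.  In uncorresponded mode each point is matched to its
    nearest reference vertex.
    """
    p = points.points
    q = reference.points
    if corresponded:
        if len(p) != len(q):
            raise ValueError(
                f"corresponded mode needs equal point counts ({len(p)} vs {len(q)})"
            )
        d = np.linalg.norm(p - q, axis=1)
    else:
        d, _ = cKDTree(q).query(p)
    return float(d.mean()), float(d.std(ddof=0)), d


def contrast_ratio(
    region1_intensities: np.ndarray, region2_intensities: np.ndarray
) -> float:
    """Contrast ratio ``(SI1 - SI2) / sqrt(SD1^2 + SD2^2)``.

    SI and SD are the mean and standard deviation of two relatively
    homogeneous regions (conventionally blood pool and myocardium; take the
    absolute value for that use).  The sign follows ``SI1 - SI2``.
    """
    r1 = np.asarray(region1_intensities, dtype=float).ravel()
    r2 = np.asarray(region2_intensities, dtype=float).ravel()
    if r1.size == 0 or r2.size == 0:
        raise ValueError("both regions must be non-empty")
    pooled = np.sqrt(r1.std(ddof=1) ** 2 + r2.std(ddof=1) ** 2) if (r1.size > 1 or r2.size > 1) else 0.0
    if pooled == 0:
        raise ValueError("contrast ratio undefined: zero pooled standard deviation")
    return float((r1.mean() - r2.mean()) / pooled)


def leave_one_out_accuracy(
    atlases,
    params=None,
    emulate_2d: bool = False,
    slice_thickness_mm: float = 8.0,
    gap_mm: float = 2.0,
    surface_step_size: int = 2,
) -> list[OverlapReport]:
    """Leave-one-out segmentation accuracy over an atlas pool.

    Each atlas in turn is segmented using all the others and scored against
    its own labels: per-structure Dice plus mean/SD nearest-point surface
    distance for the endo- and epicardium.  With ``emulate_2d`` the target
    intensity volume and its reference labels are first down-sampled to a
    thick-slice stack (``slice_thickness_mm`` + ``gap_mm``), so the 2D arm
    is compared against a reference at its own resolution.
    """
    from .core import resample_to_stack
    from .segmentation import FusionParams, fuse_labels
    from .surfaces import extract_surfaces

    if len(atlases) < 2:
        raise ValueError("leave-one-out needs at least 2 atlases")
    reports = []
    for i, held_out in enumerate(atlases):
        pool = [a for j, a in enumerate(atlases) if j != i]
        target_gray = held_out.intensity
        reference = held_out.labels
        if emulate_2d:
            target_gray = resample_to_stack(target_gray, slice_thickness_mm, gap_mm)
            reference = resample_to_stack(reference, slice_thickness_mm, gap_mm)
        fused = fuse_labels(target_gray, pool, params, held_out.landmarks)
        ref_vol = VolumeImage(reference.data, reference.spacing, reference.origin)
        report = OverlapReport(
            dice=dice_report(fused, ref_vol), subject_id=held_out.atlas_id or str(i)
        )
        try:
            f_endo, f_epi = extract_surfaces(fused, step_size=surface_step_size)
            r_endo, r_epi = extract_surfaces(ref_vol, step_size=surface_step_size)
            for tag, fm, rm in (("endocardium", f_endo, r_endo), ("epicardium", f_epi, r_epi)):
                mean, sd, d = surface_distance(fm, rm, corresponded=False)
                report.surface_mean_mm[tag] = mean
                report.surface_sd_mm[tag] = sd
                report.n_points[tag] = len(d)
        except ValueError:
            # fused segmentation missing a structure: distances undefined
            pass
        reports.append(report)
    return reports
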