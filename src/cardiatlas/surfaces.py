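"""Corresponded surface extraction and wall-thickness measurement.

Endocardial and epicardial surfaces are extracted from a label map with
marching cubes (on a lightly smoothed binary mask, which recovers sub-voxel
surface position).  A :class:`TemplateModel` — the mean shape of an atlas
pool with a fixed point count P — is registered to each subject's surfaces
by similarity alignment plus iterative-closest-point projection, so that
point k means the same anatomical location on every subject.  Wall
thickness at point k is then measured along the normal of the midwall
surface (the pointwise endo/epi midpoint surface): the distance between
where that normal line crosses the endocardium and where it crosses the
epicardium.  Points whose normal line misses a surface fall back to the
direct endo-epi point distance (counted and logged).

:class:`TemplateMapper` wraps the procedure as an estimator: ``fit`` builds
the template from an atlas pool, ``transform`` maps a subject's label map
to a fixed-length :class:`~cardiatlas.core.ThicknessMap`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes
from sklearn.base import BaseEstimator

from ._geometry import closest_point_on_mesh, line_mesh_nearest_t
from .core import Atlas, SurfaceMesh, ThicknessMap, VolumeImage
from .segmentation import initialize_alignment
from .transforms import SimilarityTransform, estimate_similarity

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Template-to-subject registration failed to converge."""


def extract_surfaces(
    labels: VolumeImage,
    step_size: int = 1,
    smooth_sigma_mm: float = 1.5,
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Marching-cubes endocardial and epicardial surfaces in mm.

    The endocardium is the boundary of the LV cavity (label 1); the
    epicardium is the outer boundary of cavity + myocardium (labels 1|2).
    Binary masks are smoothed with a physical-space Gaussian of
    ``smooth_sigma_mm`` before contouring at 0.5, which removes
    voxelisation staircase while moving the 0.5 level set negligibly for
    structures much larger than a voxel (the per-axis sigma in voxels is
    ``smooth_sigma_mm / spacing``, so thick-slice stacks are barely
    smoothed through-plane, as they should be).  ``step_size`` coarsens the marching-cubes grid (larger = fewer
    points).

    Raises
    ------
    ValueError
        If cavity or myocardium is absent.  A myocardium that does not
        close around the cavity yields a topology warning but proceeds.
    """
    data = labels.data
    cavity = data == 1
    myo = data == 2
    if not cavity.any() or not myo.any():
        raise ValueError("label map must contain both LV cavity and myocardium")

    shell = cavity | myo
    filled = ndimage.binary_fill_holes(shell)
    if (filled & ~shell).any():
        logger.warning("myocardium has internal holes; proceeding")

    meshes = []
    for mask, tag in ((cavity, "endocardium"), (shell, "epicardium")):
        sigma_vox = [smooth_sigma_mm / sp for sp in labels.spacing]
        field = ndimage.gaussian_filter(mask.astype(np.float32), sigma_vox)
        verts, faces, _, _ = marching_cubes(
            field, level=0.5, spacing=labels.spacing, step_size=step_size
        )
        verts = verts + np.asarray(labels.origin)
        meshes.append(SurfaceMesh(verts, faces, tag))
    return meshes[0], meshes[1]


@dataclass
class TemplateModel:
    """Mean-shape LV surface template with fixed correspondence.

    All three meshes share one triangulation and point count; index k is
    the same anatomical location on each.  For a base-truncated ventricle
    the marching-cubes surfaces close across the basal (valve) plane where
    no myocardial wall exists; ``valid`` flags the points that carry a
    meaningful wall thickness (None means all).  The number of valid
    points, P = ``n_points``, fixes the length of every thickness map
    produced against this template.  The full meshes (cap included) are
    retained because surface registration needs both sides to present the
    same geometry.
    """

    endo: SurfaceMesh
    epi: SurfaceMesh
    midwall: SurfaceMesh
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.endo.n_points == self.epi.n_points == self.midwall.n_points):
            raise ValueError("template surfaces must share the point count")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
            if len(self.valid) != self.endo.n_points:
                raise ValueError("valid mask must match the point count")

    @property
    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.endo.n_points, dtype=bool)
        return self.valid

    @property
    def n_points(self) -> int:
        """Number of valid (myocardial) correspondence points P."""
        return int(self.valid_mask.sum())


def smoothed_vertex_normals(mesh: SurfaceMesh, iterations: int = 10) -> np.ndarray:
    """Vertex normals after iterative 1-ring averaging (unit length).

    Marching-cubes meshes carry high-frequency normal noise from the
    voxelisation; a few rounds of neighbourhood averaging leave the
    low-frequency surface orientation, which is what a wall-thickness ray
    should follow.
    """
    from scipy.sparse import coo_matrix

    n = mesh.n_points
    tri = mesh.triangles
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    edges = np.vstack([edges, edges[:, ::-1]])
    w = np.ones(len(edges))
    adj = coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n)).tocsr()
    adj.data[:] = 1.0  # ignore duplicate-edge multiplicity
    deg = np.maximum(np.asarray(adj.sum(axis=1)).ravel(), 1.0)

    normals = mesh.vertex_normals()
    for _ in range(iterations):
        normals = 0.5 * normals + 0.5 * (adj @ normals) / deg[:, None]
        norms = np.linalg.norm(normals, axis=1)
        normals /= np.maximum(norms, 1e-12)[:, None]
    return normals


def _pair_epi_to_endo(endo: SurfaceMesh, epi: SurfaceMesh) -> np.ndarray:
    """Epicardial partner point for each endocardial vertex.

    Cast the endocardial outward vertex normal at each vertex and take the
    nearest epicardial crossing; fall back to the exact closest point on
    the epicardium where the ray misses.
    """
    from scipy.spatial import cKDTree

    normals = smoothed_vertex_normals(endo)
    d_near, _ = cKDTree(epi.points).query(endo.points)
    caps = 3.0 * d_near + 5.0
    t, hit = line_mesh_nearest_t(endo.points, normals, epi.points, epi.triangles, caps)
    pts = endo.points + np.where(hit, t, 0.0)[:, None] * normals
    if (~hit).any():
        near, _, _ = closest_point_on_mesh(endo.points[~hit], epi.points, epi.triangles)
        pts[~hit] = near
        logger.info("%d epicardial pairings fell back to closest-point", int((~hit).sum()))
    return pts


def _moment_init(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Centroid + RMS-radius similarity initialisation (no rotation)."""
    mu_s, mu_d = src.mean(0), dst.mean(0)
    rs = np.sqrt(((src - mu_s) ** 2).sum(1).mean())
    rd = np.sqrt(((dst - mu_d) ** 2).sum(1).mean())
    s = rd / rs if rs > 0 else 1.0
    return SimilarityTransform(np.eye(3), mu_d - s * mu_s, s)


def register_template(
    template: TemplateModel,
    target_endo: SurfaceMesh,
    target_epi: SurfaceMesh,
    max_iter: int = 60,
    tol_mm: float = 1e-4,
    initial_transform: SimilarityTransform | None = None,
) -> tuple[SurfaceMesh, SurfaceMesh, SimilarityTransform, float]:
    """Correspond the template to one subject's extracted surfaces.

    Similarity initialisation (a landmark-derived ``initial_transform``
    when available, otherwise centroid/RMS-radius moments), then ICP:
    closest-point matching of template endo/epi points against the
    respective target surface with a similarity update, iterated to
    convergence; finally each template point is projected exactly onto the
    target surface.

    Returns ``(endo_k, epi_k, transform, final_rms_mm)`` where the meshes
    have the template's point count and triangulation and the residual is
    the pre-projection point-to-surface RMS.

    Raises
    ------
    ConvergenceError
        If the mean residual is still changing by more than ``tol_mm``
        after ``max_iter`` iterations.
    """
    from scipy.spatial import cKDTree

    src = np.vstack([template.endo.points, template.epi.points])
    n_endo = template.endo.n_points
    tgt_pts = [target_endo.points, target_epi.points]
    tgt_tris = [target_endo.triangles, target_epi.triangles]
    trees = [cKDTree(p) for p in tgt_pts]

    tf = initial_transform or _moment_init(src, np.vstack(tgt_pts))
    prev_rms = np.inf
    converged = False
    for it in range(max_iter):
        cur = tf.apply(src)
        # nearest-vertex matching is enough to drive the similarity update;
        # the exact on-surface projection happens once after convergence
        matched = np.empty_like(cur)
        for part, sl in ((0, slice(0, n_endo)), (1, slice(n_endo, None))):
            _, nn = trees[part].query(cur[sl])
            matched[sl] = tgt_pts[part][nn]
        rms = float(np.sqrt(((cur - matched) ** 2).sum(1).mean()))
        if abs(prev_rms - rms) < tol_mm:
            converged = True
            break
        prev_rms = rms
        tf, _ = estimate_similarity(src, matched)
    if not converged:
        raise ConvergenceError(
            f"ICP did not converge in {max_iter} iterations (residual {rms:.4f} mm)"
        )

    cur = tf.apply(src)
    endo_pts, d_endo, _ = closest_point_on_mesh(cur[:n_endo], tgt_pts[0], tgt_tris[0])
    epi_pts, d_epi, _ = closest_point_on_mesh(cur[n_endo:], tgt_pts[1], tgt_tris[1])
    # final residual is point-to-*surface*, which is what projection removes
    surf_rms = float(np.sqrt(np.mean(np.concatenate([d_endo, d_epi]) ** 2)))
    endo_c = template.endo.with_points(endo_pts, "endocardium")
    epi_c = template.epi.with_points(epi_pts, "epicardium")
    return endo_c, epi_c, tf, surf_rms


def build_template(
    atlases: Sequence[Atlas],
    step_size: int = 2,
    smooth_sigma_mm: float = 1.5,
) -> TemplateModel:
    """Mean-shape template from an atlas pool.

    Surfaces are extracted per atlas; the first atlas's endocardial mesh
    (with its normal-paired epicardial partner points) provides the
    reference topology.  It is registered to every other atlas by
    :func:`register_template`, initialised from the six-landmark similarity
    transform, and the corresponded point sets are averaged pointwise.

    Points whose epicardial partner lies closer than half the median
    endo-epi separation sit on the basal-cap closure (or its rim) where no
    myocardial wall exists; they stay in the meshes for registration but
    are flagged invalid for thickness mapping.
    """
    if len(atlases) < 2:
        raise ValueError("need at least 2 atlases to build a mean-shape template")
    ref = atlases[0]
    ref_endo, ref_epi = extract_surfaces(ref.labels, step_size, smooth_sigma_mm)
    epi_paired = _pair_epi_to_endo(ref_endo, ref_epi)
    sep = np.linalg.norm(epi_paired - ref_endo.points, axis=1)
    valid = sep >= 0.5 * np.median(sep)
    if (~valid).any():
        logger.info(
            "%d basal-cap points flagged invalid for thickness", int((~valid).sum())
        )
    tri = ref_endo.triangles
    base = TemplateModel(
        endo=ref_endo,
        epi=SurfaceMesh(epi_paired, tri, "epicardium"),
        midwall=SurfaceMesh((ref_endo.points + epi_paired) / 2, tri, "midwall"),
        valid=valid,
    )
    acc_endo = np.zeros_like(base.endo.points)
    acc_epi = np.zeros_like(base.epi.points)
    for i, atlas in enumerate(atlases):
        if atlas is ref:
            endo_c, epi_c = base.endo, base.epi
        else:
            # landmark similarity initialisation puts ICP in its basin even
            # for rotated or rescaled shapes
            tf0, _ = initialize_alignment(atlas.landmarks, ref.landmarks)
            t_endo, t_epi = extract_surfaces(atlas.labels, step_size, smooth_sigma_mm)
            try:
                endo_c, epi_c, _, _ = register_template(
                    base, t_endo, t_epi, initial_transform=tf0
                )
            except ConvergenceError as exc:
                raise ConvergenceError(
                    f"registration failed for atlas {atlas.atlas_id or i}: {exc}"
                ) from exc
        acc_endo += endo_c.points
        acc_epi += epi_c.points
    n = len(atlases)
    return TemplateModel(
        endo=base.endo.with_points(acc_endo / n),
        epi=base.epi.with_points(acc_epi / n),
        midwall=SurfaceMesh((acc_endo + acc_epi) / (2 * n), tri, "midwall"),
        valid=valid,
    )


def measure_thickness(
    endo: SurfaceMesh,
    epi: SurfaceMesh,
    subject_id: str = "",
    acquisition_id: str = "",
) -> ThicknessMap:
    """Wall thickness per correspondence point, in mm.

    The midwall point is ``m_k = (endo_k + epi_k)/2``; thickness at k is
    the distance between the endocardial and epicardial crossings of the
    line through ``m_k`` along the midwall surface normal.  Where either
    crossing is missing (or the normal is degenerate) the direct distance
    ``||epi_k - endo_k||`` is used instead (logged).
    """
    if endo.n_points != epi.n_points:
        raise ValueError("corresponded meshes must share the point count")
    mid = SurfaceMesh((endo.points + epi.points) / 2, endo.triangles, "midwall")
    normals = smoothed_vertex_normals(mid)
    good_n = np.isfinite(normals).all(axis=1) & (
        np.linalg.norm(normals, axis=1) > 0.5
    )

    # The wall is local: cap the crossing search at the direct endo-epi
    # distance plus a margin, so an oblique line cannot latch onto the
    # opposite side of the shell.
    guess = np.linalg.norm(epi.points - endo.points, axis=1)
    caps = guess + 5.0
    t_endo, hit_e = line_mesh_nearest_t(mid.points, normals, endo.points, endo.triangles, caps)
    t_epi, hit_p = line_mesh_nearest_t(mid.points, normals, epi.points, epi.triangles, caps)
    ok = good_n & hit_e & hit_p
    values = np.where(ok, np.abs(t_epi - t_endo), np.nan)
    fallback = ~ok
    if fallback.any():
        values[fallback] = np.linalg.norm(epi.points[fallback] - endo.points[fallback], axis=1)
        logger.info(
            "%d/%d thickness points used the endo-epi distance fallback",
            int(fallback.sum()),
            len(values),
        )
    return ThicknessMap(values, subject_id=subject_id, acquisition_id=acquisition_id)


class TemplateMapper(BaseEstimator):
    """Atlas-pool template builder and per-subject thickness mapper.

    ``fit`` builds the mean-shape template (fixing the correspondence point
    count ``n_points_``); ``transform`` takes a subject's label map and
    returns the per-point :class:`ThicknessMap`.
    """

    def __init__(self, step_size: int = 2, smooth_sigma_mm: float = 1.5):
        self.step_size = step_size
        self.smooth_sigma_mm = smooth_sigma_mm

    def fit(self, atlases: Sequence[Atlas], y=None) -> "TemplateMapper":
        self.template_ = build_template(
            list(atlases), self.step_size, self.smooth_sigma_mm
        )
        self.n_points_ = self.template_.n_points
        return self

    def map_surfaces(self, labels: VolumeImage) -> tuple[SurfaceMesh, SurfaceMesh]:
        if not hasattr(self, "template_"):
            raise RuntimeError("TemplateMapper is not fitted")
        endo, epi = extract_surfaces(labels, self.step_size, self.smooth_sigma_mm)
        endo_c, epi_c, _, _ = register_template(self.template_, endo, epi)
        return endo_c, epi_c

    def transform(
        self, labels: VolumeImage, subject_id: str = "", acquisition_id: str = ""
    ) -> ThicknessMap:
        endo_c, epi_c = self.map_surfaces(labels)
        full = measure_thickness(endo_c, epi_c, subject_id, acquisition_id)
        return ThicknessMap(
            full.values[self.template_.valid_mask], subject_id, acquisition_id
        )
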