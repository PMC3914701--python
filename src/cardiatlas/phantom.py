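"""Analytic left-ventricle phantoms with exact ground truth.

The phantom is a truncated-ellipsoid shell: the endocardium is an ellipsoid
with semiaxes ``(a, b, c)``, the myocardium is the band of points within a
prescribed wall thickness *t* of that surface (the exact offset surface, so
for constant *t* the true normal-ray wall thickness is *t* everywhere), and
everything above the basal truncation plane is background.  The long axis is
z with the apex at ``z = -c`` and the base cut at ``z = base_fraction * c``.

Intensities mimic bright-blood b-SSFP contrast: blood pool bright,
myocardium intermediate, background dark, plus seeded Gaussian noise.

Every stochastic operation takes an explicit seed and is bit-reproducible.
Pools of atlases and test-retest acquisition pairs are derived from a base
spec by seeded perturbation of shape, wall thickness and pose, standing in
for inter-subject variability and inter-study repositioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    LANDMARK_NAMES,
    Atlas,
    LandmarkSet,
    VolumeImage,
)
from .transforms import SimilarityTransform

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Point-to-ellipsoid distance


def signed_distance_to_ellipsoid(points: np.ndarray, semiaxes: Sequence[float]) -> np.ndarray:
    """Signed Euclidean distance from points to an origin-centred ellipsoid.

    Negative inside, positive outside.  Uses the classical Lagrange
    parametrisation of the foot point, ``y_i = a_i^2 x_i / (a_i^2 + lam)``,
    solving ``sum (a_i x_i)^2/(a_i^2+lam)^2 = 1`` by vectorised bisection
    (the function is strictly decreasing in lam on the admissible interval).
    Exact closed form is used for spheres.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.asarray(semiaxes, dtype=float)
    if np.any(a <= 0):
        raise ValueError("semiaxes must be positive")
    if np.allclose(a, a[0]):
        r = np.linalg.norm(pts, axis=1)
        return r - a[0]

    # Clamp away exact zeros so the foot-point formula stays defined; the
    # perturbation (1e-9 mm) is far below voxel scale.
    x = np.where(np.abs(pts) < 1e-9, 1e-9, pts)
    ax2 = (a * x) ** 2  # (N, 3)
    a2 = a**2

    def f(lam: np.ndarray) -> np.ndarray:
        return (ax2 / (a2 + lam[:, None]) ** 2).sum(axis=1) - 1.0

    lo = np.full(len(x), -a2.min() + 1e-12)
    hi = np.sqrt(ax2.sum(axis=1))  # f(hi) <= 0 since each term <= (a_i x_i)^2 / hi^2
    hi = np.maximum(hi, lo + 1.0)
    for _ in range(90):
        mid = 0.5 * (lo + hi)
        lo, hi = np.where(f(mid) > 0, mid, lo), np.where(f(mid) > 0, hi, mid)
    lam = 0.5 * (lo + hi)
    foot = a2 * x / (a2 + lam[:, None])
    dist = np.linalg.norm(x - foot, axis=1)
    inside = (x**2 / a2).sum(axis=1) < 1.0
    return np.where(inside, -dist, dist)


# ---------------------------------------------------------------------------
# Spec and ground truth


@dataclass
class PhantomSpec:
    """Parameters of one truncated-ellipsoid LV phantom.

    ``thickness_harmonic`` optionally modulates the wall thickness with the
    polar angle theta of the endocardial foot point:
    ``t(theta) = wall_thickness * (1 + amplitude * cos(order * theta))``,
    a low-order stand-in for regional thickness variation.
    """

    endo_semiaxes: tuple[float, float, float] = (20.0, 20.0, 45.0)
    wall_thickness: float = 10.0
    base_fraction: float = 0.5
    thickness_harmonic: tuple[float, int] | None = None  # (amplitude, order)
    intensity_blood: float = 400.0
    intensity_myocardium: float = 200.0
    intensity_background: float = 50.0
    noise_sd: float = 0.0
    rotation_rotvec: tuple[float, float, float] = (0.0, 0.0, 0.0)  # radians
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.endo_semiaxes):
            raise ValueError("endo semiaxes must be positive")
        if self.min_thickness() <= 0:
            raise ValueError("wall thickness must be positive everywhere")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # base plane at z = base_fraction * c; values >= 1 + t/c leave the
        # shell untruncated (closed ellipsoid), the usual LV cut is ~0.5
        if self.base_fraction <= -1.0:
            raise ValueError("base_fraction must exceed -1")

    def min_thickness(self) -> float:
        amp = abs(self.thickness_harmonic[0]) if self.thickness_harmonic else 0.0
        return self.wall_thickness * (1.0 - amp)

    def max_thickness(self) -> float:
        amp = abs(self.thickness_harmonic[0]) if self.thickness_harmonic else 0.0
        return self.wall_thickness * (1.0 + amp)

    @property
    def pose(self) -> SimilarityTransform:
        """Phantom-frame -> world transform (rigid; scale 1)."""
        return SimilarityTransform(
            Rotation.from_rotvec(np.asarray(self.rotation_rotvec)).as_matrix(),
            np.asarray(self.translation),
            1.0,
        )

    def thickness_at_polar(self, theta: np.ndarray) -> np.ndarray:
        """Prescribed wall thickness at endocardial polar angle theta."""
        t = np.full_like(np.asarray(theta, dtype=float), self.wall_thickness)
        if self.thickness_harmonic is not None:
            amp, order = self.thickness_harmonic
            t = self.wall_thickness * (1.0 + amp * np.cos(order * np.asarray(theta)))
        return t


@dataclass
class PhantomGroundTruth:
    """Analytic reference quantities for one generated phantom."""

    spec: PhantomSpec
    pose: SimilarityTransform
    base_z: float  # truncation plane height in the phantom frame

    def thickness_at(self, theta: np.ndarray | float) -> np.ndarray:
        return self.spec.thickness_at_polar(np.asarray(theta, dtype=float))

    @property
    def mean_thickness(self) -> float:
        # Harmonic modulation integrates to zero over full periods; for the
        # constant case this is exact.
        return self.spec.wall_thickness

    def cavity_volume(self) -> float:
        """Exact truncated-ellipsoid cavity volume in mm^3."""
        a, b, c = self.spec.endo_semiaxes
        z0 = min(self.base_z, c)
        return float(np.pi * a * b * (z0 - z0**3 / (3 * c**2) + 2 * c / 3))

    def myocardium_volume(self, quad_spacing: float = 0.5) -> float:
        """Myocardium (offset-band) volume in mm^3.

        Exact spherical-cap formula when the endocardium is a sphere and the
        wall is constant; otherwise a fine-grid quadrature at
        ``quad_spacing`` mm (midpoint rule on the indicator).
        """
        a, b, c = self.spec.endo_semiaxes
        t = self.spec.wall_thickness
        if np.allclose([a, b], c) and self.spec.thickness_harmonic is None:
            r_in, r_out, z0 = c, c + t, self.base_z

            def seg(r: float) -> float:
                zc = min(z0, r)
                return float(np.pi * (zc * r**2 - zc**3 / 3 + 2 * r**3 / 3))

            return seg(r_out) - seg(r_in)
        # quadrature in the phantom frame
        tmax = self.spec.max_thickness()
        ext = np.array([a + tmax, b + tmax, c + tmax])
        h = quad_spacing
        grids = [np.arange(-e, e + h, h) + h / 2 for e in ext]
        # restrict z to the band's z-range
        gz = grids[2]
        gz = gz[gz <= self.base_z]
        xx, yy, zz = np.meshgrid(grids[0], grids[1], gz, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
        d = signed_distance_to_ellipsoid(pts, self.spec.endo_semiaxes)
        tloc = _thickness_for_points(pts, self.spec)
        inside = (d > 0) & (d <= tloc)
        return float(inside.sum() * h**3)


def _thickness_for_points(pts: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Wall-thickness bound at each point, from its endocardial foot angle."""
    if spec.thickness_harmonic is None:
        return np.full(len(pts), spec.wall_thickness)
    a = np.asarray(spec.endo_semiaxes)
    # Foot-point polar angle approximated via the normalised radial direction;
    # adequate for the low-order smooth modulations used here.
    u = pts / a
    nrm = np.linalg.norm(u, axis=1)
    nrm = np.where(nrm < 1e-12, 1.0, nrm)
    theta = np.arccos(np.clip(u[:, 2] / nrm, -1.0, 1.0))
    return spec.thickness_at_polar(theta)


# ---------------------------------------------------------------------------
# Generation


def default_grid(
    spec: PhantomSpec, spacing: Sequence[float], margin: float = 8.0
) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
    """Axis-aligned grid (shape, origin) covering the posed phantom."""
    a, b, c = spec.endo_semiaxes
    tmax = spec.max_thickness()
    r = max(a, b, c) + tmax  # bounding sphere of the shell, pose-invariant
    center = spec.pose.apply(np.zeros(3))
    sp = np.asarray(spacing, dtype=float)
    lo = center - r - margin
    hi = center + r + margin
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / sp[i])) for i in range(3))
    origin = tuple(float(lo[i] + sp[i] / 2) for i in range(3))
    return shape, origin


def generate_phantom(
    spec: PhantomSpec,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    shape: Sequence[int] | None = None,
    origin: Sequence[float] | None = None,
) -> tuple[VolumeImage, VolumeImage, LandmarkSet, PhantomGroundTruth]:
    """Voxelise one phantom.

    Returns ``(grayscale, labels, landmarks, ground_truth)``.  Labels are
    assigned by the signed distance of each voxel center to the analytic
    endocardial surface; grayscale adds seeded Gaussian noise to the
    label-dependent intensity.

    Raises
    ------
    ValueError
        If an explicit grid is given that does not contain the shell.
    """
    sp = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in sp):
        raise ValueError("spacing must be positive")
    if shape is None or origin is None:
        shape, origin = default_grid(spec, sp)
    shape = tuple(int(n) for n in shape)
    origin = tuple(float(o) for o in origin)

    a, b, c = spec.endo_semiaxes
    tmax = spec.max_thickness()
    z_base = spec.base_fraction * c

    # containment check against the posed bounding sphere
    r_bound = max(a, b, c) + tmax
    center = spec.pose.apply(np.zeros(3))
    lo = np.asarray(origin) - np.asarray(sp) / 2
    hi = lo + np.asarray(shape) * np.asarray(sp)
    if np.any(center - r_bound < lo - 1e-6) or np.any(center + r_bound > hi + 1e-6):
        raise ValueError("phantom shell exceeds the voxel grid")

    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx * np.asarray(sp) + np.asarray(origin)
    local = spec.pose.inverse().apply(world)

    # Cheap prefilter: only evaluate the exact distance near the shell.
    rad = np.linalg.norm(local / np.array([a + tmax, b + tmax, c + tmax]), axis=1)
    near = rad <= 1.15
    d = np.full(len(local), np.inf)
    d[near] = signed_distance_to_ellipsoid(local[near], spec.endo_semiaxes)

    below_base = local[:, 2] <= z_base
    tloc = np.full(len(local), spec.wall_thickness)
    if spec.thickness_harmonic is not None:
        tloc[near] = _thickness_for_points(local[near], spec)

    labels = np.zeros(len(local), dtype=np.int16)
    labels[(d <= 0) & below_base] = 1
    labels[(d > 0) & (d <= tloc) & below_base] = 2
    labels = labels.reshape(shape)

    intensity_lut = np.array(
        [spec.intensity_background, spec.intensity_blood, spec.intensity_myocardium, 0.0]
    )
    gray = intensity_lut[labels].astype(np.float64)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        gray = gray + rng.normal(0.0, spec.noise_sd, size=gray.shape)

    landmarks = _analytic_landmarks(spec, z_base).transformed(spec.pose)
    gt = PhantomGroundTruth(spec=spec, pose=spec.pose, base_z=z_base)
    return (
        VolumeImage(gray, sp, origin),
        VolumeImage(labels, sp, origin),
        landmarks,
        gt,
    )


def _analytic_landmarks(spec: PhantomSpec, z_base: float) -> LandmarkSet:
    a, b, c = spec.endo_semiaxes
    t = spec.wall_thickness
    ring = np.sqrt(max(1.0 - z_base**2 / c**2, 1e-6))
    pts = {
        "apex": np.array([0.0, 0.0, -(c + t)]),
        "base_center": np.array([0.0, 0.0, z_base]),
        "mitral_lateral": np.array([a * ring, 0.0, z_base]),
        "mitral_septal": np.array([-a * ring, 0.0, z_base]),
        "rv_insertion_anterior": np.array(
            [(a + t) * np.cos(2 * np.pi / 3), (b + t) * np.sin(2 * np.pi / 3), 0.0]
        ),
        "rv_insertion_inferior": np.array(
            [(a + t) * np.cos(4 * np.pi / 3), (b + t) * np.sin(4 * np.pi / 3), 0.0]
        ),
    }
    return LandmarkSet(pts)


@dataclass
class ShapeVariation:
    """Seeded Gaussian perturbation used to build an atlas pool."""

    semiaxes_sd: float = 1.5  # mm, per axis
    thickness_sd: float = 0.8  # mm
    rotation_sd_deg: float = 3.0  # per rotation-vector component
    translation_sd: float = 2.0  # mm, per axis


def generate_atlas_pool(
    base_spec: PhantomSpec,
    n_atlases: int,
    variation: ShapeVariation | None = None,
    rng_seed: int = 0,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> list[Atlas]:
    """Draw a pool of labeled atlases by perturbing the base phantom.

    Each atlas gets independently perturbed semiaxes, wall thickness and
    rigid pose, emulating inter-subject anatomical variability.  Draws that
    would produce a non-positive wall are rejected and redrawn (logged).
    """
    if n_atlases < 1:
        raise ValueError("n_atlases must be >= 1")
    variation = variation or ShapeVariation()
    rng = np.random.default_rng(rng_seed)
    atlases: list[Atlas] = []
    for i in range(n_atlases):
        for attempt in range(100):
            semi = np.asarray(base_spec.endo_semiaxes) + rng.normal(
                0, variation.semiaxes_sd, 3
            )
            thick = base_spec.wall_thickness + rng.normal(0, variation.thickness_sd)
            rotvec = np.deg2rad(rng.normal(0, variation.rotation_sd_deg, 3))
            trans = rng.normal(0, variation.translation_sd, 3)
            if thick > 0.5 and np.all(semi > 1.0):
                break
            logger.info("atlas draw %d attempt %d rejected (degenerate shape)", i, attempt)
        else:
            raise RuntimeError("could not draw a valid atlas shape")
        spec_i = replace(
            base_spec,
            endo_semiaxes=tuple(semi),
            wall_thickness=float(thick),
            rotation_rotvec=tuple(rotvec),
            translation=tuple(trans),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        gray, labels, lms, _ = generate_phantom(spec_i, spacing)
        atlases.append(Atlas(gray, labels, lms, atlas_id=f"phantom-{i:02d}"))
    return atlases


@dataclass
class RetestJitter:
    """Inter-study repositioning and noise model for a test-retest pair."""

    translation_sd: float = 1.5  # mm per axis
    rotation_sd_deg: float = 2.0  # per rotation-vector component


def generate_retest_pair(
    spec: PhantomSpec,
    jitter: RetestJitter | None = None,
    rng_seed: int = 0,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> tuple[
    tuple[VolumeImage, VolumeImage, LandmarkSet, PhantomGroundTruth],
    tuple[VolumeImage, VolumeImage, LandmarkSet, PhantomGroundTruth],
    SimilarityTransform,
]:
    """Two acquisitions of the same anatomy with independent noise and a
    small rigid pose offset, on a shared fixed field of view.

    Returns ``(acq1, acq2, applied_offset)`` where *applied_offset* is the
    rigid transform composed onto the anatomy pose for the second visit.
    """
    jitter = jitter or RetestJitter()
    rng = np.random.default_rng(rng_seed)
    seed1, seed2 = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    rotvec = np.deg2rad(rng.normal(0, jitter.rotation_sd_deg, 3))
    trans = rng.normal(0, jitter.translation_sd, 3)
    offset = SimilarityTransform(Rotation.from_rotvec(rotvec).as_matrix(), trans, 1.0)

    margin = 8.0 + 3 * jitter.translation_sd + 2.0
    shape, origin = default_grid(spec, spacing, margin=margin)

    spec1 = replace(spec, rng_seed=seed1)
    pose2 = offset.compose(spec.pose)
    spec2 = replace(
        spec,
        rng_seed=seed2,
        rotation_rotvec=tuple(Rotation.from_matrix(pose2.rotation).as_rotvec()),
        translation=tuple(pose2.translation),
    )
    acq1 = generate_phantom(spec1, spacing, shape, origin)
    acq2 = generate_phantom(spec2, spacing, shape, origin)
    return acq1, acq2, offset
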