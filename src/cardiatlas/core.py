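"""Core domain types and file I/O.

All geometry is expressed in physical millimetres.  A :class:`VolumeImage`
maps voxel index ``(i, j, k)`` (0-based) to the physical coordinate
``origin + index * spacing`` — a voxel-*center* convention.  Meshes and
landmarks live in the same millimetre frame, so volumes with different
spacing (e.g. 2 mm high-resolution stacks vs 10 mm thick-slice stacks)
can be compared directly.

Label volumes use the code convention::

    0  background
    1  LV cavity (blood pool)
    2  myocardium
    3  RV cavity

File formats: NIfTI-1 for volumes (via nibabel), JSON for landmark sets,
PLY for surface meshes (via trimesh), CSV for per-point tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np
import trimesh

logger = logging.getLogger(__name__)

#: Valid label codes for segmentation volumes.
LABEL_BACKGROUND = 0
LABEL_LV_CAVITY = 1
LABEL_MYOCARDIUM = 2
LABEL_RV_CAVITY = 3
VALID_LABELS = (LABEL_BACKGROUND, LABEL_LV_CAVITY, LABEL_MYOCARDIUM, LABEL_RV_CAVITY)

#: Canonical landmark names, in fixed order.  The set is a convention of this
#: package: an apical point, the centre of the basal (mitral) plane, two
#: points on the mitral ring and the two RV insertion points.
LANDMARK_NAMES = (
    "apex",
    "base_center",
    "mitral_lateral",
    "mitral_septal",
    "rv_insertion_anterior",
    "rv_insertion_inferior",
)


class FormatError(ValueError):
    """Raised for malformed or unsupported input files."""


@dataclass
class VolumeImage:
    """A 3D scalar grid with per-axis physical spacing and origin.

    Parameters
    ----------
    data:
        3D array; floating grayscale intensities or integer labels.
    spacing:
        Voxel size ``(dx, dy, dz)`` in mm, all components positive.
    origin:
        Physical coordinate in mm of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have three components")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def is_label_volume(self) -> bool:
        return np.issubdtype(self.data.dtype, np.integer)

    def validate_labels(self) -> None:
        """Check that an integer payload only contains the known label codes."""
        if not self.is_label_volume():
            raise ValueError("not an integer label volume")
        bad = np.setdiff1d(np.unique(self.data), VALID_LABELS)
        if bad.size:
            raise ValueError(f"unknown label codes present: {bad.tolist()}")

    def index_to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to physical mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) physical mm coordinates to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_grid(self, other: "VolumeImage", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def copy_with(self, **kwargs) -> "VolumeImage":
        return replace(self, **kwargs)


@dataclass
class LandmarkSet:
    """Six named anatomical fiducial points in physical mm."""

    points: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        pts = {str(k): np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        missing = set(LANDMARK_NAMES) - set(pts)
        extra = set(pts) - set(LANDMARK_NAMES)
        if missing or extra:
            raise ValueError(
                f"landmark set must contain exactly {LANDMARK_NAMES}; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        arr = np.stack([pts[n] for n in LANDMARK_NAMES])
        if not np.all(np.isfinite(arr)):
            raise ValueError("landmark coordinates must be finite")
        d = np.linalg.norm(arr[:, None] - arr[None, :], axis=-1)
        if np.any(d[np.triu_indices(len(arr), k=1)] < 1e-9):
            raise ValueError("landmarks must be pairwise distinct")
        self.points = pts

    def as_array(self) -> np.ndarray:
        """(6, 3) array in the canonical name order."""
        return np.stack([self.points[n] for n in LANDMARK_NAMES])

    def transformed(self, transform) -> "LandmarkSet":
        moved = transform.apply(self.as_array())
        return LandmarkSet({n: p for n, p in zip(LANDMARK_NAMES, moved)})

    def __iter__(self) -> Iterator[tuple[str, np.ndarray]]:
        return ((n, self.points[n]) for n in LANDMARK_NAMES)


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm with an optional fixed correspondence.

    When a mesh comes out of template registration, point index ``k``
    denotes the same anatomical location on every subject's mesh, which is
    what makes per-point group statistics meaningful.
    """

    points: np.ndarray
    triangles: np.ndarray
    surface_tag: str = "unspecified"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (P, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (T, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.points)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.points.copy(), self.triangles.copy(), process=False)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals (unit length)."""
        return np.array(self.to_trimesh().vertex_normals, dtype=float)

    def with_points(self, points: np.ndarray, surface_tag: str | None = None) -> "SurfaceMesh":
        return SurfaceMesh(points, self.triangles, surface_tag or self.surface_tag)


@dataclass
class ThicknessMap:
    """Per-correspondence-point wall thickness in mm for one acquisition."""

    values: np.ndarray
    subject_id: str = ""
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)

    @property
    def n_points(self) -> int:
        return len(self.values)


@dataclass
class Atlas:
    """A labeled reference image: intensity + labels on one grid + landmarks."""

    intensity: VolumeImage
    labels: VolumeImage
    landmarks: LandmarkSet
    atlas_id: str = ""

    def __post_init__(self) -> None:
        if not self.intensity.same_grid(self.labels):
            raise ValueError("intensity and label volumes must share grid/spacing/origin")
        if not self.labels.is_label_volume():
            raise ValueError("labels payload must be integer-typed")


# ---------------------------------------------------------------------------
# NIfTI volume I/O


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 volume; spacing and origin come from the header affine.

    Raises
    ------
    FormatError
        If the file cannot be parsed as NIfTI or the payload is not 3D.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    spacing = tuple(float(s) for s in np.linalg.norm(affine[:3, :3], axis=0))
    origin = tuple(float(o) for o in affine[:3, 3])
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float64)
    return VolumeImage(data, spacing, origin)


def write_volume(image: VolumeImage, path: str | Path) -> None:
    """Write a :class:`VolumeImage` as NIfTI-1, axis-aligned affine."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = image.spacing
    affine[:3, 3] = image.origin
    data = image.data
    if image.is_label_volume():
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Landmark and mesh I/O


def read_landmarks(path: str | Path) -> LandmarkSet:
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, Mapping):
        raise FormatError("landmark file must hold a JSON object {name: [x,y,z]}")
    return LandmarkSet({k: np.asarray(v, dtype=float) for k, v in raw.items()})


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({n: p.tolist() for n, p in landmarks}, fh, indent=1)


def read_mesh(path: str | Path, surface_tag: str = "unspecified") -> SurfaceMesh:
    tm = trimesh.load(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), surface_tag)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    mesh.to_trimesh().export(str(path), encoding="ascii")


def read_point_table(path: str | Path) -> np.ndarray:
    """Read a per-point CSV (point_index, value) into a dense value array."""
    import pandas as pd

    df = pd.read_csv(path)
    values = np.full(int(df["point_index"].max()) + 1, np.nan)
    values[df["point_index"].to_numpy()] = df["value"].to_numpy()
    return values


def write_point_table(values: np.ndarray, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"point_index": np.arange(len(values)), "value": np.asarray(values)}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# 2D multi-slice emulation


def resample_to_stack(
    image: VolumeImage, slice_thickness_mm: float, gap_mm: float = 0.0
) -> VolumeImage:
    """Down-sample the z-axis to emulate a 2D multi-slice acquisition.

    Each output slice pools a slab of ``slice_thickness_mm`` of the input
    (mean for grayscale, majority label for integer payloads, ties broken
    toward the lower label code); consecutive slabs are separated by
    ``gap_mm`` which is simply not sampled, as in a gapped 2D protocol.
    The output z-spacing is ``slice_thickness_mm + gap_mm`` and the output
    origin sits at the center of the first slab.

    Slab windows are half-open ``[start, start + thickness)`` over voxel
    *centers*, measured from the physical edge of the first voxel
    (``origin_z - dz/2``).  A final slab that extends past the volume is
    kept, truncated, and logged.
    """
    if slice_thickness_mm <= 0:
        raise ValueError("slice_thickness_mm must be positive")
    if gap_mm < 0:
        raise ValueError("gap_mm must be non-negative")
    dz = image.spacing[2]
    nz = image.shape[2]
    if nz * dz + 1e-9 < slice_thickness_mm:
        logger.warning(
            "volume z-extent %.1f mm shorter than one slab (%.1f mm); "
            "emitting a single truncated slab",
            nz * dz,
            slice_thickness_mm,
        )
    z_centers = image.origin[2] + dz * np.arange(nz)
    z_edge = image.origin[2] - dz / 2.0
    period = slice_thickness_mm + gap_mm
    # Slab s covers [z_edge + s*period, z_edge + s*period + thickness)
    rel = z_centers - z_edge
    slab = np.floor(rel / period).astype(int)
    within = (rel - slab * period) < slice_thickness_mm - 1e-9
    n_slabs = slab.max() + 1 if np.any(within) else 0
    if n_slabs == 0:
        raise ValueError("volume z-extent shorter than one slab")
    last_slab_end = z_edge + (n_slabs - 1) * period + slice_thickness_mm
    if last_slab_end > z_edge + nz * dz + 1e-9:
        logger.info("final slab truncated at the volume boundary")

    is_label = image.is_label_volume()
    out = np.empty(image.shape[:2] + (n_slabs,), dtype=image.data.dtype)
    for s in range(n_slabs):
        sel = within & (slab == s)
        block = image.data[:, :, sel]
        if block.shape[2] == 0:
            # Slab falls entirely into a gap shadow past the data; keep zeros.
            out[:, :, s] = 0
            continue
        if is_label:
            counts = np.stack(
                [(block == code).sum(axis=2) for code in VALID_LABELS], axis=-1
            )
            out[:, :, s] = np.asarray(VALID_LABELS)[np.argmax(counts, axis=-1)]
        else:
            out[:, :, s] = block.mean(axis=2)
    new_origin = (
        image.origin[0],
        image.origin[1],
        z_edge + slice_thickness_mm / 2.0,
    )
    return VolumeImage(out, (image.spacing[0], image.spacing[1], period), new_origin)
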