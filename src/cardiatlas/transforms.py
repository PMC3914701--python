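"""Similarity (rotation + isotropic scale + translation) transforms in mm space."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SimilarityTransform:
    """Maps points as ``y = scale * R @ x + translation``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.scale = float(self.scale)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = self.scale * np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        s_inv = 1.0 / self.scale
        return SimilarityTransform(r_inv, -s_inv * r_inv @ self.translation, s_inv)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform ``self ∘ other`` (apply *other* first)."""
        return SimilarityTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation + self.translation,
            self.scale * other.scale,
        )

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()


def estimate_similarity(
    source: np.ndarray,
    target: np.ndarray,
    with_scale: bool = True,
    min_points: int = 3,
    cond_limit: float = 1e8,
) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity transform mapping *source* onto *target*.

    Umeyama's closed-form solution.  Returns the transform and the RMS
    residual of ``transform.apply(source) - target``.

    Raises
    ------
    ValueError
        If fewer than *min_points* points are given or the point
        configuration is degenerate (collinear / coincident), detected via
        the conditioning of the source covariance.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must both be (N, 3)")
    n = len(src)
    if n < min_points:
        raise ValueError(f"need at least {min_points} points, got {n}")

    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    src_c, tgt_c = src - mu_s, tgt - mu_t
    cov = tgt_c.T @ src_c / n
    var_s = (src_c**2).sum() / n
    u, d, vt = np.linalg.svd(cov)
    # Degeneracy: points collinear or coincident leave the similarity
    # under-determined about the residual axis.
    if d[0] <= 0 or d[1] / max(d[0], 1e-300) < 1.0 / cond_limit:
        raise ValueError("degenerate (collinear or coincident) point configuration")
    s_fix = np.ones(3)
    if np.linalg.det(u) * np.linalg.det(vt) < 0:
        s_fix[-1] = -1.0
    rot = u @ np.diag(s_fix) @ vt
    scale = float((d * s_fix).sum() / var_s) if with_scale else 1.0
    trans = mu_t - scale * rot @ mu_s
    tf = SimilarityTransform(rot, trans, scale)
    residual = float(np.sqrt(((tf.apply(src) - tgt) ** 2).sum(axis=1).mean()))
    return tf, residual
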