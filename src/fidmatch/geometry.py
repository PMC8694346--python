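"""Planar affine geometry primitives shared by the whole pipeline.

Marker coordinates are continuous Cartesian pixel positions with an
arbitrary origin; no image-axis convention is imposed because the library
never touches pixel rasters, only detected marker positions.

The central objects are :class:`MarkerSet` (the markers of one micrograph
together with its tilt angle), :class:`AffineTransform2D` (the global
in-plane transform ``p -> A p + t`` that relates two tilted views to first
order) and :class:`Correspondence` (a one-to-one pairing of model and scene
markers with per-pair residuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DegenerateGeometryError",
    "MarkerSet",
    "AffineTransform2D",
    "Correspondence",
    "apply_affine",
    "estimate_affine_lsq",
    "count_congruent",
    "estimate_ratio_error",
]


class DegenerateGeometryError(ValueError):
    """Raised when source points are collinear or duplicated.

    Signals callers (e.g. the RANSAC loop) that the sample must be redrawn.
    """


def _as_points(obj) -> np.ndarray:
    """Coerce a MarkerSet or array-like into an (n, 2) float array."""
    if isinstance(obj, MarkerSet):
        return obj.points
    pts = np.asarray(obj, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim == 1 and pts.shape[0] == 2:
        return pts.reshape(1, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) point array, got shape {pts.shape}")
    return pts


@dataclass
class MarkerSet:
    """Detected 2D fiducial marker positions of a single micrograph.

    Parameters
    ----------
    points
        ``(n, 2)`` array of marker centres in pixels.
    tilt_angle
        Stage tilt of the micrograph in degrees, in ``(-90, 90)``.
    image_index
        Position of the micrograph in the tilt series.
    """

    points: np.ndarray
    tilt_angle: float = 0.0
    image_index: int = 0

    def __post_init__(self) -> None:
        pts = _as_points(self.points)
        if pts.size and not np.all(np.isfinite(pts)):
            raise ValueError("marker coordinates must be finite")
        if not -90.0 < float(self.tilt_angle) < 90.0:
            raise ValueError(f"tilt angle {self.tilt_angle} outside (-90, 90) degrees")
        self.points = pts
        self.tilt_angle = float(self.tilt_angle)
        self.image_index = int(self.image_index)

    def __len__(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "MarkerSet":
        """Copy of this set with replaced coordinates (same tilt/index)."""
        return MarkerSet(points, self.tilt_angle, self.image_index)


@dataclass
class AffineTransform2D:
    """In-plane affine map ``p -> A p + t`` (pixels)."""

    A: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.t = np.asarray(self.t, dtype=float).reshape(2)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.A))

    @property
    def is_invertible(self) -> bool:
        return abs(self.det) > 1e-12

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = _as_points(points)
        return pts @ self.A.T + self.t

    def compose(self, inner: "AffineTransform2D") -> "AffineTransform2D":
        """Return the map equivalent to applying ``inner`` first, then self."""
        return AffineTransform2D(self.A @ inner.A, self.A @ inner.t + self.t)

    def inverse(self) -> "AffineTransform2D":
        if not self.is_invertible:
            raise DegenerateGeometryError("transform is singular")
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(Ainv, -Ainv @ self.t)


@dataclass
class Correspondence:
    """One-to-one pairing of model and scene markers.

    ``pairs`` holds ``(model_index, scene_index)`` rows; ``residuals`` the
    matched distance of each row in pixels.
    """

    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.residuals = np.asarray(self.residuals, dtype=float).reshape(-1)
        if self.pairs.shape[0] != self.residuals.shape[0]:
            raise ValueError("pairs and residuals length mismatch")

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def model_indices(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def scene_indices(self) -> np.ndarray:
        return self.pairs[:, 1]


def apply_affine(transform: AffineTransform2D, markers: MarkerSet) -> MarkerSet:
    """Apply an affine transform to every marker, preserving order."""
    return markers.with_points(transform.apply(markers.points))


def estimate_affine_lsq(src, dst) -> AffineTransform2D:
    """Least-squares affine fit mapping ``src`` onto ``dst``.

    Minimises ``sum_i || A src_i + t - dst_i ||^2``. With exactly three
    non-collinear correspondences the fit interpolates them exactly.

    Raises
    ------
    DegenerateGeometryError
        If fewer than three points are given or the source points are
        collinear/duplicated (rank-deficient design).
    """
    src = _as_points(src)
    dst = _as_points(dst)
    if src.shape != dst.shape:
        raise ValueError("src and dst must have the same shape")
    n = src.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 correspondences")
    design = np.hstack([src, np.ones((n, 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateGeometryError("source points are collinear or duplicated")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform2D(coef[:2].T, coef[2])


def count_congruent(scene: MarkerSet, transformed_model: MarkerSet, d: float) -> Correspondence:
    """Greedy one-to-one congruence matching under distance threshold ``d``.

    All cross-set pairs within distance ``d`` are sorted by distance
    (ties broken by scene index then model index) and accepted greedily
    while both endpoints are unused. Empty inputs yield an empty
    correspondence.
    """
    if d <= 0:
        raise ValueError("distance threshold d must be positive")
    xp = _as_points(scene)
    yp = _as_points(transformed_model)
    if xp.shape[0] == 0 or yp.shape[0] == 0:
        return Correspondence()
    tree = cKDTree(xp)
    hits = tree.query_ball_point(yp, r=d)
    cand = []
    for m, scene_hits in enumerate(hits):
        for n in scene_hits:
            dist = float(np.hypot(*(yp[m] - xp[n])))
            cand.append((dist, n, m))
    cand.sort()
    used_scene: set[int] = set()
    used_model: set[int] = set()
    pairs = []
    residuals = []
    for dist, n, m in cand:
        if n in used_scene or m in used_model:
            continue
        used_scene.add(n)
        used_model.add(m)
        pairs.append((m, n))
        residuals.append(dist)
    if not pairs:
        return Correspondence()
    return Correspondence(np.asarray(pairs, dtype=int), np.asarray(residuals))


def estimate_ratio_error(localization_error: float, diagonal_length: float) -> float:
    """Relative error induced in an invariant ratio by marker localization error.

    A marker localized to within ``localization_error`` pixels perturbs the
    division ratio of a diagonal of length ``diagonal_length`` by roughly
    their quotient, which motivates discarding short-diagonal features.
    """
    if diagonal_length <= 0:
        raise ValueError("diagonal_length must be positive")
    if localization_error < 0:
        raise ValueError("localization_error must be non-negative")
    return localization_error / diagonal_length
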