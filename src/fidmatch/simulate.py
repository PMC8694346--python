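"""Ground-truth tilt-series simulator.

Generates the statistical structure the correspondence pipeline assumes:
gold beads placed in a slab (biased toward the two surfaces, where beads
settle in real specimens), single-axis projection ``u = x cos(beta) +
z sin(beta), v = y`` at each tilt angle, a per-image in-plane affine
nuisance (small rotation/scale/translation mimicking stage and optics
instability), a smooth low-frequency drift field, isotropic Gaussian
localization noise, tilt-dependent missed detections (high tilt angles
lose markers to shadowing), and spurious outlier detections drawn over a
slightly extended field of view.

The defaults mirror a mid-size cryo-ET acquisition: a 4k x 4k pixel field,
a few hundred beads, tilt range -60..60 degrees, 1 px localization noise.
Everything is bookkept in a :class:`GroundTruth` so every downstream stage
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import AffineTransform2D, MarkerSet

__all__ = [
    "SpecimenModel",
    "SimParams",
    "GroundTruth",
    "generate_specimen",
    "project_image",
    "generate_series",
]

OUTLIER_LABEL = -1


@dataclass
class SpecimenModel:
    """3D bead positions inside a slab (pixels)."""

    markers3d: np.ndarray  # (K, 3): x, y, z
    extent: float
    thickness: float

    def __post_init__(self) -> None:
        self.markers3d = np.asarray(self.markers3d, dtype=float).reshape(-1, 3)
        if self.markers3d.shape[0] < 1:
            raise ValueError("specimen needs at least one marker")

    def __len__(self) -> int:
        return self.markers3d.shape[0]


@dataclass
class SimParams:
    """Acquisition-corruption parameters of the simulator.

    Rates are fractions in [0, 1); lengths are pixels. ``miss_ref_angle``
    sets the tilt at which the tilt-dependent miss probability equals
    ``miss_rate``.
    """

    tilt_angles: Sequence[float] = field(
        default_factory=lambda: tuple(float(a) for a in range(-60, 61, 1))
    )
    sigma_loc: float = 1.0
    miss_rate: float = 0.1
    tilt_dependent_miss: bool = True
    miss_ref_angle: float = 45.0
    outlier_rate: float = 0.1
    rotation_range: float = 2.0  # degrees, +/-
    scale_range: float = 0.02  # fractional, +/-
    translation_range: float = 20.0  # pixels, +/-
    drift_amplitude: float = 5.0  # pixels; 0 disables drift
    drift_wavelength: Optional[float] = None  # defaults to extent / 3
    outlier_field_margin: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("miss_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.sigma_loc < 0 or self.drift_amplitude < 0:
            raise ValueError("noise and drift amplitudes must be non-negative")


@dataclass
class GroundTruth:
    """Per-image marker labels and per-image planted nuisance transforms.

    ``labels[i][r]`` is the specimen marker id of row ``r`` of image ``i``,
    or ``OUTLIER_LABEL`` for a spurious detection.
    """

    labels: list[np.ndarray]
    nuisances: list[AffineTransform2D]
    tilt_angles: list[float]

    def pairs(self, i: int, j: int) -> np.ndarray:
        """Truth pairs ``(row_in_i, row_in_j)`` of markers seen in both images."""
        li, lj = self.labels[i], self.labels[j]
        pos_i = {int(lab): r for r, lab in enumerate(li) if lab != OUTLIER_LABEL}
        out = [
            (pos_i[int(lab)], r)
            for r, lab in enumerate(lj)
            if lab != OUTLIER_LABEL and int(lab) in pos_i
        ]
        return np.asarray(out, dtype=int).reshape(-1, 2)

    def planted_transform(self, i: int, j: int) -> AffineTransform2D:
        """Planted affine mapping image ``j`` coordinates onto image ``i``.

        Composition of the two nuisance transforms with the projection
        rescaling ``diag(cos(beta_i) / cos(beta_j), 1)``; exact for a flat
        specimen (all ``z`` equal), first-order otherwise.
        """
        ci = np.cos(np.deg2rad(self.tilt_angles[i]))
        cj = np.cos(np.deg2rad(self.tilt_angles[j]))
        rescale = AffineTransform2D(np.diag([ci / cj, 1.0]), np.zeros(2))
        return self.nuisances[i].compose(rescale).compose(self.nuisances[j].inverse())


def generate_specimen(
    n_markers: int,
    extent: float = 4096.0,
    thickness: float = 150.0,
    surface_bias: float = 0.97,
    rng: Optional[np.random.Generator] = None,
) -> SpecimenModel:
    """Scatter beads in the slab, ``surface_bias`` of them on the support face.

    Gold beads are applied to the support film before freezing, so almost
    all of them form a monolayer on one slab face (``z = 0``); the
    remainder are suspended uniformly inside the slab and act as
    depth outliers, since their tilt-dependent parallax is not captured
    by the affine-plus-smooth-drift correspondence model.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0.0 <= surface_bias <= 1.0:
        raise ValueError("surface_bias must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    xy = rng.uniform(0.0, extent, size=(n_markers, 2))
    z = rng.uniform(0.0, thickness, size=n_markers)
    on_surface = rng.random(n_markers) < surface_bias
    z[on_surface] = 0.0
    return SpecimenModel(np.column_stack([xy, z]), extent=extent, thickness=thickness)


def _miss_probability(params: SimParams, beta_deg: float) -> float:
    if not params.tilt_dependent_miss:
        return params.miss_rate
    ref = 1.0 - np.cos(np.deg2rad(params.miss_ref_angle))
    if ref <= 0:
        return 0.0
    weight = (1.0 - np.cos(np.deg2rad(beta_deg))) / ref
    return float(min(params.miss_rate * weight, 0.95))


def _drift_field(points: np.ndarray, amplitude: float, wavelength: float,
                 phases: np.ndarray) -> np.ndarray:
    """Smooth low-frequency field: per axis, a sum of two orthogonal sinusoids."""
    k = 2.0 * np.pi / wavelength
    dx = 0.5 * amplitude * (
        np.sin(k * points[:, 0] + phases[0]) + np.sin(k * points[:, 1] + phases[1])
    )
    dy = 0.5 * amplitude * (
        np.sin(k * points[:, 0] + phases[2]) + np.sin(k * points[:, 1] + phases[3])
    )
    return np.column_stack([dx, dy])


def project_image(
    specimen: SpecimenModel,
    beta_deg: float,
    params: SimParams,
    rng: np.random.Generator,
    image_index: int = 0,
) -> tuple[MarkerSet, np.ndarray, AffineTransform2D]:
    """Project the specimen at one tilt angle with all corruptions applied.

    Returns the detected marker set, the per-row labels (specimen id or
    ``OUTLIER_LABEL``) and the planted in-plane nuisance transform.
    """
    if not -90.0 < beta_deg < 90.0:
        raise ValueError("tilt angle must be in (-90, 90) degrees")
    beta = np.deg2rad(beta_deg)
    m3 = specimen.markers3d
    proj = np.column_stack([m3[:, 0] * np.cos(beta) + m3[:, 2] * np.sin(beta), m3[:, 1]])

    theta = np.deg2rad(rng.uniform(-params.rotation_range, params.rotation_range))
    scale = 1.0 + rng.uniform(-params.scale_range, params.scale_range)
    trans = rng.uniform(-params.translation_range, params.translation_range, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    nuisance = AffineTransform2D(scale * rot, trans)
    pts = nuisance.apply(proj)

    if params.drift_amplitude > 0:
        wavelength = params.drift_wavelength or specimen.extent / 3.0
        phases = rng.uniform(0.0, 2.0 * np.pi, size=4)
        pts = pts + _drift_field(pts, params.drift_amplitude, wavelength, phases)

    if params.sigma_loc > 0:
        pts = pts + rng.normal(0.0, params.sigma_loc, size=pts.shape)

    labels = np.arange(len(specimen))
    p_miss = _miss_probability(params, beta_deg)
    if p_miss > 0:
        detected = rng.random(len(specimen)) >= p_miss
        pts = pts[detected]
        labels = labels[detected]

    n_out = int(round(params.outlier_rate * len(specimen)))
    if n_out > 0 and pts.shape[0] > 0:
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        margin = params.outlier_field_margin * (hi - lo)
        outliers = rng.uniform(lo - margin, hi + margin, size=(n_out, 2))
        pts = np.vstack([pts, outliers])
        labels = np.concatenate([labels, np.full(n_out, OUTLIER_LABEL)])

    order = rng.permutation(pts.shape[0])
    return (
        MarkerSet(pts[order], tilt_angle=beta_deg, image_index=image_index),
        labels[order],
        nuisance,
    )


def generate_series(
    specimen: SpecimenModel,
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[MarkerSet], GroundTruth]:
    """One projected marker set per configured tilt angle, plus bookkeeping."""
    if len(params.tilt_angles) < 1:
        raise ValueError("need at least one tilt angle")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    series: list[MarkerSet] = []
    labels: list[np.ndarray] = []
    nuisances: list[AffineTransform2D] = []
    for idx, beta in enumerate(params.tilt_angles):
        ms, lab, nuis = project_image(specimen, float(beta), params, rng, image_index=idx)
        series.append(ms)
        labels.append(lab)
        nuisances.append(nuis)
    truth = GroundTruth(
        labels=labels,
        nuisances=nuisances,
        tilt_angles=[float(b) for b in params.tilt_angles],
    )
    return series, truth
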