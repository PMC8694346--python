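"""Pairwise two-stage matching and track composition across a tilt series.

``match_pair`` chains stage one (feature-driven RANSAC affine) and stage
two (outlier pre-exclusion + EM drift refinement) for one micrograph pair,
degrading gracefully to the stage-one correspondence when refinement
cannot run. ``match_series`` applies it to every ``(n, n+1)`` and
``(n, n+2)`` pair of a series (2-neighbour window), and ``build_tracks``
composes the pairwise correspondences into per-bead tracks with a
residual-ordered union-find: edges are accepted from most to least
confident, and a merge that would place two different markers of the same
image in one track is rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .drift import DriftParams, RefinementFailedError, pre_exclude_outliers, refine_drift
from .geometry import AffineTransform2D, Correspondence, MarkerSet, apply_affine
from .ransac import NoTransformFoundError, RansacParams, estimate_initial_transform

__all__ = [
    "PairwiseMatch",
    "Track",
    "TrackSetStats",
    "DetectionRatio",
    "match_pair",
    "match_series",
    "build_tracks",
    "track_stats",
    "detection_ratio",
]

logger = logging.getLogger(__name__)


@dataclass
class PairwiseMatch:
    """Result of matching image ``image_j`` (model) onto ``image_i`` (scene).

    Correspondence rows are ``(index_in_image_j, index_in_image_i)`` in the
    original marker indexing of each image. ``status`` is ``"ok"`` (both
    stages ran), ``"stage1_only"`` (refinement skipped/failed) or
    ``"failed"`` (no transform found).
    """

    image_i: int
    image_j: int
    transform: Optional[AffineTransform2D]
    correspondence: Correspondence
    status: str
    drift_vectors: Optional[np.ndarray] = None  # aligned with image_j markers
    ransac_iterations: int = 0
    em_iterations: int = 0


@dataclass
class Track:
    """One physical bead's positions across the series.

    ``observations`` maps image index to ``(marker_index, (x, y))``.
    """

    track_id: int
    observations: dict[int, tuple[int, tuple[float, float]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class TrackSetStats:
    """Count and mean length of tracks covering enough of the series."""

    n_tracks: int
    mean_length: float
    coverage_threshold: float


@dataclass(frozen=True)
class DetectionRatio:
    """Recovered truth pairs over truth pairs detectable in both images."""

    matched: int
    potential: int

    @property
    def ratio(self) -> float:
        return self.matched / self.potential


def match_pair(
    scene: MarkerSet,
    model: MarkerSet,
    ransac_params: Optional[RansacParams] = None,
    drift_params: Optional[DriftParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> PairwiseMatch:
    """Two-stage correspondence between one micrograph pair."""
    ransac_params = ransac_params or RansacParams()
    drift_params = drift_params or DriftParams()
    image_i, image_j = scene.image_index, model.image_index
    try:
        stage1 = estimate_initial_transform(scene, model, ransac_params, rng=rng)
    except NoTransformFoundError as exc:
        logger.warning("pair (%d, %d): stage one failed: %s", image_i, image_j, exc)
        return PairwiseMatch(image_i, image_j, None, Correspondence(), "failed")

    ty = apply_affine(stage1.transform, model)
    d = float(ransac_params.d)
    try:
        scene_f, model_f, map_x, map_y = pre_exclude_outliers(
            scene, ty, d, drift_params.kappa_exclude
        )
        refined = refine_drift(scene_f, model_f, d, drift_params)
    except RefinementFailedError as exc:
        logger.warning(
            "pair (%d, %d): stage two unavailable (%s); keeping stage-one pairs",
            image_i, image_j, exc,
        )
        return PairwiseMatch(
            image_i, image_j, stage1.transform, stage1.correspondence,
            "stage1_only", ransac_iterations=stage1.iterations_used,
        )

    corr = refined.correspondence
    pairs = np.column_stack([map_y[corr.model_indices], map_x[corr.scene_indices]])
    drift = np.zeros((len(model), 2))
    drift[map_y] = refined.drift_vectors
    return PairwiseMatch(
        image_i, image_j, stage1.transform,
        Correspondence(pairs, corr.residuals), "ok",
        drift_vectors=drift,
        ransac_iterations=stage1.iterations_used,
        em_iterations=refined.em_iterations,
    )


def match_series(
    series: Sequence[MarkerSet],
    window: int = 2,
    ransac_params: Optional[RansacParams] = None,
    drift_params: Optional[DriftParams] = None,
    seed: Optional[int] = None,
) -> list[PairwiseMatch]:
    """Match every ``(n, n+k)`` pair for ``k = 1..window``.

    Pairs are processed in deterministic ``(n, n+k)`` order, each with its
    own child random stream derived from ``seed``, so results do not
    depend on execution order. Individual pair failures are recorded in
    the returned matches, not raised.
    """
    if len(series) < 2:
        raise ValueError("need at least two images")
    pairs = [
        (n, n + k)
        for n in range(len(series))
        for k in range(1, window + 1)
        if n + k < len(series)
    ]
    pairs.sort()
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    out = []
    for (i, j), ss in zip(pairs, streams):
        out.append(
            match_pair(
                series[i], series[j], ransac_params, drift_params,
                rng=np.random.default_rng(ss),
            )
        )
    return out


class _UnionFind:
    """Union-find over (image, marker) nodes tracking per-root image maps."""

    def __init__(self) -> None:
        self.parent: dict[tuple[int, int], tuple[int, int]] = {}
        self.images: dict[tuple[int, int], dict[int, int]] = {}

    def find(self, node: tuple[int, int]) -> tuple[int, int]:
        if node not in self.parent:
            self.parent[node] = node
            self.images[node] = {node[0]: node[1]}
            return node
        root = node
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[node] != root:  # path compression
            self.parent[node], node = root, self.parent[node]
        return root

    def union(self, a: tuple[int, int], b: tuple[int, int]) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return True
        ia, ib = self.images[ra], self.images[rb]
        if len(ia) < len(ib):
            ra, rb, ia, ib = rb, ra, ib, ia
        # reject a merge that would put two markers of one image in a track
        for img, marker in ib.items():
            if img in ia and ia[img] != marker:
                return False
        ia.update(ib)
        self.parent[rb] = ra
        del self.images[rb]
        return True


def build_tracks(
    matches: Sequence[PairwiseMatch],
    n_images: int,
    min_track_length: Optional[int] = None,
    series: Optional[Sequence[MarkerSet]] = None,
) -> list[Track]:
    """Compose pairwise correspondences into tracks.

    Edges are sorted by residual ascending (ties by image and marker
    indices) and merged with conflict-rejecting union-find. Components
    shorter than ``min_track_length`` (default: 70% of the series) are
    discarded. If ``series`` is given, observations carry coordinates.
    """
    if min_track_length is None:
        min_track_length = int(np.ceil(0.7 * n_images))
    edges = []
    for match in matches:
        if match.status == "failed":
            continue
        corr = match.correspondence
        for (m, n), res in zip(corr.pairs, corr.residuals):
            edges.append((float(res), match.image_i, match.image_j, int(n), int(m)))
    edges.sort()
    uf = _UnionFind()
    for res, img_i, img_j, n, m in edges:
        uf.union((img_i, n), (img_j, m))

    components: dict[tuple[int, int], dict[int, int]] = {}
    for node in list(uf.parent):
        root = uf.find(node)
        components.setdefault(root, uf.images[root])
    tracks = []
    keyed = sorted(components.values(), key=lambda obs: sorted(obs.items()))
    tid = 0
    for obs in keyed:
        if len(obs) < min_track_length:
            continue
        observations = {}
        for img in sorted(obs):
            marker = obs[img]
            if series is not None:
                x, y = series[img].points[marker]
                observations[img] = (marker, (float(x), float(y)))
            else:
                observations[img] = (marker, (float("nan"), float("nan")))
        tracks.append(Track(track_id=tid, observations=observations))
        tid += 1
    return tracks


def track_stats(
    tracks: Sequence[Track],
    n_images: int,
    coverage_threshold: float = 0.7,
) -> TrackSetStats:
    """Count tracks covering at least the threshold fraction of the series."""
    needed = coverage_threshold * n_images
    lengths = [len(t) for t in tracks if len(t) >= needed]
    mean_length = float(np.mean(lengths)) if lengths else 0.0
    return TrackSetStats(
        n_tracks=len(lengths),
        mean_length=mean_length,
        coverage_threshold=coverage_threshold,
    )


def detection_ratio(match: PairwiseMatch, truth_pairs: np.ndarray) -> DetectionRatio:
    """Score a pairwise match against ground-truth pairs.

    ``truth_pairs`` rows are ``(row_in_image_i, row_in_image_j)`` for
    markers detected in both images (as produced by
    :meth:`fidmatch.simulate.GroundTruth.pairs`).
    """
    truth_pairs = np.asarray(truth_pairs, dtype=int).reshape(-1, 2)
    if truth_pairs.shape[0] == 0:
        raise ValueError("no potential correspondences in ground truth")
    truth = {(int(i), int(j)) for i, j in truth_pairs}
    matched = sum(
        1 for m, n in match.correspondence.pairs if (int(n), int(m)) in truth
    )
    return DetectionRatio(matched=matched, potential=len(truth))
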