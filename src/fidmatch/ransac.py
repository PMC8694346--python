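"""Stage one: robust initial affine estimation by feature-driven RANSAC.

A query 4-point invariant feature is drawn from the moving (model) set,
its candidate congruent subsets are located in the fixed (scene) set by
the fast inquiry, and each candidate yields a least-squares affine
hypothesis that is scored by the size of the congruent subset it induces.
The iteration budget adapts to the best consensus found so far through
the classic ``I = log(1 - p_s) / log(1 - p_g^k)`` bound with ``k = 4``
(one 4-point feature per draw).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .features import (
    FeatureRejected,
    InvariantFeature,
    NeighborStats,
    inquire_feature,
    make_feature,
    neighbor_distance_stats,
    prune_pairs,
)
from .geometry import (
    AffineTransform2D,
    Correspondence,
    DegenerateGeometryError,
    MarkerSet,
    apply_affine,
    count_congruent,
    estimate_affine_lsq,
)

__all__ = [
    "NoTransformFoundError",
    "RansacParams",
    "RansacResult",
    "update_iteration_bound",
    "quick_randomized_check",
    "estimate_initial_transform",
]

logger = logging.getLogger(__name__)


class NoTransformFoundError(RuntimeError):
    """No affine hypothesis reached the minimum consensus of 4 pairs."""


@dataclass
class RansacParams:
    """Tuning knobs of the stage-one estimator.

    ``d`` (the congruence threshold) defaults to ``lambda_d *
    marker_diameter`` with ``lambda_d`` inside the 0.5-0.8 band that keeps
    the threshold below the marker spacing; ``delta`` (inquiry accuracy)
    defaults to ``d / 2`` and ``l_min`` (minimum feature diagonal) to
    ``4 * marker_diameter``, which keeps the localization-induced ratio
    error of a feature diagonal at the percent level for px-scale
    localization noise.
    """

    marker_diameter: float = 20.0
    lambda_d: float = 0.65
    d: Optional[float] = None
    xi: float = 0.15
    delta: Optional[float] = None
    l_min: Optional[float] = None
    l_max: Optional[float] = None  # override of the NN-statistics rule
    ratio_margin: float = 0.05
    p_s: float = 0.99
    initial_p_g: float = 0.2
    max_iterations: int = 10_000
    quick_check_size: int = 20
    quick_check_fraction: float = 0.1
    feature_attempts: int = 50
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.d is None:
            self.d = self.lambda_d * self.marker_diameter
        if self.delta is None:
            self.delta = 0.5 * self.d
        if self.l_min is None:
            self.l_min = 4.0 * self.marker_diameter
        if not 0 < self.p_s < 1:
            raise ValueError("p_s must be in (0, 1)")
        if self.d <= 0 or self.delta <= 0:
            raise ValueError("d and delta must be positive")
        if self.quick_check_size < 3:
            raise ValueError("quick_check_size must be >= 3")


@dataclass
class RansacResult:
    """Outcome of stage one: transform, consensus and iteration count."""

    transform: AffineTransform2D
    c_max: int
    correspondence: Correspondence
    iterations_used: int


def update_iteration_bound(p_s: float, p_g: float, k: int, cap: int = 10_000) -> int:
    """Iterations needed to hit an all-inlier sample with probability ``p_s``.

    ``ceil(log(1 - p_s) / log(1 - p_g**k))``, clamped to ``[1, cap]``;
    ``p_g <= 0`` returns the cap (nothing learned yet), ``p_g >= 1``
    returns 1.
    """
    if not 0 < p_s < 1:
        raise ValueError("p_s must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if p_g <= 0:
        return cap
    if p_g >= 1:
        return 1
    denom = math.log(1.0 - p_g**k)
    if denom == 0.0:
        return cap
    bound = math.ceil(math.log(1.0 - p_s) / denom)
    return int(min(max(bound, 1), cap))


def quick_randomized_check(
    scene: MarkerSet,
    transformed_model: MarkerSet,
    d: float,
    n_quick: int,
    fraction_needed: float,
    rng: np.random.Generator,
    scene_tree: Optional[cKDTree] = None,
) -> bool:
    """Cheap pre-test of a transform on a random subsample.

    Samples ``n_quick`` transformed model points and accepts iff at least
    ``fraction_needed`` of them have a scene point within ``d``. Avoids
    the full congruence count for hopeless hypotheses.
    """
    yp = transformed_model.points
    m = yp.shape[0]
    if m == 0:
        return False
    n_quick = min(int(n_quick), m)
    idx = rng.choice(m, size=n_quick, replace=False)
    tree = scene_tree if scene_tree is not None else cKDTree(scene.points)
    dists, _ = tree.query(yp[idx], k=1)
    return bool((dists <= d).mean() >= fraction_needed)


class _FeatureSampler:
    """Draw random query features from a pruned pair set.

    The first diagonal is drawn uniformly; the second is drawn among
    pairs whose midpoint lies within ``l_max`` of the first diagonal's
    midpoint, since only spatially overlapping pairs can intersect. This
    keeps the per-draw success rate high without biasing which local
    features are reachable.
    """

    def __init__(self, model: MarkerSet, pair_indices: np.ndarray, l_max: float,
                 ratio_margin: float) -> None:
        self.model = model
        self.pair_indices = pair_indices
        self.ratio_margin = ratio_margin
        pts = model.points
        self.midpoints = 0.5 * (pts[pair_indices[:, 0]] + pts[pair_indices[:, 1]])
        self.tree = cKDTree(self.midpoints) if len(pair_indices) else None
        self.l_max = l_max

    def sample(self, rng: np.random.Generator, attempts: int) -> Optional[InvariantFeature]:
        K = self.pair_indices.shape[0]
        if K < 2 or self.tree is None:
            return None
        for _ in range(attempts):
            k1 = int(rng.integers(0, K))
            nearby = self.tree.query_ball_point(self.midpoints[k1], r=self.l_max)
            if len(nearby) < 2:
                continue
            k2 = int(nearby[rng.integers(0, len(nearby))])
            if k2 == k1:
                continue
            ab = tuple(self.pair_indices[k1])
            cd = tuple(self.pair_indices[k2])
            if len({*ab, *cd}) != 4:
                continue
            try:
                return make_feature(self.model, ab, cd, ratio_margin=self.ratio_margin)
            except FeatureRejected:
                continue
        return None


def _local_optimize(
    scene: MarkerSet,
    model: MarkerSet,
    transform: AffineTransform2D,
    corr: Correspondence,
    d: float,
    max_rounds: int = 8,
) -> tuple[AffineTransform2D, Correspondence]:
    """Coarse-to-fine refit-recount of a consensus set.

    A hypothesis estimated from one local 4-point feature is accurate
    only near the feature (localization noise leverages across the field
    of view), so its raw consensus undercounts, and refitting at the
    final threshold alone can lock onto one region whose fit extrapolates
    poorly. Annealing the count threshold (8d, 4d, 2d, then d) lets each
    refit see points the previous transform placed almost right, pulling
    the fit from a regional to the global optimum; the returned consensus
    is always counted at ``d``.
    """
    for threshold in (8.0 * d, 4.0 * d, 2.0 * d, d):
        for _ in range(max_rounds):
            if len(corr) < 3:
                return transform, corr
            try:
                refit = estimate_affine_lsq(
                    model.points[corr.model_indices], scene.points[corr.scene_indices]
                )
            except DegenerateGeometryError:
                return transform, corr
            if not refit.is_invertible:
                return transform, corr
            new_corr = count_congruent(scene, apply_affine(refit, model), threshold)
            if len(new_corr) < len(corr) and threshold == d:
                return transform, corr
            grew = len(new_corr) > len(corr)
            transform, corr = refit, new_corr
            if not grew:
                break
    corr = count_congruent(scene, apply_affine(transform, model), d)
    return transform, corr


def estimate_initial_transform(
    scene: MarkerSet,
    model: MarkerSet,
    params: RansacParams,
    rng: Optional[np.random.Generator] = None,
) -> RansacResult:
    """RANSAC estimate of the affine transform mapping ``model`` onto ``scene``.

    Raises
    ------
    NoTransformFoundError
        If no hypothesis ever aligns at least 4 point pairs.
    """
    if len(scene) < 4 or len(model) < 4:
        raise NoTransformFoundError("need at least 4 markers in each set")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    stats_scene = neighbor_distance_stats(scene, l_min=params.l_min)
    stats_model = neighbor_distance_stats(model, l_min=params.l_min)
    if params.l_max is not None:
        # explicit window override: locality is a scalability heuristic and
        # can be released on small sets
        stats_scene = NeighborStats(
            stats_scene.l_avg, stats_scene.l_sdv, params.l_max, params.l_min
        )
        stats_model = NeighborStats(
            stats_model.l_avg, stats_model.l_sdv, params.l_max, params.l_min
        )
    pairs_scene = prune_pairs(scene, stats_scene)
    pairs_model = prune_pairs(model, stats_model)
    if len(pairs_scene) == 0 or len(pairs_model) < 2:
        raise NoTransformFoundError("min&max rule left too few point pairs")

    scene_tree = cKDTree(scene.points)
    sampler = _FeatureSampler(
        model, pairs_model.indices, stats_model.l_max, params.ratio_margin
    )
    n_min = min(len(scene), len(model))
    d = float(params.d)
    best_corr: Optional[Correspondence] = None
    best_transform: Optional[AffineTransform2D] = None
    c_max = 0
    bound = update_iteration_bound(params.p_s, params.initial_p_g, 4, params.max_iterations)
    iterations = 0
    while iterations < min(bound, params.max_iterations):
        iterations += 1
        query = sampler.sample(rng, params.feature_attempts)
        if query is None:
            continue
        candidates = inquire_feature(
            query,
            pairs_scene,
            scene,
            beta_query_deg=model.tilt_angle,
            beta_scene_deg=scene.tilt_angle,
            delta=params.delta,
            xi=params.xi,
        )
        for cand in candidates:
            src = model.points[list(query.indices)]
            dst = scene.points[list(cand.scene_indices)]
            try:
                transform = estimate_affine_lsq(src, dst)
            except DegenerateGeometryError:
                continue
            if not transform.is_invertible:
                continue
            ty = apply_affine(transform, model)
            if not quick_randomized_check(
                scene, ty, d, params.quick_check_size,
                params.quick_check_fraction, rng, scene_tree=scene_tree,
            ):
                continue
            corr = count_congruent(scene, ty, d)
            if len(corr) < 4:
                continue
            # raw counts from a local 4-point fit undercount badly, so a
            # raw comparison against the optimized best would starve true
            # candidates; optimize first, compare after
            transform, corr = _local_optimize(scene, model, transform, corr, d)
            if len(corr) > c_max:
                c_max = len(corr)
                best_corr = corr
                best_transform = transform
                p_g = min(c_max / n_min, 1.0)
                bound = update_iteration_bound(params.p_s, p_g, 4, params.max_iterations)
                logger.debug(
                    "iteration %d: c_max=%d, p_g=%.3f, bound=%d",
                    iterations, c_max, p_g, bound,
                )

    if best_corr is None or c_max < 4:
        raise NoTransformFoundError(
            f"no reliable transform after {iterations} iterations (best consensus {c_max})"
        )

    # Final refit over the full consensus set for a cleaner transform.
    best_transform, best_corr = _local_optimize(
        scene, model, best_transform, best_corr, d
    )
    logger.info(
        "stage one: %d iterations, consensus %d/%d pairs",
        iterations, len(best_corr), n_min,
    )
    return RansacResult(
        transform=best_transform,
        c_max=len(best_corr),
        correspondence=best_corr,
        iterations_used=iterations,
    )
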