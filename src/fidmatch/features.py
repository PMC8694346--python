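"""Locally constrained 4-point affine-invariant features.

Four markers ``a, b, c, d`` whose segments ``ab`` and ``cd`` (the feature's
*diagonals*) intersect at an interior point ``e`` define two division
ratios ``r1 = |a - e| / |a - b|`` and ``r2 = |c - e| / |c - d|`` that are
preserved by every invertible affine map. Searching for a congruent 4-point
subset in another micrograph therefore reduces to hypothesising where the
intersection ``e`` would fall on each candidate point pair and looking for
coincidences between the ``r1``- and ``r2``-generated hypotheses.

Two local constraints keep the search small and numerically stable:

* the *min&max rule* retains only point pairs whose length lies in
  ``[l_min, l_max]``, with ``l_max = 1.5 * l_avg + l_sdv`` derived from the
  nearest-neighbour distance distribution, and ``l_min`` bounding the
  localization-induced ratio error from below;
* an area-ratio test: corresponding planar shapes on micrographs tilted at
  ``beta1`` and ``beta2`` have area ratio close to
  ``cos(beta1) / cos(beta2)``, which is rotation- and translation-invariant
  and cheap to check before any transform is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import MarkerSet

__all__ = [
    "FeatureRejected",
    "NeighborStats",
    "PairSet",
    "InvariantFeature",
    "CandidateMatch",
    "neighbor_distance_stats",
    "prune_pairs",
    "make_feature",
    "area_ratio_ok",
    "inquire_feature",
]


class FeatureRejected(ValueError):
    """Raised when four points do not form a usable invariant feature."""


@dataclass(frozen=True)
class NeighborStats:
    """Summary of the nearest-neighbour distance distribution of one set."""

    l_avg: float
    l_sdv: float
    l_max: float
    l_min: float


@dataclass
class PairSet:
    """Point pairs of one marker set surviving the min&max length rule."""

    indices: np.ndarray  # (K, 2) int, i < j
    lengths: np.ndarray  # (K,) pixels

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int).reshape(-1, 2)
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return self.indices.shape[0]


@dataclass(frozen=True)
class InvariantFeature:
    """A 4-point feature: indices, division ratios, intersection and area."""

    a: int
    b: int
    c: int
    d: int
    r1: float
    r2: float
    intersection: tuple[float, float]
    area: float

    @property
    def indices(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class CandidateMatch:
    """A hypothesised scene 4-point subset matching a query feature.

    ``scene_indices`` is aligned with the query's ``(a, b, c, d)`` order.
    """

    scene_indices: tuple[int, int, int, int]
    conflict_distance: float
    area_ratio: float


def neighbor_distance_stats(markers: MarkerSet, l_min: float = 0.0) -> NeighborStats:
    """Nearest-neighbour distance statistics and the derived length window.

    ``l_max = 1.5 * l_avg + l_sdv``; ``l_min`` is taken from configuration
    (it depends on marker size and pixel scale, not on the data).
    """
    pts = markers.points
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points for neighbour statistics")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    nn = dists[:, 1]
    l_avg = float(nn.mean())
    l_sdv = float(nn.std())
    l_max = 1.5 * l_avg + l_sdv
    if not 0.0 <= l_min:
        raise ValueError("l_min must be non-negative")
    return NeighborStats(l_avg=l_avg, l_sdv=l_sdv, l_max=l_max, l_min=float(l_min))


def prune_pairs(markers: MarkerSet, stats: NeighborStats) -> PairSet:
    """All unordered point pairs with length in ``[l_min, l_max]``."""
    pts = markers.points
    if pts.shape[0] < 2:
        return PairSet(np.empty((0, 2), dtype=int), np.empty(0))
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=stats.l_max, output_type="ndarray")
    if pairs.size == 0:
        return PairSet(np.empty((0, 2), dtype=int), np.empty(0))
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    lengths = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    keep = lengths >= stats.l_min
    return PairSet(pairs[keep], lengths[keep])


def make_feature(
    markers: MarkerSet,
    pair_ab: tuple[int, int],
    pair_cd: tuple[int, int],
    ratio_margin: float = 0.05,
    parallel_tol: float = 1e-9,
) -> InvariantFeature:
    """Build the invariant feature with diagonals ``ab`` and ``cd``.

    The intersection of the two infinite lines is computed analytically;
    the feature is rejected (``FeatureRejected``) when the diagonals are
    near-parallel or the intersection falls within ``ratio_margin`` of a
    diagonal endpoint, where the ratios become numerically unstable.
    """
    a, b = int(pair_ab[0]), int(pair_ab[1])
    c, d = int(pair_cd[0]), int(pair_cd[1])
    if len({a, b, c, d}) != 4:
        raise FeatureRejected("diagonals must not share endpoints")
    pts = markers.points
    pa, pb, pc, pd = pts[a], pts[b], pts[c], pts[d]
    u = pb - pa
    v = pd - pc
    cross = u[0] * v[1] - u[1] * v[0]
    norm = np.linalg.norm(u) * np.linalg.norm(v)
    if norm == 0 or abs(cross) < parallel_tol * norm:
        raise FeatureRejected("diagonals are parallel or degenerate")
    w = pc - pa
    r1 = (w[0] * v[1] - w[1] * v[0]) / cross
    r2 = (w[0] * u[1] - w[1] * u[0]) / cross
    lo, hi = ratio_margin, 1.0 - ratio_margin
    if not (lo < r1 < hi and lo < r2 < hi):
        raise FeatureRejected("intersection not interior to both diagonals")
    e = pa + r1 * u
    area = 0.5 * abs(cross)
    return InvariantFeature(
        a=a, b=b, c=c, d=d,
        r1=float(r1), r2=float(r2),
        intersection=(float(e[0]), float(e[1])),
        area=float(area),
    )


def area_ratio_ok(
    area_query: float,
    area_candidate: float,
    beta1_deg: float,
    beta2_deg: float,
    xi: float,
) -> bool:
    """Tilt-consistent area-ratio test with relaxation ``xi``.

    Accepts iff ``(1 - xi) * rho <= area_query / area_candidate
    <= (1 + xi) * rho`` with ``rho = cos(beta1) / cos(beta2)``, where
    ``beta1`` is the tilt of the micrograph the query feature comes from
    and ``beta2`` that of the candidate's micrograph.
    """
    if area_query <= 0 or area_candidate <= 0:
        raise ValueError("areas must be positive")
    if not (abs(beta1_deg) < 90 and abs(beta2_deg) < 90):
        raise ValueError("tilt angles must be in (-90, 90) degrees")
    rho = np.cos(np.deg2rad(beta1_deg)) / np.cos(np.deg2rad(beta2_deg))
    ratio = area_query / area_candidate
    return bool((1.0 - xi) * rho <= ratio <= (1.0 + xi) * rho)


def inquire_feature(
    query: InvariantFeature,
    pairs_scene: PairSet,
    scene: MarkerSet,
    beta_query_deg: float,
    beta_scene_deg: float,
    delta: float,
    xi: float,
) -> list[CandidateMatch]:
    """Find candidate scene subsets congruent to a query feature.

    For every pruned scene pair ``(i, j)`` the four hypothetical
    intersections ``e_r1(ij), e_r1(ji), e_r2(ij), e_r2(ji)`` are generated
    (each ratio admits two orientations of the pair). A k-d tree over the
    ``e_r2`` hypotheses is queried with every ``e_r1`` hypothesis; a hit
    within ``delta`` between hypotheses from index-disjoint pairs is a
    candidate, which must additionally pass the area-ratio test.

    The two diagonals of a feature must be distinct pairs, so hypotheses
    from the same pair are never matched to each other.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    K = len(pairs_scene)
    if K == 0:
        return []
    pts = scene.points
    i_idx = pairs_scene.indices[:, 0]
    j_idx = pairs_scene.indices[:, 1]
    pi = pts[i_idx]
    pj = pts[j_idx]
    # Orientation 0 maps (first, second) of the query diagonal onto (i, j);
    # orientation 1 onto (j, i).
    e_r1 = np.vstack([pi + query.r1 * (pj - pi), pj + query.r1 * (pi - pj)])
    e_r2 = np.vstack([pi + query.r2 * (pj - pi), pj + query.r2 * (pi - pj)])
    tree = cKDTree(e_r2)
    hits = tree.query_ball_point(e_r1, r=delta)
    out: list[CandidateMatch] = []
    for h1, matches in enumerate(hits):
        pair1 = h1 % K
        orient1 = h1 // K
        for h2 in sorted(matches):
            pair2 = h2 % K
            if pair2 == pair1:
                continue
            orient2 = h2 // K
            ab = (i_idx[pair1], j_idx[pair1]) if orient1 == 0 else (j_idx[pair1], i_idx[pair1])
            cd = (i_idx[pair2], j_idx[pair2]) if orient2 == 0 else (j_idx[pair2], i_idx[pair2])
            if len({ab[0], ab[1], cd[0], cd[1]}) != 4:
                continue
            pa, pb = pts[ab[0]], pts[ab[1]]
            pc, pd = pts[cd[0]], pts[cd[1]]
            u = pb - pa
            v = pd - pc
            area_cand = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
            if area_cand <= 0:
                continue
            if not area_ratio_ok(query.area, area_cand, beta_query_deg, beta_scene_deg, xi):
                continue
            dist = float(np.linalg.norm(e_r1[h1] - e_r2[h2]))
            out.append(
                CandidateMatch(
                    scene_indices=(int(ab[0]), int(ab[1]), int(cd[0]), int(cd[1])),
                    conflict_distance=dist,
                    area_ratio=float(query.area / area_cand),
                )
            )
    return out
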