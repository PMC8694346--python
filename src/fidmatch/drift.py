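"""Stage two: weighted-GMM EM refinement of a smooth drift field.

After the stage-one affine correction, residual misalignment comes from
beam-induced motion and sample deformation, which vary smoothly across the
field of view. The transformed model points ``y_m`` are treated as centres
of an isotropic Gaussian mixture generating the scene points ``x_n``, with
a fixed outlier mass ``w`` spread uniformly. The correction is a coherent
displacement field ``v(z) = sum_m w_m g(z, y_m)`` expanded on the Gaussian
kernel ``g(x, y) = exp(-||x - y||^2 / (2 beta^2))``, regularized by a
Tikhonov term so nearby markers drift together.

Each EM iteration:

* E-step: posterior responsibilities
  ``p_mn = exp(-||x_n - T(y_m)||^2 / (2 s2)) /
  (sum_k exp(-||x_n - T(y_k)||^2 / (2 s2)) + 2 pi s2 w M / ((1 - w) N))``;
* M-step: solve ``(G + lambda s2 d(P1)^{-1}) W = d(P1)^{-1} P X - Y`` for
  the kernel coefficients ``W``, update positions ``T = Y + G W`` and the
  variance ``s2 = (tr(X' d(P'1) X) - 2 tr((PX)' T) + tr(T' d(P1) T)) /
  (2 N_p)`` where ``N_p = sum_mn p_mn``.

Coordinates are jointly normalized (zero mean, unit RMS radius) before EM
so that the bandwidth and regularization defaults are dataset-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.special
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import Correspondence, MarkerSet, _as_points, count_congruent

__all__ = [
    "DriftParams",
    "RefinementResult",
    "pre_exclude_outliers",
    "gaussian_kernel_matrix",
    "e_step",
    "m_step_solve",
    "update_sigma2",
    "negative_log_likelihood",
    "refine_drift",
]

logger = logging.getLogger(__name__)

_ROW_SUM_FLOOR = 1e-12


class RefinementFailedError(RuntimeError):
    """Stage-two refinement could not be run on the given inputs."""


@dataclass
class DriftParams:
    """EM refinement parameters.

    ``beta_kernel`` and ``lambda_reg`` are expressed in normalized
    coordinates (unit RMS radius); ``w`` is the fixed outlier mixture
    weight; ``kappa_exclude`` scales the congruence threshold ``d`` for
    the pre-exclusion of gross outliers.
    """

    w: float = 0.1
    lambda_reg: float = 2.0
    beta_kernel: float = 0.5
    max_em_iterations: int = 150
    tol: float = 1e-8
    kappa_exclude: float = 5.0
    sigma2_min: float = 1e-10

    def __post_init__(self) -> None:
        if not 0.0 <= self.w < 1.0:
            raise ValueError("outlier weight w must be in [0, 1)")
        if self.lambda_reg <= 0 or self.beta_kernel <= 0:
            raise ValueError("lambda_reg and beta_kernel must be positive")


@dataclass
class RefinementResult:
    """Refined model positions, per-point drift and final correspondence."""

    refined_model_points: MarkerSet
    drift_vectors: np.ndarray
    correspondence: Correspondence
    em_iterations: int
    sigma2: float
    nll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def pre_exclude_outliers(
    scene: MarkerSet,
    transformed_model: MarkerSet,
    d: float,
    kappa_exclude: float,
) -> tuple[MarkerSet, MarkerSet, np.ndarray, np.ndarray]:
    """Drop points whose nearest cross-set neighbour exceeds ``kappa * d``.

    Returns filtered scene and model sets plus index maps back into the
    original sets. Raises ``RefinementFailedError`` with fewer than 4
    survivors on either side.
    """
    xp = scene.points
    yp = transformed_model.points
    if xp.shape[0] == 0 or yp.shape[0] == 0:
        raise RefinementFailedError("empty point set")
    radius = kappa_exclude * d
    dx, _ = cKDTree(yp).query(xp, k=1)
    dy, _ = cKDTree(xp).query(yp, k=1)
    keep_x = np.flatnonzero(dx <= radius)
    keep_y = np.flatnonzero(dy <= radius)
    if keep_x.size < 4 or keep_y.size < 4:
        raise RefinementFailedError(
            f"pre-exclusion left {keep_x.size} scene / {keep_y.size} model points"
        )
    return (
        scene.with_points(xp[keep_x]),
        transformed_model.with_points(yp[keep_y]),
        keep_x,
        keep_y,
    )


def gaussian_kernel_matrix(model, beta_kernel: float) -> np.ndarray:
    """Gaussian kernel Gram matrix ``G_ij = exp(-||y_i - y_j||^2 / (2 b^2))``."""
    if beta_kernel <= 0:
        raise ValueError("beta_kernel must be positive")
    yp = _as_points(model)
    sq = cdist(yp, yp, "sqeuclidean")
    return np.exp(-0.5 * sq / beta_kernel**2)


def e_step(scene, transformed_model, sigma2: float, w: float) -> np.ndarray:
    """Posterior responsibilities ``P`` (M x N) of model points for scene points.

    Column ``n`` sums to 1 when ``w = 0`` and to at most 1 otherwise, the
    missing mass being the outlier posterior. Computed with a per-column
    shift so small ``sigma2`` does not underflow.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    xp = _as_points(scene)
    yp = _as_points(transformed_model)
    m, n = yp.shape[0], xp.shape[0]
    sq = cdist(yp, xp, "sqeuclidean")  # (M, N)
    if w == 0.0:
        c = 0.0
    else:
        c = 2.0 * np.pi * sigma2 * (w / (1.0 - w)) * (m / n)
    shift = sq.min(axis=0)  # (N,)
    with np.errstate(over="ignore", under="ignore"):
        num = np.exp(-(sq - shift) / (2.0 * sigma2))
        denom = num.sum(axis=0) + c * np.exp(shift / (2.0 * sigma2))
    p = num / denom
    # exp overflow in the outlier term means the column is pure outlier
    p[:, ~np.isfinite(denom)] = 0.0
    return p


def m_step_solve(
    scene,
    model,
    posterior: np.ndarray,
    lambda_reg: float,
    sigma2: float,
    kernel: np.ndarray,
) -> np.ndarray:
    """Solve ``(G + lambda s2 d(P1)^{-1}) W = d(P1)^{-1} P X - Y`` for ``W``.

    Row sums of the posterior are floored at 1e-12 before inversion so the
    system stays solvable when a model point collects no mass.
    """
    xp = _as_points(scene)
    yp = _as_points(model)
    p1 = np.maximum(posterior.sum(axis=1), _ROW_SUM_FLOOR)
    dinv = 1.0 / p1
    lhs = kernel + lambda_reg * sigma2 * np.diag(dinv)
    rhs = dinv[:, None] * (posterior @ xp) - yp
    try:
        w_mat = scipy.linalg.solve(lhs, rhs, assume_a="pos")
    except np.linalg.LinAlgError:
        w_mat = scipy.linalg.solve(lhs, rhs)
    if not np.all(np.isfinite(w_mat)):
        raise RefinementFailedError("singular M-step system")
    return w_mat


def update_sigma2(scene, refined, posterior: np.ndarray, sigma2_min: float = 1e-10) -> float:
    """Variance update from the three weighted trace terms, floored."""
    xp = _as_points(scene)
    tp = _as_points(refined)
    n_p = posterior.sum()
    if n_p <= 0:
        raise ValueError("degenerate posterior: total mass is zero")
    pt1 = posterior.sum(axis=0)  # (N,)
    p1 = posterior.sum(axis=1)  # (M,)
    t1 = float(np.einsum("n,ni,ni->", pt1, xp, xp))
    t2 = float(np.einsum("mn,ni,mi->", posterior, xp, tp))
    t3 = float(np.einsum("m,mi,mi->", p1, tp, tp))
    sigma2 = (t1 - 2.0 * t2 + t3) / (2.0 * n_p)
    return max(sigma2, sigma2_min)


def negative_log_likelihood(scene, refined, sigma2: float, w: float) -> float:
    """Mixture negative log-likelihood of the scene under current positions."""
    xp = _as_points(scene)
    tp = _as_points(refined)
    m, n = tp.shape[0], xp.shape[0]
    sq = cdist(tp, xp, "sqeuclidean")
    log_gauss = -sq / (2.0 * sigma2) - np.log(2.0 * np.pi * sigma2) + np.log((1.0 - w) / m)
    log_mix = scipy.special.logsumexp(log_gauss, axis=0)
    if w > 0:
        log_mix = np.logaddexp(log_mix, np.log(w / n))
    return float(-log_mix.sum())


def _normalize(xp: np.ndarray, yp: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    allp = np.vstack([xp, yp])
    mu = allp.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((allp - mu) ** 2, axis=1))))
    if scale <= 0:
        scale = 1.0
    return (xp - mu) / scale, (yp - mu) / scale, mu, scale


def refine_drift(
    scene: MarkerSet,
    transformed_model: MarkerSet,
    d: float,
    params: Optional[DriftParams] = None,
) -> RefinementResult:
    """Run the EM drift refinement and extract the final correspondence.

    ``transformed_model`` must already carry the stage-one affine. The
    variance is initialized from the mean squared cross-distance,
    ``s2_0 = sum_mn ||x_n - y_m||^2 / (2 M N)``, and EM stops when the
    relative change of ``s2`` drops below ``tol``, the iteration cap is
    hit, or ``s2`` has grown for 5 consecutive iterations (divergence
    guard; the best state seen is returned).
    """
    if params is None:
        params = DriftParams()
    xp = scene.points
    yp = transformed_model.points
    if xp.shape[0] == 0 or yp.shape[0] == 0:
        raise RefinementFailedError("empty point set")
    xn, yn, mu, scale = _normalize(xp, yp)
    m, n = yn.shape[0], xn.shape[0]
    kernel = gaussian_kernel_matrix(yn, params.beta_kernel)
    sigma2 = float(cdist(yn, xn, "sqeuclidean").sum() / (2.0 * m * n))
    sigma2 = max(sigma2, params.sigma2_min)

    tn = yn.copy()
    w_mat = np.zeros_like(yn)
    best = (sigma2, tn, w_mat)
    best_obj = np.inf
    nll_trace = []
    objective_trace = []
    grew = 0
    iterations = 0
    for iterations in range(1, params.max_em_iterations + 1):
        posterior = e_step(xn, tn, sigma2, params.w)
        if posterior.sum() <= 0:
            break
        w_mat = m_step_solve(xn, yn, posterior, params.lambda_reg, sigma2, kernel)
        tn = yn + kernel @ w_mat
        sigma2_new = update_sigma2(xn, tn, posterior, params.sigma2_min)
        nll = negative_log_likelihood(xn, tn, sigma2_new, params.w)
        penalty = 0.5 * params.lambda_reg * float(np.sum(w_mat * (kernel @ w_mat)))
        obj = nll + penalty
        nll_trace.append(nll)
        objective_trace.append(obj)
        if obj < best_obj:
            best_obj = obj
            best = (sigma2_new, tn.copy(), w_mat.copy())
        if sigma2_new > sigma2:
            grew += 1
            if grew >= 5:
                logger.debug("EM variance grew 5 iterations in a row; stopping")
                sigma2, tn, w_mat = best
                break
        else:
            grew = 0
        rel_change = abs(sigma2_new - sigma2) / max(sigma2, params.sigma2_min)
        sigma2 = sigma2_new
        if rel_change < params.tol:
            break

    drift_norm = tn - yn
    refined_points = tn * scale + mu
    drift_vectors = drift_norm * scale
    refined = transformed_model.with_points(refined_points)
    correspondence = count_congruent(scene, refined, d)
    logger.info(
        "stage two: %d EM iterations, sigma2=%.3g (normalized), %d pairs",
        iterations, sigma2, len(correspondence),
    )
    return RefinementResult(
        refined_model_points=refined,
        drift_vectors=drift_vectors,
        correspondence=correspondence,
        em_iterations=iterations,
        sigma2=sigma2,
        nll_trace=np.asarray(nll_trace),
        objective_trace=np.asarray(objective_trace),
    )
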