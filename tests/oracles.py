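"""Independent brute-force oracles used to validate the fast implementations.

Every function here deliberately avoids the code paths it checks: scalar
loops instead of vectorized linear algebra, exhaustive scans instead of
k-d trees, full enumeration instead of randomized search.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import maximum_bipartite_matching

from fidmatch.features import area_ratio_ok
from fidmatch.geometry import MarkerSet, count_congruent


def scalar_apply_affine(A, t, points):
    """Per-point scalar-loop affine evaluation."""
    out = []
    for x, y in points:
        out.append(
            (
                A[0][0] * x + A[0][1] * y + t[0],
                A[1][0] * x + A[1][1] * y + t[1],
            )
        )
    return np.asarray(out)


def normal_equations_affine(src, dst):
    """Affine least squares via explicitly assembled normal equations."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    design = np.hstack([src, np.ones((len(src), 1))])
    gram = design.T @ design
    coef = np.linalg.solve(gram, design.T @ dst)
    return coef[:2].T, coef[2]


def max_bipartite_count(scene_pts, model_pts, d):
    """Maximum-cardinality one-to-one matching under distance threshold."""
    scene_pts = np.asarray(scene_pts, float)
    model_pts = np.asarray(model_pts, float)
    diff = model_pts[:, None, :] - scene_pts[None, :, :]
    adj = (np.einsum("mns,mns->mn", diff, diff) <= d * d).astype(int)
    graph = scipy.sparse.csr_matrix(adj)
    matching = maximum_bipartite_matching(graph, perm_type="column")
    return int((matching >= 0).sum())


def exhaustive_nn_stats(points):
    """Nearest-neighbour mean/std by an O(n^2) scan."""
    points = np.asarray(points, float)
    nn = []
    for i in range(len(points)):
        best = np.inf
        for j in range(len(points)):
            if i == j:
                continue
            best = min(best, float(np.hypot(*(points[i] - points[j]))))
        nn.append(best)
    return float(np.mean(nn)), float(np.std(nn))


def brute_force_pairs(points, l_min, l_max):
    """All index pairs with length inside the window, by a double loop."""
    points = np.asarray(points, float)
    out = []
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            length = float(np.hypot(*(points[i] - points[j])))
            if l_min <= length <= l_max:
                out.append((i, j))
    return sorted(out)


def brute_force_inquire(query, pair_indices, scene_pts, beta_q, beta_s, delta, xi):
    """All ordered pair-pair hypotheses, with both filters, by full scan."""
    scene_pts = np.asarray(scene_pts, float)
    found = []
    K = len(pair_indices)
    for k1 in range(K):
        i1, j1 = pair_indices[k1]
        for o1 in range(2):
            a, b = (i1, j1) if o1 == 0 else (j1, i1)
            e1 = scene_pts[a] + query.r1 * (scene_pts[b] - scene_pts[a])
            for k2 in range(K):
                if k2 == k1:
                    continue
                i2, j2 = pair_indices[k2]
                for o2 in range(2):
                    c, dd = (i2, j2) if o2 == 0 else (j2, i2)
                    if len({a, b, c, dd}) != 4:
                        continue
                    e2 = scene_pts[c] + query.r2 * (scene_pts[dd] - scene_pts[c])
                    if float(np.hypot(*(e1 - e2))) > delta:
                        continue
                    u = scene_pts[b] - scene_pts[a]
                    v = scene_pts[dd] - scene_pts[c]
                    area = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
                    if area <= 0:
                        continue
                    if not area_ratio_ok(query.area, area, beta_q, beta_s, xi):
                        continue
                    found.append((int(a), int(b), int(c), int(dd)))
    return sorted(found)


def scalar_e_step(scene_pts, model_pts, sigma2, w):
    """Posterior responsibilities by direct scalar evaluation."""
    X = np.asarray(scene_pts, float)
    Y = np.asarray(model_pts, float)
    M, N = len(Y), len(X)
    P = np.zeros((M, N))
    for n in range(N):
        terms = [
            np.exp(-np.sum((X[n] - Y[m]) ** 2) / (2 * sigma2)) for m in range(M)
        ]
        if w == 0:
            c = 0.0
        else:
            c = 2 * np.pi * sigma2 * (w / (1 - w)) * (M / N)
        denom = sum(terms) + c
        for m in range(M):
            P[m, n] = terms[m] / denom
    return P


def scalar_sigma2(scene_pts, refined_pts, P):
    """Variance update from the three trace terms, scalar loops."""
    X = np.asarray(scene_pts, float)
    T = np.asarray(refined_pts, float)
    M, N = P.shape
    n_p = P.sum()
    t1 = sum(P[:, n].sum() * float(X[n] @ X[n]) for n in range(N))
    t2 = sum(P[m, n] * float(X[n] @ T[m]) for m in range(M) for n in range(N))
    t3 = sum(P[m, :].sum() * float(T[m] @ T[m]) for m in range(M))
    return (t1 - 2 * t2 + t3) / (2 * n_p)


def scalar_kernel(model_pts, beta):
    """Gaussian kernel matrix by element-wise evaluation."""
    Y = np.asarray(model_pts, float)
    M = len(Y)
    G = np.zeros((M, M))
    for i in range(M):
        for j in range(M):
            G[i, j] = np.exp(-np.sum((Y[i] - Y[j]) ** 2) / (2 * beta**2))
    return G


def enumeration_max_congruent(scene: MarkerSet, model: MarkerSet, d: float) -> int:
    """Maximal congruent-set size over all exact 3-point-correspondence
    transforms, by exhaustive enumeration (the O(M^3 N^3) baseline).

    A per-transform upper bound (count of model points with any scene
    point within d) prunes the exact greedy count without affecting the
    maximum.
    """
    xp, yp = scene.points, model.points
    N, M = len(xp), len(yp)
    best = 0
    dst_triples = np.array(list(permutations(range(N), 3)))
    dst_pts = xp[dst_triples]
    for s in combinations(range(M), 3):
        S = np.hstack([yp[list(s)], np.ones((3, 1))])
        if abs(np.linalg.det(S)) < 1e-9:
            continue
        Sinv = np.linalg.inv(S)
        coefs = np.einsum("ij,tjk->tik", Sinv, dst_pts)
        A = coefs[:, :2, :].transpose(0, 2, 1)
        t = coefs[:, 2, :]
        TY = np.einsum("tab,mb->tma", A, yp) + t[:, None, :]
        diff = TY[:, :, None, :] - xp[None, None, :, :]
        dist2 = np.einsum("tmns,tmns->tmn", diff, diff)
        ub = (dist2 <= d * d).any(axis=2).sum(axis=1)
        for ti in np.argsort(-ub):
            if ub[ti] <= best:
                break
            c = len(count_congruent(scene, MarkerSet(TY[ti]), d))
            if c > best:
                best = c
    return best


def _admits_feature(points) -> bool:
    """True if some disjoint pair-pair of the points forms a valid
    4-point feature (internally intersecting diagonals)."""
    from itertools import combinations

    from fidmatch.features import FeatureRejected, make_feature

    ms = MarkerSet(points)
    idx = list(combinations(range(len(points)), 2))
    for p1, p2 in combinations(idx, 2):
        if len({*p1, *p2}) != 4:
            continue
        try:
            make_feature(ms, p1, p2)
            return True
        except FeatureRejected:
            continue
    return False


def planted_tiny_instance(rng, n_inliers=6, n_outliers=2, d=1.0):
    """An 8-ish point pair with a planted near-rigid affine on the inliers.

    Outliers are rejection-sampled to stay several thresholds away from
    every point that could pair with them, so the maximal congruent set
    is unambiguously the planted one. Inlier configurations are redrawn
    until they admit at least one 4-point feature: a feature-driven
    search cannot express a solution on a point set whose diagonals never
    cross, so such draws fall outside the method's contract.
    """
    base = rng.uniform(0, 100, (n_inliers, 2))
    while not _admits_feature(base):
        base = rng.uniform(0, 100, (n_inliers, 2))
    ang = rng.uniform(-0.2, 0.2)
    s = rng.uniform(0.96, 1.04)
    A = s * np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    t = rng.uniform(-20, 20, 2)

    def far_points(k, refs, margin):
        out = []
        while len(out) < k:
            cand = rng.uniform(0, 100, 2)
            if min(np.linalg.norm(r - cand) for r in refs) > margin:
                out.append(cand)
        return out

    scene_out = far_points(n_outliers, list(base), 4 * d)
    scene_all = np.vstack([base] + [np.array(scene_out)]) if scene_out else base
    model_in = (base - t) @ np.linalg.inv(A).T
    model_out = []
    while len(model_out) < n_outliers:
        cand = rng.uniform(0, 100, 2)
        img = A @ cand + t
        if min(np.linalg.norm(p - img) for p in scene_all) > 8 * d:
            model_out.append(cand)
    model_all = np.vstack([model_in, np.array(model_out)])
    scene = MarkerSet(scene_all[rng.permutation(len(scene_all))])
    model = MarkerSet(model_all[rng.permutation(len(model_all))])
    return scene, model, (A, t)
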