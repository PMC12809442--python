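"""Independent oracles used by the test-suite and the acceptance script.

Each function here recomputes a quantity by a route deliberately different
from the library implementation (direct textbook formulas, stochastic
minimization, regular expressions), so agreement is evidence of correctness
rather than tautology.
"""

import re

import numpy as np
from scipy.spatial.transform import Rotation


def brute_force_fragment_rmsd(frag_a, frag_b, seed=0):
    """Minimum RMSD over rotations by quaternion search (no Kabsch).

    Coarse random sampling of unit quaternions followed by shrinking local
    refinement around the best candidate; resolves the optimal rotation to
    well below 1e-3 in quaternion space.
    """
    a = np.asarray(frag_a, float)
    b = np.asarray(frag_b, float)
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    rng = np.random.default_rng(seed)

    def batch_rmsd(quats):
        mats = Rotation.from_quat(quats).as_matrix()          # (m, 3, 3)
        rotated = np.einsum("mij,kj->mki", mats, b_c)          # (m, 4, 3)
        d = rotated - a_c[None]
        return np.sqrt(np.mean(np.sum(d * d, axis=2), axis=1))

    quats = rng.normal(size=(3000, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    r = batch_rmsd(quats)
    best_q = quats[np.argmin(r)]
    best = r.min()
    for scale in np.geomspace(0.3, 1e-4, 30):
        cand = best_q + rng.normal(scale=scale, size=(120, 4))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        r = batch_rmsd(cand)
        if r.min() < best:
            best = r.min()
            best_q = cand[np.argmin(r)]
    return float(best)


def descriptors_by_cosine_rule(window):
    """Fragment descriptors via an explicit coordinate-free route."""
    p = [np.asarray(x, float) for x in window]

    def dist(u, v):
        return float(sum((ui - vi) ** 2 for ui, vi in zip(u, v)) ** 0.5)

    d1 = dist(p[0], p[2])
    d2 = dist(p[0], p[3])
    d3 = dist(p[1], p[3])
    # signed height: volume of the tetrahedron over the area of the base
    u, v, w = p[1] - p[0], p[2] - p[0], p[3] - p[0]
    det = float(np.linalg.det(np.column_stack([u, v, w])))
    base = float(np.linalg.norm(np.cross(u, v)))
    h = det / base if base > 1e-10 else 0.0
    return d1, d2, d3, h


def chi2_by_formula(table):
    """Pearson χ² from the expected-counts definition."""
    t = np.asarray(table, float)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    return float(((t - expected) ** 2 / expected).sum())


def kruskal_h_by_ranks(groups):
    """Kruskal–Wallis H with tie correction, from the rank-sum definition."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        r_sum = ranks[start:start + k].sum()
        h += r_sum ** 2 / k
        start += k
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    return h / correction


def pearson_by_covariance(x, y):
    """Pearson r straight from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def runs_by_regex(calls):
    """(n_isolated, run lengths >= 2) of R_DC runs via regular expressions."""
    symbols = "".join(
        "D" if c == "R_DC" else "U" if c == "UNASSIGNED" else "C" for c in calls
    )
    lengths = [len(m.group()) for m in re.finditer(r"D+", symbols)]
    return sum(1 for l in lengths if l == 1), [l for l in lengths if l >= 2]


def two_sphere_exposed_area(r1, r2, d):
    """Analytic accessible area of sphere 1 partially occluded by sphere 2.

    Spheres of radius r1, r2 with centre distance d (overlapping,
    non-containing): the buried part of sphere 1 is a spherical cap of
    height h = r1 − (d² + r1² − r2²)/(2d), with area 2π r1 h.
    """
    if d >= r1 + r2:
        return 4.0 * np.pi * r1 ** 2
    h = r1 - (d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d)
    return 4.0 * np.pi * r1 ** 2 - 2.0 * np.pi * r1 * h
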