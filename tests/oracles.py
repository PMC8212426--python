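"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package's solvers: the TV
oracle is Condat's direct (non-iterative) algorithm, the full-objective
oracle is ADMM with a sparse LU solve, and the matching oracle is
maximum bipartite matching on the overlap graph.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu


def tv_exact(y: np.ndarray, lam: float) -> np.ndarray:
    """Exact 1-D total-variation denoising (Condat's direct method).

    Solves min_x 1/2 ||y-x||^2 + lam * sum |x_{i+1}-x_i| exactly in O(n).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return y.copy()
    if n == 1 or lam == 0:
        return y.copy()
    x = np.empty(n)
    k = k0 = km = kp = 0
    vmin = y[0] - lam
    vmax = y[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0:
                x[k0:km + 1] = vmin
                k = k0 = km = km + 1
                vmin = y[k]
                umin = lam
                umax = y[k] + lam - vmax
                continue
            if umax > 0:
                x[k0:kp + 1] = vmax
                k = k0 = kp = kp + 1
                vmax = y[k]
                umax = -lam
                umin = y[k] - lam - vmin
                continue
            x[k0:n] = vmin + umin / (k - k0 + 1)
            return x
        umin += y[k + 1] - vmin
        umax += y[k + 1] - vmax
        if umin < -lam:
            x[k0:km + 1] = vmin
            k = k0 = km = kp = km + 1
            vmin = y[k]
            vmax = y[k] + 2 * lam
            umin = lam
            umax = -lam
        elif umax > lam:
            x[k0:kp + 1] = vmax
            k = k0 = km = kp = kp + 1
            vmin = y[k] - 2 * lam
            vmax = y[k]
            umin = lam
            umax = -lam
        else:
            k += 1
            if umin >= lam:
                km = k
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
            if umax <= -lam:
                kp = k
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam


def admm_solve(y: np.ndarray, alpha: float, beta: float,
               rho: float = 1.0, iters: int = 20000) -> np.ndarray:
    """ADMM minimization of 1/2||y-x||^2 + alpha||D1 x||_1 + beta||D3 x||_1.

    Splitting z = [alpha D1; beta D3] x with scaled dual u; the x-update is
    a sparse LU solve of (I + rho D'D).  Converges to the global optimum of
    the convex objective.
    """
    from saccadekit.denoise import diff_operator

    y = np.asarray(y, dtype=float)
    n = len(y)
    blocks = []
    if alpha > 0:
        blocks.append(alpha * diff_operator(1, n))
    if beta > 0:
        blocks.append(beta * diff_operator(3, n))
    if not blocks:
        return y.copy()
    D = sparse.vstack(blocks).tocsc()
    lu = splu((sparse.eye(n) + rho * (D.T @ D)).tocsc())
    x = y.copy()
    z = D @ x
    u = np.zeros(D.shape[0])
    for _ in range(iters):
        x = lu.solve(y + rho * (D.T @ (z - u)))
        Dx = D @ x
        w = Dx + u
        z = np.sign(w) * np.maximum(np.abs(w) - 1.0 / rho, 0.0)
        u += Dx - z
    return x


def optimal_match_count(truth_intervals, detected_intervals) -> int:
    """Maximum one-to-one matching size by exhaustive enumeration.

    Intervals are (onset_s, offset_s) tuples; an edge exists when the
    intervals overlap with positive measure.  Intended for tiny instances
    (<= 4 events per list).
    """
    nt, nd = len(truth_intervals), len(detected_intervals)

    def overlaps(a, b):
        return min(a[1], b[1]) - max(a[0], b[0]) > 0

    best = 0
    for size in range(min(nt, nd), 0, -1):
        for tsub in itertools.combinations(range(nt), size):
            for dperm in itertools.permutations(range(nd), size):
                if all(overlaps(truth_intervals[i], detected_intervals[j])
                       for i, j in zip(tsub, dperm)):
                    return size
        if best:
            break
    return best
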