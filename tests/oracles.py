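"""Independent brute-force reference implementations used only by tests.

These deliberately mirror nothing of the package's internals: morphology by
explicit pixel loops / pairwise distances, GLCMs by enumerating ordered
cell pairs, BH by the textbook step-up recursion, OLS t-statistics from an
explicit QR solve.
"""

from __future__ import annotations

import numpy as np


def oracle_patch_glcm(qdata: np.ndarray, center: tuple[int, int, int],
                      n_levels: int) -> np.ndarray:
    """GLCM of the 3x3 axial patch by enumerating ordered cell pairs.

    For every ordered pair of distinct cells (a, b) inside the patch whose
    offset is one of the 8 unit directions, count (level_a, level_b) when
    both levels are foreground.
    """
    x, y, z = center
    patch = qdata[x - 1:x + 2, y - 1:y + 2, z]
    counts = np.zeros((n_levels, n_levels))
    cells = [(i, j) for i in range(3) for j in range(3)]
    for (ai, aj) in cells:
        for (bi, bj) in cells:
            if (ai, aj) == (bi, bj):
                continue
            if max(abs(ai - bi), abs(aj - bj)) != 1:
                continue  # not a distance-one neighbour in any direction
            la, lb = patch[ai, aj], patch[bi, bj]
            if la > 0 and lb > 0:
                counts[la - 1, lb - 1] += 1
    return counts


def oracle_haralick(p: np.ndarray) -> dict[str, float]:
    """Feature formulas evaluated by explicit double loops."""
    n = p.shape[0]
    contrast = energy = entropy = homog = 0.0
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            contrast += v * (i - j) ** 2
            energy += v * v
            if v > 0:
                entropy -= v * np.log(v)
            homog += v / (1 + abs(i - j))
    return {"contrast": contrast, "energy": energy, "entropy": entropy,
            "homog": homog}


def oracle_erode_2x2(mask: np.ndarray) -> np.ndarray:
    """Top-left-anchored 2x2 erosion by explicit loops."""
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy in (0, 1):
                for dx in (0, 1):
                    yy, xx = y + dy, x + dx
                    if yy >= h or xx >= w or not mask[yy, xx]:
                        ok = False
            out[y, x] = ok
    return out


def oracle_disk_dilation(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilation by the exact Euclidean disk via pairwise distances."""
    pts = np.argwhere(mask)
    out = np.zeros_like(mask, dtype=bool)
    if len(pts) == 0:
        return out
    h, w = mask.shape
    for y in range(h):
        for x in range(w):
            d2 = ((pts[:, 0] - y) ** 2 + (pts[:, 1] - x) ** 2).min()
            out[y, x] = d2 <= radius ** 2
    return out


def oracle_bh_stepup(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Textbook Benjamini-Hochberg: adjusted p-values and rejections."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj, adj <= 0.05


def oracle_ols_t(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray,
                                                        np.ndarray]:
    """(t-values, p-values) of OLS coefficients via an explicit QR solve."""
    from scipy import stats
    n, k = X.shape
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    dof = n - k
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(R.T @ R)
    t = beta / np.sqrt(np.diag(cov))
    p = 2 * stats.t.sf(np.abs(t), dof)
    return t, p
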