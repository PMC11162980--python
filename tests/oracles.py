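"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, recursion-free flood
fill, exhaustive triple enumeration) and shares no code with the package.
"""
from __future__ import annotations

import numpy as np


def brute_gldm(levels: np.ndarray, alpha: int = 0) -> tuple[dict, int]:
    """Dependence counts by direct neighbor enumeration.

    Returns ({(gray level, dependence size): count}, Nz); levels > 0 mark
    in-ROI voxels.
    """
    P: dict[tuple[int, int], int] = {}
    nx, ny, nz = levels.shape
    n_vox = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lv = levels[x, y, z]
                if lv <= 0:
                    continue
                n_vox += 1
                dep = 0
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if (dx, dy, dz) == (0, 0, 0):
                                continue
                            a, b, c = x + dx, y + dy, z + dz
                            if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz:
                                nb = levels[a, b, c]
                                if nb > 0 and abs(int(nb) - int(lv)) <= alpha:
                                    dep += 1
                key = (int(lv), dep + 1)
                P[key] = P.get(key, 0) + 1
    return P, n_vox


def flood_fill_zones(levels: np.ndarray) -> list[tuple[int, int]]:
    """(gray level, zone size) per 26-connected equal-level zone."""
    visited = np.zeros(levels.shape, dtype=bool)
    zones = []
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if levels[x, y, z] <= 0 or visited[x, y, z]:
                    continue
                lv = levels[x, y, z]
                stack = [(x, y, z)]
                visited[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                a, b, c = cx + dx, cy + dy, cz + dz
                                if (
                                    0 <= a < nx
                                    and 0 <= b < ny
                                    and 0 <= c < nz
                                    and not visited[a, b, c]
                                    and levels[a, b, c] == lv
                                ):
                                    visited[a, b, c] = True
                                    stack.append((a, b, c))
                zones.append((int(lv), size))
    return zones


def flood_fill_binary(mask: np.ndarray) -> np.ndarray:
    """26-connected component labels of a binary mask (0 = background)."""
    levels = mask.astype(np.int64)
    out = np.zeros(mask.shape, dtype=np.int64)
    next_label = 1
    nx, ny, nz = mask.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z] or out[x, y, z]:
                    continue
                stack = [(x, y, z)]
                out[x, y, z] = next_label
                while stack:
                    cx, cy, cz = stack.pop()
                    for dx in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dz in (-1, 0, 1):
                                a, b, c = cx + dx, cy + dy, cz + dz
                                if (
                                    0 <= a < nx
                                    and 0 <= b < ny
                                    and 0 <= c < nz
                                    and mask[a, b, c]
                                    and not out[a, b, c]
                                ):
                                    out[a, b, c] = next_label
                                    stack.append((a, b, c))
                next_label += 1
    return out


def onnela_clustering(A: np.ndarray) -> np.ndarray:
    """Weighted clustering by explicit triple enumeration.

    C_u = sum over pairs (v, w) of (w_uv w_uw w_vw)^(1/3) / (k_u (k_u - 1)),
    with weights normalized by the global maximum.
    """
    K = A.shape[0]
    wmax = A.max()
    W = A / wmax if wmax > 0 else A
    C = np.zeros(K)
    for u in range(K):
        k = int((A[u] > 0).sum())
        if k < 2:
            continue
        s = 0.0
        for v in range(K):
            for w in range(K):
                if v == u or w == u or v == w:
                    continue
                s += (W[u, v] * W[u, w] * W[v, w]) ** (1.0 / 3.0)
        C[u] = s / (k * (k - 1))
    return C


def _mi(a: np.ndarray, b: np.ndarray) -> float:
    vals_a, vals_b = np.unique(a), np.unique(b)
    n = a.size
    mi = 0.0
    for va in vals_a:
        for vb in vals_b:
            pj = np.mean((a == va) & (b == vb))
            if pj > 0:
                mi += pj * np.log(pj / (np.mean(a == va) * np.mean(b == vb)))
    return mi


def brute_mrmr(codes: list[np.ndarray], ycode: np.ndarray, k: int) -> list[int]:
    """Greedy MID mRMR on pre-discretized columns, explicit loops."""
    p = len(codes)
    rel = [_mi(c, ycode) for c in codes]
    selected: list[int] = []
    for _ in range(min(k, p)):
        best, best_score = None, -np.inf
        for j in range(p):
            if j in selected:
                continue
            if selected:
                red = np.mean([_mi(codes[j], codes[s]) for s in selected])
            else:
                red = 0.0
            score = rel[j] - red
            if score > best_score:
                best, best_score = j, score
        selected.append(best)
    return selected


def brute_rfe_order(X: np.ndarray, y: np.ndarray, fit_logistic) -> list[int]:
    """Backward elimination trace with an injected estimator factory:
    repeatedly refit and drop the alive column with the smallest |coef|
    (ties: the later column)."""
    alive = list(range(X.shape[1]))
    order = []
    while len(alive) > 1:
        coefs = np.abs(fit_logistic(X[:, alive], y))
        worst = None
        best_val = np.inf
        for pos, col in enumerate(alive):
            if coefs[pos] <= best_val:  # <= so later columns win ties
                best_val = coefs[pos]
                worst = pos
        order.append(alive.pop(worst))
    order.append(alive[0])
    return order
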