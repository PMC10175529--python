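"""Independent brute-force reference implementations for the texture
matrices and basic statistics.

Everything here is written as literal per-pixel / per-pair enumeration,
deliberately sharing no code with the package's vectorized builders.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def bf_glcm(levels: np.ndarray, ng: int, direction: tuple[int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts by explicit pair enumeration."""
    H, W = levels.shape
    dr, dc = direction
    P = np.zeros((ng, ng))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                a, b = levels[r, c], levels[r2, c2]
                if a > 0 and b > 0:
                    P[a - 1, b - 1] += 1
                    P[b - 1, a - 1] += 1
    return P


def bf_glrlm(levels: np.ndarray, ng: int, direction: tuple[int, int]) -> np.ndarray:
    """Run-length counts by explicit line walking."""
    H, W = levels.shape
    max_run = max(H, W)
    P = np.zeros((ng, max_run))
    seen = np.zeros((H, W), dtype=bool)
    dr, dc = direction
    for r0 in range(H):
        for c0 in range(W):
            # only start a walk at the beginning of each line
            pr, pc = r0 - dr, c0 - dc
            if 0 <= pr < H and 0 <= pc < W:
                continue
            r, c = r0, c0
            run_val, run_len = 0, 0
            while 0 <= r < H and 0 <= c < W:
                v = levels[r, c]
                if v == run_val and v > 0:
                    run_len += 1
                else:
                    if run_val > 0:
                        P[run_val - 1, run_len - 1] += 1
                    run_val, run_len = int(v), (1 if v > 0 else 0)
                seen[r, c] = True
                r, c = r + dr, c + dc
            if run_val > 0:
                P[run_val - 1, run_len - 1] += 1
    assert seen.all(), "line enumeration must visit every pixel once"
    return P


def bf_glszm(levels: np.ndarray, ng: int) -> dict[tuple[int, int], int]:
    """Zone (gray level, size) -> count via explicit 8-connected flood fill."""
    H, W = levels.shape
    visited = np.zeros((H, W), dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for r in range(H):
        for c in range(W):
            if levels[r, c] <= 0 or visited[r, c]:
                continue
            g = levels[r, c]
            stack = [(r, c)]
            visited[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGHBORS_8:
                    r2, c2 = rr + dr, cc + dc
                    if (0 <= r2 < H and 0 <= c2 < W and not visited[r2, c2]
                            and levels[r2, c2] == g):
                        visited[r2, c2] = True
                        stack.append((r2, c2))
            zones[(g, size)] = zones.get((g, size), 0) + 1
    return zones


def bf_glszm_matrix(levels: np.ndarray, ng: int, smax: int) -> np.ndarray:
    P = np.zeros((ng, smax))
    for (g, s), n in bf_glszm(levels, ng).items():
        P[g - 1, s - 1] += n
    return P


def bf_gldm(levels: np.ndarray, ng: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence counts P[i, j-1], j = 1 + #dependent in-ROI neighbors."""
    H, W = levels.shape
    P = np.zeros((ng, 9))
    for r in range(H):
        for c in range(W):
            v = levels[r, c]
            if v <= 0:
                continue
            dep = 0
            for dr, dc in NEIGHBORS_8:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < H and 0 <= c2 < W and levels[r2, c2] > 0:
                    if abs(int(levels[r2, c2]) - int(v)) <= alpha:
                        dep += 1
            P[v - 1, dep] += 1
    return P


def bf_ngtdm(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i) via per-pixel neighborhood means of in-ROI neighbors."""
    H, W = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for r in range(H):
        for c in range(W):
            v = levels[r, c]
            if v <= 0:
                continue
            nb = [levels[r + dr, c + dc] for dr, dc in NEIGHBORS_8
                  if 0 <= r + dr < H and 0 <= c + dc < W and levels[r + dr, c + dc] > 0]
            if not nb:
                continue
            n[v - 1] += 1
            s[v - 1] += abs(v - sum(nb) / len(nb))
    return n, s


def bf_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks with ties, by direct definition."""
    x = np.asarray(x, float)
    out = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        out[i] = less + (equal + 1) / 2.0
    return out


def random_masked_levels(rng: np.random.Generator, max_size: int = 8,
                         max_ng: int = 5, p_mask: float = 0.2) -> tuple[np.ndarray, int]:
    """Random discretized ROI: levels 1..ng with 0 marking out-of-ROI."""
    h = int(rng.integers(3, max_size + 1))
    w = int(rng.integers(3, max_size + 1))
    ng = int(rng.integers(1, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=(h, w))
    mask = rng.random((h, w)) >= p_mask
    if not mask.any():
        mask[h // 2, w // 2] = True
    levels = np.where(mask, levels, 0)
    return levels.astype(np.int64), ng
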