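"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as plain loops over voxels, separate
from the package's vectorized implementations, so the two code paths share
nothing but the definitions.
"""

from __future__ import annotations

import numpy as np

DIRS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]
OFFS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _inside(idx, shape) -> bool:
    return all(0 <= i < n for i, n in zip(idx, shape))


def oracle_glcm(lab: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    out = np.zeros((len(DIRS_13), n_levels, n_levels))
    for k, off in enumerate(DIRS_13):
        for idx in np.ndindex(*lab.shape):
            if not mask[idx]:
                continue
            j = tuple(i + o for i, o in zip(idx, off))
            if _inside(j, lab.shape) and mask[j]:
                a, b = lab[idx] - 1, lab[j] - 1
                out[k, a, b] += 1
                out[k, b, a] += 1
    return out


def oracle_glrlm(lab: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    mats = []
    max_len = max(lab.shape)
    for off in DIRS_13:
        P = np.zeros((n_levels, max_len))
        for idx in np.ndindex(*lab.shape):
            if not mask[idx]:
                continue
            prev = tuple(i - o for i, o in zip(idx, off))
            if _inside(prev, lab.shape) and mask[prev] and lab[prev] == lab[idx]:
                continue  # not a run start
            length = 1
            cur = idx
            while True:
                nxt = tuple(i + o for i, o in zip(cur, off))
                if _inside(nxt, lab.shape) and mask[nxt] and lab[nxt] == lab[idx]:
                    length += 1
                    cur = nxt
                else:
                    break
            P[lab[idx] - 1, length - 1] += 1
        mats.append(P)
    return mats


def oracle_glszm(lab: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    n_vox = int(mask.sum())
    P = np.zeros((n_levels, n_vox))
    seen = np.zeros(lab.shape, dtype=bool)
    for idx in np.ndindex(*lab.shape):
        if not mask[idx] or seen[idx]:
            continue
        level = lab[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFS_26:
                nb = tuple(i + o for i, o in zip(cur, off))
                if (
                    _inside(nb, lab.shape)
                    and mask[nb]
                    and not seen[nb]
                    and lab[nb] == level
                ):
                    seen[nb] = True
                    stack.append(nb)
        P[level - 1, size - 1] += 1
    return P


def oracle_ngtdm(lab: np.ndarray, mask: np.ndarray, n_levels: int):
    n = np.zeros(n_levels)
    s = np.zeros(n_levels)
    for idx in np.ndindex(*lab.shape):
        if not mask[idx]:
            continue
        nbs = []
        for off in OFFS_26:
            nb = tuple(i + o for i, o in zip(idx, off))
            if _inside(nb, lab.shape) and mask[nb]:
                nbs.append(lab[nb])
        if not nbs:
            continue
        g = lab[idx]
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(nbs) / len(nbs))
    return n, s


def oracle_gldm(lab: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    P = np.zeros((n_levels, 27))
    for idx in np.ndindex(*lab.shape):
        if not mask[idx]:
            continue
        dep = 0
        for off in OFFS_26:
            nb = tuple(i + o for i, o in zip(idx, off))
            if _inside(nb, lab.shape) and mask[nb] and abs(int(lab[nb]) - int(lab[idx])) <= alpha:
                dep += 1
        P[lab[idx] - 1, dep] += 1
    return P


def oracle_icc_a1(m: np.ndarray) -> float:
    """ICC(2,1) from explicitly accumulated sums of squares (loop-based)."""
    n, k = m.shape
    grand = sum(m[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_rows = 0.0
    for i in range(n):
        rm = sum(m[i]) / k
        ss_rows += k * (rm - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        cm = sum(m[i][j] for i in range(n)) / n
        ss_cols += n * (cm - grand) ** 2
    ss_tot = sum((m[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
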