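"""Texture-matrix feature families: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

All matrices are built in 3-D at distance 1 over the 13 unique direction
offsets of the 26-neighbourhood (GLCM and GLRLM are direction-averaged;
GLSZM, NGTDM and GLDM are direction-free by definition).  Voxels outside the
ROI never contribute to counts.  Gray levels are the integer labels produced
by :func:`conseg.features.preprocess.discretize`; formulas use the actual
label values of the levels present in the ROI, as the reference catalog does.

Each family exposes a matrix builder (useful for oracle testing) and a
feature function returning ``(values, invalid_names)``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "GLDM_NAMES",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "ngtdm_table",
    "gldm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]

_EPS = np.spacing(1.0)

# the 13 unique offsets: lexicographically positive half of the 26-neighbourhood
DIRECTIONS_13 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
OFFSETS_26 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)

GLCM_NAMES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
]

GLRLM_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]

GLSZM_NAMES = [
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
]

NGTDM_NAMES = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]

GLDM_NAMES = [
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]


def _crop(labels: np.ndarray, mask: np.ndarray, pad: int = 1):
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return labels[sl], mask[sl]


def _shift_slices(off, shape):
    """Slices (sl_a, sl_b) so arr[sl_b] is the +off neighbour of arr[sl_a]."""
    sl_a, sl_b = [], []
    for d, n in zip(off, shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return tuple(sl_a), tuple(sl_b)


def _shift_view(arr: np.ndarray, off):
    """Pair of views (a, b) such that b is the +off neighbour of a."""
    sl_a, sl_b = _shift_slices(off, arr.shape)
    return arr[sl_a], arr[sl_b]


# ---------------------------------------------------------------- GLCM


def glcm_matrices(labels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-direction symmetric co-occurrence count matrices, shape (13, Ng, Ng)."""
    labels, mask = _crop(labels, mask)
    out = np.zeros((len(DIRECTIONS_13), n_levels, n_levels), dtype=np.float64)
    lab = np.where(mask, labels, 0)
    for k, off in enumerate(DIRECTIONS_13):
        a, b = _shift_view(lab, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        pairs = a[valid] * (n_levels + 1) + b[valid]
        cnt = np.bincount(pairs, minlength=(n_levels + 1) ** 2).reshape(
            n_levels + 1, n_levels + 1
        )[1:, 1:]
        out[k] = cnt + cnt.T
    return out


def _glcm_features_single(P: np.ndarray, levels: np.ndarray) -> dict[str, float]:
    """Features of one normalized symmetric GLCM restricted to present levels."""
    ng = len(levels)
    i = levels[:, None].astype(np.float64)
    j = levels[None, :].astype(np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float((levels * px).sum())
    uy = float((levels * py).sum())
    sigx = float(np.sqrt(((levels - ux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((levels - uy) ** 2 * py).sum()))

    # diagonal (difference) and cross-diagonal (sum) distributions
    kdiff = np.abs(i - j)
    ksum = i + j
    diff_vals = np.unique(kdiff)
    pxmy = np.array([P[kdiff == k].sum() for k in diff_vals])
    sum_vals = np.unique(ksum)
    pxpy = np.array([P[ksum == k].sum() for k in sum_vals])

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((i * j * P).sum())
    out["JointAverage"] = ux
    out["ClusterProminence"] = float((((i + j - ux - uy) ** 4) * P).sum())
    out["ClusterShade"] = float((((i + j - ux - uy) ** 3) * P).sum())
    out["ClusterTendency"] = float((((i + j - ux - uy) ** 2) * P).sum())
    out["Contrast"] = float((((i - j) ** 2) * P).sum())
    if sigx > 0 and sigy > 0:
        out["Correlation"] = (out["Autocorrelation"] - ux * uy) / (sigx * sigy)
    else:
        out["Correlation"] = np.nan
    da = float((diff_vals * pxmy).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = float(-(pxmy * np.log2(pxmy + _EPS)).sum())
    out["DifferenceVariance"] = float((((diff_vals - da) ** 2) * pxmy).sum())
    out["JointEnergy"] = float((P**2).sum())
    hxy = float(-(P * np.log2(P + _EPS)).sum())
    out["JointEntropy"] = hxy
    pxpy_outer = px[:, None] * py[None, :]
    hxy1 = float(-(P * np.log2(pxpy_outer + _EPS)).sum())
    hxy2 = float(-(pxpy_outer * np.log2(pxpy_outer + _EPS)).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    div = max(hx, hy)
    out["Imc1"] = (hxy - hxy1) / div if div > 0 else np.nan
    out["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if ng > 1 else np.nan
    out["Id"] = float((P / (1.0 + kdiff)).sum())
    out["Idm"] = float((P / (1.0 + kdiff**2)).sum())
    out["Idmn"] = float((P / (1.0 + (kdiff / ng) ** 2)).sum())
    out["Idn"] = float((P / (1.0 + kdiff / ng)).sum())
    offdiag = kdiff > 0
    out["InverseVariance"] = float((P[offdiag] / kdiff[offdiag] ** 2).sum()) if offdiag.any() else 0.0
    out["MaximumProbability"] = float(P.max())
    out["SumAverage"] = float((sum_vals * pxpy).sum())
    out["SumEntropy"] = float(-(pxpy * np.log2(pxpy + _EPS)).sum())
    out["SumSquares"] = float((((i - ux) ** 2) * P).sum())
    # maximal correlation coefficient
    if ng == 1:
        out["MCC"] = 1.0
    else:
        nz = px > 0
        # Q[i,j] = sum_k P[i,k] * P[j,k] / (px[i] * py[k])
        Qn = (P[nz][:, nz] / px[nz][:, None]) @ (P[nz][:, nz] / py[nz][None, :]).T
        try:
            eig = np.sort(np.abs(np.linalg.eigvals(Qn)))
            out["MCC"] = float(np.sqrt(np.clip(eig[-2], 0.0, 1.0))) if len(eig) > 1 else 1.0
        except np.linalg.LinAlgError:
            out["MCC"] = np.nan
    return out


_GLCM_CORRELATION_TYPE = {"Correlation", "MCC", "Imc1", "Imc2"}


def glcm_features(
    labels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[dict[str, float], set[str]]:
    """Direction-averaged GLCM features; empty directions are skipped."""
    mats = glcm_matrices(labels, mask, n_levels)
    present = np.unique(labels[mask])
    per_dir: list[dict[str, float]] = []
    for P in mats:
        tot = P.sum()
        if tot == 0:
            continue
        sub = P[np.ix_(present - 1, present - 1)] / tot
        per_dir.append(_glcm_features_single(sub, present.astype(np.float64)))
    invalid: set[str] = set()
    out: dict[str, float] = {}
    if not per_dir:
        return {k: np.nan for k in GLCM_NAMES}, set(GLCM_NAMES)
    for name in GLCM_NAMES:
        vals = np.array([d[name] for d in per_dir])
        if np.any(np.isnan(vals)):
            out[name] = np.nan
            invalid.add(name)
        else:
            out[name] = float(vals.mean())
    if len(present) == 1:
        invalid |= _GLCM_CORRELATION_TYPE
        for name in _GLCM_CORRELATION_TYPE:
            out[name] = np.nan
    return out, invalid


# ---------------------------------------------------------------- GLRLM


def glrlm_matrices(labels: np.ndarray, mask: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Per-direction run-length count matrices, each (Ng, max_run_length)."""
    labels, mask = _crop(labels, mask)
    lab = np.where(mask, labels, 0)
    mats: list[np.ndarray] = []
    max_len = max(mask.shape)
    for off in DIRECTIONS_13:
        # a run starts at an in-mask voxel whose backward neighbour along the
        # direction is absent or a different level
        back = tuple(-o for o in off)
        sl_a, sl_b = _shift_slices(back, lab.shape)
        same_back = np.zeros_like(mask)
        same_back[sl_a] = (lab[sl_a] > 0) & (lab[sl_a] == lab[sl_b])
        starts = (lab > 0) & ~same_back

        # walk forward from each start while the chain continues
        sl_a, sl_b = _shift_slices(off, lab.shape)
        same_fwd = np.zeros_like(mask)
        same_fwd[sl_a] = (lab[sl_a] > 0) & (lab[sl_a] == lab[sl_b])

        P = np.zeros((n_levels, max_len), dtype=np.float64)
        pos = np.argwhere(starts)
        if len(pos):
            lengths = np.ones(len(pos), dtype=np.int64)
            cur = pos.copy()
            alive = np.ones(len(pos), dtype=bool)
            while alive.any():
                idx = tuple(cur[alive].T)
                cont = same_fwd[idx]
                lengths[np.flatnonzero(alive)[cont]] += 1
                nxt = np.flatnonzero(alive)[cont]
                alive[:] = False
                alive[nxt] = True
                cur[alive] += np.asarray(off)[None, :]
            levels = lab[tuple(pos.T)]
            np.add.at(P, (levels - 1, lengths - 1), 1.0)
        mats.append(P)
    return mats


def _rlm_style_features(
    P: np.ndarray, levels: np.ndarray, n_p: int, names: dict[str, str]
) -> dict[str, float]:
    """Shared run/zone/dependence feature forms for a (level x size) matrix.

    ``levels`` are the gray values of the rows actually present; ``P`` must be
    restricted to those rows.  ``names`` maps canonical keys to family names.
    """
    ns = P.shape[1]
    jj = np.arange(1, ns + 1, dtype=np.float64)[None, :]
    ii = levels[:, None].astype(np.float64)
    nr = P.sum()
    p = P / nr
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    mu_i = float((p * ii).sum())
    mu_j = float((p * jj).sum())
    out = {
        names["sse"]: float((P / jj**2).sum() / nr),
        names["lse"]: float((P * jj**2).sum() / nr),
        names["gln"]: float((row**2).sum() / nr),
        names["glnn"]: float((row**2).sum() / nr**2),
        names["sn"]: float((col**2).sum() / nr),
        names["snn"]: float((col**2).sum() / nr**2),
        names["pct"]: float(nr / n_p),
        names["glv"]: float((p * (ii - mu_i) ** 2).sum()),
        names["sv"]: float((p * (jj - mu_j) ** 2).sum()),
        names["ent"]: float(-(p[p > 0] * np.log2(p[p > 0] + _EPS)).sum()),
        names["lgl"]: float((P / ii**2).sum() / nr),
        names["hgl"]: float((P * ii**2).sum() / nr),
        names["slgl"]: float((P / (ii**2 * jj**2)).sum() / nr),
        names["shgl"]: float((P * ii**2 / jj**2).sum() / nr),
        names["llgl"]: float((P * jj**2 / ii**2).sum() / nr),
        names["lhgl"]: float((P * ii**2 * jj**2).sum() / nr),
    }
    return out


_GLRLM_KEYMAP = {
    "sse": "ShortRunEmphasis",
    "lse": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity",
    "snn": "RunLengthNonUniformityNormalized",
    "pct": "RunPercentage",
    "glv": "GrayLevelVariance",
    "sv": "RunVariance",
    "ent": "RunEntropy",
    "lgl": "LowGrayLevelRunEmphasis",
    "hgl": "HighGrayLevelRunEmphasis",
    "slgl": "ShortRunLowGrayLevelEmphasis",
    "shgl": "ShortRunHighGrayLevelEmphasis",
    "llgl": "LongRunLowGrayLevelEmphasis",
    "lhgl": "LongRunHighGrayLevelEmphasis",
}


def glrlm_features(
    labels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[dict[str, float], set[str]]:
    """Direction-averaged GLRLM features."""
    mats = glrlm_matrices(labels, mask, n_levels)
    n_p = int(mask.sum())
    present = np.unique(labels[mask])
    per_dir = []
    for P in mats:
        if P.sum() == 0:
            continue
        per_dir.append(
            _rlm_style_features(P[present - 1], present.astype(float), n_p, _GLRLM_KEYMAP)
        )
    if not per_dir:
        return {k: np.nan for k in GLRLM_NAMES}, set(GLRLM_NAMES)
    out = {n: float(np.mean([d[n] for d in per_dir])) for n in GLRLM_NAMES}
    return out, set()


# ---------------------------------------------------------------- GLSZM


def glszm_matrix(labels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix (Ng x max_zone_size); zones are 26-connected."""
    labels, mask = _crop(labels, mask)
    lab = np.where(mask, labels, 0)
    n_vox = int(mask.sum())
    P = np.zeros((n_levels, n_vox), dtype=np.float64)
    struct = np.ones((3, 3, 3), dtype=bool)
    for g in np.unique(lab[lab > 0]):
        cc, n = ndimage.label(lab == g, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(cc.ravel())[1:]
        for s in sizes:
            P[g - 1, s - 1] += 1.0
    return P


_GLSZM_KEYMAP = {
    "sse": "SmallAreaEmphasis",
    "lse": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity",
    "snn": "SizeZoneNonUniformityNormalized",
    "pct": "ZonePercentage",
    "glv": "GrayLevelVariance",
    "sv": "ZoneVariance",
    "ent": "ZoneEntropy",
    "lgl": "LowGrayLevelZoneEmphasis",
    "hgl": "HighGrayLevelZoneEmphasis",
    "slgl": "SmallAreaLowGrayLevelEmphasis",
    "shgl": "SmallAreaHighGrayLevelEmphasis",
    "llgl": "LargeAreaLowGrayLevelEmphasis",
    "lhgl": "LargeAreaHighGrayLevelEmphasis",
}


def glszm_features(
    labels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[dict[str, float], set[str]]:
    P = glszm_matrix(labels, mask, n_levels)
    present = np.unique(labels[mask])
    out = _rlm_style_features(P[present - 1], present.astype(float), int(mask.sum()), _GLSZM_KEYMAP)
    return {n: out[n] for n in GLSZM_NAMES}, set()


# ---------------------------------------------------------------- NGTDM


def ngtdm_table(
    labels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level voxel counts n_i and summed tone differences s_i.

    Only voxels with at least one in-mask neighbour (26-neighbourhood)
    contribute.
    """
    labels, mask = _crop(labels, mask)
    lab = np.where(mask, labels, 0)
    nb_sum = np.zeros(lab.shape, dtype=np.float64)
    nb_cnt = np.zeros(lab.shape, dtype=np.int64)
    for off in OFFSETS_26:
        a_sum, b = _shift_view(nb_sum, off)
        la, lb = _shift_view(lab, off)
        a_cnt, _ = _shift_view(nb_cnt, off)
        valid = lb > 0
        a_sum[valid] += lb[valid]
        a_cnt[valid] += 1
    n = np.zeros(n_levels, dtype=np.float64)
    s = np.zeros(n_levels, dtype=np.float64)
    sel = (lab > 0) & (nb_cnt > 0)
    levels = lab[sel]
    diffs = np.abs(levels - nb_sum[sel] / nb_cnt[sel])
    np.add.at(n, levels - 1, 1.0)
    np.add.at(s, levels - 1, diffs)
    return n, s


def ngtdm_features(
    labels: np.ndarray, mask: np.ndarray, n_levels: int
) -> tuple[dict[str, float], set[str]]:
    n, s = ngtdm_table(labels, mask, n_levels)
    nvp = n.sum()
    if nvp == 0:
        return {k: np.nan for k in NGTDM_NAMES}, set(NGTDM_NAMES)
    present = np.flatnonzero(n > 0)
    iv = (present + 1).astype(np.float64)
    p = n[present] / nvp
    si = s[present]
    ngp = len(present)

    out: dict[str, float] = {}
    denom = float((p * si).sum())
    out["Coarseness"] = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        ii = iv[:, None]
        jj = iv[None, :]
        pi = p[:, None]
        pj = p[None, :]
        out["Contrast"] = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * (si.sum() / nvp)
        )
        bus_den = float(np.abs(ii * pi - jj * pj).sum())
        out["Busyness"] = denom / bus_den if bus_den > 0 else 0.0
        out["Complexity"] = float(
            (np.abs(ii - jj) * (pi * si[:, None] + pj * si[None, :]) / (pi + pj)).sum() / nvp
        )
        s_sum = float(si.sum())
        out["Strength"] = (
            float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
        out["Complexity"] = 0.0
        out["Strength"] = 0.0
    return out, set()


# ---------------------------------------------------------------- GLDM


def gldm_matrix(
    labels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0
) -> np.ndarray:
    """Dependence count matrix (Ng x 27): j = 1 + number of neighbours whose
    gray level differs from the center by at most ``alpha``."""
    labels, mask = _crop(labels, mask)
    lab = np.where(mask, labels, 0)
    dep = np.zeros(lab.shape, dtype=np.int64)
    for off in OFFSETS_26:
        a, b = _shift_view(lab, off)
        da, _ = _shift_view(dep, off)
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        da[ok] += 1
    P = np.zeros((n_levels, 27), dtype=np.float64)
    sel = lab > 0
    np.add.at(P, (lab[sel] - 1, dep[sel]), 1.0)
    return P


_GLDM_KEYMAP = {
    "sse": "SmallDependenceEmphasis",
    "lse": "LargeDependenceEmphasis",
    "gln": "GrayLevelNonUniformity",
    "glnn": "_GLNN_unused",
    "sn": "DependenceNonUniformity",
    "snn": "DependenceNonUniformityNormalized",
    "pct": "_pct_unused",
    "glv": "GrayLevelVariance",
    "sv": "DependenceVariance",
    "ent": "DependenceEntropy",
    "lgl": "LowGrayLevelEmphasis",
    "hgl": "HighGrayLevelEmphasis",
    "slgl": "SmallDependenceLowGrayLevelEmphasis",
    "shgl": "SmallDependenceHighGrayLevelEmphasis",
    "llgl": "LargeDependenceLowGrayLevelEmphasis",
    "lhgl": "LargeDependenceHighGrayLevelEmphasis",
}


def gldm_features(
    labels: np.ndarray, mask: np.ndarray, n_levels: int, alpha: int = 0
) -> tuple[dict[str, float], set[str]]:
    P = gldm_matrix(labels, mask, n_levels, alpha)
    present = np.unique(labels[mask])
    out = _rlm_style_features(P[present - 1], present.astype(float), int(mask.sum()), _GLDM_KEYMAP)
    return {n: out[n] for n in GLDM_NAMES}, set()
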