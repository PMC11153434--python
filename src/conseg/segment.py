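"""Four automatic PET tumor segmentation methods operating inside an initial mask.

* 41MAX -- fixed threshold at 41% of the maximum uptake inside the mask.
* ST    -- contrast-oriented adaptive threshold: a weighted combination of the
           mean of a high-isocontour region and a local background estimate,
           iterated to a fixed point.
* AP    -- affinity-propagation clustering of voxel intensities; the cluster
           boundary with the best two-class separation is the cut and the
           largest connected hyperintense grouping is the tumor.
* MASAC -- a two-region piecewise-constant active contour with a boundary-length
           penalty weighted by lambda (default 3), initialized from the 41MAX
           contour and evolved inside the initial mask.

Every result is restricted to its initial mask and reduced to a single
connected component under 26-connectivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, ImageVolume, check_congruent

__all__ = [
    "STParams",
    "APParams",
    "MASACParams",
    "SegmentationResult",
    "segment_41max",
    "segment_st",
    "segment_ap",
    "segment_masac",
    "run_all",
]

logger = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class STParams:
    """Contrast-oriented threshold parameters.

    The threshold is T = a * mean(voxels >= iso_fraction * region max) + b * BG
    where BG is the mean intensity in a shell bg_shell voxels around the
    current contour.  The (a, b) calibration is scanner-specific; the shipped
    defaults weight source and background equally.
    """

    a: float = 0.5
    b: float = 0.5
    iso_fraction: float = 0.70
    bg_shell: tuple[float, float] = (2.0, 4.0)  # inner/outer radius in voxels
    max_iter: int = 50
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.iso_fraction < 1):
            raise ValueError("iso_fraction must be in (0, 1)")
        if self.a < 0 or self.b < 0:
            raise ValueError("a and b must be >= 0")


@dataclass
class APParams:
    """Affinity-propagation parameters (intensity-only features by default)."""

    damping: float = 0.9
    max_iter: int = 200
    convergence_iter: int = 15
    spatial_weight: float = 0.0  # weight of voxel coordinates in the feature vector
    max_voxels: int = 1000  # seeded subsampling threshold

    def __post_init__(self) -> None:
        if not (0.5 <= self.damping < 1):
            raise ValueError("damping must be in [0.5, 1)")


@dataclass
class MASACParams:
    """Active-contour parameters; lam weights the boundary-length penalty."""

    lam: float = 3.0
    max_iter: int = 100
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")


@dataclass
class SegmentationResult:
    """A segmentation mask plus the full parameter/flag record that produced it."""

    method: str
    mask: BinaryMask
    params_used: dict
    mask_style: str | None = None


def _largest_cc(arr: np.ndarray) -> np.ndarray:
    """Largest 26-connected component; ties broken by lowest label (stable)."""
    lab, n = ndimage.label(arr, structure=_STRUCT26)
    if n <= 1:
        return arr.copy()
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def _check_inputs(image: ImageVolume, init: BinaryMask) -> None:
    check_congruent(image, init)
    if init.is_empty():
        raise ValueError("initial mask is empty")
    vals = image.data[init.data]
    if not np.all(np.isfinite(vals)):
        raise ValueError("image contains non-finite values inside the initial mask")


def _crop_slices(mask: np.ndarray, pad: int, shape) -> tuple[slice, ...]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, shape)
    return tuple(slice(a, b) for a, b in zip(lo, hi))


def segment_41max(
    image: ImageVolume, init: BinaryMask, fraction: float = 0.41
) -> SegmentationResult:
    """Threshold at ``fraction`` of the maximum uptake inside the initial mask."""
    _check_inputs(image, init)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    vmax = image.data[init.data].max()
    sel = init.data & (image.data >= fraction * vmax)
    if not sel.any():
        raise RuntimeError("41MAX produced an empty mask")
    out = _largest_cc(sel)
    return SegmentationResult(
        method="41MAX",
        mask=BinaryMask(out, init.spacing),
        params_used={"fraction": fraction, "threshold": float(fraction * vmax)},
    )


def _shell(contour: np.ndarray, inner: float, outer: float) -> np.ndarray:
    dist = ndimage.distance_transform_edt(~contour)
    return (dist > inner) & (dist <= outer)


def segment_st(
    image: ImageVolume, init: BinaryMask, p: STParams | None = None
) -> SegmentationResult:
    """Contrast-oriented adaptive threshold, iterated to a fixed point."""
    _check_inputs(image, init)
    p = p or STParams()
    sl = _crop_slices(init.data, int(np.ceil(p.bg_shell[1])) + 2, init.shape)
    img = image.data[sl]
    initc = init.data[sl]

    contour = initc.copy()
    t_prev = None
    converged = False
    n_it = 0
    for n_it in range(1, p.max_iter + 1):
        vals = img[contour]
        cmax = vals.max()
        region = contour & (img >= p.iso_fraction * cmax)
        mean_iso = img[region].mean()
        shell = _shell(contour, *p.bg_shell)
        if shell.any():
            bg = img[shell].mean()
        else:  # contour fills the crop: fall back to everything outside init
            outside = ~initc
            bg = img[outside].mean() if outside.any() else float(img.min())
        t = p.a * mean_iso + p.b * bg
        new = initc & (img >= t)
        if not new.any():  # threshold above every voxel: keep last contour
            break
        new = _largest_cc(new)
        if np.array_equal(new, contour) or (t_prev is not None and abs(t - t_prev) < p.tol):
            contour = new
            converged = True
            break
        contour, t_prev = new, t

    out = np.zeros(init.shape, dtype=bool)
    out[sl] = contour
    params = asdict(p)
    params.update({"threshold": float(t), "iterations": n_it, "converged": converged})
    if not converged:
        logger.warning("ST did not converge in %d iterations", p.max_iter)
    return SegmentationResult("ST", BinaryMask(out, init.spacing), params)


def _otsu_split(vals: np.ndarray) -> np.ndarray:
    from skimage.filters import threshold_otsu

    t = threshold_otsu(vals)
    return vals > t


def _best_cluster_cut(vals: np.ndarray, labels: np.ndarray) -> float:
    """Segmentation threshold from a cluster partition of the intensities.

    Candidate cuts are the boundaries between intensity-adjacent clusters
    (midpoint between the max of the lower and the min of the upper); the cut
    maximizing the two-class between-class variance over ``vals`` is chosen.
    A single cluster yields a cut at the minimum (everything is foreground).
    """
    uniq = np.unique(labels)
    if len(uniq) == 1:
        return float(vals.min())
    means = np.array([vals[labels == u].mean() for u in uniq])
    order = uniq[np.argsort(means)]
    lows = np.array([vals[labels == u].max() for u in order[:-1]])
    highs = np.array([vals[labels == u].min() for u in order[1:]])
    cuts = (lows + highs) / 2.0
    best_cut, best_score = float(vals.min()), -np.inf
    for c in cuts:
        hi = vals >= c
        n1 = int(hi.sum())
        n0 = len(vals) - n1
        if n0 == 0 or n1 == 0:
            continue
        score = n0 * n1 * (vals[hi].mean() - vals[~hi].mean()) ** 2
        if score > best_score:
            best_score, best_cut = score, float(c)
    return best_cut


def segment_ap(
    image: ImageVolume,
    init: BinaryMask,
    p: APParams | None = None,
    seed: int | None = 0,
) -> SegmentationResult:
    """Affinity-propagation segmentation: cluster intensities, cut at the best
    cluster boundary, keep the largest hyperintense grouping.

    Similarity is the negative squared feature distance with the sklearn
    default (median-similarity) preference.  The AP clusters partition the
    intensity range; the candidate segmentation thresholds are the boundaries
    between consecutive clusters, and the boundary maximizing the two-class
    between-class variance (Otsu's criterion restricted to AP boundaries) is
    chosen.  The tumor is the largest connected grouping of the voxels above
    that cut -- an FDG-avid target is by definition hyperintense, so a
    background grouping is never an acceptable tumor contour.  With two
    well-separated levels this reduces to the high-level voxel set; a single
    cluster returns the whole initial region.  Above ``max_voxels`` voxels a
    seeded subsample is clustered and labels are propagated to the remaining
    voxels by nearest feature-space neighbour.  If AP fails to converge the
    method falls back to a two-class Otsu intensity split (hyperintense class
    kept), flagged in ``params_used``.
    """
    from sklearn.cluster import AffinityPropagation

    _check_inputs(image, init)
    p = p or APParams()
    coords = np.argwhere(init.data)
    vals = image.data[init.data]
    feats = vals[:, None]
    if p.spatial_weight > 0:
        scale = np.asarray(init.spacing) * p.spatial_weight
        feats = np.hstack([feats, coords * scale[None, :]])

    rng = np.random.default_rng(seed)
    n = len(vals)
    subsampled = n > p.max_voxels
    if subsampled:
        sub = rng.choice(n, size=p.max_voxels, replace=False)
        sub.sort()
    else:
        sub = np.arange(n)

    fallback = False
    if np.ptp(vals[sub]) == 0:
        labels_sub = np.zeros(len(sub), dtype=int)  # single cluster
    else:
        ap = AffinityPropagation(
            damping=p.damping,
            max_iter=p.max_iter,
            convergence_iter=p.convergence_iter,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ap.fit(feats[sub])
        centers = getattr(ap, "cluster_centers_indices_", None)
        if centers is None or len(np.atleast_1d(centers)) == 0:
            fallback = True
            labels_sub = _otsu_split(vals[sub]).astype(int)
        else:
            labels_sub = ap.labels_

    if subsampled:
        # nearest-neighbour label propagation in feature space
        from scipy.spatial import cKDTree

        tree = cKDTree(feats[sub])
        _, nn = tree.query(feats, k=1)
        labels = labels_sub[nn]
    else:
        labels = labels_sub

    counts = np.bincount(labels)
    threshold = _best_cluster_cut(vals, labels)
    fg = vals >= threshold
    out = np.zeros(init.shape, dtype=bool)
    out[tuple(coords[fg].T)] = True
    out = _largest_cc(out)
    params = asdict(p)
    params.update(
        {
            "n_voxels": int(n),
            "subsampled": bool(subsampled),
            "n_clusters": int(len(counts)),
            "threshold": float(threshold),
            "fallback_otsu": bool(fallback),
        }
    )
    return SegmentationResult("AP", BinaryMask(out, init.spacing), params)


def _perimeter(mask: np.ndarray) -> int:
    """Count of exposed voxel faces (6-connectivity) of the mask."""
    per = 0
    for ax in range(3):
        diff = np.diff(mask.astype(np.int8), axis=ax)
        per += int(np.abs(diff).sum())
        # faces at the array border
        per += int(mask.take(0, axis=ax).sum() + mask.take(-1, axis=ax).sum())
    return per


def _cv_energy(img, mask, domain, lam) -> float:
    inside = mask & domain
    outside = domain & ~mask
    e = 0.0
    if inside.any():
        c1 = img[inside].mean()
        e += float(((img[inside] - c1) ** 2).sum())
    if outside.any():
        c2 = img[outside].mean()
        e += float(((img[outside] - c2) ** 2).sum())
    return e + lam * _perimeter(mask)


def segment_masac(
    image: ImageVolume, init: BinaryMask, p: MASACParams | None = None
) -> SegmentationResult:
    """Two-region piecewise-constant active contour with length penalty.

    Minimizes sum_in (x - c1)^2 + sum_out (x - c2)^2 + lam * perimeter over
    masks inside the initial region by threshold dynamics: each sweep
    reassigns voxels by the sign of the pointwise energy difference plus a
    curvature term lam * (1/2 - smoothed indicator).  Initialized from the
    41MAX contour.  A degenerate (empty/full) evolution returns the
    initialization, flagged.
    """
    _check_inputs(image, init)
    p = p or MASACParams()
    sl = _crop_slices(init.data, 3, init.shape)
    img = image.data[sl]
    initc = init.data[sl]

    init_contour = segment_41max(image, init).mask.data[sl]
    m = init_contour.copy()
    e_prev = _cv_energy(img, m, initc, p.lam)
    degenerate = False
    converged = False
    n_it = 0
    for n_it in range(1, p.max_iter + 1):
        inside = m & initc
        outside = initc & ~m
        if not inside.any() or not outside.any():
            degenerate = not inside.any()
            converged = not degenerate  # contour filled the whole region: stable
            break
        c1 = img[inside].mean()
        c2 = img[outside].mean()
        smooth = ndimage.uniform_filter(m.astype(np.float64), size=3)
        score = (img - c1) ** 2 - (img - c2) ** 2 + p.lam * (0.5 - smooth)
        new = initc & (score < 0)
        if not new.any():
            degenerate = True
            break
        e = _cv_energy(img, new, initc, p.lam)
        if np.array_equal(new, m):
            converged = True
            break
        if abs(e - e_prev) < p.tol * max(abs(e_prev), 1.0):
            m = new
            converged = True
            break
        m, e_prev = new, e

    if degenerate:
        logger.warning("MASAC evolution degenerated; returning the initialization")
        m = init_contour

    m = _largest_cc(m)
    out = np.zeros(init.shape, dtype=bool)
    out[sl] = m
    params = asdict(p)
    params.update({"iterations": n_it, "converged": converged, "degenerate": degenerate})
    return SegmentationResult("MASAC", BinaryMask(out, init.spacing), params)


def run_all(
    image: ImageVolume,
    init: BinaryMask,
    *,
    fraction: float = 0.41,
    st_params: STParams | None = None,
    ap_params: APParams | None = None,
    masac_params: MASACParams | None = None,
    seed: int | None = 0,
    mask_style: str | None = None,
) -> dict[str, SegmentationResult]:
    """Run all four methods under the same initial mask.

    Individual failures are recorded (logged, omitted from the result) rather
    than fatal; if every method fails an error is raised.
    """
    _check_inputs(image, init)
    runners = {
        "41MAX": lambda: segment_41max(image, init, fraction),
        "ST": lambda: segment_st(image, init, st_params),
        "AP": lambda: segment_ap(image, init, ap_params, seed=seed),
        "MASAC": lambda: segment_masac(image, init, masac_params),
    }
    results: dict[str, SegmentationResult] = {}
    errors: dict[str, str] = {}
    for name, fn in runners.items():
        try:
            res = fn()
            res.mask_style = mask_style
            results[name] = res
        except Exception as exc:  # noqa: BLE001 - per-method failures are recorded
            logger.error("%s segmentation failed: %s", name, exc)
            errors[name] = str(exc)
    if not results:
        raise RuntimeError(f"all segmentation methods failed: {errors}")
    return results
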