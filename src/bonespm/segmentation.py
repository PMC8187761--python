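"""Compartment segmentation: periosteal surface, cortical/trabecular split,
non-local fuzzy c-means endosteal refinement, and soft cortical membership.

The periosteal contour is found by smoothing + thresholding + morphological
closing and keeping the filled largest connected component (edge-finding in
the autocontour spirit). The cortical/trabecular split is threshold-based:
the endosteal volume is the morphological closing of the largest marrow
component, so a trabecular lattice touching the shell does not leak into the
cortex and small intra-cortical pores stay cortical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .core import CalibratedVolume


class EmptySegmentationError(ValueError):
    """No foreground found at the requested threshold."""


def midpoint_threshold(values: np.ndarray) -> float:
    """Midpoint of the marrow/bone class means, classes split by Otsu.

    Returning the midpoint (rather than Otsu's bin center) is robust to the
    histogram-quantization artifact where the raw Otsu threshold lands
    inside the bin holding a mode.
    """
    values = np.asarray(values, np.float64).ravel()
    t = float(threshold_otsu(values))
    lo = values[values <= t]
    hi = values[values > t]
    if lo.size == 0 or hi.size == 0:
        return t
    return 0.5 * (float(lo.mean()) + float(hi.mean()))


@dataclass
class SMembershipParams:
    """S-shaped fuzzy membership: 0 at/below ``a``, 1 at/above ``b`` (mg/cm^3)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ValueError("require a < b for the s-shaped membership")


@dataclass
class CompartmentSegmentation:
    periosteal_mask: np.ndarray
    cortical_mask: np.ndarray
    trabecular_mask: np.ndarray
    bone_mask: np.ndarray
    membership: np.ndarray | None = None
    periosteal_distance: np.ndarray | None = None  # mm, inside the periosteum
    warnings: list = field(default_factory=list)

    def check_invariants(self) -> None:
        assert not np.any(self.cortical_mask & self.trabecular_mask)
        assert np.all(self.periosteal_mask[self.cortical_mask])
        assert np.all(self.periosteal_mask[self.trabecular_mask])
        if self.membership is not None:
            assert self.membership.min() >= 0 and self.membership.max() <= 1
            assert np.all(self.membership[~self.periosteal_mask] == 0)


def s_membership(x, params: SMembershipParams) -> np.ndarray:
    """Fuzzy s-shaped membership of BMD to the cortical-bone class.

    f(x) = 0 for x <= a; 2((x-a)/(b-a))^2 up to the midpoint;
    1 - 2((x-b)/(b-a))^2 up to b; 1 for x >= b. Continuous, nondecreasing.
    """
    a, b = params.a, params.b
    x = np.asarray(x, dtype=np.float64)
    t = (x - a) / (b - a)
    out = np.where(x <= (a + b) / 2, 2 * t**2, 1 - 2 * (t - 1) ** 2)
    out = np.clip(out, 0.0, 1.0)
    out = np.where(x <= a, 0.0, out)
    out = np.where(x >= b, 1.0, out)
    return out if out.ndim else float(out)


def find_periosteal_surface(
    volume: CalibratedVolume,
    threshold: float | None = None,
    closing_radius: int = 3,
    smoothing_sigma: float = 1.0,
) -> np.ndarray:
    """Binary periosteal mask: filled largest component of the smoothed,
    thresholded, morphologically closed foreground.

    ``threshold`` defaults to Otsu's threshold on the volume histogram
    (self-calibrating between the marrow and bone modes). Voxels exactly at
    the threshold are foreground. The mask is hole-filled per axial slice,
    giving one simply connected cross-section per slice.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    smoothed = ndi.gaussian_filter(data, smoothing_sigma) if smoothing_sigma > 0 else data
    if threshold is None:
        threshold = midpoint_threshold(smoothed)
    fg = smoothed >= threshold
    if not fg.any():
        raise EmptySegmentationError(
            f"no voxels at or above threshold {threshold:.1f} mg/cm^3"
        )
    if closing_radius > 0:
        fg = _ball_closing(fg, closing_radius)
    labels, n = ndi.label(fg)
    if n == 0:
        raise EmptySegmentationError("no connected foreground component")
    largest = np.argmax(ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))) + 1
    mask = labels == largest
    for k in range(mask.shape[2]):
        mask[:, :, k] = ndi.binary_fill_holes(mask[:, :, k])
    return mask


def _ball_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with a Euclidean ball via distance transforms."""
    if radius <= 0:
        return mask
    dilated = ndi.distance_transform_edt(~mask) <= radius
    eroded = ndi.distance_transform_edt(dilated) > radius
    # keep original foreground (closing is extensive)
    return eroded | mask


def split_compartments(
    volume: CalibratedVolume,
    periosteal_mask: np.ndarray,
    bone_threshold: float | None = None,
    min_cortex_voxels: int = 27,
    endosteal_closing_radius: int | None = None,
) -> CompartmentSegmentation:
    """Threshold-based cortical/trabecular split.

    bone_mask: voxels >= bone_threshold inside the periosteum (Otsu default).
    The endosteal (trabecular) volume is the morphological closing of the
    largest marrow component; marrow pockets not connected to it and smaller
    than ``min_cortex_voxels`` are treated as intra-cortical pores. The
    cortical mask is the periosteal shell minus the endosteal volume. A
    breached shell (marrow path from interior to the periosteal boundary)
    sets a warning flag rather than failing.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    if bone_threshold is None:
        bone_threshold = midpoint_threshold(data[periosteal_mask])
    bone_mask = (data >= bone_threshold) & periosteal_mask
    if not bone_mask.any():
        raise EmptySegmentationError("no bone voxels inside the periosteum")

    marrow = periosteal_mask & ~bone_mask
    warnings = []
    ring = np.zeros_like(periosteal_mask)
    if marrow.any():
        labels, n = ndi.label(marrow)
        sizes = ndi.sum_labels(marrow, labels, index=np.arange(1, n + 1))
        # in-plane periosteal boundary (axial end faces are open by design)
        struct = np.zeros((3, 3, 1), bool)
        struct[1, :, 0] = True
        struct[:, 1, 0] = True
        boundary = periosteal_mask & ~ndi.binary_erosion(periosteal_mask, struct)
        touching = set(np.unique(labels[boundary])) - {0}
        keep = [
            lbl
            for lbl in range(1, n + 1)
            if lbl not in touching and sizes[lbl - 1] >= min_cortex_voxels
        ]
        ring = np.isin(labels, sorted(touching)) if touching else ring
        if not keep:
            # breached shell: interior marrow leaks to the boundary
            main = int(np.argmax(sizes)) + 1
            keep = [main]
            ring &= labels != main
            warnings.append("cortical shell discontinuous (marrow reaches boundary)")
        seed = np.isin(labels, keep)
        if endosteal_closing_radius is None:
            # just enough to bridge marrow across a trabecula; larger radii
            # round the endosteal wall at plate junctions
            endosteal_closing_radius = 2
        endosteal = _ball_closing(seed, endosteal_closing_radius)
        endosteal &= periosteal_mask & ~ring
    else:
        endosteal = np.zeros_like(periosteal_mask)

    cortical = periosteal_mask & ~endosteal & ~ring
    trabecular = endosteal
    dist = ndi.distance_transform_edt(periosteal_mask, sampling=volume.spacing)
    seg = CompartmentSegmentation(
        periosteal_mask=periosteal_mask,
        cortical_mask=cortical,
        trabecular_mask=trabecular,
        bone_mask=bone_mask,
        periosteal_distance=dist,
        warnings=warnings,
    )
    return seg


def attach_membership(
    seg: CompartmentSegmentation,
    volume: CalibratedVolume,
    params: SMembershipParams | None = None,
) -> SMembershipParams:
    """Compute the soft cortical membership map on the periosteal domain.

    Default calibration: a, b = 10th / 90th percentile of BMD inside the
    cortical mask (self-calibrating on synthetic and real intensity scales).
    """
    if params is None:
        vals = np.asarray(volume.data)[seg.cortical_mask]
        if vals.size == 0:
            raise EmptySegmentationError("empty cortical mask for calibration")
        a, b = np.percentile(vals, [10, 90])
        if not a < b:  # constant cortical BMD: everything is cortical bone
            a, b = float(vals.min()) - 1.0, float(vals.min())
        params = SMembershipParams(float(a), float(b))
    mem = s_membership(np.asarray(volume.data, dtype=np.float64), params)
    mem[~seg.periosteal_mask] = 0.0
    seg.membership = mem
    return params


# --------------------------------------------------------------------------
# non-local fuzzy c-means
# --------------------------------------------------------------------------


@dataclass
class NLFCMResult:
    labels: np.ndarray  # int map, -1 outside domain; 0 = cortical-like
    memberships: np.ndarray  # (n_clusters, *shape)
    centroids: np.ndarray
    objective_history: np.ndarray
    converged: bool


def _nonlocal_neighbors(
    features: np.ndarray,
    domain: np.ndarray,
    patch_radius: int,
    search_radius: int,
    k_best: int,
) -> tuple[np.ndarray, np.ndarray]:
    """For each domain voxel: flat indices + similarity weights of the K most
    similar patches in the search window (patch distance on the features).

    Patch distances depend only on the (fixed) features, so this is computed
    once before the FCM iterations.
    """
    shape = domain.shape
    n_dom = int(domain.sum())
    flat_index = -np.ones(shape, dtype=np.int64)
    flat_index[domain] = np.arange(n_dom)

    offsets = [
        (dx, dy, dz)
        for dx in range(-search_radius, search_radius + 1)
        for dy in range(-search_radius, search_radius + 1)
        for dz in range(-search_radius, search_radius + 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    best_d = np.full((n_dom, k_best), np.inf)
    best_i = np.full((n_dom, k_best), -1, dtype=np.int64)

    size = 2 * patch_radius + 1
    for off in offsets:
        shifted = np.full_like(features, np.nan)
        src = tuple(
            slice(max(0, -o), features.shape[1 + ax] - max(0, o))
            for ax, o in enumerate(off)
        )
        dst = tuple(
            slice(max(0, o), features.shape[1 + ax] - max(0, -o))
            for ax, o in enumerate(off)
        )
        shifted[(slice(None),) + dst] = features[(slice(None),) + src]
        diff2 = np.nansum((features - shifted) ** 2, axis=0)
        diff2[np.isnan(shifted).all(axis=0)] = np.inf
        with np.errstate(invalid="ignore"):
            pdist = ndi.uniform_filter(
                np.where(np.isfinite(diff2), diff2, 0.0), size=size
            )
        pdist = pdist + np.where(np.isfinite(diff2), 0.0, np.inf)

        # flat index of the neighbor voxel v+off (only where it is in domain)
        neigh = np.full(shape, -1, dtype=np.int64)
        neigh[dst] = flat_index[src]
        d = pdist[domain]
        ni = neigh[domain]
        d = np.where(ni >= 0, d, np.inf)
        # replace the current worst of the K if better
        worst = np.argmax(best_d, axis=1)
        rows = np.arange(n_dom)
        better = d < best_d[rows, worst]
        best_d[rows[better], worst[better]] = d[better]
        best_i[rows[better], worst[better]] = ni[better]

    with np.errstate(over="ignore"):
        sigma2 = np.nanmean(np.where(np.isfinite(best_d), best_d, np.nan)) + 1e-12
        w = np.exp(-np.where(np.isfinite(best_d), best_d, np.inf) / sigma2)
    w[best_i < 0] = 0.0
    norm = w.sum(axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    w = w / norm
    return best_i, w


def nlfcm_endosteal(
    volume: CalibratedVolume,
    bone_mask: np.ndarray,
    periosteal_distance: np.ndarray,
    n_clusters: int = 2,
    m: float = 2.0,
    lam: float = 0.5,
    patch_radius: int = 1,
    search_radius: int = 3,
    k_best: int = 6,
    max_iter: int = 100,
    tol: float = 1e-5,
    rng: np.random.Generator | None = None,
) -> NLFCMResult:
    """Non-local fuzzy c-means over the bone voxels.

    Features per voxel (z-scored): BMD, bone-segmentation indicator smoothed
    once, and distance to the periosteal surface. Memberships are
    regularized toward the similarity-weighted average of the memberships of
    the K most similar patches inside a search window (weight ``lam``).
    Cluster 0 is resolved as cortical-like = smaller mean periosteal
    distance. Convergence: relative change of the FCM objective < ``tol``.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    domain = np.asarray(bone_mask, bool)
    if not domain.any():
        raise EmptySegmentationError("empty clustering domain")

    bmd = np.asarray(volume.data, dtype=np.float64)
    bone_smooth = ndi.gaussian_filter(domain.astype(np.float64), 1.0)
    feats_full = np.stack([bmd, bone_smooth, np.asarray(periosteal_distance, float)])
    # z-score per feature over the domain
    fdom = feats_full[:, domain]
    mu = fdom.mean(axis=1, keepdims=True)
    sd = fdom.std(axis=1, keepdims=True)
    degenerate = bool(np.all(sd < 1e-12))
    sd[sd < 1e-12] = 1.0
    feats_full = (feats_full - mu[:, :, None, None]) / sd[:, :, None, None]
    X = feats_full[:, domain].T  # (n, f)
    n = X.shape[0]

    if lam > 0 and not degenerate:
        nb_idx, nb_w = _nonlocal_neighbors(
            feats_full, domain, patch_radius, search_radius, k_best
        )
    else:
        nb_idx = nb_w = None

    if rng is None:
        rng = np.random.default_rng(0)
    u = rng.dirichlet(np.ones(n_clusters), size=n)  # (n, c)

    history = []
    converged = False
    centroids = np.zeros((n_clusters, X.shape[1]))
    for _ in range(max_iter):
        um = u**m
        centroids = (um.T @ X) / np.maximum(um.sum(axis=0)[:, None], 1e-300)
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)  # (n, c)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        if nb_idx is not None:
            u_nl = np.einsum("nk,nkc->nc", nb_w, u[nb_idx])
            u = (u + lam * u_nl) / (1.0 + lam)
            u = u / u.sum(axis=1, keepdims=True)
        obj = float((u**m * d2).sum())
        history.append(obj)
        if len(history) > 1:
            prev = history[-2]
            if abs(prev - obj) <= tol * max(abs(prev), 1e-300):
                converged = True
                break

    if degenerate:
        converged = False

    # cluster identity: cortical = smaller mean periosteal distance
    pdist = np.asarray(periosteal_distance, float)[domain]
    hard = np.argmax(u, axis=1)
    means = np.array(
        [
            pdist[hard == c].mean() if np.any(hard == c) else np.inf
            for c in range(n_clusters)
        ]
    )
    order = np.argsort(means)
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(n_clusters)

    labels = -np.ones(domain.shape, dtype=np.int8)
    labels[domain] = remap[hard]
    mem_maps = np.zeros((n_clusters,) + domain.shape)
    for c in range(n_clusters):
        mem_maps[remap[c]][domain] = u[:, c]

    return NLFCMResult(
        labels=labels,
        memberships=mem_maps,
        centroids=centroids[order],
        objective_history=np.asarray(history),
        converged=converged,
    )
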