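"""Spatial normalization to a common template and shape covariates.

Registration is driven by the geometry the analysis needs: squared
differences of signed distance maps of the periosteal masks, through an
affine stage followed by a multi-resolution symmetric-forces demons stage.
Parametric maps are resampled to the template grid with trilinear
interpolation and undefined-flag (NaN) propagation. Periosteal surface
correspondence maps template vertices through the transform into subject
space and interpolates subject per-vertex values barycentrically on the
nearest face. Shape covariates are PCA scores of Procrustes-aligned
(rotation + translation removed, scale retained) corresponded vertex sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
import trimesh
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

from .core import CalibratedVolume


class RegistrationError(RuntimeError):
    pass


@dataclass
class TemplateSpace:
    volume: CalibratedVolume
    periosteal_mask: np.ndarray
    trabecular_mask: np.ndarray
    mesh: trimesh.Trimesh
    provenance: str = "reference-subject"


@dataclass
class SubjectTransform:
    """Template -> subject mapping (the direction resampling needs)."""

    affine: np.ndarray  # 4x4, mm
    displacement: np.ndarray | None  # (nx, ny, nz, 3) mm on the template grid
    composite: sitk.Transform
    metric_initial: float
    metric_final: float


def _to_sitk(arr: np.ndarray, spacing: float) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.T, dtype=np.float64))
    img.SetSpacing((spacing,) * 3)
    img.SetOrigin((0.5 * spacing,) * 3)  # voxel centers at (i + 1/2) h
    return img


def _from_sitk(img: sitk.Image) -> np.ndarray:
    return sitk.GetArrayFromImage(img).T


#: SDFs are clamped to this band (mm): registration should care about the
#: surface neighborhood, not the far field
SDF_CAP_MM = 1.0


def signed_distance_mm(
    mask: np.ndarray, spacing: float, cap: float | None = SDF_CAP_MM
) -> np.ndarray:
    """Positive inside the mask, negative outside (mm), clamped to ±cap."""
    inside = ndi.distance_transform_edt(mask, sampling=spacing)
    outside = ndi.distance_transform_edt(~np.asarray(mask, bool), sampling=spacing)
    sdf = inside - outside
    return np.clip(sdf, -cap, cap) if cap is not None else sdf


def _mean_squares(fixed: sitk.Image, moving: sitk.Image, tx: sitk.Transform) -> float:
    """Mean squared SDF difference over the near-surface band of the fixed
    image (far-field and out-of-grid voxels carry no geometric signal)."""
    sentinel = 1e30
    resampled = sitk.Resample(moving, fixed, tx, sitk.sitkLinear, sentinel)
    a = sitk.GetArrayViewFromImage(fixed)
    b = sitk.GetArrayViewFromImage(resampled)
    band = (a > -0.75 * SDF_CAP_MM) & (b < sentinel / 2)
    if not band.any():
        return float("inf")
    return float(np.mean((a[band] - b[band]) ** 2))


def register_to_template(
    subject_mask: np.ndarray,
    template: TemplateSpace,
    spacing: float,
    demons_iterations: tuple[int, ...] = (30, 20),
    demons_sigma: float = 1.5,
    deformable: bool = True,
) -> SubjectTransform:
    """Affine + demons registration of the subject periosteal geometry onto
    the template. Fails if the image metric worsens across a stage."""
    f_sdf = _to_sitk(signed_distance_mm(template.periosteal_mask, spacing), spacing)
    m_sdf = _to_sitk(signed_distance_mm(subject_mask, spacing), spacing)

    # initialize from the mask centers of mass (the SDF images are signed,
    # so image-moment initializers are not meaningful on them)
    com_f = (np.array(ndi.center_of_mass(template.periosteal_mask)) + 0.5) * spacing
    com_m = (np.array(ndi.center_of_mass(subject_mask)) + 0.5) * spacing
    initial = sitk.AffineTransform(3)
    initial.SetTranslation(tuple(com_m - com_f))
    metric_initial = _mean_squares(f_sdf, m_sdf, initial)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=0.2, minStep=1e-5, numberOfIterations=150,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(initial, inPlace=False)
    affine_tx = reg.Execute(f_sdf, m_sdf).Downcast()
    metric_affine = _mean_squares(f_sdf, m_sdf, affine_tx)
    if metric_affine > metric_initial:
        # keep the center-of-mass initialization if the optimizer drifted
        affine_tx, metric_affine = initial, metric_initial

    composite: sitk.Transform = affine_tx
    disp_arr = None
    metric_final = metric_affine
    if deformable:
        moving_aff = sitk.Resample(m_sdf, f_sdf, affine_tx, sitk.sitkLinear, 0.0)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(sum(demons_iterations)))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(demons_sigma)
        disp = demons.Execute(f_sdf, moving_aff)
        disp_tx = sitk.DisplacementFieldTransform(sitk.Image(disp))
        comp = sitk.CompositeTransform(3)
        comp.AddTransform(affine_tx)
        comp.AddTransform(disp_tx)  # applied first: template -> warped space
        metric_def = _mean_squares(f_sdf, m_sdf, comp)
        if metric_def <= metric_affine * 1.05:
            composite = comp
            metric_final = metric_def
            disp_arr = np.moveaxis(sitk.GetArrayFromImage(disp), (0, 1, 2), (2, 1, 0))
        # else: keep affine-only (demons did not help; still a valid fit)

    if metric_final > metric_initial * 1.05:
        raise RegistrationError(
            f"registration worsened the geometric metric "
            f"({metric_initial:.4g} -> {metric_final:.4g})"
        )

    # extract the 4x4 matrix numerically (independent of the wrapper type)
    origin = np.asarray(affine_tx.TransformPoint((0.0, 0.0, 0.0)))
    cols = [
        np.asarray(affine_tx.TransformPoint(tuple(np.eye(3)[i]))) - origin
        for i in range(3)
    ]
    aff4 = np.eye(4)
    aff4[:3, :3] = np.column_stack(cols)
    aff4[:3, 3] = origin
    return SubjectTransform(
        affine=aff4,
        displacement=disp_arr,
        composite=composite,
        metric_initial=metric_initial,
        metric_final=metric_final,
    )


def resample_map_to_template(
    subject_map: np.ndarray,
    transform: SubjectTransform,
    template_shape: tuple[int, int, int],
    spacing: float,
    validity_threshold: float = 0.99,
) -> np.ndarray:
    """Trilinear resampling with NaN (undefined-flag) propagation."""
    ref = _to_sitk(np.zeros(template_shape), spacing)
    values = np.where(np.isnan(subject_map), 0.0, subject_map)
    validity = (~np.isnan(subject_map)).astype(np.float64)
    v_img = sitk.Resample(
        _to_sitk(values, spacing), ref, transform.composite, sitk.sitkLinear, 0.0
    )
    w_img = sitk.Resample(
        _to_sitk(validity, spacing), ref, transform.composite, sitk.sitkLinear, 0.0
    )
    v = _from_sitk(v_img)
    w = _from_sitk(w_img)
    out = np.full(template_shape, np.nan)
    ok = w >= validity_threshold
    out[ok] = v[ok] / w[ok]
    return out


def transform_points(transform: SubjectTransform, points_mm: np.ndarray) -> np.ndarray:
    """Map template-space points into subject space."""
    return np.array(
        [transform.composite.TransformPoint(tuple(p)) for p in np.asarray(points_mm)]
    )


def correspond_surfaces(
    subject_mesh: trimesh.Trimesh,
    subject_vertex_maps: dict,
    template_mesh: trimesh.Trimesh,
    transform: SubjectTransform,
    max_distance_mm: float = 0.5,
    n_candidates: int = 8,
) -> tuple[dict, np.ndarray]:
    """Subject per-vertex values sampled at template vertices.

    Each template vertex is mapped through the template->subject transform,
    projected onto the nearest subject face, and the subject maps are
    interpolated barycentrically. Vertices farther than ``max_distance_mm``
    from the subject surface are NaN. Returns (maps, distances)."""
    pts = transform_points(transform, template_mesh.vertices)
    tri = subject_mesh.triangles  # (f, 3, 3)
    centroids = tri.mean(axis=1)
    tree = cKDTree(centroids)
    _, cand = tree.query(pts, k=min(n_candidates, len(centroids)))
    cand = np.atleast_2d(cand)

    n = len(pts)
    out = {name: np.full(n, np.nan) for name in subject_vertex_maps}
    dists = np.full(n, np.inf)
    faces = subject_mesh.faces
    verts = subject_mesh.vertices
    for i in range(n):
        best = None
        for f in np.atleast_1d(cand[i]):
            a, b, c = verts[faces[f]]
            w, d = _closest_point_barycentric(pts[i], a, b, c)
            if d < dists[i]:
                dists[i] = d
                best = (f, w)
        if best is None or dists[i] > max_distance_mm:
            continue
        f, w = best
        for name, vals in subject_vertex_maps.items():
            vv = np.asarray(vals)[faces[f]]
            out[name][i] = float(w @ vv)  # NaN subject vertices propagate
    return out, dists


def _closest_point_barycentric(p, a, b, c):
    """Closest point on triangle abc to p: barycentric weights and distance."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab @ ap
    d2 = ac @ ap
    if d1 <= 0 and d2 <= 0:
        w = np.array([1.0, 0.0, 0.0])
    else:
        bp = p - b
        d3 = ab @ bp
        d4 = ac @ bp
        cp = p - c
        d5 = ab @ cp
        d6 = ac @ cp
        if d3 >= 0 and d4 <= d3:
            w = np.array([0.0, 1.0, 0.0])
        elif d6 >= 0 and d5 <= d6:
            w = np.array([0.0, 0.0, 1.0])
        else:
            vc = d1 * d4 - d3 * d2
            vb = d5 * d2 - d1 * d6
            va = d3 * d6 - d5 * d4
            if vc <= 0 and d1 >= 0 and d3 <= 0:
                v = d1 / (d1 - d3)
                w = np.array([1 - v, v, 0.0])
            elif vb <= 0 and d2 >= 0 and d6 <= 0:
                v = d2 / (d2 - d6)
                w = np.array([1 - v, 0.0, v])
            elif va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
                v = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                w = np.array([0.0, 1 - v, v])
            else:
                denom = va + vb + vc
                v = vb / denom
                u = vc / denom
                w = np.array([1 - v - u, v, u])
    q = w[0] * a + w[1] * b + w[2] * c
    return w, float(np.linalg.norm(p - q))


# --------------------------------------------------------------------------
# shape covariates
# --------------------------------------------------------------------------


@dataclass
class ShapeCovariates:
    scores: np.ndarray  # (n_subjects, k)
    variance_explained: np.ndarray
    k_90: int  # components needed for 90 % variance
    k_used: int


def _procrustes_align(points: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigid (rotation + translation) alignment; scale retained."""
    mu_p = points.mean(axis=0)
    mu_t = target.mean(axis=0)
    P = points - mu_p
    T = target - mu_t
    U, _, Vt = np.linalg.svd(P.T @ T)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return P @ R + mu_t


def shape_pca(
    vertex_sets: list[np.ndarray],
    k: int = 4,
    variance_target: float = 0.90,
    n_align_iters: int = 2,
) -> ShapeCovariates:
    """PCA of Procrustes-aligned corresponded periosteal vertex sets.

    Returns the first max(k, k_90) scores where k_90 is the smallest number
    of components reaching the variance target. Scores are zero-mean.
    """
    n = len(vertex_sets)
    if n < max(2, k + 1):
        raise ValueError(
            f"need at least {max(2, k + 1)} subjects for {k} shape components"
        )
    shapes = [np.asarray(v, np.float64) for v in vertex_sets]
    if len({s.shape for s in shapes}) != 1:
        raise ValueError("vertex sets must be in correspondence (equal shapes)")
    ref = shapes[0]
    for _ in range(n_align_iters):
        aligned = [_procrustes_align(s, ref) for s in shapes]
        ref = np.mean(aligned, axis=0)
    X = np.stack([a.ravel() for a in aligned])
    n_comp = min(n - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    scores_all = pca.fit_transform(X)
    var = pca.explained_variance_ratio_
    cum = np.cumsum(var)
    k_90 = int(np.searchsorted(cum, variance_target) + 1)
    k_used = min(max(k, k_90), n_comp) if k else min(k_90, n_comp)
    if n <= k_used:
        raise ValueError(f"need more than {k_used} subjects for {k_used} components")
    return ShapeCovariates(
        scores=scores_all[:, :k_used],
        variance_explained=var[:k_used],
        k_90=k_90,
        k_used=k_used,
    )


# --------------------------------------------------------------------------
# template construction
# --------------------------------------------------------------------------


def build_template(
    volumes: list[CalibratedVolume],
    periosteal_masks: list[np.ndarray],
    trabecular_masks: list[np.ndarray],
    meshes: list[trimesh.Trimesh],
    reference_index: int | None = None,
) -> TemplateSpace:
    """Designated-reference template: the subject of median global size.

    With ``reference_index`` given, that subject is used directly.
    """
    if len(volumes) == 0:
        raise ValueError("empty cohort")
    if reference_index is None:
        sizes = [m.sum() for m in periosteal_masks]
        reference_index = int(np.argsort(sizes)[len(sizes) // 2])
    return TemplateSpace(
        volume=volumes[reference_index],
        periosteal_mask=periosteal_masks[reference_index],
        trabecular_mask=trabecular_masks[reference_index],
        mesh=meshes[reference_index],
        provenance=f"reference-subject-{reference_index}",
    )
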