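"""Parametric maps: homogenized trabecular voxel maps and streamline-based
cortical surface maps.

Trabecular side: spherical-kernel means (uniform weights) of BMD, SED and
the bone indicator (local BV/TV), and a marrow local-thickness field
(inter-trabecular distance, reported in voxels) homogenized with a smaller
kernel. Maps live on the trabecular domain eroded by the kernel radius so
no kernel touches the cortex.

Cortical side: a harmonic potential (0 on the periosteal boundary, 1 on the
endosteal boundary) is solved on the cortical domain; streamlines of its
gradient connect the two surfaces without crossing. Arc length gives the
apparent cortical thickness per periosteal vertex; integrals / means of the
soft cortical membership, BMD and SED along the trajectories give the
streamline integral thickness (SIT), mean cortical BMD and mean cortical
SED.

All mm coordinates place the center of voxel (i, j, k) at ((i+.5)h, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage as ndi
from scipy import sparse
from scipy.ndimage import map_coordinates
from scipy.signal import fftconvolve
from scipy.sparse.linalg import spsolve
from skimage.measure import marching_cubes

from .core import CalibratedVolume
from .segmentation import CompartmentSegmentation


class EmptyDomainError(ValueError):
    pass


# --------------------------------------------------------------------------
# voxel maps
# --------------------------------------------------------------------------


def ball_kernel(radius: int) -> np.ndarray:
    """Voxel ball: offsets with ||u|| <= radius (center-to-center distance)."""
    r = int(radius)
    g = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    return (X**2 + Y**2 + Z**2) <= radius**2


def homogenize(values: np.ndarray, domain_mask: np.ndarray, radius: int) -> np.ndarray:
    """Spherical-kernel mean of ``values`` over ``domain_mask``.

    out(v) = mean of values over {u : ||u - v|| <= r} ∩ domain. Voxels whose
    kernel does not meet the domain are NaN. Uniform kernel weights.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    domain = np.asarray(domain_mask, bool)
    if not domain.any():
        raise EmptyDomainError("empty homogenization domain")
    kernel = ball_kernel(radius).astype(np.float64)
    vals = np.where(domain, np.asarray(values, np.float64), 0.0)
    num = fftconvolve(vals, kernel, mode="same")
    den = fftconvolve(domain.astype(np.float64), kernel, mode="same")
    out = np.full(domain.shape, np.nan)
    ok = den > 0.5  # at least one domain voxel in the kernel
    out[ok] = num[ok] / den[ok]
    return out


def local_bvtv(
    bone_mask: np.ndarray, trabecular_mask: np.ndarray, radius: int = 11
) -> np.ndarray:
    """Local bone volume fraction: bone indicator homogenized over the
    trabecular domain; values clipped to [0, 1]."""
    out = homogenize(
        np.asarray(bone_mask, np.float64), trabecular_mask, radius
    )
    return np.clip(out, 0.0, 1.0)


def local_thickness(phase: np.ndarray) -> np.ndarray:
    """Local-thickness transform: at each foreground voxel, the diameter (in
    voxels) of the largest inscribed ball that covers the voxel.

    Sphere-fitting over the distance transform, processed by decreasing
    integer radius (each radius class handled with one EDT-based dilation).
    """
    phase = np.asarray(phase, bool)
    lt = np.zeros(phase.shape, dtype=np.float64)
    if not phase.any():
        return lt
    dt = ndi.distance_transform_edt(phase)
    radii = np.unique(np.round(dt[phase]).astype(int))
    radii = radii[radii > 0]
    for r in radii[::-1]:
        centers = phase & (np.round(dt).astype(int) == r)
        if not centers.any():
            continue
        covered = ndi.distance_transform_edt(~centers) <= r
        update = covered & phase & (lt < 2 * r)
        lt[update] = 2 * r
    return lt


def inter_trabecular_distance_map(
    bone_mask: np.ndarray, trabecular_mask: np.ndarray
) -> np.ndarray:
    """Inter-trabecular distance (Tb.1/N) raw field, in voxels.

    Marrow voxels carry the local thickness of the marrow phase (diameter of
    the largest inscribed marrow sphere covering the voxel); bone voxels are
    0. Homogenize with r=5 upstream for the smooth H.Tb.1/N map.
    """
    trab = np.asarray(trabecular_mask, bool)
    if not trab.any():
        raise EmptyDomainError("empty trabecular domain")
    marrow = trab & ~np.asarray(bone_mask, bool)
    if not marrow.any():
        import warnings

        warnings.warn("no marrow in the trabecular domain; Tb.1/N map is zero")
        return np.zeros(trab.shape)
    return local_thickness(marrow)


@dataclass
class VoxelMapSet:
    h_tb_bmd: np.ndarray
    l_tb_bvtv: np.ndarray
    h_tb_1n: np.ndarray
    h_tb_sed: np.ndarray
    erosion_depth: int
    domain_mask: np.ndarray

    def names(self) -> list[str]:
        return ["h_tb_bmd", "l_tb_bvtv", "h_tb_1n", "h_tb_sed"]


def voxel_map_set(
    volume: CalibratedVolume,
    seg: CompartmentSegmentation,
    sed_map: np.ndarray | None = None,
    radius_large: int = 11,
    radius_small: int = 5,
    erosion_depth: int | None = None,
) -> VoxelMapSet:
    """Build the four trabecular maps, restricted to the trabecular domain
    eroded by the kernel radius (kernels never touch the cortex)."""
    trab = np.asarray(seg.trabecular_mask, bool)
    if not trab.any():
        raise EmptyDomainError("empty trabecular domain")
    if erosion_depth is None:
        erosion_depth = radius_large
    eroded = ndi.distance_transform_edt(trab) > erosion_depth
    if not eroded.any():
        raise EmptyDomainError(
            f"trabecular domain vanishes after erosion by {erosion_depth} voxels"
        )

    def _restrict(m):
        out = np.where(eroded, m, np.nan)
        return out

    bmd = np.asarray(volume.data, np.float64)
    h_bmd = _restrict(homogenize(bmd, trab, radius_large))
    l_bvtv = _restrict(local_bvtv(seg.bone_mask, trab, radius_large))
    tb1n_raw = inter_trabecular_distance_map(seg.bone_mask, trab)
    h_1n = _restrict(homogenize(tb1n_raw, trab, radius_small))
    if sed_map is None:
        h_sed = np.full(trab.shape, np.nan)
    else:
        sed = np.where(np.isnan(sed_map), 0.0, sed_map)  # marrow stores no energy
        h_sed = _restrict(homogenize(sed, trab, radius_large))
    return VoxelMapSet(
        h_tb_bmd=h_bmd,
        l_tb_bvtv=l_bvtv,
        h_tb_1n=h_1n,
        h_tb_sed=h_sed,
        erosion_depth=erosion_depth,
        domain_mask=eroded,
    )


# --------------------------------------------------------------------------
# Laplace potential and streamlines
# --------------------------------------------------------------------------

_FACE_OFFSETS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


@dataclass
class LaplaceField:
    potential: np.ndarray  # NaN outside the cortical domain
    extended: np.ndarray  # globally defined guidance field for tracing
    cortical_mask: np.ndarray
    endosteal_signed_mm: np.ndarray  # >0 in cortex, <0 in trabecular region
    periosteal_signed_mm: np.ndarray  # >0 inside the periosteum
    peri_level: np.ndarray  # smoothed periosteal indicator - 0.5 (>0 inside)
    endo_level: np.ndarray  # 0.5 - smoothed trabecular indicator (>0 in cortex)
    spacing: float


def solve_laplace(
    seg: CompartmentSegmentation,
    spacing: float,
    tol: float = 1e-6,
) -> LaplaceField:
    """Harmonic potential on the cortical domain: 0 on the periosteal
    boundary band, 1 on the endosteal boundary band; 6-neighbor finite
    differences, strictly inside (0, 1) in the interior (maximum principle).
    """
    cortical = np.asarray(seg.cortical_mask, bool)
    if not cortical.any():
        raise EmptyDomainError("empty cortical domain")
    exterior = ~np.asarray(seg.periosteal_mask, bool)
    trabecular = np.asarray(seg.trabecular_mask, bool)

    near_ext = ndi.binary_dilation(exterior) & cortical
    near_trab = ndi.binary_dilation(trabecular) & cortical
    if not near_ext.any() or not near_trab.any():
        raise EmptyDomainError("a Dirichlet boundary is missing")
    bc1 = near_trab
    bc0 = near_ext & ~bc1
    interior = cortical & ~bc0 & ~bc1

    pot = np.full(cortical.shape, np.nan)
    pot[bc0] = 0.0
    pot[bc1] = 1.0

    if interior.any():
        n_int = int(interior.sum())
        index = -np.ones(cortical.shape, dtype=np.int64)
        index[interior] = np.arange(n_int)
        coords = np.argwhere(interior)
        diag = np.zeros(n_int)
        rhs = np.zeros(n_int)
        rows, cols, vals = [], [], []
        shape = cortical.shape
        for off in _FACE_OFFSETS:
            nb = coords + off
            inb = (
                (nb[:, 0] >= 0) & (nb[:, 0] < shape[0])
                & (nb[:, 1] >= 0) & (nb[:, 1] < shape[1])
                & (nb[:, 2] >= 0) & (nb[:, 2] < shape[2])
            )
            nbc = np.clip(nb, 0, np.array(shape) - 1)
            in_cort = cortical[nbc[:, 0], nbc[:, 1], nbc[:, 2]] & inb
            # Neumann (reflecting) at grid edges / non-cortical neighbors
            diag += in_cort.astype(float)
            nb_idx = index[nbc[:, 0], nbc[:, 1], nbc[:, 2]]
            is_int = in_cort & (nb_idx >= 0)
            rows.append(np.nonzero(is_int)[0])
            cols.append(nb_idx[is_int])
            vals.append(-np.ones(is_int.sum()))
            is_bc = in_cort & (nb_idx < 0)
            bvals = pot[nbc[is_bc, 0], nbc[is_bc, 1], nbc[is_bc, 2]]
            np.add.at(rhs, np.nonzero(is_bc)[0], bvals)
        A = sparse.coo_matrix(
            (
                np.concatenate(vals + [diag]),
                (
                    np.concatenate(rows + [np.arange(n_int)]),
                    np.concatenate(cols + [np.arange(n_int)]),
                ),
            ),
            shape=(n_int, n_int),
        ).tocsr()
        x = spsolve(A, rhs)
        pot[interior] = x

    d_in_trab = ndi.distance_transform_edt(trabecular)
    d_out_trab = ndi.distance_transform_edt(~trabecular)
    endo_signed = (d_out_trab - d_in_trab) * spacing
    d_in_peri = ndi.distance_transform_edt(~exterior)
    d_out_peri = ndi.distance_transform_edt(exterior)
    peri_signed = (d_in_peri - d_out_peri) * spacing

    extended = pot.copy()
    extended[exterior] = -0.05 * d_out_peri[exterior]
    extended[trabecular] = 1.0 + 0.05 * d_in_trab[trabecular]
    # any remaining undefined voxels (non-cortical, non-trab, inside): ramp 0
    extended[np.isnan(extended)] = 0.0

    # level-set functions for sub-voxel surface crossings; the smoothing
    # matches extract_periosteal_mesh so streamlines start and stop on the
    # same surfaces the mesh vertices sit on
    peri_level = ndi.gaussian_filter((~exterior).astype(np.float64), 1.0) - 0.5
    endo_level = 0.5 - ndi.gaussian_filter(trabecular.astype(np.float64), 1.0)
    return LaplaceField(
        potential=pot,
        extended=extended,
        cortical_mask=cortical,
        endosteal_signed_mm=endo_signed,
        periosteal_signed_mm=peri_signed,
        peri_level=peri_level,
        endo_level=endo_level,
        spacing=spacing,
    )


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------


def extract_periosteal_mesh(
    periosteal_mask: np.ndarray,
    spacing: float,
    smoothing_sigma: float = 1.0,
    target_vertices: int = 5000,
) -> trimesh.Trimesh:
    """Triangulated periosteal surface (isosurface of the smoothed mask at
    0.5), vertices in the package's mm frame; vertex-clustered down to the
    target budget when larger."""
    padded = np.pad(np.asarray(periosteal_mask, np.float64), ((0, 0), (0, 0), (1, 1)))
    f = ndi.gaussian_filter(padded, smoothing_sigma)
    verts, faces, _, _ = marching_cubes(f, level=0.5, spacing=(spacing,) * 3)
    verts = verts + 0.5 * spacing  # voxel centers at (i + 1/2) h
    verts[:, 2] -= spacing  # undo the axial padding (closes the end caps)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if len(mesh.vertices) > target_vertices:
        mesh = _cluster_decimate(mesh, target_vertices)
    return mesh


def _cluster_decimate(mesh: trimesh.Trimesh, target_vertices: int) -> trimesh.Trimesh:
    """Simple uniform vertex clustering to approximately the vertex budget."""
    verts = mesh.vertices
    lo = verts.min(axis=0)
    span = np.ptp(verts, axis=0).max()
    n_cells = max(2, int(np.ceil(target_vertices ** (1 / 3) * 1.3)))
    cell = span / n_cells
    keys = np.floor((verts - lo) / cell).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_new = inverse.max() + 1
    new_verts = np.zeros((n_new, 3))
    counts = np.bincount(inverse, minlength=n_new).astype(float)
    for d in range(3):
        new_verts[:, d] = np.bincount(inverse, weights=verts[:, d], minlength=n_new)
    new_verts /= counts[:, None]
    new_faces = inverse[mesh.faces]
    ok = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return trimesh.Trimesh(vertices=new_verts, faces=new_faces[ok], process=True)


# --------------------------------------------------------------------------
# streamlines
# --------------------------------------------------------------------------


@dataclass
class StreamlineSet:
    points: list  # per-seed (n_i, 3) mm polylines (None where undefined)
    arc_lengths: np.ndarray  # mm, NaN where undefined
    seed_ids: np.ndarray
    defined: np.ndarray  # bool per seed


def _sample(field: np.ndarray, pts_mm: np.ndarray, spacing: float, order=1) -> np.ndarray:
    coords = (pts_mm / spacing - 0.5).T
    return map_coordinates(field, coords, order=order, mode="nearest")


def trace_streamlines(
    lap: LaplaceField,
    seeds_mm: np.ndarray,
    step_mm: float | None = None,
    max_length_mm: float | None = None,
) -> StreamlineSet:
    """Integrate the normalized potential gradient from each periosteal seed
    to the endosteal surface (RK2, step <= half a voxel).

    The arc length is measured between the periosteal and endosteal
    zero-level sets (sub-voxel crossings by linear interpolation), so it is
    the apparent cortical thickness at the seed vertex. Seeds whose
    trajectory stalls or exceeds ``max_length_mm`` are flagged undefined.
    """
    h = lap.spacing
    if step_mm is None:
        step_mm = h / 2.0
    if max_length_mm is None:
        max_length_mm = 4.0 * np.nanmax(np.abs(lap.endosteal_signed_mm)) + 20 * h

    gx, gy, gz = np.gradient(lap.extended, h)

    def grad_dir(pts):
        g = np.stack(
            [_sample(gx, pts, h), _sample(gy, pts, h), _sample(gz, pts, h)], axis=1
        )
        norm = np.linalg.norm(g, axis=1)
        ok = norm > 1e-10
        g[ok] /= norm[ok, None]
        return g, ok

    n = len(seeds_mm)
    pos = np.asarray(seeds_mm, np.float64).copy()
    arc = np.zeros(n)
    started = np.zeros(n, dtype=bool)  # crossed the periosteal surface
    active = np.ones(n, dtype=bool)
    failed = np.zeros(n, dtype=bool)
    paths = [[p.copy()] for p in pos]

    d_peri = _sample(lap.peri_level, pos, h)
    started |= d_peri >= 0  # seeds already inside count from the surface

    max_steps = int(np.ceil(max_length_mm / step_mm)) + 50
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        p = pos[idx]
        d1, ok1 = grad_dir(p)
        mid = p + 0.5 * step_mm * d1
        d2, ok2 = grad_dir(mid)
        ok = ok1 & ok2
        newp = p + step_mm * d2

        d_endo_old = _sample(lap.endo_level, p, h)
        d_endo_new = _sample(lap.endo_level, newp, h)
        d_peri_old = _sample(lap.peri_level, p, h)
        d_peri_new = _sample(lap.peri_level, newp, h)

        for j, i in enumerate(idx):
            if not ok[j]:
                failed[i] = True
                active[i] = False
                continue
            seg_len = step_mm
            entry_frac = 0.0
            if not started[i]:
                if d_peri_new[j] >= 0:  # crossing into the periosteum
                    denom = d_peri_new[j] - d_peri_old[j]
                    entry_frac = (
                        float(np.clip(-d_peri_old[j] / denom, 0.0, 1.0))
                        if abs(denom) > 1e-12
                        else 0.0
                    )
                    started[i] = True
                    # restart the polyline on the periosteal surface so the
                    # quadrature integrates over the measured arc only
                    paths[i] = [p[j] + entry_frac * (newp[j] - p[j])]
                else:
                    pos[i] = newp[j]
                    paths[i].append(newp[j].copy())
                    arc[i] += 0.0  # not counting pre-surface travel
                    if len(paths[i]) * step_mm > max_length_mm:
                        failed[i] = True
                        active[i] = False
                    continue
            if d_endo_new[j] <= 0:  # crossing the endosteal surface: stop
                denom = d_endo_new[j] - d_endo_old[j]
                frac = (
                    float(np.clip(d_endo_old[j] / -denom, 0.0, 1.0))
                    if abs(denom) > 1e-12
                    else 1.0
                )
                end = p[j] + frac * (newp[j] - p[j])
                arc[i] += (frac - entry_frac) * seg_len
                paths[i].append(end)
                active[i] = False
            else:
                arc[i] += (1.0 - entry_frac) * seg_len
                pos[i] = newp[j]
                paths[i].append(newp[j].copy())
                if arc[i] > max_length_mm:
                    failed[i] = True
                    active[i] = False

    failed |= active  # never reached the endosteal surface
    defined = ~failed
    arc_out = np.where(defined, arc, np.nan)
    out_paths = [
        np.asarray(paths[i]) if defined[i] else None for i in range(n)
    ]
    return StreamlineSet(
        points=out_paths,
        arc_lengths=arc_out,
        seed_ids=np.arange(n),
        defined=defined,
    )


def surface_aggregates(
    streamlines: StreamlineSet,
    membership: np.ndarray,
    bmd: np.ndarray,
    sed: np.ndarray | None,
    spacing: float,
) -> dict:
    """Per-vertex streamline integrals/means (composite trapezoid).

    surf_ct_sit = ∫ membership ds; surf_ct_bmd / surf_ct_sed = arc-length
    weighted means of BMD / SED along the trajectory. Undefined vertices
    propagate as NaN. Maps must be NaN-free (fill SED pores with 0 first).
    """
    n = len(streamlines.points)
    sit = np.full(n, np.nan)
    mbmd = np.full(n, np.nan)
    msed = np.full(n, np.nan)
    for i, path in enumerate(streamlines.points):
        if path is None or len(path) == 0:
            continue
        seg = np.linalg.norm(np.diff(path, axis=0), axis=1) if len(path) > 1 else np.zeros(0)
        total = seg.sum()
        if total <= 0:  # zero-thickness crossing: point sample, zero integral
            pt = path[-1][None]
            sit[i] = 0.0
            mbmd[i] = float(_sample(bmd, pt, spacing)[0])
            if sed is not None:
                msed[i] = float(_sample(sed, pt, spacing)[0])
            continue

        def trapz_of(field):
            v = _sample(field, path, spacing)
            return float(np.sum(0.5 * (v[1:] + v[:-1]) * seg))

        sit[i] = trapz_of(membership)
        mbmd[i] = trapz_of(bmd) / total
        if sed is not None:
            msed[i] = trapz_of(sed) / total
    return {"surf_ct_sit": sit, "surf_ct_bmd": mbmd, "surf_ct_sed": msed}


@dataclass
class SurfaceMapSet:
    mesh: trimesh.Trimesh
    surf_app_ct_th: np.ndarray
    surf_ct_sit: np.ndarray
    surf_ct_bmd: np.ndarray
    surf_ct_sed: np.ndarray

    def names(self) -> list[str]:
        return ["surf_app_ct_th", "surf_ct_sit", "surf_ct_bmd", "surf_ct_sed"]

    def save_ply(self, path) -> None:
        write_vertex_maps_ply(
            self.mesh, {name: getattr(self, name) for name in self.names()}, path
        )


def surface_map_set(
    volume: CalibratedVolume,
    seg: CompartmentSegmentation,
    sed_map: np.ndarray | None = None,
    mesh: trimesh.Trimesh | None = None,
    target_vertices: int = 5000,
    axial_band_voxels: int = 3,
    tol: float = 1e-6,
) -> SurfaceMapSet:
    """End-to-end cortical surface maps for one subject.

    Vertices within ``axial_band_voxels`` of the axial ends are flagged
    undefined (their streamlines would leave the scanned section).
    """
    h = volume.spacing[0]
    if mesh is None:
        mesh = extract_periosteal_mesh(
            seg.periosteal_mask, h, target_vertices=target_vertices
        )
    lap = solve_laplace(seg, h, tol=tol)
    seeds = np.asarray(mesh.vertices)
    nz = volume.shape[2]
    in_band = (seeds[:, 2] >= axial_band_voxels * h) & (
        seeds[:, 2] <= (nz - axial_band_voxels) * h
    )
    sl = trace_streamlines(lap, seeds)
    sl.defined &= in_band
    sl.arc_lengths = np.where(sl.defined, sl.arc_lengths, np.nan)

    if seg.membership is None:
        raise ValueError("segmentation carries no membership map; run attach_membership")
    sed_filled = None
    if sed_map is not None:
        sed_filled = np.where(np.isnan(sed_map), 0.0, sed_map)
    agg = surface_aggregates(
        sl, seg.membership, np.asarray(volume.data, np.float64), sed_filled, h
    )
    return SurfaceMapSet(
        mesh=mesh,
        surf_app_ct_th=sl.arc_lengths,
        surf_ct_sit=agg["surf_ct_sit"],
        surf_ct_bmd=agg["surf_ct_bmd"],
        surf_ct_sed=agg["surf_ct_sed"],
    )


def write_vertex_maps_ply(mesh: trimesh.Trimesh, vertex_maps: dict, path) -> None:
    """Binary little-endian PLY with one float property per vertex map."""
    verts = np.asarray(mesh.vertices, np.float32)
    faces = np.asarray(mesh.faces, np.int32)
    names = list(vertex_maps)
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {len(verts)}",
              "property float x", "property float y", "property float z"]
    header += [f"property float {name}" for name in names]
    header += [f"element face {len(faces)}",
               "property list uchar int vertex_indices", "end_header"]
    vdata = np.empty((len(verts), 3 + len(names)), np.float32)
    vdata[:, :3] = verts
    for j, name in enumerate(names):
        vdata[:, 3 + j] = np.asarray(vertex_maps[name], np.float32)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode())
        fh.write(vdata.astype("<f4").tobytes())
        rec = np.zeros(len(faces), dtype=[("n", "u1"), ("idx", "<i4", 3)])
        rec["n"] = 3
        rec["idx"] = faces
        fh.write(rec.tobytes())


def read_vertex_maps_ply(path) -> tuple[trimesh.Trimesh, dict]:
    """Read back the PLY written by :func:`write_vertex_maps_ply`."""
    with open(path, "rb") as fh:
        header = []
        while True:
            line = fh.readline().decode().strip()
            header.append(line)
            if line == "end_header":
                break
        n_vert = int(next(l for l in header if l.startswith("element vertex")).split()[-1])
        n_face = int(next(l for l in header if l.startswith("element face")).split()[-1])
        props = [l.split()[-1] for l in header if l.startswith("property float")]
        vdata = np.frombuffer(fh.read(n_vert * 4 * len(props)), "<f4").reshape(
            n_vert, len(props)
        )
        rec = np.frombuffer(
            fh.read(n_face * 13), dtype=[("n", "u1"), ("idx", "<i4", 3)]
        )
    mesh = trimesh.Trimesh(vertices=vdata[:, :3], faces=rec["idx"], process=False)
    maps = {name: vdata[:, 3 + j].astype(np.float64) for j, name in enumerate(props[3:])}
    return mesh, maps
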