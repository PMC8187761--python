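"""Linear voxel-based micro-finite-element analysis under axial compression.

Every bone voxel becomes an 8-node hexahedral element with isotropic linear
elasticity (default tissue modulus 6829 MPa, Poisson ratio 0.3). A 1 % axial
compression is applied by displacing the proximal face axially while the
distal face is held axially; lateral motion of the end faces is free (three
in-plane rigid-body modes are removed by statically determinate pins that
are consistent with the exact uniaxial-stress field). Outputs: reaction
force, stiffness (N/mm), per-element strain energy density (J/mm^3), and a
critical-strain failure load.

Units: lengths mm, modulus MPa, so forces are N and SED is J/mm^3 (= MPa)
without conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse.linalg import cg


class UnsolvableModelError(ValueError):
    """No axially spanning bone component."""


class FESolverError(RuntimeError):
    def __init__(self, message, residual=None, iterations=None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


_NODE_OFFSETS = np.array(
    [
        (0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
        (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1),
    ],
    dtype=np.int64,
)


@dataclass
class FEModel:
    element_mask: np.ndarray  # bool, pruned to the axially spanning set
    spacing: float  # mm
    elastic_modulus: float = 6829.0  # MPa
    poisson_ratio: float = 0.3
    applied_strain: float = 0.01
    removed_elements: int = 0
    z_bottom: int = 0  # distal element layer index
    z_top: int = 0  # proximal element layer index

    @property
    def n_elements(self) -> int:
        return int(self.element_mask.sum())

    @property
    def axial_length_mm(self) -> float:
        return (self.z_top - self.z_bottom + 1) * self.spacing


@dataclass
class FEResult:
    displacements: np.ndarray  # (n_nodes, 3) mm
    node_coords: np.ndarray  # (n_nodes, 3) voxel-corner indices
    reaction_force: float  # N, axial, on the displaced face
    stiffness: float  # N/mm
    sed_elements: np.ndarray  # per retained element, J/mm^3
    sed_map: np.ndarray  # 3D, NaN outside elements
    applied_displacement: float  # mm
    solver_iters: int
    residual: float
    energy_balance_error: float  # |sum SED*V - 0.5 F d| / max(.,eps)
    reaction_balance_error: float
    failure_load: float | None = None
    extras: dict = field(default_factory=dict)


def hex8_stiffness(elastic_modulus: float, poisson_ratio: float, h: float) -> np.ndarray:
    """24x24 stiffness of a cubic 8-node hexahedron (2x2x2 Gauss)."""
    E, nu = elastic_modulus, poisson_ratio
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[3:, 3:] = np.eye(3) * mu

    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    signs = 2 * _NODE_OFFSETS - 1  # corner signs in (-1, 1)^3
    Ke = np.zeros((24, 24))
    detJ = (h / 2.0) ** 3
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                dN = np.zeros((8, 3))
                for a in range(8):
                    sx, sy, sz = signs[a]
                    dN[a, 0] = 0.125 * sx * (1 + sy * eta) * (1 + sz * zeta)
                    dN[a, 1] = 0.125 * sy * (1 + sx * xi) * (1 + sz * zeta)
                    dN[a, 2] = 0.125 * sz * (1 + sx * xi) * (1 + sy * eta)
                dN = dN * (2.0 / h)  # physical derivatives
                B = np.zeros((6, 24))
                for a in range(8):
                    bx, by, bz = dN[a]
                    c = 3 * a
                    B[0, c] = bx
                    B[1, c + 1] = by
                    B[2, c + 2] = bz
                    B[3, c] = by
                    B[3, c + 1] = bx
                    B[4, c + 1] = bz
                    B[4, c + 2] = by
                    B[5, c] = bz
                    B[5, c + 2] = bx
                Ke += B.T @ D @ B * detJ
    return Ke


def build_model(
    bone_mask: np.ndarray,
    spacing: float,
    elastic_modulus: float = 6829.0,
    poisson_ratio: float = 0.3,
    applied_strain: float = 0.01,
) -> FEModel:
    """Mesh the bone voxels, pruning elements not face-connected (6-neighbor)
    to both end faces of the axial extent."""
    mask = np.asarray(bone_mask, bool)
    if not mask.any():
        raise UnsolvableModelError("empty bone mask")
    zs = np.nonzero(mask.any(axis=(0, 1)))[0]
    z0, z1 = int(zs[0]), int(zs[-1])
    labels, n = ndi.label(mask, structure=ndi.generate_binary_structure(3, 1))
    bottom = np.unique(labels[:, :, z0])
    top = np.unique(labels[:, :, z1])
    spanning = np.intersect1d(bottom, top)
    spanning = spanning[spanning > 0]
    if spanning.size == 0:
        raise UnsolvableModelError("no bone component spans the axial extent")
    keep = np.isin(labels, spanning)
    removed = int(mask.sum() - keep.sum())
    return FEModel(
        element_mask=keep,
        spacing=float(spacing),
        elastic_modulus=float(elastic_modulus),
        poisson_ratio=float(poisson_ratio),
        applied_strain=float(applied_strain),
        removed_elements=removed,
        z_bottom=z0,
        z_top=z1,
    )


def _mesh(model: FEModel):
    """Deterministic node numbering and element->node connectivity."""
    mask = model.element_mask
    nx, ny, nz = mask.shape
    corner = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    idx = np.argwhere(mask)
    for off in _NODE_OFFSETS:
        corner[idx[:, 0] + off[0], idx[:, 1] + off[1], idx[:, 2] + off[2]] = True
    node_id = -np.ones(corner.shape, dtype=np.int64)
    coords = np.argwhere(corner)
    node_id[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(len(coords))
    elem_nodes = np.empty((len(idx), 8), dtype=np.int64)
    for a, off in enumerate(_NODE_OFFSETS):
        elem_nodes[:, a] = node_id[
            idx[:, 0] + off[0], idx[:, 1] + off[1], idx[:, 2] + off[2]
        ]
    return coords, elem_nodes, idx


def assemble_stiffness(model: FEModel):
    """Global CSR stiffness matrix plus mesh bookkeeping."""
    coords, elem_nodes, elem_idx = _mesh(model)
    Ke = hex8_stiffness(model.elastic_modulus, model.poisson_ratio, model.spacing)
    ne = elem_nodes.shape[0]
    gdof = (3 * elem_nodes[:, :, None] + np.arange(3)).reshape(ne, 24)
    rows = np.repeat(gdof, 24, axis=1).ravel()
    cols = np.tile(gdof, (1, 24)).ravel()
    data = np.tile(Ke.ravel(), ne)
    ndof = 3 * len(coords)
    K = sparse.coo_matrix((data, (rows, cols)), shape=(ndof, ndof)).tocsr()
    return K, coords, elem_nodes, elem_idx, Ke


def _boundary_conditions(model: FEModel, coords: np.ndarray):
    """Constrained dof indices and values for the compression test."""
    z0 = model.z_bottom
    z1 = model.z_top + 1  # node layer of the proximal face
    delta = model.applied_strain * model.axial_length_mm

    bottom_nodes = np.nonzero(coords[:, 2] == z0)[0]
    top_nodes = np.nonzero(coords[:, 2] == z1)[0]

    cons_idx = [3 * bottom_nodes + 2, 3 * top_nodes + 2]
    cons_val = [np.zeros(len(bottom_nodes)), np.full(len(top_nodes), -delta)]

    # statically determinate in-plane pins on the distal face, consistent
    # with the exact uniaxial-stress field (no spurious stress)
    order = np.lexsort((coords[bottom_nodes, 1], coords[bottom_nodes, 0]))
    a = bottom_nodes[order[0]]
    cons_idx.append(np.array([3 * a, 3 * a + 1]))
    cons_val.append(np.zeros(2))
    same_y = bottom_nodes[
        (coords[bottom_nodes, 1] == coords[a, 1]) & (bottom_nodes != a)
    ]
    b = same_y[np.argmax(np.abs(coords[same_y, 0] - coords[a, 0]))] if same_y.size else None
    if b is None:
        others = bottom_nodes[bottom_nodes != a]
        b = others[0] if others.size else None
    if b is not None:
        cons_idx.append(np.array([3 * b + 1]))
        cons_val.append(np.zeros(1))

    cons_idx = np.concatenate(cons_idx)
    cons_val = np.concatenate(cons_val)
    cons_idx, unique_pos = np.unique(cons_idx, return_index=True)
    cons_val = cons_val[unique_pos]
    return cons_idx, cons_val, top_nodes, bottom_nodes, delta


def solve_compression(
    model: FEModel, tol: float = 1e-6, max_iter: int | None = None
) -> FEResult:
    """Solve the axial-compression problem to relative residual < ``tol``.

    Jacobi-preconditioned conjugate gradients on the assembled reduced
    system. Raises :class:`FESolverError` on non-convergence.
    """
    K, coords, elem_nodes, elem_idx, Ke = assemble_stiffness(model)
    cons_idx, cons_val, top_nodes, bottom_nodes, delta = _boundary_conditions(
        model, coords
    )
    ndof = K.shape[0]
    free = np.ones(ndof, dtype=bool)
    free[cons_idx] = False
    u = np.zeros(ndof)
    u[cons_idx] = cons_val

    if model.applied_strain == 0.0:
        sed = np.zeros(len(elem_nodes))
        return _package_result(
            model, coords, elem_nodes, elem_idx, u, sed, top_nodes, bottom_nodes,
            0.0, 0, 0.0, K,
        )

    Kff = K[free][:, free]
    rhs = -K[free][:, ~free] @ cons_val
    diag = Kff.diagonal()
    diag[diag <= 0] = 1.0
    M = sparse.diags(1.0 / diag)
    if max_iter is None:
        max_iter = max(2000, int(20 * np.sqrt(ndof)))
    iters = 0

    def _count(_):
        nonlocal iters
        iters += 1

    x, info = cg(Kff, rhs, rtol=tol, atol=0.0, maxiter=max_iter, M=M, callback=_count)
    resid = float(np.linalg.norm(Kff @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if info != 0:
        raise FESolverError(
            f"CG failed to converge in {iters} iterations (residual {resid:.2e})",
            residual=resid,
            iterations=iters,
        )
    u[free] = x

    ue = u[(3 * elem_nodes[:, :, None] + np.arange(3)).reshape(-1, 24)]
    energy = 0.5 * np.einsum("ei,ij,ej->e", ue, Ke, ue)
    sed = energy / model.spacing**3
    return _package_result(
        model, coords, elem_nodes, elem_idx, u, sed, top_nodes, bottom_nodes,
        resid, iters, delta, K,
    )


def _package_result(
    model, coords, elem_nodes, elem_idx, u, sed, top_nodes, bottom_nodes,
    resid, iters, delta, K,
) -> FEResult:
    reactions = K @ u
    f_top = float(reactions[3 * top_nodes + 2].sum())
    f_bottom = float(reactions[3 * bottom_nodes + 2].sum())
    f_mag = max(abs(f_top), abs(f_bottom), 1e-300)
    balance = abs(f_top + f_bottom) / f_mag if delta != 0 else 0.0
    reaction = abs(f_top)
    stiffness = reaction / delta if delta > 0 else 0.0

    total_energy = float(sed.sum() * model.spacing**3)
    external_work = 0.5 * reaction * delta
    eb = (
        abs(total_energy - external_work) / max(external_work, 1e-300)
        if delta != 0
        else 0.0
    )

    sed_map = np.full(model.element_mask.shape, np.nan)
    sed_map[elem_idx[:, 0], elem_idx[:, 1], elem_idx[:, 2]] = sed
    return FEResult(
        displacements=u.reshape(-1, 3),
        node_coords=coords,
        reaction_force=reaction,
        stiffness=stiffness,
        sed_elements=sed,
        sed_map=sed_map,
        applied_displacement=delta,
        solver_iters=iters,
        residual=resid,
        energy_balance_error=eb,
        reaction_balance_error=balance,
    )


def failure_load(
    result: FEResult,
    model: FEModel,
    critical_strain: float = 0.007,
    critical_volume_fraction: float = 0.02,
) -> float:
    """Critical-strain failure load.

    Effective strain per element from the energy-equivalent definition
    sqrt(2 SED / E). The linear model is scaled by s such that exactly the
    critical volume fraction of tissue exceeds the critical strain:
    s = critical_strain / quantile_{1-f}(effective strain). FL = s * F.
    """
    if result.sed_elements.size == 0:
        raise ValueError("result carries no elements")
    eff = np.sqrt(2.0 * np.maximum(result.sed_elements, 0.0) / model.elastic_modulus)
    q = float(np.quantile(eff, 1.0 - critical_volume_fraction))
    if q <= 0:
        raise ValueError("degenerate strain field (all zero)")
    scale = critical_strain / q
    fl = result.reaction_force * scale
    result.failure_load = fl
    return fl
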