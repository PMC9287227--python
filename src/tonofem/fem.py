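"""Small-strain isotropic linear elasticity on the tagged hexahedral meshes.

Assembly uses standard displacement-based isoparametric elements with full
Gauss quadrature (2x2x2 for trilinear, 3x3x3 for serendipity-quadratic
hexahedra).  Pressure is applied as a consistent dead load on the reference
configuration.  Rigid-body motion of the globe is removed either by six
averaged ("remote displacement zero") constraints on the outer scleral
surface, enforced with Lagrange multipliers, or by fixing a posterior
scleral patch.  The unit system is mm-N-MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tonofem import elements as EL
from tonofem.geometry import ProbeSpec
from tonofem.meshing import ShellMesh
from tonofem.units import mmhg_to_mpa

__all__ = [
    "IsotropicMaterial",
    "LoadCase",
    "LinearSystem",
    "ConstrainedSystem",
    "default_materials",
    "material_for_region",
    "assemble_stiffness",
    "apply_internal_pressure",
    "apply_remote_displacement_zero",
    "solve_displacement",
    "recover_stress",
    "StressField",
    "FEMError",
]


class FEMError(RuntimeError):
    pass


@dataclass(frozen=True)
class IsotropicMaterial:
    """Homogeneous isotropic linear-elastic material.

    ``young_modulus`` in MPa, ``poisson_ratio`` dimensionless, ``density``
    in kg/mm^3 (carried for completeness; unused in static analysis).
    """

    young_modulus: float
    poisson_ratio: float
    density: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")

    @property
    def bulk_modulus(self) -> float:
        return self.young_modulus / (3.0 * (1.0 - 2.0 * self.poisson_ratio))

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def lame_lambda(self) -> float:
        e, nu = self.young_modulus, self.poisson_ratio
        return e * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))

    @property
    def lame_mu(self) -> float:
        return self.shear_modulus


def default_materials() -> dict[str, IsotropicMaterial]:
    """Ocular tissue constants: cornea E=0.2 MPa nu=0.43, sclera E=2 MPa
    nu=0.4 (density 9.6e-7 kg/mm^3 each).  The limbal junction band is
    given scleral properties by default."""
    cornea = IsotropicMaterial(0.2, 0.43, density=9.6e-7, name="cornea")
    sclera = IsotropicMaterial(2.0, 0.4, density=9.6e-7, name="sclera")
    return {"cornea": cornea, "sclera": sclera, "junction": sclera}


def material_for_region(region: str, materials: dict[str, IsotropicMaterial]):
    """Resolve a region tag such as ``sclera_nasal`` to a material."""
    if region in materials:
        return materials[region]
    base = region.split("_", 1)[0]
    if base in materials:
        return materials[base]
    raise FEMError(f"no material mapped for region {region!r}")


@dataclass(frozen=True)
class LoadCase:
    """One tonometry loading configuration.

    IOP in mmHg (converted internally at the metrological mmHg), probe
    geometry, target plunging depth in mm measured from the undeformed
    apex plane, and the displacement increment schedule.
    """

    iop_mmhg: float = 20.0
    probe: ProbeSpec = field(default_factory=ProbeSpec)
    target_depth: float = 0.5
    n_increments: int = 10
    constraint_mode: str = "remote-rigid-body"

    def __post_init__(self) -> None:
        if self.iop_mmhg < 0:
            raise ValueError("IOP must be non-negative")
        if self.target_depth < 0:
            raise ValueError("target depth must be non-negative")
        if self.n_increments < 1:
            raise ValueError("need at least one increment")
        if self.constraint_mode not in ("remote-rigid-body", "posterior-patch",
                                        "fixed"):
            raise ValueError(f"unknown constraint mode {self.constraint_mode!r}")

    @property
    def pressure_mpa(self) -> float:
        return mmhg_to_mpa(self.iop_mmhg)


@dataclass
class LinearSystem:
    """Assembled stiffness and load (pre-constraint)."""

    K: sp.csr_matrix
    f: np.ndarray
    mesh: ShellMesh
    quadrature_order: int  # points per direction


def _element_materials(mesh: ShellMesh, materials) -> tuple[np.ndarray, np.ndarray]:
    lam = np.empty(mesh.n_elems)
    mu = np.empty(mesh.n_elems)
    for rid, name in mesh.region_names.items():
        m = material_for_region(name, materials)
        sel = mesh.region_id == rid
        lam[sel] = m.lame_lambda
        mu[sel] = m.lame_mu
    return lam, mu


def assemble_stiffness(
    mesh: ShellMesh, materials: dict[str, IsotropicMaterial], chunk: int = 2000
) -> LinearSystem:
    """Assemble the global stiffness matrix (symmetric, CSR).

    Every region tag must resolve to a material (junction regions resolve
    to the scleral default).  Gauss quadrature: 2^3 (order 1) / 3^3
    (order 2) points.
    """
    lam, mu = _element_materials(mesh, materials)
    _, dN, _, gw = EL.shape_functions(mesh.order)
    nen = mesh.elems.shape[1]
    nd = 3 * nen
    ndof = mesh.ndof

    rows, cols, vals = [], [], []
    for start in range(0, mesh.n_elems, chunk):
        sl = slice(start, min(start + chunk, mesh.n_elems))
        conn = mesh.elems[sl]
        coords = mesh.nodes[conn]
        detJ, gradN = EL.jacobians(coords, dN)
        if np.any(detJ <= 0):
            raise FEMError("non-positive Jacobian during assembly")
        w = detJ * gw[None, :]
        # A1[a,i,b,j] = sum_g w gradN[a,i] gradN[b,j]
        A1 = np.einsum("eg,egai,egbj->eaibj", w, gradN, gradN, optimize=True)
        A3 = np.einsum("eg,egak,egbk->eab", w, gradN, gradN, optimize=True)
        ne_c = conn.shape[0]
        # Ke[3a+i,3b+j] = lam A1[a,i,b,j] + mu A1[a,j,b,i] + mu d_ij A3[a,b];
        # for trilinear hexes the lam (volumetric) term uses the element-mean
        # gradient (selective reduced integration) to avoid volumetric
        # locking at the near-incompressible tissue Poisson ratios
        if mesh.order == 1:
            V = w.sum(axis=1)
            gmean = np.einsum("eg,egai->eai", w, gradN) / V[:, None, None]
            Avol = np.einsum("e,eai,ebj->eaibj", V, gmean, gmean)
        else:
            Avol = A1
        Ke = lam[sl, None, None, None, None] * Avol + mu[sl, None, None, None, None] * (
            A1.transpose(0, 1, 4, 3, 2)
        )
        Ke += mu[sl, None, None, None, None] * (
            np.eye(3)[None, None, :, None, :] * A3[:, :, None, :, None]
        )
        Ke = Ke.reshape(ne_c, nd, nd)
        edof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne_c, nd)
        rows.append(np.repeat(edof, nd, axis=1).ravel())
        cols.append(np.tile(edof, (1, nd)).ravel())
        vals.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()
    K.sum_duplicates()
    return LinearSystem(
        K=K, f=np.zeros(ndof), mesh=mesh,
        quadrature_order=2 if mesh.order == 1 else 3,
    )


def apply_internal_pressure(mesh: ShellMesh, pressure: float) -> np.ndarray:
    """Consistent nodal forces for a uniform pressure on ``inner_surface``.

    The pressure acts along the outward normal of the cavity (it inflates
    the shell); the surface must be closed, so the net resultant vanishes
    by construction.  Returns a load vector of length 3*n_nodes.
    """
    faces = mesh.face_sets.get("inner_surface")
    if faces is None or len(faces) == 0:
        raise FEMError("mesh has no inner_surface set to pressurise")
    _check_closed(faces)
    return pressure * _face_normal_forces(mesh, faces, outward_from_cavity=True)


def _check_closed(faces: np.ndarray) -> None:
    """A closed quad surface has every (corner) edge shared by two faces."""
    c = faces[:, :4]
    e = np.concatenate(
        [np.stack([c[:, k], c[:, (k + 1) % 4]], axis=1) for k in range(4)]
    )
    e = e[e[:, 0] != e[:, 1]]  # drop collapsed pole edges
    e.sort(axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    if np.any(counts != 2):
        raise FEMError("pressure surface is not closed")


def _face_normal_forces(
    mesh: ShellMesh, faces: np.ndarray, outward_from_cavity: bool
) -> np.ndarray:
    """Integral of N^T n over each face, assembled to nodes (unit pressure)."""
    N, dN, gw = EL.face_shape_functions(mesh.order, n_gauss=4)
    coords = mesh.nodes[faces]  # (nf, nfn, 3)
    # dx/dxi, dx/deta at each gauss point
    t1 = np.einsum("fai,gaj->fgij", coords, dN)  # [f,g, i, j] j in {xi,eta}
    n_vec = np.cross(t1[..., 0], t1[..., 1])  # (nf, ngp, 3), |n| = dA/dxi deta
    centroid = mesh.nodes[np.unique(faces)].mean(axis=0)
    mid = coords.mean(axis=1)
    sign = np.sign(np.einsum("fi,fi->f", mid - centroid, n_vec.mean(axis=1)))
    sign[sign == 0] = 1.0
    if not outward_from_cavity:
        sign = -sign
    contrib = np.einsum("g,ga,fgi->fai", gw, N, n_vec)  # per-face nodal force
    contrib *= sign[:, None, None]
    f = np.zeros(mesh.ndof)
    dofs = (3 * faces[:, :, None] + np.arange(3)[None, None, :]).ravel()
    np.add.at(f, dofs, contrib.ravel())
    return f


class ConstrainedSystem:
    """Stiffness with rigid-body constraints, ready for direct solution.

    mode ``remote-rigid-body``: six averaged constraints (zero mean
    translation and zero mean infinitesimal rotation of the constraint
    node set) via Lagrange multipliers -> KKT system.
    mode ``posterior-patch``: all DOFs fixed on constraint nodes whose
    polar angle about the globe centre exceeds 140 degrees from the apex.
    mode ``fixed``: all DOFs fixed on the whole constraint node set.
    """

    def __init__(self, K: sp.csr_matrix, mesh: ShellMesh, mode: str,
                 constraint_set: str = "scleral_outer"):
        self.K = K
        self.mesh = mesh
        self.mode = mode
        self.ndof = K.shape[0]
        nodes = mesh.node_set(constraint_set)
        if nodes.size == 0:
            raise FEMError(f"constraint set {constraint_set!r} is empty")
        self.constraint_nodes = nodes
        self._lu = None
        if mode == "remote-rigid-body":
            C = self._rigid_body_constraints(mesh, nodes)
            self.C = C
            self.n_lag = C.shape[0]
            self.A = sp.bmat([[K, C.T], [C, None]], format="csc")
            self.free = None
        elif mode in ("posterior-patch", "fixed"):
            if mode == "posterior-patch":
                sel = self._posterior_patch(mesh, nodes)
                if sel.size == 0:
                    raise FEMError("posterior patch is empty; globe "
                                   "rigid-body modes unconstrained")
                fixed = (3 * sel[:, None] + np.arange(3)[None, :]).ravel()
            elif "constraints" in mesh.meta:
                # per-set, per-component Dirichlet (e.g. symmetry rollers)
                parts = []
                for set_name, comps in mesh.meta["constraints"]:
                    ns = mesh.node_set(set_name)
                    for c in comps:
                        parts.append(3 * ns + c)
                fixed = np.concatenate(parts)
            else:
                fixed = (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()
            self.fixed_dofs = np.unique(fixed)
            mask = np.ones(self.ndof, dtype=bool)
            mask[self.fixed_dofs] = False
            self.free = np.flatnonzero(mask)
            self.n_lag = 0
            self.A = K[self.free][:, self.free].tocsc()
        else:
            raise FEMError(f"unknown constraint mode {mode!r}")

    @staticmethod
    def _rigid_body_constraints(mesh: ShellMesh, nodes: np.ndarray):
        n = nodes.size
        x = mesh.nodes[nodes]
        xb = x.mean(axis=0)
        r = x - xb
        scale_r = max(np.abs(r).max(), 1.0)
        rows, cols, vals = [], [], []
        # translations
        for c in range(3):
            rows += [c] * n
            cols += list(3 * nodes + c)
            vals += [1.0 / n] * n
        # rotations: sum r x u = 0
        cross_idx = [(1, 2), (2, 0), (0, 1)]
        for c, (a, b) in enumerate(cross_idx):
            rows += [3 + c] * (2 * n)
            cols += list(3 * nodes + b) + list(3 * nodes + a)
            vals += list(r[:, a] / (n * scale_r)) + list(-r[:, b] / (n * scale_r))
        C = sp.coo_matrix((vals, (rows, cols)), shape=(6, mesh.ndof))
        return C.tocsr()

    @staticmethod
    def _posterior_patch(mesh: ShellMesh, nodes: np.ndarray,
                         angle_deg: float = 140.0) -> np.ndarray:
        x = mesh.nodes[nodes]
        centre = mesh.nodes.mean(axis=0)
        apex_dir = np.array([0.0, 0.0, 0.0]) - centre
        apex_dir /= np.linalg.norm(apex_dir)
        v = x - centre
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(v @ apex_dir, -1, 1)))
        return nodes[ang > angle_deg]

    @property
    def lu(self):
        if self._lu is None:
            try:
                self._lu = spla.splu(
                    self.A,
                    permc_spec="MMD_AT_PLUS_A",
                    options=dict(SymmetricMode=True, DiagPivotThresh=1e-3),
                )
            except RuntimeError as exc:  # pragma: no cover
                raise FEMError(
                    f"factorisation failed ({exc}); the constrained system "
                    f"appears singular (unconstrained rigid-body mode?)"
                ) from exc
        return self._lu

    def solve(self, f: np.ndarray) -> np.ndarray:
        """Solve K u = f under the constraints; returns full-length u."""
        if self.free is None:
            rhs = np.concatenate([f, np.zeros(self.n_lag)])
            sol = self.lu.solve(rhs)
            u = sol[: self.ndof]
        else:
            u = np.zeros(self.ndof)
            u[self.free] = self.lu.solve(f[self.free])
        if not np.all(np.isfinite(u)):
            raise FEMError("singular constrained system (non-finite solution); "
                           f"mode={self.mode!r}")
        return u

    def solve_augmented(self, f: np.ndarray) -> np.ndarray:
        """Solve returning the internal (augmented or reduced) vector."""
        if self.free is None:
            return self.lu.solve(np.concatenate([f, np.zeros(self.n_lag)]))
        return self.lu.solve(f[self.free])

    def augmented_rhs(self, f: np.ndarray) -> np.ndarray:
        if self.free is None:
            return np.concatenate([f, np.zeros(self.n_lag)])
        return f[self.free]

    def expand(self, sol: np.ndarray) -> np.ndarray:
        """Augmented/reduced solution vector -> full displacement vector."""
        if self.free is None:
            return sol[: self.ndof]
        u = np.zeros(self.ndof)
        u[self.free] = sol
        return u

    def residual(self, sol: np.ndarray, f: np.ndarray) -> float:
        """Relative residual of the constrained (augmented/reduced) system."""
        rhs = self.augmented_rhs(f)
        r = self.A @ sol - rhs
        denom = max(np.linalg.norm(rhs), 1e-30)
        return float(np.linalg.norm(r) / denom)


def apply_remote_displacement_zero(
    system: LinearSystem, mesh: ShellMesh, mode: str = "remote-rigid-body"
) -> ConstrainedSystem:
    """Remove rigid-body motion of the globe.

    ``remote-rigid-body`` leaves the sclera free to deform but pins its
    mean translation and rotation (deformable-attachment behaviour);
    ``posterior-patch`` fixes the posterior scleral cap instead.
    """
    return ConstrainedSystem(system.K, mesh, mode)


def solve_displacement(
    csys: ConstrainedSystem, f: np.ndarray, rtol: float = 1e-9
) -> np.ndarray:
    """Direct sparse solution with a residual check (relative 1e-9)."""
    rhs = csys.augmented_rhs(f)
    sol = csys.lu.solve(rhs)
    if csys.residual(sol, f) > rtol:
        sol = sol + csys.lu.solve(rhs - csys.A @ sol)  # iterative refinement
        res = csys.residual(sol, f)
        if res > rtol:
            raise FEMError(f"linear solve residual {res:.2e} exceeds {rtol:.0e}")
    u = csys.expand(sol)
    if not np.all(np.isfinite(u)):
        raise FEMError(
            f"singular constrained system (non-finite solution); mode={csys.mode!r}"
        )
    return u


@dataclass
class StressField:
    """Element and nodal stresses plus nodal deformation magnitudes.

    stress: (ne, 6) element-averaged Voigt [xx, yy, zz, yz, xz, xy] in
    MPa, with von_mises (ne,) derived from it; nodal_von_mises (nn,) is
    computed from Gauss-point stresses extrapolated to the nodes and
    averaged across adjacent elements (the convention interactive FE
    post-processors use for contour maxima — element averages smooth
    local peaks considerably); total_deformation (nn,) mm.
    """

    stress: np.ndarray
    von_mises: np.ndarray
    nodal_von_mises: np.ndarray
    total_deformation: np.ndarray

    def max_von_mises(self) -> tuple[float, int]:
        """Maximum element-averaged von Mises stress and its element."""
        e = int(np.argmax(self.von_mises))
        return float(self.von_mises[e]), e

    def max_nodal_von_mises(self) -> tuple[float, int]:
        """Maximum averaged-nodal von Mises stress and its node."""
        n = int(np.argmax(self.nodal_von_mises))
        return float(self.nodal_von_mises[n]), n

    def max_deformation(self) -> tuple[float, int]:
        n = int(np.argmax(self.total_deformation))
        return float(self.total_deformation[n]), n


def _extrapolation_matrix(order: int) -> np.ndarray:
    """Gauss-point -> element-node stress extrapolation matrix.

    Fits the tensor-product Lagrange interpolant through the Gauss-grid
    values and evaluates it at the element nodes (values at |xi| = 1 are
    extrapolated).
    """
    if order == 1:
        # trilinear Lagrange basis with nodes on the 2x2x2 Gauss grid
        gp, _ = EL.gauss_rule_hex(2)
        s = abs(gp[0, 0])                # 1/sqrt(3)
        M, _ = EL.hex8_shape(gp / s)     # permutation (GP order vs corners)
        E, _ = EL.hex8_shape(EL._HEX_CORNERS / s)
        return E @ np.linalg.inv(M)
    # order 2: triquadratic Lagrange through the 3x3x3 Gauss grid
    x1, _ = EL.gauss_rule_1d(3)

    def lag1(x, pts):
        out = np.ones((len(np.atleast_1d(x)), 3))
        x = np.atleast_1d(x)
        for j in range(3):
            for k in range(3):
                if k != j:
                    out[:, j] *= (x - pts[k]) / (pts[j] - pts[k])
        return out

    gp, _ = EL.gauss_rule_hex(3)
    nodes = EL.HEX20_NODES

    def tensor_basis(pts):
        lx = lag1(pts[:, 0], x1)
        ly = lag1(pts[:, 1], x1)
        lz = lag1(pts[:, 2], x1)
        # ordering consistent with gauss_rule_hex meshgrid (ij indexing)
        out = np.einsum("pa,pb,pc->pabc", lx, ly, lz).reshape(len(pts), 27)
        return out

    M = tensor_basis(gp)                  # 27 x 27 (identity, kept for clarity)
    E = tensor_basis(nodes)               # 20 x 27
    return E @ np.linalg.inv(M)


def recover_stress(
    mesh: ShellMesh, materials: dict[str, IsotropicMaterial], u: np.ndarray,
    chunk: int = 4000,
) -> StressField:
    """Quadrature-point stresses averaged per element and extrapolated to
    the nodes, plus von Mises and nodal total deformation."""
    lam, mu = _element_materials(mesh, materials)
    _, dN, _, gw = EL.shape_functions(mesh.order)
    extrap = _extrapolation_matrix(mesh.order)
    ue = u.reshape(-1, 3)
    stress = np.empty((mesh.n_elems, 6))
    nodal_acc = np.zeros((mesh.n_nodes, 6))
    nodal_cnt = np.zeros(mesh.n_nodes)
    for start in range(0, mesh.n_elems, chunk):
        sl = slice(start, min(start + chunk, mesh.n_elems))
        conn = mesh.elems[sl]
        coords = mesh.nodes[conn]
        detJ, gradN = EL.jacobians(coords, dN)
        ue_c = ue[conn]  # (ne, nen, 3)
        gu = np.einsum("egai,eaj->egij", gradN, ue_c)  # du_j/dx_i
        eps = 0.5 * (gu + gu.transpose(0, 1, 3, 2))
        tr = np.trace(eps, axis1=2, axis2=3)
        w = detJ * gw[None, :]
        wsum = w.sum(axis=1)
        if mesh.order == 1:
            # consistent with the selectively reduced volumetric stiffness
            tr = np.broadcast_to(
                (np.einsum("eg,eg->e", w, tr) / wsum)[:, None], tr.shape
            )
        sig = (
            lam[sl, None, None, None] * tr[..., None, None] * np.eye(3)
            + 2.0 * mu[sl, None, None, None] * eps
        )
        sig_avg = np.einsum("eg,egij->eij", w, sig) / wsum[:, None, None]
        stress[sl, 0] = sig_avg[:, 0, 0]
        stress[sl, 1] = sig_avg[:, 1, 1]
        stress[sl, 2] = sig_avg[:, 2, 2]
        stress[sl, 3] = sig_avg[:, 1, 2]
        stress[sl, 4] = sig_avg[:, 0, 2]
        stress[sl, 5] = sig_avg[:, 0, 1]
        # Gauss -> node extrapolation, accumulated for nodal averaging
        sig_v = np.stack(
            [sig[..., 0, 0], sig[..., 1, 1], sig[..., 2, 2],
             sig[..., 1, 2], sig[..., 0, 2], sig[..., 0, 1]], axis=-1,
        )  # (ne, ngp, 6)
        sig_nodes = np.einsum("ag,egc->eac", extrap, sig_v)
        np.add.at(nodal_acc, conn.ravel(),
                  sig_nodes.reshape(-1, 6))
        np.add.at(nodal_cnt, conn.ravel(), 1.0)
    vm = von_mises(stress)
    nodal = nodal_acc / np.maximum(nodal_cnt, 1.0)[:, None]
    nodal_vm = von_mises(nodal)
    total = np.linalg.norm(ue, axis=1)
    return StressField(stress=stress, von_mises=vm, nodal_von_mises=nodal_vm,
                       total_deformation=total)


def von_mises(stress_voigt: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from Voigt [xx,yy,zz,yz,xz,xy]."""
    s = np.atleast_2d(stress_voigt)
    sx, sy, sz, syz, sxz, sxy = s.T
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + sxz**2)
    )
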