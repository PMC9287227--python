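"""Frictionless rigid flat-punch contact and applanation-force extraction.

The tonometer probe is an analytic rigid surface (never meshed) advancing
along +x from the corneal apex.  Non-penetration is enforced by a
mortar-style penalty on weighted average gaps at the Lagrange grid points
of the candidate surface, with all mortar integrals clipped to the probe
footprint (see ``_CandidateSet``); the active constraint set is iterated
to convergence at each displacement increment.

Because the penalty only adds a rank-m term to the stiffness (m =
candidate surface DOFs), each contact solve is performed exactly by block
elimination (Woodbury identity) against the single factorisation of the
constrained stiffness.  One mesh factorisation therefore serves every
probe, depth and IOP in a sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tonofem import elements as EL
from tonofem import fem as F
from tonofem.geometry import ProbeSpec
from tonofem.meshing import ShellMesh

__all__ = [
    "ContactState",
    "SolveResult",
    "ContactError",
    "probe_gap",
    "probe_face_height",
    "solve_indentation",
    "reaction_force",
    "IndentationSolver",
]


class ContactError(RuntimeError):
    pass


def probe_face_height(probe: ProbeSpec, r: np.ndarray) -> np.ndarray:
    """Axial recession of the probe face at radial offset ``r`` from the
    axis: 0 on the flat face, rising on the edge fillet, +inf beyond the
    probe radius (no contact possible)."""
    r = np.asarray(r, dtype=float)
    a = probe.radius
    f = probe.edge_fillet_radius
    h = np.where(r <= a, 0.0, np.inf)
    if f > 0:
        rim = (r > a - f) & (r <= a)
        h = np.where(
            rim, f - np.sqrt(np.maximum(f**2 - (r - (a - f)) ** 2, 0.0)), h
        )
    return h


def probe_gap(
    probe: ProbeSpec,
    probe_depth: float,
    point: np.ndarray,
    displacement: np.ndarray | None = None,
) -> np.ndarray:
    """Signed axial gap between (displaced) surface points and the probe
    face at the given plunging depth.

    Depth is measured from the undeformed apex plane (x = 0): the flat
    face sits at x = probe_depth.  Negative gap means the probe demands
    that much additional axial displacement (penetration before
    enforcement).  Points radially outside the probe face are never
    candidates (gap = +inf).
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    if displacement is not None:
        pts = pts + np.atleast_2d(displacement)
    r = np.hypot(pts[:, 1], pts[:, 2])
    h = probe_face_height(probe, r)
    gap = pts[:, 0] - (probe_depth - h)
    return np.where(np.isinf(h), np.inf, gap)


@dataclass
class ContactState:
    """Converged contact bookkeeping at the final increment."""

    candidate_nodes: np.ndarray
    active_points: np.ndarray       # boolean over mortar virtual points
    gap: np.ndarray                 # mm, signed averaged gap per virtual point
    nodal_force: np.ndarray         # N, consistent contact force per node
    probe_depth: float

    @property
    def n_active(self) -> int:
        return int(self.active_points.sum())

    @property
    def active_node_mask(self) -> np.ndarray:
        """Candidate nodes carrying a nonzero contact force."""
        return np.abs(self.nodal_force) > 1e-15


@dataclass
class SolveResult:
    """Output of one displacement-driven indentation solve."""

    u: np.ndarray                   # (ndof,) mm
    reaction_force: float           # N, along probe axis
    history: list                   # rows: (inc, depth, force, n_active, iters)
    contact: ContactState
    stress: F.StressField | None
    mesh: ShellMesh
    load_case: F.LoadCase
    converged: bool = True
    log: list = field(default_factory=list)

    @property
    def max_total_deformation(self) -> tuple[float, np.ndarray]:
        """(value mm, location xyz) of the nodal deformation maximum."""
        d = np.linalg.norm(self.u.reshape(-1, 3), axis=1)
        n = int(np.argmax(d))
        return float(d[n]), self.mesh.nodes[n]

    @property
    def max_von_mises(self) -> tuple[float, str]:
        """(value MPa, region tag) of the averaged-nodal von Mises maximum
        (the contour-map convention); the region is that of the adjacent
        element with the highest element stress."""
        if self.stress is None:
            raise ValueError("stress was not recovered for this result")
        v, n = self.stress.max_nodal_von_mises()
        adj = np.flatnonzero(np.any(self.mesh.elems == n, axis=1))
        e = adj[np.argmax(self.stress.von_mises[adj])]
        return v, self.mesh.region_names[int(self.mesh.region_id[e])]


def reaction_force(result: SolveResult) -> float:
    """Axial applanation force: the negative of the sum of contact nodal
    forces projected on the probe axis (positive in indentation)."""
    return result.reaction_force


@dataclass
class _CandidateSet:
    """Mortar (weighted average gap) contact data under one probe.

    The non-penetration condition is enforced on weighted average gaps at
    the ``virtual points`` of the candidate surface: the Lagrange grid of
    each face (its nodes, plus the face centre for quadratic faces).  The
    test function of a virtual point is the positive piecewise-bilinear
    hat on that grid, with all integrals clipped to the probe footprint:

        g_j = <x0>_j + (B u_x)_j - (depth - <h>_j),    <f>_j = int psi_j f
                                                              / int psi_j

    and B_ja = int psi_j N_a dA / D_j with D_j = int psi_j dA over the
    footprint.  Because the hats are a partition of unity, the mortar
    weights D sum exactly to the footprint area, removing the O(h)
    contact-radius bias of point-wise gap checks at a flat-punch rim.
    The penalty stiffness of virtual point j is penalty_density * D_j.
    """

    nodes: np.ndarray        # (m,) candidate node ids
    dofs: np.ndarray         # (m,) their axial DOF indices
    B: np.ndarray            # (mv, m) averaged-gap operator
    D: np.ndarray            # (mv,) mortar weights (mm^2)
    k_pt: np.ndarray         # (mv,) penalty stiffness per virtual point (N/mm)
    x0_avg: np.ndarray       # (mv,) averaged axial surface coordinate
    h_avg: np.ndarray        # (mv,) averaged probe-face recession


def _hat_1d(s: np.ndarray) -> np.ndarray:
    """Values of the three 1-D hats at {-1, 0, 1} for coordinates s."""
    return np.stack(
        [np.maximum(-s, 0.0), 1.0 - np.abs(s), np.maximum(s, 0.0)], axis=-1
    )


# local Lagrange-grid coordinates per face type: quad4 -> its 4 corners,
# quad8 -> corners, midsides and centre (VTK quad8 node order + centre)
_VIRT_COORDS = {
    4: np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float),
    8: np.array(
        [[-1, -1], [1, -1], [1, 1], [-1, 1],
         [0, -1], [1, 0], [0, 1], [-1, 0], [0, 0]], dtype=float,
    ),
}


def _hat_values(pts: np.ndarray, nfn: int) -> np.ndarray:
    """psi_j(pts) for the face's virtual points; (npt, nv)."""
    hx = _hat_1d(pts[:, 0])    # (npt, 3) for positions -1, 0, +1
    hy = _hat_1d(pts[:, 1])
    vc = _VIRT_COORDS[nfn]
    ix = (vc[:, 0] + 1).astype(int)
    iy = (vc[:, 1] + 1).astype(int)
    return hx[:, ix] * hy[:, iy]


def _build_candidates(
    mesh: ShellMesh, probe: ProbeSpec, penalty_density: float,
    face_set: str = "corneal_outer",
) -> _CandidateSet:
    faces = mesh.face_sets[face_set]
    corners = mesh.nodes[faces[:, :4]]
    rmin = np.hypot(corners[..., 1], corners[..., 2]).min(axis=1)
    sel = faces[rmin <= probe.radius + 1e-9]
    if len(sel) == 0:
        raise ContactError(
            "no contact candidate faces under the probe; refine the mesh "
            "or enlarge the probe"
        )
    if faces.shape[1] == 8:
        # quadratic faces: enforce contact on the bilinear corner
        # sub-surface; the serendipity shape functions' negative lobes
        # otherwise make the active-set iteration chatter
        sel = sel[:, :4]
    nfn = sel.shape[1]
    order = 1
    # fine fixed-weight quadrature so the curved footprint boundary is
    # integrated accurately on the faces it crosses
    N, dN, gw = EL.face_shape_functions(order, n_gauss=6)
    gp, _ = EL.gauss_rule_quad(6)
    Psi = _hat_values(gp, nfn)                     # (ngp, nv)
    nv = Psi.shape[1]
    coords = mesh.nodes[sel]                       # (nf, nfn, 3)
    t = np.einsum("fai,gaj->fgij", coords, dN)
    nvec = np.cross(t[..., 0], t[..., 1])
    dA = np.linalg.norm(nvec, axis=-1) * gw[None, :]   # (nf, ngp)
    xqp = np.einsum("ga,fai->fgi", N, coords)          # (nf, ngp, 3)
    rqp = np.hypot(xqp[..., 1], xqp[..., 2])
    h_face = probe_face_height(probe, rqp)             # inf outside footprint
    inside = np.isfinite(h_face)
    w = np.where(inside, dA, 0.0)                      # clipped, (nf, ngp)
    hf = np.where(inside, h_face, 0.0)
    x0 = xqp[..., 0]

    nodes = np.unique(sel)
    m = nodes.size
    col = np.searchsorted(nodes, sel)                  # (nf, nfn)
    nf = sel.shape[0]
    # global virtual-point ids: shared grid points take the node id slot,
    # quadratic face centres get one unique slot per face
    if nfn == 4:
        vids = col                                      # (nf, 4)
        mv = m
    else:
        vids = np.concatenate([col, m + np.arange(nf)[:, None]], axis=1)
        mv = m + nf

    # per-face integrals, accumulated into global virtual/node slots
    PwN = np.einsum("gv,fg,ga->fva", Psi, w, N)        # int psi_j N_a
    Pw = np.einsum("gv,fg->fv", Psi, w)                # int psi_j
    Pwx = np.einsum("gv,fg->fv", Psi, w * x0)          # int psi_j x0
    Pwh = np.einsum("gv,fg->fv", Psi, w * hf)          # int psi_j h

    D = np.zeros(mv)
    Mint = np.zeros((mv, m))
    x0i = np.zeros(mv)
    hi = np.zeros(mv)
    np.add.at(D, vids.ravel(), Pw.ravel())
    np.add.at(x0i, vids.ravel(), Pwx.ravel())
    np.add.at(hi, vids.ravel(), Pwh.ravel())
    fidx = np.broadcast_to(vids[:, :, None], PwN.shape)
    cidx = np.broadcast_to(col[:, None, :], PwN.shape)
    np.add.at(Mint, (fidx.ravel(), cidx.ravel()), PwN.ravel())

    used_v = D > 1e-10 * D.max()
    D = D[used_v]
    B = Mint[used_v] / D[:, None]
    x0_avg = x0i[used_v] / D
    h_avg = hi[used_v] / D
    used_n = np.abs(B).max(axis=0) > 1e-12
    # floor the penalty weight: virtual points with sliver footprint overlap
    # sit at the (singular) punch rim, where the contact pressure grows as
    # the overlap shrinks; a pure area-proportional spring there would leave
    # a mesh-dependent residual penetration
    k_pt = penalty_density * np.maximum(D, 0.25 * np.median(D))
    return _CandidateSet(
        nodes=nodes[used_n], dofs=3 * nodes[used_n], B=B[:, used_n], D=D,
        k_pt=k_pt, x0_avg=x0_avg, h_avg=h_avg,
    )


class IndentationSolver:
    """Shared factorisation + cached contact columns for one mesh.

    Reuse one instance for a whole force-depth-IOP sweep: the stiffness is
    assembled and factorised once, the unit-pressure response and the
    contact influence columns are cached, and every (probe, depth, IOP)
    point is then solved by dense algebra on the candidate set.
    """

    def __init__(
        self,
        mesh: ShellMesh,
        materials: dict[str, F.IsotropicMaterial],
        constraint_mode: str = "remote-rigid-body",
        penalty_scale: float = 1e6,
    ):
        self.mesh = mesh
        self.materials = materials
        self.constraint_mode = constraint_mode
        self.penalty_scale = penalty_scale
        system = F.assemble_stiffness(mesh, materials)
        self.system = system
        self.csys = F.ConstrainedSystem(system.K, mesh, constraint_mode)
        self._u_pressure_unit: np.ndarray | None = None
        self._columns: dict[int, np.ndarray] = {}
        self._cand_cache: dict[tuple, _CandidateSet] = {}
        self.symmetry_factor = float(mesh.meta.get("symmetry_factor", 1.0))

    # -- penalty -----------------------------------------------------------
    def penalty_density(self) -> float:
        """Penalty stiffness per unit contact area, N/mm per mm^2:
        penalty_scale * E_ref / t_ref with E_ref the contact-surface
        modulus and t_ref the reference wall thickness."""
        names = {n.split("_", 1)[0] for n in self.mesh.region_names.values()}
        base = "cornea" if "cornea" in names else sorted(names)[0]
        e_ref = F.material_for_region(base, self.materials).young_modulus
        t_ref = self.mesh.meta.get("penalty_ref_thickness", 1.0)
        return self.penalty_scale * e_ref / t_ref

    # -- cached responses ---------------------------------------------------
    @property
    def u_pressure_unit(self) -> np.ndarray:
        """Augmented response to a unit (1 MPa) internal pressure."""
        if self._u_pressure_unit is None:
            f = F.apply_internal_pressure(self.mesh, 1.0)
            self._u_pressure_unit = self.csys.lu.solve(self.csys.augmented_rhs(f))
        return self._u_pressure_unit

    def _aug_index(self, dofs: np.ndarray) -> np.ndarray:
        if self.csys.free is None:
            return dofs
        pos = np.searchsorted(self.csys.free, dofs)
        ok = (pos < len(self.csys.free)) & (self.csys.free[np.minimum(
            pos, len(self.csys.free) - 1)] == dofs)
        if not np.all(ok):
            raise ContactError("a contact candidate DOF is constrained")
        return pos

    def _columns_for(self, dofs: np.ndarray, batch: int = 64) -> np.ndarray:
        """Influence columns A^-1 e_dof for the requested DOFs (cached)."""
        missing = [int(d) for d in dofs if int(d) not in self._columns]
        if missing:
            naug = self.csys.A.shape[0]
            aug = self._aug_index(np.asarray(missing))
            for start in range(0, len(missing), batch):
                sl = slice(start, min(start + batch, len(missing)))
                E = np.zeros((naug, sl.stop - sl.start))
                E[aug[sl], np.arange(sl.stop - sl.start)] = 1.0
                G = self.csys.lu.solve(E)
                for j, d in enumerate(missing[sl]):
                    self._columns[d] = np.ascontiguousarray(G[:, j])
        return np.column_stack([self._columns[int(d)] for d in dofs])

    def candidates(self, probe: ProbeSpec) -> _CandidateSet:
        key = (probe.radius, probe.edge_fillet_radius)
        cs = self._cand_cache.get(key)
        if cs is None:
            cs = _build_candidates(self.mesh, probe, self.penalty_density())
            self._cand_cache[key] = cs
        return cs

    # -- main solve ---------------------------------------------------------
    def solve(
        self,
        load_case: F.LoadCase,
        recover: bool = True,
        penalty_scale: float | None = None,
        max_iter: int = 80,
        penetration_tol: float = 1e-4,
    ) -> SolveResult:
        if load_case.constraint_mode != self.constraint_mode:
            raise ContactError(
                "load case constraint mode does not match this solver"
            )
        p = load_case.pressure_mpa
        probe = load_case.probe
        log: list[str] = []
        history: list[tuple] = [(0, 0.0, 0.0, 0, 0)]

        up = p * self.u_pressure_unit if p else np.zeros(self.csys.A.shape[0])

        if load_case.target_depth == 0.0:
            # probe not engaged: pure IOP inflation, zero reaction force
            u = self.csys.expand(up)
            state = ContactState(
                candidate_nodes=np.array([], dtype=int),
                active_points=np.array([], dtype=bool),
                gap=np.array([]), nodal_force=np.array([]), probe_depth=0.0,
            )
            stress = F.recover_stress(self.mesh, self.materials, u) if recover else None
            return SolveResult(u=u, reaction_force=0.0, history=history,
                               contact=state, stress=stress, mesh=self.mesh,
                               load_case=load_case, log=log)

        cs = self.candidates(probe)
        k_pt = cs.k_pt if penalty_scale is None else cs.k_pt * (
            penalty_scale / self.penalty_scale
        )
        cols = self._columns_for(cs.dofs)
        aug = self._aug_index(cs.dofs)
        S = cols[aug]
        S = 0.5 * (S + S.T)
        u0x_press = up[aug]
        m = cs.nodes.size
        mv = cs.D.size

        def mortar_solve(active, pen_demand):
            """Solve for the current active virtual-point set.

            Returns (u_x at candidate nodes, nodal contact force y)."""
            if not active.any():
                return u0x_press.copy(), np.zeros(m)
            Ba = cs.B[active]
            ka = k_pt[active]
            W = (Ba * ka[:, None]).T @ Ba
            r = Ba.T @ (ka * pen_demand[active])
            M = np.eye(m) + W @ S
            y = np.linalg.solve(M, r - W @ u0x_press)
            u_x = u0x_press + S @ y
            return u_x, y

        active = np.zeros(mv, dtype=bool)
        depths = load_case.target_depth * np.arange(
            1, load_case.n_increments + 1
        ) / load_case.n_increments
        force = 0.0
        y = np.zeros(m)
        for inc, depth in enumerate(depths, start=1):
            face_x = depth - cs.h_avg
            pen_demand = face_x - cs.x0_avg   # demanded averaged penetration
            it = 0
            seen = set()
            while True:
                it += 1
                if it > max_iter:
                    raise ContactError(
                        f"contact iteration cap at depth {depth:.3f} mm with "
                        f"{int(active.sum())} active points"
                    )
                u_x, y = mortar_solve(active, pen_demand)
                gap_v = cs.x0_avg + cs.B @ u_x - face_x
                new_active = gap_v < 0.0
                if np.array_equal(new_active, active):
                    break
                key = new_active.tobytes()
                if key in seen:
                    log.append(f"inc {inc}: active-set cycle broken by union")
                    new_active = new_active | active
                seen.add(key)
                active = new_active
            pen = -gap_v[active]
            force = float(y.sum()) * self.symmetry_factor
            if pen.size:
                max_pen = float(pen.max(initial=0.0))
                if max_pen > penetration_tol:
                    raise ContactError(
                        f"residual penetration {max_pen:.2e} mm exceeds "
                        f"{penetration_tol:.0e} (penalty too soft)"
                    )
            history.append((inc, float(depth), force, int(active.sum()), it))
            log.append(
                f"inc {inc}: depth={depth:.4f} force={force:.6e} "
                f"active_pts={int(active.sum())} iters={it}"
            )

        sol = up + cols @ y
        u = self.csys.expand(sol)
        state = ContactState(
            candidate_nodes=cs.nodes, active_points=active, gap=gap_v,
            nodal_force=y, probe_depth=float(depths[-1]),
        )
        stress = F.recover_stress(self.mesh, self.materials, u) if recover else None
        return SolveResult(
            u=u, reaction_force=force, history=history, contact=state,
            stress=stress, mesh=self.mesh, load_case=load_case, log=log,
        )


def solve_indentation(
    mesh: ShellMesh,
    materials: dict[str, F.IsotropicMaterial],
    load_case: F.LoadCase,
    solver: IndentationSolver | None = None,
    recover: bool = True,
    updated_geometry: bool = False,
    **kwargs,
) -> SolveResult:
    """Displacement-driven frictionless indentation of a pressurised shell.

    The IOP pre-load is applied in one linear step, then the probe is
    advanced to the target depth in equal increments with active-set
    penalty contact at each increment; the axial reaction force is
    reported at the final depth.  ``updated_geometry=True`` re-assembles
    the stiffness on the incrementally deformed configuration (one
    re-assembly and factorisation per increment) instead of the default
    small-strain solve.
    """
    if updated_geometry:
        return _solve_updated_geometry(mesh, materials, load_case, **kwargs)
    if solver is None:
        solver = IndentationSolver(
            mesh, materials, constraint_mode=load_case.constraint_mode
        )
    return solver.solve(load_case, recover=recover, **kwargs)


def _solve_updated_geometry(
    mesh: ShellMesh,
    materials: dict[str, F.IsotropicMaterial],
    load_case: F.LoadCase,
    **kwargs,
) -> SolveResult:
    """Geometrically updated variant: fixed-point iteration in which the
    stiffness (and the pressure load) are re-assembled on the deformed
    configuration of the previous pass, while displacements and contact
    gaps remain measured from the undeformed reference.

    One assembly + factorisation per pass (n_increments passes); intended
    for coarse meshes.  Reduces to the small-strain solution when
    displacements are small.
    """
    import copy

    u_total = np.zeros(mesh.ndof)
    history = [(0, 0.0, 0.0, 0, 0)]
    log: list[str] = []
    res = None
    case_1 = F.LoadCase(
        iop_mmhg=load_case.iop_mmhg, probe=load_case.probe,
        target_depth=load_case.target_depth, n_increments=1,
        constraint_mode=load_case.constraint_mode,
    )
    pen_density = None
    for it in range(1, load_case.n_increments + 1):
        work = copy.copy(mesh)
        work.nodes = mesh.nodes + u_total.reshape(-1, 3)
        work.face_sets = mesh.face_sets
        solver = IndentationSolver(
            work, materials, constraint_mode=load_case.constraint_mode
        )
        if pen_density is None:
            pen_density = solver.penalty_density()
        # contact candidates from the *reference* surface so that depth
        # keeps its meaning (travel from the undeformed apex plane)
        key = (case_1.probe.radius, case_1.probe.edge_fillet_radius)
        solver._cand_cache[key] = _build_candidates(
            mesh, case_1.probe, pen_density
        )
        res = solver.solve(case_1, recover=False, **kwargs)
        u_total = res.u
        history.append((it, load_case.target_depth, res.reaction_force,
                        res.contact.n_active, 1))
        log.append(f"updated-geometry pass {it}: force={res.reaction_force:.6e}")
    stress = F.recover_stress(mesh, materials, u_total)
    return SolveResult(
        u=u_total, reaction_force=res.reaction_force, history=history,
        contact=res.contact, stress=stress, mesh=mesh, load_case=load_case,
        log=log,
    )
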