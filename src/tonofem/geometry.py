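"""Parametric eye-shell geometry and analytic verification fixtures.

The eyeball wall (cornea + sclera) is built from printed anatomical
dimensions.  Each of the four key meridians (superior, inferior, nasal,
temporal) is an exact arc-spline in its meridian half-plane:

* anterior corneal arc of the given radius of curvature, centred on the
  optical axis, starting at the apex;
* a sharp corneoscleral kink whose exterior angle is the quadrant-specific
  junction angle;
* a short transition arc (the 1.5 mm limbal band) whose signed radius is
  solved so that it joins tangentially onto
* the scleral arc, centred on the axis so the profile closes orthogonally
  at the posterior pole at the given axial length.

With the default dimensions a direct two-arc profile cannot realise the
printed junction angles (the circle-tangency bound requires a kink of at
least ~9 degrees), so the limbal transition band is a structural part of
the profile, not merely a region tag.

The four meridian profiles are lofted into a closed surface by periodic
trigonometric interpolation in azimuth; a slice at any key azimuth
reproduces its profile exactly.

Coordinates: origin at the corneal apex, +x toward the posterior pole
(the probe travel direction), lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "OcularGeometryParams",
    "ProbeSpec",
    "MeridianProfile",
    "ParametricShell",
    "BlockFixture",
    "GeometricInfeasibilityError",
    "QUADRANTS",
    "QUADRANT_AZIMUTH_DEG",
    "build_meridian_profile",
    "loft_eye_surface",
    "build_eye_shell",
    "make_sphere_fixture",
    "make_block_fixture",
    "export_surface_stl",
]

#: quadrant order used throughout (matches the azimuths below)
QUADRANTS = ("superior", "inferior", "nasal", "temporal")

#: azimuth (degrees, about the +x axis) at which each key meridian lives
QUADRANT_AZIMUTH_DEG = {
    "nasal": 0.0,
    "superior": 90.0,
    "temporal": 180.0,
    "inferior": 270.0,
}

#: normalised meridian parameter at the corneal kink and at the end of the
#: limbal band; fixed so all quadrants share one station layout.
U_CORNEA_END = 0.35
U_BAND_END = 0.45

#: arc length of the limbal (corneoscleral junction) transition band, mm
JUNCTION_BAND_MM = 1.5


class GeometricInfeasibilityError(ValueError):
    """The requested arcs cannot be joined at the requested angle."""


@dataclass(frozen=True)
class OcularGeometryParams:
    """Printed ocular dimensions; the single source of eye-shape truth.

    All lengths are in mm, junction angles in degrees (exterior surface
    angle at the corneoscleral kink; 180 means no kink).
    """

    corneal_anterior_radius: float = 7.75
    corneal_central_thickness: float = 0.52
    corneal_peripheral_thickness: float = 0.67
    scleral_radius: float = 11.2
    scleral_thickness: float = 0.317
    choroidal_thickness: float = 0.298
    axial_length: float = 22.7
    junction_angle_superior: float = 178.1
    junction_angle_inferior: float = 177.7
    junction_angle_nasal: float = 173.9
    junction_angle_temporal: float = 177.0
    include_choroid_in_wall: bool = False

    def __post_init__(self) -> None:
        lengths = (
            self.corneal_anterior_radius,
            self.corneal_central_thickness,
            self.corneal_peripheral_thickness,
            self.scleral_radius,
            self.scleral_thickness,
            self.choroidal_thickness,
            self.axial_length,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be strictly positive")
        for q in QUADRANTS:
            a = self.junction_angle(q)
            if not (160.0 < a <= 180.0):
                raise ValueError(
                    f"junction angle for {q} must lie in (160, 180] deg, got {a}"
                )
        if self.corneal_peripheral_thickness < self.corneal_central_thickness:
            raise ValueError("peripheral corneal thickness must be >= central")
        if self.axial_length <= self.corneal_anterior_radius:
            raise ValueError("axial length must exceed the corneal radius")
        if self.axial_length <= self.scleral_radius:
            raise ValueError("axial length must exceed the scleral radius")

    def junction_angle(self, quadrant: str) -> float:
        try:
            return getattr(self, f"junction_angle_{quadrant}")
        except AttributeError:
            raise KeyError(f"unknown quadrant {quadrant!r}") from None

    @property
    def wall_scleral_thickness(self) -> float:
        """Scleral wall thickness, including the choroid if flagged."""
        t = self.scleral_thickness
        if self.include_choroid_in_wall:
            t += self.choroidal_thickness
        return t


@dataclass(frozen=True)
class ProbeSpec:
    """Rigid flat-ended cylindrical tonometer probe.

    The probe is analytic (never meshed): its steel modulus is ~10^6 times
    the corneal modulus, so it is treated as rigid.  ``axis`` is the travel
    direction, by default apex-to-posterior-pole (+x).
    """

    diameter: float = 1.7
    edge_fillet_radius: float = 0.0
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    tip_shape: str = "flat"
    name: str = "standard"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("probe diameter must be positive")
        if not (0 <= self.edge_fillet_radius < self.diameter / 2):
            raise ValueError("fillet radius must lie in [0, diameter/2)")
        if self.tip_shape != "flat":
            raise ValueError("only flat-tipped probes are supported")
        n = math.sqrt(sum(c * c for c in self.axis))
        if abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "axis", tuple(c / n for c in self.axis))

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


#: common probe presets (diameters in mm)
PROBE_PRESETS = {
    "standard": ProbeSpec(diameter=1.7, name="standard"),
    "goldmann": ProbeSpec(diameter=3.06, name="goldmann"),
    "validation": ProbeSpec(diameter=2.0, name="validation"),
}


# ---------------------------------------------------------------------------
# arc-spline profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Arc:
    """One circular-arc segment of a meridian profile.

    Tangent direction at tangent-angle a is (sin a, cos a) in the (x, r)
    half-plane; the interior-side unit normal is (cos a, -sin a).
    Curvature is signed: positive means the centre lies on the interior
    side (the tangent angle grows along the arc).
    """

    start: tuple[float, float]
    a0: float            # tangent angle at start (rad)
    curvature: float     # 1/R, signed; ~0 allowed (straight)
    length: float        # arc length (mm)
    s0: float            # cumulative arc length at start

    def eval(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Points and tangent angles at arc-length positions ``s`` (local)."""
        s = np.asarray(s, dtype=float)
        k = self.curvature
        x0, r0 = self.start
        if abs(k) < 1e-12:
            a = np.full_like(s, self.a0)
            x = x0 + s * math.sin(self.a0)
            r = r0 + s * math.cos(self.a0)
        else:
            a = self.a0 + k * s
            R = 1.0 / k
            cx = x0 + R * math.cos(self.a0)
            cr = r0 - R * math.sin(self.a0)
            x = cx - R * np.cos(a)
            r = cr + R * np.sin(a)
        return np.stack([x, r], axis=-1), a


class MeridianProfile:
    """Outer/inner wall polylines of one meridian half-plane cross-section.

    The profile is stored exactly as an arc-spline (outer surface) plus a
    thickness function; polylines are sampled views of it.  ``s`` denotes
    outer-surface arc length from the apex; ``u`` in [0, 1] is the
    normalised meridian parameter shared by all quadrants, with the
    corneal kink always at ``u = U_CORNEA_END`` and the end of the limbal
    band at ``u = U_BAND_END``.
    """

    def __init__(
        self,
        quadrant: str,
        arcs: Sequence[_Arc],
        s_cornea: float,
        s_band: float,
        thickness_fn: Callable[[np.ndarray], np.ndarray],
        junction_angle_deg: float,
        n_points: int = 481,
    ):
        self.quadrant = quadrant
        self.arcs = tuple(arcs)
        self.s_cornea = s_cornea
        self.s_band = s_band
        self.s_total = arcs[-1].s0 + arcs[-1].length
        self._thickness_fn = thickness_fn
        self.junction_angle_deg = junction_angle_deg
        u = _profile_u_grid(n_points)
        self.u_grid = u
        self.outer = self.outer_point(u)
        self.inner = self.inner_point(u)
        self.junction_index = int(np.argmin(np.abs(u - U_CORNEA_END)))

    # -- parameter maps ----------------------------------------------------
    def u_to_s(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        s = np.empty_like(u)
        c = u <= U_CORNEA_END
        b = (u > U_CORNEA_END) & (u <= U_BAND_END)
        d = u > U_BAND_END
        s[c] = u[c] / U_CORNEA_END * self.s_cornea
        s[b] = self.s_cornea + (u[b] - U_CORNEA_END) / (U_BAND_END - U_CORNEA_END) * (
            self.s_band - self.s_cornea
        )
        s[d] = self.s_band + (u[d] - U_BAND_END) / (1.0 - U_BAND_END) * (
            self.s_total - self.s_band
        )
        return s

    def _eval_outer_s(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        s = np.asarray(s, dtype=float)
        flat = np.ravel(s)
        pts = np.empty((flat.size, 2))
        ang = np.empty(flat.size)
        starts = np.array([a.s0 for a in self.arcs])
        seg = np.clip(np.searchsorted(starts, flat, side="right") - 1, 0,
                      len(self.arcs) - 1)
        for i, arc in enumerate(self.arcs):
            m = seg == i
            if not np.any(m):
                continue
            p, a = arc.eval(np.clip(flat[m] - arc.s0, 0.0, arc.length))
            pts[m] = p
            ang[m] = a
        return pts.reshape(s.shape + (2,)), ang.reshape(s.shape)

    # -- evaluation --------------------------------------------------------
    def outer_point(self, u: np.ndarray) -> np.ndarray:
        """Outer-surface (x, r) at normalised meridian parameter ``u``."""
        pts, _ = self._eval_outer_s(self.u_to_s(u))
        return pts

    def inner_point(self, u: np.ndarray) -> np.ndarray:
        """Inner-surface (x, r): outer point offset inward by the local wall
        thickness along the exact outer normal."""
        s = self.u_to_s(u)
        pts, a = self._eval_outer_s(s)
        t = self.thickness(u)
        n = np.stack([np.cos(a), -np.sin(a)], axis=-1)  # interior normal
        return pts + t[..., None] * n

    def thickness(self, u: np.ndarray) -> np.ndarray:
        """Local wall thickness (mm) at parameter ``u``."""
        return self._thickness_fn(self.u_to_s(np.asarray(u, dtype=float)))

    # -- checks ------------------------------------------------------------
    def check(self, angle_tol_deg: float = 0.1) -> None:
        """Validate profile invariants; raises ``ValueError`` on failure."""
        a_meas = self.measured_junction_angle_deg()
        if abs(a_meas - self.junction_angle_deg) > angle_tol_deg:
            raise ValueError(
                f"{self.quadrant}: junction angle {a_meas:.3f} deg does not "
                f"match requested {self.junction_angle_deg:.3f} deg"
            )
        r_in = self.inner[:, 1]
        if np.any(r_in[1:-1] <= 0):
            raise ValueError(f"{self.quadrant}: inner polyline crosses the axis")

    def measured_junction_angle_deg(self) -> float:
        """Exterior surface angle at the corneoscleral kink, from the exact
        tangent angles on either side of the junction vertex."""
        s_k = self.s_cornea
        _, a_minus = self.arcs[0].eval(np.array([s_k - self.arcs[0].s0]))
        band = self.arcs[1]
        _, a_plus = band.eval(np.array([0.0]))
        return 180.0 - math.degrees(float(a_plus[0] - a_minus[0]))


def _profile_u_grid(n_points: int) -> np.ndarray:
    """Default sampling grid in u with the two breakpoints included."""
    nc = max(3, int(round(n_points * U_CORNEA_END)))
    nb = max(2, int(round(n_points * (U_BAND_END - U_CORNEA_END))))
    ns = n_points - 1 - nc - nb
    return np.concatenate(
        [
            np.linspace(0.0, U_CORNEA_END, nc + 1)[:-1],
            np.linspace(U_CORNEA_END, U_BAND_END, nb + 1)[:-1],
            np.linspace(U_BAND_END, 1.0, ns + 1),
        ]
    )


def _solve_junction(params: OcularGeometryParams, quadrant: str):
    """Solve the limbal transition construction for one quadrant.

    Returns (phi, band_curvature, band_start_angle, scleral_start_angle,
    scleral_arc_length).  ``phi`` is the polar extent of the corneal arc.
    """
    R1 = params.corneal_anterior_radius
    R2 = params.scleral_radius
    L = params.axial_length
    band = JUNCTION_BAND_MM
    alpha = params.junction_angle(quadrant)
    delta = math.radians(180.0 - alpha)
    CS = np.array([L - R2, 0.0])
    C1 = np.array([R1, 0.0])

    def geo(phi: float):
        P = C1 + R1 * np.array([-math.cos(phi), math.sin(phi)])
        a = phi + delta
        n2 = np.array([math.cos(a), -math.sin(a)])
        v = P - CS
        denom = 2.0 * (R2 + float(n2 @ v))
        num = R2 * R2 - float(v @ v)
        if abs(denom) < 1e-14:
            # straight transition is a measure-zero degenerate case
            return P, 0.0, a, None, math.inf
        Rj = num / denom
        kj = 1.0 / Rj
        Cj = P + Rj * n2
        Q = CS - R2 * (Cj - CS) / (Rj - R2)
        vP, vQ = P - Cj, Q - Cj
        cross = float(vP[0] * vQ[1] - vP[1] * vQ[0])
        psi = math.atan2(abs(cross), float(vP @ vQ))
        return P, kj, a, Q, abs(Rj) * psi

    def f(phi: float) -> float:
        return geo(phi)[4] - band

    phis = np.radians(np.linspace(2.0, 60.0, 233))
    vals = np.array([f(p) for p in phis])
    bracket = None
    for i in range(len(phis) - 1):
        if (
            np.isfinite(vals[i])
            and np.isfinite(vals[i + 1])
            and vals[i] > 0 > vals[i + 1]
        ):
            bracket = (float(phis[i]), float(phis[i + 1]))
            break
    if bracket is None:
        raise GeometricInfeasibilityError(
            f"cannot close the {quadrant} meridian: corneal arc (R="
            f"{R1} mm), scleral arc (R={R2} mm, axial length {L} mm) and "
            f"junction angle {alpha} deg admit no {band} mm transition band"
        )
    phi = brentq(f, *bracket, xtol=1e-14)
    P, kj, a_band, Q, _ = geo(phi)
    # scleral arc: from Q to the posterior pole along the axis-centred circle
    a_Q = a_band + kj * band
    s_scl = R2 * (math.pi - a_Q)
    if s_scl <= 0 or Q is None or Q[1] <= 0:
        raise GeometricInfeasibilityError(
            f"{quadrant}: transition band leaves no room for the scleral arc"
        )
    return phi, kj, a_band, float(a_Q), s_scl, P, np.asarray(Q)


def _thickness_fn(params: OcularGeometryParams, s_cornea: float, s_band: float):
    tc0 = params.corneal_central_thickness
    tcp = params.corneal_peripheral_thickness
    ts = params.wall_scleral_thickness

    def fn(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        t = np.empty_like(s)
        c = s <= s_cornea
        b = (s > s_cornea) & (s <= s_band)
        d = s > s_band
        t[c] = tc0 + (tcp - tc0) * s[c] / s_cornea
        # smoothstep blend across the limbal band
        xi = (s[b] - s_cornea) / (s_band - s_cornea)
        w = xi * xi * (3.0 - 2.0 * xi)
        t[b] = tcp + (ts - tcp) * w
        t[d] = ts
        return t

    return fn


def build_meridian_profile(
    params: OcularGeometryParams, quadrant: str, n_points: int = 481
) -> MeridianProfile:
    """Construct the exact meridian cross-section for one quadrant.

    The profile consists of the anterior corneal arc, the corneoscleral
    kink at the quadrant's junction angle, the 1.5 mm limbal transition
    arc and the scleral arc closing orthogonally at the posterior pole.
    """
    if quadrant not in QUADRANTS:
        raise KeyError(f"unknown quadrant {quadrant!r}")
    R1 = params.corneal_anterior_radius
    phi, kj, a_band, a_Q, s_scl, P, Q = _solve_junction(params, quadrant)
    s_cornea = R1 * phi
    s_band = s_cornea + JUNCTION_BAND_MM
    arcs = [
        _Arc((0.0, 0.0), 0.0, 1.0 / R1, s_cornea, 0.0),
        _Arc((float(P[0]), float(P[1])), a_band, kj, JUNCTION_BAND_MM, s_cornea),
        _Arc((float(Q[0]), float(Q[1])), a_Q, 1.0 / params.scleral_radius, s_scl, s_band),
    ]
    prof = MeridianProfile(
        quadrant,
        arcs,
        s_cornea,
        s_band,
        _thickness_fn(params, s_cornea, s_band),
        params.junction_angle(quadrant),
        n_points=n_points,
    )
    prof.check()
    return prof


# ---------------------------------------------------------------------------
# lofted shells
# ---------------------------------------------------------------------------

class ParametricShell:
    """Closed shell surface lofted from four meridian profiles.

    Azimuthal interpolation is periodic trigonometric (a0 + a1*cos t +
    b1*sin t + a2*cos 2t through the four key azimuths), applied to the
    (x, r) coordinates of corresponding meridian stations; the loft
    therefore reproduces each input profile exactly at its azimuth and is
    watertight (all profiles share the apex and posterior-pole points).

    ``u`` in [0, 1] runs from the anterior apex to the posterior pole,
    ``theta`` is the azimuth about +x in radians (nasal at 0, superior at
    pi/2), and ``w`` in [0, 1] is the through-wall fraction (0 = inner,
    1 = outer).
    """

    def __init__(self, profiles: dict[str, MeridianProfile], name: str = "eye"):
        for q in QUADRANTS:
            if q not in profiles:
                raise ValueError(f"missing {q} profile")
        self.profiles = dict(profiles)
        self.name = name
        self.params: OcularGeometryParams | None = None
        apexes = {q: profiles[q].outer[0] for q in QUADRANTS}
        poles = {q: profiles[q].outer[-1] for q in QUADRANTS}
        ref_a = next(iter(apexes.values()))
        ref_p = next(iter(poles.values()))
        for q in QUADRANTS:
            if not (
                np.allclose(apexes[q], ref_a, atol=1e-9)
                and np.allclose(poles[q], ref_p, atol=1e-9)
            ):
                raise ValueError("profiles do not share apex/pole points")

    # coefficients for f(theta) given values at 0, 90, 180, 270 deg
    @staticmethod
    def _trig_coeffs(f0, f90, f180, f270):
        a0 = (f0 + f90 + f180 + f270) / 4.0
        a1 = (f0 - f180) / 2.0
        b1 = (f90 - f270) / 2.0
        a2 = (f0 - f90 + f180 - f270) / 4.0
        return a0, a1, b1, a2

    def _interp_xr(self, point_of, u, theta):
        """Interpolate (x, r) azimuthally; u and theta broadcast together."""
        u = np.asarray(u, dtype=float)
        theta = np.asarray(theta, dtype=float)
        vals = {q: point_of(self.profiles[q], u) for q in QUADRANTS}
        a0, a1, b1, a2 = self._trig_coeffs(
            vals["nasal"], vals["superior"], vals["temporal"], vals["inferior"]
        )
        ct, st = np.cos(theta)[..., None], np.sin(theta)[..., None]
        c2t = np.cos(2.0 * theta)[..., None]
        return a0 + a1 * ct + b1 * st + a2 * c2t

    def outer_point3(self, u, theta) -> np.ndarray:
        xr = self._interp_xr(lambda p, uu: p.outer_point(uu), u, theta)
        return self._to3(xr, theta)

    def inner_point3(self, u, theta) -> np.ndarray:
        xr = self._interp_xr(lambda p, uu: p.inner_point(uu), u, theta)
        return self._to3(xr, theta)

    def wall_point3(self, u, theta, w) -> np.ndarray:
        """Point at through-wall fraction ``w`` (0 inner, 1 outer)."""
        w = np.asarray(w, dtype=float)[..., None]
        return (1.0 - w) * self.inner_point3(u, theta) + w * self.outer_point3(u, theta)

    @staticmethod
    def _to3(xr: np.ndarray, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        x = xr[..., 0]
        r = np.maximum(xr[..., 1], 0.0)
        return np.stack([x, r * np.cos(theta), r * np.sin(theta)], axis=-1)

    def junction_exterior_angle_deg(self, theta, eps: float = 1e-5) -> np.ndarray:
        """Exterior angle of the lofted outer surface at the junction ring."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        uc = U_CORNEA_END
        p0 = self.outer_point3(np.full_like(theta, uc - eps), theta)
        p1 = self.outer_point3(np.full_like(theta, uc), theta)
        p2 = self.outer_point3(np.full_like(theta, uc + eps), theta)
        v1 = p1 - p0
        v2 = p2 - p1
        v1 /= np.linalg.norm(v1, axis=-1, keepdims=True)
        v2 /= np.linalg.norm(v2, axis=-1, keepdims=True)
        dot = np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)
        return 180.0 - np.degrees(np.arccos(dot))

    def to_trimesh(self, n_u: int = 96, n_theta: int = 96, surface: str = "outer"):
        """Triangulate one surface (outer or inner) as a `trimesh.Trimesh`."""
        import trimesh

        fn = self.outer_point3 if surface == "outer" else self.inner_point3
        u = np.linspace(0.0, 1.0, n_u + 1)
        th = np.linspace(0.0, 2.0 * math.pi, n_theta, endpoint=False)
        U, T = np.meshgrid(u[1:-1], th, indexing="ij")
        ring_pts = fn(U.ravel(), T.ravel()).reshape(n_u - 1, n_theta, 3)
        apex = fn(np.array([0.0]), np.array([0.0]))[0]
        pole = fn(np.array([1.0]), np.array([0.0]))[0]
        verts = np.vstack([apex[None, :], ring_pts.reshape(-1, 3), pole[None, :]])
        idx = lambda i, j: 1 + i * n_theta + (j % n_theta)
        faces = []
        for j in range(n_theta):
            faces.append([0, idx(0, j + 1), idx(0, j)])
        for i in range(n_u - 2):
            for j in range(n_theta):
                faces.append([idx(i, j), idx(i + 1, j + 1), idx(i + 1, j)])
                faces.append([idx(i, j), idx(i, j + 1), idx(i + 1, j + 1)])
        last = len(verts) - 1
        for j in range(n_theta):
            faces.append([idx(n_u - 2, j), idx(n_u - 2, j + 1), last])
        mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
        return mesh


def loft_eye_surface(profiles: dict[str, MeridianProfile]) -> ParametricShell:
    """Loft four meridian profiles (superior/inferior/nasal/temporal) into a
    closed parametric shell."""
    shell = ParametricShell(profiles)
    # self-intersection guard: inner surface must stay strictly inside outer
    th = np.linspace(0.0, 2.0 * math.pi, 73)
    u = np.linspace(0.0, 1.0, 161)
    U, T = np.meshgrid(u, th, indexing="ij")
    d = shell.outer_point3(U, T) - shell.inner_point3(U, T)
    gap = np.linalg.norm(d, axis=-1)
    interior = gap[1:-1]
    if np.any(interior < 1e-6):
        bad = np.unravel_index(np.argmin(interior), interior.shape)
        raise GeometricInfeasibilityError(
            f"lofted wall self-intersects near azimuth "
            f"{math.degrees(th[bad[1]]):.1f} deg"
        )
    return shell


def build_eye_shell(params: OcularGeometryParams | None = None) -> ParametricShell:
    """Convenience: profiles for all quadrants plus the loft."""
    params = params or OcularGeometryParams()
    profiles = {q: build_meridian_profile(params, q) for q in QUADRANTS}
    shell = loft_eye_surface(profiles)
    shell.params = params
    return shell


def make_sphere_fixture(radius: float, thickness: float) -> ParametricShell:
    """Uniform spherical shell with the same data layout as the eye shell.

    ``radius`` is the mid-surface radius; the outer surface has radius
    radius + thickness/2 (verification fixture for pressure-vessel
    closed forms).
    """
    if thickness >= radius:
        raise ValueError("thickness must be smaller than the mid-surface radius")
    Ro = radius + thickness / 2.0
    s_tot = math.pi * Ro
    arcs = [_Arc((0.0, 0.0), 0.0, 1.0 / Ro, s_tot, 0.0)]
    profiles = {}
    for q in QUADRANTS:
        profiles[q] = MeridianProfile(
            q,
            arcs,
            s_cornea=U_CORNEA_END * s_tot,
            s_band=U_BAND_END * s_tot,
            thickness_fn=lambda s, t=thickness: np.full_like(
                np.asarray(s, dtype=float), t
            ),
            junction_angle_deg=180.0,
        )
    shell = ParametricShell(profiles, name=f"sphere_R{radius}_t{thickness}")
    return shell


@dataclass(frozen=True)
class BlockFixture:
    """Elastic block with one free (contact) face at x = 0.

    The block occupies x in [0, depth], y and z in [-side/2, side/2].
    The five far faces are tagged for full constraint; the top face
    (x = 0) is the contact candidate surface.  This is the flat-punch
    half-space oracle fixture; it is valid as a half-space approximation
    when side and depth are >= 10 probe radii.
    """

    side: float = 20.0
    depth: float = 20.0

    def __post_init__(self) -> None:
        if self.side <= 0 or self.depth <= 0:
            raise ValueError("block side and depth must be positive")

    @property
    def tagged_faces(self) -> tuple[str, ...]:
        return ("top", "bottom", "y_min", "y_max", "z_min", "z_max")

    @property
    def contact_face(self) -> str:
        return "top"

    def is_halfspace_valid(self, probe: ProbeSpec) -> bool:
        return min(self.side, self.depth) >= 10.0 * probe.radius


def make_block_fixture(side: float, depth: float) -> BlockFixture:
    """Rectangular solid fixture for the flat-punch contact oracle."""
    return BlockFixture(side=side, depth=depth)


def export_surface_stl(shell: ParametricShell, path, surface: str = "outer",
                       n_u: int = 96, n_theta: int = 96) -> None:
    """Write one shell surface as an STL file for inspection."""
    mesh = shell.to_trimesh(n_u=n_u, n_theta=n_theta, surface=surface)
    mesh.export(path)
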