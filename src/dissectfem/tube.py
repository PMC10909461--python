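"""Idealized bilayer aortic tube with a parametric in-plane tear.

The human descending aorta is idealized as a straight bilayer cylinder
(inner radius 7.5 mm, outer radius 9 mm, media:adventitia thickness 5:3).
A cohesive surface embedded in the media at radius Ri + t*tm carries an
initial tear parameterized by a central angle eta, an axial length s and
the dimensionless depth ratio t.  Under axial stretch and lumen pressure
the critical pressure is the smallest pressure at which the first cohesive
element is completely damaged, i.e. the tear starts to propagate; the mode
mix ratio of the failing element identifies opening- vs shear-dominated
propagation.

The module also provides a semi-analytic solver for the intact tube
(incompressible axisymmetric inflation-extension) used as a verification
oracle, and a classical opening-angle prestrain that emulates
circumferential residual stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .cohesive import CohesiveParams
from .constants import ADVENTITIA, MEDIA, default_cohesive_params
from .fem.mesh import InterfaceSet, Mesh
from .fem.model import CriticalEvent, FEModel, LoadStage, SolverControls
from .fem.solver import solve_quasi_static
from .hgo import MaterialParams, pk2_stress_and_tangent

__all__ = [
    "TearGeometry",
    "TubeSpec",
    "LoadCase",
    "build_tube_model",
    "semi_analytic_inflation",
    "opening_angle_prestrain",
    "apply_residual_prestrain",
    "run_pressurization",
    "parameter_sweep",
]


@dataclass
class TearGeometry:
    """Initial in-plane tear: central angle, axial length, depth ratio."""

    eta_deg: float = 150.0
    s_mm: float = 10.0
    t_ratio: float = 0.4

    def __post_init__(self):
        if not 0.0 < self.t_ratio < 1.0:
            raise ValueError("depth ratio t must lie in (0, 1)")
        if not 0.0 < self.eta_deg <= 360.0:
            raise ValueError("eta must lie in (0, 360] degrees")
        if self.s_mm <= 0:
            raise ValueError("axial tear length must be positive")


@dataclass
class TubeSpec:
    """Geometry and discretization of the idealized bilayer aorta.

    The media occupies 5/8 of the wall, the adventitia 3/8.  The tube is
    3 mm longer than the tear (1.5 mm per end).  ``symmetry`` reduces the
    domain: "full" models 360 deg and the whole length; "quarter" uses the
    theta in [0, 180 deg] half-circumference and the upper half-length with
    symmetry conditions (valid for a tear centered at theta = 0, z = L/2).
    """

    Ri: float = 7.5
    Ro: float = 9.0
    media_fraction: float = 5.0 / 8.0
    extra_length: float = 3.0
    n_theta: int = 36          # circumferential cells over the modeled arc
    n_axial: int = 8           # axial cells over the modeled length
    n_r_inner: int = 1         # radial cells lumen -> cohesive surface
    n_r_outer: int = 1         # radial cells cohesive surface -> media edge
    n_r_adventitia: int = 1
    symmetry: str = "quarter"

    @property
    def wall(self) -> float:
        return self.Ro - self.Ri

    @property
    def tm(self) -> float:
        """Media thickness, mm."""
        return self.media_fraction * self.wall

    def interface_radius(self, tear: TearGeometry) -> float:
        return self.Ri + tear.t_ratio * self.tm

    def length(self, tear: TearGeometry) -> float:
        return tear.s_mm + self.extra_length


@dataclass
class LoadCase:
    """Axial stretch, lumen pressures and residual-stress opening angle."""

    lambda_axial: float = 1.02
    p_TL: float = 200.0        # true-lumen pressure at full load factor, kPa
    p_FL: float | None = None  # false-lumen pressure (defaults to p_TL)
    opening_angle_deg: float = 0.0

    def __post_init__(self):
        if self.lambda_axial < 1.0:
            raise ValueError("axial stretch must be >= 1")
        if self.p_FL is None:
            self.p_FL = self.p_TL

    @property
    def LPD(self) -> float:
        """True/false luminal pressure difference, kPa."""
        return self.p_TL - self.p_FL


# ----------------------------------------------------------------------
def build_tube_model(spec: TubeSpec, tear: TearGeometry, case: LoadCase,
                     materials=(MEDIA, ADVENTITIA),
                     cohesive: CohesiveParams | None = None,
                     controls: SolverControls | None = None,
                     pressure_resolution_kPa: float = 1.0,
                     intact: bool = False) -> FEModel:
    """Hexahedral bilayer tube with a pre-torn cohesive surface and loads.

    Stage 1 ramps the axial stretch; stage 2 ramps both lumen pressures at
    the fixed ratio of the load case, watching for the first complete
    cohesive failure.
    """
    cohesive = cohesive or default_cohesive_params()
    quarter = spec.symmetry == "quarter"
    if not quarter and spec.symmetry != "full":
        raise ValueError("symmetry must be 'quarter' or 'full'")

    L = spec.length(tear)
    Rc = spec.interface_radius(tear)
    Rm = spec.Ri + spec.tm
    if not spec.Ri < Rc < Rm:
        raise ValueError("cohesive surface must lie inside the media")

    # modeled domain
    if quarter:
        thetas = np.linspace(0.0, np.pi, spec.n_theta + 1)
        zs = np.linspace(0.0, L / 2.0, spec.n_axial + 1)   # z=0: mid-plane
        z_tear_max = tear.s_mm / 2.0
        periodic = False
    else:
        thetas = np.linspace(-np.pi, np.pi, spec.n_theta + 1)[:-1]
        zs = np.linspace(0.0, L, spec.n_axial + 1)
        z_tear_lo, z_tear_hi = (L - tear.s_mm) / 2.0, (L + tear.s_mm) / 2.0
        periodic = True

    r_in = np.linspace(spec.Ri, Rc, spec.n_r_inner + 1)
    r_out = np.unique(np.concatenate([
        np.linspace(Rc, Rm, spec.n_r_outer + 1),
        np.linspace(Rm, spec.Ro, spec.n_r_adventitia + 1)]))
    nt = thetas.size if periodic else thetas.size
    ntc = spec.n_theta                       # circumferential cells

    def block_nodes(radii):
        R, T, Z = np.meshgrid(radii, thetas, zs, indexing="ij")
        return np.column_stack([(R * np.cos(T)).ravel(),
                                (R * np.sin(T)).ravel(), Z.ravel()])

    def node_id(block_off, ir, it, iz, nr):
        it = it % nt if periodic else it
        return block_off + (ir * nt + it) * zs.size + iz

    nodes_in = block_nodes(r_in)
    nodes_out = block_nodes(r_out)
    off_out = nodes_in.shape[0]
    nodes = np.vstack([nodes_in, nodes_out])

    def block_hexes(block_off, radii):
        # (r, theta) quad ordered counterclockwise about +z, at z then z+dz
        el = []
        for ir in range(radii.size - 1):
            for it in range(ntc):
                for iz in range(spec.n_axial):
                    n = [node_id(block_off, ir, it, iz, radii.size),
                         node_id(block_off, ir + 1, it, iz, radii.size),
                         node_id(block_off, ir + 1, it + 1, iz, radii.size),
                         node_id(block_off, ir, it + 1, iz, radii.size)]
                    el.append(n + [m + 1 for m in n])
        return np.array(el, dtype=int)

    elems = np.vstack([block_hexes(0, r_in), block_hexes(off_out, r_out)])
    # material tags and frames
    cent = nodes[elems].mean(axis=1)
    rad_c = np.linalg.norm(cent[:, :2], axis=1)
    mat_id = np.where(rad_c < Rm, 0, 1)
    th_c = np.arctan2(cent[:, 1], cent[:, 0])
    Qmat = np.zeros((elems.shape[0], 3, 3))
    Qmat[:, 0, 0] = -np.sin(th_c)
    Qmat[:, 1, 0] = np.cos(th_c)           # column 0: circumferential
    Qmat[:, 2, 1] = 1.0                    # column 1: axial
    Qmat[:, 0, 2] = np.cos(th_c)
    Qmat[:, 1, 2] = np.sin(th_c)           # column 2: radial
    mesh = Mesh(nodes=nodes, elems=elems, mat_id=mat_id, elem_type="hex8")

    # cohesive surface: inner-block outer shell vs outer-block inner shell
    ir_in = r_in.size - 1
    pairs, torn, s_hint, labels, fl_bot, fl_top = [], [], [], [], [], []
    for it in range(ntc):
        th_mid = 0.5 * (thetas[it] + thetas[(it + 1) % nt]) if not periodic \
            else thetas[it] + np.pi / ntc
        for iz in range(spec.n_axial):
            z_mid = 0.5 * (zs[iz] + zs[iz + 1])
            bot = [node_id(0, ir_in, it, iz, r_in.size),
                   node_id(0, ir_in, it + 1, iz, r_in.size),
                   node_id(0, ir_in, it + 1, iz + 1, r_in.size),
                   node_id(0, ir_in, it, iz + 1, r_in.size)]
            top = [node_id(off_out, 0, it, iz, r_out.size),
                   node_id(off_out, 0, it + 1, iz, r_out.size),
                   node_id(off_out, 0, it + 1, iz + 1, r_out.size),
                   node_id(off_out, 0, it, iz + 1, r_out.size)]
            pairs.append(bot + top)
            s_hint.append([-np.sin(th_mid), np.cos(th_mid), 0.0])
            if quarter:
                in_tear = (abs(th_mid) <= np.deg2rad(tear.eta_deg) / 2.0
                           and z_mid <= z_tear_max)
                d_th = max(0.0, abs(th_mid) - np.deg2rad(tear.eta_deg) / 2.0) * Rc
                d_z = max(0.0, z_mid - z_tear_max)
            else:
                in_tear = (abs(th_mid) <= np.deg2rad(tear.eta_deg) / 2.0
                           and z_tear_lo <= z_mid <= z_tear_hi)
                d_th = max(0.0, abs(th_mid) - np.deg2rad(tear.eta_deg) / 2.0) * Rc
                d_z = max(0.0, max(z_tear_lo - z_mid, z_mid - z_tear_hi))
            in_tear = in_tear and not intact
            torn.append(in_tear)
            if in_tear:
                labels.append("torn")
            elif d_th <= 1e-12 and d_z > 0:
                labels.append("axial")
            elif d_z <= 1e-12 and d_th > 0:
                labels.append("circumferential")
            else:
                labels.append("axial" if d_z >= d_th else "circumferential")
            if in_tear:
                # false-lumen pressure faces: inner flap outer surface
                # (normal +r toward the fluid) and outer wall inner surface
                fl_bot.append(bot)            # ordered with +r normal
                fl_top.append([top[0], top[3], top[2], top[1]])  # -r normal
    iface = InterfaceSet(pairs=np.array(pairs, dtype=int),
                         torn=np.array(torn, dtype=bool),
                         s_hint=np.array(s_hint))
    iface.labels = np.array(labels)

    # true-lumen pressure faces: r = Ri surface, normal pointing -r (into
    # the lumen fluid)
    tl = []
    for it in range(ntc):
        for iz in range(spec.n_axial):
            q = [node_id(0, 0, it, iz, r_in.size),
                 node_id(0, 0, it, iz + 1, r_in.size),
                 node_id(0, 0, it + 1, iz + 1, r_in.size),
                 node_id(0, 0, it + 1, iz, r_in.size)]
            tl.append(q)
    tl = np.array(tl, dtype=int)
    fl_faces = (np.array(fl_bot, dtype=int).reshape(-1, 4),
                np.array(fl_top, dtype=int).reshape(-1, 4))

    # ---- boundary conditions
    x, y, z = nodes.T
    tol = 1e-9
    if quarter:
        bottom = np.flatnonzero(np.abs(z) < tol)          # mid-plane
        top = np.flatnonzero(np.abs(z - L / 2.0) < tol)
        cut = np.flatnonzero(np.abs(y) < tol)             # theta = 0 and pi
        merid = np.flatnonzero(np.abs(x) < tol)           # theta = 90 deg
        fixed0 = np.concatenate([bottom * 3 + 2, cut * 3 + 1, merid * 3])
        stretch_dofs = top * 3 + 2
        stretch_val = (case.lambda_axial - 1.0) * (L / 2.0)
    else:
        bottom = np.flatnonzero(np.abs(z) < tol)
        top = np.flatnonzero(np.abs(z - L) < tol)
        secA = np.flatnonzero(np.abs(y) < tol)            # theta = 0, pi
        secB = np.flatnonzero(np.abs(x) < tol)            # theta = +-90 deg
        fixed0 = np.concatenate([bottom * 3 + 2, secA * 3 + 1, secB * 3])
        stretch_dofs = top * 3 + 2
        stretch_val = (case.lambda_axial - 1.0) * L
    fixed0 = np.unique(fixed0)
    stretch_dofs = np.setdiff1d(stretch_dofs, fixed0)
    dofs = np.concatenate([fixed0, stretch_dofs])

    def vals_stage1(g):
        v = np.zeros(dofs.size)
        v[fixed0.size:] = g * stretch_val
        return v

    def vals_stage2(g):
        v = np.zeros(dofs.size)
        v[fixed0.size:] = stretch_val
        return v

    stage1 = LoadStage(dirichlet_dofs=dofs, dirichlet_vals=vals_stage1,
                       name="stretch")
    pressures = [(tl, lambda g: g * case.p_TL)]
    if fl_faces[0].size:
        pressures += [(fl_faces[0], lambda g: g * case.p_FL),
                      (fl_faces[1], lambda g: g * case.p_FL)]
    stage2 = LoadStage(
        dirichlet_dofs=dofs, dirichlet_vals=vals_stage2,
        pressures=pressures, watch_failure=True,
        gamma_resolution=pressure_resolution_kPa / max(case.p_TL, 1e-9),
        name="pressurize")

    controls = controls or SolverControls(dgamma0=0.05, dgamma_max=0.1,
                                          rtol=1e-6)
    model = FEModel(mesh=mesh, materials=list(materials), interface=iface,
                    cohesive=cohesive, stages=[stage1, stage2],
                    controls=controls, Qmat=Qmat)
    return model


# ----------------------------------------------------------------------
def _wall_stress_diff(lam_t, lam_z, mat):
    """sigma_tt - sigma_rr and sigma_zz - sigma_rr of the incompressible
    material at circumferential/axial stretches (lam_t, lam_z)."""
    lam_r = 1.0 / (lam_t * lam_z)
    F = np.diag([lam_t, lam_z, lam_r])
    S, _ = pk2_stress_and_tangent(F, mat, tangent=False, volumetric=False)
    sig = F @ S @ F.T
    return sig[0, 0] - sig[2, 2], sig[1, 1] - sig[2, 2]


def semi_analytic_inflation(spec: TubeSpec, lam_z: float, p: float,
                            materials=(MEDIA, ADVENTITIA),
                            opening_angle_deg: float = 0.0,
                            n_grid: int = 200) -> dict:
    """Incompressible axisymmetric inflation-extension of the intact tube.

    Solves the radial equilibrium of the bilayer cylinder under inner
    pressure ``p`` (kPa) and axial stretch ``lam_z``; optionally with the
    opening-angle residual prestrain.  Returns deformed radii and the
    transmural Cauchy stress profiles.
    """
    Ri, Ro, Rm = spec.Ri, spec.Ro, spec.Ri + spec.tm
    k, rho_of_R, _ = opening_angle_prestrain(spec, opening_angle_deg,
                                             materials)

    def dsig(r, ri):
        # material point at deformed radius r: closed-reference radius R,
        # opened (stress-free) radius rho; elastic stretches from the
        # opened state are (k r / rho, lam_z, 1/(lam_t lam_z))
        R = np.sqrt(Ri ** 2 + (r ** 2 - ri ** 2) * lam_z)
        rho = rho_of_R(R)
        lam_t = k * r / rho
        mat = materials[0] if R < Rm else materials[1]
        dtt, dzz = _wall_stress_diff(lam_t, lam_z, mat)
        return dtt, dzz

    def pressure_of_ri(ri):
        ro = np.sqrt(ri ** 2 + (Ro ** 2 - Ri ** 2) / lam_z)
        val, _ = quad(lambda r: dsig(r, ri)[0] / r, ri, ro, limit=200)
        return val

    # solve for the deformed inner radius
    f = lambda ri: pressure_of_ri(ri) - p
    lo, hi = 0.5 * Ri, 3.0 * Ri
    ri = brentq(f, lo, hi, xtol=1e-10)
    ro = np.sqrt(ri ** 2 + (Ro ** 2 - Ri ** 2) / lam_z)
    r = np.linspace(ri, ro, n_grid)
    dtt = np.array([dsig(rr, ri)[0] for rr in r])
    dzz = np.array([dsig(rr, ri)[1] for rr in r])
    # sigma_rr by inward integration from the outer traction-free surface
    s_rr = np.zeros_like(r)
    for i in range(n_grid - 2, -1, -1):
        mid = 0.5 * (dtt[i] + dtt[i + 1])
        rm = 0.5 * (r[i] + r[i + 1])
        s_rr[i] = s_rr[i + 1] - mid / rm * (r[i + 1] - r[i])
    out = {
        "ri": ri,
        "ro": ro,
        "r": r,
        "R": np.sqrt(Ri ** 2 + (r ** 2 - ri ** 2) * lam_z),
        "sigma_rr": s_rr,
        "sigma_tt": s_rr + dtt,
        "sigma_zz": s_rr + dzz,
        "pressure": -s_rr[0],
    }
    return out


def opening_angle_prestrain(spec: TubeSpec, opening_angle_deg: float,
                            materials=(MEDIA, ADVENTITIA)):
    """Classical opening-angle kinematics of circumferential residual stress.

    The stress-free configuration is an open sector subtending
    2*(pi - alpha); closing it into the unloaded cylinder imposes a
    circumferential prestretch lam_theta = k R / rho(R) with
    k = pi/(pi - alpha) and rho the opened radius.  The opened inner radius
    is chosen so that the closed, unloaded ring is self-equilibrated (zero
    net inner pressure).

    Returns (k, rho_of_R, rho_i).  alpha = 0 gives the identity.
    """
    Ri, Ro, Rm = spec.Ri, spec.Ro, spec.Ri + spec.tm
    alpha = np.deg2rad(opening_angle_deg)
    if alpha < 0 or alpha >= np.pi:
        raise ValueError("opening angle must lie in [0, 180) degrees")
    if alpha == 0.0:
        return 1.0, lambda R: np.asarray(R, dtype=float), Ri
    k = np.pi / (np.pi - alpha)

    def rho_of_R_given(rho_i):
        return lambda R: np.sqrt(rho_i ** 2 + (np.asarray(R, dtype=float) ** 2
                                               - Ri ** 2) / k)

    def net_pressure(rho_i):
        rho = rho_of_R_given(rho_i)

        def integrand(R):
            mat = materials[0] if R < Rm else materials[1]
            lam_t = k * R / rho(R)
            dtt, _ = _wall_stress_diff(lam_t, 1.0, mat)
            return dtt / R
        val, _ = quad(integrand, Ri, Ro, limit=200)
        return val

    # The opened sector has a larger radius than the closed ring
    # (lam_theta = k R / rho ~ 1), so bracket rho_i around k * Ri where
    # the inner prestretch stays near unity.
    grid = k * Ri * np.linspace(0.75, 1.5, 16)
    vals = np.array([net_pressure(g) for g in grid])
    ok = np.isfinite(vals)
    grid, vals = grid[ok], vals[ok]
    sign = np.sign(vals)
    idx = np.flatnonzero(np.diff(sign) != 0)
    if idx.size == 0:
        raise RuntimeError("could not bracket the opened inner radius")
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    rho_i = brentq(net_pressure, lo, hi, xtol=1e-10)
    return k, rho_of_R_given(rho_i), rho_i


def apply_residual_prestrain(model: FEModel, spec: TubeSpec,
                             opening_angle_deg: float,
                             materials=(MEDIA, ADVENTITIA)) -> FEModel:
    """Attach the opening-angle prestrain field to a tube model.

    Sets the per-element inverse prestrain gradient (in the global frame)
    so that the elastic deformation is measured from the opened,
    stress-free sector.  Opening angle 0 leaves the model unchanged.
    """
    if opening_angle_deg == 0.0:
        model.Gpre = None
        return model
    k, rho_of_R, _ = opening_angle_prestrain(spec, opening_angle_deg,
                                             materials)
    cent = model.mesh.nodes[model.mesh.elems].mean(axis=1)
    R = np.linalg.norm(cent[:, :2], axis=1)
    rho = rho_of_R(R)
    lam_t = k * R / rho
    ne = R.size
    Gloc = np.zeros((ne, 3, 3))
    Gloc[:, 0, 0] = 1.0 / lam_t      # circumferential
    Gloc[:, 1, 1] = 1.0              # axial
    Gloc[:, 2, 2] = lam_t            # radial (det = 1)
    Q = model.Qmat
    model.Gpre = np.einsum("eiI,eIJ,ejJ->eij", Q, Gloc, Q)
    return model


# ----------------------------------------------------------------------
def run_pressurization(model: FEModel):
    """Solve the two-stage tube schedule and return the critical state.

    Returns (event, mode_mix_field, trajectory); the event is None when no
    cohesive element fails within the scheduled pressure range.
    """
    traj, u, surface, event = solve_quasi_static(model)
    ngp = 4
    m_field = surface.mode_mix().reshape(-1, ngp) if surface is not None \
        else None
    return event, m_field, traj


def parameter_sweep(spec: TubeSpec, cases: list[dict],
                    materials=(MEDIA, ADVENTITIA),
                    cohesive: CohesiveParams | None = None,
                    controls: SolverControls | None = None):
    """Run a list of tear/load configurations; returns a results table.

    Each case dict may set eta_deg, s_mm, t_ratio, lambda_axial, p_TL,
    p_FL, opening_angle_deg.  Failures of individual cases are recorded
    (Pc = NaN) and the sweep continues.
    """
    import pandas as pd

    rows = []
    for case_kw in cases:
        tear = TearGeometry(
            eta_deg=case_kw.get("eta_deg", 150.0),
            s_mm=case_kw.get("s_mm", 10.0),
            t_ratio=case_kw.get("t_ratio", 0.4))
        case = LoadCase(
            lambda_axial=case_kw.get("lambda_axial", 1.02),
            p_TL=case_kw.get("p_TL", 200.0),
            p_FL=case_kw.get("p_FL", case_kw.get("p_TL", 200.0)),
            opening_angle_deg=case_kw.get("opening_angle_deg", 0.0))
        row = {"eta_deg": tear.eta_deg, "s_mm": tear.s_mm,
               "t_ratio": tear.t_ratio, "lambda_axial": case.lambda_axial,
               "opening_angle_deg": case.opening_angle_deg,
               "LPD": case.LPD}
        try:
            model = build_tube_model(spec, tear, case, materials=materials,
                                     cohesive=cohesive, controls=controls)
            if case.opening_angle_deg:
                apply_residual_prestrain(model, spec,
                                         case.opening_angle_deg, materials)
            event, m_field, traj = run_pressurization(model)
            if event is None:
                row.update(Pc=np.nan, direction="none", m=np.nan,
                           Tn=np.nan, Ts=np.nan, Tt=np.nan,
                           completed=traj.completed)
            else:
                row.update(Pc=event.Pc, direction=event.direction,
                           m=event.mode_mix, Tn=event.Tn, Ts=event.Ts,
                           Tt=event.Tt, completed=True)
        except Exception as exc:   # record and continue
            row.update(Pc=np.nan, direction=f"error: {exc}", m=np.nan,
                       Tn=np.nan, Ts=np.nan, Tt=np.nan, completed=False)
        rows.append(row)
    return pd.DataFrame(rows)
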