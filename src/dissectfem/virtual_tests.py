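"""Virtual calibration experiments for the cohesive interface of the media.

Reproduces, in silico, the three delamination experiments used to calibrate
the inter-lamellar cohesive constants:

* T-peel of a medial strip (4.0 mm x 1.2 mm, r-theta plane) with a
  mid-thickness interface: the steady-state pulling force per unit width
  measures the mode-I fracture energy (for ideally flexible arms the
  plateau equals G_IC/2 per arm).
* Direct tension across the interface: the peak nominal normal traction is
  the mode-I initiation traction TnC.
* Interface shear (4 mm specimen, 1 mm radial thickness) in the
  circumferential (mode II) and axial (mode III) directions: the peak
  interface shear stress is the sliding initiation traction, and the area
  under the traction-separation history is the sliding fracture energy.

``calibrate_GIC`` inverts the peel test: it bisects the mode-I fracture
energy until the simulated plateau matches a target force per width, with
the initiation traction held fixed — the same loop used to produce the
bundled parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohesive import CohesiveParams
from .constants import MEDIA, default_cohesive_params
from .fem.assembly import Assembler
from .fem.mesh import rect_with_interface
from .fem.model import FEModel, LoadStage, SolverControls
from .fem.solver import newton_solve
from .hgo import MaterialParams

__all__ = [
    "SpecimenSpec",
    "TestCurve",
    "run_peel_test",
    "run_direct_tension",
    "run_shear_test",
    "calibrate_GIC",
]


@dataclass
class SpecimenSpec:
    """Geometry, discretization and loading schedule of a virtual specimen.

    kind: "peel" | "tension" | "shear_rtheta" | "shear_rz"
    """

    kind: str = "peel"
    length_mm: float = 4.0
    thickness_mm: float = 1.2
    nx: int = 20
    ny_arm: int = 3
    precrack_mm: float = 0.8
    max_displacement_mm: float = 3.6
    dgamma0: float = 0.02
    early_stop_consumed: float = 0.85

    def __post_init__(self):
        if self.length_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("specimen dimensions must be positive")


@dataclass
class TestCurve:
    """Load-displacement record of a virtual test.

    ``x`` is the applied displacement (mm) or amount of shear
    (dimensionless), ``y`` the force per unit width (mN/mm) or interface
    shear stress (kPa).  ``plateau``/``peak`` are the extracted summaries;
    ``propagated`` is False when the schedule ended before the interface
    damage advanced.
    """

    x: np.ndarray
    y: np.ndarray
    plateau: float = np.nan
    peak: float = np.nan
    dissipated: float = np.nan
    complete_damage_x: float = np.nan
    propagated: bool = True


def _ramp(asm, stage, surface, controls, on_step, early_stop=None):
    """Adaptive displacement ramp with per-step cohesive commits."""
    u = np.zeros(asm.ndof)
    gamma, dg = 0.0, controls.dgamma0
    u_old, g_old = None, None
    while gamma < 1.0 - 1e-12:
        g_try = min(gamma + dg, 1.0)
        surface.viscosity = controls.stabilization
        surface.pseudo_dt = g_try - gamma
        u0 = u
        if u_old is not None and gamma > g_old:
            w = (g_try - gamma) / (gamma - g_old)
            u0 = u + min(w, 2.0) * (u - u_old)
        u_new, ok, info = newton_solve(asm, stage, g_try, u0, surface,
                                       controls)
        if not ok:
            dg *= 0.5
            if dg < controls.dgamma_min:
                return False
            continue
        surface.commit(info["seps"])
        u_old, g_old = u, gamma
        u = u_new
        gamma = g_try
        on_step(gamma, u, info)
        if info["iterations"] <= controls.max_iter // 2:
            dg = min(dg * controls.grow, controls.dgamma_max)
        if early_stop is not None and early_stop():
            break
    return True


# ----------------------------------------------------------------------
def run_peel_test(spec: SpecimenSpec, bulk: MaterialParams,
                  coh: CohesiveParams) -> TestCurve:
    """Plane-strain T-peel: force per unit width vs applied separation.

    The strip is pre-cracked over ``precrack_mm`` from the pulled end; the
    two arms are gripped on that end and displaced symmetrically apart in
    the radial direction.  The plateau is the mean force over the steady
    propagation window: crack advance beyond three cohesive element
    lengths, less than 80% of the bonded interface consumed.
    """
    mesh, iface, _, _ = rect_with_interface(
        spec.length_mm, spec.thickness_mm, spec.nx, spec.ny_arm, spec.ny_arm,
        spec.thickness_mm / 2.0, torn_until_x=spec.precrack_mm)
    model = FEModel(mesh=mesh, materials=[bulk], interface=iface,
                    cohesive=coh,
                    controls=SolverControls(dgamma0=spec.dgamma0,
                                            dgamma_max=0.04))
    asm = Assembler(model)
    surface = asm.make_surface()

    left = mesh.nodes_where(lambda x: (np.abs(x[:, 0]) < 1e-12))
    # the interface row is duplicated: split the grip by block membership
    n_bot_block = (spec.nx + 1) * (spec.ny_arm + 1)
    top_arm = left[left >= n_bot_block]
    bot_arm = left[left < n_bot_block]
    # grips prescribe only the radial (opening) component; the intact far
    # end is held axially to remove the rigid translation
    right = mesh.nodes_where(
        lambda x: (np.abs(x[:, 0] - spec.length_mm) < 1e-12))
    dofs = np.concatenate([bot_arm * 2 + 1, top_arm * 2 + 1, right * 2])
    nb, nt = bot_arm.size, top_arm.size
    pull = spec.max_displacement_mm

    def vals(g):
        v = np.zeros(dofs.size)
        v[:nb] = -g * pull
        v[nb:nb + nt] = g * pull
        return v

    stage = LoadStage(dirichlet_dofs=dofs, dirichlet_vals=vals, name="peel")

    dx = spec.length_mm / spec.nx
    xc = (np.arange(spec.nx) + 0.5) * dx
    bonded0 = float(np.sum(~iface.torn))
    top_y = top_arm * 2 + 1
    xs, fs, advance, consumed = [], [], [], []

    def on_step(gamma, u, info):
        F = float(np.sum(info["R"][top_y]))
        failed_el = surface.failed.reshape(iface.n, -1).all(axis=1)
        front = failed_el | iface.torn
        a = float(np.max(xc[front], initial=0.0))
        xs.append(gamma * pull)
        fs.append(F)
        advance.append(max(a - spec.precrack_mm, 0.0))
        consumed.append(float(np.sum(failed_el & ~iface.torn)) / bonded0)

    def early():
        return consumed and consumed[-1] >= spec.early_stop_consumed

    _ramp(asm, stage, surface, model.controls, on_step, early)
    xs, fs = np.array(xs), np.array(fs)
    adv, con = np.array(advance), np.array(consumed)
    window = (adv >= 3.0 * dx) & (con < 0.80)
    curve = TestCurve(x=xs, y=fs, dissipated=asm.dissipation(surface))
    if not np.any(window):
        curve.propagated = False
        return curve
    curve.plateau = float(np.mean(fs[window]))
    curve.peak = float(np.max(fs))
    return curve


def calibrate_GIC(target_plateau: float, bulk: MaterialParams,
                  coh: CohesiveParams, spec: SpecimenSpec | None = None,
                  rtol: float = 0.02, bracket=(35.0, 80.0),
                  max_iter: int = 12) -> float:
    """Recover the mode-I fracture energy from a target peel plateau.

    Root-finds on G_IC (holding the initiation traction TnC fixed) until
    the simulated plateau force per unit width matches ``target_plateau``
    within ``rtol`` (bracketing bisection accelerated by regula falsi; the
    plateau grows monotonically with G_IC).  Raises ``ValueError`` when the
    target is outside the range achievable within the bracket.
    """
    spec = spec or SpecimenSpec()

    def plateau(gic):
        c = replace(coh, GIC=gic)
        curve = run_peel_test(spec, bulk, c)
        if not curve.propagated:
            raise RuntimeError(f"peel did not propagate at G_IC={gic}")
        return curve.plateau

    lo, hi = bracket
    if target_plateau <= 0:
        raise ValueError("target plateau must be positive")
    f_lo, f_hi = plateau(lo), plateau(hi)
    if not (f_lo <= target_plateau <= f_hi):
        raise ValueError(
            f"target {target_plateau} mN/mm outside achievable plateau range "
            f"[{f_lo:.2f}, {f_hi:.2f}] for G_IC in {bracket}")
    for _ in range(max_iter):
        # regula falsi step, safeguarded toward the middle of the bracket
        w = (target_plateau - f_lo) / max(f_hi - f_lo, 1e-12)
        mid = lo + np.clip(w, 0.15, 0.85) * (hi - lo)
        f_mid = plateau(mid)
        if abs(f_mid - target_plateau) <= rtol * target_plateau:
            return mid
        if f_mid < target_plateau:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------
def run_direct_tension(spec: SpecimenSpec | None, bulk: MaterialParams,
                       coh: CohesiveParams) -> TestCurve:
    """Uniform normal separation across a single cohesive patch.

    Rigid grips drive the separation directly, so the response is the pure
    mode-I bilinear law: peak nominal traction TnC, dissipated energy G_IC.
    """
    mesh, iface, _, _ = rect_with_interface(1.0, 0.2, 1, 1, 1, 0.1)
    model = FEModel(mesh=mesh, materials=[bulk], interface=iface,
                    cohesive=coh,
                    controls=SolverControls(dgamma0=0.005, dgamma_max=0.01,
                                            stabilization=0.0))
    asm = Assembler(model)
    surface = asm.make_surface()
    nn = mesh.n_nodes
    top = np.arange(nn // 2, nn)
    bot = np.arange(0, nn // 2)
    dofs = np.concatenate([bot * 2, bot * 2 + 1, top * 2, top * 2 + 1])
    smax = 1.2 * 2.0 * coh.GIC / coh.TnC

    def vals(g):
        v = np.zeros(dofs.size)
        v[3 * (nn // 2):] = g * smax
        return v

    stage = LoadStage(dirichlet_dofs=dofs, dirichlet_vals=vals, name="tension")
    xs, ts = [], []

    def on_step(gamma, u, info):
        xs.append(gamma * smax)
        ts.append(float(np.mean(surface.Tn)))

    _ramp(asm, stage, surface, model.controls, on_step)
    xs, ts = np.array(xs), np.array(ts)
    idx = int(np.argmax(ts))
    done = np.flatnonzero(surface_failed_x := (ts <= 1e-9) & (xs > xs[idx]))
    return TestCurve(
        x=xs, y=ts, peak=float(ts[idx]),
        dissipated=float(np.mean(surface.GI)),
        complete_damage_x=float(xs[done[0]]) if done.size else np.nan)


def run_shear_test(spec: SpecimenSpec | None, bulk: MaterialParams,
                   coh: CohesiveParams, direction: str = "rtheta") -> TestCurve:
    """Interface shear test: shear stress vs amount of shear.

    The specimen (1 mm radial thickness, interface at mid-thickness) is
    fixed on the front surface; the rear surface is displaced tangentially
    — circumferentially for mode II ("rtheta") or axially for mode III
    ("rz").  The abscissa is the tangential displacement divided by the
    1 mm radial thickness; the ordinate is the interface shear stress.
    """
    if direction not in ("rtheta", "rz"):
        raise ValueError("direction must be 'rtheta' or 'rz'")
    mode = "s" if direction == "rtheta" else "t"
    L, H = 4.0, 1.0
    mesh, iface, _, _ = rect_with_interface(L, H, 16, 2, 2, H / 2.0)
    iface.tangent_mode = mode
    # rz specimen: the plane is (z, r); fibres run circumferentially,
    # i.e. out of plane — supply the material frame accordingly
    Qmat = None
    if direction == "rz":
        ne = mesh.elems.shape[0]
        Q = np.zeros((3, 3))
        # material axes (circ, axial, radial) -> global (out-of-plane, x, y)
        Q[:, 0] = [0.0, 0.0, 1.0]
        Q[:, 1] = [1.0, 0.0, 0.0]
        Q[:, 2] = [0.0, 1.0, 0.0]
        Qmat = np.tile(Q, (ne, 1, 1))
    model = FEModel(mesh=mesh, materials=[bulk], interface=iface,
                    cohesive=coh, Qmat=Qmat,
                    controls=SolverControls(dgamma0=0.01, dgamma_max=0.03,
                                            stabilization=2e-5))
    asm = Assembler(model)
    surface = asm.make_surface()
    bot = mesh.nodes_where(lambda x: x[:, 1] < 1e-12)
    top = mesh.nodes_where(lambda x: x[:, 1] > H - 1e-12)
    dofs = np.concatenate([bot * 2, bot * 2 + 1, top * 2, top * 2 + 1])
    GC = coh.GIIC if mode == "s" else coh.GIIIC
    TC = coh.TsC if mode == "s" else coh.TtC
    umax = 1.3 * (2.0 * GC / TC + 2.0)

    def vals(g):
        v = np.zeros(dofs.size)
        v[2 * bot.size:2 * bot.size + top.size] = g * umax
        return v

    stage = LoadStage(dirichlet_dofs=dofs, dirichlet_vals=vals, name="shear")
    # the free left/right ends peel locally (edge effect of the finite
    # specimen); the interface state is uniform away from them, so the
    # reported stress is the mean over the central half of the interface
    nelem = iface.n
    ngp_per = asm.iface_ngp
    xc = np.repeat((np.arange(nelem) + 0.5) * (L / nelem), ngp_per)
    central = np.abs(xc - L / 2.0) <= L / 4.0
    xs, taus = [], []

    def on_step(gamma, u, info):
        xs.append(gamma * umax / H)
        # rate-independent tractions at the converged kinematics (free of
        # the small viscous-regularization lag)
        t = surface.Ts_target if mode == "s" else surface.Tt_target
        taus.append(float(np.mean(np.abs(t[central]))))

    def early():
        return bool(surface.failed[central].all())

    _ramp(asm, stage, surface, model.controls, on_step, early)
    xs, taus = np.array(xs), np.array(taus)
    idx = int(np.argmax(taus))
    G = surface.GII if mode == "s" else surface.GIII
    done = np.flatnonzero((taus <= 1e-6 * taus[idx]) & (xs > xs[idx]))
    return TestCurve(
        x=xs, y=taus, peak=float(taus[idx]),
        dissipated=float(np.mean(G[central])),
        complete_damage_x=float(xs[done[0]]) if done.size else np.nan)
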