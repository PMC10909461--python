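"""Newton solution, adaptive load stepping and critical-event detection.

Each :class:`~dissectfem.fem.model.LoadStage` ramps a load factor gamma
from 0 to 1.  Steps are accepted only when the Newton iteration reaches the
residual tolerance; on divergence the step is halved.  Cohesive history is
committed per accepted step, making damage irreversible across steps.

When a stage watches for failure, the first load increment in which any
cohesive integration point completes its damage (power-law energy criterion
g >= 1) triggers a bisection on gamma from the last safe committed state,
refining the critical load factor to the requested resolution.  The
reported critical state carries the element index, its direction label, the
mode mix ratio m = 1 - G_I/G_T and the tractions of the element in the
last equilibrium state before removal.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse.linalg as spla

from ..hgo import InvalidDeformationError
from .assembly import Assembler
from .model import CriticalEvent, FEModel, LoadStage, StepRecord, Trajectory

__all__ = ["solve_quasi_static", "detect_critical_event", "newton_solve"]


def newton_solve(asm: Assembler, stage: LoadStage, gamma: float,
                 u0: np.ndarray, surface, controls):
    """Newton iteration at fixed load factor; returns (u, converged, info)."""
    u = u0.copy()
    if stage.dirichlet_dofs.size:
        u[stage.dirichlet_dofs] = stage.dirichlet_vals(gamma)
    free = np.setdiff1d(np.arange(asm.ndof), stage.dirichlet_dofs,
                        assume_unique=False)
    def evaluate(uu, need_tangent):
        try:
            R, K, seps, diag = asm.assemble(uu, stage, gamma, surface,
                                            need_tangent=need_tangent)
        except (InvalidDeformationError, FloatingPointError):
            return None
        with np.errstate(over="ignore", invalid="ignore"):
            fint = R + diag["fext_vec"]
            ref = max(diag["fext_norm"], float(np.linalg.norm(fint)), 1e-6)
            rn = float(np.linalg.norm(R[free]))
        if not (np.isfinite(rn) and np.isfinite(ref)):
            return None
        return rn, ref, R, K, seps, diag

    rn_best = np.inf
    rn_old = np.inf
    u_prev, du = None, None
    scale, retries, it = 1.0, 0, 0
    factor = None
    while it < controls.max_iter:
        state = evaluate(u, True)
        if state is None:
            # unphysical trial state (inverted element / overflow):
            # retreat along the last Newton direction
            if u_prev is None or retries >= 6:
                break
            scale *= 0.25
            retries += 1
            u = u_prev.copy()
            u[free] += scale * du
            continue
        rn, ref, R, K, seps, diag = state
        # loose line search: a Newton step may increase the residual
        # moderately, but a blow-up means the step left the basin
        if du is not None and rn > 5.0 * rn_old and retries < 5:
            scale *= 0.5
            retries += 1
            u = u_prev.copy()
            u[free] += scale * du
            continue
        retries = 0
        rn_old = rn
        if controls.verbose:
            print(f"    it {it}: |R| = {rn:.3e} (ref {ref:.3e})")
        if rn <= controls.rtol * ref + controls.atol:
            return u, True, {"iterations": it, "residual": rn,
                             "seps": seps, "R": R, **diag}
        if it > 6 and rn > 1e4 * max(rn_best, ref):
            break  # diverging
        try:
            factor = spla.splu(K[free][:, free].tocsc())
        except Exception:
            break
        rn_best = min(rn_best, rn)
        du = factor.solve(-R[free])
        if not np.all(np.isfinite(du)):
            break
        u_prev = u.copy()
        scale = 1.0
        u = u.copy()
        u[free] += du
        it += 1
    return u, False, {"iterations": controls.max_iter, "residual": np.inf,
                      "seps": None}


def _new_failures(surface, seps) -> np.ndarray:
    trial = surface.trial_state(seps)
    now = (trial["g"] >= 1.0 - 1e-9) | (trial["d"] >= 1.0 - 1e-12)
    return now & ~surface.failed & ~surface.torn


def _record(asm, stage, gamma, u, info, energy_acc) -> StepRecord:
    return StepRecord(
        stage=stage.name, gamma=gamma, u=u.copy(),
        iterations=info.get("iterations", 0),
        residual=info.get("residual", np.nan),
        max_initiation=info.get("max_initiation", np.nan),
        max_failure=info.get("max_failure", 0.0),
        external_work=energy_acc["external_work"],
        strain_energy=info.get("strain_energy", np.nan),
        cohesive_dissipation=energy_acc["dissipation"],
        stabilization_energy=0.0,
    )


def solve_quasi_static(model: FEModel, record_every: int = 1):
    """Run all load stages; returns (Trajectory, final u, surface, event).

    The event is ``None`` unless a failure-watching stage detects complete
    damage of a cohesive element before its ramp ends.
    """
    asm = Assembler(model)
    surface = asm.make_surface() if model.interface is not None else None
    u = np.zeros(asm.ndof)
    traj = Trajectory()
    energy_acc = {"external_work": 0.0, "dissipation": 0.0}
    event = None

    for stage in model.stages:
        c = model.controls
        gamma = 0.0
        dg = c.dgamma0
        u_safe = u.copy()
        surf_safe = surface.copy() if surface is not None else None
        steps = 0
        # continuous force state at stage entry, for the work integrals
        R0, _, _, d0 = asm.assemble(u_safe, stage, 0.0, surf_safe,
                                    need_tangent=False)
        fext_prev = d0["fext_vec"]
        Rc_prev = R0[stage.dirichlet_dofs] if stage.dirichlet_dofs.size \
            else np.zeros(0)
        u_old, g_old = None, None
        while gamma < 1.0 - 1e-12 and steps < c.max_steps:
            steps += 1
            g_try = min(gamma + dg, 1.0)
            if surf_safe is not None:
                surf_safe.viscosity = c.stabilization
                surf_safe.pseudo_dt = g_try - gamma
            # linear extrapolation predictor from the last two states
            u0 = u_safe
            if u_old is not None and gamma > g_old:
                w = (g_try - gamma) / (gamma - g_old)
                u0 = u_safe + min(w, 2.0) * (u_safe - u_old)
            u_new, ok, info = newton_solve(asm, stage, g_try, u0,
                                           surf_safe, c)
            if ok and surface is not None:
                fail_mask = _new_failures(surf_safe, info["seps"])
                if stage.watch_failure and np.any(fail_mask):
                    event, gamma_ev, u, surface = _bisect_failure(
                        asm, stage, model, gamma, g_try, u_safe, surf_safe, c)
                    traj.records.append(_record(asm, stage, gamma_ev, u,
                                                {"max_failure": 1.0},
                                                energy_acc))
                    return traj, u, surface, event
            if ok:
                # accept: commit history, account energy increments
                # (follower pressures plus support-reaction work)
                fext_new = info["fext_vec"]
                du = u_new - u_safe
                energy_acc["external_work"] += float(
                    0.5 * (fext_prev + fext_new) @ du)
                if stage.dirichlet_dofs.size:
                    Rc_new = info["R"][stage.dirichlet_dofs]
                    energy_acc["external_work"] += float(
                        0.5 * (Rc_prev + Rc_new) @ du[stage.dirichlet_dofs])
                    Rc_prev = Rc_new
                fext_prev = fext_new
                if surface is not None:
                    surf_safe.commit(info["seps"])
                    energy_acc["dissipation"] = asm.dissipation(surf_safe)
                u_old, g_old = u_safe, gamma
                u_safe = u_new
                gamma = g_try
                if record_every and (steps % record_every == 0
                                     or gamma >= 1.0 - 1e-12):
                    traj.records.append(
                        _record(asm, stage, gamma, u_new, info, energy_acc))
                if info["iterations"] <= c.max_iter // 2:
                    dg = min(dg * c.grow, c.dgamma_max)
                if c.verbose:
                    print(f"  [{stage.name}] gamma={gamma:.4f} "
                          f"iters={info['iterations']}")
            else:
                dg *= 0.5
                if c.verbose:
                    print(f"  [{stage.name}] cut step to dg={dg:.2e}")
                if dg < c.dgamma_min:
                    if (stage.watch_failure and surf_safe is not None
                            and float(np.max(surf_safe.failure_values(),
                                             initial=0.0)) >= 0.5):
                        # static equilibrium lost while the interface is
                        # deep in softening: the tear starts to run here
                        event = _event_from_state(model, asm, stage, gamma,
                                                  surf_safe)
                        traj.records.append(_record(
                            asm, stage, gamma, u_safe,
                            {"max_failure": 1.0}, energy_acc))
                        return traj, u_safe, surf_safe, event
                    traj.completed = False
                    traj.message = (f"stage '{stage.name}' stalled at "
                                    f"gamma={gamma:.4f}")
                    return traj, u_safe, surf_safe, event
        u = u_safe
        surface = surf_safe
    return traj, u, surface, event


def _event_from_state(model, asm, stage, gamma, surface):
    """Critical event from the most damaged element of a converged state."""
    g = surface.failure_values()
    pt = int(np.argmax(np.where(surface.torn, -np.inf, g)))
    ngp = asm.iface_ngp
    e0 = pt // ngp
    labels = getattr(model.interface, "labels", None)
    GI, GII, GIII = surface.GI[pt], surface.GII[pt], surface.GIII[pt]
    GT = GI + GII + GIII
    return CriticalEvent(
        Pc=float(stage.pressures[0][1](gamma)) if stage.pressures else np.nan,
        gamma=gamma,
        element=e0,
        elements=[e0],
        direction=(labels[e0] if labels is not None else "n/a"),
        mode_mix=float(1.0 - GI / GT) if GT > 0 else float("nan"),
        Tn=float(surface.Tn[pt]), Ts=float(surface.Ts[pt]),
        Tt=float(surface.Tt[pt]),
    )


def _bisect_failure(asm, stage, model, g_lo, g_hi, u_safe, surf_safe, c):
    """Refine the failure load factor between a safe and a failing gamma."""
    res = max(stage.gamma_resolution, 1e-6)
    u_lo = u_safe.copy()
    s_lo = surf_safe.copy()
    while g_hi - g_lo > res:
        g_mid = 0.5 * (g_lo + g_hi)
        s_lo.viscosity = c.stabilization
        s_lo.pseudo_dt = g_mid - g_lo
        u_new, ok, info = newton_solve(asm, stage, g_mid, u_lo, s_lo, c)
        if ok and not np.any(_new_failures(s_lo, info["seps"])):
            s_lo.commit(info["seps"])
            u_lo = u_new
            g_lo = g_mid
        else:
            g_hi = g_mid
    # pre-failure tractions/state of the critical element from the safe state
    u_new, ok, info = newton_solve(asm, stage, g_hi, u_lo, s_lo, c)
    if ok and info["seps"] is not None:
        fail_mask = _new_failures(s_lo, info["seps"])
        trial = s_lo.trial_state(info["seps"])
    else:
        # criticality coincides with loss of convergence: use the safe state
        u_new = u_lo
        trial = {k: getattr(s_lo, k) for k in
                 ("d", "GI", "GII", "GIII", "Tn", "Ts", "Tt")}
        trial["g"] = s_lo.failure_values()
        fail_mask = trial["g"] >= 1.0 - 1e-9
        if not np.any(fail_mask):
            fail_mask = trial["g"] == trial["g"].max()
    pts = np.flatnonzero(fail_mask)
    ngp = asm.iface_ngp
    elems = np.unique(pts // ngp)
    labels = getattr(model.interface, "labels", None)

    def sort_key(e):
        lab = labels[e] if labels is not None else "n/a"
        return (lab, e)

    elems = sorted(elems.tolist(), key=sort_key)
    e0 = elems[0]
    pt = pts[pts // ngp == e0][0]
    GI, GII, GIII = trial["GI"][pt], trial["GII"][pt], trial["GIII"][pt]
    GT = GI + GII + GIII
    m = float(1.0 - GI / GT) if GT > 0 else float("nan")
    event = CriticalEvent(
        Pc=float(stage.pressures[0][1](g_hi)) if stage.pressures else np.nan,
        gamma=g_hi,
        element=int(e0),
        elements=[int(e) for e in elems],
        direction=(labels[e0] if labels is not None else "n/a"),
        mode_mix=m,
        Tn=float(s_lo.Tn[pt]), Ts=float(s_lo.Ts[pt]), Tt=float(s_lo.Tt[pt]),
    )
    return event, g_hi, u_new, s_lo


def detect_critical_event(model: FEModel):
    """Convenience wrapper: solve the model and return the critical event."""
    _, _, _, event = solve_quasi_static(model)
    return event
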