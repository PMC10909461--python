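"""Bilinear mixed-mode cohesive traction--separation law.

Models the bonding between medial lamellae as a zero-thickness interface
with one opening mode (I, normal) and two sliding modes (II, III).  Each
pure mode is bilinear: traction rises linearly with stiffness K_i to the
initiation traction T_iC (at separation S0_i = T_iC/K_i) and then softens
linearly to zero at S_t,i = 2 G_iC / T_iC, so the enclosed area is the
critical fracture energy G_iC.

Damage initiation under mixed loading follows the quadratic nominal stress
criterion

    f = <Tn>^2/TnC^2 + Ts^2/TsC^2 + Tt^2/TtC^2  (initiation when f >= 1),

with the Macaulay bracket <Tn> excluding compression.  Final failure follows
the power-law energy criterion

    g = (G_I/G_IC)^a + (G_II/G_IIC)^a + (G_III/G_IIIC)^a  (failure at g >= 1),

where the per-mode dissipated energies G_i are integrated incrementally
along the loading path.  The softening branch evolves a single scalar
damage d on the effective separation

    delta = sqrt(<dn>^2 + ds^2 + dt^2),

with the final effective separation chosen so that, on a proportional path,
complete softening (d = 1) meets the power-law energy criterion exactly;
in the pure modes this reduces to the bilinear triangles above.  Unloading
is secant (through the origin) and damage is irreversible.

Normal compression (dn < 0) never damages the interface and produces no
cohesive traction; penetration is resisted by the frictionless contact of
the finite-element layer.

Units: separations mm, tractions kPa, energies mN/mm (= N/m),
stiffnesses mN/mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CohesiveParams",
    "CohesiveState",
    "TractionResult",
    "traction_update",
    "initiation_criterion",
    "failure_criterion",
    "mode_mix_ratio",
    "CohesiveSurface",
]

_TINY = 1e-14


@dataclass(frozen=True)
class CohesiveParams:
    """Constants of the bilinear mixed-mode interface law.

    TnC, TsC, TtC    : initiation tractions, kPa
    GIC, GIIC, GIIIC : critical fracture energies, mN/mm
    Kn, Ks, Kt       : initial stiffnesses, mN/mm^3
    alpha            : power-law exponent of the energy failure criterion
    """

    TnC: float
    TsC: float
    TtC: float
    GIC: float
    GIIC: float
    GIIIC: float
    Kn: float
    Ks: float
    Kt: float
    alpha: float = 1.0

    def __post_init__(self):
        for name in ("TnC", "TsC", "TtC", "GIC", "GIIC", "GIIIC",
                     "Kn", "Ks", "Kt", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for S0, St, lab in zip(self.S0, self.St, "n s t".split()):
            if St <= S0:
                raise ValueError(
                    f"mode-{lab} final separation {St} must exceed the "
                    f"initiation separation {S0}; increase G or reduce T/K")

    @property
    def TC(self) -> np.ndarray:
        return np.array([self.TnC, self.TsC, self.TtC])

    @property
    def GC(self) -> np.ndarray:
        return np.array([self.GIC, self.GIIC, self.GIIIC])

    @property
    def K(self) -> np.ndarray:
        return np.array([self.Kn, self.Ks, self.Kt])

    @property
    def S0(self) -> np.ndarray:
        """Pure-mode initiation separations T_C/K, mm."""
        return self.TC / self.K

    @property
    def St(self) -> np.ndarray:
        """Pure-mode complete-failure separations 2 G_C/T_C, mm."""
        return 2.0 * self.GC / self.TC


@dataclass
class TractionResult:
    """Nominal tractions and the two criterion values at one interface point."""

    Tn: float
    Ts: float
    Tt: float
    initiation_value: float
    failure_value: float


@dataclass
class CohesiveState:
    """History of one cohesive integration point.

    Separations in mm (dn signed, tension positive), scalar damage d,
    per-mode dissipated energies G_I/G_II/G_III in mN/mm, the largest
    effective separation reached, and the effective separations at damage
    initiation (delta0) and at complete softening (deltaf).
    """

    dn: float = 0.0
    ds: float = 0.0
    dt: float = 0.0
    d: float = 0.0
    GI: float = 0.0
    GII: float = 0.0
    GIII: float = 0.0
    history: float = 0.0
    delta0: float = np.nan
    deltaf: float = np.nan
    failed: bool = False

    @property
    def GT(self) -> float:
        return self.GI + self.GII + self.GIII


def initiation_criterion(T: TractionResult | np.ndarray, p: CohesiveParams) -> float:
    """Quadratic stress criterion value f; damage initiates when f >= 1.

    Compressive normal traction is excluded by the Macaulay bracket.
    """
    if isinstance(T, TractionResult):
        tn, ts, tt = T.Tn, T.Ts, T.Tt
    else:
        tn, ts, tt = np.asarray(T, dtype=float)
    tn = max(tn, 0.0)
    return float((tn / p.TnC) ** 2 + (ts / p.TsC) ** 2 + (tt / p.TtC) ** 2)


def failure_criterion(state: CohesiveState, p: CohesiveParams) -> float:
    """Power-law energy criterion value g; the point fails when g >= 1."""
    G = np.array([state.GI, state.GII, state.GIII])
    if np.any(G < 0):
        raise ValueError("dissipated energies must be non-negative")
    return float(np.sum((G / p.GC) ** p.alpha))


def mode_mix_ratio(GI: float, GII: float, GIII: float) -> float:
    """Mode mix ratio m = 1 - G_I/G_T: 0 pure opening, 1 pure sliding.

    Returns NaN when no energy has been dissipated (G_T = 0).
    """
    GT = GI + GII + GIII
    if GT <= 0:
        return float("nan")
    return 1.0 - GI / GT


class CohesiveSurface:
    """Vectorized cohesive law over ``n`` interface integration points.

    Holds the committed history arrays and evaluates trial tractions and
    algorithmic tangents for arbitrary separation arrays without mutating
    the history; :meth:`commit` accepts a converged increment.
    """

    _FIELDS = ("d", "GI", "GII", "GIII", "history", "delta0", "deltaf",
               "dn", "ds", "dt", "Tn", "Ts", "Tt")

    def __init__(self, n: int, params: CohesiveParams,
                 torn: np.ndarray | None = None):
        self.n = n
        self.params = params
        #: viscous regularization: pseudo-time constant (same unit as dt);
        #: 0 disables.  The solver sets dt to the current load increment.
        self.viscosity = 0.0
        self.pseudo_dt = 0.0
        #: cumulative estimate of the energy delayed by regularization
        self.stabilization_energy = 0.0
        self.d = np.zeros(n)
        self.GI = np.zeros(n)
        self.GII = np.zeros(n)
        self.GIII = np.zeros(n)
        self.history = np.zeros(n)
        self.delta0 = np.full(n, np.nan)
        self.deltaf = np.full(n, np.nan)
        self.dn = np.zeros(n)
        self.ds = np.zeros(n)
        self.dt = np.zeros(n)
        self.Tn = np.zeros(n)
        self.Ts = np.zeros(n)
        self.Tt = np.zeros(n)
        #: points inside a pre-existing tear: no cohesive stiffness at all
        self.torn = np.zeros(n, dtype=bool) if torn is None else torn.copy()
        if torn is not None:
            self.d[self.torn] = 1.0

    # -- core update ----------------------------------------------------
    def _evaluate(self, seps: np.ndarray):
        """Trial evaluation from the committed state.

        Parameters
        ----------
        seps : (n, 3) separations [dn, ds, dt], mm.

        Returns
        -------
        T : (n, 3) tractions, kPa
        dT : (n, 3, 3) algorithmic tangent dT/dsep, mN/mm^3
        new : dict of trial history arrays (for :meth:`commit`)
        """
        p = self.params
        if not np.all(np.isfinite(seps)):
            raise ValueError("non-finite interface separations")
        dn = seps[:, 0]
        ds = seps[:, 1]
        dt = seps[:, 2]
        dnp = np.maximum(dn, 0.0)
        K = p.K
        delta = np.sqrt(dnp ** 2 + ds ** 2 + dt ** 2)

        d_new = self.d.copy()
        delta0 = self.delta0.copy()
        deltaf = self.deltaf.copy()

        # -- initiation check on intact points
        intact = np.isnan(delta0) & ~self.torn
        if np.any(intact):
            f_tr = ((K[0] * dnp[intact] / p.TnC) ** 2
                    + (K[1] * ds[intact] / p.TsC) ** 2
                    + (K[2] * dt[intact] / p.TtC) ** 2)
            just = f_tr >= 1.0
            idx = np.flatnonzero(intact)[just]
            if idx.size:
                # pre-initiation response is linear in the separations, so
                # the criterion surface is crossed at scale 1/sqrt(f)
                scale = 1.0 / np.sqrt(f_tr[just])
                delta0[idx] = delta[idx] * scale

        # -- softening: evolve damage on the effective separation
        active = ~np.isnan(delta0) & ~self.torn
        if np.any(active):
            ia = np.flatnonzero(active)
            dl = np.maximum(delta[ia], _TINY)
            # mode-mix weights of the current separation vector
            b = np.stack([dnp[ia], ds[ia], dt[ia]], axis=1)
            bn = np.linalg.norm(b, axis=1, keepdims=True)
            beta2 = (b / np.maximum(bn, _TINY)) ** 2
            # final effective separation from the power-law energy criterion
            # on a proportional path: G_i(fail) = 1/2 K_i beta_i^2 d0 df
            gi = 0.5 * K[None, :] * beta2 * delta0[ia, None]
            with np.errstate(divide="ignore"):
                df_new = np.sum((gi / p.GC[None, :]) ** p.alpha,
                                axis=1) ** (-1.0 / p.alpha)
            df_new = np.where(np.isfinite(df_new), df_new, np.nan)
            df_new = np.maximum(df_new, delta0[ia] * (1.0 + 1e-9))
            grow = dl > np.maximum(self.history[ia], delta0[ia])
            deltaf[ia] = np.where(grow | np.isnan(deltaf[ia]), df_new, deltaf[ia])
            dfv = deltaf[ia]
            d_cand = dfv * (dl - delta0[ia]) / (dl * (dfv - delta0[ia]))
            d_new[ia] = np.clip(np.maximum(self.d[ia], d_cand), 0.0, 1.0)

        # viscous regularization of the damage rate (pseudo-time):
        # d advances only a fraction dt/(mu+dt) of the way to its target,
        # smoothing snap-through during softening; mu = 0 recovers the
        # rate-independent law exactly
        if self.viscosity > 0.0 and self.pseudo_dt > 0.0:
            lam = self.pseudo_dt / (self.viscosity + self.pseudo_dt)
            d_new = self.d + lam * (d_new - self.d)

        # -- energy bookkeeping: work minus recoverable elastic energy
        stiff = np.where(self.torn | (d_new >= 1.0), 0.0, 1.0 - d_new)
        Tn = stiff * K[0] * dnp
        Ts = stiff * K[1] * ds
        Tt = stiff * K[2] * dt
        T_old = np.stack([self.Tn, self.Ts, self.Tt], axis=1)
        s_old = np.stack([np.maximum(self.dn, 0.0), self.ds, self.dt], axis=1)
        T_new = np.stack([Tn, Ts, Tt], axis=1)
        s_new = np.stack([dnp, ds, dt], axis=1)
        work = 0.5 * (T_old + T_new) * (s_new - s_old)
        elast = 0.5 * (T_new * s_new - T_old * s_old)
        dG = np.maximum(work - elast, 0.0)
        GI = self.GI + dG[:, 0]
        GII = self.GII + dG[:, 1]
        GIII = self.GIII + dG[:, 2]
        g = ((GI / p.GIC) ** p.alpha + (GII / p.GIIC) ** p.alpha
             + (GIII / p.GIIIC) ** p.alpha)
        newly_failed = (g >= 1.0 - 1e-9) | (d_new >= 1.0 - 1e-12)
        d_new = np.where(newly_failed, 1.0, d_new)
        zero = self.torn | newly_failed
        Tn = np.where(zero, 0.0, Tn)
        Ts = np.where(zero, 0.0, Ts)
        Tt = np.where(zero, 0.0, Tt)

        dT = self._tangent(dn, ds, dt, dnp, delta, d_new, delta0, deltaf, zero)

        new = dict(d=d_new, GI=GI, GII=GII, GIII=GIII,
                   history=np.maximum(self.history, delta),
                   delta0=delta0, deltaf=deltaf,
                   dn=dn.copy(), ds=ds.copy(), dt=dt.copy(),
                   Tn=Tn, Ts=Ts, Tt=Tt, g=g)
        return np.stack([Tn, Ts, Tt], axis=1), dT, new

    def _tangent(self, dn, ds, dt, dnp, delta, d, delta0, deltaf, zero):
        """Algorithmic tangent dT/dsep (n,3,3)."""
        p = self.params
        K = p.K
        n = dn.size
        dT = np.zeros((n, 3, 3))
        stiff = np.where(zero, 0.0, 1.0 - d)
        # secant part; normal stiffness only in tension
        tens = (dn > 0.0).astype(float)
        dT[:, 0, 0] = stiff * K[0] * tens
        dT[:, 1, 1] = stiff * K[1]
        dT[:, 2, 2] = stiff * K[2]
        # softening part while damage is actively growing
        growing = (~np.isnan(delta0)) & (delta >= np.maximum(self.history, delta0)) \
            & (d < 1.0) & ~zero & (delta > _TINY)
        ig = np.flatnonzero(growing)
        if ig.size:
            dl = delta[ig]
            df = deltaf[ig]
            d0 = delta0[ig]
            dd_ddelta = df * d0 / (dl ** 2 * (df - d0))
            s = np.stack([dnp[ig], ds[ig], dt[ig]], axis=1)
            Ksep = K[None, :] * s          # K_i d_i
            ddelta_ds = s / dl[:, None]
            dT[ig] -= np.einsum("p,pi,pj->pij", dd_ddelta, Ksep, ddelta_ds)
        return dT

    # -- public API ------------------------------------------------------
    def trial(self, seps: np.ndarray):
        T, dT, _ = self._evaluate(seps)
        return T, dT

    def trial_state(self, seps: np.ndarray) -> dict:
        """Trial history arrays (incl. failure criterion 'g') without commit."""
        _, _, new = self._evaluate(seps)
        return new

    def commit(self, seps: np.ndarray) -> None:
        if self.viscosity > 0.0 and self.pseudo_dt > 0.0:
            # rate-independent target state at the same separations: used
            # for the stabilization-energy diagnostic and for reporting
            # tractions free of the viscous lag
            visc, self.viscosity = self.viscosity, 0.0
            _, _, target = self._evaluate(seps)
            self.viscosity = visc
            _, _, new = self._evaluate(seps)
            K = self.params.K
            s2 = (np.maximum(new["dn"], 0.0) ** 2 * K[0]
                  + new["ds"] ** 2 * K[1] + new["dt"] ** 2 * K[2])
            self.stab_defect = 0.5 * (target["d"] - new["d"]) * s2
            self.Tn_target = target["Tn"]
            self.Ts_target = target["Ts"]
            self.Tt_target = target["Tt"]
        else:
            _, _, new = self._evaluate(seps)
            self.stab_defect = np.zeros(self.n)
            self.Tn_target = new["Tn"]
            self.Ts_target = new["Ts"]
            self.Tt_target = new["Tt"]
        for k in self._FIELDS:
            setattr(self, k, new[k])

    def failure_values(self) -> np.ndarray:
        p = self.params
        return ((self.GI / p.GIC) ** p.alpha + (self.GII / p.GIIC) ** p.alpha
                + (self.GIII / p.GIIIC) ** p.alpha)

    @property
    def failed(self) -> np.ndarray:
        return (self.failure_values() >= 1.0 - 1e-9) | (self.d >= 1.0 - 1e-12)

    def mode_mix(self) -> np.ndarray:
        GT = self.GI + self.GII + self.GIII
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(GT > 0, 1.0 - self.GI / np.maximum(GT, _TINY), np.nan)

    def copy(self) -> "CohesiveSurface":
        out = CohesiveSurface(self.n, self.params, torn=self.torn)
        for k in self._FIELDS:
            setattr(out, k, getattr(self, k).copy())
        out.viscosity = self.viscosity
        out.pseudo_dt = self.pseudo_dt
        out.stabilization_energy = self.stabilization_energy
        return out


def traction_update(state: CohesiveState, new_separations, p: CohesiveParams):
    """Advance one cohesive point to the given separations.

    Returns the updated state and the tractions together with the values of
    the stress-initiation and energy-failure criteria.  Damage and
    dissipated energies never decrease; unloading retraces the secant
    through the origin.
    """
    surf = CohesiveSurface(1, p)
    for k in ("d", "GI", "GII", "GIII", "history", "delta0", "deltaf",
              "dn", "ds", "dt"):
        getattr(surf, k)[0] = getattr(state, k) if k not in ("dn", "ds", "dt") \
            else getattr(state, k)
    # committed tractions consistent with the committed separations
    stiff = 0.0 if state.failed else (1.0 - state.d)
    surf.Tn[0] = stiff * p.Kn * max(state.dn, 0.0)
    surf.Ts[0] = stiff * p.Ks * state.ds
    surf.Tt[0] = stiff * p.Kt * state.dt
    seps = np.asarray(new_separations, dtype=float).reshape(1, 3)
    T, _, new = surf._evaluate(seps)
    out = CohesiveState(
        dn=float(seps[0, 0]), ds=float(seps[0, 1]), dt=float(seps[0, 2]),
        d=float(new["d"][0]), GI=float(new["GI"][0]), GII=float(new["GII"][0]),
        GIII=float(new["GIII"][0]), history=float(new["history"][0]),
        delta0=float(new["delta0"][0]), deltaf=float(new["deltaf"][0]),
        failed=bool(new["g"][0] >= 1.0 - 1e-9 or new["d"][0] >= 1.0 - 1e-12),
    )
    res = TractionResult(
        Tn=float(T[0, 0]), Ts=float(T[0, 1]), Tt=float(T[0, 2]),
        initiation_value=initiation_criterion(T[0], p),
        failure_value=float(new["g"][0]),
    )
    return out, res
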