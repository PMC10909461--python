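"""Fibre-reinforced nearly incompressible hyperelasticity for the aortic wall.

Implements the Holzapfel--Gasser--Ogden (HGO) strain energy with two
dispersed collagen fibre families,

    W = C10 (I1b - 3) + (1/D) ((J^2 - 1)/2 - ln J)
        + k1/(2 k2) * sum_i [exp(k2 eps_i^2) - 1],

    eps_i = kappa (I1b - 3) + (1 - 3 kappa) (I4b_or_I6b - 1),

where I1b, I4b, I6b are isochoric invariants of Cb = J^(-2/3) F^T F and the
fibre directions are M = (cos t, sin t, 0), N = (cos t, -sin t, 0) in the
local (circumferential, axial, radial) frame, t being the mean fibre angle
from the circumferential direction.  A fibre family contributes only while
its strain-like quantity eps_i is tensile (eps_i > 0); compressed fibres
carry no load.

All stress/tangent routines are batched: ``F`` may carry arbitrary leading
dimensions ``(..., 3, 3)``.  Units: stress kPa, energy density kPa
(= mJ/mm^3 * 10^-3 scale consistent with mm/mN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaterialParams",
    "KinematicState",
    "fiber_directions",
    "compute_kinematics",
    "strain_energy_density",
    "cauchy_stress",
    "material_tangent",
    "pk2_stress_and_tangent",
    "first_piola",
]

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Raised for a non-positive Jacobian det F <= 0."""


@dataclass(frozen=True)
class MaterialParams:
    """HGO constants for one wall layer.

    C10       : ground-matrix (neo-Hookean) constant, kPa
    k1        : fibre stiffness, kPa
    k2        : dimensionless fibre exponent (> 0)
    kappa     : in-plane fibre dispersion, in [0, 1/3]
    theta_deg : mean fibre angle from the circumferential direction, degrees
    D         : volumetric compliance, 1/kPa (small => nearly incompressible)
    """

    C10: float
    k1: float
    k2: float
    kappa: float
    theta_deg: float
    D: float

    def __post_init__(self):
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if not 0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12:
            raise ValueError("kappa must lie in [0, 1/3]")
        if self.D <= 0:
            raise ValueError("D must be positive")

    @property
    def bulk_modulus(self) -> float:
        """Small-strain bulk modulus 2/D, kPa."""
        return 2.0 / self.D


@dataclass
class KinematicState:
    """Kinematic quantities derived from a deformation gradient."""

    F: np.ndarray
    J: np.ndarray
    Cbar: np.ndarray
    I1bar: np.ndarray
    I4bar: np.ndarray
    I6bar: np.ndarray
    M: np.ndarray
    N: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray


def fiber_directions(theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit fibre direction vectors at +/- theta from circumferential."""
    th = np.deg2rad(theta_deg)
    M = np.array([np.cos(th), np.sin(th), 0.0])
    N = np.array([np.cos(th), -np.sin(th), 0.0])
    return M, N


def compute_kinematics(F: np.ndarray, theta_deg: float, kappa: float = 0.0) -> KinematicState:
    """Volume ratio, isochoric Cauchy--Green tensor and invariants of ``F``.

    ``kappa`` enters only through the fibre strain-like quantities eps1/eps2;
    the invariants themselves are dispersion-free.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvalidDeformationError("det F must be positive")
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cbar = J[..., None, None] ** (-2.0 / 3.0) * C
    M, N = fiber_directions(theta_deg)
    I1bar = np.trace(Cbar, axis1=-2, axis2=-1)
    I4bar = np.einsum("...ij,i,j->...", Cbar, M, M)
    I6bar = np.einsum("...ij,i,j->...", Cbar, N, N)
    eps1 = kappa * (I1bar - 3.0) + (1.0 - 3.0 * kappa) * (I4bar - 1.0)
    eps2 = kappa * (I1bar - 3.0) + (1.0 - 3.0 * kappa) * (I6bar - 1.0)
    return KinematicState(F=F, J=J, Cbar=Cbar, I1bar=I1bar, I4bar=I4bar,
                          I6bar=I6bar, M=M, N=N, eps1=eps1, eps2=eps2)


def _eps(state: KinematicState, p: MaterialParams):
    """Fibre strain-like quantities evaluated with the material's kappa."""
    e1 = p.kappa * (state.I1bar - 3.0) + (1.0 - 3.0 * p.kappa) * (state.I4bar - 1.0)
    e2 = p.kappa * (state.I1bar - 3.0) + (1.0 - 3.0 * p.kappa) * (state.I6bar - 1.0)
    return e1, e2


def strain_energy_density(state: KinematicState, p: MaterialParams) -> np.ndarray:
    """Strain energy per unit reference volume, kPa."""
    J = state.J
    e1, e2 = _eps(state, p)
    Wvol = (1.0 / p.D) * ((J ** 2 - 1.0) / 2.0 - np.log(J))
    Wiso = p.C10 * (state.I1bar - 3.0)
    with np.errstate(over="ignore", invalid="ignore"):
        for e in (e1, e2):
            active = e > 0.0
            expo = np.exp(p.k2 * np.where(active, e, 0.0) ** 2)
            Wiso = Wiso + np.where(active,
                                   p.k1 / (2.0 * p.k2) * (expo - 1.0), 0.0)
    W = Wvol + Wiso
    if not np.all(np.isfinite(W)):
        raise FloatingPointError("non-finite strain energy (overflow in fibre term)")
    return W


def _invariant_derivs(state: KinematicState, p: MaterialParams):
    """First/second partials of the isochoric energy w.r.t. (I1b, I4b, I6b)."""
    e1, e2 = _eps(state, p)
    k, q = p.kappa, 1.0 - 3.0 * p.kappa
    h = []
    f = []
    with np.errstate(over="ignore", invalid="ignore"):
        for e in (e1, e2):
            active = e > 0.0
            ee = np.where(active, e, 0.0)
            expo = np.exp(p.k2 * ee ** 2)
            h.append(np.where(active, p.k1 * ee * expo, 0.0))
            f.append(np.where(active,
                              p.k1 * expo * (1.0 + 2.0 * p.k2 * ee ** 2), 0.0))
    psi1 = p.C10 + (h[0] + h[1]) * k
    psi4 = h[0] * q
    psi6 = h[1] * q
    # second partials
    psi11 = (f[0] + f[1]) * k * k
    psi44 = f[0] * q * q
    psi66 = f[1] * q * q
    psi14 = f[0] * k * q
    psi16 = f[1] * k * q
    return (psi1, psi4, psi6), (psi11, psi44, psi66, psi14, psi16)


def _struct_tensors(state: KinematicState):
    MM = np.multiply.outer(state.M, state.M)
    NN = np.multiply.outer(state.N, state.N)
    return MM, NN


def pk2_stress_and_tangent(F: np.ndarray, p: MaterialParams, *,
                           tangent: bool = True,
                           volumetric: bool = True,
                           isochoric: bool = True):
    """Second Piola--Kirchhoff stress S and material tangent CC = 2 dS/dC.

    The volumetric and isochoric contributions can be requested separately
    (used by the selective reduced integration of the bulk elements).
    Batched over leading dimensions of ``F``.
    """
    state = compute_kinematics(F, p.theta_deg, p.kappa)
    J = state.J
    C = np.einsum("...ki,...kj->...ij", F, F)
    Cinv = np.linalg.inv(C)
    S = np.zeros_like(C)
    CC = np.zeros(C.shape + (3, 3)) if tangent else None
    # extreme trial states may overflow the fibre exponential; the resulting
    # non-finite stress is rejected by the solver's step control
    errstate = np.errstate(over="ignore", invalid="ignore")
    errstate.__enter__()

    if volumetric:
        Up = (1.0 / p.D) * (J - 1.0 / J)
        Upp = (1.0 / p.D) * (1.0 + 1.0 / J ** 2)
        S = S + (J * Up)[..., None, None] * Cinv
        if tangent:
            coef1 = J * Up + J ** 2 * Upp
            CC = CC + coef1[..., None, None, None, None] * np.einsum(
                "...ij,...kl->...ijkl", Cinv, Cinv)
            CC = CC - (2.0 * J * Up)[..., None, None, None, None] * _sym_outer(Cinv)

    if isochoric:
        (psi1, psi4, psi6), (psi11, psi44, psi66, psi14, psi16) = \
            _invariant_derivs(state, p)
        MM, NN = _struct_tensors(state)
        Jm23 = J ** (-2.0 / 3.0)
        # fictitious PK2 in the isochoric space
        Stil = 2.0 * (psi1[..., None, None] * _I3
                      + psi4[..., None, None] * MM
                      + psi6[..., None, None] * NN)
        trSC = np.einsum("...ij,...ij->...", Stil, C)
        Siso = Jm23[..., None, None] * (
            Stil - (trSC / 3.0)[..., None, None] * Cinv)
        S = S + Siso
        if tangent:
            # fictitious tangent 4 * d2W/dCbar2, pushed with J^(-4/3)
            Jm43 = J ** (-4.0 / 3.0)
            G = {}
            pairs = [
                (psi11, _I3, _I3), (psi44, MM, MM), (psi66, NN, NN),
                (psi14, _I3, MM), (psi14, MM, _I3),
                (psi16, _I3, NN), (psi16, NN, _I3),
            ]
            Ctil = np.zeros(C.shape + (3, 3))
            for coef, A, B in pairs:
                Ctil += 4.0 * coef[..., None, None, None, None] * \
                    np.multiply.outer(A, B)
            Ctil *= Jm43[..., None, None, None, None]
            # projection P : Ctil : P^T
            PCtil = Ctil - (1.0 / 3.0) * np.einsum(
                "...ij,...klmn,...kl->...ijmn", Cinv, Ctil, C, optimize=True)
            PCP = PCtil - (1.0 / 3.0) * np.einsum(
                "...ijkl,...kl,...mn->...ijmn", PCtil, C, Cinv, optimize=True)
            trace_term = (2.0 / 3.0) * (Jm23 * trSC)
            Phat = _sym_outer(Cinv) - (1.0 / 3.0) * np.einsum(
                "...ij,...kl->...ijkl", Cinv, Cinv)
            CC = CC + PCP + trace_term[..., None, None, None, None] * Phat
            CC = CC - (2.0 / 3.0) * (
                np.einsum("...ij,...kl->...ijkl", Cinv, Siso)
                + np.einsum("...ij,...kl->...ijkl", Siso, Cinv))

    errstate.__exit__(None, None, None)
    return (S, CC) if tangent else (S, None)


def _sym_outer(A: np.ndarray) -> np.ndarray:
    """(A (.) A)_ijkl = 1/2 (A_ik A_jl + A_il A_jk)."""
    return 0.5 * (np.einsum("...ik,...jl->...ijkl", A, A)
                  + np.einsum("...il,...jk->...ijkl", A, A))


def first_piola(F: np.ndarray, p: MaterialParams) -> np.ndarray:
    """First Piola--Kirchhoff stress P = F S, kPa."""
    S, _ = pk2_stress_and_tangent(F, p, tangent=False)
    return np.einsum("...ik,...kj->...ij", F, S)


def cauchy_stress(state: KinematicState, p: MaterialParams) -> np.ndarray:
    """Cauchy stress sigma = J^-1 F S F^T, kPa (symmetric)."""
    S, _ = pk2_stress_and_tangent(state.F, p, tangent=False)
    F, J = state.F, state.J
    return np.einsum("...iI,...IJ,...jJ->...ij", F, S, F) / J[..., None, None]


def material_tangent(state: KinematicState, p: MaterialParams) -> np.ndarray:
    """Spatial elasticity tensor c_ijkl = J^-1 F_iI F_jJ F_kK F_lL CC_IJKL."""
    _, CC = pk2_stress_and_tangent(state.F, p)
    F, J = state.F, state.J
    return np.einsum("...iI,...jJ,...kK,...lL,...IJKL->...ijkl",
                     F, F, F, F, CC) / J[..., None, None, None, None]
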