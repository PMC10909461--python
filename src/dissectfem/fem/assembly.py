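"""Residual and tangent assembly for bulk, interface and pressure loads.

Bulk elements use a total Lagrangian formulation with selective reduced
integration (SRI): the isochoric part of the strain energy is integrated
with the full Gauss rule, the stiff volumetric part with a single centroid
point, which keeps the nearly incompressible response (D ~ 1e-6 1/kPa)
free of volumetric locking on bilinear/trilinear elements.

Interface elements are zero-thickness: tractions follow the cohesive law in
a local frame built on the deformed mid-surface, nominal per unit reference
area.  Interpenetration is resisted by a penalty contact pressure that
remains active on torn and fully damaged elements.

Pressure loads are follower loads on the deformed surface; their load
stiffness is assembled exactly (facet forces are polynomial in the nodal
coordinates).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..cohesive import CohesiveSurface
from ..hgo import compute_kinematics, pk2_stress_and_tangent, strain_energy_density
from .mesh import Mesh
from .model import FEModel
from .shapes import (
    bulk_quadrature,
    line2_quadrature,
    line2_shape,
    quad_facet_quadrature,
    shape_fn,
)

_EYE3 = np.eye(3)


def _grads(mesh: Mesh, pts: np.ndarray, w: np.ndarray):
    """Reference shape gradients and weighted Jacobians at the given rule."""
    fn = shape_fn(mesh.elem_type)
    dN_ref = np.stack([fn(p)[1] for p in pts])          # (g, nen, dim)
    Xe = mesh.nodes[mesh.elems]                          # (ne, nen, dim)
    J = np.einsum("eai,gaj->geij", Xe, dN_ref)           # dX/dxi, (g, ne, d, d)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        raise ValueError("non-positive Jacobian in reference mesh")
    Jinv = np.linalg.inv(J)
    dNdX = np.einsum("gaj,geji->geai", dN_ref, Jinv)     # (g, ne, nen, dim)
    wdetJ = w[:, None] * detJ                            # (g, ne)
    return np.ascontiguousarray(dNdX.transpose(1, 0, 2, 3)), wdetJ.T


class Assembler:
    """Precomputes quadrature data and assembles R(u), K(u) for a model."""

    def __init__(self, model: FEModel):
        self.model = model
        mesh = model.mesh
        self.dim = mesh.dim
        (pf, wf), (pv, wv) = bulk_quadrature(mesh.elem_type)
        self.dNdX_f, self.w_f = _grads(mesh, pf, wf)     # full rule
        self.dNdX_v, self.w_v = _grads(mesh, pv, wv)     # centroid rule
        self.ngp_f = pf.shape[0]
        nen = mesh.elems.shape[1]
        self.edofs = (mesh.elems[:, :, None] * self.dim
                      + np.arange(self.dim)).reshape(mesh.elems.shape[0], -1)
        self.mat_groups = [np.flatnonzero(mesh.mat_id == k)
                           for k in range(len(model.materials))]
        self._init_interface()
        self.ndof = mesh.n_dofs
        self.nen = nen

    # ------------------------------------------------------------------
    def _init_interface(self):
        iface = self.model.interface
        if iface is None:
            self.iface_ngp = 0
            return
        if self.dim == 2:
            pts, w = line2_quadrature()
            self.iface_N = np.stack([line2_shape(p) for p in pts])    # (g, 2)
            self.iface_w = w
            self.iface_ngp = len(w)
        else:
            pts, w = quad_facet_quadrature()
            from .shapes import quad4_shape
            self.iface_N = np.stack([quad4_shape(p)[0] for p in pts])  # (g, 4)
            self.iface_dN = np.stack([quad4_shape(p)[1] for p in pts])  # (g, 4, 2)
            self.iface_w = w
            self.iface_ngp = len(w)
        m = iface.m
        self.iface_bot = iface.pairs[:, :m]
        self.iface_top = iface.pairs[:, m:]
        # reference mid-surface geometry and per-gp reference area weights
        Xb = self.model.mesh.nodes[self.iface_bot]       # (ni, m, dim)
        Xt = self.model.mesh.nodes[self.iface_top]
        Xm = 0.5 * (Xb + Xt)
        self._iface_Xmid = Xm
        if self.dim == 2:
            tau = np.einsum("ga,iad->gid", _DLINE, Xm)
            self.iface_wda = (self.iface_w[:, None]
                              * np.linalg.norm(tau, axis=-1)).T      # (ni, g)
        else:
            g12 = np.einsum("gak,iad->gikd", self.iface_dN, Xm)      # (g,ni,2,d)
            n_raw = np.cross(g12[:, :, 0, :], g12[:, :, 1, :])
            self.iface_wda = (self.iface_w[:, None]
                              * np.linalg.norm(n_raw, axis=-1)).T
        self.iface_dofs = (self.model.interface.pairs[:, :, None] * self.dim
                           + np.arange(self.dim)).reshape(iface.n, -1)

    def make_surface(self) -> CohesiveSurface:
        """Fresh cohesive history, one point per interface Gauss point."""
        iface = self.model.interface
        torn = np.repeat(iface.torn, self.iface_ngp)
        return CohesiveSurface(iface.n * self.iface_ngp,
                               self.model.cohesive, torn=torn)

    # ------------------------------------------------------------------
    def _bulk(self, u: np.ndarray, need_tangent: bool):
        model, mesh, dim = self.model, self.model.mesh, self.dim
        ue = u.reshape(-1, dim)[mesh.elems]              # (ne, nen, dim)
        ne = mesh.elems.shape[0]
        f = np.zeros((ne, self.nen, dim))
        Kdata = np.zeros((ne, self.nen * dim, self.nen * dim)) if need_tangent else None
        energy = 0.0

        for dNdX, wq, iso in ((self.dNdX_f, self.w_f, True),
                              (self.dNdX_v, self.w_v, False)):
            ngp = dNdX.shape[1]
            F = np.tile(_EYE3, (ne, ngp, 1, 1))
            F[..., :dim, :dim] += np.einsum("eai,egaj->egij", ue, dNdX)
            if model.Gpre is not None:
                G = model.Gpre[:, None, :, :]
                Fe = np.einsum("egik,eokj->egij", F, G)
                Ghat = np.einsum("egai,eoij->egaj",
                                 _pad3(dNdX, dim), G)
            else:
                Fe = F
                Ghat = _pad3(dNdX, dim)
            if model.Qmat is not None:
                # constitutive evaluation in the local material frame
                Q = model.Qmat[:, None, :, :]
                Fc = np.einsum("egik,eokj->egij", Fe, Q)
            else:
                Fc = Fe
            S = np.zeros((ne, ngp, 3, 3))
            CC = np.zeros((ne, ngp, 3, 3, 3, 3)) if need_tangent else None
            for k, idx in enumerate(self.mat_groups):
                if idx.size == 0:
                    continue
                p = model.materials[k]
                Sg, CCg = pk2_stress_and_tangent(
                    Fc[idx], p, tangent=need_tangent,
                    volumetric=not iso, isochoric=iso)
                S[idx] = Sg
                if need_tangent:
                    CC[idx] = CCg
                st = compute_kinematics(Fc[idx], p.theta_deg, p.kappa)
                W = _energy_part(st, p, iso=iso)
                energy += float(np.sum(wq[idx] * W))
            if model.Qmat is not None:
                Q = model.Qmat[:, None, :, :]
                S = np.einsum("eoiI,egIJ,eojJ->egij", Q, S, Q)
                if need_tangent:
                    for ax in range(4):
                        CC = np.einsum("eoiI,egI...->egi...",
                                       Q, np.moveaxis(CC, 2 + ax, 2))
                        CC = np.moveaxis(CC, 2, 2 + ax)
            P = np.einsum("egik,egkj->egij", Fe, S)
            f += np.einsum("eg,egiA,egaA->eai",
                           wq, P, Ghat, optimize=True)[..., :dim]
            if need_tangent:
                # A_iAjB = delta_ij S_AB + Fe_iK CC_KAJB Fe_jL
                T1 = np.einsum("egik,egkAjB->egiAjB", Fe, CC, optimize=True)
                A = np.einsum("egiAlB,egjl->egiAjB", T1, Fe, optimize=True)
                A += np.einsum("ij,egAB->egiAjB", _EYE3, S, optimize=True)
                GA = np.einsum("egaA,egiAjB->egaijB", Ghat, A, optimize=True)
                Ke = np.einsum("eg,egaijB,egbB->eaibj",
                               wq, GA, Ghat, optimize=True)
                Ke = Ke[:, :, :dim, :, :dim]
                Kdata += Ke.reshape(ne, self.nen * dim, self.nen * dim)
        return f, Kdata, energy

    # ------------------------------------------------------------------
    def interface_kinematics(self, u: np.ndarray):
        """Local separations, frames and weights at interface Gauss points."""
        iface = self.model.interface
        ue = u.reshape(-1, self.dim)[iface.pairs]
        seps, R = _iface_kin(ue, self._iface_Xmid, self.iface_N,
                             self.iface_dN if self.dim == 3 else None,
                             iface, self.dim)
        return seps, R, self.iface_wda.reshape(-1)

    def _iface_residual(self, ue: np.ndarray, surface: CohesiveSurface):
        """Element forces of the interface from element displacements.

        ue : (ni, 2m, dim) nodal displacements (bottom nodes then top).
        Returns (f (ni, 2m, dim), seps (n, 3), Tloc (n, 3), Tcontact (n,)).
        """
        iface = self.model.interface
        dim, g = self.dim, self.iface_ngp
        ni, m = iface.n, iface.m
        seps, R = _iface_kin(ue, self._iface_Xmid, self.iface_N,
                             self.iface_dN if dim == 3 else None,
                             iface, dim)
        wda = self.iface_wda.reshape(ni * g)
        Tloc, _ = surface.trial(seps)
        # frictionless penalty contact on interpenetration (all elements);
        # the compressive stiffness blends from the cohesive stiffness of an
        # intact point to the full penalty of a torn/failed one, so the
        # normal response stays continuous at zero separation
        kpen = (self.model.controls.contact_penalty_factor
                * self.model.cohesive.Kn)
        Kn = self.model.cohesive.Kn
        dmg = np.where(surface.torn, 1.0, surface.d)
        # intact fraction: linear penalty with the cohesive stiffness, so the
        # normal response is C1 across zero separation; damaged fraction:
        # full penalty with a quadratic onset over the penetration tolerance
        # (C1 at grazing contact, no stiffness chatter on torn faces)
        eps = 1e-4
        gpen = np.maximum(-seps[:, 0], 0.0)
        smooth = np.where(gpen < eps, gpen ** 2 / (2.0 * eps),
                          gpen - eps / 2.0)
        Tc = -((1.0 - dmg) * Kn * gpen + dmg * kpen * smooth)
        Tloc = Tloc.copy()
        Tloc[:, 0] += Tc
        # rotate to global; only the first `dim` global components act
        tg = np.einsum("pkd,pk->pd", R[:, :, :dim], Tloc)   # (n, dim)
        w_t = (wda[:, None] * tg).reshape(ni, g, dim)
        fel = np.einsum("ga,igd->iad", self.iface_N, w_t)   # (ni, m, dim)
        f = np.concatenate([-fel, fel], axis=1)             # bottom, top
        return f, seps, Tloc, Tc

    def _interface(self, u: np.ndarray, surface: CohesiveSurface,
                   need_tangent: bool):
        iface = self.model.interface
        dim = self.dim
        ni, m = iface.n, iface.m
        ue = u.reshape(-1, dim)[iface.pairs]                # (ni, 2m, dim)
        f, seps, Tloc, Tc = self._iface_residual(ue, surface)
        K = None
        if need_tangent:
            # consistent algorithmic tangent by forward differences of the
            # element residual: includes frame rotation, damage growth and
            # the contact active set
            nd = 2 * m * dim
            K = np.empty((ni, nd, nd))
            h = 1e-7
            for a in range(2 * m):
                for d in range(dim):
                    up = ue.copy()
                    up[:, a, d] += h
                    fp, _, _, _ = self._iface_residual(up, surface)
                    K[:, :, a * dim + d] = ((fp - f) / h).reshape(ni, nd)
        p = self.model.cohesive
        finit = ((np.maximum(Tloc[:, 0] - Tc, 0.0) / p.TnC) ** 2
                 + (Tloc[:, 1] / p.TsC) ** 2 + (Tloc[:, 2] / p.TtC) ** 2)
        diag = {
            "max_failure": float(np.max(surface.failure_values(), initial=0.0)),
            "max_initiation": float(np.max(finit, initial=0.0)),
            "penetration": float(min(np.min(seps[:, 0], initial=0.0), 0.0)),
        }
        return f, K, seps, diag

    # ------------------------------------------------------------------
    def _pressure(self, u: np.ndarray, stage, gamma: float, need_tangent: bool):
        """Follower pressure forces and exact load stiffness."""
        dim = self.dim
        x = self.model.mesh.nodes + u.reshape(-1, dim)
        fext = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        for facets, pfun in stage.pressures:
            p = pfun(gamma)
            if p == 0.0 or facets.size == 0:
                continue
            if dim == 2:
                a, b = facets[:, 0], facets[:, 1]
                t = x[b] - x[a]                       # (nf, 2)
                nvec = np.stack([t[:, 1], -t[:, 0]], axis=1)  # outward
                fe = -0.5 * p * nvec
                np.add.at(fext, a * 2, fe[:, 0])
                np.add.at(fext, a * 2 + 1, fe[:, 1])
                np.add.at(fext, b * 2, fe[:, 0])
                np.add.at(fext, b * 2 + 1, fe[:, 1])
                if need_tangent:
                    rowsI, colsI, valsI = _pressure_K_2d(a, b, p)
                    rows.append(rowsI)
                    cols.append(colsI)
                    vals.append(valsI)
            else:
                xq = x[facets]                         # (nf, 4, 3)
                fe, Kf = _pressure_quad(xq, p, need_tangent)
                for a in range(4):
                    for d in range(3):
                        np.add.at(fext, facets[:, a] * 3 + d, fe[:, a, d])
                if need_tangent:
                    nf = facets.shape[0]
                    r = (facets[:, :, None, None, None] * 3
                         + np.arange(3)[None, None, :, None, None])
                    c = (facets[:, None, None, :, None] * 3
                         + np.arange(3)[None, None, None, None, :])
                    rows.append(np.broadcast_to(r, (nf, 4, 3, 4, 3)))
                    cols.append(np.broadcast_to(c, (nf, 4, 3, 4, 3)))
                    vals.append(Kf)
        Kext = None
        if need_tangent and rows:
            Kext = sp.coo_matrix(
                (np.concatenate([v.ravel() for v in vals]),
                 (np.concatenate([r.ravel() for r in rows]),
                  np.concatenate([c.ravel() for c in cols]))),
                shape=(self.ndof, self.ndof)).tocsr()
        return fext, Kext

    # ------------------------------------------------------------------
    def assemble(self, u: np.ndarray, stage, gamma: float,
                 surface: CohesiveSurface | None, need_tangent: bool = True):
        """Global residual R = f_int - f_ext and tangent dR/du."""
        fb, Kb, energy = self._bulk(u, need_tangent)
        R = np.zeros(self.ndof)
        np.add.at(R, self.edofs.ravel(),
                  fb.reshape(fb.shape[0], -1).ravel())
        blocks = []
        if need_tangent:
            er = np.repeat(self.edofs, self.edofs.shape[1], axis=1)
            ec = np.tile(self.edofs, (1, self.edofs.shape[1]))
            blocks.append((er.ravel(), ec.ravel(), Kb.ravel()))
        diag = {"strain_energy": energy, "max_failure": 0.0,
                "penetration": 0.0, "cohesive_dissipation": 0.0}
        seps = None
        if self.model.interface is not None and surface is not None:
            fi, Ki, seps, idg = self._interface(u, surface, need_tangent)
            np.add.at(R, self.iface_dofs.ravel(),
                      fi.reshape(fi.shape[0], -1).ravel())
            if need_tangent:
                ir = np.repeat(self.iface_dofs, self.iface_dofs.shape[1], axis=1)
                ic = np.tile(self.iface_dofs, (1, self.iface_dofs.shape[1]))
                blocks.append((ir.ravel(), ic.ravel(), Ki.ravel()))
            diag.update(idg)
        fext, Kext = self._pressure(u, stage, gamma, need_tangent)
        R -= fext
        K = None
        if need_tangent:
            rows = np.concatenate([b[0] for b in blocks])
            cols = np.concatenate([b[1] for b in blocks])
            vals = np.concatenate([b[2] for b in blocks])
            K = sp.coo_matrix((vals, (rows, cols)),
                              shape=(self.ndof, self.ndof)).tocsr()
            if Kext is not None:
                K = K - Kext
        diag["fext_norm"] = float(np.linalg.norm(fext))
        diag["fext_vec"] = fext
        return R, K, seps, diag

    def cauchy_stresses(self, u: np.ndarray) -> np.ndarray:
        """Cauchy stress at element centroids, global frame (ne, 3, 3)."""
        model, mesh, dim = self.model, self.model.mesh, self.dim
        ue = u.reshape(-1, dim)[mesh.elems]
        dNdX = self.dNdX_v
        ne = mesh.elems.shape[0]
        F = np.tile(_EYE3, (ne, 1, 1, 1))
        F[:, :, :dim, :dim] += np.einsum("eai,egaj->egij", ue, dNdX)
        if model.Gpre is not None:
            F = np.einsum("egik,ekj->egij", F, model.Gpre)
        if model.Qmat is not None:
            Fc = np.einsum("egik,ekj->egij", F, model.Qmat)
        else:
            Fc = F
        S = np.zeros((ne, 1, 3, 3))
        for k, idx in enumerate(self.mat_groups):
            if idx.size == 0:
                continue
            Sg, _ = pk2_stress_and_tangent(Fc[idx], model.materials[k],
                                           tangent=False)
            S[idx] = Sg
        if model.Qmat is not None:
            S = np.einsum("eiI,egIJ,ejJ->egij", model.Qmat, S, model.Qmat)
        J = np.linalg.det(F)
        sig = np.einsum("egiI,egIJ,egjJ->egij", F, S, F) / J[..., None, None]
        return sig[:, 0]

    def dissipation(self, surface: CohesiveSurface) -> float:
        """Total cohesive energy dissipated so far, mN·mm."""
        wda = self.iface_wda.reshape(-1)
        return float(np.sum(wda * (surface.GI + surface.GII + surface.GIII)))


# ----------------------------------------------------------------------
_DLINE = np.array([[-0.5, 0.5], [-0.5, 0.5]])  # d/dxi of line2 at both gps


def _iface_kin(ue: np.ndarray, Xmid: np.ndarray, N: np.ndarray,
               dN, iface, dim: int):
    """Separations and local frames of interface elements.

    ue   : (ni, 2m, dim) nodal displacements, bottom nodes then top
    Xmid : (ni, m, dim) reference mid-surface coordinates

    The local frame rows are [normal, mode-II axis, mode-III axis]; the
    normal points from the bottom to the top side of the interface.
    """
    ni = ue.shape[0]
    m = Xmid.shape[1]
    ub, ut = ue[:, :m], ue[:, m:]
    xm = Xmid + 0.5 * (ub + ut)
    du = ut - ub
    g = N.shape[0]
    delta = np.einsum("ga,iad->igd", N, du)               # (ni, g, dim)
    if dim == 2:
        tau = np.einsum("ga,iad->igd", _DLINE, xm)
        tau = tau / np.linalg.norm(tau, axis=-1, keepdims=True)
        nrm = np.stack([-tau[..., 1], tau[..., 0]], axis=-1)
        R = np.zeros((ni, g, 3, 3))
        R[..., 0, :2] = nrm
        if iface.tangent_mode == "s":
            R[..., 1, :2] = tau
            R[..., 2, 2] = 1.0
        else:                   # in-plane sliding acts as mode III
            R[..., 2, :2] = tau
            R[..., 1, 2] = 1.0
        dloc = np.einsum("igkd,igd->igk", R[..., :2], delta)
    else:
        g12 = np.einsum("gak,iad->igkd", dN, xm)
        nr = np.cross(g12[..., 0, :], g12[..., 1, :])
        nrm = nr / np.linalg.norm(nr, axis=-1, keepdims=True)
        sh = np.broadcast_to(iface.s_hint[:, None, :], nrm.shape)
        es = sh - np.einsum("igd,igd->ig", nrm, sh)[..., None] * nrm
        es = es / np.linalg.norm(es, axis=-1, keepdims=True)
        et = np.cross(nrm, es)
        R = np.stack([nrm, es, et], axis=-2)              # (ni, g, 3, 3)
        dloc = np.einsum("igkd,igd->igk", R, delta)
    return dloc.reshape(ni * g, 3), R.reshape(ni * g, 3, 3)


def _pad3(dNdX: np.ndarray, dim: int) -> np.ndarray:
    if dim == 3:
        return dNdX
    out = np.zeros(dNdX.shape[:-1] + (3,))
    out[..., :dim] = dNdX
    return out


def _energy_part(state, p, iso: bool) -> np.ndarray:
    """Isochoric or volumetric part of the strain energy density."""
    if iso:
        e1 = p.kappa * (state.I1bar - 3.0) + (1 - 3 * p.kappa) * (state.I4bar - 1.0)
        e2 = p.kappa * (state.I1bar - 3.0) + (1 - 3 * p.kappa) * (state.I6bar - 1.0)
        W = p.C10 * (state.I1bar - 3.0)
        with np.errstate(over="ignore", invalid="ignore"):
            for e in (e1, e2):
                act = e > 0
                W = W + np.where(
                    act, p.k1 / (2 * p.k2)
                    * (np.exp(p.k2 * np.where(act, e, 0.0) ** 2) - 1.0), 0.0)
        return W
    J = state.J
    return (1.0 / p.D) * ((J ** 2 - 1.0) / 2.0 - np.log(J))


def _pressure_K_2d(a: np.ndarray, b: np.ndarray, p: float):
    """Exact load stiffness of 2D edge pressure: f_n = -p/2 (t_y, -t_x)."""
    # f depends on t = x_b - x_a; df/dt = -p/2 [[0, 1], [-1, 0]]
    Z = -0.5 * p * np.array([[0.0, 1.0], [-1.0, 0.0]])
    nf = a.size
    rows, cols, vals = [], [], []
    for fnode in (a, b):                    # force carried by node
        for cnode, sgn in ((b, 1.0), (a, -1.0)):   # coordinate dependence
            r = (fnode[:, None, None] * 2 + np.arange(2)[None, :, None])
            c = (cnode[:, None, None] * 2 + np.arange(2)[None, None, :])
            rows.append(np.broadcast_to(r, (nf, 2, 2)))
            cols.append(np.broadcast_to(c, (nf, 2, 2)))
            vals.append(np.broadcast_to(sgn * Z, (nf, 2, 2)))
    # external force enters the residual as -f_ext, handled by caller sign
    return (np.concatenate([x.ravel() for x in rows]),
            np.concatenate([x.ravel() for x in cols]),
            np.concatenate([x.ravel() for x in vals]))


def _skew(v: np.ndarray) -> np.ndarray:
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


_QFP, _QFW = quad_facet_quadrature()
_QF_N = np.stack([np.array([(1 - x) * (1 - y), (1 + x) * (1 - y),
                            (1 + x) * (1 + y), (1 - x) * (1 + y)]) / 4.0
                  for x, y in _QFP])                     # (g, 4)
_QF_dN = np.stack([np.array([
    [-(1 - y), -(1 - x)], [(1 - y), -(1 + x)],
    [(1 + y), (1 + x)], [-(1 + y), (1 - x)]]) / 4.0
    for x, y in _QFP])                                   # (g, 4, 2)


def _pressure_quad(xq: np.ndarray, p: float, need_tangent: bool):
    """Follower pressure on bilinear quad facets, 2x2 Gauss.

    f_a = -p sum_g w N_a (g1 x g2); the load stiffness is exact:
    d(g1 x g2)/dx_b = -skew(g2) dN_b^1 + skew(g1) dN_b^2.
    """
    g1 = np.einsum("ga,fad->gfd", _QF_dN[:, :, 0], xq)
    g2 = np.einsum("ga,fad->gfd", _QF_dN[:, :, 1], xq)
    nr = np.cross(g1, g2)                                # (g, nf, 3)
    fe = -p * np.einsum("g,ga,gfd->fad", _QFW, _QF_N, nr)
    K = None
    if need_tangent:
        S1 = _skew(g1)
        S2 = _skew(g2)
        # dnr/dx_b = -S2 dN_b^1 + S1 dN_b^2   (g, nf, b, 3, 3)
        dnr = (-S2[:, :, None, :, :] * _QF_dN[:, None, :, 0, None, None]
               + S1[:, :, None, :, :] * _QF_dN[:, None, :, 1, None, None])
        K = -p * np.einsum("g,ga,gfbde->fadbe", _QFW, _QF_N, dnr)
    return fe, K
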