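"""Solver machinery: assembly consistency, loads, contact, energy balance."""

import numpy as np
import pytest

from dissectfem.constants import MEDIA, default_cohesive_params
from dissectfem.fem.assembly import Assembler, _pressure_quad
from dissectfem.fem.mesh import InterfaceSet, Mesh, rect_with_interface
from dissectfem.fem.model import FEModel, LoadStage, SolverControls
from dissectfem.fem.solver import newton_solve, solve_quasi_static
from dissectfem.hgo import MaterialParams, cauchy_stress, compute_kinematics

SOFT = MaterialParams(C10=20.0, k1=50.0, k2=2.0, kappa=0.2, theta_deg=10.0,
                      D=1e-4)


def empty_stage(**kw):
    return LoadStage(dirichlet_dofs=np.array([], int),
                     dirichlet_vals=lambda g: np.array([]), **kw)


@pytest.fixture()
def patch_mesh():
    nodes = np.array([[0, 0], [1, 0], [2, 0], [0, 1], [1.1, 1.05], [2, 1],
                      [0, 2], [1, 2], [2, 2]], float)
    elems = np.array([[0, 1, 4, 3], [1, 2, 5, 4], [3, 4, 7, 6], [4, 5, 8, 7]])
    return Mesh(nodes, elems, np.zeros(4, int), "quad4")


class TestBulkAssembly:
    def test_patch_test_zero_interior_residual(self, patch_mesh):
        # a homogeneous deformation must be in exact equilibrium
        model = FEModel(mesh=patch_mesh, materials=[SOFT])
        asm = Assembler(model)
        A = np.array([[0.05, 0.02], [0.01, -0.03]])
        u = (patch_mesh.nodes @ A.T).ravel()
        R, _, _, _ = asm.assemble(u, empty_stage(), 1.0, None)
        interior = 4  # the only interior node
        assert np.abs(R[2 * interior:2 * interior + 2]).max() < 1e-9

    def test_tangent_matches_residual_differences(self, patch_mesh, rng):
        model = FEModel(mesh=patch_mesh, materials=[SOFT])
        asm = Assembler(model)
        u = 0.02 * rng.standard_normal(patch_mesh.n_dofs)
        stage = empty_stage()
        R0, K0, _, _ = asm.assemble(u, stage, 1.0, None)
        K0 = K0.toarray()
        h = 1e-7
        for k in rng.choice(patch_mesh.n_dofs, 6, replace=False):
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            Rp, _, _, _ = asm.assemble(up, stage, 1.0, None,
                                       need_tangent=False)
            Rm, _, _, _ = asm.assemble(um, stage, 1.0, None,
                                       need_tangent=False)
            fd = (Rp - Rm) / (2 * h)
            assert np.abs(fd - K0[:, k]).max() < 1e-4 * np.abs(K0).max()

    def test_single_element_homogeneous_stretch_forces(self):
        # nodal forces of a stretched element equal stress times edge area
        nodes = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        mesh = Mesh(nodes, np.array([[0, 1, 2, 3]]), np.zeros(1, int),
                    "quad4")
        model = FEModel(mesh=mesh, materials=[SOFT])
        asm = Assembler(model)
        lam = 1.05
        F2 = np.diag([lam, 1.0 / lam])  # isochoric in-plane
        u = (nodes @ (F2 - np.eye(2)).T).ravel()
        R, _, _, _ = asm.assemble(u, empty_stage(), 1.0, None)
        F3 = np.diag([lam, 1.0 / lam, 1.0])
        sig = cauchy_stress(compute_kinematics(F3, SOFT.theta_deg,
                                               SOFT.kappa), SOFT)
        # right edge: deformed height 1/lam, traction sig_xx
        fx_right = R[2 * 1] + R[2 * 2]
        assert fx_right == pytest.approx(sig[0, 0] / lam, rel=1e-6)


class TestPressureLoads:
    def test_flat_edge_force(self):
        nodes = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        mesh = Mesh(nodes, np.array([[0, 1, 2, 3]]), np.zeros(1, int),
                    "quad4")
        model = FEModel(mesh=mesh, materials=[SOFT])
        asm = Assembler(model)
        stage = empty_stage(pressures=[(np.array([[2, 3]]), lambda g: 10.0)])
        fext, _ = asm._pressure(np.zeros(8), stage, 1.0, False)
        # 10 kPa on the unit top edge -> net 10 mN downward
        assert fext.reshape(-1, 2).sum(axis=0) == pytest.approx([0.0, -10.0])

    def test_closed_quad_surface_zero_net_force(self, rng):
        # pressure on a closed polyhedron integrates to zero net force
        x = rng.standard_normal((8, 3)) * 0.2 + np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
             [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
        faces = np.array([
            [0, 3, 2, 1], [4, 5, 6, 7], [0, 1, 5, 4],
            [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]])
        fe, _ = _pressure_quad(x[faces], 7.0, False)
        assert np.abs(fe.sum(axis=(0, 1))).max() < 1e-10

    def test_pressurized_ring_matches_laplace(self):
        # thin ring under internal pressure: hoop force ~ p * r
        from dissectfem.tube import LoadCase, TearGeometry, TubeSpec, \
            build_tube_model
        spec = TubeSpec(n_theta=24, n_axial=1, n_r_inner=1, n_r_outer=1,
                        n_r_adventitia=1, symmetry="quarter")
        tear = TearGeometry()
        case = LoadCase(lambda_axial=1.0, p_TL=1.0)
        model = build_tube_model(spec, tear, case, intact=True)
        asm = Assembler(model)
        stage = model.stages[1]
        fext, _ = asm._pressure(np.zeros(asm.ndof), stage, 1.0, False)
        f = fext.reshape(-1, 3)
        # net y-force on the half ring = 2 p Ri L (resultant of p over the
        # projected area), reacted by the two cut faces
        L = spec.length(tear) / 2.0
        net_y = f[:, 1].sum()
        assert net_y == pytest.approx(2 * spec.Ri * L * 1.0, rel=0.01)

    def test_quad_pressure_load_stiffness(self, rng):
        xq = rng.standard_normal((3, 4, 3))
        f0, K0 = _pressure_quad(xq, 5.0, True)
        h = 1e-7
        for b in range(4):
            for d in range(3):
                xp = xq.copy()
                xp[:, b, d] += h
                fp, _ = _pressure_quad(xp, 5.0, False)
                fd = (fp - f0) / h
                assert np.abs(fd - K0[:, :, :, b, d]).max() < 1e-6


class TestInterfaceAndContact:
    def test_interface_tangent_consistent(self, rng, cohesive):
        mesh, iface, _, _ = rect_with_interface(2.0, 1.0, 2, 1, 1, 0.5)
        model = FEModel(mesh=mesh, materials=[SOFT], interface=iface,
                        cohesive=cohesive)
        asm = Assembler(model)
        surf = asm.make_surface()
        u = 0.01 * rng.standard_normal(asm.ndof)
        stage = empty_stage()
        R0, K0, _, _ = asm.assemble(u, stage, 1.0, surf)
        K0 = K0.toarray()
        h = 1e-7
        for k in rng.choice(asm.ndof, 8, replace=False):
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            Rp, _, _, _ = asm.assemble(up, stage, 1.0, surf,
                                       need_tangent=False)
            Rm, _, _, _ = asm.assemble(um, stage, 1.0, surf,
                                       need_tangent=False)
            fd = (Rp - Rm) / (2 * h)
            assert np.abs(fd - K0[:, k]).max() < 5e-4 * np.abs(K0).max()

    def test_no_penetration_under_compression(self, cohesive):
        # squeeze a torn interface: the gap must stay within tolerance
        mesh, iface, _, _ = rect_with_interface(1.0, 1.0, 2, 2, 2, 0.5,
                                                torn_until_x=2.0)
        model = FEModel(mesh=mesh, materials=[SOFT], interface=iface,
                        cohesive=cohesive)
        asm = Assembler(model)
        surf = asm.make_surface()
        top = mesh.nodes_where(lambda x: x[:, 1] > 1 - 1e-9)
        bot = mesh.nodes_where(lambda x: x[:, 1] < 1e-9)
        dofs = np.concatenate([bot * 2, bot * 2 + 1, top * 2, top * 2 + 1])

        def vals(g):
            v = np.zeros(dofs.size)
            v[2 * bot.size + top.size:] = -0.05 * g   # press down
            return v

        stage = LoadStage(dirichlet_dofs=dofs, dirichlet_vals=vals)
        u, ok, info = newton_solve(asm, stage, 1.0, np.zeros(asm.ndof), surf,
                                   model.controls)
        assert ok
        seps = info["seps"]
        assert seps[:, 0].min() > -2e-3   # bounded penetration
        assert surf.trial_state(seps)["d"].max() == pytest.approx(1.0)  # torn


class TestQuasiStatic:
    def test_zero_displacement_zero_force(self, cohesive):
        mesh, iface, _, _ = rect_with_interface(2.0, 1.0, 4, 2, 2, 0.5,
                                                torn_until_x=0.5)
        model = FEModel(mesh=mesh, materials=[MEDIA], interface=iface,
                        cohesive=cohesive)
        left = mesh.nodes_where(lambda x: np.abs(x[:, 0]) < 1e-12)
        dofs = np.concatenate([left * 2, left * 2 + 1])
        stage = LoadStage(dirichlet_dofs=dofs,
                          dirichlet_vals=lambda g: np.zeros(dofs.size))
        model.stages = [stage]
        traj, u, surf, _ = solve_quasi_static(model, record_every=1)
        assert traj.completed
        assert np.abs(u).max() == 0.0
        assert traj.records[-1].external_work == pytest.approx(0.0, abs=1e-12)

    def test_energy_balance_on_tension_column(self, cohesive):
        # external work = strain energy + cohesive dissipation within 2%
        mesh, iface, _, _ = rect_with_interface(1.0, 1.0, 2, 2, 2, 0.5)
        model = FEModel(mesh=mesh, materials=[SOFT], interface=iface,
                        cohesive=cohesive,
                        controls=SolverControls(dgamma0=0.01,
                                                dgamma_max=0.02,
                                                stabilization=0.0))
        top = mesh.nodes_where(lambda x: x[:, 1] > 1 - 1e-9)
        bot = mesh.nodes_where(lambda x: x[:, 1] < 1e-9)
        dofs = np.concatenate([bot * 2, bot * 2 + 1, top * 2, top * 2 + 1])
        pull = 0.35

        def vals(g):
            v = np.zeros(dofs.size)
            v[2 * bot.size + top.size:] = pull * g
            return v

        model.stages = [LoadStage(dirichlet_dofs=dofs, dirichlet_vals=vals)]
        traj, u, surf, _ = solve_quasi_static(model, record_every=1)
        assert traj.completed
        rec = traj.records[-1]
        stored_plus_diss = rec.strain_energy + rec.cohesive_dissipation
        # include the recoverable interface energy
        asm = Assembler(model)
        wda = asm.iface_wda.reshape(-1)
        elastic_iface = float(np.sum(wda * 0.5 * (
            surf.Tn * np.maximum(surf.dn, 0) + surf.Ts * surf.ds
            + surf.Tt * surf.dt)))
        total = stored_plus_diss + elastic_iface
        assert rec.external_work == pytest.approx(total, rel=0.02)
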