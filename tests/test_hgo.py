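"""Material model: kinematics, energy, stress and tangent consistency."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dissectfem.hgo import (
    InvalidDeformationError,
    MaterialParams,
    cauchy_stress,
    compute_kinematics,
    first_piola,
    material_tangent,
    pk2_stress_and_tangent,
    strain_energy_density,
)

from conftest import random_F


class TestKinematics:
    def test_identity(self):
        st = compute_kinematics(np.eye(3), theta_deg=30.0, kappa=0.2)
        assert st.J == pytest.approx(1.0)
        assert st.I1bar == pytest.approx(3.0)
        assert st.I4bar == pytest.approx(1.0)
        assert st.I6bar == pytest.approx(1.0)
        assert st.eps1 == pytest.approx(0.0)
        assert st.eps2 == pytest.approx(0.0)

    @pytest.mark.parametrize("theta", [0.0, 17.0, 45.0, 90.0])
    def test_equibiaxial_fiber_plane(self, theta):
        # isochoric equibiaxial stretch in the fibre plane: I4b = I6b = lam^2
        lam = 1.2
        F = np.diag([lam, lam, lam ** -2])
        st = compute_kinematics(F, theta)
        assert st.J == pytest.approx(1.0)
        assert st.I4bar == pytest.approx(lam ** 2)
        assert st.I6bar == pytest.approx(lam ** 2)

    def test_simple_shear_first_invariant(self):
        gam = 0.37
        F = np.eye(3)
        F[0, 1] = gam
        st = compute_kinematics(F, 0.0)
        assert st.I1bar == pytest.approx(3.0 + gam ** 2)

    def test_negative_jacobian_rejected(self):
        F = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(InvalidDeformationError):
            compute_kinematics(F, 0.0)

    def test_unit_fiber_directions(self):
        st = compute_kinematics(np.eye(3), 33.0)
        assert np.linalg.norm(st.M) == pytest.approx(1.0)
        assert np.linalg.norm(st.N) == pytest.approx(1.0)
        assert st.M[2] == st.N[2] == 0.0


class TestEnergy:
    def test_zero_at_reference(self, media, adventitia):
        for p in (media, adventitia):
            st = compute_kinematics(np.eye(3), p.theta_deg, p.kappa)
            assert strain_energy_density(st, p) == pytest.approx(0.0, abs=1e-12)

    def test_neo_hookean_limit(self, rng):
        # k1 = 0 removes the fibre term entirely
        p = MaterialParams(C10=11.0, k1=1e-12, k2=1.0, kappa=0.1,
                           theta_deg=25.0, D=1e-3)
        F = random_F(rng, near_isochoric=False)
        st = compute_kinematics(F, p.theta_deg, p.kappa)
        W = strain_energy_density(st, p)
        J = st.J
        expected = (p.C10 * (st.I1bar - 3.0)
                    + (1.0 / p.D) * ((J ** 2 - 1.0) / 2.0 - np.log(J)))
        assert W == pytest.approx(expected, rel=1e-9)

    def test_uniaxial_circumferential_scalar_oracle(self, media):
        # step-by-step scalar evaluation of the energy at an isochoric
        # uniaxial stretch along the circumferential direction
        lam = 1.1
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        th = np.deg2rad(media.theta_deg)
        I1b = lam ** 2 + 2.0 / lam
        I4b = lam ** 2 * np.cos(th) ** 2 + (1.0 / lam) * np.sin(th) ** 2
        eps = (media.kappa * (I1b - 3.0)
               + (1.0 - 3.0 * media.kappa) * (I4b - 1.0))
        W_ref = (media.C10 * (I1b - 3.0)
                 + 2.0 * media.k1 / (2.0 * media.k2)
                 * (np.exp(media.k2 * eps ** 2) - 1.0))
        st = compute_kinematics(F, media.theta_deg, media.kappa)
        assert strain_energy_density(st, media) == pytest.approx(W_ref,
                                                                 rel=1e-12)

    def test_rotation_invariance(self, media, rng):
        F = random_F(rng)
        W0 = strain_energy_density(
            compute_kinematics(F, media.theta_deg, media.kappa), media)
        for seed in range(5):
            Q = Rotation.random(random_state=seed).as_matrix()
            W = strain_energy_density(
                compute_kinematics(Q @ F, media.theta_deg, media.kappa), media)
            assert W == pytest.approx(W0, rel=1e-9)

    def test_full_dispersion_kills_anisotropy(self):
        # kappa = 1/3 makes eps independent of I4b/I6b, hence of theta
        F = np.diag([1.3, 1.0 / 1.3, 1.0])
        Ws = []
        for theta in (0.0, 30.0, 80.0):
            p = MaterialParams(C10=10.0, k1=50.0, k2=2.0, kappa=1.0 / 3.0,
                               theta_deg=theta, D=1e-4)
            st = compute_kinematics(F, p.theta_deg, p.kappa)
            Ws.append(strain_energy_density(st, p))
        assert np.ptp(Ws) == pytest.approx(0.0, abs=1e-12)


class TestStressAndTangent:
    def test_zero_stress_at_reference(self, media, adventitia):
        for p in (media, adventitia):
            st = compute_kinematics(np.eye(3), p.theta_deg, p.kappa)
            assert np.max(np.abs(cauchy_stress(st, p))) < 1e-8

    def test_first_piola_matches_energy_gradient(self, media, rng):
        h = 1e-6
        for _ in range(5):
            F = random_F(rng)
            P = first_piola(F, media)
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    Wp = strain_energy_density(
                        compute_kinematics(Fp, media.theta_deg, media.kappa),
                        media)
                    Wm = strain_energy_density(
                        compute_kinematics(Fm, media.theta_deg, media.kappa),
                        media)
                    assert P[i, j] == pytest.approx((Wp - Wm) / (2 * h),
                                                    rel=1e-5, abs=1e-4)

    def test_objectivity(self, media, rng):
        F = random_F(rng)
        st = compute_kinematics(F, media.theta_deg, media.kappa)
        s0 = cauchy_stress(st, media)
        Q = Rotation.random(random_state=7).as_matrix()
        st_rot = compute_kinematics(Q @ F, media.theta_deg, media.kappa)
        s1 = cauchy_stress(st_rot, media)
        np.testing.assert_allclose(s1, Q @ s0 @ Q.T, atol=1e-7 * np.abs(s0).max())

    def test_stress_symmetry(self, media, adventitia, rng):
        for p in (media, adventitia):
            for _ in range(20):
                F = random_F(rng)
                s = cauchy_stress(
                    compute_kinematics(F, p.theta_deg, p.kappa), p)
                np.testing.assert_allclose(s, s.T, atol=1e-8 * max(1, np.abs(s).max()))

    def test_tangent_consistency_many_states(self, media, adventitia, rng):
        # CC : dC/2 must reproduce dS by finite differences
        for p in (media, adventitia):
            F = np.stack([random_F(rng) for _ in range(60)])
            S, CC = pk2_stress_and_tangent(F, p)
            dF = 1e-6 * rng.standard_normal(F.shape)
            Sp, _ = pk2_stress_and_tangent(F + dF, p, tangent=False)
            Sm, _ = pk2_stress_and_tangent(F - dF, p, tangent=False)
            dS_fd = (Sp - Sm) / 2.0
            Fp, Fm = F + dF, F - dF
            dC = (np.einsum("...ki,...kj->...ij", Fp, Fp)
                  - np.einsum("...ki,...kj->...ij", Fm, Fm)) / 2.0
            dS = 0.5 * np.einsum("...ijkl,...kl->...ij", CC, dC)
            scale = np.abs(dS_fd).max()
            assert np.abs(dS - dS_fd).max() < 1e-4 * scale

    def test_tangent_minor_symmetry_and_definiteness(self, media):
        st = compute_kinematics(np.eye(3), media.theta_deg, media.kappa)
        c = material_tangent(st, media)
        np.testing.assert_allclose(c, np.swapaxes(c, 0, 1), atol=1e-6)
        np.testing.assert_allclose(c, np.swapaxes(c, 2, 3), atol=1e-6)
        # positive definite on symmetric perturbations at the reference
        M = c.reshape(9, 9)
        sym_basis = []
        for i in range(3):
            for j in range(i, 3):
                E = np.zeros((3, 3))
                E[i, j] = E[j, i] = 1.0
                sym_basis.append(E.ravel())
        B = np.array(sym_basis)
        eig = np.linalg.eigvalsh(B @ M @ B.T)
        assert np.all(eig > 0)

    def test_fiber_family_swap_symmetric(self, media, rng):
        # theta -> -theta exchanges M and N and leaves the response equal
        p_minus = MaterialParams(C10=media.C10, k1=media.k1, k2=media.k2,
                                 kappa=media.kappa,
                                 theta_deg=-media.theta_deg, D=media.D)
        F = random_F(rng)
        s1 = cauchy_stress(
            compute_kinematics(F, media.theta_deg, media.kappa), media)
        s2 = cauchy_stress(
            compute_kinematics(F, p_minus.theta_deg, p_minus.kappa), p_minus)
        np.testing.assert_allclose(s1, s2, rtol=1e-9, atol=1e-9)


def test_parameter_validation():
    with pytest.raises(ValueError):
        MaterialParams(C10=1.0, k1=1.0, k2=-1.0, kappa=0.1, theta_deg=0.0,
                       D=1e-6)
    with pytest.raises(ValueError):
        MaterialParams(C10=1.0, k1=1.0, k2=1.0, kappa=0.5, theta_deg=0.0,
                       D=1e-6)
    with pytest.raises(ValueError):
        MaterialParams(C10=1.0, k1=1.0, k2=1.0, kappa=0.1, theta_deg=0.0,
                       D=0.0)
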