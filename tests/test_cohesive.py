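"""Bilinear mixed-mode cohesive law: criteria, energies, path integrity."""

import numpy as np
import pytest
from dataclasses import replace

from dissectfem.cohesive import (
    CohesiveParams,
    CohesiveState,
    CohesiveSurface,
    TractionResult,
    failure_criterion,
    initiation_criterion,
    mode_mix_ratio,
    traction_update,
)


def drive(params, path, state=None):
    """Run a separation path through the point-level law."""
    st = state or CohesiveState()
    res = None
    for sep in path:
        st, res = traction_update(st, sep, params)
    return st, res


def pure_mode_path(smax, n, mode):
    out = np.zeros((n, 3))
    out[:, mode] = np.linspace(0.0, smax, n + 1)[1:]
    return out


class TestCriteria:
    def test_initiation_pure_normal_at_TnC(self, cohesive):
        T = TractionResult(Tn=131.0, Ts=0.0, Tt=0.0,
                           initiation_value=0, failure_value=0)
        assert initiation_criterion(T, cohesive) == pytest.approx(1.0)

    def test_initiation_ignores_compression(self, cohesive):
        T = TractionResult(Tn=-500.0, Ts=0.0, Tt=0.0,
                           initiation_value=0, failure_value=0)
        assert initiation_criterion(T, cohesive) == 0.0

    def test_initiation_quadratic_mix(self, cohesive):
        T = TractionResult(Tn=0.0, Ts=97.0 / np.sqrt(2), Tt=120.0 / np.sqrt(2),
                           initiation_value=0, failure_value=0)
        assert initiation_criterion(T, cohesive) == pytest.approx(1.0)

    def test_failure_pure_mode(self, cohesive):
        st = CohesiveState(GI=49.0)
        assert failure_criterion(st, cohesive) == pytest.approx(1.0)

    def test_failure_linear_mix(self, cohesive):
        st = CohesiveState(GI=24.5, GII=100.0)
        assert failure_criterion(st, cohesive) == pytest.approx(1.0)

    def test_failure_alpha_two(self, cohesive):
        p = replace(cohesive, alpha=2.0)
        st = CohesiveState(GI=0.5 * p.GIC, GII=0.5 * p.GIIC)
        assert failure_criterion(st, p) == pytest.approx(0.5)

    @pytest.mark.parametrize("G, m", [
        ((2.0, 0.0, 0.0), 0.0),
        ((0.0, 3.0, 0.0), 1.0),
        ((1.0, 3.0, 0.0), 0.75),
    ])
    def test_mode_mix(self, G, m):
        assert mode_mix_ratio(*G) == pytest.approx(m)

    def test_mode_mix_undefined_without_dissipation(self):
        assert np.isnan(mode_mix_ratio(0.0, 0.0, 0.0))


class TestPureModes:
    def test_mode_I_initiation_and_energy(self, cohesive):
        # initiation at TnC/Kn, total dissipation = G_IC within 0.1%
        path = pure_mode_path(0.80, 3000, 0)
        st, _ = drive(cohesive, path)
        assert st.failed
        assert st.delta0 == pytest.approx(131.0 / 1638.0, rel=1e-3)
        assert st.GI == pytest.approx(49.0, rel=1e-3)
        assert st.GII == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mode, TC, GC, K", [
        (1, 97.0, 200.0, 35000.0),
        (2, 120.0, 240.0, 35000.0),
    ])
    def test_sliding_modes_energy_and_peak(self, cohesive, mode, TC, GC, K):
        St = 2.0 * GC / TC
        path = pure_mode_path(1.05 * St, 4000, mode)
        peak = 0.0
        st = CohesiveState()
        for sep in path:
            st, res = traction_update(st, sep, cohesive)
            peak = max(peak, (res.Ts, res.Tt)[mode - 1])
        assert st.failed
        G = (st.GII, st.GIII)[mode - 1]
        assert G == pytest.approx(GC, rel=1e-3)
        assert peak == pytest.approx(TC, rel=2e-3)

    def test_stiffness_only_shifts_initiation(self, cohesive):
        # x10 stiffer interface: same dissipated energy, smaller S0
        stiff = replace(cohesive, Kn=10 * cohesive.Kn)
        for p in (cohesive, stiff):
            st, _ = drive(p, pure_mode_path(0.8, 4000, 0))
            assert st.GI == pytest.approx(49.0, rel=2e-3)
        assert stiff.S0[0] == pytest.approx(cohesive.S0[0] / 10.0)

    def test_alpha_insensitive_pure_mode_failure(self, cohesive):
        # pure-mode final separation changes < 5% between alpha = 1 and 2
        finals = []
        for alpha in (1.0, 2.0):
            p = replace(cohesive, alpha=alpha)
            st = CohesiveState()
            for dn in np.linspace(0, 0.9, 4000)[1:]:
                st, _ = traction_update(st, (dn, 0, 0), p)
                if st.failed:
                    finals.append(dn)
                    break
        assert abs(finals[1] - finals[0]) / finals[0] < 0.05


class TestPathHistory:
    def test_unload_reload_secant(self, cohesive):
        up = pure_mode_path(0.30, 300, 0)
        st, _ = drive(cohesive, up)
        d_mid, G_mid = st.d, st.GI
        assert 0.0 < d_mid < 1.0
        down_up = np.concatenate([up[::-1], up])
        st2, res = drive(cohesive, down_up, state=st)
        assert st2.d == pytest.approx(d_mid)
        assert st2.GI == pytest.approx(G_mid, abs=1e-9)
        # reload traction equals the secant stiffness times separation
        assert res.Tn == pytest.approx((1 - d_mid) * cohesive.Kn * 0.30,
                                       rel=1e-9)

    def test_damage_and_energy_irreversible_random_paths(self, cohesive, rng):
        for _ in range(20):
            st = CohesiveState()
            d_prev = G_prev = 0.0
            sep = np.zeros(3)
            for _ in range(150):
                sep = np.clip(sep + 0.05 * rng.standard_normal(3),
                              [-0.2, -3, -3], [0.9, 3, 3])
                st, _ = traction_update(st, tuple(sep), cohesive)
                assert st.d >= d_prev - 1e-12
                assert st.GT >= G_prev - 1e-12
                d_prev, G_prev = st.d, st.GT
                if st.failed:
                    break

    def test_compression_never_damages(self, cohesive):
        st = CohesiveState()
        for dn in np.linspace(0, -0.5, 200)[1:]:
            st, res = traction_update(st, (dn, 0, 0), cohesive)
        assert st.d == 0.0
        assert st.GT == 0.0
        assert res.initiation_value == 0.0


class TestMixedModeOracle:
    """The driver must agree with a fine-step incremental integrator."""

    def run_to_failure(self, cohesive, direction, n, smax=6.0):
        st = CohesiveState()
        direction = np.asarray(direction) / np.linalg.norm(direction)
        for s in np.linspace(0, smax, n + 1)[1:]:
            st, _ = traction_update(st, tuple(s * direction), cohesive)
            if st.failed:
                return s, st
        return np.nan, st

    @pytest.mark.parametrize("direction", [
        (1.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.3, 1.0, 0.5), (1.0, 0.2, 0.2),
    ])
    def test_proportional_paths_match_fine_integration(self, cohesive,
                                                       direction):
        s_coarse, st_c = self.run_to_failure(cohesive, direction, 1500)
        s_fine, st_f = self.run_to_failure(cohesive, direction, 20000)
        assert np.isfinite(s_coarse) and np.isfinite(s_fine)
        assert s_coarse == pytest.approx(s_fine, rel=0.01)
        assert st_c.GT == pytest.approx(st_f.GT, rel=0.01)
        m_c = mode_mix_ratio(st_c.GI, st_c.GII, st_c.GIII)
        m_f = mode_mix_ratio(st_f.GI, st_f.GII, st_f.GIII)
        assert m_c == pytest.approx(m_f, abs=0.01)

    def test_mixed_failure_satisfies_power_law(self, cohesive):
        _, st = self.run_to_failure(cohesive, (1.0, 1.0, 0.0), 4000)
        assert failure_criterion(st, cohesive) == pytest.approx(1.0, abs=0.01)


def test_parameter_validation():
    with pytest.raises(ValueError):
        CohesiveParams(TnC=-1, TsC=97, TtC=120, GIC=49, GIIC=200, GIIIC=240,
                       Kn=1638, Ks=35000, Kt=35000)
    with pytest.raises(ValueError):
        # final separation would not exceed the initiation separation
        CohesiveParams(TnC=131, TsC=97, TtC=120, GIC=1e-4, GIIC=200,
                       GIIIC=240, Kn=1638, Ks=35000, Kt=35000)


def test_surface_vector_matches_point_driver(cohesive, rng):
    """The vectorized surface must reproduce the scalar driver pointwise."""
    n = 7
    surf = CohesiveSurface(n, cohesive)
    states = [CohesiveState() for _ in range(n)]
    paths = rng.uniform(0.0, 1.0, size=(12, n, 3)) * np.array([0.6, 4.0, 4.0])
    paths = np.cumsum(paths / 12.0, axis=0)
    for step in paths:
        surf.commit(step)
        for k in range(n):
            states[k], _ = traction_update(states[k], tuple(step[k]),
                                           cohesive)
    np.testing.assert_allclose(surf.d, [s.d for s in states], atol=1e-12)
    np.testing.assert_allclose(surf.GI, [s.GI for s in states], atol=1e-12)
    np.testing.assert_allclose(surf.GII, [s.GII for s in states], atol=1e-12)
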