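import math

import numpy as np
import pytest

from wormrod.cross_section import SectionGeometry, MaterialMap
from wormrod.rod_reduction import (
    ActivationState, zeroth_order, first_order_constants, order_solutions,
    second_order_density, stiffnesses, intrinsic_loads, intrinsic_strains,
    accumulated_energy, rod_solve, RodCoefficients,
)

MU = 1e5


class TestZerothOrder:
    def test_identity(self):
        r0, P0 = zeroth_order(1.0)
        assert P0 == 1.0
        assert r0(0.7) == pytest.approx(0.7)

    def test_prestretched(self):
        r0, P0 = zeroth_order(1.8)
        assert P0 == pytest.approx(1 / 1.8)
        assert float(r0(1.0)) == pytest.approx(1 / math.sqrt(1.8), rel=1e-12)

    def test_incompressibility(self):
        # det of Diag(r0', r0/R, lam) is identically one
        lam = 1.4
        r0, _ = zeroth_order(lam)
        R = np.linspace(0.05, 1.0, 20)
        h = 1e-7
        rp = (r0(R + h) - r0(R - h)) / (2 * h)
        assert np.allclose(rp * r0(R) / R * lam, 1.0, atol=1e-7)

    def test_invalid(self):
        with pytest.raises(ValueError):
            zeroth_order(-1.0)


class TestFirstOrderConstants:
    @pytest.mark.parametrize("lam, q1, q2", [
        (1.0, -0.125, 0.625),
        (1.8, 0.479, 2.437),
        (2.0 ** (1 / 3), 0.0, 1.0),
    ])
    def test_closed_forms(self, lam, q1, q2):
        got = first_order_constants(lam)
        assert got[0] == pytest.approx(q1, abs=1e-4)
        assert got[1] == pytest.approx(q2, abs=1e-4)

    def test_incompressibility_relation(self):
        # 3 q1 - q2 + 1 = 0 holds for any pre-stretch
        for lam in (1.0, 1.3, 1.8, 2.5):
            q1, q2 = first_order_constants(lam)
            assert 3 * q1 - q2 + 1 == pytest.approx(0.0, abs=1e-12)


class TestStiffnesses:
    def test_classical_oracles(self, homogeneous_section):
        geom, mats = homogeneous_section
        K = stiffnesses(geom, mats)
        R = geom.R3 * 1e-6
        assert K.K0 == pytest.approx(3 * MU * math.pi * R**2, rel=0.01)
        assert K.K1 == pytest.approx(3 * MU * math.pi * R**4 / 4, rel=0.01)
        assert K.K2 == pytest.approx(3 * MU * math.pi * R**4 / 4, rel=0.01)
        assert K.K3 == pytest.approx(MU * math.pi * R**4 / 2, rel=0.01)

    def test_mu_linearity(self, homogeneous_section):
        geom, _ = homogeneous_section
        m1 = MaterialMap(mu_epidermis=1e5, mu_actin=1e5, mu_inner=1e5,
                         mu_muscle=1.00001e5)
        m2 = MaterialMap(mu_epidermis=2e5, mu_actin=2e5, mu_inner=2e5,
                         mu_muscle=2.00002e5)
        K1, K2 = stiffnesses(geom, m1), stiffnesses(geom, m2)
        for attr in ("K0", "K1", "K2", "K3"):
            assert getattr(K2, attr) / getattr(K1, attr) == \
                pytest.approx(2.0, rel=1e-12)

    def test_positive_for_default_section(self):
        K = stiffnesses()
        assert min(K.K0, K.K1, K.K2, K.K3) > 0


class TestIntrinsicLoads:
    def test_passive_loads_vanish(self, late_geom):
        co = intrinsic_loads(late_geom, None,
                             ActivationState(muscle_side="none"))
        assert np.allclose([co.H0, co.H1, co.H2, co.H3], 0.0, atol=1e-20)

    def test_left_pair_pure_bending(self, late_geom):
        co, st = rod_solve(late_geom, None,
                           ActivationState(gm=-0.15, muscle_side="left"))
        u1, u2, u3 = st.u_hat
        assert abs(u2) > 1.0                       # bends
        assert abs(u1) < 1e-6 * abs(u2)            # no out-of-plane part
        assert abs(u3) < 1e-6 * abs(u2)            # no twist
        assert st.kappa_hat == pytest.approx(abs(u2))
        assert st.tau_hat == 0.0

    def test_left_right_antisymmetry(self, late_geom):
        left = intrinsic_loads(late_geom, None,
                               ActivationState(gm=-0.15, muscle_side="left"))
        right = intrinsic_loads(late_geom, None,
                                ActivationState(gm=-0.15, muscle_side="right"))
        assert left.H2 == pytest.approx(-right.H2, rel=1e-9)
        assert left.H0 == pytest.approx(right.H0, rel=1e-9)

    def test_all_four_muscles_cancel_bending(self, late_geom):
        co, st = rod_solve(late_geom, None,
                           ActivationState(gm=-0.15, muscle_side="both"))
        assert abs(st.u_hat[0]) < 1e-8 * abs(1 - st.zeta_hat) / 1e-6
        assert st.kappa_hat < 1e-6 * abs(st.zeta_hat - 1.0) / 1e-6
        assert st.zeta_hat < 1.0                   # axial contraction

    def test_tilted_actin_pure_torsion(self, late_geom):
        co, st = rod_solve(
            late_geom, None,
            ActivationState(ga=-0.01, alpha_a=math.pi / 4,
                            muscle_side="none"))
        u1, u2, u3 = st.u_hat
        assert abs(u3) > 1.0
        assert abs(u1) < 1e-8 * abs(u3)
        assert abs(u2) < 1e-8 * abs(u3)
        assert st.kappa_hat < 1e-8 * abs(u3)
        assert st.tau_hat == pytest.approx(u3 / st.zeta_hat)

    def test_hoop_actin_no_torsion(self, late_geom):
        # alpha = pi/2: sin(alpha) cos(alpha) = 0, no chiral coupling
        _, st = rod_solve(late_geom, None,
                          ActivationState(ga=-0.01, alpha_a=math.pi / 2,
                                          muscle_side="none"))
        assert abs(st.u_hat[2]) < 1e-12

    def test_torsion_peaks_near_quarter_pi(self, late_geom):
        alphas = np.linspace(0.05, math.pi / 2 - 0.05, 41)
        u3 = [abs(rod_solve(late_geom, None,
                            ActivationState(ga=-0.01, alpha_a=float(a),
                                            muscle_side="none"))[1].u_hat[2])
              for a in alphas]
        amax = alphas[int(np.argmax(u3))]
        assert math.pi / 6 < amax < math.pi / 3

    def test_curvature_monotone_in_muscle_activation(self, late_geom):
        gms = np.linspace(0.0, 0.1, 6)
        kappas = [rod_solve(late_geom, None,
                            ActivationState(gm=-g, muscle_side="left")
                            )[1].kappa_hat for g in gms]
        assert all(b > a for a, b in zip(kappas, kappas[1:]))


class TestEnergy:
    def test_zero_activation_zero_energy(self, late_geom):
        co = intrinsic_loads(late_geom, None,
                             ActivationState(muscle_side="none"))
        assert accumulated_energy(co) == pytest.approx(0.0, abs=1e-25)

    def test_contractile_state_stores_energy(self, late_geom):
        co = intrinsic_loads(late_geom, None,
                             ActivationState(gm=-0.15, ga=-0.01,
                                             alpha_a=math.pi / 4))
        assert accumulated_energy(co) > 0.0

    def test_intrinsic_state_minimises_quadratic_form(self, late_geom):
        """The intrinsic strains minimise the rod energy: perturbing them
        in any direction raises E2 = sum K_i (s_i - s_hat_i)^2 / 2."""
        co, st = rod_solve(late_geom, None,
                           ActivationState(gm=-0.15, ga=-0.01,
                                           alpha_a=math.pi / 4))
        K = np.array([co.K0, co.K1, co.K2, co.K3])
        s_hat = np.array([st.zeta_hat - 1.0, *st.u_hat])

        def energy(s):
            return 0.5 * np.sum(K * (s - s_hat)**2)

        e0 = energy(s_hat)
        rng = np.random.default_rng(0)
        scale = np.maximum(np.abs(s_hat), 1e-4)
        for _ in range(100):
            pert = s_hat + rng.standard_normal(4) * 0.1 * scale
            assert energy(pert) >= e0

    def test_density_zero_at_relaxed_state(self):
        val = second_order_density((0, 0, 0, 0), (0.5, 1.0), MU)
        assert val == 0.0

    def test_density_positive_definite_passive(self):
        sol = order_solutions(1.0)
        rng = np.random.default_rng(1)
        for _ in range(50):
            R = rng.uniform(0.05, 1.0)
            Th = rng.uniform(0, 2 * math.pi)
            s = rng.standard_normal(4) * 0.2
            val = second_order_density(tuple(s), (R, Th), MU, sol=sol)
            assert val >= -1e-12

    def test_linear_terms_vanish_without_activation(self):
        # A1, B1, C1, D1 = 0 when g = c = 0
        from wormrod import _rod_coeffs as rc
        for nm in ("lin_xi", "lin_u1", "lin_u2", "lin_u3"):
            val = getattr(rc, nm)(0.7, 1.1, 1.0, MU, 0.0, 0.0, 0.3,
                                  -0.25, -1.0)
            assert val == pytest.approx(0.0, abs=1e-12)


class TestIntrinsicStrainsAlgebra:
    def test_trivial(self):
        K = RodCoefficients(K0=1.0, K1=1.0, K2=1.0, K3=1.0)
        st = intrinsic_strains(K)
        assert st.zeta_hat == 1.0
        assert st.kappa_hat == 0.0
        assert st.tau_hat == 0.0

    def test_ratios(self):
        K = RodCoefficients(K0=2.0, K1=4.0, K2=4.0, K3=8.0,
                            H0=0.2, H1=0.0, H2=1.0, H3=-2.0)
        st = intrinsic_strains(K)
        assert st.zeta_hat == pytest.approx(0.9)
        assert st.u_hat[1] == pytest.approx(0.25)
        assert st.u_hat[2] == pytest.approx(0.25)
        assert st.tau_hat == pytest.approx(0.25 / 0.9)


class TestEnergyDensityAgainstFiniteDifference:
    """Independent oracle: rebuild the 3D energy numerically from the
    deformation map and extract the second-order coefficient by finite
    differences in the slenderness."""

    @staticmethod
    def _numeric_V(eps, R, Th, lam, mu, g, c, alpha, qa, pb, strains):
        xi, u1, u2, u3 = strains
        s = math.sqrt(lam)
        S = u1 * math.sin(Th) - u2 * math.cos(Th)
        C = u1 * math.cos(Th) + u2 * math.sin(Th)
        r0 = R / s
        a1 = r0 + eps * (-r0 * xi / 2 + qa * R**2 * S)
        a2 = Th + eps * (3 * qa * s + 1 / s) * R * C
        lt = lam * (1 + eps * xi)
        da1dR = 1 / s + eps * (-xi / (2 * s) + 2 * qa * R * S)
        da1dT = eps * (-r0 * xi * 0 + qa * R**2 * C)
        da2dR = (3 * qa * s + 1 / s) * C * eps
        da2dT = 1 + eps * (3 * qa * s + 1 / s) * R * (-S)
        F = np.array([
            [da1dR, da1dT / R, 0.0],
            [a1 * da2dR, a1 * da2dT / R, eps * lt * u3 * a1],
            [0.0, 0.0, lt * (1 + eps * (u1 * a1 * math.sin(a2)
                                        - u2 * a1 * math.cos(a2)))],
        ])
        m = np.array([0.0, math.sin(alpha), math.cos(alpha)])
        G0 = np.diag([1.0, 1.0 + eps * c, 1.0])
        G = G0 @ (np.eye(3) + eps * g * np.outer(m, m))
        Fe = F @ np.linalg.inv(G)
        p = mu * (1 / lam + eps * (-xi / lam + pb * r0 * S))
        return (mu / 2 * (np.trace(Fe @ Fe.T) - 3)
                - p * (np.linalg.det(Fe) - 1))

    @pytest.mark.parametrize("lam", [1.0, 1.8])
    def test_matches_generated_coefficients(self, lam):
        sol = order_solutions(lam, None)
        rng = np.random.default_rng(42)
        eps = 1e-4
        for _ in range(5):
            R = rng.uniform(0.1, 1.0)
            Th = rng.uniform(0.0, 2 * math.pi)
            g, c, alpha = -0.12, -0.5, 0.6
            strains = tuple(rng.standard_normal(4) * 0.3)
            args = (R, Th, lam, MU, g, c, alpha, sol.qa, sol.pb)

            def V2_fd(s):
                vp = self._numeric_V(eps, *args, s)
                vm = self._numeric_V(-eps, *args, s)
                v0 = self._numeric_V(0.0, *args, s)
                return (vp + vm - 2 * v0) / (2 * eps**2)

            fd = V2_fd(strains) - V2_fd((0, 0, 0, 0))
            model = second_order_density(strains, (R, Th), MU,
                                         (g, c, alpha), sol) / R
            assert model == pytest.approx(fd, rel=2e-4, abs=1e-3)
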