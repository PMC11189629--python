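import math

import numpy as np
import pytest

from wormrod.kinematics import (
    FiberAngles, PreStrain, fiber_direction, active_tensor,
    integrate_centerline, MUSCLE_ANGLES, HOOP_ANGLES,
)


@pytest.mark.parametrize("angles, expected", [
    (FiberAngles(0.0, 0.0), (0.0, 0.0, 1.0)),            # muscle axis
    (FiberAngles(math.pi / 2, 0.0), (0.0, 1.0, 0.0)),    # hoop actin
    (FiberAngles(math.pi / 2, math.pi / 2), (1.0, 0.0, 0.0)),
])
def test_fiber_direction_examples(angles, expected):
    assert np.allclose(fiber_direction(angles), expected, atol=1e-12)


def test_fiber_direction_unit_norm_on_grid():
    for alpha in np.linspace(-math.pi / 2, math.pi / 2, 9):
        for beta in np.linspace(-math.pi / 2, math.pi / 2, 9):
            m = fiber_direction(FiberAngles(alpha, beta))
            assert abs(np.dot(m, m) - 1.0) < 1e-12


def test_fiber_angles_out_of_range():
    with pytest.raises(ValueError):
        FiberAngles(2.0, 0.0)


class TestPreStrain:
    def test_c_consistency(self):
        pre = PreStrain(g0=0.88, eps=0.2)
        assert pre.c == pytest.approx(-0.6, abs=1e-12)

    def test_inconsistent_pair_rejected(self):
        with pytest.raises(ValueError):
            PreStrain(g0=0.88, c=-0.5, eps=0.2)

    def test_bounds(self):
        with pytest.raises(ValueError):
            PreStrain(g0=1.2)


class TestActiveTensor:
    def test_zero_activation_returns_g0(self):
        pre = PreStrain(g0=0.9, eps=0.2)
        m = fiber_direction(MUSCLE_ANGLES)
        G = active_tensor(pre, 0.0, 0.2, m)
        assert np.allclose(G.matrix, pre.G0, atol=1e-15)

    @pytest.mark.parametrize("angles, axis", [
        (MUSCLE_ANGLES, 2),   # axial fibers stretch the Z entry
        (HOOP_ANGLES, 1),     # hoop fibers the Theta entry
    ])
    def test_identity_prestrain_diagonal(self, angles, axis):
        g, eps = -0.1, 0.2
        G = active_tensor(PreStrain(), g, eps, fiber_direction(angles))
        expected = np.eye(3)
        expected[axis, axis] += eps * g
        assert np.allclose(G.matrix, expected, atol=1e-12)

    def test_symmetric_when_g0_identity(self):
        m = fiber_direction(FiberAngles(0.3, 0.4))
        G = active_tensor(PreStrain(), -0.1, 0.2, m).matrix
        assert np.allclose(G, G.T, atol=1e-14)

    def test_det_first_order_in_eps(self):
        # det G = 1 + eps*g + O(eps^2) for G0 = I
        m = fiber_direction(FiberAngles(0.5, 0.1))
        g = -0.15
        dets = []
        for eps in (1e-3, 1e-4):
            G = active_tensor(PreStrain(), g, eps, m)
            dets.append((G.det - 1.0) / eps)
        assert dets[1] == pytest.approx(g, rel=1e-3)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            active_tensor(PreStrain(), -0.1, 0.2, np.array([0.0, 0.0, 2.0]))


class TestCenterline:
    def test_straight_segment(self):
        st = integrate_centerline(1.0, (0.0, 0.0, 0.0), L=90.0, n_steps=50)
        assert np.allclose(st.positions[-1], [0, 0, 90], atol=1e-12)
        assert st.arc_length() == pytest.approx(90.0, rel=1e-9)

    def test_planar_arc_radius(self):
        kappa = 0.05
        st = integrate_centerline(1.0, (0.0, kappa, 0.0), L=40.0,
                                  n_steps=2000)
        # initial frame is the identity and u2 > 0 bends toward +x, so the
        # arc center sits at +x/kappa
        center = st.positions[0] + np.array([1 / kappa, 0, 0])
        dists = np.linalg.norm(st.positions - center, axis=1)
        assert np.allclose(dists, 1 / kappa, atol=1e-6)

    def test_helix_closed_form(self):
        kappa, tau = 0.08, 0.05
        st = integrate_centerline(1.0, (0.0, kappa, tau), L=500.0,
                                  n_steps=4000)
        denom = kappa**2 + tau**2
        r_helix = kappa / denom
        pitch = 2 * math.pi * tau / denom
        # the helix axis is parallel to the (constant) Darboux vector
        # kappa d2 + tau d3 and passes through the initial curvature center
        axis = np.array([0.0, kappa, tau]) / math.sqrt(denom)
        p0 = st.positions[0] + np.array([r_helix, 0, 0])
        rel = st.positions - p0
        radial = rel - np.outer(rel @ axis, axis)
        assert np.allclose(np.linalg.norm(radial, axis=1), r_helix,
                           atol=1e-4 * r_helix)
        # pitch: axial advance per turn; turns = L sqrt(denom) / (2 pi)
        advance = rel @ axis
        turns = 500.0 * math.sqrt(denom) / (2 * math.pi)
        assert advance[-1] / turns == pytest.approx(pitch, rel=1e-6)

    def test_orthonormality_many_steps(self):
        st = integrate_centerline(1.1, (0.02, 0.03, 0.01), L=100.0,
                                  n_steps=10_000)
        assert st.orthonormality_defect() < 1e-9

    def test_bending_mirror_symmetry(self):
        up = integrate_centerline(1.0, (0.0, 0.04, 0.0), L=60.0, n_steps=500)
        dn = integrate_centerline(1.0, (0.0, -0.04, 0.0), L=60.0, n_steps=500)
        assert np.allclose(up.positions[:, 0], -dn.positions[:, 0],
                           atol=1e-12)
        assert np.allclose(up.positions[:, 2], dn.positions[:, 2],
                           atol=1e-12)

    def test_arc_length_scales_with_zeta(self):
        st = integrate_centerline(1.3, (0.0, 0.05, 0.02), L=80.0,
                                  n_steps=2000)
        assert st.arc_length() == pytest.approx(1.3 * 80.0, rel=1e-6)

    def test_invalid_steps(self):
        with pytest.raises(ValueError):
            integrate_centerline(1.0, (0, 0, 0), L=10.0, n_steps=1)
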