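import math

import numpy as np
import pytest

from wormrod.cross_section import MaterialMap
from wormrod.late_elongation import (
    CycleSchedule, RodCycleModel, simulate_late_phase, mutant_scenario,
    cycle_contraction_energy, relaxation_transfer, late_geometry,
)


class TestSchedule:
    def test_contraction_count(self):
        assert CycleSchedule().n_cycles == 210

    def test_count_follows_period(self):
        assert CycleSchedule(phase_duration_min=10, period_s=60).n_cycles == 10

    def test_efficiency_ramp_endpoints(self):
        s = CycleSchedule()
        assert s.phi(0) == 1.0
        assert s.phi(s.n_cycles - 1) == pytest.approx(0.4)

    def test_invalid_efficiency(self):
        with pytest.raises(ValueError):
            CycleSchedule(efficiency_end=0.0)


class TestCycleEnergy:
    def test_zero_activation_zero_energy(self):
        sch = CycleSchedule(gm=0.0, ga=0.0)
        model = RodCycleModel(sch, energy_scale=1.0)
        assert model.contraction_energy("left") == pytest.approx(0.0,
                                                                 abs=1e-30)

    def test_left_right_symmetry(self, default_model):
        wl = default_model.contraction_energy("left")
        wr = default_model.contraction_energy("right")
        assert wl == pytest.approx(wr, rel=1e-10)

    def test_energy_grows_with_activation(self):
        w_half = RodCycleModel(CycleSchedule(gm=-0.075),
                               energy_scale=1.0).contraction_energy("left")
        w_full = RodCycleModel(CycleSchedule(gm=-0.15),
                               energy_scale=1.0).contraction_energy("left")
        assert w_full > w_half
        # bending energy is nearly quadratic in the activation
        assert w_full / w_half == pytest.approx(4.0, rel=0.35)

    def test_calibrated_energy_positive(self):
        assert cycle_contraction_energy() > 0


class TestTransfer:
    def test_zero_energy_zero_gain(self, default_model):
        assert default_model.transfer(0.0, 1.0) == (0.0, 0.0)

    def test_gain_increasing_in_phi(self, default_model):
        Wc = default_model.energy_scale * \
            default_model.contraction_energy("left")
        gains = [default_model.transfer(Wc, phi)[1]
                 for phi in np.linspace(0.1, 1.0, 10)]
        assert all(b > a for a, b in zip(gains, gains[1:]))

    def test_near_linear_in_phi(self, default_model):
        """The pre-strain background dominates the loop energy balance,
        so the extension gain is nearly proportional to phi."""
        Wc = default_model.energy_scale * \
            default_model.contraction_energy("left")
        g_half = default_model.transfer(Wc, 0.5)[1]
        g_full = default_model.transfer(Wc, 1.0)[1]
        assert g_full / g_half == pytest.approx(2.0, rel=0.01)

    def test_contractile_increment_sign(self, default_model):
        Wc = default_model.energy_scale * \
            default_model.contraction_energy("left")
        ga1, _ = default_model.transfer(Wc, 1.0)
        assert ga1 < 0

    def test_public_wrapper_at_reference_length(self, default_model):
        Wc = default_model.energy_scale * \
            default_model.contraction_energy("left")
        ga1, dz = relaxation_transfer(Wc, 1.0, default_model)
        assert dz == pytest.approx(0.5, rel=1e-9)

    def test_invalid_phi(self, default_model):
        with pytest.raises(ValueError):
            default_model.transfer(1e-14, 1.5)


@pytest.fixture(scope="module")
def full():
    return simulate_late_phase(CycleSchedule(efficiency="full"))


@pytest.fixture(scope="module")
def wild():
    return simulate_late_phase(mutant_scenario("wild_type"))


class TestSimulation:
    def test_first_cycle_anchor(self, full):
        assert full.cycles[0].delta_zeta == pytest.approx(0.5, rel=1e-9)

    def test_full_conversion_final_length(self, full):
        assert full.final_length == pytest.approx(290.0, abs=10.0)

    def test_increments_grow_under_full_conversion(self, full):
        dz = [c.delta_zeta for c in full.cycles]
        assert all(b >= a for a, b in zip(dz, dz[1:]))
        assert dz[-1] == pytest.approx(1.5, abs=0.2)

    def test_length_monotone(self, full, wild):
        for res in (full, wild):
            L = [c.length_after for c in res.cycles]
            assert all(b >= a for a, b in zip(L, L[1:]))

    def test_ramp_rises_then_falls(self, wild):
        dz = [c.delta_zeta for c in wild.cycles]
        peak = int(np.argmax(dz))
        assert 10 < peak < len(dz) - 10
        assert dz[-1] < dz[peak]
        assert dz[0] < dz[peak]

    def test_wild_type_final_range(self, wild):
        # partial conversion ends well below the full-conversion bound
        assert 180.0 < wild.final_length < 240.0

    def test_energy_bookkeeping(self, wild):
        loss = wild.energy_loss()
        assert loss >= 0.0
        assert loss == pytest.approx(
            sum(c.Wc - c.Wr for c in wild.cycles))
        assert all(c.Wr <= c.Wc + 1e-30 for c in wild.cycles)

    def test_unc112_arrest(self):
        res = simulate_late_phase(mutant_scenario("unc112"))
        assert res.final_length == pytest.approx(90.0, abs=1e-9)
        assert all(c.Wc == 0.0 for c in res.cycles)

    def test_spc1_pak1_retraction(self):
        res = simulate_late_phase(mutant_scenario("spc1_pak1"))
        assert res.final_length < 90.0
        L = [c.length_after for c in res.cycles]
        assert all(b <= a for a, b in zip(L, L[1:]))

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            mutant_scenario("lin-12")

    def test_modulus_scale_invariance(self):
        """Scaling every shear modulus leaves the trajectory unchanged:
        the stored energy and the loop stiffness scale together, so the
        quadratic energy-strain relation predicts identical increments."""
        res1 = simulate_late_phase(CycleSchedule(efficiency="full"))
        mats = MaterialMap(mu_epidermis=0.5e5, mu_actin=0.5 * 1.83e5,
                           mu_inner=0.5e4, mu_muscle=0.5e5)
        res2 = simulate_late_phase(CycleSchedule(efficiency="full"),
                                   materials=mats)
        dz1 = [c.delta_zeta for c in res1.cycles]
        dz2 = [c.delta_zeta for c in res2.cycles]
        assert np.allclose(dz1, dz2, rtol=1e-9)
        # while the absolute energies halve
        assert res2.cycles[0].Wc / res1.cycles[0].Wc == \
            pytest.approx(0.5, rel=1e-6)
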