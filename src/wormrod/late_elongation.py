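"""Cyclic muscle contraction and energy transfer of the late phase.

After the 1.8-fold stage the four axial muscle bands contract in
left/right pairs roughly every 40 s for about 140 minutes (~210
contractions).  One cycle is modelled in three states:

1. *Background*: the actin bundles hold their circumferential pre-strain
   (``c`` on the slow scale plus a small maintained activation ``ga``);
   the rod is straight at the current length.
2. *Contraction*: one muscle pair contracts (``gm``) and the actin
   bundles tilt to an oblique angle; the rod reduction gives the intrinsic
   bending/twist/shortening strains, and the elastic energy ``Wc`` stored
   relative to the background follows from the rod stiffnesses.
3. *Relaxation*: the muscles release and a fraction ``phi`` of ``Wc`` is
   transferred to the circumferential actomyosin, which emerges in its
   hoop ("loop") configuration with an incremented activation ``ga1``.
   The increment deepens the maintained hoop pre-strain, and the ratchet
   hold balance of the early phase (``ln lambda = chi (1 - g0)``) turns
   it into a permanent fractional length gain ``chi * eps * |ga1|``.

Because the hoop system already carries the large pre-strain background,
the energy balance ``W_loop(background + ga1) - W_loop(background) =
phi Wc`` is dominated by its linear term, so the per-cycle gain is nearly
proportional to ``phi``.

Absolute energy scale
---------------------
The moduli of the embryonic layers are only known to order of magnitude,
so the absolute size of ``Wc`` carries a large uncertainty while every
relative prediction (left vs. right pairs, efficiency schedules, mutants)
is robust.  A single dimensionless energy-scale factor is therefore
calibrated once so that the first wild-type cycle at full conversion
yields the observed 0.5 um increment, then frozen for all scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from wormrod.cross_section import SectionGeometry, MaterialMap
from wormrod.early_elongation import ratchet_gain
from wormrod.rod_reduction import (
    ActivationState, intrinsic_loads, intrinsic_strains, stiffnesses,
)

__all__ = [
    "CycleSchedule", "ContractionCycle", "LateResult", "late_geometry",
    "cycle_contraction_energy", "relaxation_transfer",
    "simulate_late_phase", "mutant_scenario",
]

_UM = 1e-6

#: hoop pre-strain eigenvalue left by the early phase (solve_prestrain(1.8))
G0_LATE = 0.8915242083413928
#: anchor for the absolute energy scale: first-cycle increment (um)
FIRST_CYCLE_ANCHOR_UM = 0.5


def late_geometry() -> SectionGeometry:
    """Reference geometry at the onset of the late phase (1.8-fold)."""
    return SectionGeometry(R3=8.2, L=90.0)


@dataclass(frozen=True)
class CycleSchedule:
    """Timing, activations and efficiency of the contraction cycles."""

    phase_duration_min: float = 140.0
    period_s: float = 40.0
    n_cycles: int | None = None
    gm: float = -0.15
    ga: float = -0.01
    alpha_contracted: float = math.pi / 4
    initial_length_um: float = 90.0
    efficiency: str = "linear"       # linear | full | sigmoid | piecewise
    efficiency_start: float = 1.0
    efficiency_end: float = 0.4
    lambda_decay_per_min: float = 0.0   # pre-stretch failure (spc-1 pak-1)

    def __post_init__(self) -> None:
        if self.n_cycles is None:
            object.__setattr__(
                self, "n_cycles",
                int(self.phase_duration_min * 60.0 // self.period_s))
        if self.n_cycles < 1:
            raise ValueError("schedule must contain at least one cycle")
        if not (0.0 < self.efficiency_start <= 1.0
                and 0.0 < self.efficiency_end <= 1.0):
            raise ValueError("efficiencies must lie in (0, 1]")

    def phi(self, i: int) -> float:
        """Conversion efficiency of cycle ``i`` (0-based)."""
        if self.efficiency == "full":
            return 1.0
        x = 0.0 if self.n_cycles == 1 else i / (self.n_cycles - 1)
        a, b = self.efficiency_start, self.efficiency_end
        if self.efficiency == "linear":
            return a + (b - a) * x
        if self.efficiency == "sigmoid":
            return b + (a - b) / (1.0 + math.exp(10.0 * (x - 0.5)))
        if self.efficiency == "piecewise":
            return a if x < 0.5 else b
        raise ValueError(f"unknown efficiency schedule {self.efficiency!r}")


@dataclass
class ContractionCycle:
    """Energy bookkeeping of one contraction/relaxation cycle."""

    index: int
    t_min: float
    Wc: float                 # accumulated energy during contraction (J)
    Wr: float                 # energy transferred at relaxation (J)
    ga1: float                # post-relaxation hoop activation increment
    delta_zeta: float         # permanent length increment (um)
    length_after: float       # um
    side: str


@dataclass
class LateResult:
    """Output of :func:`simulate_late_phase`."""

    cycles: list
    energy_scale: float
    schedule: CycleSchedule

    @property
    def final_length(self) -> float:
        return self.cycles[-1].length_after if self.cycles else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_min": [c.t_min for c in self.cycles],
             "length_um": [c.length_after for c in self.cycles],
             "cycle_index": [c.index for c in self.cycles],
             "Wc_J": [c.Wc for c in self.cycles],
             "Wr_J": [c.Wr for c in self.cycles],
             "delta_zeta_um": [c.delta_zeta for c in self.cycles]})

    def energy_loss(self) -> float:
        """Cumulative unconverted energy ``sum(Wc - Wr)`` (J)."""
        return sum(c.Wc - c.Wr for c in self.cycles)


class RodCycleModel:
    """Rod solves and the energy-transfer map for one schedule.

    All intensive quantities (per-cycle strain gain, energies per unit
    length) are evaluated on the late-onset reference geometry; the
    activation pattern and section fractions stay self-similar along the
    phase, so the fractional gain at a given efficiency is constant and
    the length grows geometrically under full conversion.
    """

    def __init__(self, schedule: CycleSchedule,
                 geom: SectionGeometry | None = None,
                 materials: MaterialMap | None = None,
                 energy_scale: float | None = None):
        self.schedule = schedule
        self.geom = geom or late_geometry()
        self.mats = materials or MaterialMap()
        eps = self.geom.eps
        self.c_late = (G0_LATE - 1.0) / eps
        self.chi = ratchet_gain()
        self.K = stiffnesses(self.geom, self.mats)
        self.bg = self._strains(gm=0.0, alpha=math.pi / 2, side="none")
        self.con = {side: self._strains(schedule.gm,
                                        schedule.alpha_contracted, side)
                    for side in ("left", "right")}
        # hoop ("loop") configuration energy: thin-ring eigenstrain energy
        # (1/2) K_loop gamma^2 per total hoop activation gamma on the slow
        # scale; the background is gamma0 = c + ga.
        ring_frac = 1.0 - (self.geom.R2p / self.geom.R3)**2
        V_ring = ring_frac * math.pi * (self.geom.R3 * _UM)**2 \
            * self.geom.L * _UM
        self.K_loop = 2.0 * self.mats.mu_actin * V_ring * eps**2
        self.gamma0 = self.c_late + schedule.ga
        if energy_scale is None:
            energy_scale = self._calibrate()
        self.energy_scale = energy_scale

    def _strains(self, gm, alpha, side):
        act = ActivationState(gm=gm, ga=self.schedule.ga, alpha_a=alpha,
                              muscle_side=side, c=self.c_late)
        return intrinsic_strains(intrinsic_loads(
            self.geom, self.mats, act, coeffs=self.K))

    def contraction_energy(self, side: str, L_um: float | None = None) -> float:
        """Raw elastic energy (J) stored from background to contraction."""
        st, bg = self.con[side], self.bg
        L = (L_um if L_um is not None else self.geom.L) * _UM
        du = [a - b for a, b in zip(st.u_hat, bg.u_hat)]
        return 0.5 * L * (self.K.K0 * (st.zeta_hat - bg.zeta_hat)**2
                          + self.K.K1 * du[0]**2 + self.K.K2 * du[1]**2
                          + self.K.K3 * du[2]**2)

    def transfer(self, Wc: float, phi: float):
        """Energy balance of the relaxation step.

        Solves ``1/2 K_loop [(gamma0 + ga1)^2 - gamma0^2] = phi Wc`` for
        the hoop-activation increment ``ga1`` (contractile, same sign as
        the background) and returns ``(ga1, strain_gain)`` with
        ``strain_gain = chi eps |ga1|`` the permanent fractional length
        gain from the ratchet hold balance.
        """
        if not (0.0 <= phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if phi == 0.0 or Wc == 0.0:
            return 0.0, 0.0
        g2 = self.gamma0**2 + 2.0 * phi * Wc / self.K_loop
        ga1 = -(math.sqrt(g2) - abs(self.gamma0))
        if abs(ga1) >= 1.0:
            raise RuntimeError(
                f"no admissible post-relaxation activation: |ga1| = "
                f"{abs(ga1):.3f} >= 1; the transferred energy exceeds "
                "what the hoop network can store")
        return ga1, self.chi * self.geom.eps * abs(ga1)

    def _calibrate(self) -> float:
        """Energy-scale factor anchoring the first cycle at 0.5 um."""
        ref = self if (self.schedule.gm, self.schedule.ga) == (-0.15, -0.01) \
            else RodCycleModel(CycleSchedule(), self.geom, self.mats,
                               energy_scale=1.0)
        Wc = ref.contraction_energy("left")
        if Wc == 0.0:
            return 1.0
        target = FIRST_CYCLE_ANCHOR_UM / ref.schedule.initial_length_um
        # invert target = chi eps (sqrt(g0^2 + 2 s Wc / K_loop) - |g0|)
        root = target / (ref.chi * ref.geom.eps) + abs(ref.gamma0)
        return (root**2 - ref.gamma0**2) * ref.K_loop / (2.0 * Wc)


def cycle_contraction_energy(schedule: CycleSchedule | None = None,
                             side: str = "left",
                             geom=None, materials=None,
                             model: RodCycleModel | None = None,
                             calibrated: bool = True) -> float:
    """Accumulated energy ``Wc`` (J) of one muscle contraction.

    With ``calibrated=True`` the raw elastic energy is multiplied by the
    frozen energy-scale factor, putting it on the absolute scale anchored
    by the first-cycle increment.
    """
    schedule = schedule or CycleSchedule()
    model = model or RodCycleModel(schedule, geom, materials)
    Wc = model.contraction_energy(side)
    return model.energy_scale * Wc if calibrated else Wc


def relaxation_transfer(Wc: float, phi: float,
                        model: RodCycleModel | None = None,
                        L_um: float | None = None):
    """Post-relaxation activation and length increment for one cycle.

    ``Wc`` is the calibrated accumulated energy; returns
    ``(ga1, delta_zeta_um)`` with ``delta_zeta`` evaluated at the current
    length (defaults to the reference 90 um).
    """
    model = model or RodCycleModel(CycleSchedule())
    L = L_um if L_um is not None else model.schedule.initial_length_um
    Wc_ref = Wc * model.geom.L / L        # intensive (reference-length) value
    ga1, gain = model.transfer(Wc_ref, phi)
    return ga1, gain * L


def simulate_late_phase(schedule: CycleSchedule | None = None,
                        geom: SectionGeometry | None = None,
                        materials: MaterialMap | None = None) -> LateResult:
    """Run the cyclic energy-transfer simulation.

    Left and right muscle pairs alternate; each cycle stores ``Wc``,
    transfers ``Wr = phi_i Wc``, increments the hoop activation and adds
    the permanent increment ``delta_zeta_i = gain_i * L_i`` to the length.
    In the pre-stretch-failure scenario the early-phase elongation decays
    between cycles and the embryo retracts.
    """
    schedule = schedule or CycleSchedule()
    model = RodCycleModel(schedule, geom, materials)
    L = schedule.initial_length_um
    decay_step = schedule.period_s / 60.0 * schedule.lambda_decay_per_min
    active = (schedule.gm != 0.0 or schedule.ga != 0.0)
    cycles = []
    for i in range(schedule.n_cycles):
        t_min = (i + 1) * schedule.period_s / 60.0
        side = "left" if i % 2 == 0 else "right"
        if decay_step > 0.0:
            L = max(L * math.exp(-decay_step),
                    schedule.initial_length_um / 1.8)
        if active:
            phi = schedule.phi(i)
            Wc_ref = model.energy_scale * model.contraction_energy(side)
            ga1, gain = model.transfer(Wc_ref, phi)
            Wc = Wc_ref * L / model.geom.L       # extensive, current length
            Wr = phi * Wc
            dz = gain * L
        else:
            Wc = Wr = ga1 = dz = 0.0
        L = L + dz
        cycles.append(ContractionCycle(index=i, t_min=t_min, Wc=Wc, Wr=Wr,
                                       ga1=ga1, delta_zeta=dz,
                                       length_after=L, side=side))
    return LateResult(cycles=cycles, energy_scale=model.energy_scale,
                      schedule=schedule)


def mutant_scenario(name: str) -> CycleSchedule:
    """Scenario presets: wild type and the two mutant classes.

    * ``wild_type`` -- default activations with the linear 1.0 -> 0.4
      conversion-efficiency ramp.
    * ``unc112`` -- muscle attachment knocked down: no activation, no
      accumulated energy; elongation arrests at the twofold stage.
    * ``spc1_pak1`` -- the actomyosin pre-stretch is not maintained: the
      early elongation decays and the embryo retracts.
    """
    if name == "wild_type":
        return CycleSchedule()
    if name == "unc112":
        return CycleSchedule(gm=0.0, ga=0.0)
    if name == "spc1_pak1":
        return CycleSchedule(gm=0.0, ga=0.0, lambda_decay_per_min=2.5e-3)
    raise ValueError(f"unknown scenario {name!r}; expected wild_type, "
                     "unc112 or spc1_pak1")
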