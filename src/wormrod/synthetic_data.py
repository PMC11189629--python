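"""Seeded generators for synthetic observation series.

Every generator is a pure function of its parameters and a seed: the
noiseless output equals the forward model exactly, and observation noise
is applied observation-wise.  The default noise model is 2% multiplicative
log-normal, matching the few-percent scatter of embryo radius and length
measurements; an additive Gaussian model is available for completeness.

The generated tables use the same column schemas as the readers in
:mod:`wormrod.interface`, so synthetic data can be round-tripped through
the full fitting pipeline without touching the file system.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from wormrod.cross_section import SectionGeometry, MaterialMap
from wormrod.early_elongation import (
    MyosinParams, simulate_myosin, ratchet_gain, predict_radius,
    solve_prestrain,
)
from wormrod.late_elongation import CycleSchedule, simulate_late_phase, \
    mutant_scenario
from wormrod.rod_reduction import ActivationState, rod_solve
from wormrod.kinematics import integrate_centerline

__all__ = [
    "NoiseSpec", "gen_early_series", "gen_late_series", "gen_shape_fixture",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Observation-noise model: kind, scale and seed."""

    model: str = "multiplicative_lognormal"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.model not in ("multiplicative_lognormal", "additive_gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")

    def apply(self, values: np.ndarray, rng: np.random.Generator):
        values = np.asarray(values, dtype=float)
        if self.sigma == 0.0:
            return values.copy()
        if self.model == "multiplicative_lognormal":
            return values * rng.lognormal(0.0, self.sigma, values.shape)
        return values + self.sigma * rng.standard_normal(values.shape)


def gen_early_series(params: MyosinParams | None = None,
                     t_grid=None,
                     noise: NoiseSpec | None = None,
                     geom: SectionGeometry | None = None,
                     materials: MaterialMap | None = None) -> pd.DataFrame:
    """Early-phase observation table ``(t_min, lambda, g0_obs, radius_obs_um)``.

    The true trajectory couples the myosin recruitment ODE (``g0(t)``) to
    the ratchet hold balance (``ln lambda = chi (1 - g0)``); the radius
    follows from the layered radial BVP at each ``(lambda, g0)``.  Noise
    is applied to the observed ``g0`` and radius only.
    """
    params = params or MyosinParams()
    noise = noise or NoiseSpec()
    geom = geom or SectionGeometry()
    if t_grid is None:
        t_grid = np.linspace(0.0, 100.0, 21)
    t_grid = np.asarray(t_grid, dtype=float)
    _, Xg, g0 = simulate_myosin(params, t_grid)
    chi = ratchet_gain(params)
    lam = np.exp(chi * Xg)
    radius = np.array([
        predict_radius(float(l), geom, materials, g0=float(gg))
        for l, gg in zip(lam, g0)])
    rng = np.random.default_rng(noise.seed)
    return pd.DataFrame({
        "t_min": t_grid,
        "lambda": lam,
        "g0_obs": noise.apply(g0, rng),
        "radius_obs_um": noise.apply(radius, rng),
    })


def gen_late_series(scenario: str = "wild_type",
                    schedule: CycleSchedule | None = None,
                    noise: NoiseSpec | None = None) -> pd.DataFrame:
    """Late-phase length table ``(t_min, length_obs_um)``.

    The noiseless wild-type series starts at 90 um and increases
    monotonically; ``unc112`` stays flat and ``spc1_pak1`` retracts.
    """
    if scenario not in ("wild_type", "unc112", "spc1_pak1"):
        raise ValueError(f"unknown scenario {scenario!r}")
    schedule = schedule or mutant_scenario(scenario)
    noise = noise or NoiseSpec()
    res = simulate_late_phase(schedule)
    frame = res.to_frame()
    t = np.concatenate([[0.0], frame["t_min"].to_numpy()])
    length = np.concatenate([[schedule.initial_length_um],
                             frame["length_um"].to_numpy()])
    rng = np.random.default_rng(noise.seed)
    return pd.DataFrame({"t_min": t,
                         "length_obs_um": noise.apply(length, rng)})


def gen_shape_fixture(gm: float = -0.02, alpha_a: float = math.pi / 3,
                      ga: float = -0.01, muscle_side: str = "left",
                      with_prestrain: bool = True,
                      n_steps: int = 200):
    """Deterministic deformed-centerline fixture for regression tests.

    Solves the rod reduction at the given activation and integrates the
    centerline at the intrinsic strains.  Returns ``(state, strains)``
    with the centerline sampled over the late-phase reference length.
    """
    if max(abs(gm), abs(ga)) > 0.2:
        raise ValueError("activation magnitudes must satisfy |g| <= 0.2")
    from wormrod.late_elongation import late_geometry, G0_LATE

    geom = late_geometry()
    c = (G0_LATE - 1.0) / geom.eps if with_prestrain else 0.0
    act = ActivationState(gm=gm, ga=ga, alpha_a=alpha_a,
                          muscle_side=muscle_side, c=c)
    _, strains = rod_solve(geom, None, act)
    u_per_um = tuple(u * 1e-6 for u in strains.u_hat)   # 1/m -> 1/um
    state = integrate_centerline(strains.zeta_hat, u_per_um, L=geom.L,
                                 n_steps=n_steps)
    return state, strains
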