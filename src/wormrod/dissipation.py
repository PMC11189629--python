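"""Rotation torque and viscous dissipation estimates.

During the late phase each muscle contraction is accompanied by a partial
rotation of the embryo about its anterior-posterior axis.  The rotation is
driven by the ~6 degree deviation of the muscle sarcomeres from the body
axis at their attachment sites (the dense bodies), whose sarcomere lattice
crosses the horizontal plane at about 45 degrees.  The resisting torque
comes from the interstitial fluid sheared between the embryo and the
eggshell.  All expressions are closed forms evaluated in SI units; inputs
are accepted in the units the biology is reported in (um, mPa s).
"""

from __future__ import annotations

from dataclasses import dataclass
import math
import warnings

__all__ = [
    "RotationEnvironment", "MuscleTorqueParams", "muscle_torque",
    "concentric_viscous_torque", "eccentric_viscous_torque",
    "bending_dissipated_energy", "torque_report",
]

_UM = 1e-6


@dataclass(frozen=True)
class RotationEnvironment:
    """Fluid environment of the rotating embryo.

    Lengths in micrometres, viscosity in Pa s, angular velocity in rad/s.
    ``omega_e`` defaults to pi/4 (a quarter turn, 90 degrees, per 2 s).
    ``Lc`` is the axial extent of the near-contact zone in the eccentric
    (lubrication) estimate and defaults to the eggshell length.
    """

    eta: float = 1.9e-3
    omega_e: float = math.pi / 4
    R: float = 8.2
    L: float = 90.0
    R_egg: float = 15.0
    L_egg: float = 54.0
    delta_gap: float = 0.5
    Lc: float | None = None

    def __post_init__(self) -> None:
        if self.R >= self.R_egg:
            raise ValueError("embryo radius must be smaller than the shell")
        if self.delta_gap <= 0:
            raise ValueError("gap must be positive")
        if self.Lc is None:
            object.__setattr__(self, "Lc", self.L_egg)

    @property
    def d(self) -> float:
        """Axis separation R_egg - delta - R (um) in the eccentric case."""
        return self.R_egg - self.delta_gap - self.R


@dataclass(frozen=True)
class MuscleTorqueParams:
    """Inputs of the active muscle torque estimate.

    ``ag = sin(beta_dev) cos(alpha_cross)`` is the geometric factor that
    projects the sarcomere contraction onto the azimuthal direction.
    """

    mu_muscle: float = 1.0e5        # Pa
    sm: float = 0.025               # area fraction of one muscle pair
    pm: float = 0.75                # radial position / R
    beta_dev: float = math.radians(6.0)
    alpha_cross: float = math.pi / 4
    gm: float = 0.15                # activation magnitude
    eps: float = 11.1 / 50.0        # slenderness of the reference embryo

    def __post_init__(self) -> None:
        for name in ("mu_muscle", "sm", "pm", "beta_dev", "alpha_cross", "eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ag(self) -> float:
        return math.sin(self.beta_dev) * math.cos(self.alpha_cross)


def muscle_torque(params: MuscleTorqueParams, R_um: float = 8.2):
    """Active muscle torque ``Lambda_m = mu_m pi R^3 sm pm ag (eps gm)``.

    Returns
    -------
    (torque, prefactor):
        Torque in N m and the dimensionless prefactor
        ``Lambda_m / (mu_m pi R^3) = sm pm ag eps gm``.
    """
    pref = params.sm * params.pm * params.ag * params.eps * params.gm
    torque = pref * params.mu_muscle * math.pi * (R_um * _UM) ** 3
    return torque, pref


def concentric_viscous_torque(env: RotationEnvironment) -> float:
    """Couette torque on a cylinder rotating coaxially inside the shell.

    ``Lambda_v = 4 pi eta Omega_e L R^2 R_egg^2 / (R_egg^2 - R^2)`` (N m);
    diverges as the embryo fills the shell.
    """
    R, Re = env.R * _UM, env.R_egg * _UM
    L = env.L * _UM
    return 4 * math.pi * env.eta * env.omega_e * L * R**2 * Re**2 / (Re**2 - R**2)


def eccentric_viscous_torque(env: RotationEnvironment) -> float:
    """Small-gap (journal-bearing) torque for an off-axis embryo.

    ``Lambda~_v = 2 sqrt(2) pi eta Omega_e Lc R_egg^2 sqrt(R_egg/delta)
    (R_egg - d)/d`` with ``d = R_egg - delta - R``: the lubrication film of
    thickness ``delta`` dominates and the torque grows like
    ``delta^(-1/2)`` as the embryo presses against the shell.
    """
    delta = env.delta_gap
    if delta <= 0:
        raise ValueError("gap must be positive")
    d = env.d
    if d <= 0:
        raise ValueError("axis separation d = R_egg - delta - R must be > 0")
    if delta > 0.2 * (env.R_egg - env.R):
        warnings.warn("gap is not small compared to the annulus; the "
                      "lubrication asymptotics are out of range",
                      stacklevel=2)
    Re = env.R_egg * _UM
    Lc = env.Lc * _UM
    dm = d * _UM
    return (2.0 * math.sqrt(2.0) * math.pi * env.eta * env.omega_e * Lc
            * Re**2 * math.sqrt(env.R_egg / delta) * (Re - dm) / dm)


def bending_dissipated_energy(torque: float, angle: float) -> float:
    """Energy ``E_diss = 1/2 torque angle^2`` lost in one bending event (J)."""
    if angle < 0:
        raise ValueError("angle must be non-negative")
    return 0.5 * torque * angle**2


def torque_report(params: MuscleTorqueParams | None = None,
                  env: RotationEnvironment | None = None,
                  bend_angle: float = math.pi / 2) -> dict:
    """JSON-ready report of all torque and dissipation estimates."""
    params = params or MuscleTorqueParams()
    env = env or RotationEnvironment()
    lam_m, pref = muscle_torque(params, env.R)
    lam_v = concentric_viscous_torque(env)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lam_ve = eccentric_viscous_torque(env)
    return {
        "muscle_torque_Nm": lam_m,
        "muscle_torque_prefactor": pref,
        "concentric_viscous_torque_Nm": lam_v,
        "eccentric_viscous_torque_Nm": lam_ve,
        "ratio_viscous_over_muscle": lam_v / lam_m,
        "ratio_eccentric_over_concentric": lam_ve / lam_v,
        "dissipated_energy_J": bending_dissipated_energy(lam_m, bend_angle),
        "bend_angle_rad": bend_angle,
    }
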