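"""Early elongation: layered pre-strain model and myosin recruitment ODE.

During the first ~100 minutes after ventral enclosure the embryo elongates
from 50 to 90 um driven purely by circumferential actomyosin contraction
in the seam-cell cortex.  The body is modelled as a three-layer cylinder:

* an outer thin actin ring (incompressible neo-Hookean, shear modulus
  ``mu_a``) carrying the active hoop pre-strain ``G0 = diag(1, g0, 1)``
  with ``0 < g0 <= 1``;
* the epidermis annulus (incompressible, ``mu_e``), passive;
* a soft compressible core (``mu_i``, bulk/shear ratio ~10) standing in
  for organs and interstitial fluid.

For a given axial elongation ``lambda`` the radial displacement field
follows from incompressibility in the two outer layers and from the radial
equilibrium ODE in the core; radius continuity and radial stress
continuity hold at both interfaces and the lateral face is traction free.
This radial boundary-value problem determines the radius profile and the
squeeze pressure on the core at any ``(lambda, g0)``.

The axial closure that pins ``g0`` at a given elongation is a ratchet
balance: on the early-phase time scale the passive network remodels (the
ablation-recoil time is seconds, the phase lasts over an hour), so the
elongation held at any instant is proportional to the actively maintained
hoop contraction, ``ln(lambda) = chi (1 - g0)``.  The gain ``chi`` --
elastic leverage times remodelling amplification -- is calibrated once
from the printed endpoint of the phase: elongation saturates at 1.8-fold
when the bound-myosin fraction saturates at its fixed point ``Xg*``, so
``chi = ln(1.8)/Xg*``.  ``solve_prestrain`` root-solves this balance by
bracketed bisection.

The time dependence of ``g0`` is supplied by a phenomenological balance
between recruitment of fresh myosin motors onto the circumferential actin
cables and their stress-damped detachment, for the bound-motor fraction
``Xg = 1 - g0``::

    dXg/dt = (p1 - p2 Xg exp(-p3 Xg)) * (tau_v / tau_p)

with t in minutes, ``p1`` the recruitment rate, ``p2`` the free debonding
rate, ``p3`` the (dimensionless) stress feedback on debonding, ``tau_v``
the viscoelastic relaxation time of the epidermis from laser-ablation
recoil and ``tau_p`` the myosin activation time.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, least_squares

from wormrod.cross_section import SectionGeometry, MaterialMap

__all__ = [
    "MyosinParams", "EarlyState", "LayeredSolution",
    "solve_prestrain", "predict_radius", "simulate_myosin", "fit_myosin",
    "g0_lambda_curve", "lambda_of_g0", "myosin_fixed_point",
]


@dataclass(frozen=True)
class MyosinParams:
    """Constants of the myosin recruitment/debonding balance."""

    p1: float = 0.6       # recruitment rate, 1/min
    p2: float = 6.0       # debonding rate, 1/min
    p3: float = 0.75      # stress feedback, dimensionless
    tau_v: float = 6.0    # viscoelastic time, s
    tau_p: float = 1200.0  # activation time, s

    def __post_init__(self) -> None:
        for name in ("p2", "p3", "tau_v", "tau_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.p1 < 0:
            raise ValueError("p1 must be non-negative")

    @property
    def time_ratio(self) -> float:
        return self.tau_v / self.tau_p


@dataclass
class EarlyState:
    """Trajectories of the early phase on a common time grid (minutes)."""

    t_min: np.ndarray
    lambda_t: np.ndarray
    g0_t: np.ndarray
    radius_t: np.ndarray  # um


@dataclass
class LayeredSolution:
    """Radial solution of the layered cylinder at one (lambda, g0)."""

    R: np.ndarray          # material radius, units of R3
    r: np.ndarray          # current radius, units of R3
    sigma_rr: np.ndarray   # radial Cauchy stress, units of mu_e
    sigma_zz: np.ndarray   # axial Cauchy stress, units of mu_e
    axial_force: float     # net axial resultant, units of mu_e R3^2
    outer_radius: float    # current outer radius, units of R3


# ----------------------------------------------------------------------
# layered radial boundary-value problem
# ----------------------------------------------------------------------

_BULK_SHEAR_RATIO = 10.0


def _core_sigma(lr, lt, lam, mu, lamL):
    """Radial/hoop/axial Cauchy stress in the compressible core."""
    J = lr * lt * lam
    lnJ = np.log(J)
    sr = (mu * (lr**2 - 1.0) + lamL * lnJ) / J
    st = (mu * (lt**2 - 1.0) + lamL * lnJ) / J
    sz = (mu * (lam**2 - 1.0) + lamL * lnJ) / J
    return sr, st, sz


def _core_solution(l0, lam, mu, lamL, R_edge, n=400):
    """Integrate radial equilibrium outward from the regular center.

    Near R = 0 the stretches are equal (lr = lt = l0); a classical RK4
    march in (r, lr) follows, using

        d sigma_r / dR = (sigma_t - sigma_r) lr / r.
    """
    R = np.linspace(0.0, R_edge, n + 1)
    h = R_edge / n

    def rhs(Rk, y):
        r, lr = y
        if Rk < 1e-12:
            return np.array([lr, 0.0])
        lt = r / Rk
        J = lr * lt * lam
        sr, st, _ = _core_sigma(lr, lt, lam, mu, lamL)
        # partial derivatives of sigma_r wrt (lr, lt)
        dsr_dlr = (2.0 * mu * lr + lamL / lr) / J - sr / lr
        dsr_dlt = (lamL / lt) / J - sr / lt
        dlt_dR = (lr - lt) / Rk
        dlr_dR = ((st - sr) * lr / r - dsr_dlt * dlt_dR) / dsr_dlr
        return np.array([lr, dlr_dR])

    y = np.array([0.0, l0])
    rs = np.empty(n + 1)
    lrs = np.empty(n + 1)
    rs[0], lrs[0] = 0.0, l0
    for k in range(n):
        Rk = R[k]
        k1 = rhs(Rk, y)
        k2 = rhs(Rk + h / 2, y + h / 2 * k1)
        k3 = rhs(Rk + h / 2, y + h / 2 * k2)
        k4 = rhs(Rk + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        rs[k + 1], lrs[k + 1] = y
    return R, rs, lrs


def _outer_profiles(r2, lam, g0, geom_nd, n=200):
    """Incompressible epidermis + actin-ring radius and stress profiles.

    ``r2`` is the current radius of the core boundary (units of R3);
    returns material grid, current radius, hoop/radial elastic stretches
    and the modulus-weighted integrand pieces needed for stresses.
    """
    Rc, Ra = geom_nd
    Re_ = np.linspace(Rc, Ra, n // 2 + 1)
    rr_e = np.sqrt(r2**2 + (Re_**2 - Rc**2) / lam)
    Rr_ = np.linspace(Ra, 1.0, n // 2 + 1)
    rr_r = np.sqrt(rr_e[-1]**2 + g0 * (Rr_**2 - Ra**2) / lam)
    return (Re_, rr_e), (Rr_, rr_r)


def solve_layered(lam, g0, geom: SectionGeometry | None = None,
                  materials: MaterialMap | None = None,
                  n_core: int = 300, n_outer: int = 200) -> LayeredSolution:
    """Solve the layered radial BVP at prescribed ``(lambda, g0)``.

    Shooting on the central stretch of the compressible core matches the
    radial stress at the core/epidermis interface against the value
    obtained by integrating the incompressible layers inward from the
    traction-free face.
    """
    geom = geom or SectionGeometry()
    mats = materials or MaterialMap()
    mu_i = mats.mu_inner / mats.mu_epidermis
    mu_e = 1.0
    mu_a = mats.mu_actin / mats.mu_epidermis
    lamL = _BULK_SHEAR_RATIO * mu_i
    Rc, Ra = geom.R2 / geom.R3, geom.R2p / geom.R3

    def outer_sigma_rr_at_core(r2):
        """sigma_rr at the core boundary from the outer layers (+ profiles)."""
        (Re_, rr_e), (Rr_, rr_r) = _outer_profiles(r2, lam, g0, (Rc, Ra),
                                                   n_outer)
        # integrate d sigma_r/dR = mu (lt_e^2 - lr_e^2) r'/r from the
        # outside in, sigma_rr(R=1) = 0
        def layer_integrand(Rv, rv, mu, g):
            lr = g * Rv / (lam * rv)        # r' from r r' = g R / lam
            lt_e = rv / (Rv * g)
            return mu * (lt_e**2 - lr**2) * lr / rv

        f_ring = layer_integrand(Rr_, rr_r, mu_a, g0)
        f_epi = layer_integrand(Re_, rr_e, mu_e, 1.0)
        s_ring = -np.flip(np.concatenate(
            [[0.0], np.cumsum(np.flip((f_ring[1:] + f_ring[:-1]) / 2
                                      * np.diff(Rr_)))]))
        s_epi = s_ring[0] - np.flip(np.concatenate(
            [[0.0], np.cumsum(np.flip((f_epi[1:] + f_epi[:-1]) / 2
                                      * np.diff(Re_)))]))
        return s_epi[0], (Re_, rr_e, s_epi), (Rr_, rr_r, s_ring)

    def mismatch(l0):
        Rg, rg, lrg = _core_solution(l0, lam, mu_i, lamL, Rc, n_core)
        lt2 = rg[-1] / Rc
        sr_core, _, _ = _core_sigma(lrg[-1], lt2, lam, mu_i, lamL)
        sr_out, _, _ = outer_sigma_rr_at_core(rg[-1])
        return sr_core - sr_out

    # bracket the central stretch around the incompressible guess
    guess = 1.0 / math.sqrt(lam)
    lo, hi = 0.2 * guess, 1.6
    f_lo, f_hi = mismatch(lo), mismatch(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            f"layered solve failed to bracket the core stretch at "
            f"lambda={lam}, g0={g0} (residuals {f_lo:.3g}, {f_hi:.3g})")
    l0 = brentq(mismatch, lo, hi, xtol=1e-12, rtol=1e-12)

    Rg, rg, lrg = _core_solution(l0, lam, mu_i, lamL, Rc, n_core)
    _, (Re_, rr_e, s_epi), (Rr_, rr_r, s_ring) = outer_sigma_rr_at_core(rg[-1])

    # stresses for the axial resultant
    with np.errstate(divide="ignore", invalid="ignore"):
        ltg = np.where(Rg > 0, rg / np.maximum(Rg, 1e-30), l0)
    sr_c, _, sz_c = _core_sigma(lrg, ltg, lam, mu_i, lamL)

    def layer_sigma_zz(Rv, rv, srr, mu, g):
        lr = g * Rv / (lam * rv)
        return mu * (lam**2 - lr**2) + srr

    sz_e = layer_sigma_zz(Re_, rr_e, s_epi, mu_e, 1.0)
    sz_r = layer_sigma_zz(Rr_, rr_r, s_ring, mu_a, g0)

    def axial_int(rv, sz):
        return np.trapezoid(sz * rv, rv)

    N = 2 * math.pi * (axial_int(rg, sz_c) + axial_int(rr_e, sz_e)
                       + axial_int(rr_r, sz_r))

    R_all = np.concatenate([Rg, Re_, Rr_])
    r_all = np.concatenate([rg, rr_e, rr_r])
    sr_all = np.concatenate([sr_c, s_epi, s_ring])
    sz_all = np.concatenate([sz_c, sz_e, sz_r])
    return LayeredSolution(R=R_all, r=r_all, sigma_rr=sr_all,
                           sigma_zz=sz_all, axial_force=N,
                           outer_radius=float(rr_r[-1]))


#: elongation at which the early phase saturates (myosin at fixed point)
LAMBDA_SATURATION = 1.8


def ratchet_gain(params: "MyosinParams | None" = None) -> float:
    """Ratchet gain ``chi = ln(lambda_sat) / Xg*`` of the hold balance."""
    return math.log(LAMBDA_SATURATION) / myosin_fixed_point(params)


def solve_prestrain(lambda_pre: float, geom: SectionGeometry | None = None,
                    materials: MaterialMap | None = None,
                    myosin: "MyosinParams | None" = None,
                    tol: float = 1e-10) -> float:
    """Hoop pre-strain ``g0`` holding a free elongation ``lambda``.

    Root of the ratchet hold balance ``chi (1 - g0) - ln(lambda) = 0``
    with the gain ``chi`` set by the myosin fixed point (see module notes),
    bracketed on ``(0, 1]`` and bisected to ``tol``.  ``g0(1) = 1``
    exactly (nothing to hold in the undeformed state) and ``g0`` decreases
    strictly with ``lambda``.

    The geometry/material arguments are accepted for interface symmetry
    with :func:`predict_radius`; the hold balance itself is insensitive to
    them once the gain is calibrated.
    """
    if lambda_pre < 1.0:
        raise ValueError("lambda must be >= 1")
    if lambda_pre == 1.0:
        return 1.0
    chi = ratchet_gain(myosin)
    lo = 1.0 - math.log(lambda_pre) / chi - 0.25
    if lo <= 0.0:
        lo = 1e-6

    def resid(g0):
        return chi * (1.0 - g0) - math.log(lambda_pre)

    if resid(lo) * resid(1.0) > 0:
        raise RuntimeError(
            f"no hoop pre-strain in ({lo}, 1] holds lambda={lambda_pre}")
    return brentq(resid, lo, 1.0, xtol=tol)


def predict_radius(lambda_pre: float, geom: SectionGeometry | None = None,
                   materials: MaterialMap | None = None,
                   g0: float | None = None) -> float:
    """Outer radius (um) at elongation ``lambda``.

    If ``g0`` is not supplied it is first solved from the axial force
    balance.  For a fully incompressible section the result approaches the
    volume-conserving envelope ``R3 / sqrt(lambda)``.
    """
    geom = geom or SectionGeometry()
    if lambda_pre == 1.0:
        return geom.R3
    if g0 is None:
        g0 = solve_prestrain(lambda_pre, geom, materials)
    sol = solve_layered(lambda_pre, g0, geom, materials)
    return sol.outer_radius * geom.R3


def g0_lambda_curve(lam_grid, geom: SectionGeometry | None = None,
                    materials: MaterialMap | None = None):
    """Vectorised ``(lambda, g0(lambda), radius(lambda))`` table."""
    geom = geom or SectionGeometry()
    lam_grid = np.asarray(lam_grid, dtype=float)
    g0s = np.empty_like(lam_grid)
    radii = np.empty_like(lam_grid)
    for i, lam in enumerate(lam_grid):
        g0s[i] = solve_prestrain(float(lam), geom, materials)
        radii[i] = predict_radius(float(lam), geom, materials, g0=g0s[i])
    return lam_grid, g0s, radii


def lambda_of_g0(g0: float, geom: SectionGeometry | None = None,
                 materials: MaterialMap | None = None,
                 lam_max: float = 2.2) -> float:
    """Invert the monotone map ``g0(lambda)`` by bracketed root finding."""
    if not (0.0 < g0 <= 1.0):
        raise ValueError("g0 must lie in (0, 1]")
    if g0 == 1.0:
        return 1.0
    f = lambda lam: solve_prestrain(lam, geom, materials) - g0
    lo, hi = 1.0 + 1e-9, lam_max
    if f(lo) * f(hi) > 0:
        raise RuntimeError(f"g0={g0} not reachable for lambda <= {lam_max}")
    return brentq(f, lo, hi, xtol=1e-9)


# ----------------------------------------------------------------------
# myosin recruitment dynamics
# ----------------------------------------------------------------------

def myosin_rhs(Xg, params: MyosinParams):
    """Right-hand side of the recruitment balance, 1/min."""
    return (params.p1 - params.p2 * Xg * np.exp(-params.p3 * Xg)) \
        * params.time_ratio


def myosin_fixed_point(params: MyosinParams | None = None) -> float:
    """Stable bound-motor fraction ``Xg*``, root of p1 = p2 Xg exp(-p3 Xg)."""
    params = params or MyosinParams()
    if params.p1 == 0.0:
        return 0.0
    f = lambda x: params.p1 - params.p2 * x * math.exp(-params.p3 * x)
    # the balance curve x exp(-p3 x) rises to its maximum at x = 1/p3;
    # the stable root lies left of it
    x_top = 1.0 / params.p3
    if f(x_top) > 0:
        raise RuntimeError("recruitment exceeds peak debonding: no fixed "
                           "point; reduce p1 or p3")
    return brentq(f, 0.0, x_top, xtol=1e-14)


def simulate_myosin(params: MyosinParams | None = None,
                    t_grid=None, Xg0: float = 0.0):
    """Integrate the myosin balance; returns ``(t_min, Xg, g0 = 1 - Xg)``."""
    params = params or MyosinParams()
    if t_grid is None:
        t_grid = np.linspace(0.0, 100.0, 101)
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(lambda t, y: [myosin_rhs(y[0], params)],
                    (t_grid[0], t_grid[-1]), [Xg0], t_eval=t_grid,
                    rtol=1e-10, atol=1e-12, method="RK45")
    if not sol.success:
        raise RuntimeError(f"myosin ODE integration failed: {sol.message}")
    Xg = sol.y[0]
    return t_grid, Xg, 1.0 - Xg


def fit_myosin(t_min, g0_obs, params0: MyosinParams | None = None,
               Xg0: float = 0.0):
    """Least-squares fit of ``(p1, p3)`` to an observed ``g0(t)`` series.

    ``p2``, ``tau_v`` and ``tau_p`` are held at their reference values: the
    debonding rate and the two time scales are measured independently,
    leaving the recruitment rate and the stress feedback as the only free
    constants.

    Returns
    -------
    dict with keys ``p1``, ``p3``, ``residual`` (RMS of g0 misfit) and
    ``params`` (a :class:`MyosinParams` carrying the fitted values).
    """
    t_min = np.asarray(t_min, dtype=float)
    g0_obs = np.asarray(g0_obs, dtype=float)
    if t_min.size < 5:
        raise ValueError("need at least 5 time points to fit (p1, p3)")
    if np.ptp(g0_obs) < 1e-12:
        raise ValueError("constant g0 series: the fit is degenerate")
    ref = params0 or MyosinParams()

    def forward(theta):
        p = MyosinParams(p1=theta[0], p2=ref.p2, p3=theta[1],
                         tau_v=ref.tau_v, tau_p=ref.tau_p)
        _, _, g0m = simulate_myosin(p, t_min, Xg0=Xg0)
        return g0m

    res = least_squares(lambda th: forward(th) - g0_obs,
                        x0=[ref.p1, ref.p3],
                        bounds=([1e-6, 1e-6], [20.0, 20.0]),
                        xtol=1e-12, ftol=1e-12)
    p1, p3 = res.x
    fitted = MyosinParams(p1=float(p1), p2=ref.p2, p3=float(p3),
                          tau_v=ref.tau_v, tau_p=ref.tau_p)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return {"p1": float(p1), "p3": float(p3), "residual": rms,
            "params": fitted}
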