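"""Asymptotic reduction of the active layered cylinder to an extensible rod.

The embryo is a slender cylinder (slenderness ``eps = R/L``) of
incompressible neo-Hookean material carrying active strains
``G = G0 (I + eps g m⊗m)``.  Expanding the elastic energy in ``eps`` about
the axisymmetric base state and solving the first-order cell problem on
the cross-section turns the 3D energy into the quadratic energy of an
extensible Kirchhoff rod,

    E2 = int_S [ A1 xi + A2 xi^2 + B1 u1 + B2 u1^2
                 + C1 u2 + C2 u2^2 + D1 u3 + D2 u3^2 ] dR dTheta,

with ``xi`` the extension increment and ``(u1, u2, u3)`` the Darboux
components (two bending, one twist).  The quadratic coefficients give the
stiffnesses ``K0..K3``; the coefficients linear in the activations give
the intrinsic loads ``H0..H3`` and hence the spontaneous extension,
curvature and twist of the activated rod.

Cell-problem variants
---------------------
The first-order bending fields are parameterised by the radial-profile
constant ``qa`` (section displacement ``~ qa R^2``) and the pressure
constant ``pb``:

* ``"traction_free"`` -- the exact solution of interior equilibrium,
  pointwise incompressibility *and* zero lateral traction.  It exists in
  closed form for an unstretched reference (``lambda = 1``), where it is
  the classical Saint-Venant bending field (``qa = -1/4``) and reproduces
  the textbook stiffnesses ``EA = 3 mu pi R^2``, ``EI = 3 mu pi R^4/4``
  and ``mu J = mu pi R^4/2`` of an incompressible cylinder.
* ``"interior"`` -- interior equilibrium and incompressibility with a
  Theta-independent first-order pressure (``pb = 0``), which admits the
  closed-form constants ``q1 = (lambda^3 - 2)/8``, ``q2 =
  (2 + 3 lambda^3)/8`` at any axial pre-stretch ``lambda``; the lateral
  traction is then satisfied only on average away from ``lambda = 1``.

The default picks ``traction_free`` at ``lambda = 1`` (the late-phase
reference configuration) and ``interior`` otherwise.

Intrinsic loads are evaluated with the *passive* first-order fields; by
the envelope theorem the activation-induced corrections to the fields do
not change the energy terms linear in activation, so the loads computed
this way are exact to first order in the activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from wormrod import _rod_coeffs as _rc
from wormrod.cross_section import SectionGeometry, MaterialMap, section_nodes

__all__ = [
    "ActivationState", "OrderSolutions", "RodCoefficients",
    "IntrinsicStrains",
    "zeroth_order", "first_order_constants", "order_solutions",
    "second_order_density", "stiffnesses", "intrinsic_loads",
    "intrinsic_strains", "accumulated_energy", "rod_solve",
]

_UM = 1e-6


@dataclass(frozen=True)
class ActivationState:
    """Active strains applied to the section regions.

    ``gm`` acts along the muscle fibers (axial, ``alpha = 0``) of the
    selected ``muscle_side``; ``ga`` acts along the actin bundles of the
    ring at tilt ``alpha_a`` (``pi/2`` = circumferential hoops); ``c`` is
    the maintained hoop pre-strain of the ring on the slow scale,
    ``g0 = 1 + eps c``.  Contractile activations are negative.
    """

    gm: float = 0.0
    ga: float = 0.0
    alpha_a: float = math.pi / 2
    muscle_side: str = "left"        # left | right | both | none
    c: float = 0.0
    lambda_pre: float = 1.0

    def __post_init__(self) -> None:
        if self.muscle_side not in ("left", "right", "both", "none"):
            raise ValueError("muscle_side must be left|right|both|none")
        if not (-math.pi / 2 - 1e-12 <= self.alpha_a <= math.pi / 2 + 1e-12):
            raise ValueError("alpha_a outside [-pi/2, pi/2]")


@dataclass(frozen=True)
class OrderSolutions:
    """Base state and first-order cell-problem solution."""

    lambda_pre: float
    P0: float
    q1: float
    q2: float
    qa: float
    pb: float
    variant: str

    def r0_of_R(self, R):
        """Zeroth-order radial map of the incompressible base state."""
        return np.asarray(R) / math.sqrt(self.lambda_pre)


@dataclass(frozen=True)
class RodCoefficients:
    """Engineering stiffnesses and intrinsic loads of the reduced rod.

    ``K0`` [N] is the extensional stiffness (EA), ``K1``/``K2`` [N m^2]
    the bending stiffnesses about d1/d2, ``K3`` [N m^2] the torsional
    stiffness.  ``H0`` [N] and ``H1..H3`` [N m] are the intrinsic loads;
    they vanish when every activation is zero and satisfy
    ``zeta_hat = 1 - H0/K0``, ``u1_hat = -H1/K1``, ``u2_hat = +H2/K2``,
    ``u3_hat = -H3/K3`` (curvatures per metre).
    """

    K0: float
    K1: float
    K2: float
    K3: float
    H0: float = 0.0
    H1: float = 0.0
    H2: float = 0.0
    H3: float = 0.0
    geom: SectionGeometry | None = None

    def __post_init__(self) -> None:
        if min(self.K0, self.K1, self.K2, self.K3) <= 0:
            raise ValueError("stiffnesses must be positive")


@dataclass(frozen=True)
class IntrinsicStrains:
    """Spontaneous strains of the activated rod.

    ``zeta_hat`` is the dimensionless axial extension; ``u_hat`` the
    intrinsic Darboux components in 1/m; ``kappa_hat``/``tau_hat`` the
    Frenet curvature and torsion of the emerging centerline.
    """

    zeta_hat: float
    u_hat: tuple
    kappa_hat: float = field(init=False)
    tau_hat: float = field(init=False)

    def __post_init__(self) -> None:
        u1, u2, u3 = self.u_hat
        object.__setattr__(self, "kappa_hat", math.hypot(u1, u2))
        object.__setattr__(self, "tau_hat", u3 / self.zeta_hat)


def zeroth_order(lambda_pre: float):
    """Base-state radial map ``r0(R) = R/sqrt(lambda)`` and pressure P0.

    The zeroth-order incompressibility ODE ``r' = R/(lambda r)`` with
    ``r(0) = 0`` integrates to ``r0``; the traction-free lateral boundary
    fixes the uniform Lagrange pressure ``P0 = 1/lambda`` (units of mu).
    """
    if lambda_pre <= 0:
        raise ValueError("lambda must be positive")
    lam = float(lambda_pre)
    return (lambda R: np.asarray(R) / math.sqrt(lam)), 1.0 / lam


def first_order_constants(lambda_pre: float):
    """Interior-equilibrium bending constants ``(q1, q2)``.

    Closed forms ``q1 = (lambda^3 - 2)/8`` and ``q2 = (2 + 3 lambda^3)/8``
    from interior equilibrium plus pointwise incompressibility with a
    Theta-independent first-order pressure.
    """
    if lambda_pre <= 0:
        raise ValueError("lambda must be positive")
    lam3 = lambda_pre**3
    return (lam3 - 2.0) / 8.0, (2.0 + 3.0 * lam3) / 8.0


def order_solutions(lambda_pre: float = 1.0,
                    variant: str | None = None) -> OrderSolutions:
    """Assemble the cell-problem solution for the requested variant."""
    lam = float(lambda_pre)
    q1, q2 = first_order_constants(lam)
    if variant is None:
        variant = "traction_free" if abs(lam - 1.0) < 1e-12 else "interior"
    if variant == "traction_free":
        if abs(lam - 1.0) > 1e-12:
            raise ValueError(
                "the closed-form traction-free cell solution is available "
                "only at lambda = 1; use variant='interior' for a "
                "pre-stretched reference")
        qa = -0.25
        pb = 8.0 * qa / math.sqrt(lam) - lam**1.5 + 2.0 / lam**1.5
    elif variant == "interior":
        qa = q1 / lam            # section profile q1 r0^2 = (q1/lam) R^2
        pb = 0.0
    else:
        raise ValueError(f"unknown cell variant {variant!r}")
    return OrderSolutions(lambda_pre=lam, P0=1.0 / lam, q1=q1, q2=q2,
                          qa=qa, pb=pb, variant=variant)


def second_order_density(strains, point, mu, activation=(0.0, 0.0, 0.0),
                         sol: OrderSolutions | None = None):
    """Second-order energy density ``V2 R`` at one section point.

    Parameters
    ----------
    strains:
        ``(xi, u1, u2, u3)`` rod strains of the nondimensional rod.
    point:
        ``(R, Theta)`` with R in [0, 1].
    mu:
        Local shear modulus.
    activation:
        ``(g, c, alpha)``: local fiber activation, hoop pre-strain rate
        and fiber tilt.
    """
    sol = sol or order_solutions()
    xi, u1, u2, u3 = strains
    R, Th = point
    g, c, alpha = activation
    args = (R, Th, sol.lambda_pre, mu, g, c, alpha, sol.qa, sol.pb)
    vals = {"xi": xi, "u1": u1, "u2": u2, "u3": u3}
    total = 0.0
    for nm, sv in vals.items():
        total = total + getattr(_rc, f"lin_{nm}")(*args) * sv
        total = total + getattr(_rc, f"quad_{nm}_{nm}")(*args) * sv**2
    for ni, nj in (("xi", "u1"), ("xi", "u2"), ("xi", "u3"),
                   ("u1", "u2"), ("u1", "u3"), ("u2", "u3")):
        fn = getattr(_rc, f"quad_{ni}_{nj}", None)
        if fn is not None:
            total = total + fn(*args) * vals[ni] * vals[nj]
    return total


def _nodes(geom: SectionGeometry, n_r: int, n_t: int):
    # the generated coefficients are densities V2*R, so strip the radial
    # Jacobian from the quadrature weights and nondimensionalise by R3
    R, T, W = section_nodes(geom, n_r, n_t)
    return R / geom.R3, T, W / (R * geom.R3)


def stiffnesses(geom: SectionGeometry | None = None,
                materials: MaterialMap | None = None,
                lambda_pre: float = 1.0, variant: str | None = None,
                n_r: int = 24, n_t: int = 24) -> RodCoefficients:
    """Stiffnesses ``K0..K3`` of the heterogeneous section (SI units).

    Twice the integrals of the quadratic energy coefficients over the
    section, weighted by the local shear modulus, scaled to physical units
    with the outer radius: ``K0 ~ mu R3^2`` and ``K1..K3 ~ mu R3^4``.  For
    a homogeneous incompressible section at ``lambda = 1`` they reduce to
    the classical ``3 mu pi R^2``, twice ``3 mu pi R^4/4`` and
    ``mu pi R^4/2``.
    """
    geom = geom or SectionGeometry()
    mats = materials or MaterialMap()
    sol = order_solutions(lambda_pre, variant)
    Rn, Tn, Wn = _nodes(geom, n_r, n_t)
    mu = mats.mu_field(geom, Rn * geom.R3, Tn)
    args = (Rn, Tn, sol.lambda_pre, mu, 0.0, 0.0, 0.0, sol.qa, sol.pb)
    R3m = geom.R3 * _UM
    K0 = 2.0 * np.sum(Wn * _rc.quad_xi_xi(*args)) * R3m**2
    K1 = 2.0 * np.sum(Wn * _rc.quad_u1_u1(*args)) * R3m**4
    K2 = 2.0 * np.sum(Wn * _rc.quad_u2_u2(*args)) * R3m**4
    K3 = 2.0 * np.sum(Wn * _rc.quad_u3_u3(*args)) * R3m**4
    return RodCoefficients(K0=float(K0), K1=float(K1), K2=float(K2),
                           K3=float(K3), geom=geom)


def _activation_fields(geom: SectionGeometry, act: ActivationState, Rn, Tn):
    """Pointwise (g, c, alpha) arrays over the nondimensional nodes."""
    g = np.zeros_like(Rn)
    c = np.zeros_like(Rn)
    alpha = np.zeros_like(Rn)
    Rd = Rn * geom.R3
    ring = Rd >= geom.R2p
    c[ring] = act.c
    if act.ga != 0.0:
        g[ring] = act.ga
        alpha[ring] = act.alpha_a
    if act.gm != 0.0 and act.muscle_side != "none":
        muscle = geom.in_muscle(Rd, Tn)
        if act.muscle_side in ("left", "right"):
            sign = -1.0 if act.muscle_side == "left" else 1.0
            muscle &= sign * np.cos(Tn) > 0
        g = np.where(muscle, act.gm, g)
        alpha = np.where(muscle, 0.0, alpha)
    return g, c, alpha


def nondimensional_minimisers(geom: SectionGeometry,
                              materials: MaterialMap,
                              activation: ActivationState,
                              variant: str | None = None,
                              n_r: int = 24, n_t: int = 24):
    """Energy-minimising nondimensional strains ``(xi*, u1*, u2*, u3*)``."""
    sol = order_solutions(activation.lambda_pre, variant)
    Rn, Tn, Wn = _nodes(geom, n_r, n_t)
    mu = materials.mu_field(geom, Rn * geom.R3, Tn)
    g, c, alpha = _activation_fields(geom, activation, Rn, Tn)
    args = (Rn, Tn, sol.lambda_pre, mu, g, c, alpha, sol.qa, sol.pb)
    out = []
    for nm in ("xi", "u1", "u2", "u3"):
        lin = float(np.sum(Wn * getattr(_rc, f"lin_{nm}")(*args)))
        quad = float(np.sum(Wn * getattr(_rc, f"quad_{nm}_{nm}")(*args)))
        out.append(-lin / (2.0 * quad))
    return tuple(out)


def intrinsic_loads(geom: SectionGeometry | None = None,
                    materials: MaterialMap | None = None,
                    activation: ActivationState | None = None,
                    variant: str | None = None,
                    n_r: int = 24, n_t: int = 24,
                    coeffs: RodCoefficients | None = None) -> RodCoefficients:
    """Intrinsic loads ``H0..H3`` for an activation pattern.

    Integrates the activation-linear energy coefficients over the active
    regions (muscle sectors, actin ring) and packages them with the
    stiffnesses so that the load/stiffness ratios reproduce the physical
    intrinsic strains (axial strain dimensionless, curvatures in 1/m).
    """
    geom = geom or SectionGeometry()
    mats = materials or MaterialMap()
    act = activation or ActivationState()
    K = coeffs or stiffnesses(geom, mats, act.lambda_pre, variant, n_r, n_t)
    xi_h, u1_h, u2_h, u3_h = nondimensional_minimisers(
        geom, mats, act, variant, n_r, n_t)
    eps = geom.eps
    R3m = geom.R3 * _UM
    e_hat = eps * xi_h                        # physical axial strain
    k1 = eps * u1_h / R3m                     # physical curvatures, 1/m
    k2 = eps * u2_h / R3m
    k3 = eps * u3_h / R3m
    return RodCoefficients(K0=K.K0, K1=K.K1, K2=K.K2, K3=K.K3,
                           H0=-K.K0 * e_hat, H1=-K.K1 * k1,
                           H2=+K.K2 * k2, H3=-K.K3 * k3, geom=geom)


def intrinsic_strains(coeffs: RodCoefficients) -> IntrinsicStrains:
    """Intrinsic extension/curvature/twist from load/stiffness ratios.

    ``zeta_hat = 1 - H0/K0``, ``u1_hat = -H1/K1``, ``u2_hat = +H2/K2``,
    ``u3_hat = -H3/K3``; Frenet curvature ``sqrt(u1^2 + u2^2)`` and
    torsion ``u3_hat/zeta_hat``.
    """
    if min(coeffs.K0, coeffs.K1, coeffs.K2, coeffs.K3) <= 0:
        raise ValueError("stiffnesses must be positive")
    zeta = 1.0 - coeffs.H0 / coeffs.K0
    u1 = -coeffs.H1 / coeffs.K1
    u2 = +coeffs.H2 / coeffs.K2
    u3 = -coeffs.H3 / coeffs.K3
    return IntrinsicStrains(zeta_hat=zeta, u_hat=(u1, u2, u3))


def accumulated_energy(coeffs: RodCoefficients,
                       strains: IntrinsicStrains | None = None,
                       L_um: float = 90.0) -> float:
    """Elastic energy (J) stored between the straight and strained rod.

    ``W = L/2 [K0 (zeta-1)^2 + K1 u1^2 + K2 u2^2 + K3 u3^2]`` with
    strains measured from the relaxed straight state.  Evaluated at the
    intrinsic strains this is the energy released when the rod moves from
    straight to its activated shape -- the energy a contraction cycle can
    later convert into elongation.
    """
    st = strains or intrinsic_strains(coeffs)
    L = L_um * _UM
    u1, u2, u3 = st.u_hat
    return 0.5 * L * (coeffs.K0 * (st.zeta_hat - 1.0)**2
                      + coeffs.K1 * u1**2 + coeffs.K2 * u2**2
                      + coeffs.K3 * u3**2)


def rod_solve(geom: SectionGeometry | None = None,
              materials: MaterialMap | None = None,
              activation: ActivationState | None = None,
              variant: str | None = None):
    """One-call reduction: coefficients and intrinsic strains."""
    coeffs = intrinsic_loads(geom, materials, activation, variant)
    return coeffs, intrinsic_strains(coeffs)
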