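# Methods

`wormrod` models the elongating *C. elegans* embryo as a slender,
layered, incompressible neo-Hookean cylinder driven by two active
systems: the circumferential actomyosin of the epidermal seam cells and
the four axial muscle bands beneath the epidermis.  This note records the
model, its assumptions, the numerical choices, and the places where the
design was genuinely open.

## Geometry and active strain

The reference body is a cylinder of radius `R3` and length `L`
(slenderness `eps = R3/L`; 11.1/50 = 0.222 initially, 8.2/90 = 0.091 at
the late-phase onset).  The cross-section is partitioned into a soft core
(`R < R2`, default `0.9 R3`), the epidermis annulus (`R2..R2p`, default
`0.95 R3`), the thin actin ring (`R2p..R3`), and four muscle sectors
embedded in the core at radial position `pm R3 = 0.75 R3`, sized so each
left/right pair occupies the area fraction `sm = 0.025`.  Default shear
moduli are `mu_e = 1e5 Pa`, `mu_i = mu_e/10`, `mu_m = 1e5 Pa`
(an order of magnitude above the core), and `mu_a = 1.83e5 Pa`; the ring
modulus comes from a thin-layer force-balance estimate made once before
any end-to-end run (the layer data of the source are not published), and
all of them are configurable.

Activity is a multiplicative strain `F = Fe G1 G0`.  The early phase
leaves a hoop pre-strain `G0 = diag(1, g0, 1)` in the actin ring, written
`g0 = 1 + eps c` on the slow scale; incremental activity of a fiber
family with unit direction
`m = (sin a sin b, sin a cos b, cos a)` is `G1 = I + eps g m⊗m` with
contractile `g < 0`.  Muscles are axial (`a = b = 0`); actin bundles are
hoops (`a = pi/2`) that tilt to an oblique angle while the muscles bend
the body.  Note `det(G1) = 1 + eps g`: the printed active-strain form is
volumetric at first order, which matters below.

## Dimensional reduction to a rod

The elastic energy `V = mu/2 (tr(Fe Fe^T) - 3) - p (det Fe - 1)` is
expanded in `eps` about the axisymmetric base state (`r0 = R/sqrt(lam)`,
`P0 = mu/lam`).  The deformation gradient is assembled in the rotating
frame (current radial / azimuthal / axial): with the section described by
polar fields `(a1, a2)` and Darboux components `(u1, u2, u3)`, the twist
enters as a uniform azimuthal shear `eps lam u3 a1` and bending as the
linear axial-strain gradient `eps a1 (u1 sin a2 - u2 cos a2)`.  (Writing
the third column in the fixed director frame instead makes the trace
frame-inconsistent and localises the twist coupling in `Theta`, which is
unphysical; this was checked symbolically.)

The first-order cell problem on the section has closed-form solutions:

* extension response `a1^(1) = -r0 xi/2`, pressure `-mu xi/lam` (exact at
  any pre-stretch);
* bending response `a1^(1) = qa R^2 S`, `a2^(1) = (3 qa sqrt(lam) +
  1/sqrt(lam)) R C`, pressure `pb R S`, with `S, C` the first azimuthal
  harmonics.  Interior equilibrium plus pointwise incompressibility leave
  a one-parameter family; the lateral traction conditions close it only
  at `lam = 1`, where `qa = -1/4` reproduces the classical Saint-Venant
  bending field of an incompressible cylinder.  For a pre-stretched
  reference the package uses the interior-equilibrium variant with
  Theta-independent pressure, whose constants are the closed forms
  `q1 = (lam^3 - 2)/8`, `q2 = (2 + 3 lam^3)/8`; its lateral traction
  residual is `O(lam - 1)`.  The default picks the exact variant at
  `lam = 1` and the interior variant otherwise.  All late-phase work is
  done on the post-early reference configuration (`R = 8.2 um`,
  `L = 90 um`, `lam_rod = 1`, hoop memory `c = (g0 - 1)/eps`), where the
  reduction is exact.

The second-order energy density `V2 R = A1 xi + A2 xi^2 + B1 u1 + B2 u1^2
+ C1 u2 + C2 u2^2 + D1 u3 + D2 u3^2` was derived symbolically (sympy;
`scripts/derive_rod_coefficients.py`) and frozen as generated numpy code.
Intrinsic loads use the *passive* first-order fields: by the envelope
theorem the activation-induced field corrections do not enter the energy
terms linear in activation, so the loads are exact to first order in
`g, c` without solving the activation cell problem.  Quadratic-in-
activation (self-energy) terms evaluated this way are a Ritz upper bound;
they only enter the late-phase transfer balance, where the absolute scale
is calibrated anyway.  The generated coefficients are verified in the
test suite against an independent finite-difference expansion of the 3D
energy at random section points, and the stiffness integrals reproduce
the classical `EA = 3 mu pi R^2`, `EI = 3 mu pi R^4/4`,
`mu J = mu pi R^4/2` of a homogeneous incompressible cylinder at
`lam = 1` to better than 1%.

Stiffnesses integrate the quadratic coefficients with the local modulus
over the full section (Gauss-Legendre per radial band x per angular
sector, so no node straddles a material boundary); intrinsic loads
integrate the linear coefficients over the active regions.  Cross
couplings (e.g. extension-bending through the Theta-dependence of the
muscle sectors) integrate to zero for symmetric pair activation and are
neglected otherwise (area fraction 0.025, modulus-weighted effect < 1%).

Consequences used downstream: a left (right) muscle pair produces pure
bending with curvature strictly increasing in the activation magnitude;
four symmetric muscles produce pure axial contraction; a tilted actin
ring produces pure torsion `~ g sin a cos a` with its maximum exactly at
`a = pi/4`; an axisymmetric hoop pre-strain produces *no* net bending and
-- because the printed active strain is volumetric -- *no* first-order
extension load either (the section absorbs a hoop contraction radially;
this is also what a direct compatibility calculation of a ring-activated
incompressible cylinder gives).

## Early elongation

The radial boundary-value problem of the layered cylinder is solved
exactly at any `(lam, g0)`: incompressible area maps in the epidermis and
ring, a compressible neo-Hookean core
(`W = mu/2 (I1 - 3 - 2 ln J) + lamL/2 (ln J)^2`, `lamL = 10 mu_i`)
integrated by an RK4 march with shooting on the central stretch, radius
and radial-stress continuity at both interfaces and zero traction at the
outer face.  This yields the radius prediction (at 1.8-fold: 8.30 um
against the volume-conserving envelope 8.27 um and the observed 8.2 um)
and the squeeze pressure on the core.

Those continuity/traction conditions close the radial problem for *any*
`(lam, g0)`; an axial closure is needed to pin the pre-strain, and a
static axial force balance provably cannot hold an 80% elongation with a
12% hoop pre-strain (the leverage of a hoop eigenstrain on free axial
extension is bounded near unity).  Physically the epidermis remodels on
seconds (the ablation-recoil time is 6 s) while the phase lasts over an
hour, so elongation is a ratchet, not a spring.  The package closes the
system with the ratchet hold balance

    ln(lambda) = chi (1 - g0),

i.e. the elongation held at any instant is proportional to the
bound-myosin fraction `Xg = 1 - g0`.  The gain `chi` is fixed once by the
phase endpoint: elongation saturates at 1.8-fold when `Xg` saturates at
the fixed point of its recruitment dynamics, so `chi = ln(1.8)/Xg*`.
This gives `g0(1) = 1`, a strictly decreasing `g0(lambda)`, and
`g0(1.8) = 0.89`.

Myosin recruitment follows
`dXg/dt = (p1 - p2 Xg exp(-p3 Xg)) tau_v/tau_p` (t in minutes) with
defaults `p1 = 0.6/min`, `p2 = 6/min`, `p3 = 0.75`, `tau_v = 6 s`,
`tau_p = 1200 s`; the stress dependence of debonding is folded into
`p3`.  The fixed point `Xg* = 0.1085` is stable (negative Jacobian), and
only `(p1, p3)` are fit to `g0(t)` observations (trust-region least
squares); the debonding rate and the two times are independently
measured quantities and stay fixed.

## Late elongation

Cycles: 140 min at one contraction per 40 s = 210 contractions,
alternating left/right pairs with `gm = -0.15` and tilted actin
`ga = -0.01` at `pi/4`.  Per cycle the rod reduction gives the intrinsic
strains of the contracted state relative to the hoop background, and the
stored energy `Wc = L/2 sum K_i (Delta s_i)^2`.  On relaxation a fraction
`phi` transfers to the hoop system: the balance
`W_loop(gamma0 + ga1) - W_loop(gamma0) = phi Wc`, with
`W_loop = mu_a V_ring (eps gamma)^2` the thin-ring hoop eigenstrain
energy and `gamma0 = c + ga` the maintained background, determines the
activation increment `ga1` (about -0.011 per cycle).  Because the
background dominates, `ga1` -- and hence the gain -- is nearly linear in
`phi`.  The increment deepens the maintained hoop pre-strain, and the
same ratchet hold balance as in the early phase converts it into a
permanent fractional length gain `chi eps |ga1|`, applied to the current
length.  Activation pattern and section fractions are self-similar along
the phase, so the fractional gain at fixed `phi` is constant and the
length grows geometrically under full conversion:
`90 (1 + 0.5/90)^210 = 288 um`, with per-cycle increments growing from
0.50 to 1.59 um.

One dimensionless energy-scale factor (about 39) anchors the first
full-conversion cycle at the observed 0.5 um and is then frozen for all
scenarios; it absorbs the unknown absolute moduli of the embryonic
layers and cancels from every relative prediction.  The
conversion-efficiency schedule is linear in cycle index from 1.0 to 0.4
by default (sigmoid and piecewise alternatives are configurable); the
wild-type run then ends near 204 um with the per-cycle increment rising
to a mid-phase maximum and falling afterwards.  Mutant scenarios:
`unc112` sets all incremental activations to zero (arrest at 90 um);
`spc1_pak1` lets the early pre-stretch decay exponentially
(0.0025/min default), shrinking the length toward the pre-elongation
value -- net retraction.

## Rotation and dissipation

Closed forms in SI units: active muscle torque
`Lambda_m = mu_m pi R^3 sm pm sin(6 deg) cos(45 deg) eps gm`
(prefactor 4.62e-5 at `eps = 0.222`; the printed value 4.657e-5
back-solves to `eps = 0.224`), concentric Couette torque
`Lambda_v = 4 pi eta Omega_e L R^2 Regg^2/(Regg^2 - R^2)`, and the
small-gap journal-bearing torque
`2 sqrt(2) pi eta Omega_e Lc Regg^2 sqrt(Regg/delta) (Regg - d)/d`
(the package warns when `delta` leaves the asymptotic range).  Defaults:
`eta = 1.9 mPa s`, `Omega_e = pi/4 rad/s` (a quarter turn per 2 s),
`R = 8.2`, `L = 90`, `Regg = 15`, `Legg = Lc = 54`, `delta = 0.5` (um).
`Lambda_v/Lambda_m = 0.020`: rotational drag is negligible at muscle
onset.  One bending event through `pi/2` dissipates
`E_diss = Lambda_m (pi/2)^2 / 2 = 1.0e-14 J`, roughly a tenth of the
calibrated per-cycle energy -- order-of-magnitude agreement with the few
percent the energy budget suggests, which is all the absolute scale
supports.

## Synthetic data

Generators are pure functions of parameters and a seed.  The early-series
generator couples the myosin ODE to the ratchet balance and the layered
radius solve; the late-series generator wraps the cycle simulator; the
shape generator produces deformed centerlines (fixed-step RK4 with
per-step Gram-Schmidt re-orthonormalisation, drift < 1e-9 over 1e4
steps).  Default observation noise is 2% multiplicative log-normal per
observation, matching the few-percent scatter of radius/length
measurements.  At that noise the recruitment rate `p1` is recovered with
~6% median error (50 replicates, n = 20); the feedback exponent `p3` is
essentially unidentified, as expected from its weak effect at
`Xg ~ 0.1`.  What passing tests do *not* show: real embryos have
non-circular sections, spatially heterogeneous activity, measurement
drift and cycle-to-cycle variability none of which the generators
emulate.

## Numerical choices

Bracketed bisection/Brent to 1e-10 for all scalar roots; RK4 with 300
radial steps for the core BVP; section quadrature at 24x24 Gauss-Legendre
nodes per band/sector (the partition constraint holds to 1e-10, stiffness
oracles to 1e-5); myosin ODE via RK45 at rtol 1e-10; degenerate inputs
(zero activation, empty tables, comma decimals, out-of-range angles)
raise explicit errors.  Problem sizes throughout (210 cycles, 500-point
radial grids, 50-replicate recovery studies) keep any single entry point
under a few seconds.

## Known limitations

The traction-exact bending cell solution exists only about an
unstretched reference; pre-stretched sections fall back to the
interior-equilibrium fields.  The ratchet gain is a calibrated
phenomenological constant, not derived from a constitutive remodelling
law; absolute energies inherit the layer-modulus uncertainty through the
single calibrated scale; the eccentric-torque constant `2 sqrt(2) pi`
follows the lubrication asymptotics reading of the printed formula.  The
4% dissipated-to-stored energy figure is reproduced only at the
order-of-magnitude level.
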