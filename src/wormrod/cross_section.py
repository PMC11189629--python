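"""Heterogeneous cross-section geometry and quadrature.

The embryo section is a disk of outer radius ``R3`` partitioned into

* a soft inner core (``0 <= R < R2``) containing internal organs and fluid,
* the epidermis annulus (``R2 <= R < R2p``),
* the thin actin ring (``R2p <= R <= R3``) where circumferential
  actomyosin bundles concentrate, and
* four muscle sectors embedded in the core at radial position
  ``pm * R3``, grouped into a left and a right pair.  Each pair occupies
  an area fraction ``sm`` of the section.

The angular placement of the muscle bands is not measured; by default the
four sector centers sit at ``Theta in {pi/4, 3pi/4, 5pi/4, 7pi/4}`` so that
two bands are dorsal and two ventral, with the "left" pair the two sectors
of negative ``x = R cos(Theta)``.

Quadrature is tensor-product Gauss-Legendre in ``R`` on each radial band
crossed with a periodic composite rule in ``Theta`` split at every sector
boundary, so integrands that are smooth per region are integrated at
spectral accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "SectionGeometry", "MaterialMap", "region_of", "integrate_section",
    "Region",
]

TWO_PI = 2.0 * math.pi

#: region labels
CORE, MUSCLE, EPIDERMIS, ACTIN = "core", "muscle", "epidermis", "actin"
Region = str


@dataclass(frozen=True)
class SectionGeometry:
    """Geometry of the layered embryo cross-section (lengths in um).

    Parameters
    ----------
    R3:
        Outer radius.
    R2p:
        Inner radius of the actin ring.
    R2:
        Inner radius of the epidermis (outer radius of the core).
    L:
        Reference body length.
    sm:
        Area of one muscle pair as a fraction of the full section
        (default 0.025, i.e. 5% of the section for both pairs).
    pm:
        Radial position of the muscle band centers as a fraction of R3.
    muscle_band_halfthickness:
        Radial half-thickness of the muscle band as a fraction of R3.  The
        sector half-width in Theta is then solved so each pair's area
        fraction equals ``sm`` exactly.
    muscle_centers:
        Angular centers of the four muscle sectors (radians).
    """

    R3: float = 11.1
    R2p: float = field(default=None)  # type: ignore[assignment]
    R2: float = field(default=None)  # type: ignore[assignment]
    L: float = 50.0
    sm: float = 0.025
    pm: float = 0.75
    muscle_band_halfthickness: float = 0.05
    muscle_centers: tuple = (math.pi / 4, 3 * math.pi / 4,
                             5 * math.pi / 4, 7 * math.pi / 4)

    def __post_init__(self) -> None:
        if self.R2p is None:
            object.__setattr__(self, "R2p", 0.95 * self.R3)
        if self.R2 is None:
            object.__setattr__(self, "R2", 0.90 * self.R3)
        if not (0.0 < self.R2 < self.R2p < self.R3):
            raise ValueError("need 0 < R2 < R2p < R3")
        if not (0.0 < self.sm < 0.5):
            raise ValueError("sm must lie in (0, 0.5)")
        if not (0.0 < self.pm < 1.0):
            raise ValueError("pm must lie in (0, 1)")
        if len(self.muscle_centers) != 4:
            raise ValueError("exactly four muscle sectors are expected")

    # -- derived muscle-band geometry -------------------------------------
    @property
    def eps(self) -> float:
        """Slenderness R3/L of the reference cylinder."""
        return self.R3 / self.L

    @property
    def muscle_R_inner(self) -> float:
        return (self.pm - self.muscle_band_halfthickness) * self.R3

    @property
    def muscle_R_outer(self) -> float:
        return min((self.pm + self.muscle_band_halfthickness) * self.R3,
                   self.R2)

    @property
    def muscle_sector_halfwidth(self) -> float:
        """Half-width in Theta of one sector, solved from ``sm``.

        Each of the four sectors carries an area ``sm/2 * pi R3^2`` so that
        one left/right *pair* carries the fraction ``sm``.
        """
        band = self.muscle_R_outer**2 - self.muscle_R_inner**2
        hw = self.sm * math.pi * self.R3**2 / (2.0 * band)
        if hw >= math.pi / 4:
            raise ValueError("muscle sectors overlap; thicken the band")
        return hw

    def in_muscle(self, R, Theta):
        """Vectorised membership test for the muscle sectors."""
        R = np.asarray(R, dtype=float)
        Theta = np.asarray(Theta, dtype=float)
        hw = self.muscle_sector_halfwidth
        inband = (R >= self.muscle_R_inner) & (R <= self.muscle_R_outer)
        insect = np.zeros_like(Theta, dtype=bool)
        for c in self.muscle_centers:
            d = np.angle(np.exp(1j * (Theta - c)))
            insect |= np.abs(d) <= hw
        return inband & insect

    def pair_centers(self, side: str) -> tuple:
        """Angular centers of the left (``x<0``) or right (``x>0``) pair."""
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        sign = -1.0 if side == "left" else 1.0
        return tuple(c for c in self.muscle_centers
                     if sign * math.cos(c) > 0)


@dataclass(frozen=True)
class MaterialMap:
    """Shear moduli of the section regions (Pa).

    The absolute scale ``mu = 1e5 Pa`` is the value used in the torque
    estimates; the ratios make the actin ring the stiffest load-bearing
    layer, the core an order of magnitude softer than the epidermis and
    the muscle bands an order of magnitude stiffer than the core.
    """

    mu_epidermis: float = 1.0e5
    mu_actin: float = 1.83e5
    mu_inner: float = 1.0e4
    mu_muscle: float = 1.0e5

    def __post_init__(self) -> None:
        for name in ("mu_epidermis", "mu_actin", "mu_inner", "mu_muscle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_muscle <= self.mu_inner:
            raise ValueError("muscle modulus must exceed the core modulus")

    def mu_of(self, region: Region) -> float:
        return {CORE: self.mu_inner, MUSCLE: self.mu_muscle,
                EPIDERMIS: self.mu_epidermis, ACTIN: self.mu_actin}[region]

    def mu_field(self, geom: SectionGeometry, R, Theta):
        """Vectorised shear modulus mu(R, Theta)."""
        R = np.asarray(R, dtype=float)
        Theta = np.asarray(Theta, dtype=float)
        mu = np.full(np.broadcast(R, Theta).shape, self.mu_inner)
        mu[geom.in_muscle(R, Theta)] = self.mu_muscle
        mu = np.where(R >= geom.R2, self.mu_epidermis, mu)
        mu = np.where(R >= geom.R2p, self.mu_actin, mu)
        return mu


def region_of(point, geom: SectionGeometry) -> Region:
    """Region label for a polar point ``(R, Theta)``.

    Muscle membership wins over the core inside the muscle sectors.
    """
    R, Theta = point
    if R < 0 or R > geom.R3 * (1 + 1e-12):
        raise ValueError(f"R={R} outside the section (R3={geom.R3})")
    if R >= geom.R2p:
        return ACTIN
    if R >= geom.R2:
        return EPIDERMIS
    if bool(geom.in_muscle(R, Theta)):
        return MUSCLE
    return CORE


def _theta_breaks(geom: SectionGeometry):
    hw = geom.muscle_sector_halfwidth
    brk = set()
    for cc in geom.muscle_centers:
        brk.add((cc - hw) % TWO_PI)
        brk.add((cc + hw) % TWO_PI)
    brk |= {0.0}
    return sorted(brk) + [TWO_PI]


def _radial_bands(geom: SectionGeometry):
    edges = sorted({0.0, geom.muscle_R_inner, geom.muscle_R_outer,
                    geom.R2, geom.R2p, geom.R3})
    return list(zip(edges[:-1], edges[1:]))


def section_nodes(geom: SectionGeometry, n_r: int = 12, n_t: int = 12):
    """Quadrature nodes/weights covering the section region by region.

    Returns arrays ``(R, Theta, w)`` with ``sum w f(R,Theta)`` approximating
    ``int f R dR dTheta``; nodes never straddle a region boundary.
    """
    xg, wg = np.polynomial.legendre.leggauss(n_r)
    xt, wt = np.polynomial.legendre.leggauss(n_t)
    Rs, Ts, Ws = [], [], []
    tbreaks = _theta_breaks(geom)
    for (r_lo, r_hi) in _radial_bands(geom):
        rm, rh = 0.5 * (r_lo + r_hi), 0.5 * (r_hi - r_lo)
        rnod = rm + rh * xg
        rwts = rh * wg * rnod  # includes Jacobian R
        for t_lo, t_hi in zip(tbreaks[:-1], tbreaks[1:]):
            tm, th = 0.5 * (t_lo + t_hi), 0.5 * (t_hi - t_lo)
            tnod = tm + th * xt
            twts = th * wt
            Rg, Tg = np.meshgrid(rnod, tnod, indexing="ij")
            Wg = np.outer(rwts, twts)
            Rs.append(Rg.ravel())
            Ts.append(Tg.ravel())
            Ws.append(Wg.ravel())
    return np.concatenate(Rs), np.concatenate(Ts), np.concatenate(Ws)


def integrate_section(f, geom: SectionGeometry, n_r: int = 12, n_t: int = 12,
                      rtol: float = 1e-6, max_refine: int = 6):
    """Integrate ``f(R, Theta)`` over the section, ``int f R dR dTheta``.

    The rule is refined (doubling both directions) until the relative
    change between successive levels drops below ``rtol``.

    Raises
    ------
    RuntimeError
        If refinement stalls before reaching ``rtol``.
    """
    prev = None
    for lev in range(max_refine):
        R, T, W = section_nodes(geom, n_r * 2**lev, n_t * 2**lev)
        val = float(np.sum(W * np.asarray(f(R, T), dtype=float)))
        if prev is not None:
            scale = max(abs(val), abs(prev), 1e-300)
            if abs(val - prev) <= rtol * scale:
                return val
        prev = val
    raise RuntimeError(
        f"section quadrature did not converge to rtol={rtol}; "
        f"last two estimates {prev} (consider raising max_refine)")
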