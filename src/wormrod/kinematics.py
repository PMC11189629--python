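"""Fiber geometry, active strain tensors and centerline reconstruction.

Conventions
-----------
Cylindrical material frame ``(e_R, e_Theta, e_Z)``, right handed, with
``Theta = 0`` on the dorsal midline.  A contractile fiber family is
described by two angles ``alpha`` (tilt away from the axis ``e_Z``) and
``beta`` (tilt of the in-plane component away from ``e_Theta``)::

    m = sin(alpha) sin(beta) e_R + sin(alpha) cos(beta) e_Theta
        + cos(alpha) e_Z

Muscle fibers run axially (``alpha = beta = 0``); the actomyosin bundles
of the epidermis form circumferential hoops (``alpha = pi/2, beta = 0``)
that tilt to an oblique angle ``0 < alpha < pi/2`` while the muscles bend
the body.

Active strains are multiplicative: the total activity tensor is
``G = G0 (I + eps g m⊗m)`` where ``G0 = diag(1, 1 + eps c, 1)`` is the
hoop pre-strain accumulated during early elongation, ``g`` the incremental
(negative, contractile) activation and ``eps`` the slenderness of the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "FiberAngles", "PreStrain", "ActiveTensor", "CenterlineState",
    "fiber_direction", "active_tensor", "integrate_centerline",
    "MUSCLE_ANGLES", "HOOP_ANGLES",
]

_HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class FiberAngles:
    """Orientation of a contractile fiber family.

    Both angles are in radians and restricted to ``[-pi/2, pi/2]``.
    """

    alpha: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        for name, val in (("alpha", self.alpha), ("beta", self.beta)):
            if not (-_HALF_PI - 1e-12 <= val <= _HALF_PI + 1e-12):
                raise ValueError(f"{name}={val} outside [-pi/2, pi/2]")


MUSCLE_ANGLES = FiberAngles(0.0, 0.0)
HOOP_ANGLES = FiberAngles(_HALF_PI, 0.0)


@dataclass(frozen=True)
class PreStrain:
    """Hoop pre-strain ``G0 = diag(1, g0, 1) = diag(1, 1 + eps c, 1)``.

    ``g0`` is the circumferential eigenvalue left in the actin ring by the
    early elongation phase (``g0 = 0.88`` at the 1.8-fold stage), ``c`` its
    order-one counterpart on the slow scale and ``lambda_pre`` the axial
    pre-stretch of the early phase.
    """

    g0: float = 1.0
    c: float | None = None
    lambda_pre: float = 1.0
    eps: float = field(default=0.2)

    def __post_init__(self) -> None:
        if not (0.0 < self.g0 <= 1.0):
            raise ValueError(f"g0={self.g0} outside (0, 1]")
        if self.lambda_pre < 1.0:
            raise ValueError("axial pre-stretch must be >= 1")
        if self.c is None:
            object.__setattr__(self, "c", (self.g0 - 1.0) / self.eps)
        elif abs(self.g0 - (1.0 + self.eps * self.c)) > 1e-12:
            raise ValueError("inconsistent (g0, c): need g0 = 1 + eps*c")

    @property
    def G0(self) -> np.ndarray:
        return np.diag([1.0, self.g0, 1.0])


@dataclass(frozen=True)
class ActiveTensor:
    """A 3x3 active strain tensor in the cylindrical frame (R, Theta, Z)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("active tensor must be 3x3")
        if np.linalg.det(m) <= 0:
            raise ValueError("active tensor must have positive determinant")
        object.__setattr__(self, "matrix", m)

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.matrix))


def fiber_direction(angles: FiberAngles) -> np.ndarray:
    """Unit fiber direction in the ``(e_R, e_Theta, e_Z)`` frame."""
    sa, ca = math.sin(angles.alpha), math.cos(angles.alpha)
    sb, cb = math.sin(angles.beta), math.cos(angles.beta)
    return np.array([sa * sb, sa * cb, ca])


def active_tensor(pre: PreStrain, g: float, eps: float, m: np.ndarray) -> ActiveTensor:
    """Active strain ``G = G0 (I + eps g m⊗m)`` for fiber direction ``m``.

    Parameters
    ----------
    pre:
        Hoop pre-strain ``G0``; use ``PreStrain()`` for none.
    g:
        Dimensionless activation; contractile activity is negative.
    eps:
        Slenderness (radius over length) of the body.
    m:
        Unit fiber direction (e.g. from :func:`fiber_direction`).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    m = np.asarray(m, dtype=float)
    if abs(np.dot(m, m) - 1.0) > 1e-9:
        raise ValueError("fiber direction must be a unit vector")
    G = pre.G0 @ (np.eye(3) + eps * g * np.outer(m, m))
    return ActiveTensor(G)


@dataclass
class CenterlineState:
    """Sampled centerline ``r(Z)`` with director triads.

    ``positions`` has shape (n, 3); ``directors`` shape (n, 3, 3) with
    ``directors[k, i]`` the director ``d_{i+1}`` at sample ``k``.  ``zeta``
    is the uniform axial extension and ``u`` the (possibly Z-dependent)
    Darboux components per unit reference length.
    """

    positions: np.ndarray
    directors: np.ndarray
    zeta: float
    u: np.ndarray
    Z: np.ndarray

    def orthonormality_defect(self) -> float:
        """Largest deviation of any triad from orthonormality."""
        prods = np.einsum("kij,klj->kil", self.directors, self.directors)
        return float(np.max(np.abs(prods - np.eye(3))))

    def arc_length(self) -> float:
        seg = np.diff(self.positions, axis=0)
        return float(np.sum(np.linalg.norm(seg, axis=1)))

    def to_frame(self):
        """Export as a pandas DataFrame (Z, x, y, z, director components)."""
        import pandas as pd

        cols = {"Z": self.Z,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2]}
        for i in range(3):
            for j, ax in enumerate("xyz"):
                cols[f"d{i + 1}{ax}"] = self.directors[:, i, j]
        return pd.DataFrame(cols)


def _gram_schmidt(d: np.ndarray) -> np.ndarray:
    d1 = d[0] / np.linalg.norm(d[0])
    d2 = d[1] - np.dot(d[1], d1) * d1
    d2 /= np.linalg.norm(d2)
    d3 = np.cross(d1, d2)
    return np.array([d1, d2, d3])


def integrate_centerline(zeta, u_of_Z, L: float, n_steps: int = 1000,
                         r0=(0.0, 0.0, 0.0), directors0=None) -> CenterlineState:
    """Reconstruct the centerline from extension and Darboux components.

    Integrates ``d_i'(Z) = zeta u x d_i`` and ``r'(Z) = zeta d_3`` over
    ``Z in [0, L]`` with a fixed-step classical Runge-Kutta scheme; the
    director triad is re-orthonormalised (Gram-Schmidt) after every step so
    frames stay drift-free over many thousands of steps.

    Parameters
    ----------
    zeta:
        Axial extension (dimensionless), constant along the rod.
    u_of_Z:
        Either a length-3 sequence (constant Darboux components
        ``(u1, u2, u3)`` per unit reference length) or a callable
        ``Z -> (u1, u2, u3)``.
    L:
        Reference length of the rod.
    n_steps:
        Number of integration steps (>= 2).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if L <= 0:
        raise ValueError("L must be positive")
    if callable(u_of_Z):
        ufun = lambda Z: np.asarray(u_of_Z(Z), dtype=float)
    else:
        uconst = np.asarray(u_of_Z, dtype=float)
        ufun = lambda Z: uconst

    if directors0 is None:
        D = np.eye(3)
    else:
        D = _gram_schmidt(np.asarray(directors0, dtype=float))

    h = L / n_steps
    Z = np.linspace(0.0, L, n_steps + 1)
    pos = np.empty((n_steps + 1, 3))
    dirs = np.empty((n_steps + 1, 3, 3))
    pos[0] = np.asarray(r0, dtype=float)
    dirs[0] = D

    def rhs(Zk, state):
        r, Dm = state[:3], state[3:].reshape(3, 3)
        uloc = ufun(Zk)
        # Darboux vector in the fixed frame: u_vec = sum u_i d_i
        uvec = uloc @ Dm
        dD = np.array([zeta * np.cross(uvec, Dm[i]) for i in range(3)])
        dr = zeta * Dm[2]
        return np.concatenate([dr, dD.ravel()])

    state = np.concatenate([pos[0], D.ravel()])
    for k in range(n_steps):
        Zk = Z[k]
        k1 = rhs(Zk, state)
        k2 = rhs(Zk + h / 2, state + h / 2 * k1)
        k3 = rhs(Zk + h / 2, state + h / 2 * k2)
        k4 = rhs(Zk + h, state + h * k3)
        state = state + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        Dm = _gram_schmidt(state[3:].reshape(3, 3))
        state[3:] = Dm.ravel()
        pos[k + 1] = state[:3]
        dirs[k + 1] = Dm

    uval = np.array([ufun(z) for z in Z])
    return CenterlineState(positions=pos, directors=dirs, zeta=float(zeta),
                           u=uval, Z=Z)


def export_centerline_csv(state: CenterlineState, path) -> None:
    """Write a centerline as CSV (Z, x, y, z, d1..d3 components)."""
    state.to_frame().to_csv(path, index=False)


def export_centerline_obj(state: CenterlineState, path, radius: float = 1.0,
                          n_around: int = 16) -> None:
    """Write a Wavefront OBJ tube mesh around the centerline."""
    verts = []
    faces = []
    n = len(state.Z)
    for k in range(n):
        c0 = state.positions[k]
        d1, d2 = state.directors[k, 0], state.directors[k, 1]
        for j in range(n_around):
            phi = 2 * math.pi * j / n_around
            verts.append(c0 + radius * (math.cos(phi) * d1 + math.sin(phi) * d2))
    for k in range(n - 1):
        for j in range(n_around):
            a0 = k * n_around + j + 1
            b0 = k * n_around + (j + 1) % n_around + 1
            faces.append((a0, b0, b0 + n_around))
            faces.append((a0, b0 + n_around, a0 + n_around))
    with open(path, "w") as fh:
        fh.write("# wormrod centerline tube\n")
        for v in verts:
            fh.write(f"v {v[0]:.8g} {v[1]:.8g} {v[2]:.8g}\n")
        for f in faces:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")
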