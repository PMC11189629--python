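"""Generated second-order energy coefficients (V2*R).

Auto-generated by the symbolic reduction pipeline in
scripts/derive_rod_coefficients.py; do not edit by hand.
"""
import numpy as np
from numpy import sin, cos, sqrt

def quad_xi_xi(R, Th, lam, mu, g, c, alpha, qa, pb):
    return (1/2)*mu*(R*lam**3 + 2*R)/lam


def quad_xi_u1(R, Th, lam, mu, g, c, alpha, qa, pb):
    return (1/2)*mu*(3*R**2*lam**(9/2)*np.sin(Th) + 3*R**2*lam**(3/2)*np.sin(Th))/lam**3


def quad_xi_u2(R, Th, lam, mu, g, c, alpha, qa, pb):
    return (1/2)*mu*(-3*R**2*lam**(9/2)*np.cos(Th) - 3*R**2*lam**(3/2)*np.cos(Th))/lam**3


def quad_xi_u3(R, Th, lam, mu, g, c, alpha, qa, pb):
    return 0


def quad_u1_u1(R, Th, lam, mu, g, c, alpha, qa, pb):
    return (1/2)*mu*(lam**3*(2*R**3*lam**2*qa*np.sin(Th)**2 + 6*R**3*lam**2*qa*np.cos(Th)**2 + R**3*lam*np.sin(Th)**2 + 2*R**3*lam*np.cos(Th)**2 + 16*R**3*qa**2*np.sin(Th)**2 + 16*R**3*qa**2*np.cos(Th)**2) + lam**2*(6*R**3*qa*np.sin(Th)**2 + 2*R**3*qa*np.cos(Th)**2) + lam*(3*R**3*np.sin(Th)**2 - R**3*np.cos(Th)**2))/lam**3


def quad_u1_u2(R, Th, lam, mu, g, c, alpha, qa, pb):
    return mu*(-4*R**3*lam**2*qa*np.sin(Th)*np.cos(Th) - 4*R**3*lam*np.sin(Th)*np.cos(Th) + lam**3*(4*R**3*lam**2*qa*np.sin(Th)*np.cos(Th) + R**3*lam*np.sin(Th)*np.cos(Th)))/lam**3


def quad_u1_u3(R, Th, lam, mu, g, c, alpha, qa, pb):
    return 0


def quad_u2_u2(R, Th, lam, mu, g, c, alpha, qa, pb):
    return (1/2)*mu*(lam**3*(6*R**3*lam**2*qa*np.sin(Th)**2 + 2*R**3*lam**2*qa*np.cos(Th)**2 + 2*R**3*lam*np.sin(Th)**2 + R**3*lam*np.cos(Th)**2 + 16*R**3*qa**2*np.sin(Th)**2 + 16*R**3*qa**2*np.cos(Th)**2) + lam**2*(2*R**3*qa*np.sin(Th)**2 + 6*R**3*qa*np.cos(Th)**2) + lam*(-R**3*np.sin(Th)**2 + 3*R**3*np.cos(Th)**2))/lam**3


def quad_u2_u3(R, Th, lam, mu, g, c, alpha, qa, pb):
    return 0


def quad_u3_u3(R, Th, lam, mu, g, c, alpha, qa, pb):
    return (1/2)*R**3*lam*mu


def lin_xi(R, Th, lam, mu, g, c, alpha, qa, pb):
    return mu*(-R*g*np.cos(alpha)**2 + lam*(2*R*g*lam**2*np.sin(alpha)**2 - 2*R*g*lam**2))/lam


def lin_u1(R, Th, lam, mu, g, c, alpha, qa, pb):
    return mu*(lam**(3/2)*(4*R**2*c*qa*np.sin(Th) - 4*R**2*g*qa*np.sin(Th)*np.cos(alpha)**2 + 4*R**2*g*qa*np.sin(Th)) + np.sqrt(lam)*(2*R**2*c*np.sin(Th) - 2*R**2*g*np.sin(Th)*np.cos(alpha)**2 + 2*R**2*g*np.sin(Th)) + lam**2*(R**2*c*pb*np.sin(Th) + 2*R**2*g*lam**(3/2)*np.sin(Th)*np.sin(alpha)**2 - 2*R**2*g*lam**(3/2)*np.sin(Th) + R**2*g*pb*np.sin(Th)))/lam**2


def lin_u2(R, Th, lam, mu, g, c, alpha, qa, pb):
    return mu*(lam**(3/2)*(-4*R**2*c*qa*np.cos(Th) + 4*R**2*g*qa*np.cos(Th)*np.cos(alpha)**2 - 4*R**2*g*qa*np.cos(Th)) + np.sqrt(lam)*(-2*R**2*c*np.cos(Th) + 2*R**2*g*np.cos(Th)*np.cos(alpha)**2 - 2*R**2*g*np.cos(Th)) + lam**2*(-R**2*c*pb*np.cos(Th) - 2*R**2*g*lam**(3/2)*np.sin(alpha)**2*np.cos(Th) + 2*R**2*g*lam**(3/2)*np.cos(Th) - R**2*g*pb*np.cos(Th)))/lam**2


def lin_u3(R, Th, lam, mu, g, c, alpha, qa, pb):
    return -2*R**2*g*mu*np.sin(alpha)*np.cos(alpha)


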