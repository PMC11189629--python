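"""Symbolic derivation of the second-order rod-reduction coefficients.

Expands the incompressible neo-Hookean energy of the active slender
cylinder to second order in the slenderness, substitutes the first-order
cell-problem fields (bending profile constant qa, bending pressure
constant pb, exact extension/pressure response), and emits the quadratic
and activation-linear coefficient functions of the rod energy density as
plain numpy code (src/wormrod/_rod_coeffs.py).

Fibers are restricted to beta = 0 (hoop/tilted actin and axial muscle),
the only families the embryo model uses.  The trailing checks verify the
classical stiffness integrals of a homogeneous section at lambda = 1.

Run from the repository root:
    python scripts/derive_rod_coefficients.py
"""
import sympy as sp

R, Th, lam, eps = sp.symbols("R Th lam eps", positive=True)
xi, u1, u2, u3 = sp.symbols("xi u1 u2 u3", real=True)
mu, g, c, al = sp.symbols("mu g c alpha", real=True)
qa, pb = sp.symbols("qa pb", real=True)

r0 = R / sp.sqrt(lam)
S = u1 * sp.sin(Th) - u2 * sp.cos(Th)
C = u1 * sp.cos(Th) + u2 * sp.sin(Th)
s = sp.sqrt(lam)

f1 = -r0 * xi / 2 + qa * R**2 * S
f2 = (3 * qa * s + 1 / s) * R * C
pp = -xi / lam + pb * R * S

a1 = r0 + eps * f1
a2 = Th + eps * f2
lt = lam * (1 + eps * xi)

# rotating-frame components (e_rho, e_phi, d3); a3 = 0
F = sp.Matrix([
    [sp.diff(a1, R), sp.diff(a1, Th) / R, 0],
    [a1 * sp.diff(a2, R), a1 * sp.diff(a2, Th) / R, eps * lt * u3 * a1],
    [0, 0, lt * (1 + eps * (u1 * a1 * sp.sin(a2) - u2 * a1 * sp.cos(a2)))],
])
p = mu * (1 / lam + eps * pp)

m = sp.Matrix([0, sp.sin(al), sp.cos(al)])
G0 = sp.diag(1, 1 + eps * c, 1)
G = G0 * (sp.eye(3) + eps * g * (m * m.T))
Fe = sp.Matrix(F * G.inv())
V = mu / 2 * (sp.trace(Fe * Fe.T) - 3) - p * (Fe.det() - 1)

print("expanding ...", flush=True)
V2 = sp.series(V, eps, 0, 3).removeO().coeff(eps, 2)
V2R = sp.expand(sp.expand_trig(sp.expand(V2 * R)))
print("terms:", len(V2R.args), flush=True)

strains = (xi, u1, u2, u3)
names = {xi: "xi", u1: "u1", u2: "u2", u3: "u3"}
res = {}
for i, si in enumerate(strains):
    for j in range(i, 4):
        sj = strains[j]
        if i == j:
            e = V2R.coeff(si, 2)
            for sk in strains:
                if sk is not si:
                    e = e.subs(sk, 0)
        else:
            e = V2R.coeff(si, 1).coeff(sj, 1)
        e = sp.expand(e)
        if e != 0:
            e = sp.collect(sp.radsimp(e), [mu, g, c])
        res[f"quad_{names[si]}_{names[sj]}"] = e
for si in strains:
    e = V2R.coeff(si, 1)
    for sj in strains:
        e = e.subs(sj, 0)
    e = sp.expand(e)
    if e != 0:
        e = sp.collect(sp.radsimp(e), [mu, g, c])
    res[f"lin_{names[si]}"] = e

with open("src/wormrod/_rod_coeffs.py", "w") as fh:
    fh.write('"""Generated second-order energy coefficients (V2*R).\n\n'
             "Auto-generated by the symbolic reduction pipeline in\n"
             "scripts/derive_rod_coefficients.py; do not edit by hand.\n"
             '"""\nimport numpy as np\n'
             "from numpy import sin, cos, sqrt\n\n")
    for k, v in res.items():
        code = sp.pycode(v).replace("math.", "np.")
        fh.write(f"def {k}(R, Th, lam, mu, g, c, alpha, qa, pb):\n")
        fh.write(f"    return {code}\n\n\n")
print("wrote src/wormrod/_rod_coeffs.py", flush=True)

subs0 = {g: 0, c: 0, mu: 1, lam: 1, qa: -sp.Rational(1, 4), pb: -1}
for key in ("quad_xi_xi", "quad_u1_u1", "quad_u2_u2", "quad_u3_u3"):
    val = sp.integrate(res[key].subs(subs0), (Th, 0, 2 * sp.pi), (R, 0, 1))
    print(key, "->", sp.simplify(val), flush=True)
diag = {f"quad_{n}_{n}" for n in ("xi", "u1", "u2", "u3")}
for k in res:
    if k.startswith("quad") and k not in diag and res[k] != 0:
        val = sp.integrate(res[k].subs(subs0), (Th, 0, 2 * sp.pi), (R, 0, 1))
        print("cross", k, "->", sp.simplify(val), flush=True)
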