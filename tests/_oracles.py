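"""Independent symbolic oracles used by the test suite.

Closed-form pseudo-steady-state rates derived with sympy from the elementary
cycles — a King-Altman reduction independent of the package's numeric solver.
"""

import sympy as sp


def king_altman_uniuni():
    """Reversible Michaelis-Menten rate of the 3-step uni-uni cycle,
    lambdified over (k1..k3, m1..m3, s, p, e_total)."""
    k1, k2, k3, m1, m2, m3, s, p, et = sp.symbols(
        "k1 k2 k3 m1 m2 m3 s p et", positive=True)
    e0, e1, e2 = sp.symbols("e0 e1 e2")
    sol = sp.solve(
        [
            -k1 * s * e0 + m1 * e1 + k3 * e2 - m3 * p * e0,
            k1 * s * e0 - (m1 + k2) * e1 + m2 * e2,
            e0 + e1 + e2 - et,
        ],
        [e0, e1, e2], dict=True)[0]
    v = sp.simplify(k3 * sol[e2] - m3 * p * sol[e0])
    return sp.lambdify((k1, k2, k3, m1, m2, m3, s, p, et), v, "numpy")


def king_altman_ordered_bibi():
    """Symbolic pseudo-steady-state rate of the 5-step ordered bi-bi cycle,
    lambdified over (kp0..kp4, km0..km4, a, b, p, q, e_total)."""
    kp = sp.symbols("kp0:5", positive=True)
    km = sp.symbols("km0:5", positive=True)
    a, b, p, q, et = sp.symbols("a b p q et", positive=True)
    e = sp.symbols("e0:5")
    conc_f = [a, b, 1, 1, 1]
    conc_r = [1, 1, 1, p, q]
    flows = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]
    bal = [sp.Integer(0)] * 5
    for i, (src, tgt) in enumerate(flows):
        f = kp[i] * conc_f[i] * e[src] - km[i] * conc_r[i] * e[tgt]
        bal[src] -= f
        bal[tgt] += f
    eqs = bal[:4] + [sum(e) - et]
    sol = sp.solve(eqs, list(e), dict=True)[0]
    v = kp[4] * sol[e[4]] - km[4] * q * sol[e[0]]
    return sp.lambdify(list(kp) + list(km) + [a, b, p, q, et], v, "numpy")
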