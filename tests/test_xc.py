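"""Exchange-correlation functionals vs an independent symbolic re-derivation.

Each functional's energy density is re-typed here from its literature
definition in sympy, differentiated symbolically, and compared with the
implementation (values and all five potential ingredients) on log-spaced
random densities and gradients.
"""

import numpy as np
import pytest
import sympy as sp

from nearsight.qm import xc

ra_, rb_, gaa_, gab_, gbb_ = sp.symbols("ra rb gaa gab gbb", positive=True)
SYMS = (ra_, rb_, gaa_, gab_, gbb_)


def _slater():
    cx = sp.Rational(3, 2) * (3 / (4 * sp.pi)) ** sp.Rational(1, 3)
    return -cx * (ra_ ** sp.Rational(4, 3) + rb_ ** sp.Rational(4, 3))


def _b88():
    beta = sp.Float("0.0042")

    def term(r, g):
        x = sp.sqrt(g) / r ** sp.Rational(4, 3)
        return -r ** sp.Rational(4, 3) * beta * x**2 / (1 + 6 * beta * x * sp.asinh(x))

    return term(ra_, gaa_) + term(rb_, gbb_)


def _vwn_g(x, A, x0, b, c):
    Q = sp.sqrt(4 * c - b**2)
    X = x**2 + b * x + c
    X0 = x0**2 + b * x0 + c
    return A * (
        sp.log(x**2 / X)
        + 2 * b / Q * sp.atan(Q / (2 * x + b))
        - b * x0 / X0 * (sp.log((x - x0) ** 2 / X) + 2 * (b + 2 * x0) / Q * sp.atan(Q / (2 * x + b)))
    )


def _vwn(variant):
    rho = ra_ + rb_
    x = sp.sqrt((3 / (4 * sp.pi * rho)) ** sp.Rational(1, 3))
    z = (ra_ - rb_) / rho
    f = ((1 + z) ** sp.Rational(4, 3) + (1 - z) ** sp.Rational(4, 3) - 2) / (2 ** sp.Rational(4, 3) - 2)
    if variant == "vwn5":
        eP = _vwn_g(x, sp.Float("0.0310907"), sp.Float("-0.10498"), sp.Float("3.72744"), sp.Float("12.9352"))
        eF = _vwn_g(x, sp.Float("0.01554535"), sp.Float("-0.32500"), sp.Float("7.06042"), sp.Float("18.0578"))
        eA = _vwn_g(x, -1 / (6 * sp.pi**2), sp.Float("-0.00475840"), sp.Float("1.13107"), sp.Float("13.0045"))
        fpp0 = sp.Rational(8, 9) / (2 ** sp.Rational(4, 3) - 2)
        eps = eP + eA * f / fpp0 * (1 - z**4) + (eF - eP) * f * z**4
    else:
        eP = _vwn_g(x, sp.Float("0.0310907"), sp.Float("-0.409286"), sp.Float("13.0720"), sp.Float("42.7198"))
        eF = _vwn_g(x, sp.Float("0.01554535"), sp.Float("-0.743294"), sp.Float("20.1231"), sp.Float("101.578"))
        eps = eP + (eF - eP) * f
    return rho * eps


def _lyp():
    a, b, c, d = [sp.Float(v) for v in ("0.04918", "0.132", "0.2533", "0.349")]
    cf = sp.Rational(3, 10) * (3 * sp.pi**2) ** sp.Rational(2, 3)
    rho = ra_ + rb_
    t = rho ** sp.Rational(-1, 3)
    den = 1 + d * t
    w = sp.exp(-c * t) / den * rho ** sp.Rational(-11, 3)
    delta = c * t + d * t / den
    gt = gaa_ + 2 * gab_ + gbb_
    return -4 * a * ra_ * rb_ / (rho * den) - a * b * w * (
        ra_ * rb_ * (
            2 ** sp.Rational(11, 3) * cf * (ra_ ** sp.Rational(8, 3) + rb_ ** sp.Rational(8, 3))
            + (sp.Rational(47, 18) - sp.Rational(7, 18) * delta) * gt
            - (sp.Rational(5, 2) - delta / 18) * (gaa_ + gbb_)
            - (delta - 11) / 9 * (ra_ * gaa_ + rb_ * gbb_) / rho
        )
        - sp.Rational(2, 3) * rho**2 * gt
        + (sp.Rational(2, 3) * rho**2 - ra_**2) * gbb_
        + (sp.Rational(2, 3) * rho**2 - rb_**2) * gaa_
    )


def _random_points(n=40, seed=7):
    rng = np.random.default_rng(seed)
    return [
        10 ** rng.uniform(-6, 1, n),
        10 ** rng.uniform(-6, 1, n),
        10 ** rng.uniform(-8, 1, n),
        10 ** rng.uniform(-8, 1, n),
        10 ** rng.uniform(-8, 1, n),
    ]


@pytest.mark.parametrize(
    "name,expr_fn,impl,tol",
    [
        ("slater", _slater, xc.slater_x, 1e-12),
        ("b88", _b88, xc.b88_x, 1e-10),
        ("vwn5", _vwn, lambda *a: xc.vwn_c(*a, "vwn5"), 1e-12),
        ("vwn3", _vwn, lambda *a: xc.vwn_c(*a, "vwn3"), 1e-12),
        ("lyp", _lyp, xc.lyp_c, 1e-5),
    ],
)
def test_functional_matches_symbolic_derivatives(name, expr_fn, impl, tol):
    expr = expr_fn(name) if name.startswith("vwn") else expr_fn()
    args = _random_points()
    res = impl(*[a.copy() for a in args])
    lam_e = sp.lambdify(SYMS, expr, "numpy")
    ref_e = np.asarray(lam_e(*args), float)
    assert np.max(np.abs(res.e - ref_e) / (np.abs(ref_e) + 1e-10)) < tol
    for s, mine in zip(SYMS, (res.vra, res.vrb, res.vgaa, res.vgab, res.vgbb)):
        lam = sp.lambdify(SYMS, sp.diff(expr, s), "numpy")
        ref = np.asarray(lam(*args), float) + np.zeros(len(args[0]))
        assert np.max(np.abs(mine - ref) / (np.abs(ref) + 1e-8)) < tol, f"{name} d/d{s}"


def test_b3lyp_mixture_weights():
    """The hybrid combiner is the standard 3-parameter mixture."""
    args = _random_points(10, seed=3)
    total, a_hf = xc.b3lyp(*[a.copy() for a in args])
    assert a_hf == 0.2
    parts = (
        xc.slater_x(*[a.copy() for a in args]).e * 0.8
        + xc.b88_x(*[a.copy() for a in args]).e * 0.72
        + xc.vwn_c(*[a.copy() for a in args], "vwn3").e * 0.19
        + xc.lyp_c(*[a.copy() for a in args]).e * 0.81
    )
    assert np.allclose(total.e, parts, rtol=1e-13)


def test_spin_symmetry_of_closed_shell_potentials():
    rng = np.random.default_rng(0)
    rho = 10 ** rng.uniform(-5, 1, 25)
    g = 10 ** rng.uniform(-6, 1, 25)
    res, _ = xc.b3lyp(rho / 2, rho / 2, g / 4, g / 4, g / 4)
    # LYP's density derivatives are finite-differenced, so the two spin
    # channels agree to FD precision, not machine precision
    assert np.allclose(res.vra, res.vrb, rtol=1e-6, atol=1e-9)
    assert np.allclose(res.vgaa, res.vgbb, rtol=1e-10)
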