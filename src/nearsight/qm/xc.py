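"""Exchange-correlation functionals for the built-in Kohn-Sham engine.

Spin-resolved ingredients of B3LYP: Slater exchange, the B88 gradient
correction, VWN correlation (parametrizations 5 and 3) and LYP.  Each
ingredient maps (rho_a, rho_b, gamma_aa, gamma_ab, gamma_bb) on the
quadrature grid to an energy density per volume plus the potential
ingredients (d e / d rho_sigma and d e / d gamma_*).

Slater, B88 and VWN derivatives are closed-form.  LYP is linear in the
gamma variables, so its gamma-potentials are exact coefficient functions;
its density derivatives are evaluated by tight central differences of the
energy density (step 1e-6 relative; the functional is smooth in rho > 0,
making this accurate to ~1e-11 — far below any SCF-relevant scale).  A
symbolic re-derivation cross-checks every derivative in the test suite.

B3LYP mixing: Exc = 0.2 Ex(HF) + 0.8 Ex(Slater) + 0.72 dEx(B88)
                  + 0.19 Ec(VWN) + 0.81 Ec(LYP),
with the VWN parametrization selectable.  VWN3 is the default: it
reproduces the reference B3LYP orbital energies of the H2/He2 benchmark
systems; VWN5 is the switchable alternative convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["XCResult", "b3lyp", "slater_x", "b88_x", "vwn_c", "lyp_c"]

_RHO_CUT = 1e-11


@dataclass
class XCResult:
    e: np.ndarray  # energy density per volume
    vra: np.ndarray
    vrb: np.ndarray
    vgaa: np.ndarray
    vgab: np.ndarray
    vgbb: np.ndarray

    def __iadd__(self, other: "XCResult") -> "XCResult":
        self.e += other.e
        self.vra += other.vra
        self.vrb += other.vrb
        self.vgaa += other.vgaa
        self.vgab += other.vgab
        self.vgbb += other.vgbb
        return self

    def scaled(self, f: float) -> "XCResult":
        return XCResult(f * self.e, f * self.vra, f * self.vrb, f * self.vgaa, f * self.vgab, f * self.vgbb)


def _zeros_like(ra: np.ndarray) -> XCResult:
    z = np.zeros_like(ra)
    return XCResult(z.copy(), z.copy(), z.copy(), z.copy(), z.copy(), z.copy())


# ------------------------------------------------------------------- exchange

_CX = 1.5 * (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def slater_x(ra, rb, gaa, gab, gbb) -> XCResult:
    out = _zeros_like(ra)
    for rho, vr in ((ra, "vra"), (rb, "vrb")):
        m = rho > _RHO_CUT
        r = rho[m]
        out.e[m] += -_CX * r ** (4.0 / 3.0)
        getattr(out, vr)[m] = -(4.0 / 3.0) * _CX * r ** (1.0 / 3.0)
    return out


_BETA = 0.0042


def b88_x(ra, rb, gaa, gab, gbb) -> XCResult:
    """Becke 1988 gradient correction (the correction only, no Slater part)."""
    out = _zeros_like(ra)
    for rho, gam, vr, vg in ((ra, gaa, "vra", "vgaa"), (rb, gbb, "vrb", "vgbb")):
        m = rho > _RHO_CUT
        r = rho[m]
        g = np.maximum(gam[m], 0.0)
        sg = np.sqrt(g)
        r43 = r ** (4.0 / 3.0)
        x = sg / r43
        ash = np.arcsinh(x)
        D = 1.0 + 6.0 * _BETA * x * ash
        F = _BETA * x * x / D
        dF = _BETA * (2.0 * x * D - x * x * 6.0 * _BETA * (ash + x / np.sqrt(1.0 + x * x))) / D**2
        out.e[m] += -r43 * F
        getattr(out, vr)[m] += -(4.0 / 3.0) * r ** (1.0 / 3.0) * (F - x * dF)
        vgv = np.where(sg > 1e-14, -dF / (2.0 * np.maximum(sg, 1e-300)), 0.0)
        getattr(out, vg)[m] += vgv
    return out


# ---------------------------------------------------------------- correlation

# VWN G-function parameters: (A, x0, b, c)
_VWN5_P = (0.0310907, -0.10498, 3.72744, 12.9352)
_VWN5_F = (0.01554535, -0.32500, 7.06042, 18.0578)
_VWN5_A = (-1.0 / (6.0 * math.pi**2), -0.00475840, 1.13107, 13.0045)
_VWN3_P = (0.0310907, -0.409286, 13.0720, 42.7198)
_VWN3_F = (0.01554535, -0.743294, 20.1231, 101.578)


def _vwn_g(x, par):
    A, x0, b, c = par
    Q = math.sqrt(4.0 * c - b * b)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    at = np.arctan(Q / (2.0 * x + b))
    g = A * (
        np.log(x * x / X)
        + 2.0 * b / Q * at
        - b * x0 / X0 * (np.log((x - x0) ** 2 / X) + 2.0 * (b + 2.0 * x0) / Q * at)
    )
    Xp = 2.0 * x + b
    datdx = -2.0 * Q / (Xp * Xp + Q * Q)
    dg = A * (
        2.0 / x
        - Xp / X
        + 2.0 * b / Q * datdx
        - b * x0 / X0 * (2.0 / (x - x0) - Xp / X + 2.0 * (b + 2.0 * x0) / Q * datdx)
    )
    return g, dg


def _spin_interp(z):
    f = ((1.0 + z) ** (4.0 / 3.0) + (1.0 - z) ** (4.0 / 3.0) - 2.0) / (2.0 ** (4.0 / 3.0) - 2.0)
    df = (4.0 / 3.0) * ((1.0 + z) ** (1.0 / 3.0) - (1.0 - z) ** (1.0 / 3.0)) / (2.0 ** (4.0 / 3.0) - 2.0)
    return f, df


def vwn_c(ra, rb, gaa, gab, gbb, variant: str = "vwn3") -> XCResult:
    """VWN local correlation; ``variant`` 'vwn5' (full) or 'vwn3' (P/F only)."""
    out = _zeros_like(ra)
    rho = ra + rb
    m = rho > _RHO_CUT
    r = rho[m]
    z = np.clip((ra[m] - rb[m]) / r, -1.0 + 1e-15, 1.0 - 1e-15)
    rs = (3.0 / (4.0 * math.pi * r)) ** (1.0 / 3.0)
    x = np.sqrt(rs)
    if variant == "vwn5":
        ep, dep = _vwn_g(x, _VWN5_P)
        ef, def_ = _vwn_g(x, _VWN5_F)
        ea, dea = _vwn_g(x, _VWN5_A)
        f, df = _spin_interp(z)
        fpp0 = 8.0 / (9.0 * (2.0 ** (4.0 / 3.0) - 2.0))
        z4 = z**4
        eps = ep + ea * f / fpp0 * (1.0 - z4) + (ef - ep) * f * z4
        deps_drs = (dep + dea * f / fpp0 * (1.0 - z4) + (def_ - dep) * f * z4) / (2.0 * x)
        deps_dz = ea / fpp0 * (df * (1.0 - z4) - 4.0 * z**3 * f) + (ef - ep) * (df * z4 + 4.0 * z**3 * f)
    elif variant == "vwn3":
        ep, dep = _vwn_g(x, _VWN3_P)
        ef, def_ = _vwn_g(x, _VWN3_F)
        f, df = _spin_interp(z)
        eps = ep + (ef - ep) * f
        deps_drs = (dep + (def_ - dep) * f) / (2.0 * x)
        deps_dz = (ef - ep) * df
    else:
        raise ValueError(f"unknown VWN variant {variant!r}")
    out.e[m] = r * eps
    # v_sigma = eps + rho * (deps/drs * drs/drho + deps/dz * dz/drho_sigma)
    common = eps - rs / 3.0 * deps_drs
    out.vra[m] = common + deps_dz * (1.0 - z)
    out.vrb[m] = common - deps_dz * (1.0 + z)
    return out


_LYP_A = 0.04918
_LYP_B = 0.132
_LYP_C = 0.2533
_LYP_D = 0.349
_CF = 0.3 * (3.0 * math.pi**2) ** (2.0 / 3.0)


def _lyp_parts(ra, rb):
    """Density-dependent pieces of LYP: scalar term and gamma coefficients.

    Returns (e_scalar, caa, cab, cbb) with
    e = e_scalar + caa*gaa + cab*gab + cbb*gbb.
    """
    rho = ra + rb
    t = rho ** (-1.0 / 3.0)
    den = 1.0 + _LYP_D * t
    w = np.exp(-_LYP_C * t) / den * rho ** (-11.0 / 3.0)
    delta = _LYP_C * t + _LYP_D * t / den
    ab = _LYP_A * _LYP_B
    e_scalar = -4.0 * _LYP_A * ra * rb / (rho * den) - ab * w * ra * rb * (
        2.0 ** (11.0 / 3.0) * _CF * (ra ** (8.0 / 3.0) + rb ** (8.0 / 3.0))
    )
    # coefficient of |grad rho|^2 = gaa + 2 gab + gbb
    ct = ra * rb * (47.0 - 7.0 * delta) / 18.0 - (2.0 / 3.0) * rho * rho
    # spin-resolved extras on top of the |grad rho|^2 coefficient
    caa = ct - ra * rb * ((2.5 - delta / 18.0) + (delta - 11.0) / 9.0 * ra / rho) + (2.0 / 3.0) * rho * rho - rb * rb
    cbb = ct - ra * rb * ((2.5 - delta / 18.0) + (delta - 11.0) / 9.0 * rb / rho) + (2.0 / 3.0) * rho * rho - ra * ra
    cab = 2.0 * ct
    return e_scalar, -ab * w * caa, -ab * w * cab, -ab * w * cbb


def lyp_c(ra, rb, gaa, gab, gbb) -> XCResult:
    """Lee-Yang-Parr correlation (gradient-transformed closed form)."""
    out = _zeros_like(ra)
    rho = ra + rb
    m = rho > _RHO_CUT
    a = np.maximum(ra[m], 0.0)
    b = np.maximum(rb[m], 0.0)
    Gaa, Gab, Gbb = gaa[m], gab[m], gbb[m]

    def energy(x, y):
        es, caa, cab, cbb = _lyp_parts(x, y)
        return es + caa * Gaa + cab * Gab + cbb * Gbb

    es, caa, cab, cbb = _lyp_parts(a, b)
    out.e[m] = es + caa * Gaa + cab * Gab + cbb * Gbb
    out.vgaa[m] = caa
    out.vgab[m] = cab
    out.vgbb[m] = cbb
    # central differences in the densities (LYP is smooth for rho > 0)
    ha = 1e-6 * np.maximum(a, 1e-8)
    hb = 1e-6 * np.maximum(b, 1e-8)
    out.vra[m] = (energy(a + ha, b) - energy(np.maximum(a - ha, 0.0), b)) / (ha + np.minimum(a, ha))
    out.vrb[m] = (energy(a, b + hb) - energy(a, np.maximum(b - hb, 0.0))) / (hb + np.minimum(b, hb))
    return out


# -------------------------------------------------------------------- mixers


def b3lyp(ra, rb, gaa, gab, gbb, vwn_variant: str = "vwn3") -> tuple[XCResult, float]:
    """B3LYP semilocal part; returns (XCResult, HF-exchange fraction 0.2)."""
    out = slater_x(ra, rb, gaa, gab, gbb).scaled(0.8)
    out += b88_x(ra, rb, gaa, gab, gbb).scaled(0.72)
    out += vwn_c(ra, rb, gaa, gab, gbb, vwn_variant).scaled(0.19)
    out += lyp_c(ra, rb, gaa, gab, gbb).scaled(0.81)
    return out, 0.2


FUNCTIONALS = {
    "b3lyp": b3lyp,
    "hf": None,  # pure Hartree-Fock: no semilocal part, full exact exchange
}
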