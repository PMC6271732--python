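"""Gaussian basis set data for the elements this package computes with.

Exponents/coefficients are the standard published values (coefficients are
for unit-normalized primitives).  SP shells of the Pople sets are stored as
separate s and p shells sharing exponents.  Only H, He and C are shipped:
every molecule treated here (H2, He2, He2(2+), butane, butadiene, and
user-supplied hydrocarbon-like demos) is covered.

Layout: BASIS_SETS[name][element] = list of (l, [(exponent, coefficient), ...]).
"""

from __future__ import annotations

_STO3G = {
    "H": [
        (0, [(3.42525091, 0.15432897), (0.62391373, 0.53532814), (0.16885540, 0.44463454)]),
    ],
    "He": [
        (0, [(6.36242139, 0.15432897), (1.15892300, 0.53532814), (0.31364979, 0.44463454)]),
    ],
    "C": [
        (0, [(71.6168370, 0.15432897), (13.0450960, 0.53532814), (3.53051220, 0.44463454)]),
        (0, [(2.94124940, -0.09996723), (0.68348310, 0.39951283), (0.22228990, 0.70011547)]),
        (1, [(2.94124940, 0.15591627), (0.68348310, 0.60768372), (0.22228990, 0.39195739)]),
    ],
}

_H_631G = [
    (0, [(18.7311370, 0.03349460), (2.82539370, 0.23472695), (0.64012170, 0.81375733)]),
    (0, [(0.16127780, 1.0)]),
]
_HE_631G = [
    (0, [(38.4216340, 0.02376600), (5.77803000, 0.15467900), (1.24177400, 0.46963000)]),
    (0, [(0.29796400, 1.0)]),
]
_C_631G = [
    (0, [(3047.52490, 0.00183470), (457.369510, 0.01403730), (103.948690, 0.06884260),
         (29.2101550, 0.23218440), (9.28666300, 0.46794130), (3.16392700, 0.36231200)]),
    (0, [(7.86827240, -0.11933240), (1.88128850, -0.16085420), (0.54424930, 1.14345640)]),
    (1, [(7.86827240, 0.06899910), (1.88128850, 0.31642400), (0.54424930, 0.74430830)]),
    (0, [(0.16871440, 1.0)]),
    (1, [(0.16871440, 1.0)]),
]

_631G = {"H": _H_631G, "He": _HE_631G, "C": _C_631G}

# 6-31G*: d polarization on heavy atoms; 6-31G**: additionally p on H/He
_631G_STAR = {
    "H": _H_631G,
    "He": _HE_631G,
    "C": _C_631G + [(2, [(0.8, 1.0)])],
}
_631G_STARSTAR = {
    "H": _H_631G + [(1, [(1.1, 1.0)])],
    "He": _HE_631G + [(1, [(1.1, 1.0)])],
    "C": _631G_STAR["C"],
}

BASIS_SETS = {
    "sto-3g": _STO3G,
    "6-31g": _631G,
    "6-31g*": _631G_STAR,
    "6-31g**": _631G_STARSTAR,
}

ATOMIC_NUMBERS = {"H": 1, "He": 2, "C": 6}

#: radial scale (bohr) used only to place quadrature points, per element
GRID_RADII = {"H": 1.0, "He": 0.6, "C": 1.4}
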