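"""Reference geometries (Angstrom) for the systems studied here.

Diatomics are placed along z with the midpoint at the origin.  Butane
(anti) and s-trans butadiene are built from standard bond lengths and
angles via an internal-coordinate (z-matrix) constructor; their role is
comparative (saturated vs pi-conjugated carbon chain), not spectroscopic.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["h2", "he2", "butane", "butadiene", "zmatrix_place"]


def h2(r: float = 0.72) -> list:
    """Hydrogen molecule at bond length ``r`` (Angstrom)."""
    return [("H", np.array([0.0, 0.0, -r / 2])), ("H", np.array([0.0, 0.0, r / 2]))]


def he2(r: float = 3.0) -> list:
    """Helium dimer (charge set separately) at separation ``r`` (Angstrom)."""
    return [("He", np.array([0.0, 0.0, -r / 2])), ("He", np.array([0.0, 0.0, r / 2]))]


def zmatrix_place(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta: float, phi: float) -> np.ndarray:
    """Position D with bond C-D = r, angle B-C-D = theta, dihedral A-B-C-D = phi.

    Angles in degrees; the standard natural-extension construction.
    """
    th = math.radians(theta)
    ph = math.radians(phi)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * math.cos(th), r * math.sin(th) * math.cos(ph), r * math.sin(th) * math.sin(ph)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build(zmat) -> list:
    """zmat rows: (element, ref_c, r, ref_b, theta, ref_a, phi); refs 0-based."""
    atoms: list = []
    for row in zmat:
        el = row[0]
        if len(atoms) == 0:
            pos = np.zeros(3)
        elif len(atoms) == 1:
            pos = atoms[row[1]][1] + np.array([0.0, 0.0, row[2]])
        elif len(atoms) == 2:
            c = atoms[row[1]][1]
            b = atoms[row[3]][1]
            # in-plane placement; dummy out-of-plane reference
            a = b + np.array([1.0, 0.0, 0.0])
            pos = zmatrix_place(a, b, c, row[2], row[4], 0.0)
        else:
            pos = zmatrix_place(atoms[row[5]][1], atoms[row[3]][1], atoms[row[1]][1], row[2], row[4], row[6])
        atoms.append((el, pos))
    return atoms


def butane() -> list:
    """n-butane, anti conformer; C-C 1.530 A, CCC 112 deg, C-H ~1.095 A."""
    cc, ch, ccc, hch = 1.530, 1.095, 112.0, 109.5
    z = [
        ("C",),
        ("C", 0, cc),
        ("C", 1, cc, 0, ccc),
        ("C", 2, cc, 1, ccc, 0, 180.0),
        # methyl on C1
        ("H", 0, ch, 1, 110.5, 2, 60.0),
        ("H", 0, ch, 1, 110.5, 2, 180.0),
        ("H", 0, ch, 1, 110.5, 2, 300.0),
        # methylene on C2
        ("H", 1, ch, 0, hch, 2, 121.5),
        ("H", 1, ch, 0, hch, 2, 238.5),
        # methylene on C3
        ("H", 2, ch, 3, hch, 1, 121.5),
        ("H", 2, ch, 3, hch, 1, 238.5),
        # methyl on C4
        ("H", 3, ch, 2, 110.5, 1, 60.0),
        ("H", 3, ch, 2, 110.5, 1, 180.0),
        ("H", 3, ch, 2, 110.5, 1, 300.0),
    ]
    return _build(z)


def butadiene() -> list:
    """s-trans 1,3-butadiene, planar; C=C 1.338 A, C-C 1.454 A."""
    cd, cs, ch = 1.338, 1.454, 1.090
    z = [
        ("C",),
        ("C", 0, cd),
        ("C", 1, cs, 0, 123.6),
        ("C", 2, cd, 1, 123.6, 0, 180.0),
        # terminal CH2 on C1
        ("H", 0, ch, 1, 121.0, 2, 0.0),
        ("H", 0, ch, 1, 121.0, 2, 180.0),
        # vinyl H on C2 and C3 (cis to the distal double bond, anti to the chain)
        ("H", 1, ch, 2, 116.0, 3, 0.0),
        ("H", 2, ch, 1, 116.0, 0, 0.0),
        # terminal CH2 on C4
        ("H", 3, ch, 2, 121.0, 1, 0.0),
        ("H", 3, ch, 2, 121.0, 1, 180.0),
    ]
    return _build(z)
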