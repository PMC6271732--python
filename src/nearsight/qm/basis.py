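"""Contracted cartesian Gaussian shells and AO evaluation on point grids.

Conventions:

* coordinates in bohr internally; the public molecule API speaks Angstrom;
* cartesian components, ordered (for d) xx, yy, zz, xy, xz, yz — the Molden
  cartesian order;
* every AO (each cartesian component) is unit-normalized.  Contraction
  coefficients are stored against primitives normalized for the (l,0,0)
  component; the per-component correction sqrt((2l-1)!! / prod (2li-1)!!)
  is applied on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .basis_data import ATOMIC_NUMBERS, BASIS_SETS

ANGSTROM = 0.529177210903  # bohr -> Angstrom

CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}


def _df(n: int) -> int:
    """(n)!! with (-1)!! = 1."""
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def primitive_norm(l: int, a: float) -> float:
    """Norm of the (l,0,0) cartesian primitive with exponent a."""
    return (2.0 * a / math.pi) ** 0.75 * (4.0 * a) ** (l / 2.0) / math.sqrt(_df(2 * l - 1))


def component_norm_ratio(lx: int, ly: int, lz: int) -> float:
    l = lx + ly + lz
    return math.sqrt(_df(2 * l - 1) / (_df(2 * lx - 1) * _df(2 * ly - 1) * _df(2 * lz - 1)))


@dataclass(frozen=True)
class Shell:
    """One contracted shell: all cartesian components of angular momentum l."""

    atom: int
    l: int
    exps: np.ndarray
    coefs: np.ndarray  # raw contraction coefficients (unit-normalized primitives)
    center: np.ndarray  # bohr

    @property
    def ncart(self) -> int:
        return len(CART_COMPONENTS[self.l])

    def normalized_coefs(self) -> np.ndarray:
        """Coefficients times primitive norms, rescaled so the contracted
        (l,0,0) component has unit self-overlap."""
        c = self.coefs * np.array([primitive_norm(self.l, a) for a in self.exps])
        # contracted self-overlap of the (l,0,0) component
        aa = self.exps[:, None] + self.exps[None, :]
        s = (math.pi / aa) ** 1.5 * _df(2 * self.l - 1) / (2.0 * aa) ** self.l
        norm2 = float(c @ s @ c)
        return c / math.sqrt(norm2)


@dataclass(frozen=True)
class BasisSet:
    """Ordered shells; AO index runs shell by shell, cartesian-major."""

    shells: list[Shell]
    name: str = "custom"

    @property
    def nao(self) -> int:
        return sum(sh.ncart for sh in self.shells)

    def ao_shell_map(self) -> list[tuple[int, int]]:
        """(shell index, component index) for every AO."""
        out = []
        for i, sh in enumerate(self.shells):
            out.extend((i, c) for c in range(sh.ncart))
        return out

    # ---- flat arrays for the numba integral kernels ----
    def flat(self):
        ls, nprim, ptr, atom = [], [], [], []
        exps, coefs = [], []
        centers = []
        p = 0
        for sh in self.shells:
            ls.append(sh.l)
            nprim.append(len(sh.exps))
            ptr.append(p)
            atom.append(sh.atom)
            exps.extend(sh.exps.tolist())
            coefs.extend(sh.normalized_coefs().tolist())
            centers.append(sh.center)
            p += len(sh.exps)
        return (
            np.array(ls, dtype=np.int64),
            np.array(nprim, dtype=np.int64),
            np.array(ptr, dtype=np.int64),
            np.array(exps),
            np.array(coefs),
            np.array(centers),
        )

    def evaluate(self, points: np.ndarray, deriv: bool = False):
        """AO values (npts, nao); with ``deriv`` also gradients (npts, nao, 3).

        Vectorized over points per shell; fast enough for the XC quadrature
        and cube grids used here.
        """
        npts = points.shape[0]
        nao = self.nao
        vals = np.empty((npts, nao))
        grads = np.empty((npts, nao, 3)) if deriv else None
        iao = 0
        for sh in self.shells:
            d = points - sh.center  # (npts, 3)
            r2 = np.einsum("pi,pi->p", d, d)
            cn = sh.normalized_coefs()
            rad = np.zeros(npts)
            drad = np.zeros(npts)  # d(radial)/d(r2)
            for a, c in zip(sh.exps, cn):
                e = c * np.exp(-a * r2)
                rad += e
                drad += -a * e
            for lx, ly, lz in CART_COMPONENTS[sh.l]:
                f = component_norm_ratio(lx, ly, lz)
                ang = d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz
                vals[:, iao] = f * ang * rad
                if deriv:
                    for k, lk in enumerate((lx, ly, lz)):
                        term = 2.0 * d[:, k] * drad * ang
                        if lk > 0:
                            # lowered angular factor, recomputed to stay clean
                            # at nodal planes (no 0/0)
                            pw = [lx, ly, lz]
                            pw[k] -= 1
                            pang = d[:, 0] ** pw[0] * d[:, 1] ** pw[1] * d[:, 2] ** pw[2]
                            term = term + lk * pang * rad
                        grads[:, iao, k] = f * term
                iao += 1
        return (vals, grads) if deriv else vals


def build_basis(atoms: list[tuple[str, np.ndarray]], name: str) -> BasisSet:
    """Assemble a BasisSet for atoms given as (element, position in bohr)."""
    key = name.lower()
    if key not in BASIS_SETS:
        raise KeyError(f"unknown basis set {name!r}; available: {sorted(BASIS_SETS)}")
    table = BASIS_SETS[key]
    shells = []
    for ia, (el, pos) in enumerate(atoms):
        if el not in table:
            raise KeyError(f"basis {name!r} has no data for element {el!r}")
        for l, prims in table[el]:
            e = np.array([p[0] for p in prims])
            c = np.array([p[1] for p in prims])
            shells.append(Shell(atom=ia, l=l, exps=e, coefs=c, center=np.asarray(pos, float)))
    return BasisSet(shells=shells, name=key)


def nuclear_charges(atoms) -> np.ndarray:
    return np.array([ATOMIC_NUMBERS[el] for el, _ in atoms], dtype=float)


def nuclear_repulsion(atoms) -> float:
    """Point-charge repulsion; atom positions in bohr."""
    z = nuclear_charges(atoms)
    e = 0.0
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            rij = np.linalg.norm(np.asarray(atoms[i][1]) - np.asarray(atoms[j][1]))
            e += z[i] * z[j] / rij
    return e
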