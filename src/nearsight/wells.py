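"""One-dimensional model potentials and their exact eigenstates.

Three confining potentials are supported:

* infinite square well on ``[0, L]`` — closed-form sine states;
* harmonic oscillator — Hermite functions evaluated by the stable
  three-term recurrence;
* symmetric double well — hard walls at the ends of ``domain``, a flat
  barrier of height ``V0`` on ``barrier``, solved by parity-resolved
  transcendental matching at the barrier edge.

Energies are reported in one of two unit conventions: ``hbar_me_1``
(hbar = electron mass = 1, so a free wave exp(ikr) has E = k^2/2) or
``hbar2_over_2me_1`` (hbar^2/2m = 1, E = k^2).  The double-well pair
census depends on the convention; both are first-class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "WellSpec",
    "Eigenstate",
    "Spectrum",
    "PairCensus",
    "isw_states",
    "ho_states",
    "dw_states",
    "count_pairs_below_barrier",
]

Units = Literal["hbar_me_1", "hbar2_over_2me_1"]

#: kinetic prefactor c in E = c * k^2 for each unit convention
_KINETIC = {"hbar_me_1": 0.5, "hbar2_over_2me_1": 1.0}


class InvalidSpecError(ValueError):
    """A well specification violates its invariants."""


class SolverError(RuntimeError):
    """Eigenvalue matching failed (bracketing or refinement)."""


@dataclass(frozen=True)
class WellSpec:
    """Definition of a 1D confining potential.

    Parameters not relevant to ``kind`` are ignored (e.g. ``V0`` for the
    square well).
    """

    kind: Literal["infinite_square_well", "double_well", "harmonic"]
    L: float = 1.0
    domain: tuple[float, float] = (-2.0, 2.0)
    barrier: tuple[float, float] = (-1.0, 1.0)
    V0: float = 25.0
    omega: float = 1.0
    units: Units = "hbar_me_1"

    def __post_init__(self) -> None:
        if self.kind not in ("infinite_square_well", "double_well", "harmonic"):
            raise InvalidSpecError(f"unknown well kind {self.kind!r}")
        if self.units not in _KINETIC:
            raise InvalidSpecError(f"unknown unit convention {self.units!r}")
        if self.kind == "infinite_square_well" and not self.L > 0:
            raise InvalidSpecError("square well width L must be positive")
        if self.kind == "harmonic" and not self.omega > 0:
            raise InvalidSpecError("harmonic omega must be positive")
        if self.kind == "double_well":
            a, b = self.domain
            p, q = self.barrier
            if not (a < p < q < b):
                raise InvalidSpecError("barrier must lie strictly inside domain")
            if not math.isclose(a, -b) or not math.isclose(p, -q):
                raise InvalidSpecError("double well must be symmetric about 0")
            if self.V0 < 0:
                raise InvalidSpecError("barrier height V0 must be nonnegative")

    @property
    def kinetic_factor(self) -> float:
        return _KINETIC[self.units]

    def potential(self, r: np.ndarray) -> np.ndarray:
        """U(r) inside the hard walls (walls themselves are implicit)."""
        r = np.asarray(r, dtype=float)
        if self.kind == "harmonic":
            return 0.5 * self.omega**2 * r**2
        if self.kind == "double_well":
            p, q = self.barrier
            return np.where((r >= p) & (r <= q), self.V0, 0.0)
        return np.zeros_like(r)

    def support(self) -> tuple[float, float]:
        """Interval on which eigenstates are (numerically) supported."""
        if self.kind == "infinite_square_well":
            return (0.0, self.L)
        if self.kind == "double_well":
            return self.domain
        # harmonic: effectively infinite; callers pick a box from the energies
        return (-np.inf, np.inf)


@dataclass(frozen=True)
class Eigenstate:
    """A single normalized bound state.  Callable: ``psi(r)``."""

    n: int
    energy: float
    parity: Literal["symmetric", "antisymmetric", "none"]
    below_barrier: bool | None
    _evaluate: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def __call__(self, r) -> np.ndarray:
        return self._evaluate(np.asarray(r, dtype=float))


@dataclass(frozen=True)
class Spectrum:
    """Energy-ordered eigenstates of one :class:`WellSpec`."""

    spec: WellSpec
    states: tuple[Eigenstate, ...]

    @property
    def nmax(self) -> int:
        return len(self.states)

    @property
    def energies(self) -> np.ndarray:
        return np.array([s.energy for s in self.states])

    def evaluate_all(self, r: np.ndarray) -> np.ndarray:
        """Matrix psi[n, k] = psi_n(r_k) for all states.

        Harmonic spectra share one recurrence sweep; a per-state loop would
        cost O(nmax^2) recurrence steps.
        """
        r = np.asarray(r, dtype=float)
        if self.spec.kind == "harmonic":
            s = math.sqrt(self.spec.omega)
            return _hermite_functions(s * r, self.nmax) * math.sqrt(s)
        return np.array([s(r) for s in self.states])

    def quadrature_domain(self, pad: float = 4.0) -> tuple[float, float]:
        """Finite interval containing (numerically) all state amplitude."""
        lo, hi = self.spec.support()
        if np.isfinite(lo):
            return (lo, hi)
        # harmonic: classical turning point of the top state, padded
        e_top = self.states[-1].energy
        r_turn = math.sqrt(2.0 * e_top / self.spec.omega**2)
        return (-r_turn - pad, r_turn + pad)

    def gram(self, npts: int = 4001) -> np.ndarray:
        """Trapezoid Gram matrix on a uniform grid (orthonormality check)."""
        lo, hi = self.quadrature_domain()
        r = np.linspace(lo, hi, npts)
        psi = self.evaluate_all(r)
        w = np.full(npts, (hi - lo) / (npts - 1))
        w[0] = w[-1] = 0.5 * w[0]
        return (psi * w) @ psi.T

    def to_table(self) -> np.ndarray:
        """Structured export: columns (n, energy, parity code, below_barrier)."""
        code = {"symmetric": 1, "antisymmetric": -1, "none": 0}
        return np.array(
            [
                (s.n, s.energy, code[s.parity], -1 if s.below_barrier is None else int(s.below_barrier))
                for s in self.states
            ]
        )


# ----------------------------------------------------------------- square well


def isw_states(L: float = 1.0, nmax: int = 1, units: Units = "hbar_me_1") -> Spectrum:
    """Particle-in-a-box states psi_n(r) = sqrt(2/L) sin(n pi r / L) on [0, L].

    E_n = c (n pi / L)^2 with c the kinetic factor of ``units``.
    """
    if not L > 0 or nmax < 1:
        raise InvalidSpecError("require L > 0 and nmax >= 1")
    spec = WellSpec(kind="infinite_square_well", L=L, units=units)
    c = spec.kinetic_factor
    states = []
    for n in range(1, nmax + 1):
        k = n * math.pi / L

        def ev(r, k=k, L=L):
            out = math.sqrt(2.0 / L) * np.sin(k * r)
            return np.where((r >= 0) & (r <= L), out, 0.0)

        states.append(Eigenstate(n, c * k * k, "none", None, ev))
    return Spectrum(spec, tuple(states))


# ------------------------------------------------------------------- harmonic


def _hermite_functions(x: np.ndarray, nmax: int) -> np.ndarray:
    """phi[n, k], n = 0..nmax-1: orthonormal Hermite functions at x.

    Stable normalized recurrence:
    phi_{n+1} = x sqrt(2/(n+1)) phi_n - sqrt(n/(n+1)) phi_{n-1}.
    """
    out = np.zeros((nmax, x.size))
    out[0] = math.pi ** (-0.25) * np.exp(-0.5 * x * x)
    if nmax > 1:
        out[1] = math.sqrt(2.0) * x * out[0]
    for n in range(1, nmax - 1):
        out[n + 1] = x * math.sqrt(2.0 / (n + 1)) * out[n] - math.sqrt(n / (n + 1.0)) * out[n - 1]
    return out


def ho_states(omega: float = 1.0, nmax: int = 1) -> Spectrum:
    """Harmonic-oscillator states, E_n = omega (n - 1/2) for 1-based n.

    Only the ``hbar_me_1`` convention is meaningful here (mass enters the
    potential).  Evaluation uses the normalized recurrence, stable far past
    n = 60; a hard cap guards against silent overflow.
    """
    if not omega > 0:
        raise InvalidSpecError("omega must be positive")
    if nmax < 1:
        raise InvalidSpecError("nmax must be >= 1")
    if nmax > 5000:
        raise InvalidSpecError(f"nmax={nmax} exceeds the supported range (5000)")
    spec = WellSpec(kind="harmonic", omega=omega)
    s = math.sqrt(omega)
    states = []
    for n in range(1, nmax + 1):

        def ev(r, n=n, s=s):
            # scaled coordinate; recompute the recurrence up to n (cheap, exact)
            val = _hermite_functions(s * r, n)[n - 1] * math.sqrt(s)
            if not np.all(np.isfinite(val)):
                raise SolverError(f"harmonic state n={n} overflowed")
            return val

        states.append(Eigenstate(n, omega * (n - 0.5), "symmetric" if n % 2 else "antisymmetric", None, ev))
    return Spectrum(spec, tuple(states))


def ho_states_matrix(spectrum: Spectrum, r: np.ndarray) -> np.ndarray:
    """Fast path: evaluate every harmonic state of ``spectrum`` at once."""
    spec = spectrum.spec
    s = math.sqrt(spec.omega)
    return _hermite_functions(s * np.asarray(r, float), spectrum.nmax) * math.sqrt(s)


# ----------------------------------------------------------------- double well


def _dw_pieces(E: float, V0: float, c: float, parity: str):
    """Inner (barrier) solution value/derivative, regular at r=0.

    Wavenumbers: outer q = sqrt(E/c); barrier kappa = sqrt((V0-E)/c) when
    E < V0 (hyperbolic), k = sqrt((E-V0)/c) when E > V0 (trigonometric).
    Forms are scaled to stay continuous across E = V0.
    """
    if E < V0:
        kap = math.sqrt((V0 - E) / c)
        if parity == "symmetric":
            f = lambda r: np.cosh(kap * r)
            df = lambda r: kap * np.sinh(kap * r)
        else:
            # sinh(kap r)/kap -> r as kap -> 0
            f = lambda r: np.sinh(kap * r) / kap if kap > 1e-12 else np.asarray(r, float)
            df = lambda r: np.cosh(kap * r) if kap > 1e-12 else np.ones_like(np.asarray(r, float))
    else:
        k = math.sqrt((E - V0) / c)
        if parity == "symmetric":
            f = lambda r: np.cos(k * r)
            df = lambda r: -k * np.sin(k * r)
        else:
            f = lambda r: np.sin(k * r) / k if k > 1e-12 else np.asarray(r, float)
            df = lambda r: np.cos(k * r) if k > 1e-12 else np.ones_like(np.asarray(r, float))
    return f, df


def _dw_det(E: float, spec: WellSpec, parity: str) -> float:
    """Matching determinant at the right barrier edge; zero at eigenvalues.

    Outer solution (satisfies psi(b)=0 at the hard wall r=b):
    psi_o(r) = sin(q (b - r)) / q (scaled for continuity near E=0).
    """
    c = spec.kinetic_factor
    b = spec.domain[1]
    q_edge = spec.barrier[1]
    if E <= 0:
        return float("nan")
    q = math.sqrt(E / c)
    f, df = _dw_pieces(E, spec.V0, c, parity)
    po = math.sin(q * (b - q_edge)) / q
    dpo = -math.cos(q * (b - q_edge))
    return float(f(q_edge) * dpo - df(q_edge) * po)


def _dw_find_roots(spec: WellSpec, parity: str, n_roots: int) -> list[float]:
    """Scan the matching determinant for sign changes and refine by brentq."""
    c = spec.kinetic_factor
    width = spec.domain[1] - spec.domain[0]
    # ISW(width) level spacing as a scan-scale estimate
    e1 = c * (math.pi / width) ** 2
    roots: list[float] = []
    e_lo = 1e-9
    step = 0.01 * e1
    f_lo = _dw_det(e_lo, spec, parity)
    e = e_lo
    # adaptive upper bound: keep scanning until enough roots
    while len(roots) < n_roots:
        e_next = e + step
        f_next = _dw_det(e_next, spec, parity)
        if np.isfinite(f_lo) and np.isfinite(f_next) and f_lo * f_next < 0:
            try:
                root = brentq(_dw_det, e, e_next, args=(spec, parity), xtol=1e-12, rtol=1e-15)
            except ValueError as exc:  # pragma: no cover - defensive
                raise SolverError(
                    f"bracketing failed for {parity} parity in energy window ({e:.6g}, {e_next:.6g})"
                ) from exc
            roots.append(float(root))
        e, f_lo = e_next, f_next
        # grow the step with sqrt(E) (level spacing of a box grows linearly in n)
        step = 0.01 * e1 * max(1.0, math.sqrt(e / e1))
        if e > 1e7 * e1:  # pragma: no cover - defensive
            raise SolverError(f"could not bracket {n_roots} {parity} roots below E={e:.3g}")
    return roots


def _dw_eigenstate(E: float, spec: WellSpec, parity: str, n: int) -> Eigenstate:
    c = spec.kinetic_factor
    b = spec.domain[1]
    edge = spec.barrier[1]
    q = math.sqrt(E / c)
    f, df = _dw_pieces(E, spec.V0, c, parity)
    # amplitude of the outer branch fixed by continuity at the barrier edge
    po = math.sin(q * (b - edge)) / q
    f_edge = float(f(edge))
    if abs(po) >= abs(f_edge):
        a_in, a_out = 1.0, f_edge / po if po != 0 else 0.0
    else:
        a_in, a_out = po / f_edge, 1.0

    sgn = 1.0 if parity == "symmetric" else -1.0

    def raw(r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        ra = np.abs(r)
        inner = ra <= edge
        outer = (ra > edge) & (ra <= b)
        out[inner] = a_in * f(ra[inner])
        out[outer] = a_out * np.sin(q * (b - ra[outer])) / q
        neg = r < 0
        out[neg] *= sgn
        return out

    # piecewise Gauss-Legendre normalization (smooth integrands, near machine precision)
    norm2 = 0.0
    for lo, hi in ((0.0, edge), (edge, b)):
        x, w = np.polynomial.legendre.leggauss(80)
        rr = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
        norm2 += 0.5 * (hi - lo) * np.sum(w * raw(rr) ** 2)
    norm2 *= 2.0  # symmetric about 0
    scale = 1.0 / math.sqrt(norm2)

    def ev(r, raw=raw, scale=scale):
        return scale * raw(r)

    return Eigenstate(n, E, parity, bool(E < spec.V0), ev)


def dw_states(spec: WellSpec, nmax: int = 1) -> Spectrum:
    """Double-well eigenstates by parity-resolved transcendental matching.

    Symmetric states satisfy psi'(0)=0, antisymmetric psi(0)=0; both are
    trigonometric in the outer wells, hyperbolic (E < V0) or trigonometric
    (E > V0) in the barrier, matched in value and slope at the barrier edge
    and pinned to zero at the hard walls.
    """
    if spec.kind != "double_well":
        raise InvalidSpecError("dw_states requires kind='double_well'")
    if nmax < 1:
        raise InvalidSpecError("nmax must be >= 1")
    n_half = nmax // 2 + 2
    roots = [(e, "symmetric") for e in _dw_find_roots(spec, "symmetric", n_half)]
    roots += [(e, "antisymmetric") for e in _dw_find_roots(spec, "antisymmetric", n_half)]
    # energy order; symmetric first on (never-occurring) exact ties
    roots.sort(key=lambda t: (t[0], 0 if t[1] == "symmetric" else 1))
    states = tuple(
        _dw_eigenstate(E, spec, parity, n + 1) for n, (E, parity) in enumerate(roots[:nmax])
    )
    return Spectrum(spec, states)


# ---------------------------------------------------------------- pair census


@dataclass(frozen=True)
class PairCensus:
    """Quasi-degenerate (symmetric, antisymmetric) pairs below the barrier."""

    n_pairs: int
    splittings: tuple[float, ...]  # Delta E of each counted pair, in order

    def __int__(self) -> int:
        return self.n_pairs


def count_pairs_below_barrier(spectrum: Spectrum) -> PairCensus:
    """Count consecutive (symmetric, antisymmetric) pairs entirely below V0.

    No splitting threshold is applied; recorded splittings let callers apply
    their own quasi-degeneracy cut.
    """
    if spectrum.spec.kind != "double_well":
        raise InvalidSpecError("pair census is defined for double-well spectra only")
    states = spectrum.states
    n_pairs = 0
    splittings: list[float] = []
    for i in range(0, len(states) - 1, 2):
        s, a = states[i], states[i + 1]
        if s.parity == "symmetric" and a.parity == "antisymmetric" and s.below_barrier and a.below_barrier:
            n_pairs += 1
            splittings.append(a.energy - s.energy)
        else:
            break
    return PairCensus(n_pairs, tuple(splittings))
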