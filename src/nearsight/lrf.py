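"""Sum-over-states linear response kernels and nearsightedness metrics.

The static, independent-particle linear response function of a system of
spin-paired electrons filling the lowest ``nocc`` orbitals is

    K(r, r') = p * sum_{i occ} sum_{j virt} psi_i(r) psi_j(r) psi_i(r') psi_j(r')
                                             / (eps_i - eps_j)

with a convention-dependent positive prefactor ``p`` (default 4: the
closed-shell factor 2 times the 2 orderings of the real orbital pair).
Every term is a negative rank-1 operator, so K is symmetric, negative
semidefinite, and each column integrates to zero (particle conservation).

The virtual sum is truncated per occupied orbital: term (i, m) is dropped
once the double-space integral of its square,

    (2 * int psi_i^2 psi_m^2 dr)^2 / (eps_i - eps_m)^2,

falls below a threshold ``tau`` (default 1e-8).  The factor in the
criterion is the closed-shell 2, independent of the kernel's display
prefactor, which pins the truncation index to the documented brute-force
enumeration (square well, i=1: M_truncated = 64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .wells import Spectrum

__all__ = [
    "TruncationRule",
    "LRFMatrix",
    "LocalityMetrics",
    "truncation_limit",
    "lrf_matrix",
    "response_slice",
    "locality_metrics",
    "region_column_l1",
    "friedel_reference",
]

#: factor entering the squared truncation criterion (closed-shell 2, squared)
_TRUNC_FACTOR = 2.0


class TruncationNotConvergedError(RuntimeError):
    pass


class DegenerateDenominatorError(RuntimeError):
    pass


@dataclass(frozen=True)
class TruncationRule:
    """Virtual-sum cutoff: drop term (i, m) once its squared integral < tau."""

    tau: float = 1e-8
    jmax_cap: int = 2000

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class LRFMatrix:
    """Discretized kernel K[i, j] ~ drho(r_i)/dv(r_j) with truncation metadata."""

    grid: np.ndarray
    values: np.ndarray
    nocc: int
    m_truncated: tuple[int, ...]
    prefactor: float

    @property
    def weights(self) -> np.ndarray:
        """Trapezoid quadrature weights on the (uniform) grid."""
        h = self.grid[1] - self.grid[0]
        w = np.full(self.grid.size, h)
        w[0] = w[-1] = 0.5 * h
        return w

    def column_at(self, r_prime: float) -> tuple[int, np.ndarray]:
        idx = int(np.argmin(np.abs(self.grid - r_prime)))
        return idx, self.values[:, idx]


@dataclass(frozen=True)
class LocalityMetrics:
    """Scalar summaries of how nearsighted a kernel is.

    ``offrange_mass``: fraction of the weighted sum of |K| with |r-r'| > d.
    ``zero_sum_residual``: worst column |int K dr| (particle conservation).
    ``column_l1``: int |K(r, r'_j)| dr for every column j.
    """

    d: float
    offrange_mass: float
    zero_sum_residual: float
    column_l1: np.ndarray

    def as_dict(self) -> dict:
        return {
            "d": self.d,
            "offrange_mass": self.offrange_mass,
            "zero_sum_residual": self.zero_sum_residual,
            "column_l1_max": float(np.max(self.column_l1)),
        }


def default_grid(spectrum: Spectrum, nocc: int, points_per_unit: int = 401) -> np.ndarray:
    """Uniform kernel grid covering the occupied-orbital support.

    For hard-walled wells this is the full box.  For the harmonic
    oscillator the box is cut at the top occupied state's classical turning
    point plus a generous tail pad — high virtuals reach much further, but
    every kernel term carries an occupied factor that kills it out there.
    """
    spec = spectrum.spec
    if spec.kind == "harmonic":
        e_occ = spec.omega * (nocc - 0.5)
        half = math.sqrt(2.0 * e_occ) / spec.omega + 6.0 / math.sqrt(spec.omega)
        lo, hi = -half, half
    else:
        lo, hi = spec.support()
    n = max(2, int(round((hi - lo) * points_per_unit)) + 1)
    return np.linspace(lo, hi, n)


def _term_integrals(psi: np.ndarray, w: np.ndarray, i_occ: int, js: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Truncation-criterion values for occupied i_occ against virtuals js (0-based)."""
    dens_i = psi[i_occ] ** 2
    overlap = (psi[js] ** 2 * (dens_i * w)).sum(axis=1)  # int psi_i^2 psi_j^2 dr
    de = energies[i_occ] - energies[js]
    return (_TRUNC_FACTOR * overlap) ** 2 / de**2


def truncation_limit(
    spectrum: Spectrum,
    i_occ: int,
    nocc: int,
    rule: TruncationRule = TruncationRule(),
    grid: np.ndarray | None = None,
) -> int:
    """Smallest virtual index m (1-based) whose term falls below ``rule.tau``.

    The kernel sum for occupied orbital ``i_occ`` then runs over virtuals
    nocc+1 .. m.  The first virtual is always admissible, so the result is
    at least nocc+1.
    """
    if not (1 <= i_occ <= nocc <= spectrum.nmax):
        raise ValueError("require 1 <= i_occ <= nocc <= nmax")
    if rule.jmax_cap <= nocc:
        raise ValueError("jmax_cap must exceed nocc")
    if grid is None:
        grid = default_grid(spectrum, nocc)
    w = _trapz_weights(grid)
    psi = spectrum.evaluate_all(grid)
    energies = spectrum.energies
    top = min(spectrum.nmax, rule.jmax_cap)
    js = np.arange(nocc, top)  # 0-based virtual indices
    vals = _term_integrals(psi, w, i_occ - 1, js, energies)
    below = np.nonzero(vals < rule.tau)[0]
    if below.size == 0:
        if top < rule.jmax_cap:
            raise TruncationNotConvergedError(
                f"spectrum holds only {spectrum.nmax} states; last term integral "
                f"{vals[-1]:.3e} still >= tau={rule.tau:.1e} for i={i_occ}"
            )
        raise TruncationNotConvergedError(
            f"jmax_cap={rule.jmax_cap} reached for i={i_occ}; last term integral {vals[-1]:.3e}"
        )
    m = int(js[below[0]]) + 1  # 1-based state index whose term dipped below tau
    return max(m, nocc + 1)


def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    h = grid[1] - grid[0]
    w = np.full(grid.size, h)
    w[0] = w[-1] = 0.5 * h
    return w


def lrf_matrix(
    spectrum: Spectrum,
    nocc: int,
    grid: np.ndarray | None = None,
    rule: TruncationRule = TruncationRule(),
    prefactor: float = 4.0,
) -> LRFMatrix:
    """Assemble the dense sum-over-states kernel on ``grid``.

    The virtual sum for each occupied orbital i stops at its own truncation
    index M(i); the per-orbital counts are kept as metadata.
    """
    if not (1 <= nocc < spectrum.nmax):
        raise ValueError("need 1 <= nocc < nmax (at least one virtual)")
    if grid is None:
        grid = default_grid(spectrum, nocc)
    w = _trapz_weights(grid)
    psi = spectrum.evaluate_all(grid)
    energies = spectrum.energies

    m_trunc = [truncation_limit(spectrum, i, nocc, rule, grid) for i in range(1, nocc + 1)]

    n = grid.size
    K = np.zeros((n, n))
    for i0, m in enumerate(m_trunc):  # i0 is 0-based occupied index
        js = np.arange(nocc, m)
        de = energies[i0] - energies[js]
        bad = np.abs(de) < 1e-12
        if np.any(bad):
            j_bad = int(js[np.argmax(bad)]) + 1
            raise DegenerateDenominatorError(
                f"occupied orbital {i0 + 1} and virtual {j_bad} are degenerate"
            )
        # term functions u_ij(r) = psi_i psi_j; K += p * U diag(1/de) U^T
        U = psi[i0] * psi[js]  # (nj, n)
        K += prefactor * (U.T * (1.0 / de)) @ U
    # the operator is exactly symmetric; enforce it against BLAS
    # summation-order roundoff (visible for quasi-degenerate spectra whose
    # kernel norms reach ~1e6)
    K = 0.5 * (K + K.T)
    return LRFMatrix(grid=grid, values=K, nocc=nocc, m_truncated=tuple(m_trunc), prefactor=prefactor)


def response_slice(K: LRFMatrix, r_prime: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Column of K nearest ``r_prime``: the profile drho(r)/dv(r') vs r."""
    if not (K.grid[0] <= r_prime <= K.grid[-1]):
        raise ValueError(f"r'={r_prime} outside kernel grid [{K.grid[0]}, {K.grid[-1]}]")
    idx, col = K.column_at(r_prime)
    return K.grid, col.copy(), float(K.grid[idx])


def locality_metrics(K: LRFMatrix, d: float) -> LocalityMetrics:
    """Quantify nearsightedness of a kernel at distance scale ``d``."""
    width = K.grid[-1] - K.grid[0]
    if not (0 <= d < width):
        raise ValueError("require 0 <= d < domain width")
    w = K.weights
    absK = np.abs(K.values) * np.outer(w, w)
    dist = np.abs(K.grid[:, None] - K.grid[None, :])
    total = absK.sum()
    off = absK[dist > d].sum()
    col_sums = w @ K.values
    col_l1 = w @ np.abs(K.values)
    return LocalityMetrics(
        d=d,
        offrange_mass=float(off / total),
        zero_sum_residual=float(np.max(np.abs(col_sums))),
        column_l1=col_l1,
    )


def region_column_l1(K: LRFMatrix, r_prime: float, region: tuple[float, float]) -> float:
    """int_region |K(r, r')| dr for the column nearest ``r_prime``.

    Used for the double-well parity census: with the perturbation in one
    well, the response mass in the *other* well separates half-filled from
    full-filled quasi-degenerate shells.
    """
    _, col = K.column_at(r_prime)
    lo, hi = region
    mask = (K.grid >= lo) & (K.grid <= hi)
    return float(np.sum(K.weights[mask] * np.abs(col[mask])))


def friedel_reference(r, q_tf: float, k_f: float):
    """Homogeneous-electron-gas response at distance r from a point impurity.

    Two-term asymptotic: Thomas-Fermi exponential screening plus the
    Friedel oscillation,

        f(r) = exp(-q_tf r) / r + cos(2 k_f r) / r^3,

    with unit amplitudes (only the distance dependence is meaningful here).
    Zeros of the oscillatory term are spaced pi/k_f at large r.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("friedel_reference is singular at r <= 0")
    return np.exp(-q_tf * r) / r + np.cos(2.0 * k_f * r) / r**3
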