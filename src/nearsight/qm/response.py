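"""Molecular linear response fields from Kohn-Sham orbital sets.

The response of the density to a static local perturbation at atom X is
assembled in the LCAO sum-over-states (uncoupled) form

    drho(r)/dv(X) = sum_sigma f_sigma sum_{i occ} sum_{j virt}
        psi_i(r) psi_j(r) <psi_i| v_X |psi_j> / (eps_i - eps_j)

with f = 4 for a restricted closed shell (spin factor 2 times the two
orderings of the real orbital pair) and f = 2 per spin channel for an
unrestricted set.

Two perturbation conventions are available.  The default, ``mulliken``,
is the atom-condensed operator v_X = (P_X S + S P_X)/2 with P_X the
projector onto the AOs of atom X: it couples only orbital pairs with
amplitude on the perturbed atom, kills same-symmetry virtual couplings in
symmetric molecules, and is the convention under which the HOMO->LUMO
two-level picture of the closed-shell diatomics holds quantitatively.
``gaussian`` is a real-space repulsive bump exp(-alpha |r - R_X|^2),
basis-independent but with strong couplings to compact high-lying
virtuals.  Locality *contrasts* (which systems respond far away) agree
between the two; absolute field values are convention-dependent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .basis import ANGSTROM
from .engines import run_scf
from .grids import becke_grid
from .moset import MOSet
from .scf import Method, SCFConvergenceError

__all__ = [
    "SitePerturbation",
    "GridSpec3D",
    "ResponseField3D",
    "ScanResult",
    "lcao_response",
    "two_level_response",
    "response_magnitude",
    "dissociation_scan",
    "junction_audit",
]


class DegenerateResponseError(RuntimeError):
    pass


@dataclass(frozen=True)
class SitePerturbation:
    """Repulsive local perturbation centred on one atom.

    ``form`` selects the operator: ``"mulliken"`` (atom-condensed AO
    projector, default) or ``"gaussian"`` (real-space bump of sharpness
    ``alpha`` bohr^-2).  ``sign`` scales the perturbation; the response is
    exactly linear in it.
    """

    atom_index: int
    form: str = "mulliken"
    alpha: float = 5.0
    sign: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.form not in ("mulliken", "gaussian"):
            raise ValueError(f"unknown perturbation form {self.form!r}")

    def evaluate(self, points_bohr: np.ndarray, center_bohr: np.ndarray) -> np.ndarray:
        """Real-space potential values (gaussian form only)."""
        d = points_bohr - center_bohr
        return self.sign * np.exp(-self.alpha * np.einsum("pi,pi->p", d, d))


@dataclass(frozen=True)
class GridSpec3D:
    """Uniform rectilinear grid; origin and spacing in bohr."""

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]

    @classmethod
    def around(cls, atoms, padding: float = 4.0, spacing: float = 0.15) -> "GridSpec3D":
        """Cubic-voxel box around ``atoms`` (Angstrom in, bohr out).

        The grid is centred on the atoms' bounding box, so a molecule with a
        mirror plane through grid-aligned coordinates gets a mirror-symmetric
        grid (odd/even field decompositions are then exact on the grid).
        """
        coords = np.array([pos for _, pos in atoms], dtype=float) / ANGSTROM
        pad = padding / ANGSTROM
        h = spacing / ANGSTROM
        lo = coords.min(axis=0) - pad
        hi = coords.max(axis=0) + pad
        shape = tuple(int(math.ceil((b - a) / h)) | 1 for a, b in zip(lo, hi))
        center = 0.5 * (lo + hi)
        origin = center - 0.5 * h * (np.array(shape) - 1)
        return cls(origin=origin, spacing=h, shape=shape)

    def points(self) -> np.ndarray:
        nx, ny, nz = self.shape
        ax = self.origin[0] + self.spacing * np.arange(nx)
        ay = self.origin[1] + self.spacing * np.arange(ny)
        az = self.origin[2] + self.spacing * np.arange(nz)
        g = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([c.ravel() for c in g], axis=1)

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def refined(self) -> "GridSpec3D":
        return GridSpec3D(self.origin, self.spacing / 2.0, tuple(2 * n - 1 for n in self.shape))


@dataclass
class ResponseField3D:
    """drho(r)/dv(X) sampled on a uniform grid (cube-compatible)."""

    grid: GridSpec3D
    values: np.ndarray  # shape = grid.shape
    perturbation: SitePerturbation
    source: str
    metadata: dict = field(default_factory=dict)

    def integral(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume)

    def l1_norm(self) -> float:
        return float(np.abs(self.values).sum() * self.grid.voxel_volume)

    def max_abs(self) -> float:
        return float(np.max(np.abs(self.values)))


def _perturbation_elements(mos: MOSet, channel: str, pert: SitePerturbation, pts, grid: GridSpec3D, iocc, jvir):
    """Occupied x virtual matrix <psi_i | v_X | psi_j> for either operator form."""
    c = mos.channels[channel][0]
    if pert.form == "gaussian":
        center = np.asarray(mos.atoms[pert.atom_index][1], float) / ANGSTROM
        v = pert.evaluate(pts, center)
        ao = mos.basis.evaluate(pts)
        mo_occ = ao @ c[iocc].T
        mo_vir = ao @ c[jvir].T
        return np.einsum("pi,pj,p->ij", mo_occ, mo_vir, v) * grid.voxel_volume
    # mulliken: (P_X S + S P_X)/2 condensed onto atom X
    from . import integrals as ints

    S = ints.overlap(mos.basis)
    on_x = np.array(
        [mos.basis.shells[sh].atom == pert.atom_index for sh, _ in mos.basis.ao_shell_map()]
    )
    sc = S @ c.T  # (nao, nmo)
    cx = c[:, on_x]  # (nmo, nao_X)
    scx = sc[on_x]  # (nao_X, nmo)
    M = 0.5 * (cx[iocc] @ scx[:, jvir] + scx[:, iocc].T @ cx[jvir].T)
    return pert.sign * M


def _channel_term(mos: MOSet, channel: str, pert: SitePerturbation, pts, gap_min: float, grid: GridSpec3D, spin_factor: float):
    c, e, occ = mos.channels[channel]
    iocc = np.nonzero(occ > 0)[0]
    jvir = np.nonzero(occ == 0)[0]
    if iocc.size == 0 or jvir.size == 0:
        raise ValueError(f"channel {channel} lacks occupied or virtual orbitals")
    gaps = e[jvir][None, :] - e[iocc][:, None]
    if np.min(gaps) < gap_min:
        i, j = np.unravel_index(np.argmin(gaps), gaps.shape)
        raise DegenerateResponseError(
            f"occupied-virtual gap {gaps[i, j]:.3e} Hartree below gap_min for "
            f"pair (occ {iocc[i] + 1}, virt {jvir[j] + 1}) in channel {channel}"
        )
    M = _perturbation_elements(mos, channel, pert, pts, grid, iocc, jvir)
    ao = mos.basis.evaluate(pts)
    mo_occ = ao @ c[iocc].T  # (npts, nocc)
    mo_vir = ao @ c[jvir].T
    W = M / (e[iocc][:, None] - e[jvir][None, :])
    return spin_factor * np.einsum("pi,ij,pj->p", mo_occ, W, mo_vir)


def lcao_response(
    mos: MOSet,
    pert: SitePerturbation,
    grid: GridSpec3D | None = None,
    gap_min: float = 1e-6,
    refine_check: bool = False,
) -> ResponseField3D:
    """Full sum-over-states response field of ``mos`` to ``pert``.

    With ``refine_check`` the field is recomputed on a half-spacing grid
    and an accuracy warning is recorded in the metadata if the L1 norm
    moves by more than 1%.
    """
    if not (0 <= pert.atom_index < len(mos.atoms)):
        raise ValueError(f"atom index {pert.atom_index} out of range")
    if grid is None:
        grid = GridSpec3D.around(mos.atoms)
    pts = grid.points()
    vals = np.zeros(pts.shape[0])
    if mos.restricted:
        vals += _channel_term(mos, "alpha", pert, pts, gap_min, grid, spin_factor=4.0)
    else:
        for ch in mos.channel_names:
            vals += _channel_term(mos, ch, pert, pts, gap_min, grid, spin_factor=2.0)
    out = ResponseField3D(
        grid=grid,
        values=vals.reshape(grid.shape),
        perturbation=pert,
        source=mos.method,
        metadata={},
    )
    out.metadata["integral"] = out.integral()
    out.metadata["l1"] = out.l1_norm()
    if refine_check:
        fine = lcao_response(mos, pert, grid.refined(), gap_min, refine_check=False)
        drift = abs(fine.l1_norm() - out.l1_norm()) / max(fine.l1_norm(), 1e-300)
        out.metadata["refinement_l1_drift"] = drift
        if drift > 0.01:
            out.metadata["accuracy_warning"] = (
                f"L1 norm changed by {drift:.1%} on grid refinement; grid too coarse"
            )
    return out


def two_level_response(
    mos: MOSet,
    pert: SitePerturbation,
    grid: GridSpec3D | None = None,
    gap_min: float = 1e-6,
) -> ResponseField3D:
    """HOMO->LUMO-only approximation to :func:`lcao_response` (restricted)."""
    if not mos.restricted:
        raise ValueError("the two-level approximation is defined for restricted sets")
    c, e, occ = mos.channels["alpha"]
    nocc = int(np.sum(occ > 0))
    trimmed = MOSet(
        atoms=mos.atoms,
        charge=mos.charge,
        multiplicity=mos.multiplicity,
        basis=mos.basis,
        restricted=True,
        channels={"alpha": (c[nocc - 1 : nocc + 1], e[nocc - 1 : nocc + 1], occ[nocc - 1 : nocc + 1])},
        method=mos.method + " (two-level)",
        validate_electron_count=False,
    )
    return lcao_response(trimmed, pert, grid, gap_min)


def response_magnitude(
    mos: MOSet,
    pert: SitePerturbation,
    grid: GridSpec3D | None = None,
    kind: str = "l1",
) -> float:
    """Scalar size of the response: L1 integral (default) or max |field|."""
    f = lcao_response(mos, pert, grid)
    if kind == "l1":
        return f.l1_norm()
    if kind == "max":
        return f.max_abs()
    raise ValueError("kind must be 'l1' or 'max'")


def _spin_density_l1(mos: MOSet) -> float:
    """int |rho_a - rho_b| d3r on the XC quadrature grid."""
    if mos.restricted:
        return 0.0
    atoms_bohr = [(el, np.asarray(p) / ANGSTROM) for el, p in mos.atoms]
    pts, w = becke_grid(atoms_bohr, 50, 12)
    ao = mos.basis.evaluate(pts)
    da = mos.density_matrix("alpha")
    db = mos.density_matrix("beta")
    diff = np.einsum("pi,ij,pj->p", ao, da - db, ao)
    return float(np.dot(w, np.abs(diff)))


@dataclass
class ScanResult:
    """Restricted vs unrestricted response magnitude along a bond scan."""

    r_values: np.ndarray  # Angstrom, strictly increasing
    restricted_magnitude: np.ndarray
    unrestricted_magnitude: np.ndarray
    broken_symmetry: np.ndarray  # bool per R
    errors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r_values) <= 0):
            raise ValueError("R values must be strictly increasing")


def dissociation_scan(
    r_list,
    method: Method = Method(),
    engine: str = "internal",
    kind: str = "l1",
    guess_mix: float = 0.6,
    spacing: float = 0.15,
    padding: float = 4.0,
) -> ScanResult:
    """H2 dissociation: response magnitude per R for RKS and (seeded) UKS.

    The unrestricted runs start from a HOMO/LUMO-mixed guess so the
    broken-symmetry branch is reached deterministically wherever it is
    lower.  SCF failures are recorded per point and the scan continues.
    """
    from .molecules import h2

    r_arr = np.asarray(sorted(float(r) for r in r_list))
    rmag = np.full(r_arr.size, np.nan)
    umag = np.full(r_arr.size, np.nan)
    broken = np.zeros(r_arr.size, dtype=bool)
    errors: dict = {}
    for k, r in enumerate(r_arr):
        atoms = h2(r)
        grid = GridSpec3D.around(atoms, padding=padding, spacing=spacing)
        pert = SitePerturbation(atom_index=1)
        try:
            rks = run_scf(atoms, method=method, restricted=True, engine=engine)
            rmag[k] = response_magnitude(rks, pert, grid, kind)
        except (SCFConvergenceError, DegenerateResponseError) as exc:
            errors[(float(r), "restricted")] = str(exc)
        try:
            uks = run_scf(atoms, method=method, restricted=False, engine=engine, guess_mix=guess_mix)
            umag[k] = response_magnitude(uks, pert, grid, kind)
            broken[k] = _spin_density_l1(uks) > 1e-3
        except (SCFConvergenceError, DegenerateResponseError) as exc:
            errors[(float(r), "unrestricted")] = str(exc)
    return ScanResult(r_arr, rmag, umag, broken, errors)


def junction_audit(
    mos: MOSet,
    pert: SitePerturbation,
    far_atoms,
    grid: GridSpec3D | None = None,
    field_in: ResponseField3D | None = None,
) -> float:
    """Fraction of the response's L1 mass in the far region.

    Voxels are assigned to their nearest atom; the far region is the union
    of cells of ``far_atoms`` (0-based indices).  Near + far = 1 exactly.
    """
    far = sorted(set(int(a) for a in far_atoms))
    if not far or len(far) >= len(mos.atoms):
        raise ValueError("partition must leave both a near and a far set nonempty")
    if any(a < 0 or a >= len(mos.atoms) for a in far):
        raise ValueError("far-atom index out of range")
    f = field_in if field_in is not None else lcao_response(mos, pert, grid)
    pts = f.grid.points()
    coords = mos.coords_bohr()
    d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    absv = np.abs(f.values).ravel()
    total = absv.sum()
    far_mask = np.isin(nearest, far)
    return float(absv[far_mask].sum() / total)
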