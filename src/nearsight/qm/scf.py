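"""Self-consistent Kohn-Sham (and Hartree-Fock) solver.

Restricted and unrestricted, hybrid-GGA capable (B3LYP), with DIIS
acceleration and an optional symmetry-breaking HOMO/LUMO-mixed initial
guess for the unrestricted dissociation runs.  Symmetry is never enforced,
so broken-symmetry solutions are reachable wherever they exist.

The engine is registered under the name ``"internal"`` in
:mod:`nearsight.qm.engines`; the response code only ever sees the
resulting :class:`~nearsight.qm.moset.MOSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from . import integrals as ints
from .basis import ANGSTROM, BasisSet, build_basis, nuclear_charges, nuclear_repulsion
from .grids import becke_grid
from .moset import MOSet
from .xc import FUNCTIONALS, b3lyp


class SCFConvergenceError(RuntimeError):
    def __init__(self, msg: str, history=None):
        super().__init__(msg)
        self.history = history or []


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class Method:
    """Electronic-structure method specification."""

    functional: str = "b3lyp"
    basis: str = "6-31g**"
    vwn_variant: str = "vwn3"  # reproduces the reference orbital energies; 'vwn5' available
    conv_tol: float = 1e-8
    max_iter: int = 150
    n_radial: int = 75
    n_theta: int = 20
    diis_size: int = 8

    def tag(self) -> str:
        return f"{self.functional}/{self.basis}"


@dataclass
class _GridCache:
    points: np.ndarray
    weights: np.ndarray
    ao: np.ndarray | None  # (npts, nao) if it fits in memory
    dao: np.ndarray | None


_AO_CACHE_LIMIT = 2.5e8  # bytes of AO value + gradient cache


def _prepare_grid(atoms_bohr, basis: BasisSet, method: Method) -> _GridCache:
    pts, w = becke_grid(atoms_bohr, method.n_radial, method.n_theta)
    nbytes = pts.shape[0] * basis.nao * 4 * 8
    if nbytes <= _AO_CACHE_LIMIT:
        ao, dao = basis.evaluate(pts, deriv=True)
        return _GridCache(pts, w, ao, dao)
    return _GridCache(pts, w, None, None)


def _xc_build(cache: _GridCache, basis: BasisSet, da, db, method: Method, restricted: bool):
    """Exchange-correlation energy and AO-basis potential matrices.

    Standard GGA quadrature: for each spin,
    V_sigma = X^T diag(w vr) X + sum_k [X^T diag(w u_k) dX_k + h.c.] with
    u_k = 2 vg_ss grad rho_s + vg_ab grad rho_sbar.
    """
    nao = basis.nao
    exc = 0.0
    va = np.zeros((nao, nao))
    vb = np.zeros((nao, nao))
    npts = cache.points.shape[0]
    chunk = npts if cache.ao is not None else 50000
    for lo in range(0, npts, chunk):
        hi = min(npts, lo + chunk)
        if cache.ao is not None:
            ao, dao = cache.ao, cache.dao
        else:
            ao, dao = basis.evaluate(cache.points[lo:hi], deriv=True)
        w = cache.weights[lo:hi]
        ta = ao @ da
        rho_a = np.einsum("pi,pi->p", ta, ao)
        grad_a = 2.0 * np.einsum("pi,pik->pk", ta, dao)
        if restricted:
            rho_b, grad_b = rho_a, grad_a
        else:
            tb = ao @ db
            rho_b = np.einsum("pi,pi->p", tb, ao)
            grad_b = 2.0 * np.einsum("pi,pik->pk", tb, dao)
        rho_a = np.maximum(rho_a, 0.0)
        rho_b = np.maximum(rho_b, 0.0)
        gaa = np.einsum("pk,pk->p", grad_a, grad_a)
        gab = np.einsum("pk,pk->p", grad_a, grad_b)
        gbb = np.einsum("pk,pk->p", grad_b, grad_b)
        res, _ = b3lyp(rho_a, rho_b, gaa, gab, gbb, method.vwn_variant)
        exc += float(np.dot(w, res.e))
        for (vr, vgs, vgx, grad_s, grad_x, vmat) in (
            (res.vra, res.vgaa, res.vgab, grad_a, grad_b, va),
            (res.vrb, res.vgbb, res.vgab, grad_b, grad_a, vb),
        ):
            aw = ao * (0.5 * w * vr)[:, None]
            u = 2.0 * vgs[:, None] * grad_s + vgx[:, None] * grad_x
            gw = np.einsum("pk,pik->pi", w[:, None] * u, dao)
            half = ao.T @ (aw + gw)
            vmat += half + half.T
            if restricted:
                break
    if restricted:
        vb = va
    return exc, va, vb


def _diis_extrapolate(fock_list, err_list):
    n = len(fock_list)
    B = -np.ones((n + 1, n + 1))
    B[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = np.sum(err_list[i] * err_list[j])
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return fock_list[-1]
    out = [np.zeros_like(f) for f in fock_list[-1]]
    for ci, fs in zip(c, fock_list):
        for k, f in enumerate(fs):
            out[k] = out[k] + ci * f
    return out


def run_scf(
    atoms: list,
    charge: int = 0,
    multiplicity: int = 1,
    method: Method = Method(),
    restricted: bool = True,
    guess_mix: float = 0.0,
) -> MOSet:
    """Converge a Kohn-Sham (or HF) single determinant.

    ``atoms``: (element, xyz in Angstrom).  ``guess_mix`` rotates the alpha
    HOMO/LUMO pair of the initial guess by the given angle (radians) and the
    beta pair by its negative — the deterministic broken-symmetry seed used
    by the dissociation scans.
    """
    if method.functional not in FUNCTIONALS:
        raise ConfigurationError(f"unknown functional {method.functional!r}")
    atoms_ang = [(el, np.asarray(pos, float)) for el, pos in atoms]
    atoms_bohr = [(el, pos / ANGSTROM) for el, pos in atoms_ang]
    basis = build_basis(atoms_bohr, method.basis)
    z = nuclear_charges(atoms_bohr)
    coords = np.array([p for _, p in atoms_bohr])
    nelec = int(round(z.sum())) - charge
    if nelec <= 0:
        raise ConfigurationError("no electrons")
    na = (nelec + multiplicity - 1) // 2
    nb = nelec - na
    if na - nb != multiplicity - 1 or nb < 0:
        raise ConfigurationError(f"multiplicity {multiplicity} incompatible with {nelec} electrons")
    if restricted and na != nb:
        raise ConfigurationError("restricted requires a closed shell")

    S = ints.overlap(basis)
    T = ints.kinetic(basis)
    V = ints.nuclear_attraction(basis, z, coords)
    eri = ints.eri_tensor(basis)
    hcore = T + V
    enuc = nuclear_repulsion(atoms_bohr)

    hybrid = method.functional == "b3lyp"
    a_hf = 0.2 if hybrid else 1.0
    use_xc = hybrid
    cache = _prepare_grid(atoms_bohr, basis, method) if use_xc else None

    # symmetric orthogonalization
    s_val, s_vec = np.linalg.eigh(S)
    keep = s_val > 1e-10
    X = s_vec[:, keep] / np.sqrt(s_val[keep])

    def diag(F):
        fp = X.T @ F @ X
        w, cp = np.linalg.eigh(fp)
        return w, (X @ cp).T  # rows = MOs

    # core guess
    e0, C = diag(hcore)
    Ca = Cb = C
    if guess_mix != 0.0 and not restricted and na >= 1:
        th = guess_mix
        Ca = C.copy()
        Cb = C.copy()
        h, l = na - 1, na
        if l < C.shape[0]:
            Ca[h] = math.cos(th) * C[h] + math.sin(th) * C[l]
            Ca[l] = -math.sin(th) * C[h] + math.cos(th) * C[l]
            Cb[h] = math.cos(th) * C[h] - math.sin(th) * C[l]
            Cb[l] = math.sin(th) * C[h] + math.cos(th) * C[l]

    da = Ca[:na].T @ Ca[:na]
    db = Cb[:nb].T @ Cb[:nb] if nb > 0 else np.zeros_like(da)

    e_old = 0.0
    fock_hist: list = []
    err_hist: list = []
    history = []
    converged = False
    ea = eb = None
    for it in range(method.max_iter):
        dtot = da + db
        J = np.einsum("pqrs,rs->pq", eri, dtot)
        Ka = np.einsum("prqs,rs->pq", eri, da)
        Kb = np.einsum("prqs,rs->pq", eri, db) if not restricted else Ka
        if use_xc:
            exc, vxa, vxb = _xc_build(cache, basis, da, db, method, restricted)
        else:
            exc, vxa, vxb = 0.0, 0.0, 0.0
        Fa = hcore + J - a_hf * Ka + vxa
        Fb = hcore + J - a_hf * Kb + vxb
        energy = (
            float(np.sum((da + db) * hcore))
            + 0.5 * float(np.sum(dtot * J))
            - 0.5 * a_hf * (float(np.sum(da * Ka)) + float(np.sum(db * Kb)))
            + exc
            + enuc
        )
        err_a = X.T @ (Fa @ da @ S - S @ da @ Fa) @ X
        err_b = X.T @ (Fb @ db @ S - S @ db @ Fb) @ X
        err = np.concatenate([err_a.ravel(), err_b.ravel()])
        history.append((energy, float(np.max(np.abs(err)))))
        if it > 0 and abs(energy - e_old) < method.conv_tol and np.max(np.abs(err)) < 1e-5:
            converged = True
            break
        e_old = energy
        fock_hist.append((Fa, Fb))
        err_hist.append(err)
        if len(fock_hist) > method.diis_size:
            fock_hist.pop(0)
            err_hist.pop(0)
        if len(fock_hist) >= 2:
            Fa, Fb = _diis_extrapolate(fock_hist, err_hist)
        ea, Ca = diag(Fa)
        if restricted:
            eb, Cb = ea, Ca
        else:
            eb, Cb = diag(Fb)
        da = Ca[:na].T @ Ca[:na]
        db = Cb[:nb].T @ Cb[:nb] if nb > 0 else np.zeros_like(da)
    if not converged:
        raise SCFConvergenceError(
            f"SCF not converged in {method.max_iter} iterations "
            f"(last dE={history[-1][0] - history[-2][0]:.2e}, err={history[-1][1]:.2e})",
            history,
        )

    tagr = "R" if restricted else "U"
    if restricted:
        occ = np.zeros(len(ea))
        occ[:na] = 2.0
        channels = {"alpha": (Ca, ea, occ)}
    else:
        occa = np.zeros(len(ea))
        occa[:na] = 1.0
        occb = np.zeros(len(eb))
        occb[:nb] = 1.0
        channels = {"alpha": (Ca, ea, occa), "beta": (Cb, eb, occb)}
    return MOSet(
        atoms=atoms_ang,
        charge=charge,
        multiplicity=multiplicity,
        basis=basis,
        restricted=restricted,
        channels=channels,
        method=f"{tagr}{method.functional.upper()}/{method.basis}",
        energy=energy,
        converged=True,
        extra={"iterations": it + 1, "history": history, "method": method},
    )
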