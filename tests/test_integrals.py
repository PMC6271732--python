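"""Molecular integrals against published values, quadrature, and symmetry."""

import numpy as np
import pytest

from nearsight.qm import integrals as ints
from nearsight.qm.basis import build_basis, nuclear_charges, nuclear_repulsion


@pytest.fixture(scope="module")
def h2_sto3g():
    atoms = [("H", np.zeros(3)), ("H", np.array([0.0, 0.0, 1.4]))]
    return atoms, build_basis(atoms, "sto-3g")


class TestPublishedMinimalBasisValues:
    """H2/STO-3G at R = 1.4 bohr: the classic worked example's integrals."""

    def test_overlap(self, h2_sto3g):
        _, b = h2_sto3g
        S = ints.overlap(b)
        assert S[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert S[0, 1] == pytest.approx(0.6593, abs=2e-4)

    def test_kinetic(self, h2_sto3g):
        _, b = h2_sto3g
        T = ints.kinetic(b)
        assert T[0, 0] == pytest.approx(0.7600, abs=2e-4)
        assert T[0, 1] == pytest.approx(0.2365, abs=2e-4)

    def test_nuclear_attraction(self, h2_sto3g):
        atoms, b = h2_sto3g
        V = ints.nuclear_attraction(b, nuclear_charges(atoms), np.array([a[1] for a in atoms]))
        assert V[0, 0] == pytest.approx(-1.2266 - 0.6538, abs=5e-4)

    def test_repulsion_integrals(self, h2_sto3g):
        _, b = h2_sto3g
        eri = ints.eri_tensor(b)
        assert eri[0, 0, 0, 0] == pytest.approx(0.7746, abs=2e-4)
        assert eri[0, 0, 1, 1] == pytest.approx(0.5697, abs=2e-4)
        assert eri[0, 0, 0, 1] == pytest.approx(0.4441, abs=2e-4)
        assert eri[0, 1, 0, 1] == pytest.approx(0.2970, abs=2e-4)

    def test_hartree_fock_energy_and_orbitals(self, h2_sto3g):
        """Restricted HF on the fixed two-AO problem: E = -1.1167 Eh."""
        from scipy.linalg import eigh

        atoms, b = h2_sto3g
        S = ints.overlap(b)
        H = ints.kinetic(b) + ints.nuclear_attraction(
            b, nuclear_charges(atoms), np.array([a[1] for a in atoms])
        )
        eri = ints.eri_tensor(b)
        D = np.zeros_like(S)
        for _ in range(60):
            F = H + np.einsum("pqrs,rs->pq", eri, D) - 0.5 * np.einsum("prqs,rs->pq", eri, D)
            w, C = eigh(F, S)
            D = 2.0 * np.outer(C[:, 0], C[:, 0])
        e_tot = 0.5 * np.sum(D * (H + F)) + nuclear_repulsion(atoms)
        assert e_tot == pytest.approx(-1.1167, abs=2e-4)
        assert w[0] == pytest.approx(-0.5782, abs=2e-4)
        assert w[1] == pytest.approx(0.6703, abs=2e-4)


@pytest.fixture(scope="module")
def soft_basis():
    """Soft-exponent s/p/d shells on two off-axis centres.

    Keeps every integrand resolvable on a uniform grid (Pople core
    exponents are far too sharp for that); the angular machinery
    exercised is identical.
    """
    from nearsight.qm.basis import BasisSet, Shell

    c1 = np.array([0.0, 0.0, -0.7])
    c2 = np.array([0.4, -0.3, 0.9])
    shells = [
        Shell(atom=0, l=0, exps=np.array([1.1, 0.35]), coefs=np.array([0.4, 0.7]), center=c1),
        Shell(atom=0, l=1, exps=np.array([0.8]), coefs=np.array([1.0]), center=c1),
        Shell(atom=1, l=1, exps=np.array([1.4, 0.5]), coefs=np.array([0.5, 0.6]), center=c2),
        Shell(atom=1, l=2, exps=np.array([0.9]), coefs=np.array([1.0]), center=c2),
    ]
    return BasisSet(shells=shells, name="soft-spd")


@pytest.fixture(scope="module")
def quad(soft_basis):
    """Chunked uniform-grid quadrature of S, T and a smooth potential."""
    n, half = 121, 6.5
    x = np.linspace(-half, half, n)
    w = (x[1] - x[0]) ** 3
    far_charge = np.array([0.0, 0.0, 6.0])
    nao = soft_basis.nao
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    V = np.zeros((nao, nao))
    for xs in np.array_split(x, 12):
        pts = np.stack(np.meshgrid(xs, x, x, indexing="ij"), axis=-1).reshape(-1, 3)
        ao, dao = soft_basis.evaluate(pts, deriv=True)
        S += w * (ao.T @ ao)
        T += 0.5 * w * np.einsum("pik,pjk->ij", dao, dao)
        pot = -2.0 / np.linalg.norm(pts - far_charge, axis=1)
        V += w * np.einsum("pi,p,pj->ij", ao, pot, ao)
    return S, T, V, far_charge


class TestQuadratureOracle:
    """One-electron integrals with p/d shells vs brute-force 3D quadrature."""

    def test_overlap_vs_quadrature(self, soft_basis, quad):
        S = ints.overlap(soft_basis)
        assert np.max(np.abs(S - quad[0])) < 1e-6

    def test_kinetic_vs_gradient_quadrature(self, soft_basis, quad):
        T = ints.kinetic(soft_basis)
        assert np.max(np.abs(T - quad[1])) < 1e-6

    def test_offcenter_coulomb_vs_quadrature(self, soft_basis, quad):
        """Attraction to a charge outside the basis support (smooth integrand)."""
        V = ints.nuclear_attraction(soft_basis, np.array([2.0]), quad[3][None, :])
        assert np.max(np.abs(V - quad[2])) < 1e-6

    def test_eri_permutation_symmetry(self, soft_basis):
        eri = ints.eri_tensor(soft_basis)
        assert np.allclose(eri, eri.transpose(1, 0, 2, 3), atol=1e-12)
        assert np.allclose(eri, eri.transpose(0, 1, 3, 2), atol=1e-12)
        assert np.allclose(eri, eri.transpose(2, 3, 0, 1), atol=1e-12)


class TestRotationalInvariance:
    def test_hf_energy_invariant_under_rotation(self):
        """A rigid rotation must not change the electronic energy.

        Two-electron H/He pair with polarization functions: any angular
        bookkeeping error in the p-function integrals breaks this at once.
        """
        from scipy.linalg import eigh

        def hf_energy(atoms):
            b = build_basis(atoms, "6-31g**")
            S = ints.overlap(b)
            z = nuclear_charges(atoms)
            coords = np.array([a[1] for a in atoms])
            H = ints.kinetic(b) + ints.nuclear_attraction(b, z, coords)
            eri = ints.eri_tensor(b)
            D = np.zeros_like(S)
            e_old = 0.0
            for _ in range(80):
                J = np.einsum("pqrs,rs->pq", eri, D)
                K = np.einsum("prqs,rs->pq", eri, D)
                F = H + J - 0.5 * K
                w, C = eigh(F, S)
                D_new = 2.0 * np.outer(C[:, 0], C[:, 0])
                D = 0.5 * D + 0.5 * D_new
                e = 0.5 * np.sum(D * (H + F)) + nuclear_repulsion(atoms)
                if abs(e - e_old) < 1e-11:
                    break
                e_old = e
            return e

        base = [("H", np.array([0.0, 0.0, 0.0])), ("He", np.array([0.0, 0.0, 1.6]))]
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [0.3, -1.1, 0.7]).as_matrix()
        rotated = [(el, rot @ pos) for el, pos in base]
        e1 = hf_energy(base)
        e2 = hf_energy(rotated)
        assert e1 == pytest.approx(e2, abs=1e-9)
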