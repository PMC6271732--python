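"""Kohn-Sham engine and molecular response fields."""

import numpy as np
import pytest

from nearsight.qm.engines import EngineNotRegisteredError, available_engines, register_engine, run_scf
from nearsight.qm.moset import NoVirtualError, homo_lumo_gap
from nearsight.qm.response import (
    DegenerateResponseError,
    GridSpec3D,
    SitePerturbation,
    junction_audit,
    lcao_response,
    response_magnitude,
    two_level_response,
)
from nearsight.qm.scf import ConfigurationError, Method


class TestEngineContract:
    def test_internal_engine_registered(self):
        assert "internal" in available_engines()

    def test_unknown_engine_is_actionable(self):
        with pytest.raises(EngineNotRegisteredError, match="internal"):
            run_scf([("H", [0, 0, 0])], engine="does-not-exist")

    def test_custom_engine_dispatch(self, h2_fixture_moset):
        register_engine("fixture", lambda *a, **k: h2_fixture_moset)
        try:
            out = run_scf([("H", [0, 0, 0])], engine="fixture")
            assert out is h2_fixture_moset
        finally:
            from nearsight.qm import engines

            engines._ENGINES.pop("fixture")

    def test_bad_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            run_scf([("H", [0, 0, 0]), ("H", [0, 0, 0.7])], method=Method(functional="xyz"))
        with pytest.raises(ConfigurationError):
            run_scf([("H", [0, 0, 0]), ("H", [0, 0, 0.7])], multiplicity=2, restricted=True)


class TestConvergedOrbitals:
    def test_h2_energy_ordering_and_occupation(self, h2_mos):
        c, e, occ = h2_mos.channels["alpha"]
        assert np.all(np.diff(e) >= -1e-10)
        assert occ[0] == 2.0 and np.all(occ[1:] == 0.0)
        assert h2_mos.converged

    def test_h2_homo_lumo_gap_arithmetic(self, h2_mos):
        g = homo_lumo_gap(h2_mos)
        assert g.gap == pytest.approx(g.lumo - g.homo, abs=1e-14)
        assert g.gap == pytest.approx(0.543, abs=0.01)

    def test_density_integrates_to_electron_count(self, h2_mos):
        from nearsight.qm.basis import ANGSTROM
        from nearsight.qm.grids import becke_grid

        atoms_bohr = [(el, np.asarray(p) / ANGSTROM) for el, p in h2_mos.atoms]
        pts, w = becke_grid(atoms_bohr, 75, 20)
        ao = h2_mos.basis.evaluate(pts)
        rho = np.einsum("pi,ij,pj->p", ao, h2_mos.density_matrix(), ao)
        assert np.dot(w, rho) == pytest.approx(2.0, abs=1e-5)

    def test_no_virtual_error(self, h2_mos):
        import dataclasses

        c, e, occ = h2_mos.channels["alpha"]
        allocc = occ.copy()
        allocc[:] = 2.0 / len(occ) * 1  # nonzero everywhere
        bad = dataclasses.replace(h2_mos, channels={"alpha": (c, e, allocc)}, validate_electron_count=False)
        with pytest.raises(NoVirtualError):
            homo_lumo_gap(bad)


@pytest.fixture(scope="module")
def h2_field(h2_mos):
    pert = SitePerturbation(atom_index=1)
    return lcao_response(h2_mos, pert), pert


class TestResponseFields:
    def test_electron_conservation(self, h2_field):
        f, _ = h2_field
        assert abs(f.integral()) < 1e-4 * f.l1_norm()

    def test_field_predominantly_odd(self, h2_field):
        f, _ = h2_field
        odd = 0.5 * (f.values - f.values[:, :, ::-1])
        assert np.abs(odd).sum() > 0.9 * np.abs(f.values).sum()

    def test_two_level_dominance(self, h2_mos, h2_field):
        f, pert = h2_field
        two = two_level_response(h2_mos, pert, f.grid)
        rel = np.abs(two.values - f.values).sum() / np.abs(f.values).sum()
        assert rel < 0.15

    def test_two_level_shape_is_homo_lumo_product(self, h2_mos, h2_field):
        f, pert = h2_field
        two = two_level_response(h2_mos, pert, f.grid)
        pts = f.grid.points()
        prod = h2_mos.mo_on_grid(pts, indices=[0]) * h2_mos.mo_on_grid(pts, indices=[1])
        prod = prod.ravel()
        vals = two.values.ravel()
        cos = np.dot(vals, prod) / np.linalg.norm(vals) / np.linalg.norm(prod)
        assert abs(cos) > 1.0 - 1e-10

    def test_linearity_in_perturbation(self, h2_mos, h2_field):
        f, pert = h2_field
        import dataclasses

        scaled = lcao_response(h2_mos, dataclasses.replace(pert, sign=-2.5), f.grid)
        assert np.allclose(scaled.values, -2.5 * f.values, rtol=1e-12, atol=1e-15)

    def test_gaussian_form_also_conserves_electrons(self, h2_mos):
        f = lcao_response(h2_mos, SitePerturbation(atom_index=1, form="gaussian", alpha=5.0))
        assert abs(f.integral()) < 1e-4 * f.l1_norm()

    def test_degenerate_gap_guard(self, h2_mos):
        with pytest.raises(DegenerateResponseError, match="gap"):
            lcao_response(h2_mos, SitePerturbation(atom_index=1), gap_min=10.0)

    def test_restricted_unrestricted_consistency_at_equilibrium(self, h2_mos):
        """At 0.72 A the unrestricted solution collapses to the restricted one."""
        from nearsight.qm.molecules import h2

        uks = run_scf(h2(0.72), restricted=False)
        grid = GridSpec3D.around(h2_mos.atoms)
        pert = SitePerturbation(atom_index=1)
        fr = lcao_response(h2_mos, pert, grid)
        fu = lcao_response(uks, pert, grid)
        assert np.abs(fr.values - fu.values).sum() < 0.01 * np.abs(fr.values).sum()

    def test_magnitude_kinds(self, h2_mos, h2_field):
        f, pert = h2_field
        assert response_magnitude(h2_mos, pert, f.grid, "l1") == pytest.approx(f.l1_norm())
        assert response_magnitude(h2_mos, pert, f.grid, "max") == pytest.approx(f.max_abs())
        with pytest.raises(ValueError):
            response_magnitude(h2_mos, pert, f.grid, "l7")


class TestJunctionAudit:
    def test_fraction_bounds_and_partition(self, hydrocarbon_study):
        mos, field, pert = hydrocarbon_study["butane"]
        fr = junction_audit(mos, pert, far_atoms={2, 3}, field_in=field)
        near = junction_audit(mos, pert, far_atoms=set(range(1, len(mos.atoms))), field_in=field)
        assert 0.0 <= fr <= 1.0
        assert near > fr  # "far" = everything but the perturbed atom
        with pytest.raises(ValueError):
            junction_audit(mos, pert, far_atoms=set(), field_in=field)
        with pytest.raises(ValueError):
            junction_audit(mos, pert, far_atoms=set(range(len(mos.atoms))), field_in=field)

    def test_near_far_partition_is_exhaustive(self, hydrocarbon_study):
        mos, field, pert = hydrocarbon_study["butadiene"]
        far = junction_audit(mos, pert, far_atoms={2, 3}, field_in=field)
        near = junction_audit(mos, pert, far_atoms=set(range(len(mos.atoms))) - {2, 3}, field_in=field)
        assert far + near == pytest.approx(1.0, abs=1e-12)


class TestMoldenRoundTrip:
    def test_write_read_identity(self, h2_fixture_moset, tmp_path):
        from nearsight.qm.molden import read_molden, write_molden

        path = tmp_path / "fixture.molden"
        write_molden(h2_fixture_moset, path)
        back = read_molden(path)
        c0, e0, o0 = h2_fixture_moset.channels["alpha"]
        c1, e1, o1 = back.channels["alpha"]
        assert np.allclose(c0, c1, atol=1e-10)
        assert np.allclose(e0, e1, atol=1e-10)
        assert np.allclose(o0, o1, atol=1e-10)
        a0 = np.array([p for _, p in h2_fixture_moset.atoms])
        a1 = np.array([p for _, p in back.atoms])
        assert np.allclose(a0, a1, atol=1e-8)

    def test_scf_output_round_trip_gap(self, h2_mos, tmp_path):
        from nearsight.qm.molden import read_molden, write_molden

        path = tmp_path / "h2.molden"
        write_molden(h2_mos, path)
        back = read_molden(path)
        assert homo_lumo_gap(back).gap == pytest.approx(homo_lumo_gap(h2_mos).gap, abs=1e-9)

    def test_missing_energy_is_parse_error(self, h2_fixture_moset, tmp_path):
        from nearsight.qm.molden import MoldenParseError, read_molden, write_molden

        path = tmp_path / "broken.molden"
        write_molden(h2_fixture_moset, path)
        text = path.read_text().replace(" Ene= ", " EXX= ")
        path.write_text(text)
        with pytest.raises(MoldenParseError, match="Ene"):
            read_molden(path)

    def test_missing_section_is_parse_error(self, tmp_path):
        from nearsight.qm.molden import MoldenParseError, read_molden

        path = tmp_path / "empty.molden"
        path.write_text("[Molden Format]\n[Atoms] (Angs)\nH 1 1 0.0 0.0 0.0\n")
        with pytest.raises(MoldenParseError, match=r"\[GTO\]"):
            read_molden(path)


class TestCubeFormat:
    def test_round_trip(self, h2_fixture_moset, tmp_path):
        from nearsight.qm.cube import read_cube, write_cube

        grid = GridSpec3D.around(h2_fixture_moset.atoms, padding=2.0, spacing=0.4)
        f = lcao_response(h2_fixture_moset, SitePerturbation(atom_index=1), grid)
        path = tmp_path / "f.cube"
        write_cube(f, path, atoms=h2_fixture_moset.atoms)
        back = read_cube(path)
        assert back.grid.shape == f.grid.shape
        assert np.max(np.abs(back.values - f.values)) < 1e-6
        assert len(back.metadata["atoms"]) == 2

    def test_voxel_ordering_against_handwritten_file(self, tmp_path):
        """A 2x2x2 cube written by hand pins the z-fastest convention."""
        from nearsight.qm.cube import read_cube

        text = (
            "tiny\n"
            "handmade\n"
            "   0      0.000000      0.000000      0.000000\n"
            "   2      0.500000      0.000000      0.000000\n"
            "   2      0.000000      0.500000      0.000000\n"
            "   2      0.000000      0.000000      0.500000\n"
            " 111.0 112.0 121.0 122.0\n"
            " 211.0 212.0 221.0 222.0\n"
        )
        path = tmp_path / "tiny.cube"
        path.write_text(text)
        f = read_cube(path)
        # value at (ix, iy, iz) is coded as 100*ix+10*iy+iz (1-based)
        for ix in range(2):
            for iy in range(2):
                for iz in range(2):
                    assert f.values[ix, iy, iz] == 100 * (ix + 1) + 10 * (iy + 1) + (iz + 1)

    def test_nonuniform_axes_rejected(self, tmp_path):
        from nearsight.qm.cube import CubeFormatError, read_cube

        text = (
            "bad\naxes\n"
            "   0      0.0 0.0 0.0\n"
            "   2      0.5 0.1 0.0\n"
            "   2      0.0 0.5 0.0\n"
            "   2      0.0 0.0 0.5\n" + " 0.0" * 8 + "\n"
        )
        path = tmp_path / "bad.cube"
        path.write_text(text)
        with pytest.raises(CubeFormatError):
            read_cube(path)
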