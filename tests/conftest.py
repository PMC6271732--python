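"""Shared fixtures.

SCF runs are expensive, so every converged orbital set used by more than
one test lives here with session scope; all inputs are generated in
memory (no data files).
"""

from __future__ import annotations

import numpy as np
import pytest

from nearsight.wells import WellSpec, dw_states, ho_states, isw_states


@pytest.fixture(scope="session")
def isw_spectrum():
    """Square well L=1, enough states for nocc=50 kernels at tight tau."""
    return isw_states(1.0, 450)


@pytest.fixture(scope="session")
def dw25_spectrum():
    return dw_states(WellSpec(kind="double_well", V0=25.0), 450)


@pytest.fixture(scope="session")
def dw100_spectrum():
    return dw_states(WellSpec(kind="double_well", V0=100.0), 450)


@pytest.fixture(scope="session")
def ho_spectrum():
    return ho_states(1.0, 1300)


@pytest.fixture(scope="session")
def h2_mos():
    """Restricted B3LYP/6-31G** H2 at the 0.72 A equilibrium distance."""
    from nearsight.qm.engines import run_scf
    from nearsight.qm.molecules import h2

    return run_scf(h2(0.72))


@pytest.fixture(scope="session")
def he2pp_mos():
    from nearsight.qm.engines import run_scf
    from nearsight.qm.molecules import he2

    return run_scf(he2(3.0), charge=2)


@pytest.fixture(scope="session")
def he2_mos():
    from nearsight.qm.engines import run_scf
    from nearsight.qm.molecules import he2

    return run_scf(he2(3.0), charge=0)


@pytest.fixture(scope="session")
def h2_fixture_moset():
    from nearsight.oracles import make_h2_minimal_fixture

    return make_h2_minimal_fixture()


@pytest.fixture(scope="session")
def hydrocarbon_study():
    """Butane and butadiene: B3LYP/6-31G orbital sets plus response fields.

    One SCF each at a lean-but-converged quadrature grid; shared by the
    junction-audit unit tests and the acceptance contrast.
    """
    from nearsight.qm.engines import run_scf
    from nearsight.qm.molecules import butadiene, butane
    from nearsight.qm.response import SitePerturbation, lcao_response
    from nearsight.qm.scf import Method

    method = Method(basis="6-31g", n_radial=60, n_theta=14)
    pert = SitePerturbation(atom_index=0)
    out = {}
    for name, atoms in (("butane", butane()), ("butadiene", butadiene())):
        mos = run_scf(atoms, method=method)
        out[name] = (mos, lcao_response(mos, pert), pert)
    return out


@pytest.fixture(scope="session")
def h2_scan():
    """Dissociation scan over the printed R set plus the symmetry-breaking window."""
    from nearsight.qm.response import dissociation_scan

    return dissociation_scan([0.8, 1.2, 1.5, 1.8, 2.2, 2.5, 3.5])
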