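"""Sum-over-states kernel: truncation rule, invariants, locality metrics."""

import numpy as np
import pytest

from nearsight.lrf import (
    DegenerateDenominatorError,
    LRFMatrix,
    TruncationNotConvergedError,
    TruncationRule,
    friedel_reference,
    locality_metrics,
    lrf_matrix,
    region_column_l1,
    response_slice,
    truncation_limit,
)
from nearsight.wells import Spectrum, isw_states


class TestTruncation:
    def test_square_well_brute_force_value(self, isw_spectrum):
        """tau = 1e-8 truncates the i=1 square-well sum at virtual 64.

        Frozen from direct enumeration: int psi_i^2 psi_m^2 dr = 1 for
        i != m, so the criterion is (2/de)^2 < 1e-8, first satisfied at
        m = 64 (de = 19581 at m = 63, 20208 at m = 64).
        """
        assert truncation_limit(isw_spectrum, 1, 1) == 64

    def test_infinite_tau_keeps_first_virtual_only(self, isw_spectrum):
        m = truncation_limit(isw_spectrum, 2, 3, TruncationRule(tau=1e300))
        assert m == 4

    def test_monotone_in_tau(self, isw_spectrum):
        ms = [truncation_limit(isw_spectrum, 1, 1, TruncationRule(tau=t)) for t in (1e-6, 1e-8, 1e-10)]
        assert ms[0] <= ms[1] <= ms[2]

    def test_cap_failure_reports_last_term(self, isw_spectrum):
        with pytest.raises(TruncationNotConvergedError, match="term integral"):
            truncation_limit(isw_spectrum, 1, 1, TruncationRule(tau=1e-30, jmax_cap=100))

    def test_rejects_bad_indices(self, isw_spectrum):
        with pytest.raises(ValueError):
            truncation_limit(isw_spectrum, 5, 3)


@pytest.fixture(scope="module")
def K1(isw_spectrum) -> LRFMatrix:
    return lrf_matrix(isw_spectrum, 1)


@pytest.fixture(scope="module")
def K50(isw_spectrum) -> LRFMatrix:
    return lrf_matrix(isw_spectrum, 50)


class TestKernelInvariants:
    def test_symmetry(self, K1):
        assert np.max(np.abs(K1.values - K1.values.T)) < 1e-10

    def test_zero_column_integrals(self, K1):
        assert locality_metrics(K1, 0.2).zero_sum_residual < 1e-6

    def test_interior_diagonal_strictly_negative(self, K1):
        assert np.all(np.diag(K1.values)[1:-1] < 0)

    def test_negative_semidefinite(self, K1):
        assert np.linalg.eigvalsh(K1.values).max() <= 1e-8

    def test_two_state_kernel_is_rank_one(self):
        sp_full = isw_states(1.0, 2)
        K = lrf_matrix(sp_full, 1, rule=TruncationRule(tau=1e300))
        r = K.grid
        psi1 = sp_full.states[0](r)
        psi2 = sp_full.states[1](r)
        de = sp_full.energies[0] - sp_full.energies[1]
        expected = 4.0 * np.outer(psi1 * psi2, psi1 * psi2) / de
        assert np.allclose(K.values, expected, atol=1e-12)
        s = np.linalg.svd(K.values, compute_uv=False)
        assert s[1] < 1e-12 * s[0]

    def test_prefactor_scales_linearly(self, isw_spectrum):
        K4 = lrf_matrix(isw_spectrum, 1, prefactor=4.0)
        K1 = lrf_matrix(isw_spectrum, 1, prefactor=1.0)
        assert np.allclose(K4.values, 4.0 * K1.values)

    def test_degenerate_denominator_aborts(self, isw_spectrum):
        sp = isw_spectrum
        states = sp.states[:3]
        # forge a spectrum with a virtual degenerate to the occupied level
        import dataclasses

        bad = dataclasses.replace(states[1], energy=states[0].energy)
        forged = Spectrum(sp.spec, (states[0], bad, states[2]))
        with pytest.raises(DegenerateDenominatorError, match="degenerate"):
            lrf_matrix(forged, 1, rule=TruncationRule(tau=1e300))


class TestSliceAndMetrics:
    def test_slice_minimum_at_perturbed_site(self, K1):
        r, col, used = response_slice(K1, 0.5)
        assert used == pytest.approx(0.5, abs=2e-3)
        assert r[np.argmin(col)] == pytest.approx(0.5, abs=2e-3)

    def test_slice_integral_zero(self, K50):
        r, col, _ = response_slice(K50, 0.5)
        assert abs(np.trapezoid(col, r)) < 1e-6

    def test_slice_outside_domain_rejected(self, K1):
        with pytest.raises(ValueError):
            response_slice(K1, 1.7)

    def test_offrange_mass_localizes_with_filling(self, K1, K50):
        """Most response mass sits beyond 0.2 for one pair, but within for 50."""

        def offrange_of_slice(K):
            r, col, _ = response_slice(K, 0.5)
            mask = np.abs(r - 0.5) > 0.2
            w = K.weights
            return np.sum(w[mask] * np.abs(col[mask])) / np.sum(w * np.abs(col))

        # computed values: ~0.20 for 50 pairs vs ~0.41 for one
        assert offrange_of_slice(K50) < 0.25
        assert offrange_of_slice(K1) > 2.0 * offrange_of_slice(K50)

    def test_offrange_mass_bounds_and_monotone_in_d(self, K1):
        masses = [locality_metrics(K1, d).offrange_mass for d in (0.0, 0.1, 0.3, 0.6)]
        assert all(0.0 <= m <= 1.0 for m in masses)
        assert all(a >= b for a, b in zip(masses, masses[1:]))

    def test_bad_distance_rejected(self, K1):
        with pytest.raises(ValueError):
            locality_metrics(K1, 5.0)


class TestNearsightTrends:
    def test_square_well_offrange_decreases_with_filling(self, isw_spectrum):
        """The response range shrinks as the occupied ladder fills."""
        masses = [
            locality_metrics(lrf_matrix(isw_spectrum, n), 0.2).offrange_mass
            for n in (1, 5, 10, 50)
        ]
        assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_double_well_parity_effect(self, dw25_spectrum):
        """Full quasi-degenerate shells respond locally, half-filled do not.

        Perturbing the left well, the response mass arriving in the right
        well collapses by far more than 10x between odd and even fillings.
        """
        far = {}
        for nocc in (1, 2, 3, 4):
            K = lrf_matrix(dw25_spectrum, nocc)
            far[nocc] = region_column_l1(K, -1.5, (1.0, 2.0))
        assert far[2] < 0.1 * far[1]
        assert far[4] < 0.1 * far[3]


class TestFriedelReference:
    def test_decays_to_zero(self):
        assert abs(friedel_reference(200.0, 1.0, 1.0)) < 1e-6

    def test_oscillation_zero_spacing(self):
        """cos(2 k_f r) zeros: consecutive pi/(2 k_f) apart, period pi/k_f."""
        kf = 1.7
        r = np.linspace(40, 60, 200001)
        vals = friedel_reference(r, 1.0, kf)
        sign_flips = r[:-1][np.diff(np.sign(vals)) != 0]
        spacings = np.diff(sign_flips)
        assert np.allclose(spacings, np.pi / (2 * kf), atol=1e-3)
        assert np.allclose(spacings[:-1] + spacings[1:], np.pi / kf, atol=2e-3)

    def test_matches_independent_symbolic_form(self):
        """Re-typed screening + oscillation formula, evaluated via sympy."""
        import sympy as sp

        r_, q_, k_ = sp.symbols("r q k", positive=True)
        expr = sp.exp(-q_ * r_) / r_ + sp.cos(2 * k_ * r_) / r_**3
        f = sp.lambdify((r_, q_, k_), expr, "numpy")
        r = np.linspace(1.0, 20.0, 101)
        assert np.max(np.abs(friedel_reference(r, 1.0, 1.0) - f(r, 1.0, 1.0))) < 1e-12

    def test_singular_origin_rejected(self):
        with pytest.raises(ValueError):
            friedel_reference(0.0, 1.0, 1.0)
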