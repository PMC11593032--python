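"""Numeric vs analytic eigenvalues and the Routh-Hurwitz criterion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from crimodyn import (analytic_charpoly, analytic_eigenvalues,
                      analytic_equilibria, numeric_eigenvalues,
                      routh_hurwitz_cubic)
from crimodyn.bifurcation import critical_alphas
from crimodyn.equilibria import UnsupportedCaseError
from crimodyn.stability import RegimeError

from conftest import parameter_sets


def _eq(params, label):
    (eq,) = [e for e in analytic_equilibria(params) if e.label == label]
    return eq


def _sorted_real(eigenvalues):
    return np.sort_complex(np.asarray(eigenvalues))


class TestNumericEigenvalues:
    def test_crime_free_stable_below_threshold(self, fig1_params):
        rep = numeric_eigenvalues(_eq(fig1_params, "E0"), fig1_params)
        assert rep.verdict == "stable"
        reals = sorted(z.real for z in rep.eigenvalues)
        # Explicit factors -kappa = -50 and -eta = -0.1 are in the spectrum.
        assert any(abs(r + 50.0) < 1e-9 for r in reals)
        assert any(abs(r + 0.1) < 1e-9 for r in reals)

    def test_crime_free_unstable_above_threshold(self, fig1_params):
        p = fig1_params.replace(alpha=50.0)
        rep = numeric_eigenvalues(_eq(p, "E0"), p)
        assert rep.verdict == "unstable"
        # lambda1 = (R0 - 1) gamma delta / eta = 0.25 * 800 = +200.
        assert max(z.real for z in rep.eigenvalues) == pytest.approx(200.0)

    def test_lower_endemic_branch_unstable_in_window(self, fig3_params):
        rep = numeric_eigenvalues(_eq(fig3_params, "E6"), fig3_params)
        assert rep.verdict == "unstable"

    def test_upper_endemic_branch_stable_in_window(self, fig3_params):
        rep = numeric_eigenvalues(_eq(fig3_params, "E5"), fig3_params)
        assert rep.verdict == "stable"

    def test_complex_coordinates_rejected(self, fig3_params):
        p = fig3_params.replace(alpha=2.0)  # below r1: no real endemic roots
        with pytest.raises(ValueError):
            numeric_eigenvalues(_eq(p, "E5"), p)


class TestAnalyticEigenvalues:
    def test_case1_crime_free_explicit_spectrum(self, fig1_params):
        rep = analytic_eigenvalues(_eq(fig1_params, "E0"), fig1_params)
        got = sorted(z.real for z in rep.eigenvalues)
        # (R0-1)*gamma*delta/eta = -200, -eta, -gamma*phi/eta = -20, -kappa.
        assert got == pytest.approx(sorted([-200.0, -0.1, -20.0, -50.0]))
        assert rep.verdict == "stable"

    def test_case1_endemic_explicit_spectrum(self, fig1_params):
        p = fig1_params.replace(alpha=50.0)
        rep = analytic_eigenvalues(_eq(p, "E1"), p)
        got = sorted(z.real for z in rep.eigenvalues)
        assert got == pytest.approx(sorted([-200.0, -0.1, -20.0, -50.0]))

    def test_case3_stated_factors_present(self, fig1_params):
        p = fig1_params.replace(rho=0.1, alpha=50.0)  # case 3, R0 > 1
        eq = _eq(p, "E3")
        rep = analytic_eigenvalues(eq, p)
        reals = [z.real for z in rep.eigenvalues]
        g3 = eq.coordinates.G
        expected_factor = -p.phi * p.gamma / (p.eta + p.rho * g3)
        assert any(abs(r - expected_factor) < 1e-9 for r in reals)
        assert any(abs(r + p.kappa) < 1e-9 for r in reals)

    @given(params=parameter_sets(rho_zero=True, beta_zero=True))
    def test_case1_matches_numeric_oracle(self, params):
        for eq in analytic_equilibria(params):
            a = _sorted_real(analytic_eigenvalues(eq, params).eigenvalues)
            n = _sorted_real(numeric_eigenvalues(eq, params).eigenvalues)
            np.testing.assert_allclose(a, n, atol=1e-8)

    @given(params=parameter_sets(rho_zero=True))
    def test_case2_matches_numeric_oracle(self, params):
        for eq in analytic_equilibria(params):
            a = _sorted_real(analytic_eigenvalues(eq, params).eigenvalues)
            n = _sorted_real(numeric_eigenvalues(eq, params).eigenvalues)
            scale = 1.0 + np.max(np.abs(n))
            assert np.max(np.abs(a - n)) / scale < 1e-8

    @given(params=parameter_sets(beta_zero=True))
    def test_case3_matches_numeric_oracle(self, params):
        for eq in analytic_equilibria(params):
            if not np.all(np.isfinite(eq.to_array())):
                continue
            a = _sorted_real(analytic_eigenvalues(eq, params).eigenvalues)
            n = _sorted_real(numeric_eigenvalues(eq, params).eigenvalues)
            scale = 1.0 + np.max(np.abs(n))
            assert np.max(np.abs(a - n)) / scale < 1e-8

    def test_case4_near_equivalence_in_small_rate_regime(self, fig3_params):
        # With rho = phi = 1e-6 the small-rate factorisation is accurate
        # to ~1e-4 at the physical equilibria and improves as the rates
        # shrink further.  alpha = 20 keeps the upper endemic branch
        # physical as rho -> 0 (R0 = 0.5 stays above r2).
        errs = []
        for rate in (1e-6, 1e-8):
            p = fig3_params.replace(alpha=20.0, rho=rate, phi=rate)
            err = 0.0
            compared = 0
            for eq in analytic_equilibria(p):
                if not eq.exists_physically:
                    continue
                a = _sorted_real(analytic_eigenvalues(eq, p).eigenvalues)
                n = _sorted_real(numeric_eigenvalues(eq, p).eigenvalues)
                err = max(err, float(np.max(np.abs(a - n))))
                compared += 1
            assert compared >= 2  # E0 and E5
            errs.append(err)
        assert errs[0] < 1e-4
        assert errs[1] < errs[0]

    def test_case4_regime_flag_and_strict_mode(self, fig3_params, fig5_params):
        rep = analytic_eigenvalues(_eq(fig3_params, "E5"), fig3_params)
        assert not rep.analytic_regime_ok  # rho = 0.1 is not small
        with pytest.raises(RegimeError):
            analytic_eigenvalues(_eq(fig3_params, "E5"), fig3_params, strict=True)
        rep5 = analytic_eigenvalues(_eq(fig5_params, "E5"), fig5_params)
        assert rep5.analytic_regime_ok  # rho = 2.5e-5, phi = 1e-2


class TestCharPoly:
    def test_case1_has_no_reduced_polynomial(self, fig1_params):
        with pytest.raises(UnsupportedCaseError):
            analytic_charpoly(_eq(fig1_params, "E0"), fig1_params)

    def test_case2_endemic_coefficients(self, fig1_params):
        p = fig1_params.replace(beta=30.0, alpha=50.0)
        eq = _eq(p, "E2")
        cp = analytic_charpoly(eq, p)
        assert cp.v2 == pytest.approx(p.alpha * p.kappa * eq.coordinates.G)
        assert cp.v2 > 0  # endemic state stable whenever G2* > 0

    def test_case4_routh_hurwitz_verdicts_match_paper(self, fig3_params):
        cp5 = analytic_charpoly(_eq(fig3_params, "E5"), fig3_params)
        assert cp5.y1 > 0 and cp5.y2 > 0 and cp5.y3 > 0 and cp5.delta > 0
        assert routh_hurwitz_cubic(cp5.y1, cp5.y2, cp5.y3)
        cp6 = analytic_charpoly(_eq(fig3_params, "E6"), fig3_params)
        assert cp6.y3 < 0
        assert not routh_hurwitz_cubic(cp6.y1, cp6.y2, cp6.y3)

    @given(params=parameter_sets())
    def test_no_hopf_on_physical_upper_branch(self, params):
        # The Routh-Hurwitz determinant is strictly positive whenever the
        # upper endemic state is physical and beta <= kappa, so no Hopf
        # bifurcation can occur there.
        eqs = {e.label: e for e in analytic_equilibria(params)}
        e5 = eqs.get("E5")
        assume(e5 is not None and e5.exists_physically and e5.coordinates.G > 0)
        cp = analytic_charpoly(e5, params)
        assert cp.delta > 0


class TestRouthHurwitzCubic:
    @pytest.mark.parametrize(
        "coeffs, expected",
        [
            ((3.0, 3.0, 1.0), True),   # delta = 8 > 0
            ((1.0, 1.0, 2.0), False),  # delta = -1 < 0
            ((1.0, 1.0, -0.5), False),  # y3 < 0: a positive real root
        ],
    )
    def test_reference_cases_against_root_finding(self, coeffs, expected):
        assert routh_hurwitz_cubic(*coeffs) is expected
        roots = np.roots([1.0, *coeffs])
        assert bool(np.max(roots.real) < 0) is expected

    @given(y=st.tuples(*[st.floats(-10, 10, allow_nan=False) for _ in range(3)]))
    def test_agrees_with_brute_force_roots(self, y):
        roots = np.roots([1.0, *y])
        assume(np.max(np.abs(roots.real)) > 1e-7)  # avoid marginal cases
        assert routh_hurwitz_cubic(*y) is bool(np.max(roots.real) < 0)


class TestTranscriticalExchange:
    def test_verdicts_swap_across_critical_alpha(self, fig1_params):
        alpha_crit = critical_alphas(fig1_params).transcritical
        verdicts = {}
        for side in (-1, +1):
            p = fig1_params.replace(alpha=alpha_crit * (1 + 0.01 * side))
            verdicts[side] = {
                e.label: numeric_eigenvalues(e, p).verdict
                for e in analytic_equilibria(p)
            }
        assert verdicts[-1] == {"E0": "stable", "E1": "unstable"}
        assert verdicts[+1] == {"E0": "unstable", "E1": "stable"}

    @given(params=parameter_sets(rho_zero=True))
    def test_total_recidivism_destabilises_crime_free_state(self, params):
        # beta = kappa makes E0 unstable regardless of R0 (case 2) ...
        p2 = params.replace(beta=params.kappa)
        assert numeric_eigenvalues(_eq(p2, "E0"), p2).verdict == "unstable"

    @given(params=parameter_sets(rho_range=(1e-3, 0.5)))
    def test_total_recidivism_destabilises_crime_free_state_case4(self, params):
        # ... and with corruption present (case 4) as well.
        p4 = params.replace(beta=params.kappa)
        assert numeric_eigenvalues(_eq(p4, "E0"), p4).verdict == "unstable"
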