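"""Equilibrium solver, titration simulation, and both fitters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from felig import speciation as sp
from felig.errors import (
    DegenerateFitError,
    DomainError,
    FitFailureError,
    InsufficientDataError,
)

from conftest import bisect_fe_prime


class TestSideReactionCoefficient:
    def test_zero_sa_gives_zero(self):
        assert sp.side_reaction_coefficient(0.0, 1e6, 1e11, use_bis=True) == 0.0

    def test_mono_only(self):
        assert sp.side_reaction_coefficient(5e-6, K1=1e6, beta2=0.0) == pytest.approx(5.0)

    def test_bis_term_added_when_enabled(self):
        a = sp.side_reaction_coefficient(5e-6, K1=1e6, beta2=1e11, use_bis=True)
        assert a == pytest.approx(5.0 + 2.5)
        # disabled by default
        assert sp.side_reaction_coefficient(5e-6, K1=1e6, beta2=1e11) == pytest.approx(5.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            sp.side_reaction_coefficient(-1e-6, 1e6, 0.0)


class TestEquilibriumSolver:
    def test_no_ligand_partitions_between_fe_prime_and_fesa(self):
        st_ = sp.solve_one_ligand_equilibrium(1e-9, 0.0, 11.3, 5.0)
        assert st_.fe_prime == pytest.approx(1e-9 / 6.0, rel=1e-12)
        assert st_.feL == 0.0

    def test_typical_seawater_case_matches_bisection_oracle(self):
        st_ = sp.solve_one_ligand_equilibrium(1e-9, 2e-9, 11.3, 5.0)
        f_oracle = bisect_fe_prime(1e-9, 2e-9, 11.3, 5.0)
        assert st_.fe_prime == pytest.approx(f_oracle, rel=1e-12)
        # frozen values from the oracle
        assert st_.feL == pytest.approx(9.7159e-10, rel=1e-4)
        assert st_.feSA == pytest.approx(2.3675e-11, rel=1e-4)

    def test_saturated_ligand_limit(self):
        st_ = sp.solve_one_ligand_equilibrium(1e-7, 2e-9, 11.3, 5.0)
        assert st_.feL / 2e-9 > 0.98

    def test_zero_iron_gives_zero_state(self):
        st_ = sp.solve_one_ligand_equilibrium(0.0, 2e-9, 11.3, 5.0)
        assert (st_.fe_prime, st_.feL, st_.feSA, st_.fe_total) == (0, 0, 0, 0)

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(DomainError):
            sp.solve_one_ligand_equilibrium(math.nan, 2e-9, 11.3, 5.0)

    def test_solver_agrees_with_bisection_over_random_draws(self, rng):
        """Quadratic closed form vs bisection oracle, 1000 draws, 1e-10 rel."""
        for _ in range(1000):
            fet = 10.0 ** rng.uniform(-10, -7)
            lt = 10.0 ** rng.uniform(-10, -7)
            logk = rng.uniform(9.0, 13.0)
            alpha = 10.0 ** rng.uniform(0, 2.5)
            st_ = sp.solve_one_ligand_equilibrium(fet, lt, logk, alpha)
            f_oracle = bisect_fe_prime(fet, lt, logk, alpha)
            assert st_.fe_prime == pytest.approx(f_oracle, rel=1e-10, abs=1e-30)
            total = st_.fe_prime + st_.feL + st_.feSA
            assert total == pytest.approx(fet, rel=1e-10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        fet=st.floats(1e-11, 1e-6), lt=st.floats(0, 1e-6),
        logk=st.floats(8.0, 14.0), alpha=st.floats(0.0, 1e3),
    )
    def test_mass_balance_and_nonnegativity(self, fet, lt, logk, alpha):
        st_ = sp.solve_one_ligand_equilibrium(fet, lt, logk, alpha)
        assert st_.fe_prime >= 0 and st_.feL >= 0 and st_.feSA >= 0
        assert st_.fe_prime + st_.feL + st_.feSA == pytest.approx(fet, rel=1e-10)

    def test_fel_monotone_in_logk(self):
        fels = [sp.solve_one_ligand_equilibrium(1e-9, 2e-9, k, 14.0).feL
                for k in np.linspace(9.0, 13.5, 40)]
        assert all(b >= a - 1e-25 for a, b in zip(fels, fels[1:]))


class TestSimulateTitration:
    def test_no_ligand_gives_line_through_origin(self):
        c = sp.simulate_titration(dfe0=0.0, L_T=0.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9)
        ratio = c.peak_current[1:] / c.fe_total[1:]
        assert np.allclose(ratio, ratio[0], rtol=1e-12)
        assert c.peak_current[0] == 0.0

    def test_curve_convex_with_ligand_and_tail_slope_approaches_asymptote(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9,
                                  additions=np.linspace(0, 50, 30))
        d1 = np.diff(c.peak_current) / np.diff(c.fe_total)
        assert np.all(np.diff(d1) > -1e-9)  # convex increasing
        asymptote = 1e9 * 5.0 / 6.0 * 1e-9  # S * alpha/(1+alpha) per nM
        assert d1[-1] == pytest.approx(asymptote, rel=1e-3)

    def test_seeded_noise_is_reproducible(self):
        kw = dict(dfe0=1.0, L_T=2.0, logK=11.3, alpha_sa=5.0,
                  sensitivity=1e9, noise_sd=0.05, seed=42)
        c1, c2 = sp.simulate_titration(**kw), sp.simulate_titration(**kw)
        assert np.array_equal(c1.peak_current, c2.peak_current)

    def test_noise_without_seed_is_an_error(self):
        with pytest.raises(DomainError, match="seed"):
            sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3, noise_sd=0.02)


class TestSensitivity:
    def test_exact_recovery_without_ligand(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=0.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=3.3e8)
        s, _ = sp.estimate_sensitivity(c, k_tail=3)
        assert s == pytest.approx(3.3e8, rel=1e-9)

    def test_tail_estimate_within_5pct_with_unsaturated_ligand(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9)
        s, _ = sp.estimate_sensitivity(c)
        assert s == pytest.approx(1e9, rel=0.05)

    def test_flat_signal_is_degenerate(self):
        c = sp.TitrationCurve(fe_added=np.linspace(0, 9, 6),
                              peak_current=np.full(6, 2.0), dfe0=1.0,
                              alpha_sa=5.0)
        with pytest.raises(DegenerateFitError):
            sp.estimate_sensitivity(c)


class TestFitters:
    def test_vdb_exact_roundtrip_with_true_sensitivity(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9)
        fit = sp.fit_vdb_linearization(c, sensitivity=1e9)
        assert fit.L_T == pytest.approx(2.0, rel=1e-6)
        assert fit.logK == pytest.approx(11.3, rel=1e-6)
        assert fit.method == "linearization"

    def test_nonlinear_exact_roundtrip_self_calibrated(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9)
        fit = sp.fit_nonlinear(c)
        assert fit.L_T == pytest.approx(2.0, rel=1e-6)
        assert fit.logK == pytest.approx(11.3, rel=1e-6)
        assert fit.sensitivity == pytest.approx(1e9, rel=1e-5)

    def test_nonlinear_with_true_init_stays_at_optimum(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9)
        init = sp.LigandFit(L_T=2.0, logK=11.3, sensitivity=1e9,
                            se_LT=0.0, se_logK=0.0, method="linearization",
                            n_points=10, dfe0=1.0)
        fit = sp.fit_nonlinear(c, init=init)
        assert fit.L_T == pytest.approx(2.0, rel=1e-8)
        assert fit.logK == pytest.approx(11.3, rel=1e-8)

    def test_nonlinear_never_worsens_initialisation(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9, noise_sd=0.05, seed=7)
        # deliberately poor start: the optimiser must still not end worse
        init = sp.LigandFit(L_T=3.5, logK=10.5, sensitivity=8e8,
                            se_LT=0.0, se_logK=0.0, method="linearization",
                            n_points=10, dfe0=1.0)
        fit = sp.fit_nonlinear(c, init=init)

        def rss(f):
            model = np.array([
                f.sensitivity * sp.solve_one_ligand_equilibrium(
                    ft * 1e-9, f.L_T * 1e-9, f.logK, c.alpha_sa).feSA
                for ft in c.fe_total])
            return float(np.sum((model - c.peak_current) ** 2))

        assert rss(fit) <= rss(init) * (1 + 1e-9)

    def test_no_ligand_curve_fails_the_linearisation(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=0.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9)
        with pytest.raises((InsufficientDataError, FitFailureError)):
            sp.fit_vdb_linearization(c, sensitivity=1e9)

    def test_fit_invariant_to_common_rescaling_of_currents_and_sensitivity(self):
        c = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3, alpha_sa=5.0,
                                  sensitivity=1e9, noise_sd=0.02, seed=11)
        fit1 = sp.fit_vdb_linearization(c, sensitivity=1e9)
        c2 = sp.TitrationCurve(fe_added=c.fe_added,
                               peak_current=c.peak_current * 37.5,
                               dfe0=c.dfe0, alpha_sa=c.alpha_sa)
        fit2 = sp.fit_vdb_linearization(c2, sensitivity=1e9 * 37.5)
        assert fit2.L_T == pytest.approx(fit1.L_T, rel=1e-10)
        assert fit2.logK == pytest.approx(fit1.logK, rel=1e-10)

    def test_saturated_fit_flags_negative_excess_ligand(self):
        c = sp.simulate_titration(dfe0=5.0, L_T=2.0, logK=11.5, alpha_sa=5.0,
                                  sensitivity=1e9)
        fit = sp.fit_nonlinear(c)
        assert fit.excess_ligand < 0
        assert "negative excess ligand" in fit.warnings


class TestMonteCarloRecovery:
    def test_recovery_under_2pct_noise(self):
        """100 noisy titrations: median |L_T error| < 5%, logK bias < 0.15."""
        lt_err, logk_err = [], []
        for seed in range(100):
            c = sp.simulate_titration(dfe0=1.0, L_T=2.0, logK=11.3,
                                      alpha_sa=sp.default_alpha_sa(),
                                      sensitivity=1e9, noise_sd=0.02,
                                      seed=seed)
            try:
                fit = sp.fit_nonlinear(c)
            except (FitFailureError, InsufficientDataError):
                continue
            lt_err.append(abs(fit.L_T - 2.0) / 2.0)
            logk_err.append(fit.logK - 11.3)
        assert len(lt_err) >= 90
        assert np.median(lt_err) < 0.05
        assert abs(np.mean(logk_err)) < 0.15
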