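"""Steady states, Jacobians, eigenvalues, stability and regime boundaries."""

import cmath

import numpy as np
import pytest

import cryptdyn as cd
from tests.conftest import nontrivial


class TestSteadyStates:
    def test_standard_parametrisation(self, standard_spec):
        """(S_bar, D_bar) = (omega/beta * delta^{-1}(beta), delta^{-1}(beta))."""
        rep = nontrivial(standard_spec)
        assert rep.S_bar == pytest.approx(100.0, rel=1e-12)
        assert rep.D_bar == pytest.approx(1000.0, rel=1e-12)
        assert rep.regime == "homeostasis"

    def test_trivial_state_always_present(self, standard_spec, escape_spec):
        for spec in (standard_spec, escape_spec):
            trivial = cd.steady_states(spec)[0]
            assert trivial.kind == "trivial"
            assert trivial.S_bar == 0.0 and trivial.D_bar == 0.0

    def test_no_interior_state_when_feedback_saturates_low(self, escape_spec):
        """beta above the differentiation ceiling removes homeostasis."""
        reps = cd.steady_states(escape_spec)
        assert all(r.kind == "trivial" for r in reps)
        assert reps[0].regime == "unbounded_growth"

    def test_dediff_with_zero_rho_reduces_to_basic(self, standard_spec):
        rho = cd.piecewise_linear(0.0, -1e-9, 0.0)
        # a rho that is zero everywhere relevant: intercept 0, floored at 0
        ext = cd.ModelSpec(topology="delta_of_D", beta=1.0, omega=0.1,
                           delta=cd.piecewise_linear(0.9, 1e-4, 2.0), rho=rho)
        rep_base = nontrivial(standard_spec)
        rep_ext = nontrivial(ext)
        assert rep_ext.S_bar == pytest.approx(rep_base.S_bar, rel=1e-9)
        assert rep_ext.D_bar == pytest.approx(rep_base.D_bar, rel=1e-9)

    def test_dediff_root_against_scalar_oracle_and_simulation(self):
        """The interior state solves beta - delta((beta/omega)S) +
        (beta/omega) rho(S) = 0; cross-checked by brute-force bisection and
        by long-time integration of the extended model."""
        from scipy.optimize import bisect

        beta, omega = 1.0, 0.1
        delta = cd.piecewise_linear(0.9, 1e-4, 2.0)
        rho = cd.piecewise_linear(0.5, -0.01, 0.0)
        spec = cd.ModelSpec(topology="delta_of_D", beta=beta, omega=omega,
                            delta=delta, rho=rho)
        rep = nontrivial(spec)

        def g(S):
            return beta - delta.value(10.0 * S) + 10.0 * rho.value(S)

        S_oracle = bisect(g, 1.0, 5000.0, xtol=1e-10)
        assert rep.S_bar == pytest.approx(S_oracle, rel=1e-8)
        assert rep.D_bar == pytest.approx(10.0 * S_oracle, rel=1e-8)

        traj = cd.integrate(spec, (rep.S_bar * 0.5, rep.D_bar * 1.2), 400.0)
        assert traj.S[-1] == pytest.approx(rep.S_bar, rel=1e-5)
        assert traj.D[-1] == pytest.approx(rep.D_bar, rel=1e-5)


class TestJacobian:
    def test_trivial_state_eigenvalues(self, standard_spec):
        """At extinction the spectrum is (beta - delta(0), -omega)."""
        trivial = cd.steady_states(standard_spec)[0]
        eigs = sorted(ev.real for ev in trivial.eigenvalues)
        assert eigs[0] == pytest.approx(-0.1)
        assert eigs[1] == pytest.approx(1.0 - 0.9)

    def test_interior_jacobian_standard(self, standard_spec):
        """[[0, -S delta'], [beta, S delta' - omega]] at (100, 1000)."""
        J = cd.jacobian_at(standard_spec, 100.0, 1000.0)
        assert np.allclose(J, [[0.0, -0.01], [1.0, -0.09]], atol=1e-12)

    def test_jacobian_matches_finite_differences(self, random_stable_set):
        rng = np.random.default_rng(5)
        for spec in random_stable_set[:25]:
            rep = nontrivial(spec)
            S = rep.S_bar * rng.uniform(0.5, 1.5)
            D = rep.D_bar * rng.uniform(0.5, 1.5)
            if spec.delta.saturation_start is not None and \
                    abs(D - spec.delta.saturation_start) < 1.0:
                continue
            J = cd.jacobian_at(spec, S, D)
            h = 1e-6
            fd = np.empty((2, 2))
            for j, (dS, dD) in enumerate(((h * max(1, S), 0), (0, h * max(1, D)))):
                up = cd.rhs(spec, S + dS, D + dD)
                dn = cd.rhs(spec, S - dS, D - dD)
                step = 2 * (dS or dD)
                fd[0, j] = (up[0] - dn[0]) / step
                fd[1, j] = (up[1] - dn[1]) / step
            assert np.allclose(J, fd, rtol=1e-5, atol=1e-8)

    def test_dediff_jacobian_reduces_without_rho(self, standard_spec):
        rho = cd.piecewise_linear(0.0, -1e-9, 0.0)
        ext = cd.ModelSpec(topology="delta_of_D", beta=1.0, omega=0.1,
                           delta=cd.piecewise_linear(0.9, 1e-4, 2.0), rho=rho)
        J0 = cd.jacobian_at(standard_spec, 100.0, 1000.0)
        J1 = cd.jacobian_at(ext, 100.0, 1000.0)
        assert np.allclose(J0, J1, atol=1e-12)


class TestClosedFormEigenvalues:
    def test_standard_values(self):
        lam1, lam2 = cd.eigenvalues_piecewise_linear(1.0, 0.1, 0.9)
        disc = cd.node_focus_discriminant(1.0, 0.1, 0.9)
        assert disc == pytest.approx(-0.0319)
        assert lam1 == pytest.approx((-0.09 + cmath.sqrt(-0.0319)) / 2.0)
        assert lam1.real == pytest.approx(-0.045)

    def test_matches_numeric_spectrum_random(self, random_stable_set):
        """Closed form vs numpy spectrum of the analytic Jacobian, 100 draws."""
        specs = random_stable_set + cd.random_stable_specs(50, seed=77)
        for spec in specs:
            rep = nontrivial(spec)
            lam = cd.eigenvalues_piecewise_linear(
                spec.beta, spec.omega, spec.delta.intercept)
            numeric = sorted(rep.eigenvalues, key=lambda z: (z.real, z.imag))
            closed = sorted(lam, key=lambda z: (z.real, z.imag))
            for a, b in zip(numeric, closed):
                assert abs(a - b) <= 1e-6 * max(abs(a), 1e-12)

    def test_eigenvalues_vanish_with_omega(self):
        lam1, lam2 = cd.eigenvalues_piecewise_linear(1.0, 1e-9, 0.9)
        assert abs(lam1) < 1e-4 and abs(lam2) < 1e-4

    def test_repeated_root_at_discriminant_zero(self):
        """Solve the discriminant for delta0 and check the double eigenvalue."""
        beta, omega = 1.0, 0.1
        # delta0^2 omega + 4 beta^2 delta0 - 4 beta^3 = 0
        d0 = (-4 * beta**2 + np.sqrt(16 * beta**4 + 16 * beta**3 * omega)) \
            / (2 * omega)
        lam1, lam2 = cd.eigenvalues_piecewise_linear(beta, omega, d0)
        # rounding in d0 leaves a ~eps discriminant residual, so the pair
        # splits by ~sqrt(eps)
        assert lam1 == pytest.approx(lam2, rel=1e-5)
        assert (lam1 + lam2).real / 2 == pytest.approx(
            -d0 * omega / (2 * beta), rel=1e-12)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(cd.InfeasibleParameterError):
            cd.eigenvalues_piecewise_linear(1.0, 0.1, 1.2)   # delta0 > beta
        with pytest.raises(cd.InfeasibleParameterError):
            cd.eigenvalues_piecewise_linear(1.0, 0.1, 0.0)


class TestClassification:
    def test_node_focus_boundary(self):
        """Classification flips exactly where the discriminant crosses zero."""
        beta, omega = 1.0, 0.1
        d0_star = (-4 * beta**2 + np.sqrt(16 * beta**4 + 16 * beta**3 * omega)) \
            / (2 * omega)
        for d0, expected in ((d0_star - 1e-3, "stable_focus"),
                             (d0_star + 1e-3, "stable_node")):
            spec = cd.ModelSpec(topology="delta_of_D", beta=beta, omega=omega,
                                delta=cd.piecewise_linear(d0, 1e-4, 2.0))
            assert nontrivial(spec).stability == expected

    def test_feasible_states_always_stable(self, random_stable_set):
        """Any biologically feasible interior state of the piecewise-linear
        crypt model is stable (Routh-Hurwitz)."""
        for spec in random_stable_set:
            assert nontrivial(spec).is_stable

    def test_sigmoidal_steepness_threshold(self):
        """Instability sets in at p = 4 beta / delta_max when the steady
        state sits at the Hill midpoint."""
        for p, stab, regime in ((1.8, "stable_focus", "homeostasis"),
                                (2.2, "unstable", "sustained_oscillation")):
            spec = cd.ModelSpec(topology="delta_of_D", beta=1.0, omega=0.1,
                                delta=cd.sigmoidal(0.0, 2.0, 1000.0, p))
            rep = nontrivial(spec)
            assert rep.stability == stab
            assert rep.regime == regime


class TestOscillationMetrics:
    def test_decay_rate_standard(self, standard_spec):
        rep = nontrivial(standard_spec)
        m = cd.oscillation_metrics(standard_spec, rep)
        assert m.decay_rate == pytest.approx(-0.045, rel=1e-12)
        assert m.angular_frequency == pytest.approx(
            abs(cmath.sqrt(-0.0319)) / 2.0, rel=1e-12)

    def test_alternative_frequency_formula_reported_with_flag(self, standard_spec):
        """The closed-form frequency expression in circulation for this model
        does not match |Im lambda|; it must be reported, flagged, and not
        silently reconciled."""
        rep = nontrivial(standard_spec)
        m = cd.oscillation_metrics(standard_spec, rep)
        assert m.angular_frequency_alt is not None
        expected_alt = np.sqrt(1e-4 * 1000.0 * (4 * 0.1 + 0.01) - 0.01) / 2.0
        assert m.angular_frequency_alt == pytest.approx(expected_alt, rel=1e-12)
        assert m.alt_consistent is False

    def test_steeper_feedback_slower_decay_higher_frequency(self):
        """With the steady state pinned at (100, 1000), increasing the slope
        (and re-solving delta0) prolongs and speeds up the oscillations."""
        decays, freqs = [], []
        for slope in (3e-5, 1e-4, 3e-4):
            d0 = 1.0 - slope * 1000.0
            spec = cd.ModelSpec(topology="delta_of_D", beta=1.0, omega=0.1,
                                delta=cd.piecewise_linear(d0, slope, 2.0))
            rep = nontrivial(spec)
            m = cd.oscillation_metrics(spec, rep)
            decays.append(m.decay_rate)
            freqs.append(m.angular_frequency)
        assert decays[0] < decays[1] < decays[2] < 0    # slower decay
        assert freqs[0] < freqs[1] < freqs[2]

    def test_node_raises(self):
        spec = cd.ModelSpec(topology="delta_of_D", beta=1.0, omega=0.1,
                            delta=cd.piecewise_linear(0.999, 1e-6, 2.0))
        rep = nontrivial(spec)
        assert rep.stability == "stable_node"
        with pytest.raises(cd.NotAFocusError):
            cd.oscillation_metrics(spec, rep)

    def test_simulated_envelope_recovers_decay_rate(self, standard_spec):
        """Exponential fit of |D - D_bar| peaks matches Re(lambda) within 5%."""
        rep = nontrivial(standard_spec)
        traj = cd.integrate(standard_spec, (90.0, 1000.0), 250.0,
                            t_eval=np.linspace(0, 250, 5000))
        fitted = cd.fit_decay_rate(traj, rep.D_bar)
        assert fitted == pytest.approx(rep.decay_rate, rel=0.05)


class TestDedifferentiationThreshold:
    def test_rho0_critical_values(self):
        assert cd.rho0_critical(1.0, 0.9, 0.1) == pytest.approx(0.022)
        assert cd.rho0_critical(1.0, 2.0, 0.1) == pytest.approx(0.0)
        assert cd.rho0_critical(1.0, 0.9, 0.0) == pytest.approx(0.0)

    def test_frequency_reduced_only_above_threshold(self):
        """With near-constant rho the eigenfrequency rises below rho0* and
        falls above it, relative to no dedifferentiation."""
        base = cd.ModelSpec(topology="delta_of_D", beta=1.0, omega=0.1,
                            delta=cd.piecewise_linear(0.9, 1e-4, 2.0))
        f0 = nontrivial(base).angular_frequency
        star = cd.rho0_critical(1.0, 0.9, 0.1)
        freqs = {}
        for rho0 in (star - 0.01, star + 0.0025):
            spec = cd.ModelSpec(
                topology="delta_of_D", beta=1.0, omega=0.1,
                delta=cd.piecewise_linear(0.9, 1e-4, 2.0),
                rho=cd.piecewise_linear(rho0, -1e-6, 0.0))
            freqs[rho0] = nontrivial(spec).angular_frequency
        assert freqs[star - 0.01] > f0
        assert freqs[star + 0.0025] < f0


class TestBifurcationScan:
    def test_regime_flips_at_growth_equals_ceiling(self, standard_spec):
        table = cd.bifurcation_scan(standard_spec, "beta",
                                    np.linspace(1.5, 2.5, 21))
        below = table[table.value <= 2.0]
        above = table[table.value > 2.0]
        assert (below.regime == "homeostasis").all()
        assert (above.regime == "unbounded_growth").all()

    def test_regime_flips_to_extinction_past_beta(self, standard_spec):
        table = cd.bifurcation_scan(standard_spec, "delta0",
                                    np.linspace(0.5, 1.5, 20))
        assert (table[table.value < 1.0].regime == "homeostasis").all()
        assert (table[table.value > 1.0].regime == "extinction").all()

    def test_differentiated_pool_invariant_to_apoptosis_rate(self, standard_spec):
        table = cd.bifurcation_scan(standard_spec, "omega",
                                    np.array([0.01, 0.1, 1.0]))
        D = table.D_bar.to_numpy()
        assert np.all(np.abs(D - D[0]) <= 1e-9 * D[0])

    def test_empty_grid_rejected(self, standard_spec):
        with pytest.raises(ValueError):
            cd.bifurcation_scan(standard_spec, "beta", [])
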