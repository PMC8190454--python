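"""Structural model variants: reductions, migration, gene flow, dual-cost
modifiers, alternative formulations, fluctuating antibiotic pressure."""

import numpy as np
import pytest

import plasmidfate as pf
from plasmidfate.model import IDX
from plasmidfate.variants import (FluctuationConfig, MigrationParameters,
                                  VariantConfig, dual_cost_regime,
                                  fluctuation_experiment, make_rhs)


class TestReductions:
    def test_default_variant_is_core_rhs_bitwise(self, params, rng):
        v = VariantConfig()
        assert v.is_default
        for _ in range(20):
            n = rng.uniform(0, 1.5, 6)
            assert np.array_equal(pf.rhs_variant(0.7, n, params, v),
                                  pf.rhs(0.7, n, params))

    def test_zero_migration_is_core_rhs(self, params, rng):
        m = MigrationParameters(mu=0.0)
        for _ in range(10):
            n = rng.uniform(0, 1.5, 6)
            assert np.array_equal(pf.rhs_migration(0.0, n, params, m),
                                  pf.rhs(0.0, n, params))

    def test_migration_influx_split(self, params):
        m = MigrationParameters(mu=0.3, f_imm=0.25)
        n = np.zeros(6)
        d = pf.rhs_migration(0.0, n, params, m)
        assert d[IDX["S0"]] == pytest.approx(0.3 * 0.75)
        assert d[IDX["SS"]] == pytest.approx(0.3 * 0.25)

    def test_independent_segregation_matches_replication_coupled(self, params,
                                                                 rng):
        """A standalone loss rate sigma = s*lambda_type reproduces the
        replication-coupled formulation exactly: growth (1-s)*lam equals
        lam - sigma and the influx terms coincide."""
        v = VariantConfig(segregation_mode="independent_rate")
        for _ in range(20):
            n = rng.uniform(0, 1.5, 6)
            assert np.allclose(pf.rhs_variant(0.0, n, params, v),
                               pf.rhs(0.0, n, params), rtol=1e-12, atol=1e-14)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            VariantConfig(segregation_mode="co_infection")
        with pytest.raises(ValueError):
            VariantConfig(single_copy_protection=1.5)
        with pytest.raises(ValueError):
            MigrationParameters(mu=-0.1)


class TestAlternativeFormulations:
    def test_growth_slowing_antibiotic_calibration(self, settings):
        """A lone susceptible population reaches the same equilibrium
        density whether the antibiotic kills or slows growth (A < lam)."""
        p = pf.ModelParameters(A=0.5)
        v = VariantConfig(antibiotic_mode="growth_slowing")
        res_death = pf.integrate(pf.state_vector(S0=0.3), p, settings)
        res_slow = pf.integrate(pf.state_vector(S0=0.3), p, settings,
                                rhs=make_rhs(p, variant=v))
        target = (p.lam - p.A) / p.gamma
        assert res_death.raw_state[IDX["S0"]] == pytest.approx(target,
                                                               rel=1e-6)
        assert res_slow.raw_state[IDX["S0"]] == pytest.approx(target,
                                                              rel=1e-6)

    def test_death_mode_costs_keep_single_type_equilibria(self, settings):
        """Cost as extra death leaves the net growth rate, and hence the
        lone-type equilibrium density, unchanged."""
        p = pf.ModelParameters(A=0.0)
        v = VariantConfig(cost_mode="death")
        res = pf.integrate(pf.state_vector(R0=0.2), p, settings,
                           rhs=make_rhs(p, variant=v))
        assert res.raw_state[IDX["R0"]] == pytest.approx(p.lamR / p.gamma,
                                                         rel=1e-6)


class TestGeneFlow:
    def test_transposition_maintains_excluded_form_at_low_frequency(
            self, params, settings):
        """Gene flow between replicons acts like mutation-selection balance:
        the losing location persists at a tiny frequency without changing
        the established outcome."""
        v = VariantConfig(transposition_rate=1e-9)
        eq = pf.reduced_equilibrium(params, "chromosomal_with_plasmid")
        res = pf.integrate(eq.state, params,
                           settings.replace(horizon=1e6, early_stop=None),
                           rhs=make_rhs(params, variant=v))
        SR = res.raw_state[IDX["SR"]]
        assert 0 < SR < 1e-4
        # the chromosomal resident is essentially unchanged
        assert res.raw_state[IDX["RS"]] == pytest.approx(
            eq.state[IDX["RS"]], rel=1e-3)


class TestDualResistanceModifiers:
    def test_knockout_abolishes_bistability(self, params):
        """No extra cost for the second copy removes the invasion barrier."""
        for A in (0.5, 1.0, 1.5):
            for cR in (0.02, 0.05, 0.2):
                r = dual_cost_regime(params.replace(A=A, cR=cR), 0.0)
                assert r != "bistable", (A, cR)

    def test_default_second_copy_cost_recovers_classification(self, params):
        for A in (0.5, 1.0):
            p = params.replace(A=A)
            assert dual_cost_regime(p, p.cR) == pf.classify_regime(p).regime

    def test_dual_resistance_dominates_without_extra_cost(self, params,
                                                          settings):
        v = VariantConfig(dual_cost_second_copy=0.0)
        n0 = pf.state_vector(S0=0.25, SR=0.25, R0=0.25, RS=0.25)
        res = pf.integrate(n0, params, settings, rhs=make_rhs(params,
                                                              variant=v))
        assert res.state[IDX["RR"]] > 0.1
        assert pf.classify_outcome(res.state) == "mixed"

    def test_dual_benefit_also_favors_dual_resistance(self, params, settings):
        """Partial single-copy protection plus no extra cost makes dual
        carriage strictly fittest."""
        v = VariantConfig(dual_cost_second_copy=0.0,
                          single_copy_protection=0.5)
        n0 = pf.state_vector(S0=0.25, SR=0.25, R0=0.25, RS=0.25)
        res = pf.integrate(n0, params, settings, rhs=make_rhs(params,
                                                              variant=v))
        assert res.state[IDX["RR"]] > 0.1


class TestFluctuation:
    def test_square_wave_schedule(self):
        f = FluctuationConfig(period=10.0, duty=0.3, A_on=1.0, A_off=0.2)
        assert f.value(0.0) == 1.0
        assert f.value(2.9) == 1.0
        assert f.value(3.1) == 0.2
        assert f.value(13.1) == 0.2

    def test_full_duty_matches_constant_antibiotic(self, params):
        # duty = 1 is constant pressure: both forms persist (bistable regime)
        df = fluctuation_experiment(params, periods=[20.0], duty=1.0)
        assert df["persists"].all()

    def test_no_antibiotic_loses_resistance(self, params):
        # duty = 0 removes selection; below the parasitic-persistence
        # threshold of beta the resistance gene is lost from both locations
        p = params.replace(beta=0.1)
        df = fluctuation_experiment(p, periods=[20.0], duty=0.0)
        assert not df["persists"].any()

    def test_bistability_robust_to_moderate_fluctuation(self, params):
        df = fluctuation_experiment(params, periods=[10.0, 50.0], duty=0.5)
        assert df["persists"].all()
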