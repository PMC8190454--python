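"""Candidate equilibria, Jacobian, stability verdicts, regime classification."""

import numpy as np
import pytest

import plasmidfate as pf
from plasmidfate.equilibria import (EQUILIBRIUM_LABELS, EquilibriumError,
                                    find_parasite_paradox_point)
from plasmidfate.model import IDX

from conftest import random_parameters


class TestReducedEquilibria:
    def test_chromosomal_no_plasmid_closed_form(self, params):
        eq = pf.reduced_equilibrium(params, "chromosomal_no_plasmid")
        assert eq.exists
        assert eq.state[IDX["R0"]] == pytest.approx(0.95, abs=1e-12)
        assert np.count_nonzero(eq.state) == 1

    def test_sensitive_no_plasmid_closed_form(self, params):
        eq = pf.reduced_equilibrium(params.replace(A=0.4),
                                    "sensitive_no_plasmid")
        assert eq.exists
        assert eq.state[IDX["S0"]] == pytest.approx(0.6, abs=1e-12)

    def test_sensitive_population_not_viable_at_high_antibiotic(self, params):
        # A >= lam: (lam - A)/gamma <= 0, susceptible cells cannot persist
        for A in (1.0, 1.7):
            eq = pf.reduced_equilibrium(params.replace(A=A),
                                        "sensitive_no_plasmid")
            assert not eq.exists

    @pytest.mark.parametrize("label", EQUILIBRIUM_LABELS)
    def test_residuals_within_tolerance(self, params, label):
        eq = pf.reduced_equilibrium(params, label)
        assert eq.residual <= 1e-10

    def test_zero_pattern_matches_label(self, params):
        eq = pf.reduced_equilibrium(params, "plasmid_borne")
        assert eq.exists
        support = {i for i in range(6) if eq.state[i] > 0}
        assert support == {IDX["S0"], IDX["SR"]}

    def test_plasmid_borne_confirmed_by_integration(self, params, settings,
                                                    rng):
        """Perturbed equilibrium relaxes back: it is a genuine attractor."""
        eq = pf.reduced_equilibrium(params, "plasmid_borne")
        pert = np.maximum(
            eq.state * (1 + 1e-3 * rng.standard_normal(6)), 0.0)
        res = pf.integrate(pert, params, settings)
        assert np.max(np.abs(res.raw_state - eq.state)) < 1e-6

    def test_unknown_label_rejected(self, params):
        with pytest.raises(ValueError):
            pf.reduced_equilibrium(params, "coexistence")

    def test_nontransmissible_plasmid_equilibria(self, params):
        # beta = 0 with s > 0: a plasmid riding a host type that has a
        # fitter plasmid-free competitor cannot persist ...
        p0 = params.replace(beta=0.0)
        for label in ("sensitive_with_plasmid", "chromosomal_with_plasmid"):
            assert not pf.reduced_equilibrium(p0, label).exists
        # ... the plasmid-borne-resistance state can still exist purely
        # vertically (the antibiotic kills its segregants' competitors),
        # but the resistant chromosome always invades it
        eq = pf.reduced_equilibrium(p0, "plasmid_borne")
        assert eq.exists
        assert not pf.stability(p0, "plasmid_borne").stable


class TestJacobian:
    def test_matches_finite_differences(self, params, rng):
        h = 1e-6
        for _ in range(100):
            p = random_parameters(rng)
            n = rng.uniform(0.0, 1.5, 6)
            J = pf.jacobian(n, p)
            Jfd = np.empty((6, 6))
            for j in range(6):
                e = np.zeros(6)
                e[j] = h
                Jfd[:, j] = (pf.rhs(0, n + e, p) - pf.rhs(0, n - e, p)) / (2 * h)
            assert np.max(np.abs(J - Jfd) / (1.0 + np.abs(Jfd))) < 1e-6

    def test_extinction_linearization(self, params):
        """At the empty state growth is linear: diagonal rates + s-influx."""
        J = pf.jacobian(np.zeros(6), params)
        p = params
        expected_diag = [p.lam - p.A, (1 - p.s) * p.lamP - p.A,
                         (1 - p.s) * p.lamRP, p.lamR,
                         (1 - p.s) * p.lamRP, (1 - p.s) * p.lamRRP]
        assert np.allclose(np.diag(J), expected_diag)
        # the R0 growth direction carries eigenvalue lamR
        assert p.lamR in np.round(np.linalg.eigvals(J).real, 12)

    def test_chromosome_relabeling_symmetry(self, rng):
        """With cR=0 and A=0 the model cannot tell R from S chromosomes."""
        p = pf.ModelParameters(cR=0.0, A=0.0)
        perm = [IDX["R0"], IDX["RS"], IDX["RR"], IDX["S0"], IDX["SS"],
                IDX["SR"]]
        P = np.eye(6)[perm]
        for _ in range(5):
            n = rng.uniform(0, 1, 6)
            assert np.allclose(pf.jacobian(P @ n, p), P @ pf.jacobian(n, p) @ P.T)


class TestStability:
    def test_both_resistance_locations_stable_at_reference(self, params):
        for label in ("chromosomal_with_plasmid", "plasmid_borne"):
            st = pf.stability(params, label)
            assert st.applicable and st.stable
            assert np.all(st.eigenvalues.real < 0)

    def test_nonexistent_equilibrium_not_applicable(self, params):
        st = pf.stability(params, "sensitive_no_plasmid")
        assert not st.applicable and not st.stable

    def test_resistance_unstable_without_antibiotic(self, params):
        # A = 0 and cR > 0: the sensitive chromosome invades
        st = pf.stability(params.replace(A=0.0), "chromosomal_no_plasmid")
        assert st.applicable and not st.stable
        assert st.max_real > 0

    def test_plasmid_free_chromosomal_invaded_by_sensitive_plasmid(self,
                                                                   params):
        # at the reference parameters the sensitive plasmid spreads into a
        # chromosomally resistant population, so the plasmid-free version is
        # unstable and the with-plasmid version is the stable chromosomal form
        assert not pf.stability(params, "chromosomal_no_plasmid").stable
        assert pf.stability(params, "chromosomal_with_plasmid").stable


class TestRegimeClassification:
    def test_reference_parameters_bistable(self, params):
        res = pf.classify_regime(params)
        assert res.regime == "bistable"
        assert res.plasmid_presence == "with_plasmid"
        assert not res.review

    def test_no_antibiotic_no_resistance(self, params):
        assert pf.classify_regime(params.replace(A=0.0)).regime == \
            "no_resistance"

    def test_nontransmissible_plasmid_never_bistable(self, params):
        for A in (0.5, 1.0, 1.5):
            r = pf.classify_regime(params.replace(beta=0.0, A=A))
            assert r.regime not in ("bistable", "plasmid_only")

    def test_low_resistance_cost_gives_chromosomal_only(self, params):
        # weak dual-cost barrier: the resistant plasmid invades chromosomally
        # resistant cells (via dual carriers) and vice versa fails
        assert pf.classify_regime(params.replace(cR=0.004)).regime == \
            "chromosomal_only"

    def test_phase_sweep_degenerate_grid_matches_pointwise(self, params):
        df = pf.phase_sweep(params, ("A", np.array([1.0])),
                            ("cR", np.array([0.05])))
        assert len(df) == 1
        assert df.loc[0, "regime"] == pf.classify_regime(params).regime

    def test_phase_sweep_schema_and_labels(self, params):
        df = pf.phase_sweep(params, ("A", np.linspace(0.2, 2.0, 4)),
                            ("cR", np.linspace(0.01, 0.4, 4)))
        assert len(df) == 16
        assert set(df["regime"]) <= {"no_resistance", "chromosomal_only",
                                     "plasmid_only", "bistable"}
        assert {"A", "cR", "plasmid_presence", "review"} <= set(df.columns)

    def test_sweep_axes_must_differ(self, params):
        with pytest.raises(ValueError):
            pf.phase_sweep(params, ("A", np.array([1.0])),
                           ("A", np.array([2.0])))


class TestParasitePersistence:
    def test_no_transmission_no_persistence(self, params):
        assert pf.parasite_persistence(params.replace(A=0.0, beta=0.0)) is False

    def test_free_lossless_plasmid_always_invades(self):
        p = pf.ModelParameters(s=0.0, cP=0.0, beta=0.1, A=0.0)
        assert pf.parasite_persistence(p) is True

    def test_not_applicable_when_hosts_not_viable(self, params):
        assert pf.parasite_persistence(params) is None  # A = lam

    def test_matches_two_type_equilibrium_stability(self, params):
        # where the invasion eigenvalue is positive, the host-plus-parasite
        # equilibrium exists and is stable within the sensitive subsystem
        p = params.replace(A=0.3)
        assert pf.parasite_persistence(p) is True
        eq = pf.reduced_equilibrium(p, "sensitive_with_plasmid")
        assert eq.exists

    def test_paradox_point_search(self):
        """There are parameters where the plasmid cannot persist as a
        parasite yet plasmid-borne resistance is evolutionarily stable."""
        p = find_parasite_paradox_point()
        assert p is not None
        assert pf.parasite_persistence(p) is False
        assert pf.stability(p, "plasmid_borne").stable
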