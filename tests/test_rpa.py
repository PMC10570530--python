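"""Elimination ideals, RPA polynomials, lift certificates and syzygies."""

import pytest
import sympy as sp

from crnrpa.crn import parse_reactions
from crnrpa.mass_action import build_ode_system
from crnrpa.rpa import (
    IdealMembershipError,
    classify_rpa,
    dynamic_stoichiometry_syzygies,
    elimination_ideal,
    integral_variable,
    lift_combination,
    linear_syzygies,
    rpa_report,
    steady_state_ideal,
)
from crnrpa.synthetic import RandomCrnConfig, random_crn

from _oracles import rank_fraction_elimination, stoichiometry_rows


@pytest.fixture(scope="module")
def gens(odes):
    return steady_state_ideal(odes)


@pytest.fixture(scope="module")
def ring(odes):
    return list(odes.variables) + list(odes.inputs)


def sym(odes, name):
    return odes.symbol(name)


class TestSteadyStateIdeal:
    def test_thirteen_generators(self, gens):
        assert len(gens) == 13

    def test_antithetic_difference_is_regulation_error(self, odes, gens):
        theta, mu, Ce = (sym(odes, n) for n in ("theta", "mu", "Ce"))
        assert sp.expand(gens[1] - gens[0] - (theta * Ce - mu)) == 0

    def test_empty_system(self):
        crn = parse_reactions("@chemostat A\n@species A\n")
        system = build_ode_system(crn)
        assert steady_state_ideal(system) == []


class TestEliminationIdeal:
    def test_sensor_species_gives_antithetic_polynomial(self, odes, gens, ring):
        Ce, CL = sym(odes, "Ce"), sym(odes, "CL")
        theta, mu = sym(odes, "theta"), sym(odes, "mu")
        ideal = elimination_ideal(gens, ring, [Ce, CL], verify_seeds=5)
        assert len(ideal) == 1
        # up to unit: content-free with positive leading coefficient
        assert sp.expand(ideal[0] - (theta * Ce - mu)) == 0

    def test_ester_pool(self, odes, gens, ring):
        E, CL = sym(odes, "E"), sym(odes, "CL")
        k7, k8, mu, theta = (sym(odes, n) for n in ("k7", "k8", "mu", "theta"))
        (gen,) = elimination_ideal(gens, ring, [E, CL], verify_seeds=3)
        (root,) = sp.solve(gen, E)
        assert sp.simplify(root - k7 * mu / (k8 * theta)) == 0

    def test_receptor_depends_on_input(self, odes, gens, ring):
        R, CL = sym(odes, "R"), sym(odes, "CL")
        (gen,) = elimination_ideal(gens, ring, [R, CL], verify_seeds=3)
        assert sp.Poly(gen, CL).degree() >= 1


class TestClassifyRpa:
    def test_accepts_antithetic_polynomial(self, odes):
        Ce, CL = sym(odes, "Ce"), sym(odes, "CL")
        theta, mu = sym(odes, "theta"), sym(odes, "mu")
        res = classify_rpa(theta * Ce - mu, Ce, CL)
        assert res is not None
        assert sp.simplify(res.setpoint - mu / theta) == 0
        assert res.verify()

    def test_accepts_constructed_factorization(self, odes):
        Ce, CL = sym(odes, "Ce"), sym(odes, "CL")
        res = classify_rpa((CL + 1) * (Ce - 5), Ce, CL)
        assert res is not None and res.setpoint == 5

    def test_rejects_input_dependent_root(self, odes):
        Ce, CL, mu = sym(odes, "Ce"), sym(odes, "CL"), sym(odes, "mu")
        assert classify_rpa(Ce * CL - mu, Ce, CL) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_recovers_setpoint(self, odes, seed):
        import random

        rng = random.Random(seed)
        Ce, CL = sym(odes, "Ce"), sym(odes, "CL")
        mu, theta, k7 = (sym(odes, n) for n in ("mu", "theta", "k7"))
        c = sp.Rational(rng.randint(1, 9), rng.randint(1, 5)) * mu / theta
        g = (
            rng.randint(1, 4) * k7
            + rng.randint(0, 3) * CL
            + rng.randint(0, 2) * Ce * CL
        )
        res = classify_rpa(sp.expand(g * (Ce - c)), Ce, CL)
        assert res is not None
        assert sp.simplify(res.setpoint - c) == 0


class TestLift:
    def test_antithetic_certificate(self, odes, gens, ring):
        Ce = sym(odes, "Ce")
        theta, mu = sym(odes, "theta"), sym(odes, "mu")
        cert = lift_combination(gens, theta * Ce - mu, ring)
        assert cert.coefficients == (-1, 1) + (0,) * 11
        assert cert.is_constant and cert.unique
        assert cert.verify(gens)

    def test_single_generator_target(self, odes, gens, ring):
        cert = lift_combination(gens, gens[2], ring)
        assert cert.coefficients[2] == 1
        assert sum(map(abs, cert.coefficients)) == 1

    def test_zero_target(self, gens, ring):
        cert = lift_combination(gens, sp.Integer(0), ring)
        assert all(c == 0 for c in cert.coefficients)

    def test_non_member_raises(self, odes, gens, ring):
        Ce = sym(odes, "Ce")
        with pytest.raises(IdealMembershipError):
            lift_combination(gens, Ce + 1, ring)

    def test_integral_variable_is_sequestration_difference(self, odes, gens, ring):
        Ce = sym(odes, "Ce")
        theta, mu = sym(odes, "theta"), sym(odes, "mu")
        cert = lift_combination(gens, theta * Ce - mu, ring)
        ivar = integral_variable(cert, odes.variables)
        C, Sci = sym(odes, "C"), sym(odes, "Sci")
        assert sp.expand(ivar - (C - Sci)) == 0

    def test_integral_variable_trivial_and_degenerate(self, odes, gens, ring):
        cert3 = lift_combination(gens, gens[2], ring)
        assert integral_variable(cert3, odes.variables) == sym(odes, "Sr")
        cert0 = lift_combination(gens, sp.Integer(0), ring)
        assert integral_variable(cert0, odes.variables) == 0


class TestSyzygies:
    def test_cholesterol_has_no_conservation_laws(self, gens, ring):
        assert linear_syzygies(gens, ring).linear_syzygies == ()

    def test_closed_conversion_conserves_total(self):
        crn = parse_reactions("A -> B ; rate=k")
        system = build_ode_system(crn)
        report = linear_syzygies(
            steady_state_ideal(system), list(system.variables)
        )
        assert len(report.linear_syzygies) == 1
        (vec,) = report.linear_syzygies
        assert vec[0] == vec[1] != 0
        assert report.verify(steady_state_ideal(system))

    @pytest.mark.parametrize("seed", range(12))
    def test_dimension_matches_rank_nullity(self, seed):
        crn = random_crn(RandomCrnConfig(n_species=4, n_reactions=5, seed=seed))
        system = build_ode_system(crn)
        gens = steady_state_ideal(system)
        ring = list(system.variables) + list(system.inputs)
        basis = linear_syzygies(gens, ring)
        rank = rank_fraction_elimination(stoichiometry_rows(crn, dynamic_only=True))
        assert len(basis.linear_syzygies) == len(crn.dynamic_species) - rank
        assert basis.verify(gens)
        # agrees with the stoichiometric-matrix formulation
        alt = dynamic_stoichiometry_syzygies(crn)
        assert len(alt.linear_syzygies) == len(basis.linear_syzygies)


@pytest.fixture(scope="module")
def report(crn, odes):
    return rpa_report(crn, odes)


class TestRpaReport:
    def test_four_rpa_species_with_printed_setpoints(self, odes, report):
        k4, k5, k6, k7, k8, k12 = (
            sym(odes, n) for n in ("k4", "k5", "k6", "k7", "k8", "k12")
        )
        mu, theta, alpha = (sym(odes, n) for n in ("mu", "theta", "alpha"))
        expected = {
            "Ce": mu / theta,
            "Cp": ((k6 + k12) * mu - theta * alpha) / (k5 * theta),
            "Cf": (k12 * mu - theta * alpha) / (k4 * theta),
            "E": k7 * mu / (k8 * theta),
        }
        assert set(report.rpa_species) == set(expected)
        for name, expr in expected.items():
            assert sp.simplify(report.rpa_species[name] - expr) == 0

    def test_nine_non_rpa_species(self, report):
        assert len(report.non_rpa_species) == 9
        assert set(report.non_rpa_species) == {
            "Sci", "C", "Sr", "Sh", "R", "HR", "H", "Sp", "P",
        }

    def test_integral_variable_and_unique_certificate(self, odes, report):
        C, Sci = sym(odes, "C"), sym(odes, "Sci")
        assert sp.expand(report.integral_variable - (C - Sci)) == 0
        assert report.certificate.unique
        assert report.syzygies.linear_syzygies == ()

    def test_matches_graph_screen(self, crn, subnets, report):
        from crnrpa.graph import shinar_feinberg_screen

        screen = shinar_feinberg_screen(crn.subnetwork(subnets["subnetwork_1"]))
        assert set(report.rpa_species) == set(screen.species)

    def test_setpoints_satisfy_steady_state(self, steady_state, report, odes):
        ss = steady_state.by_name()
        for name, setpoint in report.rpa_species.items():
            assert sp.simplify(ss[name] - setpoint) == 0

    def test_pure_degradation_has_no_rpa(self):
        crn = parse_reactions("@chemostat B\nA -> B ; rate=k")
        assert rpa_report(crn).rpa_species == {}
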