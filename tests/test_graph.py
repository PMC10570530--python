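"""Graph invariants, decompositions and the Shinar-Feinberg screen."""

import pytest

from crnrpa.crn import parse_reactions
from crnrpa.graph import (
    SubnetworkPartition,
    deficiency,
    enumerate_complexes,
    linkage_classes,
    shinar_feinberg_screen,
    stoichiometric_rank,
    strong_linkage_classes,
    verify_independent_decomposition,
)
from crnrpa.crn import ValidationError
from crnrpa.synthetic import RandomCrnConfig, random_crn

from _oracles import (
    count_complexes_bruteforce,
    linkage_classes_union_find,
    rank_fraction_elimination,
    stoichiometry_rows,
    strong_components_reachability,
)

AB = parse_reactions("A -> B ; rate=k")
ABC = parse_reactions("A -> B ; rate=k1\nB -> C ; rate=k2")
AB_REV = parse_reactions("A <-> B ; fwd=k1, rev=k2")

RANDOM_CORPUS = [
    random_crn(RandomCrnConfig(n_species=4 + s % 3, n_reactions=3 + s % 5, seed=s))
    for s in range(60)
]


class TestComplexEnumeration:
    def test_cholesterol_has_23_complexes(self, crn):
        assert len(enumerate_complexes(crn)) == 23

    def test_trivial(self):
        assert len(enumerate_complexes(AB)) == 2

    @pytest.mark.parametrize("i", range(0, 60, 3))
    def test_matches_bruteforce_oracle(self, i):
        net = RANDOM_CORPUS[i]
        assert len(enumerate_complexes(net)) == count_complexes_bruteforce(net)


class TestLinkageClasses:
    def test_cholesterol_two_classes_with_uptake_pair(self, crn):
        classes = linkage_classes(crn)
        assert len(classes) == 2
        sizes = sorted(len(cls) for cls in classes)
        small = min(classes, key=len)
        assert sizes == [2, 21]
        assert {str(cx) for cx in small} == {"CL + R", "Cf + R"}

    def test_chain_is_single_class(self):
        assert len(linkage_classes(ABC)) == 1

    @pytest.mark.parametrize("i", range(1, 60, 3))
    def test_matches_union_find_oracle(self, i):
        net = RANDOM_CORPUS[i]
        ours = {frozenset(tuple(sorted(c.terms)) for c in cls)
                for cls in linkage_classes(net)}
        assert ours == set(map(frozenset, linkage_classes_union_find(net)))


class TestStrongLinkageClasses:
    def test_reversible_pair_is_terminal(self):
        classes = strong_linkage_classes(AB_REV)
        assert len(classes) == 1
        scc, terminal = classes[0]
        assert len(scc) == 2 and terminal

    def test_subnetwork_1a_nonterminal_complexes(self, crn, subnets):
        sub = crn.subnetwork(subnets["subnetwork_1A"])
        summary = deficiency(sub)
        names = {str(c) for c in summary.nonterminal_complexes}
        assert {"Ce", "∅"} <= names
        assert names == {"∅", "C + Sci", "Ce"}

    @pytest.mark.parametrize("i", range(2, 60, 3))
    def test_matches_reachability_oracle(self, i):
        net = RANDOM_CORPUS[i]
        ours = {frozenset(tuple(sorted(c.terms)) for c in scc)
                for scc, _ in strong_linkage_classes(net)}
        assert ours == set(map(frozenset, strong_components_reachability(net)))


class TestRank:
    def test_subnetwork_1_rank(self, crn, subnets):
        assert stoichiometric_rank(crn.subnetwork(subnets["subnetwork_1"])) == 5

    def test_trivial(self):
        assert stoichiometric_rank(AB) == 1

    def test_full_network_rank_is_exactly_14(self, crn):
        # the rank of a 14-species system cannot exceed 14, and the exact
        # fraction-free oracle confirms it is attained
        assert stoichiometric_rank(crn) == 14
        assert rank_fraction_elimination(stoichiometry_rows(crn)) == 14


class TestDeficiency:
    def test_subnetwork_1(self, crn, subnets):
        s = deficiency(crn.subnetwork(subnets["subnetwork_1"]))
        assert (s.m, s.l, s.s, s.deficiency) == (8, 2, 5, 1)

    def test_reversible_pair(self):
        assert deficiency(AB_REV).deficiency == 0

    def test_subnetwork_1a_1b(self, crn, subnets):
        a = deficiency(crn.subnetwork(subnets["subnetwork_1A"]))
        b = deficiency(crn.subnetwork(subnets["subnetwork_1B"]))
        assert (a.m, a.l, a.s, a.deficiency) == (5, 2, 2, 1)
        assert b.deficiency == 0

    def test_full_network_computed_values(self, crn):
        s = deficiency(crn)
        assert (s.m, s.l, s.s, s.deficiency) == (23, 2, 14, 7)


class TestDecomposition:
    def test_top_level_partition_independent(self, crn, subnets):
        part = SubnetworkPartition(
            {k: subnets[k] for k in ("subnetwork_1", "subnetwork_2")}
        )
        rep = verify_independent_decomposition(crn, part)
        assert rep.independent
        assert rep.rank_sum == rep.parent_rank == 14
        assert rep.summaries["subnetwork_1"].s == 5
        assert rep.summaries["subnetwork_2"].s == 9

    def test_refinement_of_subnetwork_1(self, crn, subnets):
        sub1 = crn.subnetwork(subnets["subnetwork_1"])
        local = {
            "1A": tuple(subnets["subnetwork_1"].index(i) for i in subnets["subnetwork_1A"]),
            "1B": tuple(subnets["subnetwork_1"].index(i) for i in subnets["subnetwork_1B"]),
        }
        rep = verify_independent_decomposition(sub1, SubnetworkPartition(local))
        assert rep.independent
        assert rep.summaries["1A"].s == 2 and rep.summaries["1B"].s == 3
        assert rep.rank_sum == 5

    def test_trivial_partition_independent(self, crn):
        part = SubnetworkPartition({"all": tuple(range(len(crn.reactions)))})
        assert verify_independent_decomposition(crn, part).independent

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_split_flag_matches_direct_ranks(self, crn, seed):
        import random

        rng = random.Random(seed)
        idx = list(range(len(crn.reactions)))
        rng.shuffle(idx)
        cut = rng.randint(3, 20)
        part = SubnetworkPartition({"a": idx[:cut], "b": idx[cut:]})
        rep = verify_independent_decomposition(crn, part)
        direct = (
            stoichiometric_rank(crn.subnetwork(idx[:cut]))
            + stoichiometric_rank(crn.subnetwork(idx[cut:]))
        )
        assert rep.rank_sum == direct
        assert rep.independent == (direct == 14)

    def test_incomplete_partition_rejected(self, crn):
        with pytest.raises(ValidationError):
            verify_independent_decomposition(
                crn, SubnetworkPartition({"a": (0, 1, 2)})
            )


class TestShinarFeinberg:
    def test_subnetwork_1a_witness(self, crn, subnets):
        res = shinar_feinberg_screen(crn.subnetwork(subnets["subnetwork_1A"]))
        assert res.applicable
        assert res.species == {"Ce"}
        ((species, (a, b)),) = res.hits
        assert species == "Ce"
        assert {str(a), str(b)} == {"∅", "Ce"}

    def test_subnetwork_1_species_set(self, crn, subnets):
        res = shinar_feinberg_screen(crn.subnetwork(subnets["subnetwork_1"]))
        assert res.species == {"Ce", "Cp", "Cf", "E"}

    def test_not_applicable_at_deficiency_zero(self):
        res = shinar_feinberg_screen(AB_REV)
        assert not res.applicable and res.hits == ()


class TestInvariants:
    """Structural invariants over the random corpus."""

    @pytest.mark.parametrize("i", range(60))
    def test_summary_consistency(self, i):
        net = RANDOM_CORPUS[i]
        s = deficiency(net)
        assert s.deficiency >= 0
        assert s.m == len(enumerate_complexes(net))
        assert s.l <= s.m
        assert s.s <= min(len(net.species), len(net.reactions))
        assert sum(len(lc) for lc in s.linkage_classes) == s.m
        # every SCC is contained in one linkage class
        for scc in s.strong_classes:
            containers = [lc for lc in s.linkage_classes if set(scc) <= set(lc)]
            assert len(containers) == 1
        # terminal + nonterminal == all complexes
        terminal_members = {c for tc in s.terminal_classes for c in tc}
        assert terminal_members | set(s.nonterminal_complexes) == set(
            enumerate_complexes(net)
        )
        assert not terminal_members & set(s.nonterminal_complexes)
        # exact rank agrees with the Fraction elimination oracle
        assert s.s == rank_fraction_elimination(stoichiometry_rows(net))
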