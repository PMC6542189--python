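"""Combinatorics of the variant space, half-site groups, and state algebra."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from invsym import (
    SCHEMAS,
    HIERARCHIES,
    VacancyHierarchy,
    VariantElement,
    axis_order,
    count_distinct_states,
    element_from_id,
    enumerate_half_site_groups,
    enumerate_variants,
    ere_grouping,
    group_members,
    grouping_from_signature,
    hre_grouping,
    iter_variants,
    revcomp,
    state_of_group,
    state_vector,
    variant_count,
)
from invsym.element_space import HalfSiteGroup


class TestSchema:
    def test_consensus_is_perfect_inverted_repeat(self):
        for schema in SCHEMAS.values():
            for p in range(1, schema.n + 1):
                b = schema.consensus_base(p)
                assert b == revcomp(schema.consensus_base(schema.n + 1 - p))
            assert revcomp(schema.consensus) == schema.consensus

    @pytest.mark.parametrize(
        "name,consensus",
        [
            ("ERE13", "GGTCANNNTGACC"),
            ("HRE13", "GAACANNNTGTTC"),
            ("ERE15", "AGGTCANNNTGACCT"),
            ("HRE15", "AGAACANNNTGTTCT"),
            ("P53RE", "TGCCCGGGCA"),
        ],
    )
    def test_known_consensus_sequences(self, name, consensus):
        assert SCHEMAS[name].consensus == consensus

    def test_pair_map_is_involution(self, ere13):
        for pair in ere13.pairs:
            assert ere13.pair_of(pair.high) == pair
        assert len(ere13.pairs) == 5


class TestEnumeration:
    @pytest.mark.parametrize(
        "k,expected", [(0, 1), (1, 30), (2, 405), (3, 3240), (4, 17010), (5, 61236)]
    )
    def test_level_sizes_10_positions(self, ere13, k, expected):
        assert variant_count(ere13, k) == expected
        if k <= 2:
            elems = enumerate_variants(ere13, k)
            assert len(elems) == expected
            assert len(set(e.element_id for e in elems)) == expected

    def test_cumulative_totals(self, ere13, ere15):
        assert sum(variant_count(ere13, k) for k in range(6)) == 81_922
        assert variant_count(ere15, 6) == 673_596
        assert sum(variant_count(ere15, k) for k in range(7)) == 912_718

    def test_enumeration_matches_closed_form(self, ere13):
        for k in range(4):
            assert sum(1 for _ in iter_variants(ere13, k)) == variant_count(ere13, k)

    def test_k_out_of_range(self, ere13):
        with pytest.raises(ValueError):
            enumerate_variants(ere13, 11)
        with pytest.raises(ValueError):
            enumerate_variants(ere13, -1)

    def test_realized_length_and_spacer_untouched(self, ere13):
        for e in iter_variants(ere13, 2):
            seq = e.realize()
            assert len(seq) == ere13.footprint
            assert seq[5:8] == "NNN"
            break

    def test_substitution_must_differ_from_consensus(self, ere13):
        with pytest.raises(ValueError):
            VariantElement(ere13, ((1, "G"),))  # G is the consensus base at 1


class TestReverseComplement:
    def test_consensus_is_self_rc(self, ere13):
        e = VariantElement(ere13)
        assert e.reverse_complement() == e

    def test_mirror_example_1T_to_10A(self, ere13):
        e = element_from_id(ere13, "1T")
        assert e.realize() == "TGTCANNNTGACC"
        rc = e.reverse_complement()
        assert rc.element_id == "10A"
        assert rc.realize() == "GGTCANNNTGACA"
        assert rc.realize() == revcomp(e.realize())

    def test_involution_exhaustive_low_levels(self, ere13):
        for k in (1, 2):
            for e in iter_variants(ere13, k):
                assert e.reverse_complement().reverse_complement() == e
                assert e.reverse_complement().k == e.k

    def test_rc_is_bijection_of_each_level(self, ere13):
        level = set(e.element_id for e in iter_variants(ere13, 2))
        image = set(e.reverse_complement().element_id for e in iter_variants(ere13, 2))
        assert level == image

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_rc_realizes_biological_revcomp(self, data):
        schema = SCHEMAS[data.draw(st.sampled_from(sorted(SCHEMAS)))]
        k = data.draw(st.integers(0, 4))
        positions = data.draw(
            st.lists(
                st.integers(1, schema.n), min_size=k, max_size=k, unique=True
            )
        )
        subs = []
        for p in positions:
            alt = [b for b in "ACGT" if b != schema.consensus_base(p)]
            subs.append((p, data.draw(st.sampled_from(alt))))
        e = VariantElement(schema, tuple(subs))
        assert e.reverse_complement().realize() == revcomp(e.realize())


class TestHalfSiteGroups:
    def test_group_count_and_vacancy_census(self, ere13):
        groups = enumerate_half_site_groups(ere13)
        assert len(groups) == 252
        reps = [g for g in groups if sorted(g.fixed) <= sorted(g.rc_fixed())]
        assert len(reps) == 126
        census = Counter(len(g.vacancies) for g in reps)
        assert census == {0: 16, 1: 80, 2: 30}

    def test_structural_invariants(self, ere13, ere15):
        for schema in (ere13, ere15):
            for g in enumerate_half_site_groups(schema):
                assert len(g.vacancies) == len(g.double_occupants)
                assert (
                    len(g.vacancies) + len(g.double_occupants) + len(g.singles)
                    == schema.n // 2
                )
                assert g.rc_group.rc_group == g
                # closure under the pair map <=> every pair contributes 0 or 2
                assert g.innate == (len(g.singles) == 0)
            if schema.n == 10:
                assert not any(g.innate for g in enumerate_half_site_groups(schema))

    def test_15nt_taxonomy(self, ere15):
        groups = enumerate_half_site_groups(ere15)
        assert len(groups) == 924
        assert sum(g.innate for g in groups) == 20
        for g in groups:
            if g.innate:
                assert len(g.vacancies) == 3 and not g.singles

    def test_group_census_identity(self, ere13, ere15):
        # sum over vacancy counts v of C(h,v)*C(h-v,v)*2^(h-2v) = C(n, h)
        for schema in (ere13, ere15):
            h = schema.n // 2
            total = sum(
                math.comb(h, v) * math.comb(h - v, v) * 2 ** (h - 2 * v)
                for v in range(h // 2 + 1)
            )
            assert total == math.comb(schema.n, h)
            census = Counter(
                len(g.vacancies) for g in enumerate_half_site_groups(schema)
            )
            for v in census:
                assert census[v] == math.comb(h, v) * math.comb(h - v, v) * 2 ** (
                    h - 2 * v
                )

    def test_example_group_classification(self, ere13):
        g = HalfSiteGroup(ere13, frozenset({2, 4, 5, 7, 9}))
        assert {p.label for p in g.vacancies} == {"1-10", "3-8"}
        assert {p.label for p in g.double_occupants} == {"2-9", "4-7"}
        assert g.vacancy_label == "2V1-3"

    def test_group_members_palindrome_half_site(self, ere13):
        g = HalfSiteGroup(ere13, frozenset({1, 2, 3, 4, 5}))
        ids = sorted(e.element_id for e in group_members(g, 1))
        expected = sorted(
            ["6A", "6C", "6G", "7A", "7C", "7T", "8C", "8G", "8T",
             "9A", "9G", "9T", "10A", "10G", "10T"]
        )
        assert ids == expected

    def test_members_per_group_totals(self, ere13, ere15):
        g13 = enumerate_half_site_groups(ere13)[0]
        sizes = [len(group_members(g13, k)) for k in range(6)]
        assert sizes == [1, 15, 90, 270, 405, 243]
        assert sum(sizes) == 1024
        g15 = enumerate_half_site_groups(ere15)[0]
        assert sum(len(group_members(g15, k)) for k in range(7)) == 4096

    def test_level1_membership_count_identity(self, ere13):
        # every 1-nt variant belongs to exactly C(n-1, n/2) = 126 groups
        groups = enumerate_half_site_groups(ere13)
        e = element_from_id(ere13, "3C")
        n_containing = sum(g.contains(e) for g in groups)
        assert n_containing == math.comb(9, 5) == 126
        assert 30 * 126 == 252 * 15

    def test_member_k_out_of_range(self, ere13):
        g = enumerate_half_site_groups(ere13)[0]
        with pytest.raises(ValueError):
            group_members(g, 6)


class TestAxisOrder:
    def test_ends_are_the_palindrome_half_sites(self, ere13):
        groups = enumerate_half_site_groups(ere13)
        order = axis_order(groups, HIERARCHIES["ERE13"])
        assert groups[order[0]].gid == "1-2-3-4-5"
        assert groups[order[-1]].gid == "6-7-8-9-10"

    def test_mirror_pairing(self, ere13):
        groups = enumerate_half_site_groups(ere13)
        order = axis_order(groups, HIERARCHIES["ERE13"])
        for i in range(252):
            assert groups[order[i]].rc_group.fixed == groups[order[251 - i]].fixed

    def test_left_block_sorted_by_vacancy_count(self, ere13):
        groups = enumerate_half_site_groups(ere13)
        order = axis_order(groups, HIERARCHIES["ERE13"])
        vacancies = [len(groups[i].vacancies) for i in order[:126]]
        assert vacancies == sorted(vacancies)
        assert Counter(vacancies) == {0: 16, 1: 80, 2: 30}

    def test_innate_center_block_15nt(self, ere15):
        groups = enumerate_half_site_groups(ere15)
        order = axis_order(groups, HIERARCHIES["ERE15"])
        assert len(order) == 924
        center = order[452:472]
        assert all(groups[i].innate for i in center)
        assert not any(groups[i].innate for i in order[:452] + order[472:])

    def test_bad_hierarchy_rejected(self, ere13):
        groups = enumerate_half_site_groups(ere13)
        with pytest.raises(ValueError):
            axis_order(groups, VacancyHierarchy((1, 2, 3, 4, 4)))


class TestStateAlgebra:
    def test_state_examples(self, ere13, hre13):
        ere = ere_grouping(ere13)
        g = HalfSiteGroup(ere13, frozenset({2, 4, 5, 7, 9}))  # V = {3-8, 1-10}
        assert state_of_group(g, ere) == 2.0
        zero_vac = HalfSiteGroup(ere13, frozenset({1, 2, 3, 4, 5}))
        assert state_of_group(zero_vac, ere) == 0.0
        hre = hre_grouping(hre13)
        g2 = HalfSiteGroup(hre13, frozenset({2, 9, 1, 3, 4}))  # 2-9 doubly occupied
        assert state_of_group(g2, hre) == -1.0

    def test_rc_preserves_state_complement_negates_it(self, ere13):
        # the pair map keeps each pair's number of fixed members, so a group
        # and its reverse complement share a plateau (mirror-symmetric
        # profile); fixing the complementary positions swaps V with D and
        # negates the state
        grouping = ere_grouping(ere13)
        for g in enumerate_half_site_groups(ere13):
            s = state_of_group(g, grouping)
            assert state_of_group(g.rc_group, grouping) == s
            assert state_of_group(g.complement_group, grouping) == -s
            assert set(g.complement_group.vacancies) == set(g.double_occupants)

    @pytest.mark.parametrize(
        "signature,n_states",
        [
            ((4, 1, 0, 0, 0), 3),
            ((3, 2, 0, 0, 0), 5),
            ((3, 1, 1, 0, 0), 9),
            # direct enumeration with generic weights: the two-class-of-two
            # partition admits 13 states (six +/- ladder pairs around zero)
            ((2, 2, 1, 0, 0), 13),
            ((2, 1, 1, 1, 0), 25),
            ((1, 1, 1, 1, 1), 51),
        ],
    )
    def test_distinct_state_counts(self, ere13, signature, n_states):
        result = count_distinct_states(ere13, signature)
        assert result.n_states == n_states
        assert sum(result.census.values()) == 252

    @pytest.mark.parametrize(
        "signature",
        [(4, 1, 0, 0, 0), (3, 2, 0, 0, 0), (3, 1, 1, 0, 0),
         (2, 2, 1, 0, 0), (2, 1, 1, 1, 0), (1, 1, 1, 1, 1)],
    )
    def test_generic_weight_bruteforce_oracle(self, ere13, signature):
        """Numeric oracle: square roots of distinct primes as weights,
        distinctness decided at 1e-9; must agree with the exact vector count."""
        grouping = grouping_from_signature(ere13, signature)
        primes = [2, 3, 5, 7, 11]
        labels = grouping.class_labels
        w = {lab: primes[i] ** 0.5 for i, lab in enumerate(labels)}
        values = []
        for g in enumerate_half_site_groups(ere13):
            s = sum(w[grouping.classes[p.low]] for p in g.vacancies)
            s -= sum(w[grouping.classes[p.low]] for p in g.double_occupants)
            values.append(s)
        values.sort()
        distinct = 1 + sum(
            1 for a, b in zip(values, values[1:]) if abs(b - a) > 1e-9
        )
        assert distinct == count_distinct_states(ere13, signature).n_states

    def test_plateau_censuses(self, ere13, hre13):
        ere = count_distinct_states(ere13, ere_grouping(ere13))
        assert sorted(ere.census.values()) == [6, 6, 60, 60, 120]
        hre = count_distinct_states(hre13, hre_grouping(hre13))
        assert sorted(hre.census.values()) == [56, 56, 140]

    def test_census_symmetric_about_zero(self, ere13):
        grouping = ere_grouping(ere13)
        census = Counter()
        for g in enumerate_half_site_groups(ere13):
            census[state_of_group(g, grouping)] += 1
        for s, n in census.items():
            assert census[-s] == n

    def test_signature_property(self, ere13):
        assert ere_grouping(ere13).signature == (3, 2, 0, 0, 0)
        assert hre_grouping().signature == (4, 1, 0, 0, 0)
        with pytest.raises(ValueError):
            grouping_from_signature(ere13, (3, 3, 0, 0, 0))

    def test_state_vector_consistency(self, ere13):
        grouping = ere_grouping(ere13)
        for g in enumerate_half_site_groups(ere13)[:40]:
            vec = state_vector(g, grouping)
            numeric = sum(
                c * grouping.weights[lab]
                for c, lab in zip(vec, grouping.class_labels)
            )
            assert numeric == state_of_group(g, grouping)
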