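"""Scoring rules: band lookups, boundary closures, range and monotonicity."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import nephroscore as ns
from nephroscore.scoring import (
    AnatomicClass,
    Hydronephrosis,
    enumerate_shalin_totals,
    enumerate_stone_totals,
)

from conftest import make_profile

H = Hydronephrosis
A = AnatomicClass


class TestStoneBurden:
    @pytest.mark.parametrize(
        "stones, expected",
        [
            ([(30, 20)], 600.0),
            ([(30, 20), (10, 10)], 700.0),
            ([(40, 40)], 1600.0),
        ],
    )
    def test_rectangle_area_sum(self, stones, expected):
        assert ns.stone_burden_total(stones) == pytest.approx(expected)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ns.stone_burden_total([])

    def test_ellipse_option_applies_pi_over_4(self):
        rules = ns.load_rules()
        from dataclasses import replace

        ellipse = replace(rules, area_formula="ellipse")
        assert ns.stone_burden_total([(30, 20)], rules=ellipse) == pytest.approx(
            math.pi / 4 * 600.0
        )

    @given(
        st.lists(
            st.tuples(
                st.floats(1.0, 100.0, allow_nan=False),
                st.floats(1.0, 100.0, allow_nan=False),
            ),
            min_size=1,
            max_size=6,
        ),
        st.lists(
            st.tuples(
                st.floats(1.0, 100.0, allow_nan=False),
                st.floats(1.0, 100.0, allow_nan=False),
            ),
            min_size=1,
            max_size=6,
        ),
    )
    def test_additivity_over_concatenation(self, part_a, part_b):
        total = ns.stone_burden_total(part_a + part_b)
        assert total == pytest.approx(
            ns.stone_burden_total(part_a) + ns.stone_burden_total(part_b)
        )

    def test_largest_stone_selects_max_area(self):
        assert ns.largest_stone_area([(30, 20), (40, 40), (10, 5)]) == 1600.0


class TestMeanHu:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ((900, 900, 900, 900, 900), 900.0),
            ((800, 900, 1000, 1100, 1200), 1000.0),
            ((951, 950, 950, 950, 950), 950.2),
        ],
    )
    def test_mean(self, points, expected):
        assert ns.mean_ct_hu(points) == pytest.approx(expected)

    @pytest.mark.parametrize("points", [(900,) * 4, (900,) * 6, ()])
    def test_wrong_count_rejected(self, points):
        with pytest.raises(ValueError):
            ns.mean_ct_hu(points)


class TestShalinComponents:
    def test_all_minimum_case(self):
        p = make_profile(stones=((30, 10),), tract_length_mm=90, hu_points=(800,) * 5,
                         involved_calyces=2)
        assert tuple(ns.shalin_components(p)) == (1, 1, 1, 1, 1, 1)
        assert ns.shalin_total(p) == 6

    def test_all_maximum_case(self):
        p = make_profile(
            stones=((170, 10),), hydronephrosis=H.SEVERE, anatomic_class=A.COMPLETE_STAGHORN,
            tract_length_mm=110, hu_points=(1000,) * 5, involved_calyces=4)
        assert tuple(ns.shalin_components(p)) == (4, 3, 4, 2, 2, 2)
        assert ns.shalin_total(p) == 17

    def test_band_edges_closed_on_printed_side(self):
        # burden exactly 400 starts the second band; tract exactly 100 and a
        # mean HU of exactly 950 stay in the low-point category
        p = make_profile(stones=((40, 10),), tract_length_mm=100.0, hu_points=(950,) * 5)
        c = ns.shalin_components(p)
        assert (c.s, c.l, c.i) == (2, 1, 1)

    def test_zero_calyces_counts_as_low_band(self):
        # a pure pelvic stone involves no calyx and still scores 1 point
        p = make_profile(involved_calyces=0)
        assert ns.shalin_components(p).n == 1

    def test_hand_summed_mixed_case(self):
        p = make_profile(
            stones=((90, 10),), hydronephrosis=H.MODERATE, anatomic_class=A.UPPER_CALYX,
            tract_length_mm=80, hu_points=(960,) * 5, involved_calyces=2)
        assert tuple(ns.shalin_components(p)) == (3, 2, 2, 1, 2, 1)
        assert ns.shalin_total(p) == 11


class TestStrata:
    @pytest.mark.parametrize(
        "total, label",
        [(6, "6-8"), (7, "6-8"), (8, "6-8"), (9, "9-11"), (11, "9-11"),
         (12, "12-14"), (14, "12-14"), (15, "15-17"), (17, "15-17")],
    )
    def test_shalin_stratum_bands(self, total, label):
        assert ns.shalin_stratum(total) == label

    @pytest.mark.parametrize("total", [5, 18, 0])
    def test_out_of_range_total_rejected(self, total):
        with pytest.raises(ValueError):
            ns.shalin_stratum(total)

    @pytest.mark.parametrize(
        "total, label", [(5, "5-6"), (6, "5-6"), (7, "7-8"), (8, "7-8"), (9, "9-13"), (13, "9-13")]
    )
    def test_stone_stratum_bands(self, total, label):
        assert ns.stone_stratum(total) == label


class TestStoneScore:
    def test_all_minimum_profile(self):
        p = make_profile(stones=((30, 10),), tract_length_mm=90, hu_points=(900,) * 5,
                         involved_calyces=2)
        comps, total, stratum = ns.stone_nephrolithometry(p)
        assert tuple(comps) == (1, 1, 1, 1, 1)
        assert (total, stratum) == (5, "5-6")

    def test_all_maximum_profile(self):
        p = make_profile(
            stones=((160, 10),), hydronephrosis=H.SEVERE, anatomic_class=A.COMPLETE_STAGHORN,
            tract_length_mm=110, hu_points=(1000,) * 5, involved_calyces=4)
        comps, total, stratum = ns.stone_nephrolithometry(p)
        assert tuple(comps) == (4, 2, 2, 3, 2)
        assert (total, stratum) == (13, "9-13")

    def test_hand_summed_mixed_case(self):
        p = make_profile(stones=((50, 10),), hydronephrosis=H.MODERATE,
                         tract_length_mm=90, hu_points=(900,) * 5, involved_calyces=2)
        comps, total, stratum = ns.stone_nephrolithometry(p)
        assert tuple(comps) == (2, 1, 2, 1, 1)
        assert (total, stratum) == (7, "7-8")

    def test_size_uses_largest_stone_not_sum(self):
        # two 500 mm^2 stones: SHA.LIN burden band sees 1000, S.T.O.N.E. sees 500
        p = make_profile(stones=((50, 10), (50, 10)))
        assert ns.shalin_components(p).s == 3
        assert ns.stone_nephrolithometry(p)[0].s == 2

    def test_density_boundary_differs_from_shalin(self):
        # exactly 950 HU: SHA.LIN scores low (<=950), S.T.O.N.E. high (>=950)
        p = make_profile(hu_points=(950,) * 5)
        assert ns.shalin_components(p).i == 1
        assert ns.stone_nephrolithometry(p)[0].e == 2


class TestGuysGrade:
    @pytest.mark.parametrize(
        "kwargs, count, expected",
        [
            (dict(), 1, "I"),  # solitary pelvic stone, normal anatomy
            (dict(anatomic_class=A.UPPER_CALYX), 1, "II"),
            (dict(), 3, "II"),  # multiple stones, normal anatomy
            (dict(abnormal_anatomy=True), 1, "II"),
            (dict(anatomic_class=A.DIVERTICULUM_OR_PARTIAL_STAGHORN), 1, "III"),
            (dict(abnormal_anatomy=True), 2, "III"),
            (dict(anatomic_class=A.COMPLETE_STAGHORN), 1, "IV"),
            (dict(neuro_condition=True), 1, "IV"),
            # precedence: complete staghorn outranks everything below it
            (dict(anatomic_class=A.COMPLETE_STAGHORN, abnormal_anatomy=True), 4, "IV"),
        ],
    )
    def test_precedence_rules(self, kwargs, count, expected):
        assert ns.guys_grade(make_profile(**kwargs), count).value == expected

    def test_invalid_stone_count(self):
        with pytest.raises(ValueError):
            ns.guys_grade(make_profile(), 0)


class TestEnumeration:
    def test_shalin_range_over_full_cross_product(self):
        totals = enumerate_shalin_totals()
        assert len(totals) == 4 * 3 * 4 * 2 * 2 * 2
        assert set(totals) == set(range(6, 18))
        # each total maps to exactly one stratum
        for t in set(totals):
            assert isinstance(ns.shalin_stratum(t), str)

    def test_stone_range_over_full_cross_product(self):
        totals = enumerate_stone_totals()
        assert len(totals) == 96
        assert min(totals) == 5
        assert max(totals) == 13
        assert set(totals) == set(range(5, 14))


_profiles = st.builds(
    make_profile,
    stones=st.lists(
        st.tuples(st.floats(3, 120), st.floats(3, 120)), min_size=1, max_size=5
    ).map(tuple),
    hydronephrosis=st.sampled_from(list(H)),
    anatomic_class=st.sampled_from(list(A)),
    tract_length_mm=st.floats(40, 180),
    hu_points=st.tuples(*[st.floats(200, 1800)] * 5),
    involved_calyces=st.integers(0, 10),
    abnormal_anatomy=st.booleans(),
    neuro_condition=st.booleans(),
)


class TestProperties:
    @given(_profiles)
    def test_totals_within_range_and_consistent(self, profile):
        panel = ns.score_panel(profile)
        assert 6 <= panel.shalin_total <= 17
        assert 5 <= panel.stone_total <= 13
        assert panel.shalin_total == sum(panel.shalin_components)
        assert panel.stone_total == sum(panel.stone_components)
        assert panel.shalin_stratum == ns.shalin_stratum(panel.shalin_total)
        assert panel.stone_stratum == ns.stone_stratum(panel.stone_total)

    @given(_profiles)
    def test_width_normalised_not_longer_than_length(self, profile):
        for length, width in profile.stones:
            assert width <= length

    @given(_profiles)
    def test_single_category_upgrades_never_decrease_total(self, profile):
        from dataclasses import replace

        base = ns.shalin_total(profile)
        worse = [
            replace(profile, stones=profile.stones + ((60.0, 40.0),)),
            replace(profile, hydronephrosis=H.SEVERE),
            replace(profile, anatomic_class=A.COMPLETE_STAGHORN),
            replace(profile, tract_length_mm=profile.tract_length_mm + 100),
            replace(profile, hu_points=tuple(min(h + 900, 3000) for h in profile.hu_points)),
            replace(profile, involved_calyces=profile.involved_calyces + 3),
        ]
        for variant in worse:
            assert ns.shalin_total(variant) >= base
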