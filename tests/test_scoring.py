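"""Percent-of-ideal component scoring, percentile ranking and index assembly."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vhi import (
    AnimalRecord,
    CohortSummary,
    Direction,
    HealthStandard,
    InvalidInputError,
    MissingStandardError,
    NormalizationError,
    component_percent,
    compute_standards,
    compute_vhi,
    percentile_ranks,
    relative_improvement,
    summarize_cohorts,
    time_average,
)

STD_17_SKEL = HealthStandard(17, "skeletal", 136.5, 863.1, 3.1, 48)


def make_record(i, group="OZR", age=17, bed="skeletal", ach=122.6, mvd=656.3, beta=6.2, **kw):
    return AnimalRecord(f"{group}-{i}", group, age, bed, ach_upper=ach, mvd=mvd,
                        beta=beta, **kw)


class TestComponentPercent:
    @pytest.mark.parametrize("m, s, direction, expected", [
        (136.5, 136.5, Direction.DECREASES_WITH_DISEASE, 100.0),
        (6.2, 3.1, Direction.INCREASES_WITH_DISEASE, 0.0),
        (122.6, 136.5, Direction.DECREASES_WITH_DISEASE, 89.82),
        (2.4, 2.6, Direction.INCREASES_WITH_DISEASE, 107.69),
    ])
    def test_worked_values(self, m, s, direction, expected):
        assert component_percent(m, s, direction) == pytest.approx(expected, abs=0.005)

    def test_scores_are_not_clamped(self):
        assert component_percent(7.0, 3.1, Direction.INCREASES_WITH_DISEASE) < 0
        assert component_percent(900.0, 863.1, Direction.DECREASES_WITH_DISEASE) > 100

    @given(st.floats(min_value=0.1, max_value=1e3), st.floats(min_value=0.1, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, m, dm):
        lo = component_percent(m, 50.0, Direction.DECREASES_WITH_DISEASE)
        hi = component_percent(m + dm, 50.0, Direction.DECREASES_WITH_DISEASE)
        assert hi > lo
        lo_i = component_percent(m, 50.0, Direction.INCREASES_WITH_DISEASE)
        hi_i = component_percent(m + dm, 50.0, Direction.INCREASES_WITH_DISEASE)
        assert hi_i < lo_i

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(InvalidInputError):
            component_percent(100.0, 0.0, Direction.DECREASES_WITH_DISEASE)


class TestPercentileRanks:
    def test_hazen_formula(self):
        np.testing.assert_allclose(percentile_ranks([10, 20, 30, 40]),
                                   [12.5, 37.5, 62.5, 87.5])

    def test_complete_tie_maps_to_midpoint(self):
        np.testing.assert_allclose(percentile_ranks([7, 7, 7]), [50, 50, 50])

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_mean_rank_is_fifty(self, scores):
        assert np.mean(percentile_ranks(scores)) == pytest.approx(50.0, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            percentile_ranks([])


class TestStandards:
    def test_mean_of_one_and_two(self):
        one = [make_record(0, group="LZR", ach=136.5, mvd=863.1, beta=3.1)]
        std = compute_standards(one)[0]
        assert (std.ach_upper_std, std.mvd_std, std.beta_std) == (136.5, 863.1, 3.1)
        assert std.n_lzr == 1
        two = one + [make_record(1, group="LZR", ach=136.5, mvd=863.1, beta=3.3)]
        assert compute_standards(two)[0].beta_std == pytest.approx(3.2)

    def test_non_lzr_records_ignored(self):
        recs = [make_record(0, group="LZR"), make_record(1, group="OZR", beta=99.0)]
        assert compute_standards(recs)[0].beta_std == pytest.approx(6.2)

    def test_no_lzr_raises(self):
        with pytest.raises(InvalidInputError):
            compute_standards([make_record(0, group="OZR")])


class TestComputeVhi:
    def test_percentage_worked_example(self):
        """OZR 17-wk skeletal cohort means vs LZR standards."""
        res = compute_vhi([make_record(0)], [STD_17_SKEL])[0]
        assert res.ach_score == pytest.approx(89.82, abs=0.005)
        assert res.mvd_score == pytest.approx(76.04, abs=0.005)
        assert res.stiffness_score == pytest.approx(0.0, abs=1e-9)
        assert res.vhi == pytest.approx(55.29, abs=0.005)

    def test_self_scored_cohort_means_100(self, rng):
        recs = [make_record(i, group="LZR", ach=rng.uniform(120, 150),
                            mvd=rng.uniform(700, 900), beta=rng.uniform(2.5, 3.5))
                for i in range(25)]
        res = compute_vhi(recs, compute_standards(recs))
        for attr in ("ach_score", "mvd_score", "stiffness_score"):
            assert np.mean([getattr(r, attr) for r in res]) == pytest.approx(100.0, abs=1e-9)

    def test_equal_weighting_under_component_permutation(self):
        """Swapping the two decrease-direction components leaves the index alone."""
        a = compute_vhi([make_record(0, ach=120, mvd=700)],
                        [HealthStandard(17, "skeletal", 140, 800, 3.1, 5)])[0]
        b = compute_vhi([make_record(0, ach=700, mvd=120)],
                        [HealthStandard(17, "skeletal", 800, 140, 3.1, 5)])[0]
        assert a.vhi == pytest.approx(b.vhi, rel=1e-12)

    def test_missing_standard_raises(self):
        with pytest.raises(MissingStandardError):
            compute_vhi([make_record(0, age=7)], [STD_17_SKEL])

    def test_incomplete_animal_excluded_with_warning(self):
        recs = [make_record(0), AnimalRecord("x", "OZR", 17, "skeletal", ach_upper=120.0)]
        with pytest.warns(UserWarning, match="missing"):
            res = compute_vhi(recs, [STD_17_SKEL])
        assert [r.animal_id for r in res] == ["OZR-0"]

    def test_clamp_zero_flag(self):
        res = compute_vhi([make_record(0, beta=7.0)], [STD_17_SKEL], clamp_zero=True)[0]
        assert res.stiffness_score == 0.0


class TestPercentileMode:
    def _population(self, rng, n_lzr=12, n_ozr=12):
        recs = [make_record(i, group="LZR", ach=rng.normal(136.5, 4), mvd=rng.normal(863, 30),
                            beta=abs(rng.normal(3.1, 0.4))) for i in range(n_lzr)]
        recs += [make_record(i, group="OZR", ach=rng.normal(122.6, 6), mvd=rng.normal(656, 50),
                             beta=abs(rng.normal(6.2, 1.0))) for i in range(n_ozr)]
        return recs

    def test_lzr_cohort_mean_is_exactly_100(self, rng):
        recs = self._population(rng)
        res = compute_vhi(recs, [STD_17_SKEL], mode="percentile")
        lzr = [r.vhi for r in res if r.group == "LZR"]
        assert np.mean(lzr) == pytest.approx(100.0, abs=1e-9)
        assert all(r.component_ranks is not None for r in res)
        assert all(0 < rank < 100 for r in res for rank in r.component_ranks)

    def test_rank_domination_guard(self, rng):
        """An order-preserving rescaling of beta cannot move any rank or the index."""
        recs = self._population(rng)
        res_a = compute_vhi(recs, [STD_17_SKEL], mode="percentile")
        scaled = [dataclasses.replace(r, beta=r.beta * 10) for r in recs]
        res_b = compute_vhi(scaled, [STD_17_SKEL], mode="percentile")
        for a, b in zip(res_a, res_b):
            assert a.component_ranks == pytest.approx(b.component_ranks)
            assert a.vhi == pytest.approx(b.vhi, rel=1e-12)

    def test_output_order_matches_input(self, rng):
        recs = self._population(rng)[::-1]
        res = compute_vhi(recs, [STD_17_SKEL], mode="percentile")
        assert [r.animal_id for r in res] == [r.animal_id for r in recs]

    def test_no_lzr_in_population_raises(self):
        recs = [make_record(i, group="OZR", beta=3.0 + 0.1 * i) for i in range(4)]
        with pytest.raises(NormalizationError):
            compute_vhi(recs, [STD_17_SKEL], mode="percentile")

    def test_single_animal_population_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_vhi([make_record(0, group="LZR")], [STD_17_SKEL], mode="percentile")


class TestAggregation:
    def test_summaries_and_se(self):
        recs = [make_record(i, ach=120 + i) for i in range(4)]
        res = compute_vhi(recs, [STD_17_SKEL])
        s = summarize_cohorts(res)[0]
        vals = [r.vhi for r in res]
        assert s.n == 4
        assert s.vhi_mean == pytest.approx(np.mean(vals))
        assert s.vhi_se == pytest.approx(np.std(vals, ddof=1) / 2)

    def test_time_average_mean_and_se(self):
        summ = [CohortSummary("OZR", a, "skeletal", 10, m, se)
                for a, m, se in [(7, 100, 3), (13, 80, 4), (17, 60, 5)]]
        ta = time_average(summ)
        assert ta.vhi_mean == pytest.approx(80.0)
        assert ta.vhi_se == pytest.approx(np.sqrt(9 + 16 + 25) / 3)
        assert ta.age_wk is None
        single = time_average(summ[:1])
        assert single.vhi_mean == 100 and single.vhi_se == 3

    def test_time_average_rejects_mixed_groups(self):
        summ = [CohortSummary("OZR", 7, "skeletal", 5, 80, 1),
                CohortSummary("LZR", 13, "skeletal", 5, 100, 1)]
        with pytest.raises(InvalidInputError):
            time_average(summ)

    def test_relative_improvement(self):
        treated = CohortSummary("OZR+CAP", None, "skeletal", 30, 73.6, 2.0)
        untreated = CohortSummary("OZR", None, "skeletal", 30, 55.3, 2.0)
        assert relative_improvement(treated, untreated) == pytest.approx(33.09, abs=0.005)
        assert relative_improvement(untreated, untreated) == 0.0
        worse = CohortSummary("OZR+HYD", None, "skeletal", 30, 50.0, 2.0)
        assert relative_improvement(worse, untreated) < 0

    def test_relative_improvement_stratum_mismatch(self):
        a = CohortSummary("OZR+CAP", 17, "skeletal", 30, 73.6, 2.0)
        b = CohortSummary("OZR", 13, "skeletal", 30, 55.3, 2.0)
        with pytest.raises(InvalidInputError):
            relative_improvement(a, b)
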