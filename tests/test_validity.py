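"""Pearson correlation, one-way ANOVA and Newman-Keuls post hoc testing."""

import math

import numpy as np
import pytest
from scipy import stats

from vhi import (
    CohortSummary,
    DegenerateInputError,
    InvalidInputError,
    criterion_validity,
    discriminant_check,
    newman_keuls,
    one_way_anova,
    pearson,
)

# Published studentized-range critical values (Harter's tables, 3 decimals),
# alpha = 0.05, df = 24 — the independent oracle for Newman-Keuls decisions
Q_TABLE = {
    (2, 24): 2.919, (3, 24): 3.532, (4, 24): 3.901, (5, 24): 4.166,
}


def nk_oracle(groups, q_table=Q_TABLE, alpha=0.05):
    """Independent Newman-Keuls using tabulated critical values.

    Iterative span-descending formulation (the package uses a recursive one):
    test spans from widest to narrowest, skipping pairs inside any already
    non-rejected span.
    """
    k = len(groups)
    means = [float(np.mean(g)) for g in groups]
    ns = [len(g) for g in groups]
    df = sum(ns) - k
    msw = sum(float(np.sum((np.asarray(g) - np.mean(g)) ** 2)) for g in groups) / df
    order = sorted(range(k), key=lambda i: means[i])
    blocked = []
    sig = {}
    for span in range(k, 1, -1):
        for start in range(k - span + 1):
            i, j = start, start + span - 1
            key = frozenset((order[i], order[j]))
            if any(bi <= i and j <= bj for bi, bj in blocked):
                sig[key] = False
                continue
            n_h = 2.0 / (1.0 / ns[order[i]] + 1.0 / ns[order[j]])
            q = (means[order[j]] - means[order[i]]) / math.sqrt(msw / n_h)
            if q > q_table[(span, df)]:
                sig[key] = True
            else:
                sig[key] = False
                blocked.append((i, j))
    return sig


class TestPearson:
    def test_exact_negative_linearity(self):
        x = [1.0, 2.0, 5.0, 9.0]
        rep = pearson(x, [-2 * v + 7 for v in x])
        assert rep.r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        rep = pearson([1, 2, 3], [1, 2, 4])
        assert rep.r == pytest.approx(0.98198, abs=5e-6)

    def test_matches_closed_form(self, rng):
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            n = len(x)
            num = n * np.sum(x * y) - x.sum() * y.sum()
            den = math.sqrt((n * np.sum(x * x) - x.sum() ** 2)
                            * (n * np.sum(y * y) - y.sum() ** 2))
            assert pearson(x, y).r == pytest.approx(num / den, abs=1e-12)

    def test_joint_permutation_invariance(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        perm = rng.permutation(12)
        assert pearson(x[perm], y[perm]).r == pytest.approx(pearson(x, y).r, abs=1e-12)

    def test_degenerate_and_short_inputs(self):
        with pytest.raises(DegenerateInputError):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(InvalidInputError):
            pearson([1, 2], [1, 2])


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        assert one_way_anova([[3, 3, 3], [3, 3, 3]]) == (0.0, 1.0)

    def test_hand_sum_of_squares(self):
        f, p = one_way_anova([[1, 2, 3], [2, 3, 4]])
        # SSB = 1.5 (df 1), SSW = 4 (df 4) -> F = 1.5
        assert f == pytest.approx(1.5)
        assert p == pytest.approx(float(stats.f.sf(1.5, 1, 4)))

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(10):
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(3, 9)) for _ in range(4)]
            f, p = one_way_anova(groups)
            ref = stats.f_oneway(*groups)
            assert f == pytest.approx(float(ref.statistic), rel=1e-10)
            assert p == pytest.approx(float(ref.pvalue), rel=1e-8)

    def test_scale_invariance(self, rng):
        groups = [rng.normal(i, 1, 6) for i in range(3)]
        f1, _ = one_way_anova(groups)
        f2, _ = one_way_anova([np.asarray(g) * 7.3 for g in groups])
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(InvalidInputError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestNewmanKeuls:
    def test_two_groups_match_t_test_decision(self, rng):
        """With k = 2, q = sqrt(2) * t, so NK and the equal-variance t test agree."""
        for _ in range(20):
            a = rng.normal(0, 1, 8)
            b = rng.normal(rng.uniform(0, 2), 1, 8)
            rep = newman_keuls([a, b], alpha=0.05, labels=["a", "b"])
            t_sig = stats.ttest_ind(a, b).pvalue < 0.05
            assert rep.pairs[0][2] == t_sig

    def test_identical_groups_no_rejections(self):
        rep = newman_keuls([[1.0, 2.0, 3.0]] * 4)
        assert not any(sig for *_, sig in rep.pairs)

    def test_three_group_pattern_close_means_grouped(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.1, 5.0)]
        rep = newman_keuls(groups, labels=["lo", "mid", "hi"])
        sig = {frozenset((a, b)): s for a, b, s in rep.pairs}
        assert sig[frozenset(("lo", "hi"))] and sig[frozenset(("mid", "hi"))]
        assert not sig[frozenset(("lo", "mid"))]

    def test_matches_table_based_oracle(self, rng):
        """Random 3-5 group instances, df_within = 24 to match the printed table."""
        sizes = {3: [9, 9, 9], 4: [7, 7, 7, 7], 5: [6, 6, 6, 6, 5]}
        for trial in range(20):
            k = int(rng.integers(3, 6))
            groups = [rng.normal(rng.uniform(0, 2.5), 1, n) for n in sizes[k]]
            rep = newman_keuls(groups, alpha=0.05, labels=list(range(k)))
            expected = nk_oracle(groups)
            got = {frozenset((a, b)): s for a, b, s in rep.pairs}
            assert got == expected, f"trial {trial}"

    def test_containment_rule(self, rng):
        """No pair inside a non-significant span is ever marked significant."""
        for _ in range(30):
            k = int(rng.integers(3, 6))
            groups = [rng.normal(rng.uniform(0, 1.5), 1, 6) for _ in range(k)]
            rep = newman_keuls(groups, labels=list(range(k)))
            sig = {frozenset((a, b)): s for a, b, s in rep.pairs}
            order = np.argsort([np.mean(g) for g in groups])
            for span in range(k, 1, -1):
                for start in range(k - span + 1):
                    outer = frozenset((int(order[start]), int(order[start + span - 1])))
                    if not sig[outer]:
                        for a in range(start, start + span):
                            for b in range(a + 1, start + span):
                                assert not sig[frozenset((int(order[a]), int(order[b])))]

    def test_dominates_tukey(self, rng):
        """NK rejects a superset of Tukey HSD rejections on the same data."""
        from vhi.validity import studentized_range_crit

        for _ in range(20):
            k = int(rng.integers(3, 6))
            groups = [rng.normal(rng.uniform(0, 2), 1, 8) for _ in range(k)]
            rep = newman_keuls(groups, labels=list(range(k)))
            nk_sig = rep.significant_pairs()
            df = sum(len(g) for g in groups) - k
            msw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups) / df
            q_crit = studentized_range_crit(0.05, k, df)
            tukey = set()
            for a in range(k):
                for b in range(a + 1, k):
                    q = abs(groups[a].mean() - groups[b].mean()) / math.sqrt(msw / 8)
                    if q > q_crit:
                        tukey.add(frozenset((a, b)))
            assert tukey <= nk_sig


class TestCriterionValidity:
    def test_perfect_negative_coupling_passes(self):
        vhi = [100.0, 80.0, 60.0, 40.0]
        biomarker = [10.0 - 0.05 * v for v in vhi]
        rep, verdict = criterion_validity(vhi, biomarker, threshold=-0.9)
        assert rep.r == pytest.approx(-1.0)
        assert verdict

    def test_independent_biomarker_fails(self, rng):
        vhi = rng.normal(70, 10, 100)
        biomarker = rng.normal(5, 1, 100)
        rep, verdict = criterion_validity(vhi, biomarker, threshold=-0.5)
        assert abs(rep.r) < 0.3
        assert not verdict

    def test_threshold_zero_boundary(self):
        vhi = [100.0, 80.0, 61.0, 40.0]
        biomarker = [1.0, 2.0, 2.5, 4.0]
        _, verdict = criterion_validity(vhi, biomarker, threshold=0.0)
        assert verdict

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            criterion_validity([1.0, 2.0, 3.0], [1.0, 2.0])


class TestDiscriminantCheck:
    def _summaries(self, lzr, ozr, lnm):
        return [CohortSummary("LZR", 17, "skeletal", 10, lzr, 1),
                CohortSummary("OZR", 17, "skeletal", 10, ozr, 1),
                CohortSummary("OZR+LNM", 17, "skeletal", 10, lnm, 1)]

    def test_orderings(self):
        assert discriminant_check(self._summaries(100, 55, 40))
        assert not discriminant_check(self._summaries(100, 40, 55))

    def test_missing_group_rejected(self):
        with pytest.raises(InvalidInputError):
            discriminant_check(self._summaries(100, 55, 40)[:2])
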