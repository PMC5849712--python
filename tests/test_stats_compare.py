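"""G-test, Wilcoxon rank-sum and the comparative summary tables."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from ecas_splice.annotation_model import CDS, UTR3, UTR5
from ecas_splice.as_caller import ALTA, ALTD, ASEvent, ES, IR
from ecas_splice.consequence_caller import ECAS_CLASS, NON_ECAS_CLASS
from ecas_splice.stats_compare import (
    g_test,
    length_summary,
    position_comparison,
    wilcoxon_rank_sum,
)


def brute_force_rank_sum_p(a, b):
    """Independent oracle: full enumeration of rank assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    w = ranks[:n].sum()
    sums = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n)]
    p_le = sum(1 for s in sums if s <= w + 1e-9) / len(sums)
    p_ge = sum(1 for s in sums if s >= w - 1e-9) / len(sums)
    return min(1.0, 2 * min(p_le, p_ge))


class TestGTest:
    def test_homogeneous_table_has_zero_statistic(self):
        result = g_test([[10, 10], [10, 10]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        result = g_test([[5, 0], [0, 5]])
        assert result.statistic == pytest.approx(2 * 10 * math.log(2))
        assert result.p_value < 0.01

    def test_printed_ptc_totals_give_milli_scale_p(self):
        result = g_test([[158, 43], [1928, 290]])
        assert 1e-4 < result.p_value < 1e-2

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            g_test([[1.5, 2], [3, 4]])
        with pytest.raises(ValueError):
            g_test([[-1, 2], [3, 4]])

    def test_matches_scipy_log_likelihood_variant(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            table = rng.integers(1, 200, size=(2, 3))
            mine = g_test(table)
            ref_stat, ref_p, ref_df, _ = chi2_contingency(table, correction=False,
                                                          lambda_="log-likelihood")
            assert mine.statistic == pytest.approx(ref_stat)
            assert mine.p_value == pytest.approx(ref_p)
            assert mine.df == ref_df

    def test_close_to_chi_square_for_large_expecteds(self):
        # asymptotic equivalence holds near independence with big expecteds
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(100):
            p, q = rng.uniform(0.2, 0.8, size=2)
            probs = np.outer([p, 1 - p], [q, 1 - q]).ravel()
            table = rng.multinomial(2000, probs).reshape(2, 2)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if expected.min() < 20:
                continue
            g = g_test(table).statistic
            x2 = chi2_contingency(table, correction=False)[0]
            if x2 > 0.5:
                assert abs(g - x2) / x2 < 0.05
                checked += 1
        assert checked > 20

    def test_williams_correction_shrinks_statistic(self):
        plain = g_test([[12, 3], [4, 11]])
        corrected = g_test([[12, 3], [4, 11]], williams_correction=True)
        assert corrected.statistic < plain.statistic


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_fully_separated_three_vs_three(self):
        result = wilcoxon_rank_sum([1, 2, 3], [101, 102, 103])
        assert result.p_value == pytest.approx(0.1)  # 2/C(6,3)·... exact two-sided floor

    def test_exact_matches_brute_force_small_samples(self):
        rng = np.random.default_rng(5)
        for n in range(1, 5):
            for m in range(1, 5):
                a = rng.integers(0, 6, size=n).astype(float)  # ties likely
                b = rng.integers(0, 6, size=m).astype(float)
                mine = wilcoxon_rank_sum(a, b).p_value
                assert mine == pytest.approx(brute_force_rank_sum_p(a, b))

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = rng.normal(size=9)
            b = rng.normal(size=9)
            exact = wilcoxon_rank_sum(a, b, exact_max=9).p_value
            approx = wilcoxon_rank_sum(a, b, exact_max=0).p_value
            assert abs(exact - approx) <= 0.02

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def _length_event(etype, length, gene="g1"):
    return ASEvent("sp", gene, etype, ((101, 100 + length),), length, CDS,
                   ref_junction=(101, 200) if etype in (ALTD, ALTA) else None)


class TestLengthSummary:
    def test_mean_and_median(self):
        labeled = [
            (_length_event(IR, L), ECAS_CLASS) for L in (90, 100, 110)
        ] + [(_length_event(IR, L), NON_ECAS_CLASS) for L in (80, 120, 130)]
        table = length_summary(labeled)
        row = table[(table.event_type == IR) & (table["class"] == ECAS_CLASS)].iloc[0]
        assert row.mean_bp == 100.00
        assert row.median_bp == 100

    def test_degenerate_class_propagates_na(self):
        labeled = [(_length_event(ES, 50), ECAS_CLASS),
                   (_length_event(ES, 70), NON_ECAS_CLASS)]
        table = length_summary(labeled)
        assert np.isnan(table[table.event_type == ES].wilcoxon_p).all()

    def test_planted_shorter_ecas_lengths_detected(self):
        rng = np.random.default_rng(7)
        labeled = [
            (_length_event(IR, int(L)), ECAS_CLASS)
            for L in rng.normal(120, 20, size=500).clip(30)
        ] + [
            (_length_event(IR, int(L)), NON_ECAS_CLASS)
            for L in rng.normal(160, 20, size=500).clip(30)
        ]
        table = length_summary(labeled)
        assert table[table.event_type == IR].wilcoxon_p.iloc[0] < 1e-3


class TestPositionComparison:
    def test_identical_distributions_give_zero_g(self):
        labeled = []
        for cls in (ECAS_CLASS, NON_ECAS_CLASS):
            for region, n in ((CDS, 60), (UTR5, 20), (UTR3, 20)):
                labeled += [
                    (ASEvent("sp", "g", IR, ((1, 10),), 10, region), cls)
                ] * n
        table = position_comparison(labeled)
        assert (table.g_test_p > 0.999).all()

    def test_shares_sum_to_hundred_per_class(self):
        rng = np.random.default_rng(8)
        labeled = [
            (ASEvent("sp", "g", IR, ((1, 10),), 10,
                     str(rng.choice([CDS, UTR5, UTR3]))),
             str(rng.choice([ECAS_CLASS, NON_ECAS_CLASS])))
            for _ in range(300)
        ]
        table = position_comparison(labeled)
        for cls in (ECAS_CLASS, NON_ECAS_CLASS):
            assert table[table["class"] == cls].pct.sum() == pytest.approx(100.0, abs=0.05)

    def test_planted_region_skew_detected(self):
        rng = np.random.default_rng(9)
        labeled = []
        for _ in range(400):
            region = CDS if rng.random() < 0.9 else UTR3
            labeled.append((ASEvent("sp", "g", IR, ((1, 10),), 10, region), ECAS_CLASS))
        for _ in range(400):
            region = CDS if rng.random() < 0.6 else UTR3
            labeled.append((ASEvent("sp", "g", IR, ((1, 10),), 10, region), NON_ECAS_CLASS))
        table = position_comparison(labeled)
        assert table[table.region == CDS].g_test_p.iloc[0] < 0.05
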