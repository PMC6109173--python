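import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epismoke import peaks as pk
from epismoke.types import GenomicInterval, Peak


def make_peak(start, end, name="p", x_air=0.0, x_smoke=0.0, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), name, x_air, x_smoke)


class TestComputeMA:
    def test_closed_form(self):
        m, a = pk.compute_ma(25, 100, pseudocount=0)
        assert m == pytest.approx(2.0)
        assert a == pytest.approx(0.5 * math.log2(2500), abs=1e-9)

    @given(st.integers(min_value=1, max_value=10**6))
    @settings(derandomize=True, max_examples=50)
    def test_equal_counts_give_zero_m(self, x):
        m, _ = pk.compute_ma(x, x, pseudocount=0)
        assert m == 0.0

    def test_pseudocount_handles_double_zero(self):
        m, a = pk.compute_ma(0, 0, pseudocount=0.5)
        assert m == 0.0
        assert a == pytest.approx(math.log2(0.5))

    def test_double_zero_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            pk.compute_ma(0, 0, pseudocount=0)


class TestClassify:
    def test_lone_air_peak_is_air_unique(self):
        out = pk.classify_peaks([make_peak(100, 200, "a1")], [])
        assert [p.label for p in out] == ["air_unique"]

    def test_overlap_merges_to_union(self):
        out = pk.classify_peaks(
            [make_peak(100, 200, "a1", 10, 1)],
            [make_peak(150, 300, "s1", 2, 20)],
        )
        (p,) = out
        assert p.label == "common"
        assert (p.interval.start, p.interval.end) == (100, 300)
        assert p.x_air == 12 and p.x_smoke == 21
        assert set(p.members) == {"a1", "s1"}

    def test_adjacent_half_open_do_not_merge(self):
        out = pk.classify_peaks(
            [make_peak(100, 200, "a1")], [make_peak(200, 300, "s1")]
        )
        assert sorted(p.label for p in out) == ["air_unique", "smoke_unique"]

    def test_chain_merges_transitively(self):
        out = pk.classify_peaks(
            [make_peak(0, 100, "a1"), make_peak(150, 250, "a2")],
            [make_peak(90, 160, "s1")],
        )
        (p,) = out
        assert p.label == "common"
        assert (p.interval.start, p.interval.end) == (0, 250)
        assert set(p.members) == {"a1", "a2", "s1"}

    def test_recovers_planted_classes_exactly(self, sim_default, classified_default):
        classified, _ = classified_default
        truth = dict(
            zip(
                sim_default.truth.peak_classes["peak_name"],
                sim_default.truth.peak_classes["true_class"],
            )
        )
        assert all(
            truth[member] == p.label for p in classified for m in [0]
            for member in p.members
        )

    def test_partition_arithmetic(self, sim_default, classified_default):
        classified, _ = classified_default
        n_air_unique = sum(p.label == "air_unique" for p in classified)
        common = [p for p in classified if p.label == "common"]
        air_members_of_common = sum(
            1 for p in common for m in p.members if m.startswith("air")
        )
        assert len(sim_default.air_peaks) == n_air_unique + air_members_of_common

    def test_swapping_inputs_swaps_labels_and_negates_m(self, sim_default):
        fwd = pk.classify_peaks(sim_default.air_peaks, sim_default.smoke_peaks)
        swapped_air = [
            make_peak(p.interval.start, p.interval.end, p.name,
                      p.x_smoke, p.x_air, p.interval.chrom)
            for p in sim_default.smoke_peaks
        ]
        swapped_smoke = [
            make_peak(p.interval.start, p.interval.end, p.name,
                      p.x_smoke, p.x_air, p.interval.chrom)
            for p in sim_default.air_peaks
        ]
        rev = pk.classify_peaks(swapped_air, swapped_smoke)
        pk.annotate_ma(fwd)
        pk.annotate_ma(rev)
        flip = {"air_unique": "smoke_unique", "smoke_unique": "air_unique",
                "common": "common"}
        by_iv_fwd = {(p.interval.start, p.interval.end): p for p in fwd}
        for p in rev:
            q = by_iv_fwd[(p.interval.start, p.interval.end)]
            assert p.label == flip[q.label]
            assert p.M == pytest.approx(-q.M, abs=1e-12)


class TestMAFit:
    def test_constant_m_exact(self):
        a = np.linspace(2, 10, 50)
        b0, b1, _, _ = pk.huber_irls(a, np.full(50, 0.5))
        assert b0 == pytest.approx(0.5, abs=1e-8)
        assert b1 == pytest.approx(0.0, abs=1e-8)

    def test_linear_m_exact(self):
        a = np.linspace(2, 10, 50)
        b0, b1, _, _ = pk.huber_irls(a, 0.1 * a)
        assert b0 == pytest.approx(0.0, abs=1e-8)
        assert b1 == pytest.approx(0.1, abs=1e-8)

    def test_outlier_resistance_vs_ols(self, rng):
        a = rng.uniform(3, 10, 600)
        m = np.full(600, 0.5)
        m[rng.choice(600, 30, replace=False)] = 8.0
        b0, b1, _, _ = pk.huber_irls(a, m)
        X = np.column_stack([np.ones_like(a), a])
        ols = np.linalg.lstsq(X, m, rcond=None)[0]
        assert abs(b0 - 0.5) < 0.05
        # OLS is dragged toward the outliers: its fitted trend at the centre
        # of the A range is pulled well off the bulk level of 0.5
        a_mid = a.mean()
        assert abs((ols[0] + ols[1] * a_mid) - 0.5) > 0.1
        assert abs((b0 + b1 * a_mid) - 0.5) < 0.05

    def test_matches_statsmodels_rlm(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        a = rng.uniform(2, 9, 400)
        m = 0.3 + 0.05 * a + rng.normal(0, 0.2, 400)
        m[:20] += 5.0
        b0, b1, _, _ = pk.huber_irls(a, m)
        X = statsmodels.add_constant(a)
        rlm = statsmodels.RLM(
            m, X, M=statsmodels.robust.norms.HuberT(t=1.345)
        ).fit()
        assert b0 == pytest.approx(rlm.params[0], abs=0.02)
        assert b1 == pytest.approx(rlm.params[1], abs=0.01)

    def test_too_few_points_rejected(self):
        peaks = [make_peak(0, 10, x_air=5, x_smoke=5)]
        pk.annotate_ma(peaks)
        with pytest.raises(ValueError, match=">=3"):
            pk.fit_ma_normalization(peaks)


class TestScoring:
    def test_central_split_p_one(self):
        assert pk.conditional_binomial_p(5, 5) == pytest.approx(1.0)

    def test_one_sided_extreme(self):
        assert pk.conditional_binomial_p(5, 0) == pytest.approx(2 * 0.5**5)

    def test_binomial_matches_enumeration_small_n(self):
        for n in range(1, 13):
            pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
            for k in range(n + 1):
                expected = sum(q for q in pmf if q <= pmf[k] + 1e-12)
                assert pk.conditional_binomial_p(n - k, k) == pytest.approx(
                    min(expected, 1.0), rel=1e-9
                )

    def test_monotone_in_imbalance(self):
        # fixed total, growing imbalance -> smaller p
        ps = [pk.conditional_binomial_p(20 - k, k) for k in range(10, 21)]
        assert all(p2 <= p1 + 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_median_mnorm_near_zero_on_common(self, classified_default):
        classified, _ = classified_default
        m_norm = [p.m_norm for p in classified if p.label == "common"]
        assert abs(np.median(m_norm)) < 0.05


class TestRank:
    def _scored(self, name, p_value, m_norm, start=0):
        p = make_peak(start, start + 10, name)
        p.label = "smoke_unique"
        p.p_value = p_value
        p.m_norm = m_norm
        p.M = p.A = 0.0
        return p

    def test_orders_by_p_then_abs_mnorm(self):
        peaks = [
            self._scored("weak", 0.01, 1.0, 0),
            self._scored("strong", 0.001, 0.5, 10),
            self._scored("tied_big", 0.01, 2.0, 20),
        ]
        ranked = pk.rank_peaks(peaks, "smoke_unique")
        assert [p.name for p in ranked] == ["strong", "tied_big", "weak"]

    def test_empty_class_and_bad_label(self):
        assert pk.rank_peaks([], "air_unique") == []
        with pytest.raises(ValueError, match="unknown peak class"):
            pk.rank_peaks([], "bogus")
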