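from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from octamnv.stats import (
    bootstrap_ci,
    fisher_exact_2x2,
    normality_gate,
    percent_smaller,
    pooled_t_ci,
    pooled_t_ci_from_samples,
    summarize,
    visit_change,
)


class TestVisitChange:
    def test_no_change(self):
        assert visit_change(3.0, 3.0, 90) == (0.0, 0.0)

    def test_choroidal_thickness_example(self):
        # 169.66 → 182.18 µm over 84 days
        diff, rate = visit_change(169.66, 182.18, 84)
        assert diff == pytest.approx(12.52)
        assert rate == pytest.approx(4.54, abs=0.005)

    def test_rate_scales_inversely_with_interval(self):
        _, r1 = visit_change(1.0, 2.0, 30)
        _, r2 = visit_change(1.0, 2.0, 60)
        assert r1 == pytest.approx(2 * r2)

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            visit_change(1.0, 2.0, 0)


class TestPooledT:
    @pytest.mark.parametrize("m1,s1,m2,s2,diff,lo,hi,dp", [
        # square-root MNV size at visit 2
        (1.74, 0.79, 1.28, 0.71, 0.46, -0.24, 1.16, 2),
        # mean choroidal thickness at visit 2
        (192.8, 83.9, 244.7, 95.3, -51.9, -133.9, 30.1, 1),
        # cube-root MNV–PED volume at visit 2
        (0.403, 0.143, 0.268, 0.133, 0.135, 0.007, 0.263, 3),
    ])
    def test_published_intervals_reproduced(self, m1, s1, m2, s2, diff, lo, hi, dp):
        ci = pooled_t_ci(m1, s1, 12, m2, s2, 9)
        assert round(ci.diff, dp) == diff
        assert round(ci.lo, dp) == lo
        assert round(ci.hi, dp) == hi

    def test_vsd_interval_bounds_from_printed_difference(self):
        # the published visit-2 VSD difference (0.037) with the group SDs
        ci = pooled_t_ci(0.037, 0.024, 12, 0.0, 0.030, 9)
        assert round(ci.lo, 3) == 0.012
        assert round(ci.hi, 3) == 0.062
        rate = pooled_t_ci(0.002, 0.003, 12, -0.003, 0.005, 9)
        assert round(rate.lo, 3) == 0.001
        assert round(rate.hi, 3) == 0.009

    def test_zero_sds_collapse_to_point(self):
        ci = pooled_t_ci(2.0, 0.0, 5, 1.0, 0.0, 5)
        assert ci.lo == ci.hi == ci.diff == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        m1=st.floats(-10, 10), m2=st.floats(-10, 10),
        s1=st.floats(0.1, 5), s2=st.floats(0.1, 5),
        n1=st.integers(2, 30), n2=st.integers(2, 30),
    )
    def test_group_swap_mirrors_interval(self, m1, m2, s1, s2, n1, n2):
        a = pooled_t_ci(m1, s1, n1, m2, s2, n2)
        b = pooled_t_ci(m2, s2, n2, m1, s1, n1)
        assert a.diff == pytest.approx(-b.diff, abs=1e-12)
        assert a.lo == pytest.approx(-b.hi, rel=1e-9, abs=1e-12)
        assert a.hi == pytest.approx(-b.lo, rel=1e-9, abs=1e-12)


class TestBootstrap:
    def test_constant_identical_samples_give_degenerate_interval(self):
        ci = bootstrap_ci([2.0] * 10, [2.0] * 10, B=500, seed=0)
        assert ci.lo == ci.hi == 0.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.normal(0, 1, 15), rng.normal(1, 1, 12)
        a = bootstrap_ci(x1, x2, seed=11)
        b = bootstrap_ci(x1, x2, seed=11)
        assert (a.lo, a.hi) == (b.lo, b.hi)

    def test_large_sample_agreement_with_pooled_t(self):
        rng = np.random.default_rng(1)
        x1 = rng.normal(10, 2, 500)
        x2 = rng.normal(9, 2, 500)
        bt = bootstrap_ci(x1, x2, B=2000, seed=5)
        pt = pooled_t_ci_from_samples(x1, x2)
        assert bt.lo == pytest.approx(pt.lo, rel=0.10)
        assert bt.hi == pytest.approx(pt.hi, rel=0.10)

    def test_low_resample_count_warns(self):
        with pytest.warns(UserWarning):
            bootstrap_ci([1.0, 2.0], [3.0, 4.0], B=50, seed=0)


class TestNormalityGate:
    def test_lognormal_group_selects_bootstrap(self):
        chosen = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            skewed = np.exp(rng.normal(0, 1, 12))
            normal = rng.normal(0, 1, 12)
            gate = normality_gate(skewed, normal)
            chosen += gate["method"] == "bootstrap_percentile"
        assert chosen >= 16  # ≥ 80% detection across seeds

    def test_exact_normal_quantiles_select_pooled_t(self):
        q = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        assert normality_gate(q, q)["method"] == "pooled_t"

    def test_alpha_zero_always_pooled_t(self):
        q = sps.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        assert normality_gate(q, np.exp(q), alpha=0.0)["method"] == "pooled_t"

    def test_pooled_residual_mode(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(5, 1, 15), rng.normal(3, 1, 15)
        out = normality_gate(x1, x2, mode="pooled_residuals")
        assert len(out["shapiro_pvalues"]) == 1


def _fisher_enumeration_oracle(a, b, c, d):
    """Exact-fraction enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = [
        Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    ]
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    return float(sum(p for p in probs if p <= p_obs))


class TestFisherExact:
    def test_published_contingency_table(self):
        # 6/18 monofocal vs 3/3 multifocal eyes developing exudation
        assert round(fisher_exact_2x2(6, 12, 3, 0), 3) == 0.063

    def test_modal_table_gives_one(self):
        assert fisher_exact_2x2(2, 2, 2, 2) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_tables(self):
        for n in range(1, 17):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    r2 = n - r1
                    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                        b, c = r1 - a, c1 - a
                        d = r2 - c
                        got = fisher_exact_2x2(a, b, c, d)
                        want = _fisher_enumeration_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-9), (a, b, c, d)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestPercentSmaller:
    @pytest.mark.parametrize("ref,other,want", [
        (0.515, 0.390, 24),  # visit-2 vessel area density
        (0.51, 0.42, 18),    # visit-1 vessel area density
        (0.18, 0.16, 11),    # visit-1 vessel skeleton density
        (0.403, 0.268, 33),  # visit-2 cube-root PED volume
        (1.0, 1.0, 0),
    ])
    def test_reported_percentages(self, ref, other, want):
        assert percent_smaller(ref, other) == want

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_smaller(0.0, 1.0)


class TestSummarize:
    def test_moments_and_quantiles(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s.n == 5 and s.mean == 3.0 and s.median == 3.0
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1))
        assert s.iqr == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
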