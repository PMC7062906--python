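"""Agreement statistics, effect sizes and the normality-gated group test."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from marrowfat import (MethodAgreement, agreement, cohens_d, group_compare,
                       sample_size_per_group)
from marrowfat.errors import ValidationError


def brute_force_u(g1, g2):
    """Mann-Whitney U for g1: pairwise wins plus half-ties."""
    u = 0.0
    for a in g1:
        for b in g2:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


class TestAgreement:
    def test_identical_inputs(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        rep = agreement(x, x)
        assert rep.mean_diff == 0.0 and rep.sd_diff == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rep = agreement(x, x + 5.0)
        assert rep.mean_diff == pytest.approx(-5.0)
        assert rep.sd_diff == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # diffs (0, 0, 0, -1): mean -0.25, sample SD 0.5, limits mean ± 2 SD
        rep = agreement([1, 2, 3, 4], [1, 2, 3, 5])
        assert rep.mean_diff == pytest.approx(-0.25)
        assert rep.sd_diff == pytest.approx(0.5)
        assert rep.loa_low == pytest.approx(-1.25)
        assert rep.loa_high == pytest.approx(0.75)
        # paired t cross-checked against scipy on the same pairs
        t, p = stats.ttest_rel([1, 2, 3, 4], [1, 2, 3, 5])
        assert rep.paired_t == pytest.approx(t)
        assert rep.paired_p == pytest.approx(p)

    def test_limits_span_four_sd(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rep = agreement(x, y)
        assert rep.loa_high - rep.loa_low == pytest.approx(4 * rep.sd_diff)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            agreement([1, 2, 3], [1, 2])

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError):
            agreement([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])

    def test_zero_variance_flags_undefined_r(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rep = agreement([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(rep.pearson_r)

    def test_model_wrapper_and_plot(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, size=15)
        rep = MethodAgreement(x, x + rng.normal(0, 0.1, 15),
                              labels=("T1", "IDEAL")).fit()
        assert "T1" in rep.summary()
        ax = rep.plot_bland_altman()
        assert len(ax.lines) == 3   # mean line + two limits


class TestCohensD:
    @pytest.mark.parametrize("m1,s1,m2,s2,expected", [
        (18.0, 27.0, 58.0, 29.0, 1.428),   # height percentile
        (35.0, 35.0, 59.0, 25.0, 0.789),   # body-mass percentile
        (26.5, 10.2, 28.6, 7.0, 0.240),    # body mass (kg)
        (1.22, 0.14, 1.30, 0.11, 0.635),   # height (m)
        (17.1, 3.4, 16.8, 2.4, 0.102),     # BMI
    ])
    def test_published_group_summaries(self, m1, s1, m2, s2, expected):
        assert cohens_d(m1, s1, 15, m2, s2, 15) == pytest.approx(expected,
                                                                 abs=5e-4)

    def test_equal_means_give_zero(self):
        assert cohens_d(5.0, 1.0, 10, 5.0, 2.0, 10) == 0.0

    @given(shift=st.floats(-100, 100), scale=st.floats(0.01, 100))
    @settings(max_examples=100, derandomize=True)
    def test_shift_and_scale_invariance(self, shift, scale):
        base = cohens_d(10.0, 2.0, 15, 13.0, 3.0, 15)
        moved = cohens_d(scale * 10.0 + shift, scale * 2.0, 15,
                         scale * 13.0 + shift, scale * 3.0, 15)
        assert moved == pytest.approx(base, rel=1e-9)

    def test_matches_pingouin_at_equal_n(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(0.6, 1.3, 20)
        ours = cohens_d(x.mean(), x.std(ddof=1), 20, y.mean(), y.std(ddof=1), 20)
        assert ours == pytest.approx(abs(pg.compute_effsize(x, y, eftype="cohen")),
                                     rel=1e-9)


class TestGroupCompare:
    def test_identical_groups(self):
        g = [3.0, 3.0, 3.0, 3.0]
        with pytest.warns(UserWarning, match="constant group"):
            comp = group_compare(g, g)
        assert comp.d == 0.0
        assert comp.test_used == "Mann-Whitney"
        assert comp.p == 1.0

    def test_mann_whitney_u_matches_enumeration(self):
        g1, g2 = [1, 2, 3, 4, 5], [6, 7, 8, 9, 10]
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
        assert res.statistic == brute_force_u(g1, g2) == 0.0

    def test_brute_force_u_on_small_samples_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n1, n2 = rng.integers(3, 9, size=2)
            g1 = rng.integers(0, 6, size=n1).astype(float)
            g2 = rng.integers(0, 6, size=n2).astype(float)
            res = stats.mannwhitneyu(g1, g2, alternative="two-sided")
            assert res.statistic == pytest.approx(brute_force_u(g1, g2))

    def test_normal_groups_use_t_test(self):
        rng = np.random.default_rng(11)
        comp = group_compare(rng.normal(0, 1, 15), rng.normal(1, 1, 15))
        assert comp.test_used == "t"
        assert comp.d > 0

    def test_skewed_group_falls_to_mann_whitney(self):
        rng = np.random.default_rng(12)
        skewed = rng.exponential(1.0, 40) ** 3
        normal = rng.normal(5, 1, 40)
        comp = group_compare(skewed, normal)
        assert comp.test_used == "Mann-Whitney"

    def test_constant_group_warns_and_uses_mann_whitney(self):
        with pytest.warns(UserWarning, match="constant group"):
            comp = group_compare([2.0, 2.0, 2.0, 2.0], [1.0, 3.0, 5.0, 7.0])
        assert comp.test_used == "Mann-Whitney"

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSampleSize:
    def test_reference_case(self):
        # 2 * (1.960 + 0.842)^2 = 15.70 -> 16 per group
        assert sample_size_per_group(1.0, alpha=0.05, power=0.80) == 16

    def test_power_half_drops_the_power_term(self):
        import math
        d = 0.7
        z = stats.norm.ppf(0.975)
        assert sample_size_per_group(d, 0.05, 0.5) == math.ceil(2 * z**2 / d**2)

    def test_inverse_square_scaling(self):
        n1 = sample_size_per_group(0.4)
        n2 = sample_size_per_group(0.8)
        assert n1 / n2 == pytest.approx(4.0, rel=0.1)

    def test_zero_effect_rejected(self):
        with pytest.raises(ValidationError):
            sample_size_per_group(0.0)
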