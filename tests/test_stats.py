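"""Statistical battery checked against closed forms, brute-force
formula evaluation, permutation resampling and an independent
repeated-measures implementation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import sonictal as s
from sonictal.stats import DegenerateDataError


class TestPairedT:
    def test_identical_pairs(self):
        res = s.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_computed_closed_form(self):
        # differences {1,2,3}: t = 2 / (1/sqrt(3)) = 3.4641, df = 2
        res = s.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), rel=1e-6)
        assert res.df == 2

    def test_one_tailed_halves_two_tailed_in_direction(self):
        x = np.array([3.0, 5.0, 4.0, 6.0, 7.0, 5.5, 4.5, 6.5])
        y = x - np.array([1.0, 0.5, 1.5, 0.2, 0.8, 1.1, 0.4, 0.9])
        two = s.paired_t(x, y, tail="two-sided")
        one = s.paired_t(x, y, tail="greater")
        assert one.p == pytest.approx(two.p / 2)

    def test_agrees_with_sign_flip_permutation(self, rng):
        x = rng.normal(0.4, 1.0, 8)
        y = rng.normal(0.0, 1.0, 8)
        res = s.paired_t(x, y, tail="greater")
        d = x - y
        # exact sign-flip null distribution of the t statistic (2^8 flips)
        signs = np.array(
            [[1 if (m >> b) & 1 else -1 for b in range(8)] for m in range(256)]
        )
        flipped = d * signs
        t_null = flipped.mean(1) / (flipped.std(1, ddof=1) / np.sqrt(8))
        p_perm = np.mean(t_null >= res.t)
        assert abs(res.p - p_perm) <= 0.05

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(99)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            d = rng.normal(0.0, 1.0, 10)
            rejections += s.paired_t(d, np.zeros(10)).p < 0.05
        rate = rejections / n_sim
        envelope = 2 * np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= envelope

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            s.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateDataError):
            s.paired_t([1.0], [2.0])


def _brute_force_anova(groups):
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_b = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_w = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    f = (ss_b / df_b) / (ss_w / df_w)
    return f, float(scipy.stats.f.sf(f, df_b, df_w))


class TestOneWayAnova:
    def test_identical_groups_give_zero_f(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = s.one_way_anova([g, g, g])
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_three_by_ten_degrees_of_freedom(self, rng):
        res = s.one_way_anova([rng.normal(size=10) for _ in range(3)])
        assert (res.df_between, res.df_within) == (2, 27)

    def test_agrees_with_brute_force_formula(self, rng):
        groups = [rng.normal(loc=i * 0.3, size=10) for i in range(3)]
        res = s.one_way_anova(groups)
        f, p = _brute_force_anova(groups)
        assert res.F == pytest.approx(f, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_shift_and_relabel_invariance(self, rng):
        groups = [rng.normal(size=6) for _ in range(3)]
        res = s.one_way_anova(groups)
        shifted = s.one_way_anova([g + 17.3 for g in groups])
        permuted = s.one_way_anova([groups[2], groups[0], groups[1]])
        assert shifted.F == pytest.approx(res.F, rel=1e-9)
        assert permuted.F == pytest.approx(res.F, rel=1e-9)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            s.one_way_anova([[1.0, 2.0], [3.0]])


class TestRmAnova:
    def test_eight_by_six_degrees_of_freedom(self, rng):
        res = s.rm_anova(rng.normal(size=(8, 6)))
        assert (res.df_between, res.df_within) == (5, 35)

    def test_condition_constant_matrix_gives_zero_f(self, rng):
        subj = rng.normal(size=(5, 1))
        table = np.repeat(subj, 4, axis=1)
        assert s.rm_anova(table).F == pytest.approx(0.0, abs=1e-12)

    def test_hand_sums_of_squares_on_toy_matrix(self):
        table = np.array([[1.0, 2.0, 4.0], [2.0, 3.0, 6.0], [0.0, 2.0, 5.0]])
        # hand decomposition: SS_cond = 3*sum((colmean-grand)^2) etc.
        grand = table.mean()
        ss_cond = 3 * np.sum((table.mean(0) - grand) ** 2)
        ss_subj = 3 * np.sum((table.mean(1) - grand) ** 2)
        ss_err = np.sum((table - grand) ** 2) - ss_cond - ss_subj
        f_expected = (ss_cond / 2) / (ss_err / 4)
        res = s.rm_anova(table)
        assert res.F == pytest.approx(f_expected, rel=1e-9)

    def test_agrees_with_independent_implementation(self, rng):
        table = rng.normal(size=(7, 4)) + rng.normal(size=(7, 1))
        res = s.rm_anova(table)
        import pingouin

        long = pd.DataFrame(
            {
                "y": table.ravel(),
                "subject": np.repeat(np.arange(7), 4),
                "condition": np.tile(np.arange(4), 7),
            }
        )
        ref = pingouin.rm_anova(
            data=long, dv="y", within="condition", subject="subject"
        )
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_missing_cells_rejected(self):
        table = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            s.rm_anova(table)


class TestPosthocs:
    def test_two_group_tukey_equals_pooled_t(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(0.5, 1.0, 8)
        [res] = s.tukey_kramer([a, b], ["a", "b"])
        t_p = scipy.stats.ttest_ind(a, b).pvalue
        assert res.p_adjusted == pytest.approx(t_p, rel=1e-6)

    def test_equal_n_matches_statsmodels_hsd(self, rng):
        groups = [rng.normal(loc=i * 0.5, size=9) for i in range(3)]
        ours = s.tukey_kramer(groups, ["g0", "g1", "g2"])
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        data = np.concatenate(groups)
        labels = np.repeat(["g0", "g1", "g2"], 9)
        ref = pairwise_tukeyhsd(data, labels)
        assert np.allclose(
            sorted(r.p_adjusted for r in ours), sorted(ref.pvalues), rtol=1e-4
        )

    def test_lsd_matches_pooled_pairwise_t(self, rng):
        groups = [rng.normal(size=6) for _ in range(3)]
        results = s.lsd(groups, ["a", "b", "c"])
        n_total = 18
        mse = sum(np.sum((g - g.mean()) ** 2) for g in groups) / (n_total - 3)
        a, b = groups[0], groups[1]
        t = (a.mean() - b.mean()) / np.sqrt(mse * (2 / 6))
        p = 2 * scipy.stats.t.sf(abs(t), n_total - 3)
        assert results[0].p_adjusted == pytest.approx(p, rel=1e-9)

    def test_bonferroni_arithmetic_and_cap(self):
        adjusted = s.bonferroni([0.02], m=3)
        assert adjusted[0] == pytest.approx(0.06)
        assert s.bonferroni([0.5, 0.9], m=3).max() == 1.0
        raw = np.array([0.01, 0.04, 0.2])
        assert (s.bonferroni(raw) >= raw).all()


class TestReports:
    def test_dialysis_zero_noise_relative_increase(self):
        cfg = s.DialysisConfig(
            condition_sds={c: 0.0 for c in s.synthetic.DEFAULT_DIALYSIS_MEANS},
            run_effect_sd=0.0,
            seed=0,
        )
        report = s.analyze_dialysis(s.generate_dialysis_samples(cfg))
        increase = report["relative_increase_vs_ctrl_percent"]["FF_set4"]
        assert increase == pytest.approx(18.18, abs=0.01)

    def test_dialysis_rm_design_dfs(self):
        report = s.analyze_dialysis(s.generate_dialysis_samples(s.DialysisConfig(seed=3)))
        assert report["rm_anova_ff_sets"]["df_between"] == 5
        assert report["rm_anova_ff_sets"]["df_within"] == 35
        assert report["rm_anova_ctrl_fo_ff"]["df_between"] == 2
        assert report["rm_anova_ctrl_fo_ff"]["df_within"] == 14

    def test_single_group_cohort_skips_between_tests(self):
        norm = pd.DataFrame(
            {
                "animal_id": ["A1", "A2", "A3"],
                "group": "G",
                "count_ratio": [0.5, 0.6, 0.7],
                "count_percent_change": [-50.0, -40.0, -30.0],
                "duration_ratio": [1.0, 1.1, 0.9],
                "duration_percent_change": [0.0, 10.0, -10.0],
                "amplitude_ratio": [1.0, 1.0, 1.0],
                "amplitude_percent_change": [0.0, 0.0, 0.0],
            }
        )
        with pytest.warns(UserWarning):
            report = s.analyze_cohort(norm)
        assert report["between_groups"]["count"] is None

    def test_null_cohort_anova_p_uniform(self):
        # between-group ANOVA p under the null is Uniform(0,1) across seeds
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(500):
            groups = [rng.normal(size=10) for _ in range(3)]
            pvals.append(s.one_way_anova(groups).p)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
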