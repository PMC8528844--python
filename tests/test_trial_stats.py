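"""Trial statistics: transforms, rank tests vs brute-force nulls, effect sizes."""

import dataclasses
import itertools
import json

import numpy as np
import pandas as pd
import pytest

from ki67window.simulate.trial import TrialSimSpec, generate_trial_table
from ki67window.trial_stats import (
    TrialTable,
    classify_responders,
    e2_association,
    effect_size_summary,
    kruskal_wallis,
    log_transform,
    mann_whitney,
    paired_change_ratio,
    resolve_range,
    run_trial_analysis,
    wilcoxon_signed_rank,
)


class TestTransforms:
    @pytest.mark.parametrize(
        "value,expected", [((10, 20), 20.0), (15, 15.0), ((7, 7), 7.0)]
    )
    def test_range_resolves_to_highest(self, value, expected):
        assert resolve_range(value) == expected

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            resolve_range((20, 10))

    @pytest.mark.parametrize("x,expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
    def test_log_transform_values(self, x, expected):
        assert log_transform(x) == pytest.approx(expected)

    def test_log_transform_rejects_negative(self):
        with pytest.raises(ValueError):
            log_transform(-1.0)

    @pytest.mark.parametrize(
        "pre,post,ratio", [(10, 10, 1.0), (19, 9, 0.5), (0, 0, 1.0)]
    )
    def test_paired_ratio_plus_one_convention(self, pre, post, ratio):
        r, lr = paired_change_ratio(pre, post)
        assert r == pytest.approx(ratio)
        assert lr == pytest.approx(np.log10(ratio))

    def test_decrease_percent_consistent_with_ratio(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(0, 80, 50)
        post = rng.uniform(0, 80, 50)
        ratio, _ = paired_change_ratio(pre, post)
        assert np.allclose(100 * (1 - ratio), 100 * (1 - (post + 1) / (pre + 1)))


class TestWilcoxon:
    def test_uniform_shift_n8_exact_p_is_one_over_256(self):
        pre = np.array([10.0, 12, 15, 20, 25, 30, 40, 50])
        post = pre - 3.0
        res = wilcoxon_signed_rank(pre, post, alternative="less")
        assert res.method == "wilcoxon-exact"
        assert res.p_value == pytest.approx(1 / 256)

    def test_all_zero_differences_flagged_p_one(self):
        pre = np.array([5.0, 6, 7, 8, 9])
        res = wilcoxon_signed_rank(pre, pre, alternative="less")
        assert res.flag == "all-zero"
        assert res.p_value == 1.0

    def test_exact_p_matches_sign_flip_enumeration_n10(self):
        rng = np.random.default_rng(17)
        pre = rng.uniform(5, 50, 10)
        post = pre + rng.normal(-2, 4, 10)
        res = wilcoxon_signed_rank(pre, post, alternative="less")
        # oracle: enumerate all 2^10 sign assignments of the |d| ranks
        d = post - pre
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        null = [
            np.sum(ranks[list(signs)])
            for n in range(11)
            for signs in itertools.combinations(range(10), n)
        ]
        expected = np.mean([w <= w_obs + 1e-9 for w in null])
        assert res.method == "wilcoxon-exact"
        assert res.p_value == pytest.approx(expected, abs=1e-12)


class TestMannWhitney:
    def test_most_extreme_arrangement_p_one_twentieth(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p_value == pytest.approx(1 / 20)
        assert res.statistic == 0.0

    def test_identical_groups_two_sided_p_one(self):
        res = mann_whitney([1.0, 2, 3], [1.0, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_p_matches_252_arrangement_enumeration(self):
        rng = np.random.default_rng(23)
        a = rng.uniform(0, 2, 5)
        b = rng.uniform(0.5, 2.5, 5)
        res = mann_whitney(a, b, alternative="less")
        pooled = np.concatenate([a, b])

        def u_of(idx_a):
            aa = pooled[list(idx_a)]
            bb = pooled[[i for i in range(10) if i not in idx_a]]
            return (aa[:, None] > bb[None, :]).sum() + 0.5 * (
                aa[:, None] == bb[None, :]
            ).sum()

        u_obs = u_of(range(5))
        null = [u_of(c) for c in itertools.combinations(range(10), 5)]
        assert len(null) == 252
        expected = np.mean([u <= u_obs + 1e-9 for u in null])
        assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_groups_below_three_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1, 2], [3, 4, 5])


class TestKruskalWallis:
    def test_three_identical_groups_h_zero_p_one(self):
        res = kruskal_wallis([[1.0, 2], [1.0, 2], [1.0, 2]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_groups_closed_form_h(self):
        # rank sums 3, 7, 11 over N=6: H = 12/42 * (9/2 + 49/2 + 121/2) - 21 = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32.0 / 7.0)

    def test_p_consistent_with_permutation_null(self):
        rng = np.random.default_rng(31)
        groups = [rng.normal(0, 1, 5), rng.normal(0.5, 1, 5), rng.normal(1.0, 1, 5)]
        res = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        h_obs = res.statistic
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            h = kruskal_wallis([pooled[:5], pooled[5:10], pooled[10:]]).statistic
            count += h >= h_obs - 1e-12
        p_mc = count / n_perm
        se = np.sqrt(p_mc * (1 - p_mc) / n_perm) + 1e-4
        # chi-square approximation within Monte-Carlo error (plus approx slack)
        assert res.p_value == pytest.approx(p_mc, abs=4 * se + 0.02)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [3, 4]])


def _table_from_pairs(pairs_by_arm):
    rows = []
    i = 0
    for arm, pairs in pairs_by_arm.items():
        meno = "pre" if arm == "tamoxifen_pre" else "post"
        for pre, post in pairs:
            rows.append(
                dict(
                    patient_id=f"T{i:03d}", arm=arm, menopause=meno,
                    ki67_pre=pre, ki67_post=post, e2_pre=44.0,
                    e2_pre_censored=True, e2_post=44.0, e2_post_censored=True,
                    treatment_days=20.0,
                )
            )
            i += 1
    return TrialTable(pd.DataFrame(rows))


class TestRespondersAndEffectSizes:
    def test_response_categories(self):
        t = _table_from_pairs(
            {"tamoxifen_post": [(20, 10), (10, 10), (10, 15)]}
        )
        resp = classify_responders(t)
        assert list(resp["category"]) == ["decrease", "equal", "increase"]
        assert list(resp["responder"]) == [True, False, False]

    def test_uniform_halving_gives_50_percent_sem_zero(self):
        t = _table_from_pairs(
            {"tamoxifen_post": [(19, 9), (39, 19), (9, 4), (99, 49), (59, 29)]}
        )
        es = effect_size_summary(t).table.set_index("arm")
        assert es.loc["tamoxifen_post", "mean_decrease_all"] == pytest.approx(50.0)
        assert es.loc["tamoxifen_post", "sem_all"] == pytest.approx(0.0)

    def test_all_patient_mean_below_responders_only_mean(self):
        t = _table_from_pairs({"tamoxifen_post": [(39, 19), (19, 39)]})
        es = effect_size_summary(t).table.set_index("arm")
        row = es.loc["tamoxifen_post"]
        assert row["mean_decrease_all"] < row["mean_decrease_responders"]
        assert row["n_responders"] == 1


class TestE2Association:
    def test_all_censored_flagged_insufficient(self):
        t = _table_from_pairs(
            {"tamoxifen_post": [(20, 10)] * 6}
        )
        res = e2_association(t)
        assert res.insufficient

    def test_power_under_strong_inverse_coupling(self):
        hits = 0
        for rep in range(200):
            spec = dataclasses.replace(
                TrialSimSpec(), n_tamoxifen_pre=32, e2_coupling_slope=0.8,
                seed=91_000 + rep,
            )
            res = e2_association(generate_trial_table(spec))
            hits += (not res.insufficient) and res.spearman_p < 0.05
        assert hits / 200 >= 0.90

    def test_size_under_no_coupling(self):
        hits = 0
        n = 400
        for rep in range(n):
            spec = dataclasses.replace(
                TrialSimSpec(), n_tamoxifen_pre=32, e2_coupling_slope=0.0,
                ratio_tamoxifen_post=TrialSimSpec().ratio_tamoxifen_pre,
                seed=95_000 + rep,
            )
            res = e2_association(generate_trial_table(spec))
            hits += (not res.insufficient) and res.spearman_p < 0.05
        assert 0.01 <= hits / n <= 0.10


class TestRunTrialAnalysis:
    def test_report_is_deterministic_and_serialisable(self, default_trial):
        a = json.dumps(run_trial_analysis(default_trial), sort_keys=True,
                       default=float)
        b = json.dumps(run_trial_analysis(default_trial), sort_keys=True,
                       default=float)
        assert a == b

    def test_simulated_table_detects_arm_difference(self, default_trial):
        report = run_trial_analysis(default_trial)
        assert report["within_arm_wilcoxon_post_lt_pre"]["tamoxifen_post"][
            "p_value"
        ] < 0.05
        assert "tamoxifen_pre_vs_post_mwu_on_ratios" in report
        assert report["multiple_testing"] == "uncorrected"

    def test_null_table_shows_no_effect(self):
        pairs = [(20.0 + i, 20.0 + i) for i in range(8)]
        t = _table_from_pairs(
            {"tamoxifen_pre": pairs, "tamoxifen_post": pairs,
             "anastrozole": pairs, "fulvestrant": pairs}
        )
        report = run_trial_analysis(t)
        for arm_res in report["within_arm_wilcoxon_post_lt_pre"].values():
            assert arm_res["p_value"] == 1.0
        assert report["postmenopausal_arms_kruskal_wallis"]["p_value"] == pytest.approx(1.0)

    def test_range_valued_ki67_uses_highest(self):
        t = _table_from_pairs({"tamoxifen_post": [(20, 10)] * 5})
        t.table["ki67_pre_high"] = [30.0, np.nan, np.nan, np.nan, np.nan]
        resolved = t.resolved("ki67_pre")
        assert resolved.iloc[0] == 30.0
        assert resolved.iloc[1] == 20.0
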