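"""Expression readouts: imputation, probe collapse, signatures, moderated t."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ki67window.expression import (
    ExpressionMatrix,
    GeneSet,
    collapse_probes,
    compare_arm_effects_mrna,
    fit_variance_prior,
    knn_impute,
    moderated_t,
    paired_differences,
    signature_score,
)


def _matrix(values, probes=None, genes=None, meta=None):
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    genes = genes or probes
    df = pd.DataFrame(values, index=probes,
                      columns=[f"s{i}" for i in range(values.shape[1])])
    if meta is None:
        meta = pd.DataFrame(
            {
                "patient_id": [f"pt{i // 2}" for i in range(values.shape[1])],
                "time": ["before", "after"] * (values.shape[1] // 2),
                "arm": "tamoxifen_post",
                "menopause": "post",
                "batch": "batch1",
            },
            index=df.columns,
        )
    return ExpressionMatrix(values=df, probe_to_gene=pd.Series(genes, index=probes),
                            meta=meta)


class TestKnnImpute:
    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(12, 6)))
        assert knn_impute(df, k=3).equals(df)

    def test_duplicated_row_with_hole_filled_by_twin(self):
        base = np.arange(6, dtype=float)
        df = pd.DataFrame([base, base, base + 50.0])
        df.iloc[0, 2] = np.nan
        out = knn_impute(df, k=1)
        assert out.iloc[0, 2] == 2.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 20))
        mask = rng.random(x.shape) < 0.08
        df = pd.DataFrame(np.where(mask, np.nan, x))
        k = 10
        out = knn_impute(df, k=k)

        # independent quadratic oracle, straight from the definition
        vals = df.to_numpy()
        for i in range(50):
            for j in range(20):
                if not np.isnan(vals[i, j]):
                    continue
                dists = []
                for r in range(50):
                    if r == i or np.isnan(vals[r, j]):
                        continue
                    shared = ~np.isnan(vals[i]) & ~np.isnan(vals[r])
                    if not shared.any():
                        continue
                    d = np.sqrt(np.mean((vals[i, shared] - vals[r, shared]) ** 2))
                    dists.append((d, r))
                dists.sort()
                donors = [r for _, r in dists[:k]]
                expected = np.mean([vals[r, j] for r in donors])
                assert out.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 8))
        mask = rng.random(x.shape) < 0.1
        df = pd.DataFrame(np.where(mask, np.nan, x))
        out = knn_impute(df, k=5)
        obs = ~df.isna()
        assert np.array_equal(out.values[obs.values], df.values[obs.values])

    def test_fully_missing_row_rejected_by_name(self):
        df = pd.DataFrame(np.ones((5, 3)), index=list("abcde"))
        df.loc["c"] = np.nan
        with pytest.raises(ValueError, match="'c'"):
            knn_impute(df, k=2)


class TestCollapseProbes:
    def test_odd_count_median(self):
        m = _matrix(np.array([[1.0], [2.0], [9.0]]) * np.ones((1, 4)),
                    probes=["a1", "a2", "a3"], genes=["G", "G", "G"])
        out = collapse_probes(m)
        assert (out.loc["G"] == 2.0).all()

    def test_even_count_median_is_mean_of_middle_two(self):
        m = _matrix(np.array([[1.0], [3.0]]) * np.ones((1, 4)),
                    probes=["a1", "a2"], genes=["G", "G"])
        assert (collapse_probes(m).loc["G"] == 2.0).all()

    def test_single_probe_passthrough(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(3, 4))
        m = _matrix(vals, probes=["a", "b", "c"], genes=["X", "Y", "Z"])
        out = collapse_probes(m)
        assert np.allclose(out.loc[["X", "Y", "Z"]].to_numpy(), vals)

    def test_collapse_commutes_with_subsetting_disjoint_sets(self):
        rng = np.random.default_rng(5)
        genes = ["A", "A", "B", "C", "C", "C", "D"]
        probes = [f"p{i}" for i in range(7)]
        m = _matrix(rng.normal(size=(7, 4)), probes=probes, genes=genes)
        full = collapse_probes(m)
        keep = ["A", "C"]
        sub_probes = [p for p, g in zip(probes, genes) if g in keep]
        m_sub = ExpressionMatrix(
            values=m.values.loc[sub_probes],
            probe_to_gene=m.probe_to_gene[sub_probes],
            meta=m.meta,
        )
        assert collapse_probes(m_sub).equals(full.loc[keep])


class TestSignatureScore:
    def test_single_gene_set_without_standardisation(self):
        rng = np.random.default_rng(2)
        gm = pd.DataFrame(rng.normal(size=(3, 5)), index=["A", "B", "C"])
        score = signature_score(gm, GeneSet("solo", ["B"]), standardize=False)
        assert np.allclose(score.to_numpy(), gm.loc["B"].to_numpy())

    def test_noiseless_members_rank_correlate_with_latent_factor(self):
        rng = np.random.default_rng(6)
        factor = rng.normal(size=12)
        gm = pd.DataFrame(
            {f"s{i}": factor[i] + np.zeros(4) for i in range(12)},
            index=["g1", "g2", "g3", "g4"],
        )
        gm = gm + rng.normal(0, 1, size=(4, 1))  # per-gene baselines
        score = signature_score(gm, GeneSet("set", ["g1", "g2", "g3", "g4"]))
        rho = stats.spearmanr(score.to_numpy(), factor).statistic
        assert rho == pytest.approx(1.0)

    def test_weight_flip_negates_contribution(self):
        rng = np.random.default_rng(9)
        gm = pd.DataFrame(rng.normal(size=(2, 6)), index=["up", "down"])
        plus = signature_score(
            gm, GeneSet("s", ["up", "down"], weights=[1, 1]), standardize=False
        )
        minus = signature_score(
            gm, GeneSet("s", ["up", "down"], weights=[1, -1]), standardize=False
        )
        diff = (plus - minus).to_numpy()
        assert np.allclose(diff, gm.loc["down"].to_numpy())

    def test_missing_members_warn_and_no_members_error(self):
        gm = pd.DataFrame(np.ones((2, 3)), index=["A", "B"])
        with pytest.warns(UserWarning, match="LOW-COVERAGE"):
            signature_score(gm, GeneSet("s", ["A", "x", "y", "z"]))
        with pytest.raises(ValueError, match="no genes"):
            signature_score(gm, GeneSet("s", ["q"]))


class TestModeratedT:
    def test_zero_prior_df_equals_ordinary_paired_t(self):
        rng = np.random.default_rng(11)
        diffs = pd.DataFrame(rng.normal(0, 1, size=(100, 9)))
        res = moderated_t(diffs, d0_override=0.0)
        t_ref, p_ref = stats.ttest_1samp(diffs.to_numpy(), 0.0, axis=1)
        assert np.allclose(res.table["t"], t_ref, atol=1e-12)
        assert np.allclose(res.table["p_value"], p_ref, atol=1e-12)

    def test_matches_limma_reference_on_frozen_fixture(self):
        """Reference values computed once with limma (lmFit + eBayes, R) on
        the identical deterministically generated difference matrix."""
        rng = np.random.default_rng(777)
        G, n = 200, 8
        sigma2 = 0.04 * 5.0 / rng.chisquare(5.0, G)
        mu = np.where(rng.random(G) < 0.1, rng.normal(0, 0.5, G), 0.0)
        x = mu[:, None] + rng.normal(0, np.sqrt(sigma2)[:, None], (G, n))
        diffs = pd.DataFrame(x, index=[f"g{i:03d}" for i in range(G)])
        res = moderated_t(diffs)
        assert res.d0 == pytest.approx(4.664155, abs=1e-4)
        assert res.s0_squared == pytest.approx(0.04553707, rel=1e-5)
        expected = {
            "g000": (-4.6913856824, 5.631896996e-4),
            "g007": (1.5500854633, 0.1478155438186),
            "g023": (0.2123875677, 0.8354708768708),
            "g111": (0.8659081044, 0.4039999522045),
            "g199": (-0.9044707890, 0.3840467160386),
        }
        for gene, (t_ref, p_ref) in expected.items():
            assert res.table.loc[gene, "t"] == pytest.approx(t_ref, rel=1e-6)
            assert res.table.loc[gene, "p_value"] == pytest.approx(p_ref, rel=1e-6)

    def test_shrunken_variances_concentrate_under_shared_truth(self):
        rng = np.random.default_rng(15)
        diffs = pd.DataFrame(rng.normal(0, 0.5, size=(2000, 6)))
        res = moderated_t(diffs)
        assert res.table["s2_posterior"].var() < res.table["s2_gene"].var()

    def test_prior_recovery_from_hierarchical_truth(self):
        rng = np.random.default_rng(21)
        d0, s0, dg = 6.0, 0.09, 9
        s2 = s0 * d0 / rng.chisquare(d0, 20000) * rng.chisquare(dg, 20000) / dg
        d0_hat, s0_hat = fit_variance_prior(s2, dg)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0, rel=0.05)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            moderated_t(pd.DataFrame(np.ones((5, 2))))


class TestArmComparison:
    def test_identical_difference_vectors_one_sided_p_half(self):
        d = np.array([-0.4, -0.2, -0.6, -0.3, -0.5])
        rep = compare_arm_effects_mrna(
            {"tamoxifen_pre": d, "tamoxifen_post": d.copy()}
        )
        assert rep["tamoxifen_pre_vs_post_t"]["p_one_sided"] == pytest.approx(0.5)

    def test_identical_postmenopausal_arms_anova_p_one(self):
        d = np.array([-0.4, -0.2, -0.6, -0.3])
        rep = compare_arm_effects_mrna(
            {
                "tamoxifen_pre": d - 0.1,
                "tamoxifen_post": d,
                "anastrozole": d.copy(),
                "fulvestrant": d.copy(),
            }
        )
        assert rep["postmenopausal_arms_anova"]["p_value"] == pytest.approx(1.0)

    def test_power_to_detect_mki67_downshift(self):
        """A 1-SD paired down-shift at n=14 is detected (one-sided p < 0.05)
        in at least 80% of replicates by the moderated t."""
        rng = np.random.default_rng(33)
        hits = 0
        reps = 200
        for _ in range(reps):
            diffs = pd.DataFrame(
                rng.normal(0, 0.4, size=(150, 14)),
                index=[f"g{i}" for i in range(150)],
            )
            diffs.iloc[0] -= 0.4  # MKI67-like gene shifted down by 1 SD
            res = moderated_t(diffs)
            hits += res.table.iloc[0]["p_one_sided_down"] < 0.05
        assert hits / reps >= 0.80


def test_paired_differences_orders_after_minus_before():
    vals = np.zeros((2, 4))
    vals[0] = [1.0, 3.0, 2.0, 7.0]
    m = _matrix(vals, probes=["a", "b"], genes=["A", "B"])
    gm = collapse_probes(m)
    diffs = paired_differences(gm, m.meta)
    assert diffs.loc["A", "pt0"] == pytest.approx(2.0)
    assert diffs.loc["A", "pt1"] == pytest.approx(5.0)
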