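"""Study-level evaluation routines: every headline quantity, recomputed.

Each function here runs the package end to end under the default study
conditions and measures one headline property — scoring concordance,
classifier reliability, effect-size recovery, test calibration, power.
They are shared by the acceptance checks and the analysis drivers so the
same computation backs both.

Problem sizes are desk-scale by design (sub-megapixel slides, hundreds of
simulated trials); the methods note documents the sizes used.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps
from scipy.spatial import cKDTree

from .concordance import PairedScores, icc, spearman
from .expression import moderated_t
from .ihc.classifier import PatchClassifier, train_patch_classifier
from .ihc.patches import sample_training_patches, training_split_counts
from .ihc.scoring import PipelineParams, detect_and_classify, score_roi
from .simulate.slides import SlideSpec, generate_slide
from .simulate.trial import TrialSimSpec, generate_trial_table
from .trial_stats import (
    e2_association,
    effect_size_summary,
    kruskal_wallis,
    log_transform,
    mann_whitney,
    paired_change_ratio,
    wilcoxon_signed_rank,
)

__all__ = [
    "patch_bookkeeping",
    "train_default_classifier",
    "scoring_concordance_panel",
    "detection_metrics",
    "effect_size_recovery",
    "null_trial_spec",
    "type_i_error_rates",
    "e2_association_calibration",
    "moderated_t_calibration",
]

#: the archive-scale sampling campaign whose bookkeeping is exactly reproducible
ARCHIVE_N_SLIDES = 4599
ARCHIVE_PATCHES_PER_SLIDE = 4000
ARCHIVE_SPLIT = 0.8


def patch_bookkeeping() -> dict[str, int]:
    """Exact patch counts of the archive-scale training campaign."""
    return training_split_counts(
        ARCHIVE_N_SLIDES, ARCHIVE_PATCHES_PER_SLIDE, ARCHIVE_SPLIT
    )


def train_default_classifier(
    seed: int,
    n_slides: int = 6,
    per_slide: int = 500,
    positivity_range: tuple[float, float] = (0.05, 0.60),
) -> PatchClassifier:
    """Train the classical patch classifier on a default synthetic panel."""
    rng = np.random.default_rng(seed)
    lo, hi = positivity_range
    panel = [
        generate_slide(
            SlideSpec(
                positive_fraction=float(rng.uniform(lo, hi)),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
        for _ in range(n_slides)
    ]
    sample = sample_training_patches(panel, per_slide=per_slide, seed=seed)
    return train_patch_classifier(sample, seed=seed)


def scoring_concordance_panel(
    classifier: PatchClassifier,
    seed: int,
    n_rois: int = 20,
    positivity_range: tuple[float, float] = (0.05, 0.60),
    params: PipelineParams | None = None,
) -> dict:
    """Score a panel of ROIs spanning the positivity range vs ground truth.

    Returns Spearman rho and ICC(2,1) between the pipeline index and the
    generator's ground-truth index — the synthetic mirror of validating an
    automated scorer against exhaustive visual counts.
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(seed)
    lo, hi = positivity_range
    fractions = np.linspace(lo, hi, n_rois)
    truth, estimated = [], []
    for frac in fractions:
        slide, gt = generate_slide(
            SlideSpec(positive_fraction=float(frac), seed=int(rng.integers(2**31 - 1)))
        )
        h, w = slide.shape
        score = score_roi(slide, (0, 0, h, w), classifier, params)
        truth.append(gt.ki67_index())
        estimated.append(score.index)
    paired = PairedScores.from_arrays(truth, estimated)
    sp = spearman(paired)
    ic = icc(paired)
    return {
        "n_rois": n_rois,
        "true_index": truth,
        "pipeline_index": estimated,
        "spearman_rho": sp.rho,
        "icc2_1": ic.icc,
        "icc_ci": (ic.ci_low, ic.ci_high),
    }


def detection_metrics(
    classifier: PatchClassifier,
    slide_spec: SlideSpec,
    params: PipelineParams | None = None,
    match_radius_px: float = 10.0,
) -> dict:
    """Detection recall/precision and positivity accuracy vs ground truth."""
    params = params or PipelineParams()
    slide, gt = generate_slide(slide_spec)
    calls = [c for c in detect_and_classify(slide.image, classifier, params) if c.valid]
    tumor = gt.table[gt.table["cell_class"] == "tumor"]
    xy = tumor[["center_row", "center_col"]].to_numpy()
    labels = tumor["ki67_positive"].to_numpy()
    det = np.array([[c.center_row, c.center_col] for c in calls])
    if len(det) == 0 or len(xy) == 0:
        return {"recall": 0.0, "precision": 0.0, "positivity_accuracy": float("nan")}
    d_det, idx = cKDTree(xy).query(det)
    precision = float((d_det <= match_radius_px).mean())
    d_gt, _ = cKDTree(det).query(xy)
    recall = float((d_gt <= match_radius_px).mean())
    matched = d_det <= match_radius_px
    agree = [
        bool(calls[i].positive) == bool(labels[idx[i]])
        for i in range(len(calls))
        if matched[i]
    ]
    return {
        "recall": recall,
        "precision": precision,
        "positivity_accuracy": float(np.mean(agree)) if agree else float("nan"),
        "n_detected": len(calls),
        "n_true_tumor": len(xy),
    }


def effect_size_recovery(seed: int, n_replicates: int = 500) -> dict:
    """Recover the per-arm mean percent decreases across simulated trials.

    Also reports how often the one-sided Mann-Whitney comparing the two
    tamoxifen arms' ratios rejects at alpha = 0.05.
    """
    base = TrialSimSpec()
    dec_post, dec_pre, mwu_reject = [], [], 0
    for rep in range(n_replicates):
        table = generate_trial_table(
            dataclasses.replace(base, seed=seed + rep)
        )
        es = effect_size_summary(table).table.set_index("arm")
        dec_post.append(es.loc["tamoxifen_post", "mean_decrease_all"])
        dec_pre.append(es.loc["tamoxifen_pre", "mean_decrease_all"])
        a = table.arm("tamoxifen_pre")
        b = table.arm("tamoxifen_post")
        ra, _ = paired_change_ratio(a["ki67_pre"].to_numpy(), a["ki67_post"].to_numpy())
        rb, _ = paired_change_ratio(b["ki67_pre"].to_numpy(), b["ki67_post"].to_numpy())
        mwu_reject += mann_whitney(ra, rb, alternative="greater").p_value < 0.05
    dec_post = np.asarray(dec_post)
    dec_pre = np.asarray(dec_pre)
    return {
        "n_replicates": n_replicates,
        "postmenopausal_mean_decrease": float(dec_post.mean()),
        "postmenopausal_se": float(dec_post.std(ddof=1) / np.sqrt(n_replicates)),
        "premenopausal_mean_decrease": float(dec_pre.mean()),
        "premenopausal_se": float(dec_pre.std(ddof=1) / np.sqrt(n_replicates)),
        "target_postmenopausal": 100.0 * (1.0 - base.ratio_tamoxifen_post),
        "target_premenopausal": 100.0 * (1.0 - base.ratio_tamoxifen_pre),
        "mwu_rejection_rate": mwu_reject / n_replicates,
    }


def null_trial_spec(**overrides) -> TrialSimSpec:
    """The no-effect study conditions: exchangeable pairs, no coupling.

    Mean log-ratio is zero in every arm (arithmetic mean ratio
    ``exp(sigma^2/2)``), the E2 coupling is off, and pre-treatment Ki67 is
    truncated to [5, 40] so the [0, 100] clamp cannot break pre/post
    exchangeability.
    """
    base = TrialSimSpec()
    null_ratio = float(np.exp(base.ratio_log_sd**2 / 2.0))
    return TrialSimSpec(
        ratio_tamoxifen_pre=null_ratio,
        ratio_tamoxifen_post=null_ratio,
        ratio_anastrozole=null_ratio,
        ratio_fulvestrant=null_ratio,
        e2_coupling_slope=0.0,
        ki67_low=5.0,
        ki67_high=40.0,
        **overrides,
    )


def type_i_error_rates(seed: int, n_replicates: int = 2000, alpha: float = 0.05) -> dict:
    """Rejection rates of every trial test under the no-effect simulation."""
    spec = null_trial_spec()
    w = m = k = 0
    for rep in range(n_replicates):
        table = generate_trial_table(dataclasses.replace(spec, seed=seed + rep))
        b = table.arm("tamoxifen_post")
        a = table.arm("tamoxifen_pre")
        w += (
            wilcoxon_signed_rank(
                log_transform(b["ki67_pre"].to_numpy()),
                log_transform(b["ki67_post"].to_numpy()),
                alternative="less",
            ).p_value
            < alpha
        )
        ra, _ = paired_change_ratio(a["ki67_pre"].to_numpy(), a["ki67_post"].to_numpy())
        rb, _ = paired_change_ratio(b["ki67_pre"].to_numpy(), b["ki67_post"].to_numpy())
        m += mann_whitney(ra, rb, alternative="greater").p_value < alpha
        groups = []
        for arm in ("tamoxifen_post", "anastrozole", "fulvestrant"):
            sub = table.arm(arm)
            r, _ = paired_change_ratio(
                sub["ki67_pre"].to_numpy(), sub["ki67_post"].to_numpy()
            )
            groups.append(np.atleast_1d(r))
        k += kruskal_wallis(groups).p_value < alpha
    return {
        "n_replicates": n_replicates,
        "alpha": alpha,
        "wilcoxon": w / n_replicates,
        "mann_whitney": m / n_replicates,
        "kruskal_wallis": k / n_replicates,
    }


def e2_association_calibration(
    seed: int,
    n_power: int = 200,
    n_null: int = 2000,
    strong_slope: float = 0.8,
    n_patients: int = 32,
    alpha: float = 0.05,
) -> dict:
    """Power under strong inverse E2 coupling and size under the null.

    The null uses equal arm means (no coupling, no between-arm confounding
    of effect size with the E2 distribution).
    """
    power_hits = 0
    for rep in range(n_power):
        spec = dataclasses.replace(
            TrialSimSpec(),
            n_tamoxifen_pre=n_patients,
            e2_coupling_slope=strong_slope,
            seed=seed + rep,
        )
        res = e2_association(generate_trial_table(spec))
        power_hits += (not res.insufficient) and res.spearman_p < alpha
    null_hits = 0
    for rep in range(n_null):
        spec = dataclasses.replace(
            TrialSimSpec(),
            n_tamoxifen_pre=n_patients,
            e2_coupling_slope=0.0,
            ratio_tamoxifen_post=TrialSimSpec().ratio_tamoxifen_pre,
            seed=seed + n_power + rep,
        )
        res = e2_association(generate_trial_table(spec))
        null_hits += (not res.insufficient) and res.spearman_p < alpha
    return {
        "power": power_hits / n_power,
        "null_rejection_rate": null_hits / n_null,
        "n_power": n_power,
        "n_null": n_null,
        "strong_slope": strong_slope,
    }


def moderated_t_calibration(
    seed: int, n_genes: int = 5000, n_pairs: int = 14, d0_true: float = 4.0,
    s0_true: float = 0.05,
) -> dict:
    """Null-uniformity of moderated-t p-values under the hierarchical model.

    Simulates gene variances from the scaled inverse-chi-square prior and
    zero-mean paired differences, then KS-tests the p-values against
    uniformity and reports the recovered prior.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n_genes)
    x = rng.normal(0.0, np.sqrt(sigma2)[:, None], (n_genes, n_pairs))
    diffs = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)])
    res = moderated_t(diffs)
    ks = sps.kstest(res.table["p_value"].dropna(), "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "d0_estimated": res.d0,
        "d0_true": d0_true,
        "s0_estimated": res.s0_squared,
        "s0_true": s0_true,
        "n_genes": n_genes,
        "n_pairs": n_pairs,
    }
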