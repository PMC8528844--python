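"""Synthetic window-trial tables with known paired-response truth.

Emulates the study conditions of a presurgical endocrine trial: four arms
with paired pre/post Ki67, arm-specific multiplicative treatment effects on
the (post+1)/(pre+1) ratio, lognormal pre-treatment Ki67, menopause-specific
estradiol (E2) with a 44 pmol/L assay detection limit, and an optional
inverse E2-response coupling (higher post-treatment E2 dampens the Ki67
decrease) acting on patients whose post-treatment E2 is above the limit.

Distributional choices and how they map to the emulated trial:

* arm sizes default to the study's paired counts (29/14/15/13);
* mean post/pre ratios default to 0.65 (premenopausal tamoxifen) and 0.37
  (postmenopausal tamoxifen), i.e. ~35% and ~63% mean decreases; the
  postmenopausal anastrozole/fulvestrant means are set near the tamoxifen
  arm, since the three postmenopausal arms were not clearly separable;
* pre-treatment E2 is far above the detection limit for premenopausal
  women and almost entirely below it for postmenopausal women.

Ratios are drawn so the *arithmetic* mean ratio per arm equals the spec
value: lognormal with mean-correcting offset, and the coupling factor is
renormalised within each arm to have unit sample mean, so the coupling
shifts individual patients without moving the arm mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..trial_stats import ARMS, E2_DETECTION_LIMIT_PMOL_L, TrialTable

__all__ = ["TrialSimSpec", "generate_trial_table"]

_ARM_MENOPAUSE = {
    "tamoxifen_pre": "pre",
    "tamoxifen_post": "post",
    "anastrozole": "post",
    "fulvestrant": "post",
}


@dataclass(frozen=True)
class TrialSimSpec:
    """Study conditions for one simulated trial."""

    n_tamoxifen_pre: int = 29
    n_tamoxifen_post: int = 14
    n_anastrozole: int = 15
    n_fulvestrant: int = 13
    #: arithmetic mean of the (post+1)/(pre+1) ratio per arm
    ratio_tamoxifen_pre: float = 0.65
    ratio_tamoxifen_post: float = 0.37
    ratio_anastrozole: float = 0.40
    ratio_fulvestrant: float = 0.50
    #: natural-log SD of the per-patient ratio around its arm mean
    ratio_log_sd: float = 0.4
    #: pre-treatment Ki67 %, truncated lognormal (natural-log median and SD)
    ki67_median: float = 11.0
    ki67_log_sd: float = 0.8
    #: the +1 ratio scale cannot express strong decreases when pre ~ 0
    #: (ratio >= 1/(pre+1)), so pre-treatment Ki67 is truncated away from 0
    ki67_low: float = 4.0
    ki67_high: float = 80.0
    #: E2 pmol/L lognormal medians and natural-log SDs by menopausal status
    e2_pre_median_premenopausal: float = 300.0
    e2_log_sd_premenopausal: float = 0.7
    e2_pre_median_postmenopausal: float = 15.0
    e2_log_sd_postmenopausal: float = 0.6
    #: natural-log SD of the post/pre E2 multiplier (captures both rises and falls)
    e2_change_log_sd: float = 0.5
    e2_detection_limit: float = E2_DETECTION_LIMIT_PMOL_L
    #: d(ln ratio) / d(log10 post-E2); > 0 = inverse coupling (high E2 damps effect)
    e2_coupling_slope: float = 0.4
    treatment_days_mean_premenopausal: float = 23.8
    treatment_days_mean_postmenopausal: float = 18.0
    treatment_days_sd: float = 8.0
    seed: int = 0

    def n_for(self, arm: str) -> int:
        return {
            "tamoxifen_pre": self.n_tamoxifen_pre,
            "tamoxifen_post": self.n_tamoxifen_post,
            "anastrozole": self.n_anastrozole,
            "fulvestrant": self.n_fulvestrant,
        }[arm]

    def ratio_for(self, arm: str) -> float:
        return {
            "tamoxifen_pre": self.ratio_tamoxifen_pre,
            "tamoxifen_post": self.ratio_tamoxifen_post,
            "anastrozole": self.ratio_anastrozole,
            "fulvestrant": self.ratio_fulvestrant,
        }[arm]

    def validate(self) -> list[str]:
        problems = []
        if any(self.n_for(a) < 1 for a in ARMS):
            problems.append("all arm sample sizes must be >= 1")
        if any(self.ratio_for(a) <= 0 for a in ARMS):
            problems.append("mean ratios must be positive")
        if self.e2_detection_limit <= 0:
            problems.append("E2 detection limit must be positive")
        if self.ratio_log_sd < 0 or self.ki67_log_sd <= 0:
            problems.append("dispersions must be positive")
        if not 0 < self.ki67_low < self.ki67_high <= 100:
            problems.append("Ki67 truncation bounds must satisfy 0 < low < high <= 100")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))


def _truncated_lognormal(
    rng: np.random.Generator, n: int, median: float, log_sd: float,
    low: float, high: float,
) -> np.ndarray:
    """Exact truncated-lognormal draws via inverse-CDF (KS-testable)."""
    dist = stats.lognorm(s=log_sd, scale=median)
    u = rng.uniform(dist.cdf(low), dist.cdf(high), size=n)
    return dist.ppf(u)


def generate_trial_table(spec: TrialSimSpec) -> TrialTable:
    """Simulate one trial; deterministic given ``spec.seed``.

    The hidden ``true_ratio`` column records each patient's drawn
    (post+1)/(pre+1) ratio before Ki67 bounds are applied, for
    parameter-recovery diagnostics.
    """
    spec.require_valid()
    rng = np.random.default_rng(spec.seed)
    frames = []
    counter = 1
    for arm in ARMS:
        n = spec.n_for(arm)
        meno = _ARM_MENOPAUSE[arm]
        pre = _truncated_lognormal(
            rng, n, spec.ki67_median, spec.ki67_log_sd, spec.ki67_low, spec.ki67_high
        )
        if meno == "pre":
            e2_median, e2_sd = (
                spec.e2_pre_median_premenopausal,
                spec.e2_log_sd_premenopausal,
            )
            days_mean = spec.treatment_days_mean_premenopausal
        else:
            e2_median, e2_sd = (
                spec.e2_pre_median_postmenopausal,
                spec.e2_log_sd_postmenopausal,
            )
            days_mean = spec.treatment_days_mean_postmenopausal
        e2_pre_raw = e2_median * rng.lognormal(0.0, e2_sd, size=n)
        e2_post_raw = e2_pre_raw * rng.lognormal(0.0, spec.e2_change_log_sd, size=n)

        mean_ratio = spec.ratio_for(arm)
        noise = rng.normal(0.0, spec.ratio_log_sd, size=n)
        ln_ratio = np.log(mean_ratio) - 0.5 * spec.ratio_log_sd**2 + noise

        uncensored = e2_post_raw > spec.e2_detection_limit
        if spec.e2_coupling_slope != 0.0 and uncensored.sum() >= 2:
            x = np.zeros(n)
            x[uncensored] = np.log10(e2_post_raw[uncensored])
            x[uncensored] -= x[uncensored].mean()
            effect = spec.e2_coupling_slope * x
            # renormalise so the coupling factor has unit sample mean per arm
            effect -= np.log(np.exp(effect).mean())
            ln_ratio = ln_ratio + effect

        ratio = np.exp(ln_ratio)
        post = np.clip(ratio * (pre + 1.0) - 1.0, 0.0, 100.0)

        days = np.clip(
            rng.normal(days_mean, spec.treatment_days_sd, size=n), 7.0, 60.0
        )
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"P{counter + i:03d}" for i in range(n)],
                    "arm": arm,
                    "menopause": meno,
                    "ki67_pre": pre,
                    "ki67_post": post,
                    "e2_pre": np.where(
                        e2_pre_raw < spec.e2_detection_limit,
                        spec.e2_detection_limit,
                        e2_pre_raw,
                    ),
                    "e2_pre_censored": e2_pre_raw < spec.e2_detection_limit,
                    "e2_post": np.where(
                        e2_post_raw < spec.e2_detection_limit,
                        spec.e2_detection_limit,
                        e2_post_raw,
                    ),
                    "e2_post_censored": e2_post_raw < spec.e2_detection_limit,
                    "treatment_days": days,
                    "true_ratio": ratio,
                }
            )
        )
        counter += n
    return TrialTable(pd.concat(frames, ignore_index=True))
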