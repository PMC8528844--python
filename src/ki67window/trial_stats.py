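"""Paired-response statistics for a presurgical endocrine window trial.

Patients provide a Ki67 proliferation index before and after a few weeks of
endocrine treatment (tamoxifen in pre- and postmenopausal women,
anastrozole or fulvestrant in postmenopausal women).  The analysis works on
the post/pre ratio with a +1 offset, ``(post + 1) / (pre + 1)``, so a
pre-treatment index of 0 stays defined, and on ``log10(Ki67 + 1)`` where a
log scale is needed.  All hypothesis tests are nonparametric and reported
uncorrected, with their sidedness labelled:

* within-arm change: one-sided Wilcoxon signed-rank (post < pre) on
  ``log10(Ki67 + 1)`` values — signed ranks assume symmetric differences,
  which holds on the log scale for multiplicative treatment effects,
* between the two tamoxifen arms: one-sided Mann-Whitney U on the ratios
  (premenopausal ratios stochastically greater = smaller effect),
* across the three postmenopausal arms: two-sided Kruskal-Wallis,
* estradiol gradient: association between post-treatment E2 (above the
  44 pmol/L assay detection limit) and the magnitude of Ki67 decrease.

Small samples use exact nulls (signed-rank enumeration, exhaustive
two-sample permutation); larger ones use tie-corrected normal or chi-square
approximations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ARMS",
    "POSTMENOPAUSAL_ARMS",
    "E2_DETECTION_LIMIT_PMOL_L",
    "TrialTable",
    "TestResult",
    "ResponseSummary",
    "resolve_range",
    "log_transform",
    "paired_change_ratio",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "kruskal_wallis",
    "classify_responders",
    "effect_size_summary",
    "e2_association",
    "run_trial_analysis",
]

ARMS = ("tamoxifen_pre", "tamoxifen_post", "anastrozole", "fulvestrant")
POSTMENOPAUSAL_ARMS = ("tamoxifen_post", "anastrozole", "fulvestrant")
E2_DETECTION_LIMIT_PMOL_L = 44.0

_EXACT_MAX_N = 12

REQUIRED_COLUMNS = [
    "patient_id",
    "arm",
    "menopause",
    "ki67_pre",
    "ki67_post",
    "e2_pre",
    "e2_pre_censored",
    "e2_post",
    "e2_post_censored",
    "treatment_days",
]


@dataclass
class TrialTable:
    """Per-patient paired biomarker records with arm/menopause metadata.

    ``ki67_pre``/``ki67_post`` may alternatively be ranges; ranges are stored
    in companion ``*_high`` columns and resolved to the highest value (the
    range -> highest convention) by :meth:`resolved`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        bad_arm = set(self.table["arm"]) - set(ARMS)
        if bad_arm:
            raise ValueError(f"unknown arms: {sorted(bad_arm)}")
        t = self.table
        pre_arm = t["arm"] == "tamoxifen_pre"
        if not (t.loc[pre_arm, "menopause"] == "pre").all():
            raise ValueError("tamoxifen_pre arm must be premenopausal")
        if not (t.loc[~pre_arm, "menopause"] == "post").all():
            raise ValueError("non-tamoxifen_pre arms must be postmenopausal")
        for col in ("ki67_pre", "ki67_post"):
            vals = self.resolved(col)
            ok = vals.isna() | ((vals >= 0) & (vals <= 100))
            if not ok.all():
                raise ValueError(f"{col} outside [0, 100]")

    def resolved(self, col: str) -> pd.Series:
        """Ki67 column with the range -> highest rule applied."""
        vals = self.table[col].astype(float)
        high_col = f"{col}_high"
        if high_col in self.table.columns:
            high = self.table[high_col].astype(float)
            if ((high < vals) & high.notna()).any():
                raise ValueError(f"{high_col} below {col} for some patients")
            vals = vals.where(high.isna(), high)
        return vals

    def arm(self, name: str) -> pd.DataFrame:
        sub = self.table[self.table["arm"] == name].copy()
        for col in ("ki67_pre", "ki67_post"):
            sub[col] = self.resolved(col)[sub.index]
        return sub

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrialTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    alternative: str
    flag: str | None = None

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "method": self.method,
            "alternative": self.alternative,
            "correction": "uncorrected",
            **({"flag": self.flag} if self.flag else {}),
        }


def resolve_range(value) -> float:
    """Collapse a (low, high) Ki67 range to its highest value.

    Scalars pass through; a degenerate range returns its single value.
    """
    if isinstance(value, (tuple, list)):
        low, high = value
        if low > high:
            raise ValueError(f"range low {low} exceeds high {high}")
        return float(high)
    return float(value)


def log_transform(ki67) -> np.ndarray | float:
    """``log10(Ki67 + 1)``; defined at 0, rejects negative input."""
    arr = np.asarray(ki67, dtype=float)
    if np.any(arr < 0):
        raise ValueError("Ki67 percentages must be non-negative")
    out = np.log10(arr + 1.0)
    return float(out) if out.ndim == 0 else out


def paired_change_ratio(pre, post) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Post/pre ratio with the +1 offset, and its log10.

    Returns ``((post + 1) / (pre + 1), log10 thereof)``; the offset is
    applied uniformly so ``pre = post = 0`` gives ratio 1.
    """
    pre_a = np.asarray(pre, dtype=float)
    post_a = np.asarray(post, dtype=float)
    if np.any(pre_a < 0) or np.any(post_a < 0):
        raise ValueError("Ki67 percentages must be non-negative")
    ratio = (post_a + 1.0) / (pre_a + 1.0)
    log_ratio = np.log10(ratio)
    if ratio.ndim == 0:
        return float(ratio), float(log_ratio)
    return ratio, log_ratio


def wilcoxon_signed_rank(pre, post, alternative: str = "less") -> TestResult:
    """Wilcoxon signed-rank test on paired (pre, post) values.

    ``alternative='less'`` tests post < pre.  Zero differences are dropped
    (classic Wilcoxon); if everything is zero the result is flagged with
    p = 1.  Exact sign-flip enumeration on tie-averaged ranks for n <= 12,
    otherwise the tie-corrected normal approximation (no continuity
    correction).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired")
    d = post - pre
    nz = d[d != 0]
    if len(nz) == 0:
        return TestResult(np.nan, 1.0, 0, "degenerate", alternative, flag="all-zero")
    if len(nz) < 5:
        flag = "n<5 after dropping zeros"
    else:
        flag = None
    if len(nz) <= _EXACT_MAX_N:
        # sign-flip enumeration on tie-averaged ranks (valid with ties)
        ranks = stats.rankdata(np.abs(nz))
        w_obs = float(ranks[nz > 0].sum())
        n = len(nz)
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        null = signs @ ranks
        tol = 1e-9
        p_less = float((null <= w_obs + tol).mean())
        p_greater = float((null >= w_obs - tol).mean())
        if alternative == "less":
            p = p_less
        elif alternative == "greater":
            p = p_greater
        else:
            p = min(1.0, 2.0 * min(p_less, p_greater))
        return TestResult(w_obs, p, n, "wilcoxon-exact", alternative, flag=flag)
    res = stats.wilcoxon(
        post, pre, zero_method="wilcox", alternative=alternative, method="approx"
    )
    return TestResult(
        float(res.statistic), float(res.pvalue), len(nz), "wilcoxon-approx",
        alternative, flag=flag,
    )


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * ties)


def mann_whitney(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U on two independent samples (e.g. post/pre ratios).

    Exact exhaustive-permutation null for nA + nB <= 12 (valid with ties);
    tie-corrected normal approximation with continuity correction otherwise.
    ``alternative='greater'`` means group A stochastically greater.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    u_obs = _u_statistic(a, b)
    n_tot = len(a) + len(b)
    pooled_all = np.concatenate([a, b])
    if np.all(pooled_all == pooled_all[0]):
        return TestResult(u_obs, 1.0, n_tot, "mann-whitney-degenerate",
                          alternative, flag="all-identical")
    if n_tot <= _EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        idx = range(n_tot)
        null = []
        for combo in itertools.combinations(idx, len(a)):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(combo)] = True
            null.append(_u_statistic(pooled[mask], pooled[~mask]))
        null = np.array(null)
        tol = 1e-9
        p_greater = float((null >= u_obs - tol).mean())
        p_less = float((null <= u_obs + tol).mean())
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        method = "exact-permutation"
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        p = float(res.pvalue)
        method = "normal-approximation"
    return TestResult(u_obs, p, n_tot, f"mann-whitney-{method}", alternative)


def kruskal_wallis(groups) -> TestResult:
    """Tie-corrected Kruskal-Wallis H across >= 3 groups, chi-square p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis requires at least 3 non-empty groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    if all(np.all(g == groups[0][0]) for g in groups):
        return TestResult(0.0, 1.0, sum(map(len, groups)), "kruskal-wallis",
                          "two-sided", flag="all-identical")
    h, p = stats.kruskal(*groups)
    return TestResult(float(h), float(p), sum(map(len, groups)),
                      "kruskal-wallis", "two-sided")


def classify_responders(table: TrialTable, readout: str = "ki67") -> pd.DataFrame:
    """Per-patient response category: decrease (responder), equal, increase.

    A responder shows a strict post < pre decrease; equality is its own
    category (distinct from increase), matching the trial's colour coding.
    Patients missing either value are excluded.
    """
    pre = table.resolved(f"{readout}_pre")
    post = table.resolved(f"{readout}_post")
    keep = pre.notna() & post.notna()
    out = pd.DataFrame(
        {
            "patient_id": table.table.loc[keep, "patient_id"],
            "arm": table.table.loc[keep, "arm"],
            "category": np.select(
                [post[keep] < pre[keep], post[keep] == pre[keep]],
                ["decrease", "equal"],
                default="increase",
            ),
        }
    )
    out["responder"] = out["category"] == "decrease"
    return out.reset_index(drop=True)


@dataclass
class ResponseSummary:
    """Per-arm effect sizes: mean % decrease over all patients / responders."""

    table: pd.DataFrame

    def as_dict(self) -> dict:
        return self.table.set_index("arm").to_dict(orient="index")


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    if len(x) == 0:
        return float("nan"), float("nan")
    sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return float(np.mean(x)), sem


def effect_size_summary(table: TrialTable, readout: str = "ki67") -> ResponseSummary:
    """Per-arm mean percent decrease, ``100 * (1 - (post+1)/(pre+1))``.

    Reported over all paired patients and over responders only, with SEM.
    """
    responders = classify_responders(table, readout).set_index("patient_id")
    rows = []
    for arm in ARMS:
        sub = table.arm(arm)
        sub = sub[sub[f"{readout}_pre"].notna() & sub[f"{readout}_post"].notna()]
        if len(sub) == 0:
            continue
        ratio, _ = paired_change_ratio(
            sub[f"{readout}_pre"].to_numpy(), sub[f"{readout}_post"].to_numpy()
        )
        decrease = 100.0 * (1.0 - np.atleast_1d(ratio))
        is_resp = responders.loc[sub["patient_id"], "responder"].to_numpy()
        mean_all, sem_all = _mean_sem(decrease)
        mean_resp, sem_resp = _mean_sem(decrease[is_resp])
        rows.append(
            {
                "arm": arm,
                "n_pairs": len(sub),
                "n_responders": int(is_resp.sum()),
                "mean_decrease_all": mean_all,
                "sem_all": sem_all,
                "mean_decrease_responders": mean_resp,
                "sem_responders": sem_resp,
            }
        )
    return ResponseSummary(pd.DataFrame(rows))


@dataclass
class E2AssociationResult:
    spearman_rho: float
    spearman_p: float
    slope: float
    slope_p: float
    n: int
    insufficient: bool = False

    def as_dict(self) -> dict:
        return {
            "spearman_rho": self.spearman_rho,
            "spearman_p_one_sided": self.spearman_p,
            "log_linear_slope": self.slope,
            "slope_p_one_sided": self.slope_p,
            "n": self.n,
            "insufficient": self.insufficient,
        }


def e2_association(
    table: TrialTable,
    detection_limit: float = E2_DETECTION_LIMIT_PMOL_L,
    readout: str = "ki67",
) -> E2AssociationResult:
    """Association between post-treatment estradiol and the Ki67 decrease.

    Restricted to tamoxifen-treated patients whose post-treatment E2 exceeds
    the assay detection limit (censored values carry no gradient
    information and are excluded).  Primary readout: one-sided Spearman test
    of a *negative* association between E2 and the decrease magnitude.
    Secondary: least-squares slope of log10 Ki67 ratio on log10 E2, with a
    one-sided p for slope > 0.  Fewer than 5 usable patients flags the
    result insufficient.
    """
    t = table.table
    tam = t[t["arm"].isin(["tamoxifen_pre", "tamoxifen_post"])].copy()
    usable = (
        (~tam["e2_post_censored"].astype(bool))
        & (tam["e2_post"] > detection_limit)
        & tam["ki67_pre"].notna()
        & tam["ki67_post"].notna()
    )
    tam = tam[usable]
    if len(tam) < 5:
        return E2AssociationResult(np.nan, np.nan, np.nan, np.nan, len(tam),
                                   insufficient=True)
    pre = table.resolved("ki67_pre")[tam.index].to_numpy()
    post = table.resolved("ki67_post")[tam.index].to_numpy()
    ratio, log_ratio = paired_change_ratio(pre, post)
    decrease = 100.0 * (1.0 - np.atleast_1d(ratio))
    e2 = tam["e2_post"].to_numpy(dtype=float)
    rho, p_two = stats.spearmanr(e2, decrease)
    p_one = p_two / 2.0 if rho < 0 else 1.0 - p_two / 2.0
    reg = stats.linregress(np.log10(e2), np.atleast_1d(log_ratio))
    slope_p_one = reg.pvalue / 2.0 if reg.slope > 0 else 1.0 - reg.pvalue / 2.0
    return E2AssociationResult(
        spearman_rho=float(rho),
        spearman_p=float(p_one),
        slope=float(reg.slope),
        slope_p=float(slope_p_one),
        n=len(tam),
    )


def _arm_ratios(table: TrialTable, arm: str, readout: str = "ki67") -> np.ndarray:
    sub = table.arm(arm)
    sub = sub[sub[f"{readout}_pre"].notna() & sub[f"{readout}_post"].notna()]
    ratio, _ = paired_change_ratio(
        sub[f"{readout}_pre"].to_numpy(), sub[f"{readout}_post"].to_numpy()
    )
    return np.atleast_1d(ratio)


def run_trial_analysis(
    table: TrialTable,
    detection_limit: float = E2_DETECTION_LIMIT_PMOL_L,
    readout: str = "ki67",
) -> dict:
    """Full paired-response report over all arms; deterministic for a table.

    Every p-value is one of the labelled, uncorrected tests described in the
    module docstring.
    """
    report: dict = {"readout": readout, "multiple_testing": "uncorrected"}

    within = {}
    for arm in ARMS:
        sub = table.arm(arm)
        sub = sub[sub[f"{readout}_pre"].notna() & sub[f"{readout}_post"].notna()]
        if len(sub) == 0:
            continue
        res = wilcoxon_signed_rank(
            log_transform(sub[f"{readout}_pre"].to_numpy()),
            log_transform(sub[f"{readout}_post"].to_numpy()),
            alternative="less",
        )
        within[arm] = {**res.as_dict(), "scale": "log10(value + 1)"}
    report["within_arm_wilcoxon_post_lt_pre"] = within

    ratios = {arm: _arm_ratios(table, arm, readout) for arm in ARMS}
    if len(ratios["tamoxifen_pre"]) >= 3 and len(ratios["tamoxifen_post"]) >= 3:
        report["tamoxifen_pre_vs_post_mwu_on_ratios"] = mann_whitney(
            ratios["tamoxifen_pre"], ratios["tamoxifen_post"], alternative="greater"
        ).as_dict()
        resp = classify_responders(table, readout)
        resp_ids = set(resp.loc[resp["responder"], "patient_id"])
        resp_ratios = {}
        for arm in ("tamoxifen_pre", "tamoxifen_post"):
            sub = table.arm(arm)
            sub = sub[sub["patient_id"].isin(resp_ids)]
            r, _ = paired_change_ratio(
                sub[f"{readout}_pre"].to_numpy(), sub[f"{readout}_post"].to_numpy()
            )
            resp_ratios[arm] = np.atleast_1d(r)
        if all(len(v) >= 3 for v in resp_ratios.values()):
            report["tamoxifen_pre_vs_post_mwu_responders_only"] = mann_whitney(
                resp_ratios["tamoxifen_pre"],
                resp_ratios["tamoxifen_post"],
                alternative="greater",
            ).as_dict()

    post_groups = [ratios[a] for a in POSTMENOPAUSAL_ARMS]
    if all(len(g) >= 2 for g in post_groups):
        report["postmenopausal_arms_kruskal_wallis"] = kruskal_wallis(
            post_groups
        ).as_dict()

    report["effect_sizes"] = effect_size_summary(table, readout).as_dict()
    resp = classify_responders(table, readout)
    report["response_categories"] = (
        resp.groupby(["arm", "category"]).size().unstack(fill_value=0).to_dict(orient="index")
    )
    report["e2_association"] = e2_association(table, detection_limit, readout).as_dict()
    return report
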