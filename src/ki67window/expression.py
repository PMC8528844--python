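"""Expression-side proliferation readouts for the paired trial design.

The chain mirrors a standard two-colour-array workflow downstream of
normalisation: impute missing values (k-nearest-rows, k=10), optionally
median-centre per batch (a labelled, deliberately simple stand-in — not
ComBat; a pre-corrected matrix can be supplied instead), collapse multiple
probes per gene by the median, score per-sample proliferation signatures,
and test paired before/after differences per gene with an empirical-Bayes
moderated t-statistic.

The moderated t shrinks each gene's variance toward a prior fitted by
closed-form moment matching on the log sample variances: with ``s_g^2`` on
``d_g`` df per gene, the model ``s_g^2 | sigma_g^2 ~ sigma_g^2 chi^2_dg/dg``
and ``sigma_g^2 ~ s_0^2 d_0 / chi^2_d0`` implies

    Var[log s_g^2] = trigamma(d_g/2) + trigamma(d_0/2)
    E[log s_g^2]   = log s_0^2 + digamma(d_g/2) - log(d_g/2)
                                - digamma(d_0/2) + log(d_0/2)

so ``d_0`` comes from inverting the trigamma function and ``s_0^2`` from
the mean.  The posterior variance ``(d_0 s_0^2 + d_g s_g^2)/(d_0 + d_g)``
feeds a t-statistic on ``d_0 + d_g`` df.  No numerical identity with any
particular published implementation is claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "ModeratedTResult",
    "load_gene_set",
    "load_gene_sets",
    "knn_impute",
    "collapse_probes",
    "signature_score",
    "paired_differences",
    "fit_variance_prior",
    "moderated_t",
    "compare_arm_effects_mrna",
    "run_expression_analysis",
]

META_COLUMNS = ["patient_id", "time", "arm", "menopause", "batch"]


@dataclass
class ExpressionMatrix:
    """Probe x sample log-scale matrix with probe->gene map and sample metadata."""

    values: pd.DataFrame
    probe_to_gene: pd.Series
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing_meta = set(self.values.columns) - set(self.meta.index)
        if missing_meta:
            raise ValueError(f"metadata missing for samples: {sorted(missing_meta)}")
        unmapped = set(self.values.index) - set(self.probe_to_gene.index)
        if unmapped:
            raise ValueError(f"probe->gene map missing probes: {sorted(unmapped)[:5]}")
        missing_cols = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_cols:
            raise ValueError(f"metadata missing columns: {missing_cols}")

    def to_tsv(self, matrix_path, meta_path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", self.probe_to_gene[out.index])
        out.to_csv(matrix_path, sep="\t", index_label="probe")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, matrix_path, meta_path) -> "ExpressionMatrix":
        raw = pd.read_csv(matrix_path, sep="\t", index_col="probe")
        probe_to_gene = raw["gene"]
        values = raw.drop(columns="gene")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(values=values, probe_to_gene=probe_to_gene, meta=meta)


@dataclass
class GeneSet:
    """Named proliferation signature: member genes and optional +/-1 weights."""

    name: str
    genes: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.genes):
                raise ValueError(f"gene set {self.name!r}: weights/genes length mismatch")


def load_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a gene set from a one-gene-per-line file (optional weight column)."""
    path = Path(path)
    genes, weights = [], []
    has_weights = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        genes.append(parts[0])
        if len(parts) > 1:
            has_weights = True
            weights.append(float(parts[1]))
        else:
            weights.append(1.0)
    return GeneSet(
        name=name or path.stem,
        genes=genes,
        weights=np.array(weights) if has_weights else None,
    )


def load_gene_sets(directory) -> dict[str, GeneSet]:
    """Load every ``*.tsv`` gene-set file in a directory, keyed by set name."""
    sets = {}
    for path in sorted(Path(directory).glob("*.tsv")):
        gs = load_gene_set(path)
        sets[gs.name] = gs
    if not sets:
        raise FileNotFoundError(f"no gene-set files (*.tsv) under {directory}")
    return sets


def knn_impute(values: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing entries from the k nearest rows observed at that column.

    Row distance is the root-mean-square difference over columns observed in
    both rows (rows sharing no column are infinitely far).  For each hole,
    the k nearest candidate rows that are observed at that column are
    averaged; ties in distance break deterministically by row order.
    Observed entries are never altered.
    """
    x = values.to_numpy(dtype=float)
    n_rows, n_cols = x.shape
    if k < 1 or k > n_rows - 1:
        raise ValueError(f"k={k} must lie in [1, n_rows - 1]")
    mask = np.isnan(x)
    if not mask.any():
        return values.copy()
    fully_missing = np.where(mask.all(axis=1))[0]
    if len(fully_missing):
        names = [str(values.index[i]) for i in fully_missing]
        raise ValueError(f"rows with no observed values cannot be imputed: {names}")
    out = x.copy()
    rows_with_holes = np.where(mask.any(axis=1))[0]
    observed = ~mask
    for i in rows_with_holes:
        shared = observed & observed[i]  # (n_rows, n_cols)
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, x - x[i], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.nansum(diff**2, axis=1) / n_shared)
        dist[n_shared == 0] = np.inf
        dist[i] = np.inf
        order = np.lexsort((np.arange(n_rows), dist))
        for j in np.where(mask[i])[0]:
            donors = [r for r in order if observed[r, j] and np.isfinite(dist[r])]
            if not donors:
                raise ValueError(
                    f"no finite-distance donor rows for entry "
                    f"({values.index[i]}, {values.columns[j]})"
                )
            out[i, j] = x[donors[:k], j].mean()
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def collapse_probes(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene x sample matrix: per-gene median across that gene's probes.

    Even probe counts use the conventional mean-of-middle-two median;
    single-probe genes pass through unchanged.
    """
    genes = matrix.probe_to_gene[matrix.values.index]
    return matrix.values.groupby(genes.to_numpy()).median()


def signature_score(
    gene_matrix: pd.DataFrame, gene_set: GeneSet, standardize: bool = True
) -> pd.Series:
    """Per-sample signature score: weighted mean of member-gene values.

    With ``standardize`` the member genes are z-scored across the cohort
    first.  Missing members are dropped with a warning; below 50% coverage
    the warning flags the score as low-coverage; no members at all is an
    error.
    """
    present = [g for g in gene_set.genes if g in gene_matrix.index]
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in matrix")
    coverage = len(present) / len(gene_set.genes)
    if len(present) < len(gene_set.genes):
        level = "LOW-COVERAGE: " if coverage < 0.5 else ""
        warnings.warn(
            f"{level}gene set {gene_set.name!r}: {len(present)}/{len(gene_set.genes)} "
            "members present; missing members dropped",
            stacklevel=2,
        )
    sub = gene_matrix.loc[present]
    if gene_set.weights is not None:
        w = np.array(
            [gene_set.weights[gene_set.genes.index(g)] for g in present], dtype=float
        )
    else:
        w = np.ones(len(present))
    if standardize:
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
        sub = sub.sub(mu, axis=0).div(sd, axis=0)
    score = sub.mul(w, axis=0).sum(axis=0) / np.abs(w).sum()
    score.name = gene_set.name
    return score


def paired_differences(
    gene_matrix: pd.DataFrame, meta: pd.DataFrame, arm: str | None = None
) -> pd.DataFrame:
    """Per-patient (after - before) differences, genes x patients.

    Only patients with exactly one before and one after sample are kept.
    """
    m = meta
    if arm is not None:
        m = m[m["arm"] == arm]
    diffs = {}
    for patient, grp in m.groupby("patient_id"):
        before = grp.index[grp["time"] == "before"]
        after = grp.index[grp["time"] == "after"]
        if len(before) == 1 and len(after) == 1:
            diffs[patient] = gene_matrix[after[0]] - gene_matrix[before[0]]
    if not diffs:
        raise ValueError("no complete before/after pairs")
    return pd.DataFrame(diffs)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the standard recurrence)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, dg: int) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square variance prior (d0, s0^2)."""
    s2 = np.asarray(s2, dtype=float)
    usable = s2[s2 > 0]
    if len(usable) < 2:
        raise ValueError("need at least 2 genes with positive variance")
    z = np.log(usable)
    e_z, var_z = z.mean(), z.var(ddof=1)
    excess = var_z - special.polygamma(1, dg / 2.0)
    if excess <= 1e-10:
        d0 = np.inf
        log_s0 = e_z - special.polygamma(0, dg / 2.0) + np.log(dg / 2.0)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        log_s0 = (
            e_z
            - special.polygamma(0, dg / 2.0)
            + np.log(dg / 2.0)
            + special.polygamma(0, d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    return float(d0), float(np.exp(log_s0))


@dataclass
class ModeratedTResult:
    """Per-gene moderated paired t-test plus the fitted prior."""

    table: pd.DataFrame
    d0: float
    s0_squared: float
    n_pairs: int


def moderated_t(
    diffs: pd.DataFrame, d0_override: float | None = None
) -> ModeratedTResult:
    """Empirical-Bayes moderated paired t-test on (after - before) differences.

    ``d0_override=0`` disables shrinkage, reproducing the ordinary paired
    t-test exactly.  Genes with zero sample variance are flagged (p = NaN)
    when no prior mass is available.
    """
    x = diffs.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 3:
        raise ValueError("moderated t requires at least 3 complete pairs")
    dg = n - 1
    mean = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    if d0_override is not None:
        d0 = float(d0_override)
        # the scale is still fitted so only the shrinkage weight changes
        s0 = fit_variance_prior(s2, dg)[1] if d0 > 0 else float("nan")
    else:
        d0, s0 = fit_variance_prior(s2, dg)
    if d0 == 0.0:
        s2_post = s2.copy()
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0)
    else:
        s2_post = (d0 * s0 + dg * s2) / (d0 + dg)
    df = d0 + dg
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / n)
    t_df = df if np.isfinite(df) else 1e12
    p_two = 2.0 * stats.t.sf(np.abs(t), t_df)
    p_less = stats.t.cdf(t, t_df)  # one-sided: after < before
    flagged = (s2_post == 0.0) | ~np.isfinite(t)
    p_two = np.where(flagged, np.nan, p_two)
    p_less = np.where(flagged, np.nan, p_less)
    table = pd.DataFrame(
        {
            "log_fold_change": mean,
            "t": t,
            "df": df,
            "p_value": p_two,
            "p_one_sided_down": p_less,
            "s2_gene": s2,
            "s2_posterior": s2_post,
            "flagged_zero_variance": flagged,
        },
        index=diffs.index,
    )
    return ModeratedTResult(table=table, d0=float(d0), s0_squared=float(s0), n_pairs=n)


def compare_arm_effects_mrna(diffs_by_arm: dict[str, np.ndarray]) -> dict:
    """Between-arm comparison of per-patient paired differences for one gene.

    One-sided two-sample t-test of premenopausal vs postmenopausal tamoxifen
    (alternative: premenopausal differences greater, i.e. a smaller drop),
    plus a one-way ANOVA across the three postmenopausal arms.
    """
    report: dict = {}
    a = np.asarray(diffs_by_arm.get("tamoxifen_pre", ()), dtype=float)
    b = np.asarray(diffs_by_arm.get("tamoxifen_post", ()), dtype=float)
    if len(a) >= 3 and len(b) >= 3:
        res = stats.ttest_ind(a, b, alternative="greater")
        report["tamoxifen_pre_vs_post_t"] = {
            "statistic": float(res.statistic),
            "p_one_sided": float(res.pvalue),
            "n": [len(a), len(b)],
            "alternative": "premenopausal differences greater",
        }
    else:
        raise ValueError("need >= 3 paired differences per tamoxifen arm")
    post = [
        np.asarray(diffs_by_arm[arm], dtype=float)
        for arm in ("tamoxifen_post", "anastrozole", "fulvestrant")
        if arm in diffs_by_arm
    ]
    if len(post) == 3 and all(len(g) >= 3 for g in post):
        if all(
            len(g) == len(post[0]) and np.allclose(g, post[0]) for g in post
        ):
            report["postmenopausal_arms_anova"] = {
                "statistic": 0.0, "p_value": 1.0, "flag": "identical groups",
            }
        else:
            f = stats.f_oneway(*post)
            report["postmenopausal_arms_anova"] = {
                "statistic": float(f.statistic),
                "p_value": float(f.pvalue),
            }
    return report


def run_expression_analysis(
    matrix: ExpressionMatrix,
    gene_sets: dict[str, GeneSet],
    mki67_gene: str = "MKI67",
    k_impute: int = 10,
    batch_center: bool = False,
) -> dict:
    """Expression arm of the trial analysis; returns a JSON-able report.

    Imputes, optionally median-centres per batch (labelled as such; not
    ComBat), collapses probes, then reports the per-arm moderated t for the
    Ki67 gene, the between-arm comparison on its paired differences, and
    per-arm one-sided Wilcoxon signed-rank tests on every signature score.
    """
    from .trial_stats import kruskal_wallis, mann_whitney, wilcoxon_signed_rank

    values = knn_impute(matrix.values, k=k_impute)
    if batch_center:
        for b, cols in matrix.meta.groupby("batch").groups.items():
            cols = [c for c in cols if c in values.columns]
            values[cols] = values[cols].sub(values[cols].median(axis=1), axis=0)
    completed = ExpressionMatrix(
        values=values, probe_to_gene=matrix.probe_to_gene, meta=matrix.meta
    )
    gene_matrix = collapse_probes(completed)
    report: dict = {
        "batch_correction": "per-batch median centering (not ComBat)"
        if batch_center
        else "none (pre-corrected matrix assumed)",
    }

    arms = [a for a in ("tamoxifen_pre", "tamoxifen_post", "anastrozole", "fulvestrant")
            if (matrix.meta["arm"] == a).any()]
    mki67 = {}
    diffs_by_arm = {}
    for arm in arms:
        diffs = paired_differences(gene_matrix, matrix.meta, arm=arm)
        res = moderated_t(diffs)
        row = res.table.loc[mki67_gene]
        mki67[arm] = {
            "log_fold_change": float(row["log_fold_change"]),
            "moderated_t": float(row["t"]),
            "df": float(row["df"]),
            "p_one_sided_down": float(row["p_one_sided_down"]),
            "prior_d0": res.d0,
            "n_pairs": res.n_pairs,
        }
        diffs_by_arm[arm] = diffs.loc[mki67_gene].to_numpy()
    report["mki67_moderated_t"] = mki67
    report["mki67_between_arms"] = compare_arm_effects_mrna(diffs_by_arm)

    signature_report = {}
    for name, gs in gene_sets.items():
        score = signature_score(gene_matrix, gs)
        per_arm = {}
        deltas_by_arm = {}
        for arm in arms:
            sub = matrix.meta[matrix.meta["arm"] == arm]
            pairs = paired_differences(score.to_frame().T, sub)
            deltas = pairs.iloc[0].to_numpy()
            before = deltas * 0.0  # paired test of deltas against zero
            per_arm[arm] = wilcoxon_signed_rank(
                before, deltas, alternative="less"
            ).as_dict()
            deltas_by_arm[arm] = deltas
        entry = {"per_arm_wilcoxon_after_lt_before": per_arm}
        if (
            "tamoxifen_pre" in deltas_by_arm
            and "tamoxifen_post" in deltas_by_arm
            and min(len(deltas_by_arm["tamoxifen_pre"]), len(deltas_by_arm["tamoxifen_post"])) >= 3
        ):
            entry["tamoxifen_pre_vs_post_mwu"] = mann_whitney(
                deltas_by_arm["tamoxifen_pre"],
                deltas_by_arm["tamoxifen_post"],
                alternative="greater",
            ).as_dict()
        post = [deltas_by_arm[a] for a in ("tamoxifen_post", "anastrozole", "fulvestrant")
                if a in deltas_by_arm]
        if len(post) == 3 and all(len(g) >= 2 for g in post):
            entry["postmenopausal_arms_kruskal_wallis"] = kruskal_wallis(post).as_dict()
        signature_report[name] = entry
    report["signatures"] = signature_report
    return report
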