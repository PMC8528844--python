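"""Synthetic probe-level expression matrices tied to a simulated trial.

Each patient contributes a before and an after sample.  A latent
proliferation factor per sample drives every signature-set gene (with the
set's direction weights); the after-treatment factor drops by the patient's
log10 Ki67 ratio, so expression-based proliferation readouts co-vary with
the simulated IHC response.  Genes are represented by 1-3 probes, missing
values are injected at a configurable rate, and samples carry batch labels.

The shipped gene-set files are synthetic placeholders that mimic the shape
(name, size, direction weights) of published proliferation signatures;
real, licensed gene lists can be supplied by the user instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from ..expression import ExpressionMatrix, GeneSet, load_gene_set
from ..trial_stats import TrialTable, paired_change_ratio

__all__ = ["ExpressionSimSpec", "default_gene_sets", "generate_expression"]


def default_gene_sets() -> dict[str, GeneSet]:
    """The synthetic placeholder signature sets shipped with the package."""
    sets = {}
    root = resources.files("ki67window").joinpath("data/gene_sets")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".tsv"):
            with resources.as_file(entry) as path:
                gs = load_gene_set(path)
            sets[gs.name] = gs
    return sets


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Study conditions for the synthetic expression matrices."""

    n_background_genes: int = 600
    mki67_gene: str = "MKI67"
    #: SD of the per-patient baseline latent proliferation factor
    latent_sd: float = 0.7
    #: loading of signature genes on the latent factor
    loading: float = 1.0
    #: residual per-probe-per-sample noise SD
    noise_sd: float = 0.3
    #: SD of stable per-probe offsets within a gene
    probe_offset_sd: float = 0.1
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    background_sample_sd: float = 0.5
    missing_rate: float = 0.02
    n_batches: int = 2
    #: probabilities that a gene is covered by 1, 2 or 3 probes
    probe_multiplicity_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    #: optional closed gene universe; set members outside it are an error
    restrict_to_genes: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if not 0.0 <= self.missing_rate < 1.0:
            problems.append("missing_rate must lie in [0, 1)")
        if self.n_background_genes < 0:
            problems.append("n_background_genes must be non-negative")
        if abs(sum(self.probe_multiplicity_probs) - 1.0) > 1e-9:
            problems.append("probe_multiplicity_probs must sum to 1")
        if self.noise_sd < 0 or self.latent_sd < 0:
            problems.append("noise and latent SDs must be non-negative")
        if self.n_batches < 1:
            problems.append("n_batches must be >= 1")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("; ".join(problems))


def generate_expression(
    spec: ExpressionSimSpec,
    trial: TrialTable,
    gene_sets: dict[str, GeneSet] | None = None,
) -> ExpressionMatrix:
    """Simulate probe x sample expression for every patient of a trial.

    Deterministic given ``spec.seed``.  Signature-set genes load on the
    latent proliferation factor (respecting direction weights); background
    genes are noise around stable baselines.
    """
    spec.require_valid()
    if len(trial.table) == 0:
        raise ValueError("trial table is empty")
    if gene_sets is None:
        gene_sets = default_gene_sets()
    rng = np.random.default_rng(spec.seed)

    signature_genes: dict[str, float] = {spec.mki67_gene: 1.0}
    for gs in gene_sets.values():
        weights = gs.weights if gs.weights is not None else np.ones(len(gs.genes))
        for g, w in zip(gs.genes, weights):
            signature_genes.setdefault(g, float(w))
    if spec.restrict_to_genes is not None:
        known = set(spec.restrict_to_genes)
        unknown = sorted(set(signature_genes) - known)
        if unknown:
            raise ValueError(f"gene sets reference unknown genes: {unknown}")

    background = [f"BG{i:04d}" for i in range(spec.n_background_genes)]
    genes = list(signature_genes) + background

    patients = trial.table["patient_id"].tolist()
    pre = trial.resolved("ki67_pre").to_numpy()
    post = trial.resolved("ki67_post").to_numpy()
    _, log_ratio = paired_change_ratio(pre, post)
    log_ratio = np.atleast_1d(log_ratio)

    sample_ids, meta_rows = [], []
    factors = []
    f_before = rng.normal(0.0, spec.latent_sd, size=len(patients))
    for i, pid in enumerate(patients):
        arm = trial.table["arm"].iloc[i]
        meno = trial.table["menopause"].iloc[i]
        batch = f"batch{int(rng.integers(spec.n_batches)) + 1}"
        for time, f in (("before", f_before[i]), ("after", f_before[i] + log_ratio[i])):
            sample_ids.append(f"{pid}_{time}")
            meta_rows.append(
                {"patient_id": pid, "time": time, "arm": arm, "menopause": meno,
                 "batch": batch}
            )
            factors.append(f)
    factors = np.asarray(factors)
    n_samples = len(sample_ids)

    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(genes))
    multiplicity = rng.choice(
        [1, 2, 3], size=len(genes), p=spec.probe_multiplicity_probs
    )

    probe_ids, probe_genes, rows = [], [], []
    for gi, gene in enumerate(genes):
        if gene in signature_genes:
            w = signature_genes[gene]
            gene_expr = baselines[gi] + spec.loading * w * factors
        else:
            gene_expr = baselines[gi] + rng.normal(
                0.0, spec.background_sample_sd, size=n_samples
            )
        for p in range(multiplicity[gi]):
            offset = rng.normal(0.0, spec.probe_offset_sd)
            noise = (
                rng.normal(0.0, spec.noise_sd, size=n_samples)
                if spec.noise_sd > 0
                else 0.0
            )
            probe_ids.append(f"{gene}_p{p + 1}")
            probe_genes.append(gene)
            rows.append(gene_expr + offset + noise)

    values = pd.DataFrame(np.asarray(rows), index=probe_ids, columns=sample_ids)
    if spec.missing_rate > 0:
        holes = rng.random(values.shape) < spec.missing_rate
        # never blank out an entire row
        full = holes.all(axis=1)
        holes[full, 0] = False
        values = values.mask(holes)

    meta = pd.DataFrame(meta_rows, index=sample_ids)
    return ExpressionMatrix(
        values=values,
        probe_to_gene=pd.Series(probe_genes, index=probe_ids),
        meta=meta,
    )
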