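"""End-to-end orchestration: simulate -> score -> validate -> trial-stats -> expression.

A :class:`RunConfig` carries one named seed per stochastic stage plus
parameter overrides for every stage spec; it round-trips losslessly through
YAML.  ``run_end_to_end`` executes the five stages into a run directory and
writes a manifest with parameters and SHA-256 checksums of every artefact,
so identical configs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .concordance import PairedScores, icc, spearman
from .expression import run_expression_analysis
from .ihc.classifier import train_patch_classifier
from .ihc.patches import sample_training_patches
from .ihc.scoring import PipelineParams, detect_and_classify, score_roi
from .io import write_calls_csv, write_image
from .simulate.expression import ExpressionSimSpec, default_gene_sets, generate_expression
from .simulate.slides import SlideSpec, generate_slide
from .simulate.trial import TrialSimSpec, generate_trial_table
from .trial_stats import run_trial_analysis

__all__ = ["RunConfig", "validate_config", "run_end_to_end", "build_default_classifier"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "validate", "trial_stats", "expression")


@dataclass
class RunConfig:
    """Declarative description of one end-to-end run."""

    seeds: dict = field(
        default_factory=lambda: {
            "slides": 101,
            "classifier": 202,
            "trial": 303,
            "expression": 404,
        }
    )
    #: training panel for the patch classifier
    n_train_slides: int = 6
    patches_per_slide: int = 400
    split_fraction: float = 0.8
    #: evaluation panel scored against ground truth
    n_eval_slides: int = 8
    positivity_range: tuple[float, float] = (0.05, 0.60)
    slide: dict = field(default_factory=dict)
    trial: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    pipeline: dict = field(default_factory=dict)
    output_dir: str = "runs/default"
    verbosity: str = "INFO"

    def slide_spec(self, **overrides) -> SlideSpec:
        return SlideSpec(**{**self.slide, **overrides})

    def trial_spec(self) -> TrialSimSpec:
        return TrialSimSpec(**{**self.trial, "seed": self.seeds["trial"]})

    def expression_spec(self) -> ExpressionSimSpec:
        return ExpressionSimSpec(
            **{**self.expression, "seed": self.seeds["expression"]}
        )

    def pipeline_params(self) -> PipelineParams:
        return PipelineParams(**self.pipeline)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "positivity_range" in raw:
            raw["positivity_range"] = tuple(raw["positivity_range"])
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Static check of all stage invariants; returns violations (empty = ok)."""
    violations: list[str] = []
    for stage in ("slides", "classifier", "trial", "expression"):
        if stage not in config.seeds:
            violations.append(f"seeds: missing explicit seed for stage {stage!r}")
        elif not isinstance(config.seeds[stage], int):
            violations.append(f"seeds: seed for {stage!r} must be an integer")
    if not 0.0 < config.split_fraction < 1.0:
        violations.append("split_fraction: must lie strictly in (0, 1)")
    if config.n_train_slides < 2 or config.n_eval_slides < 2:
        violations.append("slide panels need at least 2 slides each")
    lo, hi = config.positivity_range
    if not 0.0 <= lo < hi <= 1.0:
        violations.append("positivity_range: must satisfy 0 <= low < high <= 1")
    try:
        violations += [f"slide.{v}" for v in config.slide_spec(seed=0).validate()]
    except TypeError as exc:
        violations.append(f"slide: {exc}")
    try:
        violations += [f"trial.{v}" for v in config.trial_spec().validate()]
    except (TypeError, KeyError) as exc:
        violations.append(f"trial: {exc}")
    try:
        violations += [f"expression.{v}" for v in config.expression_spec().validate()]
    except (TypeError, KeyError) as exc:
        violations.append(f"expression: {exc}")
    try:
        violations += [f"pipeline.{v}" for v in config.pipeline_params().validate()]
    except TypeError as exc:
        violations.append(f"pipeline: {exc}")
    return violations


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def build_default_classifier(config: RunConfig):
    """Train the default patch classifier on a fresh synthetic panel."""
    rng = np.random.default_rng(config.seeds["slides"])
    lo, hi = config.positivity_range
    panel = []
    for i in range(config.n_train_slides):
        spec = config.slide_spec(
            positive_fraction=float(rng.uniform(lo, hi)),
            seed=int(rng.integers(2**31 - 1)),
        )
        panel.append(generate_slide(spec))
    sample = sample_training_patches(
        panel,
        per_slide=config.patches_per_slide,
        split_fraction=config.split_fraction,
        seed=config.seeds["classifier"],
    )
    return train_patch_classifier(sample, seed=config.seeds["classifier"])


def run_end_to_end(config: RunConfig, output_dir=None) -> dict:
    """Execute all five stages; returns the manifest dictionary.

    Any stage failure is re-raised with the stage name attached.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "artifacts": {},
    }
    artifacts: dict[str, Path] = {}
    stage = "simulate"
    try:
        # --- simulate ------------------------------------------------------
        rng = np.random.default_rng(config.seeds["slides"] + 1)
        lo, hi = config.positivity_range
        eval_fractions = np.linspace(lo, hi, config.n_eval_slides)
        eval_panel = []
        for i, frac in enumerate(eval_fractions):
            spec = config.slide_spec(
                positive_fraction=float(frac), seed=int(rng.integers(2**31 - 1))
            )
            slide, gt = generate_slide(spec)
            img_path = outdir / f"slide_{i:02d}.tiff"
            gt_path = outdir / f"slide_{i:02d}_ground_truth.csv"
            write_image(slide, img_path)
            gt.to_csv(gt_path)
            artifacts[img_path.name] = img_path
            artifacts[gt_path.name] = gt_path
            eval_panel.append((slide, gt))
        trial = generate_trial_table(config.trial_spec())
        trial_path = outdir / "trial_table.tsv"
        trial.to_tsv(trial_path)
        artifacts[trial_path.name] = trial_path
        expr = generate_expression(config.expression_spec(), trial)
        expr_path = outdir / "expression_matrix.tsv"
        meta_path = outdir / "expression_metadata.tsv"
        expr.to_tsv(expr_path, meta_path)
        artifacts[expr_path.name] = expr_path
        artifacts[meta_path.name] = meta_path
        manifest["stages"].append("simulate")

        # --- score ---------------------------------------------------------
        stage = "score"
        classifier = build_default_classifier(config)
        params = config.pipeline_params()
        scores = []
        for i, (slide, gt) in enumerate(eval_panel):
            calls = detect_and_classify(slide.image, classifier, params)
            h, w = slide.shape
            score = score_roi(slide, (0, 0, h, w), classifier, params, calls=calls)
            logger.info(
                "slide %02d: %d nuclei counted, %d positive", i, score.n_total,
                score.n_positive,
            )
            calls_path = outdir / f"slide_{i:02d}_nuclei.csv"
            write_calls_csv(calls, calls_path)
            artifacts[calls_path.name] = calls_path
            scores.append(
                {
                    "slide": i,
                    "true_index": gt.ki67_index(),
                    **score.as_dict(),
                    "classifier_val_accuracy": classifier.val_accuracy,
                }
            )
        scores_path = outdir / "roi_scores.json"
        _write_json(scores, scores_path)
        artifacts[scores_path.name] = scores_path
        manifest["stages"].append("score")

        # --- validate ------------------------------------------------------
        stage = "validate"
        paired = PairedScores.from_arrays(
            [s["true_index"] for s in scores], [s["index"] for s in scores]
        )
        sp = spearman(paired)
        ic = icc(paired)
        validation = {
            "n_rois": paired.n,
            "spearman_rho": sp.rho,
            "spearman_p": sp.p_value,
            "icc2_1": ic.icc,
            "icc_ci": [ic.ci_low, ic.ci_high],
            "icc_p": ic.p_value,
            "classifier_val_accuracy": classifier.val_accuracy,
        }
        val_path = outdir / "validation.json"
        _write_json(validation, val_path)
        artifacts[val_path.name] = val_path
        manifest["stages"].append("validate")

        # --- trial stats ---------------------------------------------------
        stage = "trial_stats"
        trial_report = run_trial_analysis(trial)
        trial_report_path = outdir / "trial_analysis.json"
        _write_json(trial_report, trial_report_path)
        artifacts[trial_report_path.name] = trial_report_path
        manifest["stages"].append("trial_stats")

        # --- expression ----------------------------------------------------
        stage = "expression"
        expr_report = run_expression_analysis(expr, default_gene_sets())
        expr_report_path = outdir / "expression_analysis.json"
        _write_json(expr_report, expr_report_path)
        artifacts[expr_report_path.name] = expr_report_path
        manifest["stages"].append("expression")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["artifacts"] = {name: _sha256(p) for name, p in sorted(artifacts.items())}
    _write_json(manifest, outdir / "manifest.json")
    return manifest
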