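"""Simulate the study inputs: a trial table, expression data and one slide.

Writes the synthetic cohort under results/cohort/ and prints a short
summary of what was generated.
"""

from pathlib import Path

from ki67window.io import write_image
from ki67window.simulate.expression import ExpressionSimSpec, generate_expression
from ki67window.simulate.slides import SlideSpec, generate_slide
from ki67window.simulate.trial import TrialSimSpec, generate_trial_table

OUT = Path("results/cohort")
OUT.mkdir(parents=True, exist_ok=True)

trial = generate_trial_table(TrialSimSpec(seed=303))
trial.to_tsv(OUT / "trial_table.tsv")
counts = trial.table.groupby("arm").size()
print("trial table:", dict(counts), "->", OUT / "trial_table.tsv")

expr = generate_expression(ExpressionSimSpec(seed=404), trial)
expr.to_tsv(OUT / "expression_matrix.tsv", OUT / "expression_metadata.tsv")
print(
    f"expression: {expr.values.shape[0]} probes x {expr.values.shape[1]} samples, "
    f"{expr.values.isna().to_numpy().mean():.1%} missing"
)

slide, gt = generate_slide(SlideSpec(positive_fraction=0.3, seed=101))
write_image(slide, OUT / "example_slide.tiff")
gt.to_csv(OUT / "example_slide_ground_truth.csv")
print(
    f"example slide: {slide.shape[0]}x{slide.shape[1]} px, "
    f"{gt.n_tumor} tumour nuclei, ground-truth index {gt.ki67_index():.1f}%"
)
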