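"""Paired-response analysis of the simulated window trial.

Runs the full nonparametric report (within-arm Wilcoxon, between-arm
Mann-Whitney and Kruskal-Wallis, responder classification, effect sizes,
estradiol association) on the cohort written by 01_simulate_cohort.py.
"""

import json
from pathlib import Path

from ki67window.trial_stats import TrialTable, run_trial_analysis

OUT = Path("results")
table = TrialTable.from_tsv(OUT / "cohort" / "trial_table.tsv")
report = run_trial_analysis(table)
(OUT / "trial_analysis.json").write_text(
    json.dumps(report, indent=2, sort_keys=True, default=float)
)

for arm, res in report["within_arm_wilcoxon_post_lt_pre"].items():
    print(f"{arm}: Wilcoxon (post<pre, log scale) p = {res['p_value']:.2e} "
          f"(n = {res['n']})")
mwu = report["tamoxifen_pre_vs_post_mwu_on_ratios"]
print(f"tamoxifen pre- vs postmenopausal ratios: MWU one-sided p = "
      f"{mwu['p_value']:.3f}")
kw = report["postmenopausal_arms_kruskal_wallis"]
print(f"postmenopausal arms: Kruskal-Wallis p = {kw['p_value']:.3f}")
for arm, row in report["effect_sizes"].items():
    print(f"{arm}: mean decrease {row['mean_decrease_all']:.1f}% "
          f"(responders only {row['mean_decrease_responders']:.1f}%)")
e2 = report["e2_association"]
print(f"E2 gradient: Spearman rho {e2['spearman_rho']:.2f}, one-sided p = "
      f"{e2['spearman_p_one_sided']:.4f} (n = {e2['n']})")
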