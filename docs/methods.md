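# Methods

This note documents the models behind `ki67window`: what the generators
emulate, how the scoring chain works, which statistical conventions the
analysis uses, and where the genuinely open design choices were decided.

## 1. Synthetic slides

A slide is rendered in optical-density (OD) space with a linear
two-chromogen model: an RGB pixel is `I = I0 · 10^(−C·M)`, where the rows
of `M` are the standard Ruifrok–Johnston unit colour vectors for
hematoxylin and DAB (plus an orthogonal residual axis) and `C` holds
per-pixel stain concentrations. Tumour nuclei are soft elliptical blobs:
DAB-positive nuclei carry DAB plus a weak hematoxylin counterstain,
negative nuclei hematoxylin only; stromal nuclei are elongated,
hematoxylin-only and act as structured "noise" the scorer must reject.
Because the renderer and the scorer share one stain matrix, colour
deconvolution is an exactly well-posed inverse — deliberately so: it lets
the positivity rule be tested against construction rather than against a
second estimation problem.

Geometry defaults (desk scale): 480×480 px at 0.5 µm/px, 120 tumour + 30
stromal nuclei, nucleus radius 8 ± 1.2 px (4 µm), minimum centre
separation 24 px (12 µm). The separation matters: the probability map
lives on a 10 px grid, and nuclei closer than ~2 grid cells merge into
monotone probability ridges whose weaker peak is not a local maximum. At
0.5 µm/px a 1 mm² hotspot is 2000×2000 px; tests use smaller ROIs with
areas reported in mm² so the hotspot semantics carry over. The number of
DAB-positive tumour nuclei is the nearest integer (ties to even) of
`positive_fraction × n_tumor`, making the ground-truth index reproduce the
requested fraction up to that rounding. Positivity is assigned after
layout, so regenerating a slide with the same seed and a higher fraction
turns the positive set into a superset — the basis of the monotonicity
test. What the renderer does **not** model: tissue texture, scanner
artefacts, stain variability beyond Gaussian amplitude jitter, overlapping
nuclei, pyramidal/whole-slide formats. Passing tests therefore demonstrate
the pipeline's internal correctness and its behaviour under idealised
staining, not performance on real slides.

## 2. Synthetic trial tables

Per arm: paired sample sizes 29 (premenopausal tamoxifen), 14
(postmenopausal tamoxifen), 15 (anastrozole), 13 (fulvestrant).
Pre-treatment Ki67 is truncated-lognormal (median 11%, log-SD 0.8,
support [4, 80]); the truncation away from 0 exists because the
`(post+1)/(pre+1)` ratio is bounded below by `1/(pre+1)`, so a patient
with pre ≈ 0 cannot express a strong multiplicative decrease and the
[0, 100] clamp would otherwise bias the arm mean. Each patient draws a
ratio from a lognormal whose **arithmetic** mean is the arm parameter
(0.65 / 0.37 / 0.40 / 0.50; log-SD 0.4), then `post = ratio·(pre+1) − 1`
clamped to [0, 100]. The anastrozole and fulvestrant means are the
package's own choice — set near the postmenopausal tamoxifen arm so that
the three postmenopausal arms are similar but not identical, matching a
between-arm comparison that hovers near the significance boundary.

Estradiol: premenopausal pre-treatment E2 is lognormal with median
300 pmol/L (log-SD 0.7), postmenopausal median 15 pmol/L (log-SD 0.6), so
≈96% of postmenopausal pre-treatment values fall below the 44 pmol/L assay
detection limit. Censored values are stored as (value = limit,
censored = true), never as missing. Post-treatment E2 multiplies the
pre-treatment value by a lognormal factor (log-SD 0.5), giving both rises
and falls. The inverse E2–response coupling adds
`slope · (log10 E2_post − mean)` to each uncensored patient's log-ratio
(default slope 0.4; 0.8 is used as the "strong coupling" condition in the
power study); the multiplicative factor is renormalised to unit sample
mean within the arm so the coupling redistributes response across patients
without moving the arm mean.

## 3. The scoring chain

* **Patch grid.** 80×80 px window, 10 px stride, 0-based row-major
  top-left anchors; map dimensions `floor((dim − 80)/10) + 1`. One grid
  implementation serves training-tile sampling and inference. For
  detection the image is reflect-padded by half a window so tile centres
  cover the borders; the padded grid's centres coincide with multiples of
  the stride in original coordinates.
* **Classifier.** The nucleus-at-centre classifier is pluggable; the
  shipped backend is a scikit-learn logistic regression (standardised
  features, C = 1) on 12 windowed moments — small (20 px) and large
  (40 px) centre-anchored means plus the small-window SD of four per-pixel
  channels: hematoxylin OD, DAB OD, brightness, Sobel gradient magnitude.
  A per-patch path and a whole-image separable-filter path produce
  identical features (tested to 1e-10); the map path makes probability
  maps cheap. Training tiles are labelled positive when a tumour-nucleus
  centre lies within 7.5 px of the tile centre — just above the 7.07 px
  worst-case distance from a nucleus to its nearest tile centre at stride
  10, so every nucleus has at least one positive anchor. Stroma is
  labelled background. A convolutional backend can be registered by
  callers; the feature model is already near ceiling on the synthetic
  renderer, so none is shipped.
* **Nucleus map and contours.** The probability map is smoothed with a
  Gaussian of σ = nucleus_radius/(2·stride) grid units (reflect boundary;
  configurable). Nuclei are local maxima above 0.3 probability,
  non-maximum-suppressed at 14 px. Each peak's contour is a radial
  half-peak level set: along 16 rays the radius where the map falls below
  50% of the peak, averaged, clipped to 14 px, rendered as a 24-gon.
  Contours with fewer than 3 interior pixels are flagged invalid and
  excluded from counting.
* **Positivity.** Inside the contour, mean DAB OD > 0.15 **and** mean
  brightness < 230 (of 255) ⇒ positive. The brightness test rejects
  unstained bright debris. Both thresholds were calibrated once on a
  held-out synthetic calibration slide and frozen; on the default renderer
  the two classes separate by an order of magnitude in DAB OD (negative
  nuclei ≤ 0.04, positive ≥ 0.2).
* **ROI score and hotspot.** Only calls whose centres lie in the half-open
  ROI rectangle are counted; an ROI with zero detected nuclei is flagged
  undefined rather than scored 0. The hotspot finder slides a fixed-area
  square at a coarse stride (side/8) and keeps the highest-index ROI with
  at least `min_cells` nuclei (default 1000, matching the recommended
  minimum for a 1 mm² hotspot; desk-scale tests lower it), ties broken by
  more nuclei then top-left position.

## 4. Trial statistics

All paired quantities use the `+1` convention uniformly:
`ratio = (post+1)/(pre+1)`, `decrease% = 100·(1 − ratio)`,
`log10(Ki67+1)` for log-scale values, so pre = 0 stays defined. Range-
valued Ki67 readings resolve to the highest value. "Responder" means a
strict decrease; equality is its own category, distinct from increase.

* Within-arm change: one-sided Wilcoxon signed-rank (post < pre) computed
  on `log10(Ki67+1)` values. The log scale is not cosmetic: the signed-rank
  test assumes symmetric null differences, which a multiplicative
  (lognormal-ratio) effect model delivers on the log scale but not on the
  raw scale (raw-scale differences `(pre+1)(e^Z − 1)` are right-skewed,
  measured as 0.027 type-I at nominal 0.05 vs 0.053 on the log scale).
  Zero differences are dropped (classic Wilcoxon, recorded in the report).
  For n ≤ 12 the null is the exact 2^n sign-flip enumeration on
  tie-averaged ranks; above that, the tie-corrected normal approximation
  without continuity correction (the correction measured conservative at
  n = 14–29).
* Between the tamoxifen arms: one-sided Mann–Whitney U on the ratios
  (premenopausal stochastically greater = smaller effect), exact
  exhaustive permutation for nA+nB ≤ 12, tie-corrected normal
  approximation otherwise; also run on responders only.
* Across postmenopausal arms: two-sided tie-corrected Kruskal–Wallis.
* E2 association: restricted to tamoxifen-treated patients with
  uncensored post-treatment E2 above 44 pmol/L; fewer than 5 usable
  patients flags the result insufficient. The method is not pinned down by
  the emulated protocol, so two readouts are reported and neither is
  claimed to be "the" original: primary, a one-sided Spearman test of
  negative association between E2 and decrease magnitude; secondary, the
  least-squares slope of log10 ratio on log10 E2 with a one-sided p.
* No multiple-testing correction anywhere; every p in the report is
  labelled with its sidedness and "uncorrected".

The no-effect calibration conditions are defined a priori as: every arm's
mean **log**-ratio zero (arithmetic mean ratio `exp(σ²/2)`), coupling off,
pre-treatment Ki67 truncated to [5, 40] so the [0, 100] clamp cannot break
pre/post exchangeability. Under these conditions the measured rejection
rates at α = 0.05 over 2000 replicates sit near nominal for all three
tests (the acceptance band is [0.03, 0.07]).

## 5. Expression readouts

* **Imputation**: each missing entry is the mean, at that column, of the
  k = 10 nearest rows among those observed there; row distance is the
  root-mean-square difference over columns observed in both rows (RMS
  rather than raw Euclidean so distances are comparable across different
  overlap sizes), ties broken by row order. Observed entries are never
  altered; fully missing rows are an error.
* **Batch handling**: the pipeline accepts a pre-corrected matrix, or
  applies optional per-batch median centring clearly labelled as such —
  a deliberately simple stand-in, not an empirical-Bayes batch correction.
* **Probe collapse**: per-gene median across probes (even counts: mean of
  the middle two).
* **Signature scores**: the published per-sample scoring formula behind
  each signature is not restated by the emulated protocol, so the package
  uses a documented convention — the weighted mean of cohort-z-scored
  member genes, honouring ±1 direction weights where the set defines them.
  Gene sets ship as editable one-gene-per-line files; the shipped lists
  are synthetic placeholders with the published sets' shapes (sizes,
  GENE70's mixed signs), and users supply real lists for real data.
* **Moderated t**: per-gene paired (after − before) differences; gene
  variance s²_g on d_g = n−1 df; prior (d₀, s₀²) by closed-form moment
  matching of E[log s²] and Var[log s²] (trigamma inversion by Newton);
  posterior variance (d₀s₀² + d_g s²_g)/(d₀+d_g); t on d₀+d_g df. Setting
  d₀ = 0 reproduces the ordinary paired t exactly (tested to machine
  precision), and the implementation agrees with an independent
  linear-model empirical-Bayes reference to ~6 significant digits on a
  frozen fixture. Var[log s²] at or below trigamma(d_g/2) ⇒ d₀ = ∞ and
  full shrinkage to s₀². Zero-variance genes with d₀ = 0 are flagged
  rather than scored.

## 6. Evaluation study sizes

The evaluation module fixes the problem sizes the package's own headline
study uses: a 6-slide training panel (500 tiles each, 80/20 split), a
20-ROI concordance panel spanning 5–60% positivity, 500 simulated trials
for effect-size recovery, 2000 for type-I calibration, 200 for E2 power
and 2000 for E2 size, and 5000 genes × 14 pairs for moderated-t null
uniformity. These sizes make the whole study reproducible in about a
minute on one CPU while keeping Monte-Carlo errors well inside the
decision bands.

## 7. Known limitations

* The renderer's idealised staining makes the scoring problem easier than
  real IHC; concordance numbers near 1.0 on synthetic panels say nothing
  quantitative about real slides.
* The classifier contract is probability-calibrated only implicitly
  (logistic regression); a CNN backend would need its own calibration
  before the 0.3 detection threshold transfers.
* Effect-size recovery carries a residual bias of ~0.1–0.3 percentage
  points from the [0, 100] clamp at extreme draws; this is inside the
  recovery band but would matter for much larger simulation studies.
* The generator's ratio dispersion (log-SD 0.4) reproduces the all-patient
  mean decreases by construction, but it produces few Ki67 *increases*, so
  responders-only effect sizes sit close to the all-patient ones (~63% /
  ~42% at the defaults). A real cohort's responders-only figures can sit
  far above the all-patient mean only when a substantial fraction of
  patients increase; emulating that would need a much wider (or mixture)
  ratio distribution than the single lognormal used here.
* The E2 association at trial scale (n ≈ 29) with the default moderate
  coupling is underpowered, as the worked example shows; the power study
  uses the strong-coupling condition.
* Signature scoring and the E2-association method are documented
  conventions, not claimed reproductions of any specific published
  implementation.
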