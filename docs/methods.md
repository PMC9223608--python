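# Methods

This note documents the models, estimators and defaults implemented in
`pdgbo`, the assumptions behind the synthetic-data generator, and the
choices made where the underlying experimental platform leaves the
computation underdetermined.

## Screen scoring

**Normalization.** Each well's fluorescence-area readout is divided by the
*median* of the vehicle (DMSO) wells of the same plate, so the vehicle
median maps to exactly 1.0. The median (rather than mean) resists single
outlier vehicle wells. Normalization is strictly per-plate because plate-
level multiplicative effects (seeding density, staining, exposure) are the
dominant nuisance in pillar-plate screens. Viabilities are never clipped;
values above 1.2 are flagged (`high_viability`) since modest growth
stimulation is a real phenomenon worth seeing.

**AUC ratio.** The dose–response curve is the mean normalized viability per
concentration, concentrations ascending. The summary statistic is the
trapezoidal integral over log10 concentration divided by the integral of
the constant curve 1.0 on the same grid. On a geometric dilution series the
grid is uniform in log space, so a flat curve at viability 1 scores exactly
1.0, complete kill scores 0.0, and the statistic is invariant to the unit
of concentration (only log-spacing enters). Lower is a stronger effect.

**Panel z-scores and hit calls.** For one tumor sample, the AUC ratios of
all screened drugs except the positive control form the reference panel;
each drug's z is its AUC ratio standardized by the panel mean and sample
standard deviation (n−1). `z < −1` calls a strong candidate and
`−1 ≤ z < −0.5` a predicted responder, with strict inequalities at both
boundaries. The cross-drug (within-sample) reference is used because it
requires no external calibration data; a historical per-drug reference
distribution, if available, can be substituted by computing z externally
and reusing `call_hits`. A zero-variance panel (all drugs identical)
returns all-zero z with a warning rather than failing.

**QC.** A screen passes when every plate's vehicle coefficient of variation
is ≤ 0.2 and the bortezomib-like positive control retains ≤ 0.5 viability
at the top dose. Failing screens are flagged (`vehicle_unstable`,
`positive_control_inactive`) but still fully scored — QC gates
interpretation, not computation.

**4PL fitting.** `fit_4pl` is a validation aid (the screen statistic is the
AUC ratio, which needs no curve model). It is a bounded least-squares fit
(top ∈ [0.5, 1.5], bottom ∈ [0, 1], IC50 within 100× of the tested range,
hill ∈ (0, 10]) with three starts spread geometrically across the tested
concentrations. Non-convergence returns a flagged result; a curve with
< 0.05 dynamic range or an IC50 standard error above 10× the estimate is
flagged unidentifiable.

## Imaging

All analysis is 2-D on maximum intensity projections (MIPs); volumetric
reconstruction is out of scope. Background thresholds are robust
(median + k·MAD of the image) because the organoid can occupy a large
fraction of the frame and would corrupt a mean/SD estimate.

* **Vital area S** (calcein MIP): threshold at median + 3·MAD, components
  under 5 px removed. Constant images return S = 0 with a warning. The
  statistic is a pixel count, so it is invariant to intensity scaling above
  threshold and to constant offsets.
* **Organoid footprint**: permissive threshold (median + 0.5·MAD), holes
  filled, largest connected component. The viability index is the fraction
  of footprint pixels that are vital; counting vital pixels inside the
  footprint keeps the index in [0, 1]. The footprint (not the full frame)
  is the denominator so organoids of different sizes are comparable.
* **Nuclei**: Gaussian smoothing (σ = 2 px), Otsu threshold, hole filling,
  distance-transform watershed with 5 px minimum marker separation to split
  touching nuclei.
* **Tumor-microtube network**: detection and delineation are deliberately
  separate. A multiscale Sato ridge (tubeness) filter at scales 1–4 px
  marks where filaments run while suppressing blob-like structures; its
  median + 3·MAD threshold gives a detection mask. Because the ridge
  response spreads over roughly the filter scale, the reported footprint is
  refined by an Otsu intensity threshold restricted to the dilated detected
  region. On filament phantoms this recovers the planted footprint to a few
  percent, where thresholding the raw ridge response alone overestimates
  the width about threefold.
* **Network density index**: nestin area / nuclear area; an error is raised
  when no nuclei are present. When several organoids share a well, vital
  areas are additionally reported per connected component.

The commercial deep-learning segmenter used by such platforms is
intentionally replaced by these classical operators: they are deterministic,
parameter-transparent, and need no trained weights. All parameters are
exposed in the pipeline config.

## Calcium transients

Raw per-cell traces (frame interval 1.52 s, 10-minute default window) are
converted to ΔF/F0 with F0 the 10th percentile of the trace — robust even
when transients occupy much of the recording — then smoothed with a
discrete Gaussian (σ = 2 frames, reflective boundaries).

**Peak detection.** Local maxima with prominence at least
max(0.1, 4·σ̂) and ≥ 3 frames separation. σ̂ estimates the noise sd of the
*smoothed* trace from the MAD of its first difference; the first difference
is insensitive to transients and baseline drift, but smoothing leaves
neighbouring samples correlated (lag-1 autocorrelation
ρ₁ = exp(−1/(4σ²))), shrinking differences by √(2(1−ρ₁)) — the estimator
divides that factor back out. Without this correction the adaptive term is
an order of magnitude too small and the fixed floor (0.1 ΔF/F0, ~2.7 noise
sd at the default settings) admits a false peak every few dozen frames; at
a transient SNR of 5 the corrected rule achieves ~0.95 recall and ~0.97
precision over 50 seeded simulations.

**Classification and synchrony.** Cells with no detected peaks are
non-participating; otherwise event frequency (peaks per minute) is binned
at 0.5 and 1.5 events/min. Pairwise synchrony is the number of greedily
matched peak pairs within ±2 frames divided by the larger train length —
1 for identical trains, 0 for disjoint or empty trains. The synchrony
metric is this package's construction (the platform literature describes
network synchrony only qualitatively); it is symmetric, bounded in [0, 1],
and in simulations separates network-connected from unconnected cells in
essentially every run.

## Pathway enrichment and drug correlation

**ssGSEA.** For one sample, genes are ranked by expression (average ranks
on ties; walk order is by descending expression with gene-name tie-break so
the score is reproducible). With normalized ranks nr ∈ (0, 1] and weight
nr^α (α = 0.25 default), the enrichment score is the sum over the walk of
the difference between the weighted in-set cumulative distribution and the
unweighted out-of-set cumulative distribution. The implementation is
vectorized; an independent brute-force loop implementation (in the test
suite and acceptance script) agrees to 1e-12 on every admissible subset of
a 5-gene profile. Note that the classic sign antisymmetry between a top-k
and a bottom-k set holds only for the unweighted walk (α = 0); with α > 0
the weighted in-set CDF breaks the mirror symmetry.

**Downstream panel.** Enrichment scores are standardized per pathway across
samples (n−1; constant rows zeroed and flagged). Pathway–drug association
is the Pearson correlation across shared samples, with n recorded and
n < 5 flagged low-n (a four-patient cohort is the realistic regime). The
pathway rows of the correlation matrix are clustered hierarchically
(average linkage, cut at k = 3) and labelled C1/C2/C3 by mean correlation:
most negative, most positive, remainder. The default row distance is
Euclidean, not 1 − Pearson: the clusters of interest are defined by the
*level* of the correlations (uniformly negative vs uniformly positive vs
near zero), and a correlation distance would center each row, discarding
precisely that signal — with it, planted blocks were recovered at only 65%
label agreement versus 100% with Euclidean distance. Per-drug target-
pathway regression is ordinary least squares with the two-sided t-test
p-value (n−2 df); p-values are reported raw, with no multiple-testing
correction, matching how such exploratory panels are read. The drug
response score fed to correlation is the negated AUC ratio by default
(higher = more response, so "response negatively correlated with
enrichment" keeps its usual sign); raw AUC is a config switch.

## Synthetic data generator

The generator emulates the screening platform's statistical structure, not
its biology:

* **Screen**: 41 drugs (plus bortezomib) in duplicate fourfold seven-point
  dilution from 30 µM, laid out on as many 384-well plates as needed (574
  drug wells split across two), 8 vehicle wells per plate. Latent curves
  are 4PL; readouts are baseline × v(c) × lognormal noise (σ = 0.05
  default) with a lognormal per-plate baseline factor (σ = 0.02). The 4PL
  family is an implementation choice — it is the standard pharmacology
  family and has an analytic midpoint for tests. Multiplicative lognormal
  noise reflects positive, heteroscedastic fluorescence-area readouts.
* **Images**: cells cluster inside a central organoid region of a
  512×512×5 stack (the full 2560×2160 well image is available by config but
  unnecessary for testing); nuclei are anti-aliased disks (radius 6–9 px),
  the network is 3 px filaments along a nearest-neighbour adjacency plus
  soma rings, and the calcein channel carries a faint organoid-body glow
  plus live-cell disks whose radius scales with √viability (area ∝
  viability — dying cells round up and lose dye-retaining cytoplasm) while
  cells at ≤ 0.2 viability are dark. Ground-truth masks are computed
  analytically from the geometry, so segmentation accuracy is measured
  against exact planted areas.
* **Calcium**: event times are homogeneous Poisson per network component
  (1/min default, thinned to ≥ 15 s separation), shared by connected cells
  with 1-frame Gaussian jitter; traces are baseline × (1 + Σ transients)
  with instant rise, 8 s exponential decay, amplitude 0.8 ΔF/F0 and
  Gaussian read noise. The 8 s decay keeps the sampled peak height stable
  across event phases at the 1.52 s frame interval.
* **Expression**: a latent per-sample sensitivity factor u drives every
  drug's response score; positive-block pathways shift member genes by +u,
  negative-block by −u, and mixed-block by an orthogonal factor v (all with
  30% pathway-specific noise), on top of i.i.d. Gaussian log-expression.
  This plants exactly the three-cluster pathway–response structure the
  analysis is meant to recover.

All randomness flows from explicit integer seeds; per-stage sub-seeds in
the pipeline derive deterministically from the run seed, so every stage can
be deleted and regenerated bit-identically.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: spatial plate effects beyond a scalar
per-plate factor, edge evaporation, optical vignetting and depth
attenuation, segmentation-confounding debris, photobleaching and motion in
calcium movies, gene–gene correlation structure beyond the planted blocks,
and any pharmacology linking the imaging, calcium and expression modalities
to the screen beyond the planted couplings.

## Problem sizes and numerics

Default verification sizes: 100 seeded screens for hit recovery and IC50
recovery, 20 image phantoms at 512×512, 50 traces (10 min at SNR 5) for
peak recovery plus 60 simulations for synchrony, 20 expression cohorts of
20 samples for cluster recovery. These sizes give stable rates (the same
rates reproduce across unrelated master seeds) while keeping the whole
verification run under a minute.

Degenerate inputs are handled explicitly rather than by exception where a
value is still meaningful: constant images (S = 0 with warning), zero-
variance z panels (all zero with warning), constant enrichment rows
(zeroed, flagged), empty peak trains (synchrony 0, class non-participating).
Errors are reserved for inputs with no defensible answer: no vehicle wells,
non-positive baselines, empty gene-set overlap, fewer than three samples or
pathways.

## Known limitations

* The z reference is the within-sample drug panel; with one potent drug the
  panel sd inflates and other drugs' z-scores compress toward zero. This is
  inherent to cross-drug standardization and is why the hit threshold is a
  robust −1 rather than a p-value.
* The viability index depends on the footprint detection; on dim or
  fragmented organoids the largest-component heuristic may truncate the
  denominator.
* ssGSEA scores are not normalized across gene-set sizes; comparisons are
  within a pathway across samples (the inter-sample z), never between
  pathways of different sizes.
* With four real samples (the realistic cohort), pathway–drug correlations
  carry n = 4 and are flagged low-n; they are hypothesis-generating, not
  confirmatory.
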