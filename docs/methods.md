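# Methods

This note documents the models, heuristics and numerical choices behind
`sputumflow`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the procedure was genuinely open.

## Scales and transforms

Raw instrument values live on an 18-bit scale (full scale 262,144).
Scatter and Time are kept linear throughout. Fluorescence is compensated
and displayed on the logicle scale, the inverse of the biexponential
B(y) = a·e^{by} − c·e^{−dy} − f with parameters solved from
(T, M, W, A). Defaults are T = 262144, M = 4.5 decades, W = 0.5, A = 0 —
a common cytometry convention; they are configurable per channel. The
forward transform is computed by vectorized bisection (90 iterations,
well below float64 resolution); the round-trip relative error is
< 10⁻⁶ over [−1000, T] by test. The top of scale maps to exactly M
decades and logicle(0) = W.

Spillover is estimated de novo from single-stain controls: each control
is split into positive/negative populations by a two-component 1-D
Gaussian mixture (robust to outliers, standard practice); entry (i, j) is
the background-subtracted median signal in detector j of detector-i
positive events, normalized to a unit diagonal, clipped to [0, 0.999].
A control is *uninformative* — a fatal configuration error — when the
mixture components are closer than 2 pooled SDs, the positive population
has under 10 events, or the positive median fails to clear both 5× the
baseline MAD-spread and 0.2% of full scale. Negative compensated values
are retained; the logicle scale is designed for them.

## Flow-rate QC

Events are binned by acquisition time into `bin_count` (default 100)
equal-width bins; a bin is anomalous when its event count deviates from
the median count by more than `k` (default 5) median absolute deviations
(MAD floor of 1 guards the degenerate all-equal case). Detection is on
event rate only; per-channel drift detection was considered and left out
of scope. Equal-width binning over the span makes the mask invariant to
affine rescaling of the Time channel; re-running with the same bin edges
on a cleaned subset removes no further events (flagged empty bins stay
empty). If every bin is flagged the sample is unusable.

## Gating cascade

* **Bead anchor.** A Gaussian mixture (BIC over 1–3 components) on
  (FSC-A, SSC-A) of the bead tube finds the dominant cluster; the sample
  FSC-A minimum is that cluster's mean minus the 99% chi-square contour
  radius times its SD. Bead QC fails when no component both holds ≥ 20%
  of events and is compact (geometric-mean SD below 8% of the observed
  range, or 2% of full scale for noise-free tubes).
* **Size gate.** fsc_min ≤ FSC-A ≤ 2.5×10⁵ and SSC-A ≤ 2.5×10⁵, all
  thresholds closed on the kept side (a documented convention; the
  boundary event is kept).
* **Corner artifacts.** A mixture component with its FSC-H centroid above
  75% of full scale and its SSC-H centroid below the 5th percentile (or
  0.5% of full scale, whichever is larger) is a detached artifact
  population and is removed; absent such a component the mask is
  untouched. The absolute anchors keep the degenerate corner-only case
  detectable.
* **Core viable gate (temporary).** A BIC-selected mixture on
  (FSC-H, SSC-H) of non-debris events; the component with the lowest
  SSC-H centroid (small in area and height — mostly live cells) is kept
  inside its 0.90 Mahalanobis contour, widened to 0.99 when the gate
  captures under 10% of events (`core_quantile_fallback` logged).
* **Viability tail gate.** Kernel density (Silverman bandwidth — smooth
  and parameter-free, adequate for a tail criterion) of logicle FVS510 on
  the core viable singlets; the threshold is the smallest value above the
  dominant mode where density falls to ≤ 10% of the mode density. For a
  Gaussian signal this lands at m + s·√(2 ln 10) ≈ m + 2.146 s; the KDE
  bandwidth inflates this by under 0.05 logicle units at the event counts
  used. Raising the tolerance moves the threshold toward the mode
  (tolerance 1 returns the mode exactly).
* **Singlets polygon.** Ordinary least squares of the configured channel
  pair (default FSC-A vs FSC-W; FSC-A vs FSC-H available) on viable
  events, with a band at the median ± normal-quantile × 1.4826·MAD of the
  residuals (99% band by default). MAD-based half-widths mean a few
  percent of doublet outliers cannot stretch the band, while a grossly
  skewed fit still trips the malformation check. The top-right corner is
  forced to (2.5×10⁵, 2.5×10⁵) to keep the upper diagonal. A malformed
  polygon (lower-left corner below zero, or top-left above bottom-right)
  triggers the repair: refit on events with SSC-A ≤ 5×10⁴ and apply to
  the full viable population (`ssc_temp_gate` logged); a second
  malformation is fatal.
* **Viability refinement.** When the tail threshold exceeds the natural
  cutoff 2.5 and more than 10% of singlets carry FVS510 between 2.5 and
  the threshold, and either a two-component mixture confirms a distinct
  upper component or under 5% of the singlet signal lies below the
  cutoff (a wholly dying sample), the threshold is reset to 2.5 and the
  singlets polygon refit (`viability_reset` logged).

All mixture fits are seeded; a gating run is bit-reproducible given its
input and seed, and each applied heuristic is recorded in the result.
The viability threshold is computed per tube (whether it should be shared
across a sample's tubes is an open choice; per-tube is the more
conservative default).

## Features

Density features divide logicle fluorescence by log₁₀ of the *raw*
scatter area (the axes are log-transformed scatter, not logicle).
Region boundaries follow the "< 0.25, 0.25–0.6, > 0.6" reading: R2 is closed
([0.25, 0.6]), R1/R3 open; grid windows (1.5, 2.5, 3.0) are closed on the
lower edge. Per-10K counts are integers apportioned by largest remainder
(deterministic index-order tie-break), so regions and grid cells each sum
to exactly 10,000 for any non-empty input and are invariant to
duplicating every event. TCPP and FVS510 density features come from the
blood tube by default (both assay tubes carry those stains; the choice is
config-switchable and logged). The epithelial EpCAM × Pan-CK grid is
computed and reported but feeds no model term. Lineage "mid" for the
CD206-low sector is the [2.5, 3) window, config-exposed.

Eligibility requires ≥ 10,000 viable singlets and ≥ 10 events in the
lung-macrophage area (CD206 mid+high × lineage low+low-mid, raw count);
ineligible samples receive no model call anywhere in the pipeline.

## Classifier

Maximum-likelihood logistic regression on unnormalized predictors
(coefficients stay interpretable in raw units). For optimizer stability
the design is standardized internally and the estimates and covariance
mapped back exactly — the ML solution is identical. Wald statistics come
from the transformed covariance. True separation falls back to a
penalized (ridge) fit, flagged, with no Wald statistics. Refits on the
same data are bit-identical. Rows with missing labels (status-unknown
samples) are accepted in the cohort table but excluded from the
likelihood.

Stepwise selection repeats forward/backward steps (enter p < 0.05,
remove p ≥ 0.05 — Wald-based, matching the retained-predictor criterion;
an AIC mode of the same loop would be a drop-in) over seeded random
training splits of 100 samples with 20 cancers, preserving the 20%
training ratio, and reports per-variable selection frequencies.
Interactions obey the hierarchy principle both entering and leaving.

The ROC cutoff steps through candidate values — midpoints between
consecutive distinct probabilities — and picks the Youden-J maximizer;
midpoints honour the strict "cancer iff p > cutoff" rule (the boundary
value is non-cancer). The full grid is returned so any externally chosen
cutoff (0.28-style) can be audited. An ablation harness refits the model
with each predictor group removed (a dropped main effect takes its
interaction with it) and counts misclassifications.

## Diagnostics

Wilson score intervals for sensitivity, specificity and accuracy;
trapezoid AUC with a class-stratified percentile bootstrap (default 2000
replicates, seeded; the replicate count is a package choice). Prevalence-
adjusted PPV/NPV use the logit-transformed (Mercaldo-style) intervals
with a 0.5 continuity correction for zero cells. PDLR is flagged
infinite at specificity 1. Rates are kept at full precision internally
and rounded to two decimals for display.

## Synthetic data

The generator emulates, per sample: a bead tube (dominant Gaussian
cluster at FSC-A 3×10⁴ ± 2×10³ plus 10% uniform noise), unstained and
isotype controls, one single-stain control per detector, and blood and
epithelial tubes of 50,000 events by default (comfortably above the
10,000 viable-singlet bar; tests use 20,000–30,000 to keep desk-scale
runtimes). Populations: debris (10%), dead cells (12%, FVS510 ≈ 3.6),
and live cells split into bulk leukocytes, lung macrophages (6% of
live), and three feature-bearing subsets whose fractions are the class
targets divided by 10⁴ — TCPP-bright events (generated at a target
density ratio of 0.75 against the event's own SSC-A, so they land in R3
deterministically), an FVS-intermediate small-cell population (R2), and
CD206-low/lineage-mid leukocytes. Scatter is lognormal; fluorescence is
normal on the logicle scale, converted to raw and mixed through a known
spillover matrix (12/8/6/5% off-diagonal bleeds by default). Doublets
(6% of live events) sum two singlet areas and share their width, placing
them below the pulse-geometry ridge. Optional scenario populations plant
corner artifacts, a high-SSC-A singlets-gate contaminant, and an
intermediate-viability population (with leukocyte-like
pulse height so it contaminates the core gate and drags the tail
threshold past 2.5, as the refinement heuristic expects).

Class-conditional per-10K targets default to 150/400 (TCPP R3),
800/1500 (FVS R2) and 700/1200 (CD206-low/lineage-mid) for
non-cancer/cancer, with ages 65 ± 5.5 vs 72 ± 6 years — the predictor
directions and demographic contrast of a lung-cancer screening cohort.
Cohorts
add between-sample logit-normal heterogeneity (SD 0.85), chosen so a
default cohort trains to an AUC near 0.9, the regime the assay operates
in; the cancer-class FVS-density shift attenuates with age
(`age_fvs_interaction`), inducing the model's negative age × FVS term.
The default cohort is 150 samples with 28 cancers. Feature-only mode
draws the per-10K counts directly (binomial over 10,000 with the
heterogeneous rates); full-FCS mode generates complete tube sets with
per-sample rates drawn the same way, and the two modes agree on the
planted class contrasts up to gating noise and small baseline leakage
(bulk-tail events drifting into R2 and the lineage-mid window add a
roughly class-independent offset of order 100–400 per 10K to those two
features).

What the generator does *not* emulate: staining chemistry and antibody
titration, instrument noise beyond Gaussian/lognormal spread, autofluorescence
structure, time-dependent signal drift, or biophysically realistic
sputum composition. Passing tests therefore demonstrate the pipeline's
correctness against planted truth and its statistical behaviour at
study-like effect sizes — not clinical performance on real sputum.

## Numerical choices and degenerate inputs

Gate boundaries are closed on the kept side. Mixture fits use
`reg_covar` 10⁻³ and two seeded initializations; BIC selects the
component count (1–3). Empty masks, zero-variance viability signal,
scatter ≤ 1 after gating, single-class label vectors, zero margins in a
confusion matrix, and degenerate prevalences all raise explicit errors
naming the quantity. The per-10K apportionment breaks remainder ties by
index order. Problem sizes in tests (20,000–30,000 events per tube,
20 gating replicates, 50 type-I replicates, 30-sample end-to-end
cohorts) are desk-scale choices that keep the full suite in the
few-minute range while leaving every statistical check well-powered.

## Known limitations

The corner-artifact region and bead-cluster contour have no canonical
numeric extents; both are config-exposed heuristics. The coefficients of
a clinically fitted model depend on its training cohort, so this package
reproduces the model's structure, signs and workflow — never any
particular fitted values. PDLR is always reported as the quotient the
package computes from its own confusion counts, at full precision.
Clinical headline AUCs require a real patient cohort; synthetic cohorts
characterize the pipeline's statistical behaviour, not the assay's
clinical performance.
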