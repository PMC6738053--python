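# Methods

## Overview

`hypoxvasc` implements a digital pipeline that links two slide-level tumour
biomarkers — a hypoxia surrogate and vascular density — to time-to-event
outcome in an endometrial-carcinoma cohort:

1. **fCAIX** — the fraction of carbonic anhydrase IX (CAIX)-positive pixels
   over the analysable tumour area of an immunofluorescence channel. CAIX is
   an HIF-1 target induced under hypoxia; a slide is called CAIX-positive
   when fCAIX exceeds 1%.
2. **MVD** — hotspot microvessel density by the Weidner method: the vessel
   channel is segmented, discrete vessel objects are counted in the three
   densest non-overlapping fields, and the per-slide MVD is dichotomised
   over the cohort median.
3. A survival stage: biomarker groups (CAIX+/MVD-high vs the rest),
   Kaplan–Meier curves with log-rank tests, and Cox proportional-hazards
   models entered through a univariable p < 0.20 screen.

Because the cohort and slides this design targets are not publicly
deposited, a synthetic-data module generates both inputs with known ground
truth, and a margins-based reconstruction turns the published baseline table
into a patient-level table for the descriptive stage.

## Image quantification

**Thresholding.** The original workflow sets segmentation thresholds
interactively above background, per sample. That step is irreproducible by
definition, so three deterministic surrogates are provided
(`if_quant.determine_threshold`):

- `background`: mean + k·SD over a supplied background region (default
  k = 3). This is the default intent-preserving surrogate — "above the
  background staining" — and is what the validation experiments use, with
  the non-tumour area of the synthetic slide as the background region.
- `otsu`: Otsu's bimodal split over the masked pixels. Works well when a
  genuine foreground class exists; on an all-background channel it will
  split the noise, so it should not be used for possibly-empty markers.
- `fixed`: a constant from configuration.

**Segmentation** is strict (`intensity > threshold`) and restricted to the
tumour inclusion mask. Positivity is scored at pixel level; no membrane
geometry is modelled, matching a thresholded-pixel readout.

**Size filtering.** "Exceeding n pixels" is read strictly: components of
area ≤ n are removed (n = 5 for the hypoxia channel, n = 2 for vessels).
Component connectivity is 8-neighbour by default (4-neighbour available).
The strict reading and the connectivity choice are configurable because the
underlying convention is not standardised.

**fCAIX** = filtered positive pixels inside the mask ÷ mask pixel count.
The 1% positivity cut-off is strict (fCAIX = 0.010 exactly is negative);
the boundary behaviour is documented and configurable since a tie at the
cut-off is not otherwise defined.

## Microvessel density

**Field geometry.** A "×200 field" has no universal area; the conventional
0.74 mm² high-power field is the default, converted to a square pixel field
via the image's µm/pixel scale. Fully configurable.

**Hotspot search** replaces the assessor's manual selection with a
reproducible scan: every candidate origin on a stride grid is scored by its
frame count, and the k = 3 highest-count fields are selected greedily in
descending count with lexicographic (row, col) tie-breaks, skipping fields
that overlap an already selected one (non-overlap is enforced by default)
or whose centre falls outside the tumour mask. At stride 1 the first
selected field provably attains the exhaustive maximum; the default stride
of a quarter field side is a speed/selectivity compromise for large slides.

**Counting frame.** Objects crossing a field's left or upper border are
counted; objects crossing the right or lower border are excluded. The
implementation makes this precise in the discrete setting by assigning each
object to the field that contains the bottom-right corner of its bounding
box (provided nothing crosses the right/bottom edge). For any object that
actually intersects the field the two formulations coincide; the
bounding-box form additionally assigns the rare object that straddles a
field corner diagonally — touching neither of its two candidate fields — to
exactly one field. That detail is what makes the classical
unbiased-counting-frame property hold exactly: counting over a complete
tiling of the image counts every object exactly once, which the test suite
verifies against brute force.

**Summary and dichotomisation.** The per-slide MVD is the mean of the three
hotspot counts by default (max and sum are available; which summary the
original measurement used is not stated). Cohort-level dichotomisation is
strict: high iff value > median, with the even-n median taken as the
midpoint of the two central order statistics, so at most ⌊n/2⌋ slides are
labelled high.

## Cohort model and endpoints

- **LVSI**: missing values are recoded to negative before analysis
  (unreported LVSI is taken to mean none was seen). Idempotent.
- **DSS**: event = death from disease at the death date; death from other
  causes censors at the death date; otherwise censored at last follow-up.
- **DFS**: event = any recurrence at the recurrence date.
- **DDFS**: event = distant recurrence (distant organs and para-aortic
  nodes). A local/regional recurrence censors DDFS at last follow-up by
  default; censoring at the recurrence date is available
  (`ddfs_censor_at_recurrence`) because the handling of non-distant events
  in a distant-recurrence endpoint is a genuine modelling choice.
- **Groups**: three levels (CAIX−, CAIX+/MVD-low, CAIX+/MVD-high) plus the
  binary double-positive view; CAIX+/MVD-high ⇔ caix_positive AND mvd_high.
- **Descriptive tables** report n (%) with within-column percentages
  rounded half-up to one decimal.

## Statistics

- Categorical contrasts: Pearson chi-square without continuity correction;
  automatic switch to Fisher's exact test when any expected cell of a 2×2
  table is below 5 (the switch rule is configurable; Yates correction is
  available by flag). On the reconstructed reference cohort the uncorrected
  chi-square on the recurrence-by-group cells gives p = 0.0079 → 0.008.
- Continuous contrasts: two-sided Mann–Whitney U, exact enumeration for
  combined n ≤ 20 without ties, normal approximation with tie correction
  otherwise.
- Kaplan–Meier product-limit curves; k-group log-rank with χ²(k−1). The
  log-rank statistic is undefined for a single group or zero events and
  raises, while the curves remain available.
- Cox proportional hazards via lifelines with Efron tie handling and Wald
  95% intervals. Reference levels: grade low, histology endometrioid, FIGO
  I–II, myometrial invasion <50%, LVSI no; age enters per year.
- Screening: every candidate with univariable p strictly below 0.20 enters
  one multivariable model; p = 0.20 exactly is excluded; if nothing passes,
  the multivariable stage is skipped with an explicit status.
- Report formatting: three decimals, "<0.001" below that.

## Synthetic data

**Slides.** A two-level intensity model (constant background and foreground
plus Gaussian noise, 16-bit range) — the simplest model that exercises
threshold segmentation. The tumour mask is a centred ellipse sized to the
requested area fraction. Marker-positive pixels are painted as compact
elliptical blobs inside the mask with an exact total: the recorded positive
fraction equals painted pixels ÷ mask pixels to the last pixel. Vessels are
filled ellipses (random orientation, aspect ≤ 2, area within a configurable
range) kept pairwise disjoint and non-adjacent so connected-component
labelling recovers them exactly; planted hotspot clusters carry per-region
truth counts, and background vessels avoid the planted zones. Noise
speckles are generated only at sizes at or below the exclusion cutoffs
(≤5 px hypoxia, ≤2 px vessel) and never adjacent to true objects, so size
filtering is observable end to end. Defaults: 768×768 frame at 4 µm/pixel
(~3×3 mm of tissue, so three 0.74 mm² fields fit without overlap), mask
fraction 0.6, background 100, foreground 1000, noise SD 10. Intensity
scales are free parameters, not calibrated to any scanner. One master seed
fans out to independent substreams per channel.

What the generator does **not** emulate: real staining texture and
vignetting, membranous staining geometry, overlapping or touching vessels,
autofluorescence gradients, pyramidal whole-slide formats. Passing recovery
tests therefore demonstrates the correctness of the measurement machinery,
not robustness to real-slide artefacts.

**Cohorts.** Covariates are drawn from configurable frequencies whose
defaults match a 385-patient endometrial-carcinoma cohort (16.4%
double-positive, 27.5% CAIX-positive, 17.4% high grade, 3.4%
non-endometrioid, median age 64). Event times follow an exponential
proportional-hazards model (Weibull shape available) with baseline
0.002 events/month (~12% cumulative events by five years) and independent
exponential censoring at 0.012/month (median follow-up near 58 months),
administratively capped at 156 months. Each record stores its true linear
predictor, so parameter recovery is testable against the simulator's own
truth. The observed event is narrated as a recurrence with a site drawn
from configurable probabilities; a fraction of recurrences progresses to
disease-specific death. MVD-high frequency is held near one half to mimic a
median split.

**Margins reconstruction.** `cohort_from_margins` rebuilds a patient-level
categorical table from group sizes plus within-group level counts; filling
is deterministic, and cross-tabulating the output returns every supplied
cell exactly (`crosstab ∘ cohort_from_margins = identity` on consistent
maps). Recurrence-site rows and cause-specific death are separate binary
variables because one patient can appear under more than one site.

## Validation scale

The recovery battery runs at these sizes (chosen as the package's own
desk-scale defaults): 20 synthetic 384×384 slides across true fractions
{0, 0.005, 0.01, 0.05, 0.12, 0.3} for fCAIX recovery (observed maximum
error ~6×10⁻⁵ against a ±0.01 tolerance); 100 random 64×64 maps for frame
brute-force agreement and 10 slides for tiling exactness; 50 maps for
hotspot optimality; 200 replicates of n = 5000 for Cox bias/coverage and
400 replicates of n = 300 for the log-rank null.

## Known limitations

- The per-sample interactive thresholds of the original workflow have no
  calibration target; only the synthetic oracle constrains
  `determine_threshold`.
- The cohort-dependent headline hazard ratios of the motivating study
  cannot be reproduced without its patient-level data; the pipeline instead
  demonstrates unbiased recovery of known simulated effects.
- Whether the original MVD summarised the three hotspot counts by mean, sum
  or max is unknown; the default (mean) changes only the scale of the
  median split, not the dichotomy, when the three counts are similar.
- Fisher's exact switching is implemented for 2×2 tables; larger sparse
  tables fall back to chi-square.
- `cohort_from_margins` assigns variables independently within groups, so
  joint distributions across variables (beyond the group margin) are not
  preserved — sufficient for one-variable-at-a-time descriptive tables,
  not for multivariable modelling.
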