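# Methods

## The assay being modeled

Primary neurons in multiwell plates are exposed to a brief NMDA insult;
20 h later cells are fixed, nuclei are stained with Hoechst, and each well
is imaged in multiple fields with a 12-bit camera. Dying neurons are
recognizable by pyknotic nuclei (condensed, brightly stained); survival is
the fraction of live nuclei, and a compound's effect is expressed relative
to the assay window spanned by untreated and NMDA-only wells. A companion
live assay follows the mitochondrial membrane potential with TMRE: after
NMDA, polarized mitochondria lose the dye and the well's fluorescence
decays; protective compounds delay and attenuate that decay.

## Synthetic data: what is emulated, and what is not

The generators reproduce the features downstream algorithms depend on, not
photorealism.

* **Nuclear fields.** Nuclei are isotropic Gaussian discs,
  `I(r) = peak · exp(−r²/2σ²)` with `σ = radius/2`, placed by rejection
  sampling with a minimum center distance of 1.5× the summed radii (100
  attempts per nucleus; failure raises an error naming the achievable
  density). Defaults: 250 nuclei per 512×512 field, 12 fields per well;
  live nuclei 6 ± 1 px radius at 900 ± 120 ADU peak, dead nuclei
  3.5 ± 0.4 px at 2200 ± 250 ADU (at a 10× objective scale a healthy
  nucleus is ~12 px across and a condensed one roughly half that, several-
  fold brighter); background pedestal 100 ADU, additive Gaussian camera
  noise of SD 20 ADU, values clipped to the 12-bit range [0, 4095] and
  stored in 16-bit containers. Each nucleus's class is an independent
  Bernoulli draw with its condition's death probability; the anchor
  conditions default to 75.7 % untreated survival and 20 % after NMDA.
  Irregular ("amorphous") nuclear outlines, glia, debris, focus drift and
  uneven illumination are *not* modeled — passing tests show the pipeline
  recovers known truth under clean geometry, not that absolute counts from
  real plates would be error-free.
* **Count-level screens.** Screen-scale statistics (hundreds of compounds ×
  replicates) use a binomial well simulator (default 1000 cells/well, i.e.
  ~3000 per pooled triplicate) with an optional per-well random effect on
  the survival scale (`well_sd`, default 0). The default of 0 reflects that
  cell-level sampling is the irreducible noise floor; the pooling analysis
  sets `well_sd = 0.12` explicitly, matching the between-well variability
  typical of primary cultures.
* **TMRE stacks.** A well trace is a delayed single exponential toward a
  plateau: `F(t) = plateau + (1 − plateau) · exp(−k · max(t − onset, 0))`,
  rendered onto flat-top discs (supergaussian `exp(−(r/R)⁸)`, since
  dye-filled somata image as near-uniform discs) at one frame per 30 s for
  20 min. The two knobs map directly onto the protective phenotype: longer
  onset = delayed loss, smaller rate = less pronounced loss. Known integer
  frame shifts can be injected for registration tests. Photobleaching and
  per-mitochondrion dynamics are not modeled.
* **Dose–response tables.** Four-parameter logistic responses with Gaussian
  noise; the antagonist convention (response falls with concentration) is
  the default.

All generators are deterministic: identical seed and configuration produce
bit-identical output (seeds fan out through `numpy` `SeedSequence` spawning
per well and field).

## Segmentation and classification

Background is estimated by grayscale morphological opening with a disc of
radius 5× the expected mean nucleus radius (default 30 px, decomposed for
speed) and subtracted. The global threshold is Otsu's method computed on
log-transformed intensities: nuclear brightness is strongly bimodal (dead
nuclei are several-fold brighter than live), and a linear-intensity Otsu
can settle *between* the two object classes rather than between background
and foreground; the log compresses the bright mode and restores the
background/foreground split. A robust noise floor (median + 5 MAD of the
corrected image) guards the empty-field case, where Otsu would otherwise
bisect camera noise. Touching objects are split by watershed on the
negated distance transform (peak markers at minimum distance 5 px);
objects under 20 px or touching the border are removed. Coordinates are
0-based row/col pixel centers.

Features (area in px, mean and integrated intensity in ADU, eccentricity)
are measured on the *original* image so that background subtraction cannot
bias intensities. The default classifier is a transparent two-threshold
rule — `dead ⇔ area < θ_A ∧ mean intensity > θ_I`, strict inequalities,
ties at a threshold resolved to "live" — calibrated by exhaustive search
over all threshold pairs (an outer sweep over area cuts with an inner
vectorized intensity sweep; exact optimum in O(n²)); ties in training error
break toward higher dead recall, since missing dying cells inflates
survival. A logistic-regression alternative on the same two features is
available. Calibration requires at least 20 labeled examples per class.

## Plate statistics

Survival, protection scores, QC and hit calls follow the conventions
stated in the README. Numerical conventions worth pinning down:

* Sample (n−1) SDs everywhere, including Z-scores — condition groups are
  small.
* The QC boundary is strict (`n_total < 0.10 × screen average` fails;
  exactly 10 % passes); the hit boundary is strict (`score > 50`). The
  screen-wide average is taken across all compounds in one invocation.
* Zero total cells is a hard error, deliberately distinct from the QC
  exclusion, which withholds a score with a reason string.
* Scores below 0 and above 100 are reported unclipped — negative scores
  are real (toxic compounds) and informative.
* Pooling groups wells in disjoint consecutive runs in acquisition
  (row-major) order, dropping a trailing remainder; pooled survival then
  equals the count-weighted mean of member survivals and totals are
  conserved. Because a 30-well plate yields only 6 pooled values at k = 5,
  variance-reduction checks average the per-plate SDs over ~20 simulated
  plates — the single-plate SD of a 6-sample SD is ~⅓ of its value, too
  noisy to assert monotonicity honestly.

## TMRE quantification

Frames are registered to frame 0 by integer-pixel phase cross-correlation
(plain, un-normalized correlation: the normalized variant is noticeably
noise-sensitive on low-texture frames), with corrections capped at 20 px
and vacated pixels filled with the frame median. Background is the 5th
percentile of each frame, subtracted and clipped at 0 (idempotent within
tolerance). The ROI is Otsu's threshold on corrected frame 0 and is frozen
for the series, so depolarizing (dimming) mitochondria keep contributing
signal instead of silently leaving a per-frame ROI. The loss statistic
integrates the deficit below baseline with the trapezoid rule, clipping
F > 1 inside the integral only; the plain AUC of F(t) is also reported.
Loss is monotone (pointwise lower traces lose more) and bounded by the
recording span T (1200 s) for traces in [0, 1].

## Estimation statistics

BCa intervals follow the standard construction: nonparametric bootstrap of
the mean difference (within-group resampling unpaired, pair resampling
paired), bias correction `z₀ = Φ⁻¹(#{Δ* < Δ̂}/B)` (clamped away from ±∞
when the observed value falls outside the bootstrap range), acceleration
from the jackknife skewness (leave-one-out over all observations unpaired,
over pairs paired), and quantiles at the adjusted percentiles. A degenerate
bootstrap distribution collapses the CI to a point with a warning. B
defaults to 5000.

Permutation tests use |Δ| as statistic. The unpaired null permutes group
labels over the pooled sample, canonicalized (sorted pool, smaller group
first) so exchanging the test/control labels reproduces the identical null
stream and hence an identical p; the paired null flips pair signs. p is
the raw proportion of resampled statistics ≥ the observed one (ties count,
with a tiny float tolerance), reported to three decimals so extreme
results print as `0.000`; the (b+1)/(R+1) variant is behind `add_one=True`.
R defaults to 5000. The provided rows are the resampling units.

## Dose–response fitting

Fits run on `log10(xc50)` with `scipy.optimize.least_squares`, multi-started
over seven log-spaced midpoints spanning one decade beyond the tested
range; slope bounded to [0.1, 10]. For antagonist curves the bottom is
fixed at 0 with the top free (3 parameters); the full 4-parameter fit needs
four distinct concentrations. A fitted midpoint above the highest tested
concentration is reported as a censored bound (`xc50 > c_max`) rather than
a point estimate — extrapolated midpoints are not identifiable. Standard
errors come from the Gauss–Newton covariance at the optimum.
Non-convergence is flagged, never silently replaced.

## Pipeline and reproducibility

`RunConfig` holds every threshold plus the global seed and serializes to
YAML; each output directory receives the config snapshot and a hash of the
analysis parameters (paths and logging excluded). The seed expands into
named per-stage substreams, so stages re-run in isolation reproduce their
in-pipeline results. No stage mutates its inputs.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` exercise: the image pipeline on
3 wells × 12 fields × 250 nuclei at default noise; a count-level spike-in
screen (12 compounds at 60 % true protection among 100 inert ones,
triplicate wells, 20 replicates); pooling on 20 × 30-well plates;
statistics calibration with 1000 null permutation replications and 500
BCa coverage replications at B = 1000; and 20 paired TMRE simulations.
These sizes give binomial/Monte-Carlo noise comfortably below the asserted
margins while keeping a full run in the minutes range on one CPU.

## Known limitations

* Absolute nucleus counts, thresholds and classifier parameters are tied to
  the synthetic image model; real plates need recalibration on annotated
  fields (the `ClassifierModel` JSON round-trips for exactly that reason).
* The segmentation assumes mostly isolated, roughly circular nuclei;
  heavily clumped or irregular nuclei would need stronger splitting logic
  than the distance-transform watershed shipped here.
* Registration is translation-only and integer-pixel; rotation or
  sub-pixel drift is out of scope.
* No multiple-testing correction across compounds is applied — the screen's
  hit call is a fixed threshold on the protection score, and verification
  is expected to follow in independent experiments.
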