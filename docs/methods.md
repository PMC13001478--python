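# Methods

## Scope and model

`omiflim` analyzes label-free optical metabolic imaging (OMI) of immune
cells: fluorescence-lifetime (FLIM) images of the metabolic cofactors
NAD(P)H and FAD, acquired by time-correlated single photon counting
(TCSPC).  At each pixel the observable is a photon-arrival-time histogram
over one laser repetition period, modeled as a biexponential decay

    I(t) = α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) + C

convolved with the instrument response function (IRF).  τ₁ and τ₂ are the
short (quenched / free-NAD(P)H-like) and long (unquenched / bound-like)
lifetime components, α₁ and α₂ their amplitudes, and C a constant
background.  Derived per-pixel quantities are the amplitude-weighted mean
lifetime τ_m = (α₁τ₁ + α₂τ₂)/(α₁ + α₂) and the normalized fractions
α₁/(α₁+α₂), reported as percentages.  At the cell level the optical redox
ratio ORR = I_NAD(P)H / (I_NAD(P)H + I_FAD) is computed from summed
intensities, bounding it in [0, 1].

## Time axis and periodic convolution

The default time axis is 256 bins spanning 12.5 ns (one period of an
80 MHz source), bin width 48.828125 ps; both are configurable.  The long
component (τ₂ ≈ 2.5 ns) is not negligible against the period, so incomplete
decay wraps into the next period.  The periodic sum of an exponential
differs from a single period only by a constant factor, so after unit-sum
normalization the bin shape is unchanged and the wrap enters solely through
*circular* convolution with the IRF.  Simulator and fitter share this
forward model, so fitting is consistent with generation by construction;
the independent cross-checks (analytic curves, moment oracles, exhaustive
grid) guard against a shared implementation error.

Amplitude convention: component shapes are normalized to unit area before
scaling, so the raw amplitudes are expected photon counts per component and
the normalized α₁ is the short-component photon fraction.  Generated
`alpha1_frac` values and fitted normalized α₁ are therefore directly
comparable without rescaling.

## Pixel processing

* **Spatial binning.** A bin factor *b* sums photon histograms over a
  (2b+1)×(2b+1) sliding kernel centered on each pixel (b=2 → 25 pixels,
  b=3 → 49), preserving the image grid, with zero padding at edges.
  Convention: b=2 for NAD(P)H, b=3 for FAD, chosen to bring decays to the
  2,500-photon floor.  The sliding sum is computed exactly in integer
  arithmetic.
* **Thresholding.** Pixels whose binned decay holds fewer than 2,500
  photons (configurable) are excluded; the floor is inclusive (exactly
  2,500 passes).
* **Fitting.** Parameters (τ₁, τ₂, a₁, a₂, C) maximize the Poisson
  log-likelihood of the observed counts — at ~10 counts/bin the Gaussian
  approximation behind least squares is poor in the decay tail.  L-BFGS-B
  with an analytic gradient; lifetimes are bounded to (half a bin, one
  period), amplitudes and background to nonnegative values.
  Initialization is method-of-moments: τ_m from the background-corrected
  mean arrival time minus the IRF centroid (period-wrapped if negative),
  τ₁/τ₂ at 0.4×/2.5× that value, α₁ = 0.7, C from the last 5% of bins.
  On non-convergence the optimizer restarts from a fixed schedule of
  perturbed lifetimes (deterministic, so identical inputs give identical
  fit maps).  The τ₁ ≤ τ₂ ordering is imposed by sorting after
  optimization, keeping the objective smooth.
* **Goodness of fit.** Pearson reduced χ² over bins with expected counts
  ≥ 5, divided by (bins used − 5) free parameters.  An exhaustive grid scan
  (τ₁ step 25 ps, τ₂ step 50 ps, α₁ step 0.02, amplitude and background
  profiled at each point by monotone multiplicative updates) provides a
  lower bound on the attainable likelihood that the gradient fit must meet
  or beat; this is exercised in tests and the acceptance script.

## Per-cell features and QC

Cell masks arrive as integer label images (segmentation itself is out of
scope).  Lifetime variables are unweighted means over valid fitted pixels
inside the mask; each record carries the valid-pixel fraction.  ORR and
mean NAD(P)H intensity use summed raw (unbinned) counts over *all* mask
pixels; sum-then-ratio equals the intensity-weighted mean of pixel ratios,
which is verified numerically.  Four exclusion rules (all strict
inequalities, boundary values retained): mean NAD(P)H intensity < 10 a.u.,
area < 70 px, reduced χ² > 1.3, NAD(P)H τ₁ < 350 ps.

The per-cell χ² statistic defaults to the *mean* per-pixel reduced χ² in
the mask.  The maximum is also reported (`chi2_max`) and can be selected
for the rule, but a maximum over the 100–200 pixels of a typical mask
exceeds 1.3 under a correctly specified model with high probability and
grows with cell area, which would bias QC against large cells (monocytes);
a 1.3 cutoff presumes a unit-mean statistic.  In the synthetic pipeline
the intensity "a.u." are photon counts; the 10 a.u. rule is configurable
because arbitrary units do not transfer across instruments.

Stain gating: CD69⁺ is called strictly above mean + 1.5 SD of the
quiescent population (sample SD, n−1 — the convention everywhere SD
appears); CD56-bright NK cells are called strictly above a 100 a.u.
threshold chosen to capture roughly the top 10% brightest.

## Statistics

Cohen's d = (M₁ − M₂)/√((SD₁² + SD₂²)/2) with sample SDs; the
equal-weight root-mean-square denominator is the standard two-group form.
Categories: |d| < 0.2 none, 0.2–0.5 small, 0.5–0.8 medium, ≥ 0.8 large,
each lower boundary belonging to the higher band.  Groups under 100 cells
warn rather than error.  Heterogeneity is the coefficient of variation
SD/mean per (cell type, condition, variable), undefined for nonpositive
means.  For clustering, the 10 OMI variables are z-scored per variable
across all included cells and clustered with Ward's minimum-variance
linkage on Euclidean distances (scipy's Lance–Williams implementation);
condition/donor/cell-type annotations are carried alongside and never
enter the distances.  The first split (k=2) is reported by default.

## Classification

Classes are balanced by randomly undersampling every category to the
minority count, then split 70/30 into train/test cells.  Balancing before
the split keeps test sets balanced so accuracy is comparable across
classes; strict train-only undersampling is available
(`balance_order="after_split"`).  A single multi-class random forest (500
trees, unlimited depth, √p features per split — conventional defaults, not
tuned) provides per-class probabilities used as one-vs-rest scores; a
literal per-class-forest mode exists for strict one-vs-rest fidelity.
Reported: per-class ROC (threshold sweep, trapezoidal AUC; constant scores
give 0.5), confusion matrices in counts and row percentages, accuracy
(overall fraction correct), per-class precision/recall, and feature
importances (mean decrease in impurity, summing to 1).

## Synthetic data: what it emulates and what it does not

The generator is the package's canonical input source.  The imaging path
renders non-overlapping elliptical cells (area-controlled, jittered
eccentricity) on a configurable field, draws each cell's per-channel
emitter parameters from cell-type profiles given as (mean, CV) pairs, and
Poisson-samples per-pixel histograms from the IRF-convolved biexponential;
photon streams are keyed by (seed, channel, cell id) so scenes are exactly
reproducible and partially regenerable.  The default PBMC profiles encode
the qualitative contrasts of interest — monocytes with low NAD(P)H τ_m,
high α₁ and large area; B cells with slightly elevated α₁; NK cells with
shifted FAD kinetics — with literature-typical lifetime values.
`contrast_pair` builds a lymphocyte/monocyte-like pair whose NAD(P)H τ_m
gap is calibrated to a requested Cohen's d via the delta method on the
profile CVs, alongside the α₁ and area contrasts that accompany that
separation in real PBMCs.  `activated_profiles` applies the activation
direction pattern (lymphocyte τ_m down/α₁ up, monocyte opposite, ORR up
and τ₁ down for all); at its default strength 1.0 the pooled shifts are
medium-to-large, and sensitivity studies use strength 1.5, the point where
every shifted variable's pooled |d| reaches the large band (≥ 0.8).  The statistical path (`sample_feature_table`)
draws the 10 OMI variables directly from profiles, bypassing photon
physics, for fast tests of downstream stages; `effect_pair` confines
between-cell variation to NAD(P)H τ₁ with equal absolute SDs so the τ_m
separation equals the target d exactly in expectation.

Not emulated: optical blur (PSF), detector afterpulsing and pile-up,
autofluorescence heterogeneity within a cell, segmentation errors,
motion artifacts, or spectral bleed-through.  Passing tests therefore
demonstrate correctness of the estimators and procedures under the stated
noise model, not robustness to those instrument- and sample-level effects.

## Problem sizes and numerical choices

Parameter-recovery studies use 500 decays per photon budget (2,500 /
25,000 / 250,000 photons, τ₁ = 400 ps, τ₂ = 2500 ps, α₁ = 70%, IRF FWHM
220 ps centered at 1 ns).  Grid-dominance checks use 20 decays at the
photon floor.  End-to-end studies use a 256×256 field with 100 cells (two
types), which the package fits, extracts and classifies in a few minutes
on one core; field size, cell count and photon budgets scale freely.
Degenerate inputs are handled explicitly: all-zero decays error; zero
total amplitude errors in τ_m and α normalization; zero-variance z-score
columns are dropped with a warning; a zero-variance quiescent population
collapses the CD69 gate to its mean with a warning.  Ties in Ward merges
follow scipy's deterministic ordering.

## Known limitations

* The χ² aggregation choice (mean vs max) changes which cells the 1.3
  cutoff removes; both are reported so the rule can be audited.
* The Gaussian IRF is a convenient stand-in for a measured second-harmonic
  IRF; asymmetric tails and afterpulses are not modeled.
* One-vs-rest via multi-class probabilities is the default reporting
  surface; per-class forests can differ slightly on small test sets.
* Cell placement is rejection sampling; very dense fields fail with a
  density report rather than overlapping masks.
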