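# Methods

## The scientific setting

A population of visual-cortex (V4-like) neurons is probed with small
image patches whose only figure–ground (FG) information is local: a
contour passes through the patch centre and divides it into a figural and
a ground region. For each neuron and stimulus, the *veridical label* is
the region (figure or ground) covering the neuron's classical receptive
field (CRF) centre. The analyses ask (i) whether single neurons fire
differently for figure vs ground on their CRF, (ii) how consistent that
signal is across many stimuli, (iii) when it arises after stimulus onset,
and (iv) how well a pseudo-population of such neurons supports FG
classification as more neurons are integrated.

All data here are synthetic with known ground truth; the package's claim
is therefore about the *analysis chain* (its calibration, exactness and
recovery properties), not about cortex.

## Stimuli

A patch is a square frame of `scale` degrees (default 8°), centred at
(0, 0), rasterised on a 69×69 lattice of pixel centres. The contour
family is analytic: on each side of the centre a circular arc (per-side
radius and turn angle, C¹ at the centre) continued by its end-tangent
ray; zero turn gives a straight border. The figure is the concave
("pocket") side or its complement.

Shape descriptors are stand-ins — the literature the stimulus design
follows does not define numeric scales, so the package declares its own
and documents them:

* closure = total tangent turning / 2π ∈ [0, 1] (straight 0, full circle 1);
* convexity = sign · κ̄s/(1 + κ̄s) ∈ [−1, 1], κ̄ the mean one-sided
  curvature at the centre, positive when the figure is enclosed;
* symmetry = IoU of the figure mask with its reflection about the centre
  normal ∈ [0, 1].

`generate_patch` realises closure and convexity analytically and matches
the symmetry target by bisecting a joint turn/curvature imbalance that
preserves both other descriptors; unreachable triples (e.g. nonzero
closure with near-zero curvature, or an arc too flat for the frame) raise
a named error. The three descriptors are *not* independent in this
family: flat arcs with large total turn do not fit in the frame, so high
closure requires high |convexity|. `random_patch` samples only feasible
triples.

Variant families per base: natural = {original, mirrored}; filled =
contrast(2) × mirror(2) × translation(2); square = single/pair(2) ×
contrast(2) × translation(2) × mirror(2) × rotation(4) on one synthetic
square base; gratings = 3 frequencies × 4 orientations × 25 positions.
Mirroring reflects about the contour tangent at the centre and carries a
colour inversion, so the colour of each *spatial* side of the border is
preserved while figure and ground swap; translation shifts the whole
patch along the border normal by 25 % of the side (within the 0.6–4.8°
range the stimulus scaling implies), moving colours with the geometry.
Each patch carries a perceptual-consistency value (Beta-distributed,
mean 0.69 for natural and 0.77 for filled patches) for label-noise
experiments; the analyses in this package use the veridical labels.

## Generative population model

Spike counts are Poisson with piecewise-constant rate

    rate(t) = b                                   t < onset
            = b + g·D·(1 + c·s_c)                 onset ≤ t < mod
            = b + g·D·(1 + m·s_fg)(1 + c·s_c)     t ≥ mod

with baseline b (Gamma, mean 5 Hz), drive D (Gamma, mean 30 Hz), signed
FG modulation ratio m, contrast modulation c, and s_fg/s_c = ±1 the
figure/contrast signs at the CRF centre (s_c = 0 for natural patches,
which carry no polarity). g is the product of a per-(neuron, base patch)
Bernoulli responsiveness gate and a lognormal drive jitter (σ = 0.5, unit
mean). Gating and jitter attach to the *base* patch, not the displayed
variant, so all mirror/translation/contrast variants of a base share
them: this is the stimulus-identity nuisance (shape selectivity) that
single-stimulus thresholds suffer from and pair differencing cancels.

Default study conditions: 24.3 % of neurons carry genuine FG modulation
(`fg_significant_truth`), with |m| Gamma-distributed around mean 0.326;
the remaining cells carry a residual mean 0.054; 24 % of modulated cells
prefer ground (m < 0). CRF half-height diameters are Normal(1.8°, 0.45°),
centres uniform in ±0.22·scale (so the grating grid covers each field
with margin, as experimental stimulus placement would). Onset and
modulation latencies default to 52.5 and 79.4 ms. 10 trials per stimulus;
analysis windows 50–250 ms (stimulus) and −50–50 ms (baseline).
`responsive_fraction` defaults to 0.11, calibrated so that the mean
number of *favorite* stimuli (mean response above half the peak trial
count) is ≈ 8.4 on a full mirror-session stimulus set.

Two deliberate simplifications: m is a generative rate parameter, not the
measured modulation-ratio statistic — under sparse responsiveness the
measured ratio is smaller than m (the 0.326/0.054 means hold for the
parameters, and are tested as such); and there is no correlated noise
across neurons (a config hook exists in spirit via sessions, default
off), so within- vs across-session decoding differences are nil by
construction.

Counts and 1-ms-binned histograms are drawn from shared per-segment
Poisson totals (bins are multinomial splits of each segment), making
"bins summed over a window == window counts" an exact identity rather
than a distributional one. Every neuron has its own counter-derived
substream, so any subset of a population is bit-reproducible.

## CRF mapping

Grating position-response maps (5×5 grid, 10 Poisson repeats) are fitted
with offset + amplitude · elliptical Gaussian (free orientation) by
bounded nonlinear least squares with a deterministic multi-start (centre
at the map argmax; widths at 0.5/1/2 grid spacings). The extent is fixed
analytically: the half-height contour of a 2D Gaussian is an ellipse of
area 2π ln2 σₓσᵧ, hence extent_diameter = 2√(2 ln2 σₓσᵧ). Non-positive
amplitude or failed convergence flags the estimate invalid; downstream
stages drop such neurons, as they drop centres outside the patch frame.

## Labelling and pairs

The centre rule labels by the region at the (fitted or generative) CRF
centre; the overlap rule compares the areas of the half-height ellipse
intersected with figure vs ground, integrated on the 69×69 lattice by
cell-centre sampling. Exact area ties fall back to the centre rule (tie
counts are logged), which keeps the two rules nested. Contrast labels are
a point property and always use the centre. A mirror/translation pair is
usable for a neuron iff exactly one member is labelled figure, so each
usable pair contributes one figure and one ground response.

## Single-cell statistics

* Responsiveness: paired two-sided t-test of stimulus- vs pre-window
  counts over all (stimulus, trial) observations, α = 0.05; zero-variance
  neurons get p = 1 by convention.
* FG × contrast ANOVA: observations are per-stimulus mean counts with FG
  and contrast as between-stimulus factors (the simplest design matching
  `response = FG + contrast + FG·contrast + noise`); a trial-level
  observation mode exists behind a flag. Effects are Type-II
  nested-model F tests on statsmodels OLS fits; one-way (FG only) for
  natural patches; optional Anscombe transform 2√(x + 3/8) before
  averaging. An empty design cell demotes to one-way with a warning.
* Preference = the FG label with the higher mean rate (ties → figure,
  logged). Modulation ratio = |preferred − non-preferred| / overall mean.
* Paired differentials: preferred-minus-non-preferred mean responses over
  usable pairs; their zero-mean F test (squared one-sample t) is the
  paired ANOVA.
* Exclusion rules, kept as two separately named criteria exactly as
  printed: `single_cell` drops a neuron with spikes in *fewer than* 80
  trials of either class; `population` drops one with spikes in *at most*
  80 stimuli of either class.
* Correct rate: a response is correct iff strictly above threshold for a
  preferred-label stimulus or strictly below for a non-preferred one
  (exactly at threshold counts incorrect). The threshold is either the
  exhaustive-search optimum over midpoints of adjacent observed values
  (ties → lower threshold; provably optimal over all real thresholds) or
  a 1-D soft-margin linear SVM on standardised counts with a small C grid
  chosen by in-sample rule accuracy. Paired correct rates count positive
  preferred-minus-non-preferred differences (the zero crossing of the
  descending rank curve); a zero difference counts incorrect.

## Latency

Population PSTHs (per-neuron mean first, then across neurons) for
preferred and non-preferred labelled stimuli are baseline-subtracted
(−50–50 ms mean), cumulated, and smoothed with a 5-ms centred moving
average (smoothing after cumulation by default; a flag flips the order —
the two differ only at the edges). Onset latency is estimated on the sum
of the two traces, modulation latency on their difference. Two-phase
regression fits independent least-squares lines left and right of every
candidate breakpoint on the bin grid (excluding 3 edge bins so both
segments keep ≥ 4 points) and returns the analytic intersection of the
SSE-minimising pair, which may fall off-grid; parallel lines fall back to
the breakpoint with a warning. Suppressed neurons (stimulus-window rate
below baseline) are excluded before averaging.

One pitfall the pipeline guards against: the preferred side must be
estimated on count data *independent* of the draws entering the PSTH,
otherwise argmax selection noise masquerades as FG modulation beginning
at response onset and biases the modulation latency toward the onset
latency.

## Population decoding

Each neuron's dataset pairs per-stimulus 10-trial summed counts with its
veridical label (raw mode) or per-usable-pair signed differences with the
first member's label (paired mode), balanced by subsampling the majority
class without repetition. Pseudo-samples are assembled
class-conditionally: for each class, one record per neuron without
within-neuron repetition, the per-class sample count being the minimum
class count over the sampled neurons — stimulus identity is deliberately
absent from the records, and the construction is declared as this
package's choice since the original combination rule is under-specified.
Records are drawn from per-neuron substreams keyed by neuron id, so
permuting neurons permutes feature columns without changing any draw.

Classification: RBF soft-margin SVM (scikit-learn/libsvm) inside a
per-fold standardisation pipeline, stratified 5-fold CV, grid search over
C ∈ 2⁻⁵…2¹⁵ and γ ∈ 2⁻¹⁵…2³ stepping by powers of four. Among grid
points whose mean training accuracy reaches 0.99, the best
cross-validated point is selected (logged fallback to the best trainer
otherwise); the *reported* correct rate is the held-out accuracy of the
selected parameters on an independent fold partition — re-using the
selection CV score would inflate null decoding by several points
(winner's curse over the grid). Integration curves repeat
{sample neurons → rebuild balanced datasets → assemble → decode} with
per-repeat substreams and report mean ± SD across repeats.

## Problem sizes and numerical choices

Defaults used by the pipeline, tests and the acceptance script: 105
contour bases (840 filled stimuli), populations of 60–200 neurons for
decoding analyses and 2 000 for null calibration, 80 all-modulated
neurons × 480 stimuli for latency recovery, decoding repeats 12–50 with a
64-or-fewer records-per-class cap, and a 30-point (C, γ) grid. These
sizes keep a full run at desk scale while leaving every statistical
margin comfortable (binomial or repeat-distribution CIs are quoted in the
tests). Rates are floored at zero by truncation; with the default
modulation bounds the floor never binds. JSON summaries round floats to
six decimals and sort keys, making reproducibility a byte-level property.

## What passing tests do and do not show

The synthetic generator reproduces the *structure* of the recorded-data
analyses — sparse idiosyncratic responsiveness, shared-within-base
nuisance, weak signed FG modulation, latency steps, session grouping —
but not receptive-field surround structure, spike-sorting artefacts,
correlated noise between simultaneously recorded neurons, or perceptual
label noise (consistency values are carried but labels are veridical).
Recovery and calibration results therefore validate the estimators and
the pipeline plumbing under a known model, not the biological claims; in
particular the detected FG-significant fraction is power-limited and only
approximately matches the generative 24.3 % under default conditions.
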