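# fgpop

Figure–ground (FG) population coding analysis for V4-like spike-count
populations.

When a macaque views a small patch cut from a natural scene, individual
V4 neurons modulate their firing depending on whether the *figural* or
the *ground* side of the patch covers their classical receptive field
(CRF) — but each neuron does so consistently for only a narrow slice of
stimuli. The question this package addresses is how a *population* of
such weakly consistent neurons can nevertheless signal figure vs ground
across a wide variety of natural patches, and how many neurons must be
integrated before the read-out becomes reliable.

`fgpop` provides the complete analysis chain as a tested, reproducible
pipeline operating on synthetic data with known ground truth:

* **stimulus_geometry** — contour patches on a 69×69 lattice with a
  contour through the patch centre, enumerated into natural (2/base),
  filled (contrast × mirror × translation = 8/base), square (64) and
  grating (300) variant families with veridical FG labels;
* **synthetic_population** — Poisson spike-count simulator with per-neuron
  CRF geometry, signed FG modulation ratio *m* (rate ∝ 1 + *m·s*, *s* = ±1
  for figure/ground on the CRF centre), contrast modulation, per-base
  responsiveness gates and drive nuisance, and onset/modulation latencies;
* **crf_mapping** — elliptical 2D-Gaussian fits of grating position maps;
  the CRF extent is the diameter of the circle matching the half-height
  contour area, d = 2√(2 ln2 · σₓσᵧ);
* **fg_labeling** — centre-rule and overlap-rule veridical labels and
  mirror/translation pair indices with usability flags;
* **single_cell_stats** — responsiveness t-tests, FG × contrast ANOVA
  (raw or Anscombe-transformed), modulation ratios, favorite stimuli,
  paired differentials and per-neuron correct rates with exhaustive-search
  or 1-D SVM thresholds;
* **latency** — onset and FG-modulation latency by two-phase (broken
  stick) regression on baseline-subtracted cumulative spike-count curves;
* **population_decoding** — balanced per-neuron datasets, class-conditional
  pseudo-population assembly and RBF soft-margin SVM decoding with libsvm
  style grid search and 5-fold cross-validation, giving correct rate as a
  function of the number of integrated neurons.

## Worked example

```python
import numpy as np
from fgpop import stimulus_geometry as sg, synthetic_population as sp
from fgpop import fg_labeling as fl, single_cell_stats as scs

bases = sg.default_bases(105, seed=0)          # 105 contour bases
stims = sg.enumerate_set(bases, ["filled"], seed=0)   # 840 filled variants
pop   = sp.sample_population(120, sp.PopulationConfig(), seed=1)
tab   = sp.simulate_counts(pop, stims, seed=2)  # Poisson counts, 10 trials
lab   = fl.label_by_center(pop, stims)          # veridical FG labels

stats = scs.neuron_stats(tab, lab)
sig = np.array([s.fg_significant for s in stats])
print(f"FG-significant: {sig.mean():.2f}")
rates = [scs.correct_rate(tab, lab, i).correct_rate
         for i in np.flatnonzero(sig)]
print(f"mean single-cell correct rate: {np.mean(rates):.3f}")
```

prints

```
FG-significant: 0.19
mean single-cell correct rate: 0.541
```

— about a fifth of the simulated cells test FG-significant (the
generative fraction is 0.243; detection is power-limited), and each of
them classifies figure vs ground correctly for barely more than half of
the stimuli, the hallmark of weak single-cell FG consistency that
motivates the population read-out. Running the decoder over the same
population (`fgpop.population_decoding.integration_curve`) shows the
correct rate rising with the number of integrated neurons, and rising
substantially faster when mirror-pair response differences are decoded
instead of raw counts.

The full chain, including CRF mapping, latency estimation and decoding
curves, runs from one seeded configuration:

```bash
fgpop run --out results/run --seed 1          # writes summary.json + CSVs
fgpop config-template > run.yaml              # editable configuration
```

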