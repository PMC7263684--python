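# Methods

## Signal model

The pipeline treats the fly eye's steady-state response to sinusoidal
contrast flicker as a sum of two phase-stable harmonics plus noise:

```
V(t) = A1·sin(2π f1 t + φ1) + A2·sin(2π·2f1 t + φ2) + ε(t)
```

with `A1` the photoreceptor component at the stimulus fundamental and `A2`
the lamina-neuron component at its double. Epochs are cut to a whole
number of stimulus cycles, so a rectangular window introduces no spectral
leakage and the harmonic bins can be read off exactly. The amplitude
scaling convention is one-sided: a pure sinusoid of peak amplitude A
contributes exactly A to its bin, and the DC bin carries the epoch mean.
Harmonics above 2F1 are measured by nothing and influence nothing —
including the noise floors, which exclude every integer multiple of f1.

Assumptions this model makes: stationarity within an epoch, uniform
sampling, and response phase that may drift between repeats (hence
incoherent repeat averaging by default) but is constant within one epoch.

## Stimulus

`L(t) = mean_level·(1 + c·sin(2π f1 t))`, Michelson contrast `c`, mean
luminance fixed so that contrast is the only variable across the series.
Defaults: f1 = 12 Hz, mean level 0.5, 1 s epochs at 1 kHz, 9 contrasts
linearly spaced from 10% to 100%, 5 repeats per contrast. The true rig
frequency and waveform are not asserted anywhere downstream: every stage
reads f1 and the grid from the stimulus specification, and the constructor
rejects configurations whose harmonics would fall off the FFT grid
(`f1·duration` non-integral) or alias (`sample_rate ≤ 4·f1`).

## Synthetic screen generator

The generator exists so that every statistic the screen computes can be
checked against known ground truth. Per fly:

* photoreceptor amplitude: Naka–Rushton, `A1(c) = Rmax·cⁿ/(cⁿ + c50ⁿ)`
  with defaults Rmax = 10 µV, c50 = 0.3, n = 2 — a saturating CRF of the
  shape the empirical "best response at high contrast" rule presumes;
* lamina stage: static quadratic, `A2 = g_L·A1²` (default g_L = 0.05 /µV),
  the simplest nonlinearity that maps a pure fundamental into a pure
  second harmonic and therefore admits closed-form oracles;
* genotype: multiplicative gains per stage (`gain_P`, `gain_L`), with
  `synergy_P`/`synergy_L` multipliers applied only on the co-expression
  arm — the generative definition of epistasis the X/Y statistic targets;
* fly-to-fly variability: each positive parameter drawn lognormal with a
  common coefficient of variation (default cv = 0.3), matched in mean
  (`µ = ln m − σ²/2`). Phases are circular, not positive-scale, quantities
  and are carried over unchanged; cv = 0 reproduces the population means
  exactly. An option allows arm-specific cv (the co-expression arms of
  real screens are noticeably more variable), off by default;
* recording noise: additive white Gaussian on the voltage (default
  0.5 µV). No 1/f component is modelled.

Determinism: one design-level seed fans out through `SeedSequence` keyed by
(arm, Rab, fly index), so partial re-runs regenerate identical flies and
identical traces.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real recordings: phototransduction dynamics and
adaptation, phase drift within an epoch, line noise and movement artifacts,
higher harmonics, age-dependent degeneration (day-1 vs day-7 conditions are
represented only as different effect tables), and any correlation structure
between flies recorded on the same day.

## Analysis choices

* **Repeat averaging** is incoherent (mean of amplitude spectra): robust to
  phase drift between presentations. A coherent complex-mean mode exists
  behind a flag; it rewards phase locking and cancels drifting responses.
* **Noise floor**: mean amplitude of the k = 5 nearest bins on each side of
  the harmonic bin, excluding DC and all multiples of f1. SNR is
  amplitude/floor; a zero floor reports SNR 0 for a zero amplitude and
  infinity otherwise.
* **Best response** is the plain maximum of the empirical CRF, computed
  independently per harmonic; ties resolve to the lowest contrast. No
  model fit, no smoothing, and no SNR exclusion by default (an optional
  `min_snr` gate zeroes sub-threshold points before the maximum).
* **Aggregation**: mean ± SE (sample SD, n−1) and median ± IQR (linear
  interpolation). A single fly gets SE 0 by convention.
* **Spectrum fit**: unweighted OLS of Y on X with intercept; above/below
  classification by raw residual sign. A 1/se_Y² weighted mode exists
  behind a flag. Both harmonics are fitted and reported separately.
* **Enrichment**: Fisher's exact test on the 2×2 (annotation × above-line)
  table, two-sided by the probability-mass rule (sum of tables with the
  observed margins no more probable than the observed one; delegated to
  `scipy.stats.fisher_exact`, which implements exactly this rule, and
  cross-checked in the tests against rational hypergeometric enumeration).
  Degenerate tables (a zero margin) return p = 1. Odds ratio is ad/bc with
  ∞ for bc = 0 (ad > 0), 0 for ad = 0, NaN for 0/0.
* **Signaling regression**: the G2019S-induced increase in lamina signal
  (Δ best 2F1, co-expression minus rab-only arm) against the increase in
  photoreceptor signal (Δ best 1F1). The alternative reading of the
  x-axis — the co-expression arm's absolute 1F1 — is computable from the
  same summaries; the increase is used as the primary definition because
  it makes both axes measure the same contrast (the effect of adding
  G2019S).
* **Outlier rule**: for each Rab, an OLS line is fitted to the *other*
  points and the externally studentized residual
  `(y − ŷ)/(s·√(1 + h))` is compared with a threshold of 3 (configurable).
  The observed/predicted ratio ("how many times the expected value") is
  reported alongside; it is meaningful only when the prediction is
  substantially nonzero. A perfect leave-one-out line with a nonzero
  residual studentizes to ±∞ and is flagged; a degenerate leave-one-out
  fit (no x spread) leaves the point unflagged with a warning record.
* **ANOVA/Dunnett**: one-way ANOVA (F, df, p) plus Dunnett many-to-one
  comparisons against the shared control. Adjusted p-values are computed
  by seeded Monte-Carlo of the joint null (group means as independent
  normals with variance 1/n_g, pooled variance as χ²(df)/df, adjusted
  p = P(max|T| ≥ |t_obs|)), 10⁵ draws by default. With one comparison
  this reduces to the pooled two-sample t-test, and it agrees with
  `scipy.stats.dunnett` within Monte-Carlo tolerance — both are asserted
  in the tests.

## Reference recovery scenario

`recovery_screen_config()` freezes the screen used for end-to-end
validation: 23 Rabs × 4 arms, 10 flies/arm, 9 contrasts, 5 repeats,
cv = 0.15 (moderate variability), 0.5 µV recording noise. Planted
structure:

* **Rab10** — lamina-only synergy, `synergy_L = 8`: its co-expression
  lamina response is 8× what its photoreceptor signal predicts. Because
  the lamina stage is quadratic, *any* pure `synergy_L > 1` breaks the
  photoreceptor→lamina relation by construction, so Rab10 must be (and is
  designed to be) the unique signaling outlier.
* **Rab14, Rab27** — photoreceptor-driven synergy, `synergy_P = √6, √5`.
  Their lamina folds of 6 and 5 arise through the quadratic stage, keeping
  them *on* the signaling relation while giving them (with Rab10) the
  three largest positive lamina-spectrum residuals.
* **Rab3, Rab32, Rab1** — strong solo effects (photoreceptor gains
  1.8/1.6/1.5, lamina gains 2.0/1.8/1.6) with a mild co-expression ceiling
  (`synergy_P` 0.8/0.85/0.9). These populate the high-X end of the
  spectrum at or below zero Y and anchor the negative fitted slope —
  the inverse relationship between a Rab's solo effect and its G2019S
  synergy.
* the remaining 17 Rabs are null.

The expected read-out (asserted in the acceptance tests and recomputed by
`scripts/acceptance.py`): the three synergy Rabs carry the three largest
positive 2F1 spectrum residuals, the fitted slope is negative, and Rab10
is the only flagged outlier.

## Problem sizes

The validation suite scales simulations to desk size as its own design
choice: the reference screen runs at full protocol size (23 Rabs, 10
flies/arm, 9 contrasts × 5 repeats, 1 s epochs); null calibration of the
synergy coordinates uses 500 replicates of a reduced single-Rab design
(3 flies/arm, 3 contrasts, 0.25 s epochs); Dunnett family-wise calibration
uses 2000 null ANOVA runs at 2×10⁴ draws each, while accuracy-critical
Dunnett comparisons use 10⁵–4×10⁵ draws.

## Known limitations

* The quadratic lamina stage is a caricature: real lamina responses adapt,
  saturate and feed back; the generator's ground truth is exact only for
  the model class the analysis itself assumes.
* Incoherent amplitude averaging is positively biased at low SNR (a noise
  bin has nonzero mean amplitude); the screen statistics difference this
  bias away between arms but single-arm amplitudes carry it.
* The leave-one-out outlier rule studentizes against a homoscedastic
  residual scale, while amplitudes (and hence their errors) scale
  multiplicatively; very large responses are therefore easier to flag
  than equally discrepant small ones.
* Fisher enrichment on ~23 Rabs has limited power; a single reassignment
  can move p across 0.05.
* The shipped Rab annotation table is a synthetic placeholder for
  exercising the enrichment machinery (only the in-vitro phosphorylation
  set and one active-site residue reflect published biochemistry); it is
  not a curated resource.
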