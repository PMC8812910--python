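# Methods

This note documents the models, algorithms and numerical choices behind
`tripletmmn`: a simulation and analysis pipeline for statistical-learning
auditory oddball experiments in which a continuous stream of sound
triplets carries statistical (transition-probability), physical
(location) and combined deviants, presented either isochronously or with
randomly jittered stimulus-onset asynchronies (SOAs).

## Stimulus paradigm

Six sounds, labelled A–F, form four triplets: roots AB and CD (sounds
A–D), endings E and F. Ending identity follows the root with transition
probability 0.9 (high) or 0.1 (low); AB→E and CD→F are the frequent
continuations. Each sound comes from a *standard* or *deviant*
loudspeaker: roots are standard-sided with probability 0.95 (sampled
i.i.d., since no count structure is imposed on roots), endings with
probability 0.80. Crossing transition probability and ending location
gives four ending categories with occurrence probabilities

| category       | TP × location       | p    |
|----------------|---------------------|------|
| standard       | high × standard     | 0.72 |
| stat_deviant   | low × standard      | 0.08 |
| phys_deviant   | high × deviant      | 0.18 |
| double_deviant | low × deviant       | 0.02 |

**Quota construction.** A block realizes these probabilities *exactly*:
category counts are `n × p` (the configuration is rejected when any
product is non-integer), split across the two root families as evenly as
the counts allow under the constraint that each family contributes
exactly `n/2` triplets. At the canonical block size of 400 this gives
288/32/72/8 endings and 200 AB / 200 CD roots. Quotas (rather than
i.i.d. sampling) make the frequency contracts deterministic and testable
per block.

**Arrangement.** Triplets with low-probability endings (statistical and
double deviants) must be separated by at least three other triplets. The
arranger shuffles uniformly, then repairs violations by swapping an
offending low-probability triplet into a uniformly chosen admissible
position (bounded retries, then a fresh shuffle). The resulting
distribution over admissible orders is approximately but not exactly
uniform; the root-family transition probability after any ending remains
0.5 within ±0.02 empirically. Because roots are balanced and the
constraint touches only 10 % of triplets, no measurable sequential bias
is introduced.

**Timing.** Non-isochronous mode: 150 ms sounds, each followed by a
pause drawn uniformly from the 301 integer milliseconds 0–300, so the
SOA is uniform on {150, …, 450} ms with mean 300 ms. Isochronous mode:
220 ms sounds with a fixed 80 ms pause (constant 300 ms SOA). Onsets are
stored in milliseconds and snapped to the 500 Hz sample grid only when
EEG is synthesized.

**Cover task.** Target sounds are inserted between triplets at a
configurable rate (default 2/min — the experimental rate is not part of
the design specification) and elicit simulated button presses for a
configurable hit fraction (default 0.979) with lognormal latency
(median 450 ms). These exist to exercise the epoch-exclusion rules, not
to model behaviour.

**Familiarity test.** Twelve two-alternative trials per block: each of
the four pairings (high-probability triplet first or second, per root
family) occurs three times; with six trials per family, the
no-repeated-root constraint forces strict alternation, which is sampled
uniformly by shuffling within family and interleaving.

## Information-theoretic characterization

Surprisal `h = log2(1/p)` and entropy `H = Σ p log2(1/p)` are reported
in bits. For the default design: standard endings 0.15 bits, statistical
deviants 3.32 bits, conditional entropy of the ending 0.469 bits,
standard/deviant locations 0.32/2.32 bits; temporal entropy 0
(isochronous) vs `log2(301) = 8.23` bits (jittered). The pause set is
treated as 301 equiprobable integer values by construction of the
generator, so the temporal entropy statement is exact rather than an
estimate.

## Synthetic EEG

The montage has 59 scalp electrodes (10-10 system; the 51 electrodes of
the nine analysis ROIs plus a prefrontal row), two mastoids (left =
recording reference), four EOG channels, 500 Hz sampling. Recordings
emulate left-mastoid referencing: every stored channel is scalp minus
the M1 noise trace.

ERP ground truth is parametric: Gaussian kernels
`amp · exp(−(t−latency)²/2σ²)` with per-channel gain maps
(fronto-central maximum; the location MMN gets a slight left bias). No
volume-conduction model is attempted — the kernels exist to give the
downstream pipeline a known answer. Defaults (peak µV): N50 −1.5 at
50 ms, P130 +2 at 130 ms on every sound; sMMN −2 at 220 ms (σ 25 ms) on
low-probability endings; location MMN −2.5 at 170 ms (σ 20 ms) on
deviant-side endings; double deviants receive both, additively. MMN
amplitudes are multiplied by per-mode scale factors (default 1.0
isochronous; 0.15 / 0.6 non-isochronous for sMMN / location MMN),
encoding the empirical direction that temporal unpredictability
attenuates both mismatch responses. Absolute amplitudes are
order-of-magnitude ERP values and config-exposed; they are not fitted to
any dataset.

Background noise is spatially independent 1/f^α (default α = 1,
SD 8 µV), generated by spectral shaping of white noise in single
precision. Blinks are 400 ms raised cosines (peak 150 µV) on the
vertical EOG, propagated into frontal rows with decaying gain
(FP 0.4, AF 0.25, F 0.15, FC 0.08). All random draws are consumed in an
order independent of the kernel amplitudes, so recordings sharing a seed
differ only by the injected ERPs — the basis of the linearity and
parameter-recovery tests.

What the generator does **not** emulate: volume conduction and channel
covariance, non-stationary alpha/muscle artifacts, habituation or
learning dynamics across blocks, latency jitter of components, and any
behavioural strategy. Passing recovery tests therefore demonstrates that
the pipeline is algebraically and statistically sound, not that it would
be robust to every pathology of real recordings.

## Preprocessing

Order: mastoid-mean re-reference → 30 Hz low-pass FIR (2750 taps,
Blackman) → gliding-window rejection → epoching.

* **Re-reference**: with M1 as recording reference, subtracting half the
  stored M2 trace converts all channels to the (M1+M2)/2 reference;
  re-running is an error.
* **Filter**: the linear-phase design is applied forward and backward
  (via its autocorrelation kernel and a single real FFT), giving exact
  zero phase for any tap parity; the effective magnitude is the squared
  design (≪ −40 dB above 60 Hz, < 0.01 dB passband ripple below 25 Hz).
  FFTs run in the data's precision (float32 for synthetic recordings).
* **Rejection**: a sample is rejected iff it lies in ≥1 gliding-window
  position (200 ms *or* 800 ms, step one sample, any channel including
  EOG) whose within-channel SD (ddof = 1) exceeds 25 µV. Implemented as
  a single-pass running-sum kernel (numba) with float64 accumulators;
  rejection is monotone in the threshold by construction.
* **Epoching**: triplet-ending events only, −100–400 ms half-open on the
  2 ms grid (250 samples), 100 ms pre-stimulus baseline per channel.
  Exclusions, with precedence (each event counted once): (1) onset
  within 3 s after a target sound or button press, (2) any other
  stimulus onset closer than 200 ms, (3) overlap with rejected samples.
  "Acoustical deviants" in rule (1) is read as the cover-task targets
  (the rule exists to remove task-related activity); location deviants
  are ordinary epochs.
* **Bad channels**: visual inspection is replaced by an automated screen
  (flat channels, or overall SD above 5× the median channel SD); the
  synthetic generator produces none by default.
* **ROI averaging**: epochs are averaged per condition and block group,
  then over the electrodes of each of nine ROIs (frontal/central/
  parietal × left/middle/right).

## Statistics

Window means (sMMN 180–260 ms and 150–200 ms; location MMN 150–220 ms;
early negativity 0–100 ms; positivity 100–200 ms) are computed per
subject × condition × ROI, with the ROI axis re-expressed as scalp area
× lateralisation. Blocks 1–6 are grouped {1,2}/{3,4}/{5,6}.

The repeated-measures / mixed ANOVA is implemented from scratch for
balanced designs: effect cell deviations are obtained by Möbius
inversion over the marginal-means lattice (subject level ordered
grand < group < subject, with subjects nested in the between-subjects
isochronicity factor); each within effect is tested against its own
effect × subject(group) stratum; p-values come from the F distribution.
In balanced designs these sums of squares coincide with the
least-squares projection decomposition, which is exactly what the test
suite verifies against an independently written sequential-projection
oracle (and against `pingouin` for the designs it supports). Sums of
squares below 1e−12 of the total sum of squares are cleared so constant
strata yield F = 0 rather than 0/0.

Effect size: classical η² = SS_effect / SS_total (corrected) is the
headline value, with partial η² = SS/(SS+SS_error) alongside — reported
F/df pairs and η² magnitudes in this literature are consistent with the
classical definition, and the two variants bracket the plausible
choices. No sphericity correction is applied by default (integer
degrees of freedom are reported); tests are two-sided at α = 0.05.
The behavioural familiarity score is tested against chance 0.5 with a
one-sample t (Cohen's d = mean difference / SD; degenerate zero-variance
input returns t = d = 0 when exactly at chance).

## Validation studies and problem sizes

Because no human recordings accompany the design, the statistical claims
are validated by simulation:

* **Oracle agreement**: the ANOVA matches the projection oracle to 1e−8
  on random balanced designs up to 2×3×3×3 with and without a
  between-subjects factor.
* **Type-I calibration**: the deviance effect rejects at 0.03–0.07 over
  1000 null cohorts (n = 21, 2×3×3×3 cells, subject intercepts plus
  i.i.d. noise).
* **Parameter recovery**: 100 end-to-end simulations (n = 21, one
  50-triplet block per subject, default noise) recover the injected
  location-MMN window effect — predicted analytically from the kernel,
  gain map and mode scaling — within ±10 % on the across-simulation
  mean.
* **Interaction power**: 40 end-to-end simulations (n = 21 per group,
  two 50-triplet blocks per subject) with the sMMN injected only in the
  isochronous group detect the deviance × isochronicity interaction at
  α = 0.001 in ≥95 % of runs.

The reduced block counts (one or two blocks of 50 triplets, the smallest
size at which all category quotas are integers) are the package's chosen
study scale: they preserve the exact quota structure and every
preprocessing rule while keeping thousands of simulated subjects
tractable; block-group factors are dropped from the reduced-scale ANOVAs
(a single block group carries no variance).

Statistical deviants are rare (8 %), so the reduced trial count leaves
only ~5 surviving deviant epochs per subject where the full design has
~115; at the default 8 µV noise this would starve the interaction
contrast of the precision the full design affords. The interaction study
therefore scales the background noise SD to preserve the full design's
per-subject contrast standard error, `sd·√(1/n_dev + 1/n_std)`: matching
8 µV at (115, 1040) surviving epochs requires ≈1.7 µV at (5, 43). The
recovery study keeps the default 8 µV noise — its ±10 % criterion
concerns the across-simulation mean, whose precision comes from 2100
simulated subjects rather than per-subject trial counts.

## Degenerate inputs and tie-breaks

Non-integer quotas, odd block sizes, single-subject cohorts, unequal
group sizes, one-level factors, double re-referencing, records shorter
than the filter, and missing ROI electrodes raise errors naming the
offence. Odd per-category family splits assign the extra triplet to the
currently lighter family (AB on ties). Epoch windows are half-open;
sample indices are `round(onset/2 ms)`. A condition with zero surviving
epochs triggers a warning carrying the exclusion tallies.

## Known limitations

* The arranger's distribution over admissible orders is only
  approximately uniform.
* η² from the human studies cannot be reproduced (no data are
  deposited); the exact η² flavour used there is not determinable from
  the printed values, so effect sizes are validated structurally, not
  numerically.
* Mixed designs require equal group sizes; Greenhouse–Geisser correction
  is not implemented (dfs are reported uncorrected, matching the
  analysis convention the pipeline replicates).
* EDF+ export is not provided; raw output is BrainVision core format
  (read back via MNE).
* Bayesian repeated-measures ANOVA (Bayes factors) is out of scope.
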