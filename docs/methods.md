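# Methods

## Data model and conventions

A visual field is a vector of 52 total-deviation (TD) values in dB on the
Humphrey 24-2 grid after excluding the two blind-spot locations at
(15°, ±3°). Points are stored in printout scan order (superior to inferior
rows, left to right), right-eye orientation with nasal field at positive x;
left-eye fields are mirrored at ingest by reversing each row
(`mirror_td`). 30-2 exams are reduced to the 52 shared locations through a
coordinate-matched mask (`reduce_30_2`; the 30-2 grid holds 74 points after
blind-spot exclusion). Exams carry fixation-loss / false-positive /
false-negative percentages; reliability filtering uses strict `< 33%`
thresholds on all three, applied before any analysis and configurable.
Time is decimal years from the eye's first retained exam; dates are not
modelled. TD values live in the instrument range [−38, +5] dB, which is
also the fixed scaling window of the autoencoder, so trained models are
dataset-independent.

## Synthetic cohort generator

The generator emulates a progressing open-angle-glaucoma population at the
level of summary statistics: baseline mTD ~ Normal(−6.9, 6.3²) dB, eye
progression rate ~ Normal(−0.26, 0.46²) dB/year, ten exams at a mean
interval of 0.6 years (jittered ±20% to avoid collinear designs, ~5.4-year
follow-up). Reliability indices are truncated normals with means
4.9/3.7/2.9% (SDs 6.4/5.4/4.5) for FL/FP/FN.

Spatial structure comes from mixtures of three nerve-fiber-bundle
archetypes (superior arcuate, inferior arcuate, nasal step) drawn per eye
from a Dirichlet(0.8) prior; baseline damage is the archetype mixture
scaled to the drawn baseline mTD plus 1 dB of per-point jitter. A uniform
"diffuse" pattern is deliberately **not** a default archetype: focal loss is
what characterizes this disease, and keeping the true-field manifold
structured is what allows a denoiser to tell a genuine defect from a
diffuse exam-level fluctuation — with uniform fields on the manifold the
two are indistinguishable in principle. (`diffuse_archetype()` is available
for users modelling media opacity.)

Progression is linear in time, concentrated on the defect (per-point slope
share ∝ archetype loading plus a small diffuse floor). Fields are clamped
to [−38, +5] dB; after clamping, a small uniform correction restores the
eye-level mean, so the mTD trajectory stays linear (saturating only at the
range limits) while individual points saturate naturally. This keeps the
configured population parameters recoverable: at n = 2000 the noise-free
cohort reproduces the baseline and slope means within Monte-Carlo error.

### Noise model

Measurement noise has four components, each mirroring a documented source
of perimetric variability:

- **damage-dependent Gaussian noise**: per-point SD
  `min(6.0, 1.0 + 0.15·max(0, −td_true))` dB — damaged locations fluctuate
  more, saturating at 6 dB;
- **visit-level reliability factor**: a lognormal multiplier (log-SD 0.5,
  median 1) on all of that exam's SDs — attention and fatigue vary between
  visits;
- **whole-field shift per exam**: Normal(0, 1.5 dB), the classic long-term
  fluctuation;
- **response lapses**, spatially inconsistent with the rest of the field:
  with per-point probability 0.08 (scaled by the visit factor) a damaged
  point (true TD ≤ −10 dB) reads spuriously near-normal (uniform on
  [−5, +3] dB, the "trigger-happy" false positive), and with probability
  0.04 a healthy point (true TD ≥ −6 dB) drops by 8–20 dB (inattention
  false negative).

The last three components are essential, not decorative. Reciprocal-error
weighting can only help when noise level varies *across the exams of one
eye*, and an autoencoder can only flag an exam as unreliable if its errors
push the field off the manifold of plausible fields. Purely independent
per-point Gaussian noise fails both requirements — in particular, the
component of such noise that shifts the exam mean lies inside the span of
any learned manifold (overall field depth is always a latent direction), so
no autoencoder trained on noisy fields can correct it; we verified this
directly (the correlation between reconstruction-based and true mean-error
is ≈ 0 under iid noise). Asymmetric lapses and coherent visit effects are
what real unreliable exams look like, and they are detectable.

Randomness uses named substreams (structure / noise / reliability) keyed by
`(seed, stream, eye)`, so changing the noise model leaves the true fields
bit-identical, and the whole generator is deterministic per (config, seed).

What the generator does **not** emulate: staircase psychophysics (SITA),
learning and fatigue trends across visits, cataract progression, floor
effects of pattern deviation, spatial correlation of the *noise* (only the
signal is spatially structured). Passing tests on these cohorts therefore
demonstrates internal consistency of the method under a plausible noise
model, not clinical performance.

## The autoencoder

Architecture: input 52 → hidden 38 → hidden 26 (rectified-linear) → 8-D
diagonal-Gaussian latent (mean and log-variance heads) → mirrored decoder
26 → 38 → 52 with a logistic output layer, operating on TD scaled to
[0, 1] via the fixed window [−38, +5] dB. Training minimizes per-element
mean squared reconstruction error (a binary-cross-entropy option exists)
with one reparameterized latent sample per field, plus `kl_weight` times
the closed-form KL divergence from the standard-normal prior, by Adam
(learning rate 3·10⁻³, batch 64, 150 epochs, ~3 s for 2000 fields on one
core). The implementation is plain numpy — forward pass, backpropagation
and Adam are a few hundred lines for a network this small — and training is
bit-reproducible under the seed, which matters because downstream weights
must be reproducible. Gradients are unit-tested against central finite
differences. A non-finite loss aborts with a diagnostic.

`kl_weight` is the one genuinely consequential hyperparameter. With the
reconstruction term a per-element mean, the Gaussian-likelihood-equivalent
weight is `2σ²/52` for observation noise σ on the scaled values; the
default 10⁻³ corresponds to the ~5–7 dB per-point SD of damaged regions.
Orders of magnitude larger collapses the 8-D posterior onto the prior
(reconstructions degenerate to the cohort mean); orders of magnitude
smaller leaves spare latent capacity that learns the highest-variance
*noise* direction (the visit-level shift) instead of field structure. Both
failure modes were mapped empirically on held-out diagnostic cohorts.

Inference decodes from the posterior mean — no sampling — so TD_VAE,
mTD_VAE and all derived weights are deterministic. Models serialize to a
self-describing JSON container (config, weights, loss history) that
round-trips bit-exactly.

## Weighted trend statistics

`weighted_fit` minimizes Σ wᵢ(yᵢ − a − b·tᵢ)² in closed form (vectorized
normal equations; statsmodels WLS is the test oracle, not the
implementation) with the slope p-value from the t-distribution on n − 2
degrees of freedom; equal weights reproduce OLS exactly, and exact fits
(zero residual variance) are assigned p = 0 for a nonzero slope and the
symmetric p (1 two-sided, 0.5 one-sided) for a zero slope.

Weights are reciprocal absolute reconstruction differences, floored at ε:
per exam (|mTD − mTD_VAE|) for the mTD trend, per exam-and-point
(|TD − TD_VAE|) for pointwise PLR. The `WeightScheme` default is
ε = 0.01 dB; the experiment pipeline uses ε = 0.25 dB at the exam level,
for a methodological reason worth stating: the floor must sit near the
noise floor of the quantity being compared. An exam whose reconstruction
happens to agree to 0.01 dB is not 25× more trustworthy than one agreeing
to 0.25 dB — mTD itself cannot be measured that precisely — and with a
tiny floor a single chance-perfect exam receives enormous weight and
dominates the fit, *adding* variance instead of removing it.

Pointwise PLR uses one-sided deterioration p-values, P(slope < observed |
no change): under the null these are uniform, which the binomial argument
requires (a two-sided option exists). The binomial PLR counts locations
with p strictly below each cutoff (0.025, 0.05, 0.075, 0.1), computes the
exact Binomial(52, c) upper tail — no normal approximation; 52 trials is
cheap — and summarizes the four tail probabilities by their median, defined
as the mean of the two middle order statistics; the field is called
progressing when this median is below 0.025. The mTD-trend call is
slope < 0 with two-sided p < 0.05. Both rules are configurable.

## Evaluation framework

The full 10-exam series is the surrogate truth. For each truncation
VF1-k (k = 3..9) and each method:

- **PBP** = #(full significant ∧ truncated significant) / #(full
  significant) — true-positive surrogate;
- **PBNP** = #(full not ∧ truncated not) / #(full not) — true-negative
  surrogate;
- **PIP** = #(truncated significant ∧ full not) / #(truncated
  significant) — false-positive surrogate.

Denominators are reported alongside every proportion; 0/0 is reported as
missing rather than coerced. These denominators are a design choice (the
proportions could be defined against other margins); they are chosen so PBP
/ PBNP track sensitivity / specificity against the full-series call while
PIP can be small even when few truncated calls are made.

Prediction error is the mean over eyes of the squared difference between
the extrapolated trend at the final exam's date and the observed final
mTD. Method comparisons across the seven truncation lengths use the exact
two-sided Wilcoxon signed-rank test (zeros dropped; all-tied input reports
p = 1). Time to first detection scans truncations in order — a non-monotone
call pattern counts at its first significant call — with never-detected
eyes censored at ten exams; survival uses the Kaplan-Meier product-limit
estimator and the standard 1-df logrank test (via lifelines, cross-checked
against risk-set enumeration in the tests). The survival timescale is exam
count; years are recoverable from the series.

## Experiments and problem sizes

The two built-in experiments run from one `ExperimentConfig`: the VAE is
always trained on a generator substream disjoint from the evaluation
cohort (a train-hospital / test-hospital split). Default sizes — 2000
training fields (200 eyes × 10 exams), 500 evaluation eyes, 104
test-retest pairs, 2000 null eyes for the type-I check — keep the full
suite plus acceptance script under two minutes on one core while leaving
Monte-Carlo error well below the effect sizes of interest. Reports carry a
hash of the resolved configuration, and identical configs produce
byte-identical reports.

## Known limitations

- The exam-level weighting benefit depends on the trained network's
  reconstruction quality. Across replicate experiment seeds the weighted
  mTD trend lowers final-exam prediction MSE by 6–14% on average and is at
  least as accurate at every truncation length in most replicates, but
  occasional training realizations yield exam weights too noisy to help
  (observed in 1 of 8 replicates). The pointwise (PLR) weights, which
  average over 52 locations, are more stable.
- The VAE corrects only the off-manifold part of an exam's error; the
  fraction of the *mean* error it recovers is modest (~10–15% at default
  noise), enough for a clearly significant test-retest relationship at 104
  pairs but far from an efficient estimator of exam quality.
- Archetype mixtures span a low-dimensional defect space; real fields are
  more varied, and the 8-D latent would be proportionally more strained on
  clinical data.
- The binomial PLR's independence assumption is violated by spatially
  correlated noise; the generator's noise is point-independent apart from
  the visit-level components, so the type-I calibration shown here is a
  best case.
- Proportions and survival are computed per eye; no between-eye or
  within-patient correlation is modelled.
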