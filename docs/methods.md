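# Methods

## The design being modeled

A two-part forced-choice emotion recognition experiment with point-light
face stimuli. Each stimulus is a 2500 ms animation of 68 facial landmarks
(600 × 800 px canvas, face ≈ 200 × 250 px), one per (actor, expression)
pair over the six basic expressions; a session is one viewing plus one
forced choice among the six labels and a 1–7 confidence rating. In part 1
the whole face is visible; in part 2 only a small aperture around the
mouse cursor is, so the cursor trajectory operationalizes *conscious*
observational behavior. Participants also carry Big-Five scores (TIPI-type
inventory, item-pair means on a continuous 1–7 scale).

## Preprocessing: traces → band weights

Cursor samples are translated from screen to video coordinates by
subtracting the stimulus origin. Each in-canvas sample deposits an
isotropic Gaussian kernel (σ = 10 px, truncated at 4σ, discretely
normalized to unit mass) on a 1-px grid; the per-session map is the sum
over samples (each sample contributes equal mass — no time-interval
weighting by default). The face box is the union over frames of the
landmark bounding box (fixed within a session), split into three
horizontal bands with heights in proportion 1 : 0.8 : 0.6; a grid cell
belongs to the band containing its centre row. The band weight is the
band's share of *total* accumulated mass, so the triple lies in [0, 1]
with sum ≤ 1 and the remainder is reported as `out_of_bbox_fraction`
(mass conservation holds to 1e−6 by construction). Normalizing by total
mass (rather than leaving raw accumulated mass) is a deliberate choice:
the zero-inflated beta model needs G ∈ [0, 1), and the raw mass is still
emitted (`raw_mass_total`) for inspection.

## The three models

All models are fit separately per presented-expression condition,
mirroring how such results are tabulated.

**Choice likelihood.** The six candidate responses are independent
Bernoulli indicators y_k with logit p_k = α_k + x·β_k + r_subj + r_stim —
deliberately *not* a softmax; the independent-Bernoulli product is the
model as written, and a categorical variant exists only behind a flag for
sensitivity analysis. Predictors x are the band-weight triple (variant A)
or the five raw, uncentered 1–7 trait scores (variant B). Random effects
are one per (participant × response) and (stimulus × response), each
normal(0, scale) with a single scale per family.

**Zero-inflated beta.** Band weight G is 0 with probability 1 − q, else
Beta(a, b) with a = φμ, b = φ(1 − μ) (so a + b = φ and E[Beta] = μ);
logit q and logit μ are linear in the traits with their own random-effect
families. q is explicitly the probability of a *nonzero* observation. φ is
shared across the three bands by default.

**Priors.** normal(0, sd 10) on intercepts and fixed effects (sd 10 ≡
variance 100, so all three analyses share it); gamma(shape 10, rate 10) on
every random-effect scale (mode 0.9, concentrating scales near 1);
gamma(shape 2, rate 0.1) on φ — weakly informative with positive support,
a choice this package makes since no φ prior is otherwise determined.

## Inference

No probabilistic-programming backend is required: both log-posteriors are
implemented with analytic gradients (the Beta block uses digamma terms)
on an unconstrained scale — non-centered random effects (r = s·z),
log-transformed scales and φ with Jacobians folded in. The sampler is
adaptive Hamiltonian Monte Carlo: leapfrog integration with the step
count jittered uniformly in 1..32, dual-averaging step-size adaptation to
a 0.85 target acceptance rate, and a diagonal mass matrix re-estimated
from warmup draws in two windows (closing at 45% and 85% of warmup, with
Stan-style regularization toward a small constant). Non-finite or
out-of-range states (|θ| > 1e3) are treated as divergent and rejected;
initialization retries up to 10 times from small random starts. Chains are
seeded independently via `SeedSequence.spawn`, making runs bit-for-bit
reproducible for a fixed seed.

The default schedule is 4 chains × 2000 iterations with the first 1000
discarded as warmup — "iterations" counts warmup plus retained, which is
the reading consistent with a retained total of 4000 draws.

**Diagnostics and significance.** Split R̂ splits each chain in half and
compares between- to within-half variance; ≤ 1.1 is treated as converged,
and an unconverged fit warns (and is flagged in the CLI convergence
report) but is never silently dropped. Note the plain estimator can dip
slightly below 1 (exact floor √((n−1)/n)). HDIs are the shortest
contiguous window holding ⌈0.95·n⌉ sorted draws, pooled across chains,
ties broken toward the lowest lower bound; a coefficient is significant
iff its HDI strictly excludes 0 (0 on the boundary counts as included).
Random effects are monitored for convergence but excluded from
significance tables.

## Synthetic data generator

The generator emulates the study conditions, not any particular dataset:

- **Traits**: independent truncated normal(4, 1.2) on [1, 7] per trait
  (a conventional choice — trait-score distributions are not otherwise
  specified); profiles carry final scores, not items.
- **Stimuli**: a fixed 68-point neutral template (17 jaw, 2 × 5 brow,
  9 nose, 2 × 6 eye, 20 mouth points) with per-expression displacement
  fields ramped smoothly after a 500 ms neutral onset; mouth-opening
  motion for happiness/surprise/fear, brow motion for
  anger/sadness/disgust. Actor identity is a small rigid shift/scale
  perturbation. Geometry and timing envelope are what matter downstream;
  no visual realism is attempted.
- **Band weights** are drawn from the zero-inflated beta law itself.
  Because the three bands are independent in that law, a draw can sum
  above 1; such draws are proportionally rescaled onto the simplex (a
  cursor trace must realize them as dwell fractions). The raw-law sampler
  is exposed separately for distributional tests.
- **Choices** come from the choice models with the six Bernoulli
  probabilities normalized to a categorical draw (participants pick
  exactly one label); the unnormalized form remains the likelihood.
  Confidence is uniform 1–7 noise and is never modeled.
- **Cursor traces** invert preprocessing: samples dwell at band centres in
  proportion to the target weights (2 px jitter, 20 ms sampling over
  2500 ms), leftover mass dwelling > 4σ outside the face box, so
  preprocessing recovers the generating triple within L1 ≤ 0.05.
- **Default ground truth**: per condition, the correct response gets an
  intercept advantage (±1 around a predictor-centred baseline) and one
  sparse moderate fixed effect per block — ±1.0–1.5 on band weights,
  ±0.35–0.5 on traits, ±0.08–0.25 in the ZIB blocks, φ = 10, random-effect
  scales 0.3 — magnitudes on the order such studies report.

What the generator does *not* emulate: real landmark kinematics, serial
dependence within cursor traces (dwell points are i.i.d. around band
centres), confidence that carries signal, or trait correlations. Passing
tests therefore demonstrate correctness of the pipeline and calibration of
the inference under the stated generative laws — not conclusions about
human data.

## Validation results computed by the suite

- A 20-participant × 48-session simulated experiment fit under the full
  schedule keeps max split R̂ ≤ 1.1 over all monitored coefficients in all
  six conditions (the acceptance script recomputes this; typical values
  ≈ 1.005).
- Parameter-recovery smoke (5 replicates × 12 participants, one condition,
  reduced 2 × 800 schedule): 95% HDI coverage of the generating fixed
  effects within binomial 3σ of 0.95; with all-zero fixed effects the
  flagged fraction stays within 3σ of 5%. The band-weight predictors are
  compositional (near-collinear with the intercept), so individual-cell
  point estimates can trade off against each other while intervals remain
  calibrated — a property of the design, visible in wide HDIs.
- HDI equals exhaustive window search; split R̂ matches an independent
  transcription to 1e−10; the ZIB density integrates to 1 to 1e−8; the
  trajectory → preprocessing round trip closes to L1 ≤ 0.05.

Problem sizes in the default test runs (small studies, reduced schedules
for unit tests, the 20 × 48 study for convergence) are the package's
validation scale; larger studies run with the same code paths.

## Known limitations

- Fixed-length jittered HMC trajectories (no NUTS); adequate for these
  posteriors but less efficient near strong funnels than dynamic
  trajectory lengths would be.
- The independent-Bernoulli choice likelihood is intentionally faithful to
  the model definition; its probabilities need not sum to 1, which is why
  reports normalize per draw before comparing against the 1/6 chance line.
- Pixel-level quadrature of band masses assigns whole cells by centre row;
  sub-pixel band boundaries are resolved at 1 px granularity.
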