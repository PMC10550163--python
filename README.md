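# facetrait

Hierarchical Bayesian analysis of how Big-Five personality traits and
*conscious observational behavior* — where people deliberately choose to
look on a face — shape recognition of facial expressions represented by a
sparse set of 68 landmarks.

The experimental setting: participants watch short point-light face videos
(68 Dlib-style landmarks per frame, six basic expressions — happiness,
sadness, anger, disgust, surprise, fear — acted by several actors) and make
a forced choice among the six labels. In a restricted-viewing part, only a
small aperture around the mouse cursor is visible, so the cursor trace
records which face regions the participant deliberately inspected.
`facetrait` implements the full analysis pipeline for this design and a
synthetic-data generator that emulates it end to end, so every stage is
testable with known ground truth.

## Models

Cursor traces are converted into attention weights over three horizontal
face bands (heights upper : middle : low = 1 : 0.8 : 0.6): each sample
deposits a unit-mass Gaussian (σ = 10 px), and the band weight
G<sub>g</sub> is that band's share of the session's accumulated density.

**Choice models.** For participant *i*, stimulus *j*, each candidate
response *k* carries an independent Bernoulli indicator y<sub>k</sub>
(1 iff chosen) with

  logit P(y<sub>k</sub> = 1) = α<sub>k</sub> + Σ<sub>g</sub> G<sub>ijg</sub> β<sub>kg</sub> + r<sub>ik</sub><sup>subj</sup> + r<sub>jk</sub><sup>stim</sup>

using the three band weights as predictors (variant A, restricted-viewing
part), or the five trait scores P<sub>ip</sub> in place of G (variant B).

**Behavior model.** Each band weight follows a zero-inflated beta law:
zero with probability 1 − q, else Beta(φμ, φ(1−μ)), with logit(q) and
logit(μ) linear in the five traits plus participant and stimulus random
effects.

Priors are weakly informative — normal(0, sd 10) on fixed effects,
gamma(10, 10) on random-effect scales, gamma(2, 0.1) on φ. Models are fit
separately per presented expression by an in-package adaptive Hamiltonian
Monte Carlo sampler (analytic gradients, dual-averaging step size,
diagonal mass adaptation); the default schedule is 4 chains × 2000
iterations with 1000 warmup, retaining 4000 draws. Convergence is checked
with split R̂ (≤ 1.1), and a coefficient is *significant* when its 95%
highest-density interval excludes 0.

Everything is exposed as scikit-learn-style estimators
(`BayesianChoiceModel`, `ZeroInflatedBetaModel`, `CursorWeightExtractor`)
plus thin functional wrappers, and as a CLI
(`facetrait simulate|preprocess|fit|report`).

## Worked example

```python
import facetrait as ft

study = ft.simulate_study(n_participants=20, seed=42, parts=(1,))
fits = ft.fit_choice_models(
    study.trials, study.participants_frame, "B",
    conditions=("happiness",), part=1, seed=0,
)
m = fits["happiness"]
print("max split R-hat:", round(m.rhat_max_, 3), "| draws:", m.draws_.total_draws)
print(m.summary_[m.summary_["Significant"]])
sweep = ft.trait_sweep(m.draws_, "happiness", "agreeableness")
print(sweep[sweep["response"] == "happiness"])
```

prints (abridged):

```
max split R-hat: 1.021 | draws: 4000
Expression Response         Predictor   Mean  HDI_low  HDI_high
 happiness    anger conscientiousness -0.771   -1.444    -0.092
 trait_value  mean  hdi_low  hdi_high
           1 0.016      0.0     0.077
           4 0.040      0.0     0.180
           7 0.091      0.0     0.311
```

The sampler converged (R̂ well below 1.1) with the full 4 × 1000 retained
draws. The significance table flags the generating negative
conscientiousness → "answer anger" effect (truth −0.35; the posterior mean
−0.77 sits in a wide HDI at this sample size), and the agreeableness sweep
shows the probability of answering *happiness* rising monotonically as the
swept trait goes 1 → 7 with the other four traits pinned at 0 —
exactly the generating positive agreeableness effect.

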