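# pausekit

Automated pause and fluency analysis for connected speech, aimed at the
clinical profiling of primary progressive aphasia (PPA).

Fluency — continuity, rate and effort of speech — separates the nonfluent
variant of PPA (nfvPPA) from the semantic variant (svPPA) and from healthy
speakers, and it is observable directly in audio: lack of fluency produces
silent pauses.  `pausekit` turns a speech/non-speech segmentation of a
narration (from its own energy-based voice activity detector, a Praat
TextGrid, or an interval CSV) into a quantitative fluency profile and a set
of statistical comparisons between speaker groups.

## The models at the core

**Pause durations.**  A *pause* is a non-speech run of at least 50 ms.  On a
cohort of narrations, pause durations are bimodal and are modelled as a
two-component Gaussian mixture: a short-pause class (breathing-scale
interruptions) and a long-pause class (cognitive/discourse pauses), each
component with mean, SD and mixing weight λ.  Because every observed
duration is floored at 50 ms, the EM fit models each component as a
left-truncated Gaussian.  The data-driven boundary between the classes is
the duration *c* where the weighted component densities intersect,

    λ_s · N(c; μ_s, σ_s) = λ_l · N(c; μ_l, σ_l),   μ_s < c < μ_l,

solved by bracketed root finding.  With the published control-group
component parameters this lands at ≈ 304 ms, matching the reported ≈ 293 ms
boundary for Dutch within the rounding of the printed parameters.

**Pause rates.**  The number of pauses per 20-second fragment is
overdispersed count data, modelled as Gamma-Poisson (negative binomial) with
mean μ and dispersion β (variance μ + μ²/β).  Group-specific log μ and a
shared β are estimated by adaptive random-walk Metropolis MCMC under
weakly-informative priors; group contrasts are judged by whether the 89%
highest-density interval (HDI) of μ_A − μ_B excludes zero.  A Bayesian
multinomial-logit classifier (MAP with Normal(0, 2.5) coefficient priors)
predicts the speaker group of a single 20-s fragment from its fluency
features.

**Fluency variables** per narration: locution time (total duration),
phonation time (Σ speech), proportion of silence (Σ pause / locution),
pause rate (pauses per second of phonation), and average pause length
(silence / number of pauses).  The group battery includes one-way ANOVA with
Tukey HSD contrasts, a Bray–Curtis PERMANOVA confirmation, Kruskal–Wallis,
and ICC1 to check independence of repeated samples per speaker.

Because clinical recordings are private, the package ships a first-class
synthetic-cohort generator whose defaults are the published group
parameters (three groups, component mixtures, Gamma-Poisson rates), so the
entire pipeline is testable end to end — including audio rendering and the
voice activity detector — without any recording.

## Worked example

```python
import pausekit as pk

profiles = pk.default_group_profiles()

# the short/long pause boundary from the control group's components
cutoff = pk.pause_cutoff(profiles["control"].short, profiles["control"].long)
print(f"cutoff = {cutoff:.2f} ms")

# effect size between the control and nfvPPA short-pause components
cmp = pk.compare_components(profiles["control"].short,
                            profiles["nfvPPA"].short, n=1000, seed=0)
print(f"d = {cmp.cohens_d:.3f}, t = {cmp.t_statistic:.2f}")

# recover the mixture from 5000 synthetic control pauses
durations = pk.sample_pause_durations(profiles["control"], 5000, seed=1)
fit = pk.fit_pause_mixture(durations, seed=0)
print(fit.summary())
```

prints

```
cutoff = 303.74 ms
d = -0.633, t = -14.16
PauseMixtureResults: k=2, domain=linear_ms, n=5000, floor=50.0 ms
  loglik=-36521.692  BIC=73085.969  converged=True (150 iterations)
  short: mean=   163.633  sd=   93.596  lambda=0.308
   long: mean=   787.916  sd=  485.004  lambda=0.692
  cutoff = 315.1 ms
```

The cutoff of 303.74 ms is the density intersection of the published
control components; the negative d and t say the nfvPPA short-pause
component sits ~0.6 pooled SDs above the control one (longer short pauses).
The fitted mixture recovers the generating means (165.22/759.97 ms) and the
long-pause weight (0.71) from the synthetic draws, and its own data-driven
cutoff lands nearby.

The full pipeline — synthesis, segmentation, metrics, mixture, rate model,
classifier — runs from the shell:

```bash
pausekit --seed 42 --out-dir run run
pausekit --out-dir run report
```

writing `metrics.csv`, `mixture.json`, `counts.csv`, `contrasts.csv`,
`report.json` and a reproducibility `manifest.json` into `run/`.

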