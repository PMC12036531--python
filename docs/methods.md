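# Methods

This note documents the models implemented in `pausekit`, the choices made
where the design was genuinely open, and what the synthetic data can and
cannot establish.

## Segmentation and pause extraction

Time is measured in seconds on a 0-based half-open `[start, end)` axis;
pause durations are reported in milliseconds.  A pause is a contiguous
non-speech interval of at least 50 ms; shorter silent gaps are treated as
articulatory and merged into the surrounding speech.  A symmetric 50 ms
floor is applied to speech runs (merged into the surrounding silence), with
short pauses absorbed first when both floors could apply.

The voice activity detector computes frame log-energies over 25 ms windows
centred on 10 ms hop slots.  By default the decision threshold is
`max(Q95(log E) − 3 dB, −60 dBFS)`.  The 3 dB margin below the speech level
makes the threshold cross exactly where half the analysis window is speech,
so interval boundaries are recovered essentially unbiased (≤ 1 hop) on
clean input; the absolute −60 dBFS floor keeps silence-only input from
being promoted to speech.  A plain quantile threshold
(`threshold_quantile`) is also available, but note that a fixed quantile
can only sit in the gap between the silence and speech energy clusters if
it matches the file's silence fraction — which varies from ~5% to ~60%
across speaker groups — so the level-anchored default is more robust.  An
optional hangover keeps the speech label alive for a configurable time
after the last supra-threshold frame (default 0 ms; useful for real
recordings with trailing voicing energy).  Frame/hop sizes and the margin
are configurable; the values above are conventional, not estimated.

Narrations are cut into non-overlapping, left-aligned 20-second fragments;
intervals straddling a cut are split, and a trailing short fragment is kept
but flagged partial.

## Fluency variables

Per narration or fragment: locution time (total duration), phonation time
(sum of speech intervals), silence time, pause count, proportion of silence
(silence / locution), pause rate, and average pause length
(silence / pause count, NaN — not zero — when there are no pauses).  The
pause-rate denominator is phonation time by default; locution time is
available as an option since usage varies between studies.

The group battery: one-way ANOVA with Tukey HSD 95% contrasts (optional
Bonferroni adjustment on top), a PERMANOVA on squared Bray–Curtis distances
as a normality-free confirmation (add-one permutation p-value
`(1 + #{F* ≥ F}) / (1 + n_perm)`; an exhaustive mode enumerates all
distinct label assignments on small designs), Kruskal–Wallis with tie
correction (H = 0 returned for fully tied data), and ICC1 from one-way
variance components with the unbalanced group-size correction
`n0 = (N − Σn_i²/N)/(k − 1)`, truncated at zero and clamped to [0, 1].

## Pause-duration mixture

Durations are modelled as a k = 2 Gaussian mixture.  Because the extraction
floor censors everything below 50 ms, each component is modelled as a
left-truncated Gaussian: the E-step uses truncated component densities and
the M-step matches responsibility-weighted sample moments to
truncated-normal moments.  This M-step is exact maximum likelihood — the
truncated normal is an exponential family in (x, x²), so moment matching
solves the score equations — and reduces to a single monotone 1-D root
problem in the standardised truncation point α, solved by bracketed root
finding.  If the unconstrained update would push a component mean below
zero (a component degenerating into a pure tail), the M-step switches to a
constrained maximiser on the boundary (mean pinned, scale profiled), which
keeps the log-likelihood monotone.

Fitting runs in the linear-millisecond domain by default.  A log10 domain
is offered, but the recovery target is linear: the printed per-group
component tables are in milliseconds, and the log of a 50 ms-truncated
linear mixture is *not* a Gaussian mixture with the same weights — fitting
Gaussians on the log scale shifts the long-component weight from 0.71 to
≈ 0.57 on control-parameter draws and moves the density-intersection
boundary by > 100 ms.  Linear truncated EM recovers the generating means
within ~3% and the weight within ±0.03 at n = 5000.

Restarts: one k-quantile initialisation plus random initialisations
(default 8 starts), best final log-likelihood kept; convergence when the
log-likelihood improves by less than 1e-8; BIC (−2 LL + (3k−1) ln n) for
comparing component counts, which prefers k = 2 on two-component data.
Raw (unbinned) durations are used throughout; histogram binning is
presentation only.

The short/long boundary is the root of
`λ_s N(x; μ_s, σ_s) = λ_l N(x; μ_l, σ_l)` strictly between the component
means, located to 0.01 ms.  If the weighted densities do not cross between
the means (e.g., one weight near zero, or one broad component dominating
throughout) a no-crossing error is raised rather than returning an
extrapolated value.  Durations exactly at the boundary are classed *long*
(the boundary is where the long component's density starts to exceed).
Component-level effect sizes are Monte-Carlo: n samples per side from each
component Gaussian, Welch's t with Welch–Satterthwaite df, Cohen's d with
pooled SD `sqrt((s_a² + s_b²)/2)`.

## Pause-rate model

Counts per fragment follow a Gamma-Poisson law with mean μ and dispersion
β, variance μ + μ²/β (β → ∞ recovers Poisson).  For each pause class
(short/long), the linear predictor is `log μ_i = a_g` with group-specific
intercepts and one shared β; optional centred covariates add the fragment's
silence, its average pause length, and their interaction on the log scale
(the link and centering are our interpretation; the source analysis does
not pin them down).  Priors: `log μ ~ Normal(log 5, 1.5)`,
`β ~ Exponential(0.1)`, covariate coefficients `Normal(0, 1)` — weakly
informative on the scale of a 20-s fragment.

Sampling is componentwise adaptive random-walk Metropolis on
log-transformed parameters, proposal scales adapted every 50 warmup
iterations toward a 30–45% acceptance window; 2 chains × 4000 iterations
(half warmup) by default.  Gelman–Rubin R̂ and effective sample size are
computed with ArviZ, with a warning when R̂ exceeds 1.01.  An off-the-shelf
HMC sampler would mix faster per iteration; the random-walk sampler keeps
the dependency footprint small and is fully adequate for these
few-parameter posteriors.

The HDI is the shortest contiguous window containing ⌈mass·n⌉ sorted
draws (default mass 0.89).  Group contrasts are the elementwise difference
of matched posterior μ draws; a difference "excludes zero" when its HDI
does.  Per-group HDI overlap can be read from the posterior summary as the
alternative decision rule, but the difference-HDI is primary since it is
the quantity plotted and interpreted.  The posterior predictive check
simulates replicate count sets from posterior draws and scores the total
variation distance between observed and predicted count pmfs per group.

The speaker-group classifier is a multinomial logit over standardised
fragment features (silence proportion, pause rate, counts, average pause
length, short/long counts) with Normal(0, 2.5) coefficient priors and the
first class as zero-fixed reference, estimated at the MAP (equivalent to an
L2-penalised multinomial regression) for speed; evaluation uses
speaker-grouped cross-validation so accuracy reflects unseen speakers.

## Synthetic cohorts

The generator emulates the assumed data structure: three groups (control,
nfvPPA, svPPA) with published component parameters read as linear-ms
Gaussians (the component table's SDs are clearly millisecond-scale, so the
linear reading is the only self-consistent one); per-fragment pause counts
Gamma-Poisson with `rate_mu` = published per-second pause rate × 20 s
(0.23/0.40/0.41 s⁻¹ → 4.6/8.0/8.2 per fragment) and `rate_beta = 10`
(mild overdispersion; no published value exists).  Durations are sampled by
choosing a component by its weight and redrawing *within* that component
until ≥ 50 ms, so membership fractions equal the nominal weights and each
component is exactly a left-truncated Gaussian — the model the EM fits.
Speech runs between pauses are uniform random splits of the remaining time
(nothing is assumed about speech-run lengths); fragments sum to exactly
20 s, with resampling when sampled pauses would exceed 95% of the fragment.
Audio rendering uses band-limited (300–3400 Hz) noise at a reference level
for speech and 30 dB lower for pauses.  Cohort defaults mirror the study
design (14/7/8 speakers); per-speaker streams are spawned from the master
seed, so cohorts are bit-reproducible.

What the synthetic data does *not* emulate: filled pauses (uh/uhm),
interviewer turns, per-speaker random effects (fragments are i.i.d. within
a group), fricative-induced VAD bias, and any lexical content.  Passing
tests therefore demonstrate correct recovery of the assumed generative
structure, not robustness to real conversational audio.

One consequence of generating strictly from the published group-level
parameters is worth stating plainly: the implied *short*-pause rates per
fragment differ between groups (control ≈ 1.6, nfvPPA ≈ 1.1, svPPA ≈ 1.5,
after applying the ~300 ms boundary to each group's truncated mixture),
because the groups' mixing weights and duration distributions differ while
the published per-second pause rates are similar.  On cohorts of the
study's size this control-vs-nfvPPA short-rate difference is about two
posterior standard errors, so the original finding of *no* short-pause
rate difference between groups is not reproduced by cohorts synthesised
from the printed parameters — the printed group parameters do not jointly
encode that equality.  The long-pause contrasts (patients ≫ controls)
reproduce robustly.

## Problem sizes used in the shipped analyses

Mixture recovery uses 5000 draws; component contrasts use 1000 per side
averaged over 20 seeds; the reference synthetic cohort is 14/7/8 speakers
× 5 fragments (≈ 100 s of narration per speaker, matching the published
mean locution time); the rate model runs 2 chains × 4000 iterations.
These sizes give Monte-Carlo error comfortably below the tolerances being
checked while keeping a full run in tens of seconds.

## Known limitations

- The energy VAD assumes a stationary noise floor; it has no model of
  fricatives, breath noise or channel variation.
- The truncated-mixture EM can be weakly identified when components
  overlap heavily and one weight is small (svPPA-like data at small n);
  restarts mitigate but do not eliminate this.
- The rate model treats fragments as exchangeable within group; speaker
  random effects are deliberately out of scope (the ICC1 check is the
  supporting evidence for that simplification).
- MAP classification ignores posterior uncertainty in the classifier
  coefficients; class probabilities are point estimates.
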