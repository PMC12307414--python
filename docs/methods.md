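# Methods

## Task model

Each block of the two-armed bandit has one hidden correct option for its
whole duration (no reversals). The correct option yields a good outcome with
probability 0.70 per trial, the wrong option with 0.30. Outcomes are coded
1 = good, 0 = bad in both block types; points follow from the block type
(gain: good → +1,000, bad → 0; loss: good → 0, bad → −1,000), so one
likelihood serves both blocks. A session is 40 loss trials followed by 40
gain trials; block order is fixed loss-then-gain by default and
configurable.

Outcomes are pre-drawn per trial *and per option* when a schedule is built.
Two consequences: (i) agents with different parameters or models can be run
through identical worlds, enabling paired comparisons; (ii) equal
(config, seed) pairs reproduce schedules bit-for-bit. Missed/timeout trials
are not simulated; when present in imported data they are dropped from the
likelihood with a logged count.

## The six learning models

All variants share the chosen-option Rescorla–Wagner update
`v_{t+1} = v_t + ε·(outcome_t − v_t)` with error sensitivity ε ∈ [0,1] and
values v ∈ [0,1] initialized at 0.5/0.5 (the unique symmetric,
choice-indifferent start). They differ in:

* unchosen option — complement `1 − v_chosen` (model 1, applied to the
  *post-update* chosen value so `v_A + v_B = 1` holds exactly), frozen
  (models 2, 3, 5), or multiplicative decay `λ·v` (models 4, 6);
* choice rule — plain softmax on the values (models 1, 2, 5, 6), a
  temperature softmax `σ(τ·(v_A − v_B))` with τ ∈ [0,1] (models 3, 4), or a
  lapse mixture `p·(1−L) + L/2` on top of the plain softmax (models 5, 6).

τ is deliberately kept on [0,1] (not the conventional unbounded inverse
temperature). With values bounded to [0,1] this caps any choice probability
at σ(1) ≈ 0.73 — an expressive ceiling that matters twice below.

Parameter bounds are exported as machine-readable metadata; every update
rule preserves v ∈ [0,1], and the likelihood is evaluated strictly
sequentially (probability from current values, then update with the observed
choice/outcome).

## Inference

`BanditModel(data, model).fit()` samples the posterior with a random-walk
Metropolis sampler on logit-transformed parameters — adequate here because
every model has ≤ 3 parameters on bounded support. Defaults: 4 chains,
1,000 warmup + 2,000 kept iterations each, proposal scale adapted toward a
20–50% acceptance rate during warmup only. Priors are independent Beta on
[0,1], uniform by default; on the logit scale a Beta(a,b) prior contributes
`a·log θ + b·log(1−θ)` (the Jacobian supplies the extra power of each
factor). Per-parameter split-R-hat and effective sample size come from
arviz; a fit is flagged non-convergent if any R-hat > 1.05 and is excluded
(with a count) from recovery studies and comparisons, never imputed. A
non-default two-stage empirical-Bayes mode (`fit_population`) moment-matches
Beta population priors from first-pass posterior means and refits.

PSIS-LOO: for each observation the leave-one-out importance ratios
`1/p(y_n|θ_s)` are Pareto-smoothed (generalized-Pareto fit of the largest
ratios, delegated to `arviz.psislw`), giving
`elpd_n = log Σ w_s p(y_n|θ_s) / Σ w_s` and `LOOIC = −2 Σ elpd_n`.
Observations with Pareto k > 0.7 are flagged. Degenerate (zero-variance)
posteriors bypass the log-sum-exp so the identity `LOOIC = −2 Σ ℓ_n` is
exact. Cohort-level comparison sums pointwise elpd over subjects; pairwise
standard errors use `SE = √(N·Var(elpd_A,n − elpd_B,n))`. Fits are per
subject per block by default (separate gain and loss parameters); passing
several blocks to one `BanditModel` fits a shared vector with values
re-initialized at each block start.

## Synthetic cohort

The generator produces a complete surrogate study with the target joint
structure; every calibration is computed by deterministic Gauss–Hermite
quadrature at configuration time, not tuned by simulation.

* A latent standard normal `z` sets baseline AIC Glx
  (mean 10, between-subject SD 6%, measurement SD 1.5%, institutional
  units — the scale is arbitrary because all downstream analyses use
  correlations or percent changes).
* Per-block error sensitivity is `ε = invlogit(a₀ + s·w)` with
  `w = ρ·z + √(1−ρ²)·u`. ρ is solved so that the *measured* baseline
  Glx–ε Pearson correlation equals the target (0.437 loss, 0.408 gain),
  accounting for both the inverse-logit distortion (via the quadrature
  moments of f(w)) and measurement attenuation. Unsatisfiable targets raise
  a configuration error.
* The general factor is `G = b·ε̄_z + d·z + noise` with standardized mean
  error sensitivity ε̄_z (population moments again by quadrature, including
  the loss–gain covariance), b = 0.762 and direct effect d = 0 by default —
  full mediation by construction; residual variance closes G to unit scale.
* Questionnaire items load 0.6 on G and 0.4 on an instrument factor;
  responses are discretized by equally spaced thresholds solved so the
  expected sum scores match the configured means (PHQ-9 1.7, GAD-7 2.2,
  STAI-X1 43.0). Item ranges are enforced structurally (a k-level item is a
  count of exceeded thresholds).
* Block series: AIC Glx is flat through rest1/loss/rest2, drops by the
  configured −2.21% in the gain block, and stays at the dropped level in
  rest3 (no rebound). mPFC Glx is exchangeable across blocks (null), and
  CrPCr/NAA rows are uncorrelated with everything — the specificity
  controls. CRLB% is drawn uniform on [3, 25] so the <20% filter is
  exercised on both sides.
* Choices are simulated from the winning model (ε, τ, λ) with
  τ ~ U(0.5, 1), λ ~ U(0.6, 0.95) independent of Glx by default (an option
  induces the known ε–τ correlation for stress tests); loss block first.
* Demographics (age ≈ 22 ± 2, ~23% women) feed the G-score regression.

What the generator does *not* emulate: raw spectra or LCModel fitting,
reaction times, missed trials, and — importantly — the full perseveration of
real subjects. Because the winning model's τ ∈ [0,1] caps choice
probabilities at ≈ 0.73, simulated cohorts reach ~54% correct with win-stay
~0.58 > lose-stay ~0.50; empirical cohorts show higher values (~62% correct,
win-stay ~0.85), which the model family itself cannot produce. Passing
tests therefore demonstrate the statistical machinery and the configured
effect structure, not behavioural realism beyond the model class.

## Statistics

* **rm-ANOVA:** classical within-subject F with df (k−1, (n−1)(k−1));
  Greenhouse–Geisser ε̂ = tr(A)²/((k−1)·tr(A²)) from the double-centered
  condition covariance, clipped to [1/(k−1), 1]; the GG p evaluates F at
  (ε̂·df1, ε̂·df2). The multivariate-style df pair (k−1, n−k+1) is reported
  alongside for cross-reading against articles that print that convention.
  Under exact sphericity the GG test is mildly conservative (measured
  type-I ≈ 4.1% at α = 5%, n = 52, k = 5) — a known property of the
  correction, not an implementation artifact.
* **Post hocs:** paired t per declared pair, p multiplied by the declared
  family size and capped at 1. Family sizes are always explicit arguments.
* **Correlations:** Pearson or Spearman (average ranks, t-approximation)
  via scipy, with explicit Bonferroni m.
* **Regression:** statsmodels OLS behind a thin result type; rank-deficient
  designs are rejected naming the collinear columns.
* **Mediation:** Baron–Kenny on standardized variables — step 1 DV~IV (c),
  step 2 M~IV (a), step 3 DV~M+IV (b, c′); the verdict (step 4) is *full*
  when steps 1–3 are significant and c′ is not, *partial* when c′ remains
  significant but attenuated, *none* when step 1 or 2 fails. An optional
  percentile bootstrap for a·b is provided but is not part of the classic
  procedure.
* **Moderation:** DV ~ IV + moderator + IV×moderator on standardized
  inputs, plus the reduced model without the interaction.
* **Bifactor scoring:** regression-method scores `Σ⁻¹λ_g` on standardized
  items, with Σ the model-implied covariance of the orthogonal bifactor
  structure; ω_h = (Σλ_g)²/Var(total), ω_t adds each group factor's
  (Σλ)². Estimating the bifactor model itself is out of scope — loadings
  are inputs. The default scoring loadings are solved in closed form so the
  scoring model's own ω_h/ω_t equal 0.72/0.97, the battery's reported
  reliabilities: with p = 36 items, uniform general loading g and group
  loading r per instrument, `T = 1/((1−ω_t)/p + ω_h/p² + (ω_t−ω_h)/Σn_k²)`,
  `g² = ω_h·T/p²`, `r² = (ω_t−ω_h)·T/Σn_k²`.
* α = 0.05 two-tailed throughout.

## Numerical and design choices

* Softmax always subtracts the max exponent even though bounded values
  cannot overflow.
* The compiled (numba) likelihood/sampler kernels are mirrored by a pure
  Python reference implementation; agreement to 1e−12 is enforced by tests.
* Sub-model identities (model 3 at τ=1 ≡ model 2; model 4 at λ=1 ≡ model 3;
  model 5 at L=0 ≡ model 2; model 6 at L=0, λ=1 ≡ model 2) hold pointwise
  to 1e−12 and anchor the registry.
* Seeds: a single root seed derives stage/subject/chain seeds through
  `numpy.random.SeedSequence`; reports are byte-identical across reruns and
  contain no wall-clock data.
* ΔGlx always references the immediately preceding rest block; explicit
  baseline(pre-task) comparisons are requested separately by the analysis
  layer.
* Generalized Dice is the group-wise pairwise formulation
  `Σ_pairs |A∩B| / Σ_pairs |A∪B|` (for two masks:
  intersection-over-union, the monotone analog of classic Dice); the
  pairwise-mean classic Dice is available as an option since published
  values do not always state which form was used.

## Problem sizes and known limitations

Recovery studies run at desk scale: parameter recovery uses 52 subjects ×
two 40-trial blocks; model recovery uses 20 replicate cohorts of 20
subjects × 80 trials with reduced chains (2 × 500 kept draws), sizes chosen
so the full studies complete in minutes on one CPU.

Two identifiability limits of the model family at this scale are worth
stating plainly, because they bound what any fitting machinery can deliver:

1. **ε recovery.** With values and τ bounded to [0,1], choices carry little
   information about ε: the Monte-Carlo Fisher information is ≈ 7–12 per
   80-trial session across regimes, i.e. a posterior SD of ≈ 0.3–0.4
   against a U(0.1, 0.9) true spread (SD 0.23). The attainable
   true-vs-posterior-mean correlation is therefore ≈ 0.5–0.6 in expectation
   (measured 0.50 averaged over four replicate studies); it is an
   information ceiling, not an estimator defect — the MLE reaches r ≈ 0.97
   at 2,000 trials per subject.
2. **Temperature vs lapse.** On the bounded value scale,
   `σ(τ·Δv)` and `σ(Δv)(1−L) + L/2` agree to `(τ−τ³)Δv³/48 ≤ 0.008` in
   probability, so the temperature+decay model and the lapse+decay model
   are nearly observationally equivalent: per-cohort LOOIC differences
   between them are |d| < 1 with coin-flip sign at 20 × 80 observations,
   while both separate cleanly (9–30 LOOIC) from the simpler variants.
   Model-recovery win rates against the full six-model set hover near 50%
   for this reason.
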