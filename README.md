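# banditglx

Reinforcement-learning modelling of two-armed bandit behaviour coupled to
functional MRS (fMRS) neurometabolite analyses, for computational-psychiatry
studies linking anterior insular cortex (AIC) glutamate+glutamine (Glx) to
error sensitivity and a general psychopathology factor (G-score).

The package provides, end to end:

* **Task engine** — the 70/30 two-armed bandit with gain (+1,000 / 0) and
  loss (0 / −1,000) blocks, pre-drawn per-option outcome schedules, agent
  simulation, and model-free summaries (correct rate, win-stay / lose-stay).
* **Model family** — six Rescorla–Wagner variants. All share the chosen-option
  update `v ← v + ε·(outcome − v)` with error sensitivity ε ∈ [0,1]; they
  differ in the unchosen-option rule (complement `1 − v`, frozen, or decay
  `λ·v`) and in the choice rule (plain softmax `e^v / (e^{v_A} + e^{v_B})`,
  temperature softmax `e^{τv}`, or lapse mixture `p·(1−L) + L/2`).
* **Bayesian inference** — statsmodels-style `BanditModel(...).fit()` →
  `BanditResults` with posterior draws (random-walk Metropolis on
  logit-transformed parameters, compiled with numba), R-hat/ESS diagnostics,
  PSIS-LOO (`LOOIC = −2·elpd_loo`), cohort-level model comparison, and
  parameter/model recovery studies.
* **Synthetic cohort** — a full surrogate study (choices, block-wise
  metabolite panels with CRLB%, PHQ-9/GAD-7/STAI-X1 items) whose effect
  sizes are calibrated by quadrature to the structure under study: baseline
  AIC Glx → error sensitivity (r ≈ 0.44 / 0.41), full mediation of the
  Glx → G-score path through error sensitivity (b ≈ 0.76), a −2.21% AIC Glx
  dip during gain learning that persists post-task, and null mPFC controls.
* **Neurometabolite QC** — strict CRLB < 20% filtering, Cr+PCr referencing,
  ΔGlx change scores, generalized Dice overlap of VOI masks.
* **Stats suite** — repeated-measures ANOVA with Greenhouse–Geisser
  correction, Bonferroni post hocs, Pearson/Spearman correlations with
  explicit comparison families, multiple regression, Baron–Kenny mediation,
  moderation, bifactor G-score computation and ω reliability.
* **Pipeline + CLI** — `bandit-glx run` executes the whole replica from one
  config with bit-reproducible reports.

## Worked example

```python
from banditglx import (TaskConfig, AgentParameters, make_block_schedule,
                       simulate_agent, BanditModel, correct_rate)

schedule = make_block_schedule(TaskConfig(block_type="gain", n_trials=40), seed=7)
agent = AgentParameters(epsilon=0.6, tau=1.0, decay=0.9)
data = simulate_agent(4, agent, schedule, seed=8)
print(correct_rate(data, schedule.config))      # 0.65

res = BanditModel(data, model=4).fit(seed=1)
print(res.summary().round(3))
loo = res.loo()
print(f"LOOIC = {loo.looic:.2f}")
```

Output:

```
0.65
            mean     sd  hdi_2.5%  hdi_97.5%  r_hat      ess
parameter
epsilon    0.532  0.264     0.057      0.967  1.002  804.938
tau        0.621  0.260     0.076      0.984  1.005  655.218
decay      0.544  0.300     0.024      0.988  1.008  569.361
LOOIC = 53.50
```

The agent beat chance (65% vs 50%); with only 40 trials the posterior for ε
is wide (mean 0.53, 95% interval 0.06–0.97) — single-block fits are
deliberately weakly informed, which is why the study-scale analyses pool 80+
trials per subject and compare models on summed LOOIC. All R-hat ≤ 1.05 and
no Pareto-k warnings, so the fit and its LOO estimate are trustworthy.

A full synthetic study runs from the shell:

```bash
bandit-glx simulate-cohort --subjects 52 --seed 1 --out data/
bandit-glx run --out study_out --seed 1
```

`study_out/report.json` then contains the behavioural summaries, the
model-comparison table (lowest LOOIC wins), the Glx rm-ANOVAs, the
correlation/regression tables, and the mediation and moderation results.

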