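# padem

A probabilistic decision-analytic model of intravenous medicines
administration errors, built to evaluate whether **user-testing** a written
medicines guideline — an iterative interview-and-revision process for
improving how nurses find and understand preparation instructions — is
cost-effective for the NHS compared with keeping the current guideline.

The package is aimed at health-economic modellers and medication-safety
researchers who want a fully scriptable, reproducible implementation of
this class of model: a per-dose decision tree, Bayesian (Dirichlet)
parameter uncertainty, Monte Carlo probabilistic sensitivity analysis
(PSA), and one-way sensitivity scenarios.

## The model

Each administered dose passes through a four-node chance tree:

1. **Error type** — no error, or one of 11 guideline-related error types.
   Probabilities are Dirichlet-distributed posteriors from observed study
   counts with a flat prior of 0.1 per cell, separately for each guideline
   arm (current vs user-tested).
2. **Detection** — an error may be caught by a second nurse double-checking
   the prepared dose. The probability it remains undetected is the risk
   ratio of an error after double-checking, pooled from trials by
   random-effects (DerSimonian–Laird) meta-analysis and entered as a
   lognormal distribution from the 95% prediction interval.
3. **Harm** — an undetected error causes no harm with Beta(217, 23)
   probability.
4. **Severity** — a harmful undetected error (a preventable adverse drug
   event, pADE) is minor, moderate or severe, with error-type-specific
   Dirichlet severity splits.

Detected errors incur a correction cost; pADEs incur severity-specific
treatment costs and QALY decrements. Per-dose expectations are scaled to
4,000 doses/year over 5 years; costs and QALYs are discounted at 3.5% a
year, while event counts are reported undiscounted. The one-off
user-testing intervention cost (interviews, transcription, analysis,
revision, training, equipment) is added to the user-tested arm.

Headline outcomes per PSA iteration, with current-minus-user differences
so positive values favour user-testing:

- **ICS** (incremental cost-saving) = health-system cost with the current
  guideline − cost with the user-tested guideline (intervention included);
- **NMB** (net monetary benefit) = λ·ΔQALY + ICS at willingness-to-pay
  λ = £20,000/QALY;
- pADE and QALY-decrement reductions, credible intervals, exceedance
  probabilities and the cost-effectiveness acceptability curve (CEAC).

## Worked example

```python
import padem

config = padem.base_case_config()          # bundled published inputs
result = padem.run_psa(config, n_samples=20000, seed=20210817)
print(result.summary().loc[["delta_pades", "ics", "nmb", "ut_cost"]].round(1))
print("P(cost-saving)    =", result.p_cost_saving)
print("P(cost-effective) =", result.p_cost_effective())
```

prints

```
                   mean  ci_lower   ci_upper
delta_pades       414.0     211.3      677.9
ics            242262.6   38611.9   495738.8
nmb           3157301.7 -445221.2  8494500.9
ut_cost          6318.5    6012.5     6626.4
P(cost-saving)    = 0.99105
P(cost-effective) = 0.95895
```

That is: over 5 years the user-tested guideline is expected to avoid
about 414 pADEs and save about £242k for a one-off £6.3k intervention,
with a 99% chance of being cost-saving and a 96% chance of being
cost-effective at £20,000/QALY.

The same run is available from the shell, including CEAC and
cost-effectiveness-plane CSV exports and a reproducibility manifest:

```sh
padem run --samples 20000 --seed 20210817 --out results/
padem suite --out results/          # all built-in sensitivity scenarios
padem meta trials.csv               # pool double-checking trials
```

Built-in scenarios cover 1- and 10-year horizons, 20,000 doses/year,
deterministic detection and no-harm variants, and the lower-risk setting
in which the undetected-error frequency with current guidelines is
rescaled to 32% of doses (optionally with the relative effect of
user-testing halved).

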