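# Methods

## Model structure

The unit of analysis is one intravenous dose prepared and administered by
a nurse following a written guideline. A four-node chance tree maps each
dose to one of 56 terminal paths: no error, or one of 11 error types
crossed with {detected before administration; undetected without harm;
undetected with minor / moderate / severe harm}. An undetected harmful
error is a preventable adverse drug event (pADE). Two versions of the
tree — identical in structure, different in the node-1 error-type and
node-4 severity probabilities and in administration time — represent the
current and the user-tested guideline.

Single-pass evaluation is assumed: a detected error leads to correction
at a small cost and the dose is not re-modelled through the tree. The
detection probability and the no-harm probability are common to all 11
error types; only the severity split is type-specific.

## Parameters

All base-case inputs ship in `src/padem/data/base_case.yaml`.

| Input | Distribution | Notes |
| --- | --- | --- |
| Error-type probabilities (node 1) | Dirichlet, 12 categories per arm | posterior = observed study counts + 0.1 prior per cell |
| Severity split per error type (node 4) | Dirichlet, 3 categories ×11 per arm | row sums equal the node-1 pseudo-counts |
| P(error undetected) (node 2) | Lognormal(−0.25, 0.086), clamped ≤ 1 | risk ratio after nurse double-checking, used directly as a probability; derived from the 95% prediction interval of a random-effects meta-analysis |
| P(no harm \| undetected) (node 3) | Beta(217, 23) | 217 of 240 observed infusion errors harmless |
| Administration time | Normal(13.3, 0.41) / Normal(11.9, 0.31) min | per arm; (mean, standard error); costed at £37/h (band 5 nurse) |
| Detected-error cost | Lognormal(−1.29, 1.10) £ | |
| pADE treatment cost | Lognormal(4.82, 0.14) / (7.13, 0.07) / (7.52, 0.06) £ | minor / moderate / severe |
| QALY decrement | Normal(0.004, 0.0011) / (0.035, 0.0089) / (3.50, 0.83) | clamped ≥ 0 |
| User-testing resources | 11 Normal duration inputs + deterministic counts/rates | see below |
| Cohort | 4,000 doses/year, 5 years, 3.5%/year discount, λ = £20,000/QALY | deterministic |

The user-testing intervention model: 4 pilot interviews and 3 rounds of
10 interviews, each interview costing pharmacist (£65/h) plus nurse
(£37/h) time and £1.75/min transcription; analysis time is **per
interview**, revision time per round, both pharmacist-only; £562 training
and £4 equipment are fixed. At the input means this totals £6,318
(interviews £1,387.2 + transcription £1,428.0 + analysis £2,346.5 +
revisions £590.4 + fixed £566) — the per-interview reading of the
analysis times is the only one consistent with the published mean cost.
The cost is incurred once at the start of the horizon and is not
discounted.

## Numerical conventions

- **Dirichlet consistency.** Node-1 error-type pseudo-counts are stored
  redundantly alongside the severity triples and cross-validated (each
  node-1 entry must equal its severity row sum). Node-1 and node-4
  vectors are sampled independently per draw; joint cell-level sampling
  is not used. Dirichlet draws are normalised gamma variates and sum to
  one to machine precision.
- **Clamping, not rejection.** Truncation is applied by clipping after
  sampling. The only non-negligible clip is the detection ratio above 1
  (≈0.2% of draws); normal times and QALY decrements are clipped at 0
  where the mass involved is far-tail. Expected-value computations use
  the untruncated analytic means.
- **Discounting.** Annual amounts for years t = 1..H are weighted by
  (1+r)^(−t) (discount-factor sum 4.5151 at 3.5% over 5 years). The
  alternative year-1-undiscounted convention overstates the published
  discounted totals by ~4%, so the end-of-year convention is used. Event
  counts are never discounted; only costs and QALYs are.
- **Common random numbers.** Within a PSA iteration all shared inputs
  (detection, no-harm, costs, QALY decrements, user-testing durations)
  are drawn once and used by both arms; arm-specific Dirichlets and
  administration times are drawn independently. This is standard PSA
  practice, leaves all means unchanged and narrows incremental credible
  intervals somewhat relative to fully independent arms.
- **Summaries.** Credible intervals are empirical 2.5/97.5 percentiles
  with linear interpolation. The default run size is 20,000 iterations
  with a fixed documented seed; the running-mean convergence check
  (`convergence_check`, 1% tolerance over the final quarter) passes at
  this size.

## Scenario analyses

Scenarios are expressed as typed edits of the base configuration:
horizon (1 or 10 years), dose volume (20,000/year), deterministic
replacement of the detection probability (at the prediction-interval
endpoints 0.655 / 0.918) or the no-harm probability (0.75 / 0.99), and
the lower-risk rescaling. In the rescaling, the current arm's error-type
mass is multiplied by k = target / (P(error) · E[P(undetected)]) so the
expected undetected-error frequency equals the target (32%), with freed
mass reassigned to no-error and severity compositions and total Dirichlet
concentration preserved; the user arm is scaled so its relative reduction
in undetected-error frequency equals the base-case reduction times an
effectiveness multiplier (1 by default, 0.5 for the halved-effect
variant). Uniform scaling is a modelling choice: the published variant of
this scenario with the effect halved is sensitive to exactly how the
severity mix is adjusted, and our uniform scheme is not guaranteed to
match other implementations of it.

## Meta-analysis stage

Double-checking trials enter as 2×2 tables. Log risk ratios are pooled
with the DerSimonian–Laird estimator (tau² from the Q statistic, floored
at 0; 0.5 continuity correction when any cell is zero). The 95%
prediction interval uses a t(k−2) multiplier on √(se² + tau²) — with two
trials it is undefined and flagged unreliable. The interval is converted
to the model's lognormal detection input with mu the pooled log risk
ratio and sigma the log-interval width over 2×1.96. Note that with very
few trials the z-based DerSimonian–Laird confidence interval undercovers
when heterogeneity dominates the within-trial variance; the coverage
property test therefore runs in a within-trial-dominated regime (three
trials of 150–200 administrations per arm, tau = 0.05), where coverage is
nominal.

## Synthetic data

The generators emulate exactly the data structures the model consumes:
(a) a two-arm study as one multinomial draw per arm over the 34 joint
cells (11 types × 3 severities + no-error), with the default truth set at
the posterior means of the bundled base case; and (b) two-arm trials
with trial-specific log risk ratios drawn Normal(true, tau²) and binomial
event counts. They do not emulate individual nurse behaviour, multiple
errors per dose, observation error in severity scoring, or correlations
between error type and administration time — so passing recovery tests
demonstrates statistical self-consistency of the pipeline, not external
validity of the published inputs.

## Limitations

- The detection risk ratio is treated as a probability, inheriting the
  published modelling shortcut.
- Litigation costs, drug-acquisition costs and societal-perspective costs
  are out of scope; only the most severe error per dose is modelled
  (no additive multiple-error structure).
- The discounting timing and random-number-sharing conventions above are
  the package's own calibrated choices; the source model's exact
  conventions are not published in the main text.
- Severe-harm QALY decrements rest on sparse published evidence; the
  scenario machinery exists precisely to probe them.
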