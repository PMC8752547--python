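# Base-case model inputs: intravenous voriconazole administration by nurses
# following current vs user-tested injectable-medicines guidelines.
#
# Dirichlet pseudo-counts are Bayesian posteriors: observed clinical-study
# counts (133 current / 140 user-tested participants) plus a flat prior of
# 0.1 per cell.  Node-1 vectors list the no-error category first, then
# error types 1-11; each error type's node-1 entry equals the sum of its
# severity (minor, moderate, severe) pseudo-counts.
arms:
  current:
    node1_pseudo_counts:
      [26.3, 0.3, 0.3, 10.8, 0.3, 6.3, 27.3, 0.3, 3.3, 33.3, 0.3, 27.8]
    severity_pseudo_counts:
      - [0.1, 0.1, 0.1]
      - [0.1, 0.1, 0.1]
      - [5.1, 5.6, 0.1]
      - [0.1, 0.1, 0.1]
      - [0.1, 6.1, 0.1]
      - [0.1, 27.1, 0.1]
      - [0.1, 0.1, 0.1]
      - [0.1, 3.1, 0.1]
      - [4.1, 29.1, 0.1]
      - [0.1, 0.1, 0.1]
      - [19.1, 3.6, 5.1]
    admin_time: # minutes per dose, mean (standard error)
      family: normal
      params: [13.3, 0.41]
      truncation: [0.0, null]
  user_tested:
    node1_pseudo_counts:
      [67.3, 0.3, 0.3, 4.3, 1.3, 0.3, 48.3, 0.3, 6.3, 11.3, 0.3, 3.3]
    severity_pseudo_counts:
      - [0.1, 0.1, 0.1]
      - [0.1, 0.1, 0.1]
      - [2.1, 2.1, 0.1]
      - [0.1, 1.1, 0.1]
      - [0.1, 0.1, 0.1]
      - [3.1, 45.1, 0.1]
      - [0.1, 0.1, 0.1]
      - [0.1, 6.1, 0.1]
      - [0.1, 11.1, 0.1]
      - [0.1, 0.1, 0.1]
      - [0.1, 2.1, 1.1]
    admin_time:
      family: normal
      params: [11.9, 0.31]
      truncation: [0.0, null]

shared:
  # Risk ratio of an error remaining undetected after nurse double-checking,
  # applied directly as the node-2 probability; lognormal on the natural-log
  # scale, from the 95% prediction interval of a random-effects meta-analysis
  # of three trials.  Clamped to 1 because it is used as a probability.
  p_undetected:
    family: lognormal
    params: [-0.25, 0.086]
    truncation: [null, 1.0]
  # Probability an undetected error causes no harm (217 of 240 observed
  # infusion errors rated harmless).
  p_no_harm:
    family: beta
    params: [217.0, 23.0]
  # GBP cost of correcting an error detected before administration.
  cost_detected:
    family: lognormal
    params: [-1.29, 1.10]
  # GBP treatment cost of a preventable adverse drug event by severity.
  cost_pade:
    minor: { family: lognormal, params: [4.82, 0.14] }
    moderate: { family: lognormal, params: [7.13, 0.07] }
    severe: { family: lognormal, params: [7.52, 0.06] }
  # QALY decrement following a preventable adverse drug event by severity.
  qaly_decrement:
    minor:
      family: normal
      params: [0.004, 0.0011]
      truncation: [0.0, null]
    moderate:
      family: normal
      params: [0.035, 0.0089]
      truncation: [0.0, null]
    severe:
      family: normal
      params: [3.50, 0.83]
      truncation: [0.0, null]
  staff_rates: # GBP per hour (hospital pharmacist band 8a, nurse band 5)
    pharmacist_per_hour: 65.0
    nurse_per_hour: 37.0
  user_testing:
    # Interview / analysis minutes are per interview; revision minutes per
    # round.  Normal parameters are (mean, standard error), clamped at 0.
    interview_minutes:
      pilot: { family: normal, params: [24.0, 2.2], truncation: [0.0, null] }
      round1: { family: normal, params: [29.0, 2.5], truncation: [0.0, null] }
      round2: { family: normal, params: [23.0, 2.1], truncation: [0.0, null] }
      round3: { family: normal, params: [20.0, 1.2], truncation: [0.0, null] }
    analysis_minutes:
      pilot: { family: normal, params: [94.0, 6.1], truncation: [0.0, null] }
      round1: { family: normal, params: [76.0, 3.5], truncation: [0.0, null] }
      round2: { family: normal, params: [53.0, 6.9], truncation: [0.0, null] }
      round3: { family: normal, params: [50.0, 2.2], truncation: [0.0, null] }
    revision_minutes:
      round1: { family: normal, params: [265.0, 20.0], truncation: [0.0, null] }
      round2: { family: normal, params: [140.0, 11.0], truncation: [0.0, null] }
      round3: { family: normal, params: [140.0, 11.0], truncation: [0.0, null] }
    n_pilot: 4
    n_per_round: 10
    transcription_rate_per_min: 1.75
    training_cost: 562.0
    equipment_cost: 4.0

cohort:
  doses_per_year: 4000 # conservative estimate of annual IV voriconazole doses
  horizon_years: 5
  discount_rate: 0.035 # annual, applied to costs and QALYs (not counts)
  wtp_per_qaly: 20000.0 # GBP willingness-to-pay per QALY
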