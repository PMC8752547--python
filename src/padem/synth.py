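"""Synthetic data generators mirroring the statistical structure of the inputs.

Two kinds of data feed the model: a two-arm clinical study producing
multinomial counts over 34 joint cells per arm (11 error types x 3
severities plus no-error), and a set of two-arm double-checking trials
with between-trial heterogeneity on the log risk ratio.  The generators
here draw from those exact structures, so parameter recovery and
end-to-end tests can run without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import discount_sum, user_testing_cost
from .meta import TrialTable
from .params import (
    ModelConfig,
    N_ERROR_TYPES,
    N_SEVERITIES,
    arm_spec_from_counts,
    base_case_config,
    expected_draw,
)
from .psa import run_psa
from .tree import expected_dose_outcome

__all__ = [
    "ArmTruth",
    "TrueModel",
    "base_case_truth",
    "simulate_clinical_study",
    "study_counts_to_frame",
    "simulate_double_check_trials",
    "trials_to_frame",
    "end_to_end_recovery",
]


@dataclass(frozen=True)
class ArmTruth:
    """True per-arm generating probabilities for the synthetic study."""

    node1_probs: tuple[float, ...]  # 12: no-error then error types 1-11
    severity_probs: tuple[tuple[float, float, float], ...]  # 11 conditional triples

    def __post_init__(self):
        n1 = np.asarray(self.node1_probs)
        sev = np.asarray(self.severity_probs)
        if n1.shape != (N_ERROR_TYPES + 1,) or not np.isclose(n1.sum(), 1.0):
            raise ValueError("node1_probs must be a 12-vector summing to 1")
        if sev.shape != (N_ERROR_TYPES, N_SEVERITIES) or not np.allclose(
            sev.sum(axis=1), 1.0
        ):
            raise ValueError("severity_probs must be 11 triples each summing to 1")

    def joint_cell_probs(self) -> np.ndarray:
        """Probabilities of the 34 joint cells: no-error first, then
        (type, severity) in row-major order."""
        n1 = np.asarray(self.node1_probs)
        joint = n1[1:, np.newaxis] * np.asarray(self.severity_probs)
        return np.concatenate([[n1[0]], joint.ravel()])


@dataclass(frozen=True)
class TrueModel:
    """Ground truth for the synthetic clinical study and downstream model."""

    current: ArmTruth
    user: ArmTruth
    p_undetected: float
    p_no_harm: float
    n_per_arm: int = 273 // 2

    def __post_init__(self):
        if not (0 <= self.p_undetected <= 1 and 0 <= self.p_no_harm <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_per_arm < 0:
            raise ValueError("n_per_arm must be >= 0")


def _arm_truth_from_counts(node1: np.ndarray, sev: np.ndarray) -> ArmTruth:
    sev_cond = sev / sev.sum(axis=1, keepdims=True)
    return ArmTruth(
        node1_probs=tuple(node1 / node1.sum()),
        severity_probs=tuple(tuple(r) for r in sev_cond),
    )


def base_case_truth(config: ModelConfig | None = None) -> TrueModel:
    """True model at the posterior means of the bundled base case."""
    config = config or base_case_config()
    return TrueModel(
        current=_arm_truth_from_counts(config.current.node1, config.current.severity),
        user=_arm_truth_from_counts(config.user.node1, config.user.severity),
        p_undetected=float(config.shared.p_undetected.mean()),
        p_no_harm=float(config.shared.p_no_harm.mean()),
    )


def simulate_clinical_study(
    truth: TrueModel, n_per_arm: int, rng: np.random.Generator
) -> dict[str, dict]:
    """Simulate observed study counts for both arms.

    Each arm is one multinomial draw over the 34 joint cells.  Returns,
    per arm label, the no-error count and the (11, 3) severity count
    table; counts sum to ``n_per_arm``.
    """
    if n_per_arm < 0:
        raise ValueError("n_per_arm must be >= 0")
    out = {}
    for label, arm in (("current", truth.current), ("user_tested", truth.user)):
        cells = rng.multinomial(n_per_arm, arm.joint_cell_probs())
        out[label] = {
            "no_error": int(cells[0]),
            "severity_counts": cells[1:].reshape(N_ERROR_TYPES, N_SEVERITIES),
        }
    return out


def study_counts_to_frame(counts: dict[str, dict]) -> pd.DataFrame:
    """Tidy CSV-ready view of simulated study counts (one row per cell)."""
    rows = []
    for label, arm in counts.items():
        rows.append({"arm": label, "error_type": 0, "severity": "none", "count": arm["no_error"]})
        sev = arm["severity_counts"]
        for i in range(N_ERROR_TYPES):
            for s, name in enumerate(("minor", "moderate", "severe")):
                rows.append(
                    {
                        "arm": label,
                        "error_type": i + 1,
                        "severity": name,
                        "count": int(sev[i, s]),
                    }
                )
    return pd.DataFrame(rows)


def simulate_double_check_trials(
    true_log_rr: float,
    tau: float,
    trial_sizes: list[tuple[int, int]],
    baseline_risks: list[float],
    rng: np.random.Generator,
) -> list[TrialTable]:
    """Simulate two-arm double-checking trials with heterogeneity.

    Each trial draws its own log risk ratio from
    ``Normal(true_log_rr, tau^2)``; the unchecked arm has the given
    baseline error risk and the checked arm risk ``baseline * RR``.
    Event counts are binomial.
    """
    if len(trial_sizes) != len(baseline_risks):
        raise ValueError("trial_sizes and baseline_risks must have equal length")
    trials = []
    for j, ((n_checked, n_unchecked), risk) in enumerate(zip(trial_sizes, baseline_risks)):
        if not (0 < risk < 1):
            raise ValueError("baseline risks must lie in (0, 1)")
        if min(n_checked, n_unchecked) < 1:
            raise ValueError("trial sizes must be >= 1")
        rr_j = np.exp(rng.normal(true_log_rr, tau))
        risk_checked = risk * rr_j
        if risk_checked > 1:
            raise ValueError("baseline risk x risk ratio exceeds 1")
        trials.append(
            TrialTable(
                label=f"trial_{j + 1}",
                events_checked=int(rng.binomial(n_checked, risk_checked)),
                n_checked=n_checked,
                events_unchecked=int(rng.binomial(n_unchecked, risk)),
                n_unchecked=n_unchecked,
            )
        )
    return trials


def trials_to_frame(trials: list[TrialTable]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [t.label for t in trials],
            "events_checked": [t.events_checked for t in trials],
            "n_checked": [t.n_checked for t in trials],
            "events_unchecked": [t.events_unchecked for t in trials],
            "n_unchecked": [t.n_unchecked for t in trials],
        }
    )


def end_to_end_recovery(
    truth: TrueModel,
    n_per_arm: int,
    psa_n: int,
    seed: int,
    base: ModelConfig | None = None,
) -> dict:
    """Simulate a study, rebuild posteriors, run the PSA, compare to truth.

    The base configuration supplies everything the synthetic study does
    not generate (costs, QALY decrements, admin times, cohort).  The
    report contains the PSA means and the closed-form outcomes implied
    by the true probabilities, so callers can verify the former
    approaches the latter as ``n_per_arm`` and ``psa_n`` grow.
    """
    base = base or base_case_config()
    rng = np.random.default_rng(seed)
    counts = simulate_clinical_study(truth, n_per_arm, rng)
    current = arm_spec_from_counts(
        "current",
        counts["current"]["no_error"],
        counts["current"]["severity_counts"],
        base.current.admin_time,
    )
    user = arm_spec_from_counts(
        "user_tested",
        counts["user_tested"]["no_error"],
        counts["user_tested"]["severity_counts"],
        base.user.admin_time,
    )
    config = ModelConfig(current=current, user=user, shared=base.shared, cohort=base.cohort)
    psa = run_psa(config, n_samples=psa_n, seed=int(rng.integers(2**31 - 1)))

    # closed-form expected outcomes directly at the true probabilities
    ev = expected_draw(base)
    for arm_draw, arm_truth in ((ev.current, truth.current), (ev.user, truth.user)):
        arm_draw.node1 = np.asarray(arm_truth.node1_probs, dtype=float)
        arm_draw.severity = np.asarray(arm_truth.severity_probs, dtype=float)
    ev.p_undetected = np.asarray(truth.p_undetected, dtype=float)
    ev.p_no_harm = np.asarray(truth.p_no_harm, dtype=float)
    ev_out_c = expected_dose_outcome(ev, "current")
    ev_out_u = expected_dose_outcome(ev, "user_tested")
    doses = base.cohort.doses_per_year * base.cohort.horizon_years
    report = {
        "psa_mean_delta_pades": float(psa.iterations["delta_pades"].mean()),
        "true_delta_pades": float((ev_out_c.p_pade - ev_out_u.p_pade) * doses),
        "psa_mean_ics": float(psa.iterations["ics"].mean()),
        "psa_mean_ut_cost": float(psa.iterations["ut_cost"].mean()),
        "true_ut_cost": float(
            user_testing_cost(ev, base.shared.user_testing, base.shared.staff_rates)
        ),
        "n_per_arm": n_per_arm,
        "psa_n": psa_n,
        "seed": seed,
    }
    # closed-form ICS at the truth: cost difference per year x discount sum,
    # minus the undiscounted user-testing cost
    dsum = discount_sum(base.cohort.horizon_years, base.cohort.discount_rate)
    nurse = base.shared.staff_rates.nurse_per_hour
    cost_c = (
        float(ev.current.admin_minutes) / 60.0 * nurse + float(ev_out_c.expected_error_cost)
    ) * base.cohort.doses_per_year
    cost_u = (
        float(ev.user.admin_minutes) / 60.0 * nurse + float(ev_out_u.expected_error_cost)
    ) * base.cohort.doses_per_year
    report["true_ics"] = (cost_c - cost_u) * dsum - report["true_ut_cost"]
    return report
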