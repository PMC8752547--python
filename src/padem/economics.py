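"""Cohort scaling, discounting, intervention cost and incremental outcomes.

Per-dose tree expectations are scaled to an annual dose volume over a
multi-year horizon.  Event counts (pADEs) are reported undiscounted;
costs and QALY decrements accrue annually and are discounted at the
annual rate with weights ``(1 + r)^-t`` for years ``t = 1..H``.  The
one-off user-testing intervention cost is incurred at the start of the
horizon and is not discounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CohortSpec, ParameterDraw, StaffRates, UserTestingSpec
from .tree import DoseOutcome

__all__ = [
    "ArmResult",
    "IncrementalResult",
    "discount_factor",
    "discount_sum",
    "user_testing_cost",
    "arm_totals",
    "incremental",
]


def discount_factor(year_index: int, rate: float) -> float:
    """Discount weight ``(1 + rate)^-t`` for year ``t >= 1``.

    Year 1 is discounted once (amounts treated as accruing at the end of
    each year).
    """
    if year_index < 1:
        raise ValueError("year_index must be >= 1")
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    return float((1.0 + rate) ** (-year_index))


def discount_sum(horizon_years: int, rate: float) -> float:
    """Sum of discount factors over years 1..H (4.5151 at 3.5% over 5 years)."""
    return sum(discount_factor(t, rate) for t in range(1, horizon_years + 1))


def user_testing_cost(
    draw: ParameterDraw, spec: UserTestingSpec, staff: StaffRates
) -> np.ndarray:
    """One-off cost (GBP) of the user-testing intervention for a draw.

    Interviews cost pharmacist-plus-nurse time and transcription per
    spoken minute; analysis time (per interview) and revision time (per
    round) cost pharmacist time; training and equipment are fixed.
    """
    counts = spec.interview_counts  # (4,): pilot, rounds 1-3
    pharm = staff.pharmacist_per_hour / 60.0
    nurse = staff.nurse_per_hour / 60.0
    interviews = np.einsum(
        "j,...j->...", counts, draw.ut_interview_minutes * (pharm + nurse + spec.transcription_rate)
    )
    analysis = np.einsum("j,...j->...", counts, draw.ut_analysis_minutes) * pharm
    revision = draw.ut_revision_minutes.sum(axis=-1) * pharm
    return interviews + analysis + revision + spec.training_cost + spec.equipment_cost


@dataclass
class ArmResult:
    """Cohort-level expected outcomes for one arm (possibly batched)."""

    total_pades: np.ndarray  # expected count over horizon, undiscounted
    moderate_severe_pades: np.ndarray  # ditto, moderate + severe only
    total_qaly_decrement: np.ndarray  # QALYs, discounted
    health_system_cost: np.ndarray  # GBP, discounted
    cohort: CohortSpec


@dataclass
class IncrementalResult:
    """Current-minus-user differences; positive values favour user-testing."""

    delta_pades: np.ndarray
    delta_mod_severe_pades: np.ndarray
    delta_qaly_decrement: np.ndarray
    incremental_cost_saving: np.ndarray  # GBP
    nmb_at_wtp: np.ndarray  # GBP
    wtp: float


def arm_totals(
    dose_outcome: DoseOutcome,
    admin_time_minutes: np.ndarray,
    cohort: CohortSpec,
    nurse_rate_per_hour: float,
    user_testing_cost: np.ndarray | None = None,
) -> ArmResult:
    """Scale per-dose expectations to the cohort over the time horizon.

    Administration time is costed at the nurse hourly rate.
    ``user_testing_cost`` (GBP, undiscounted) is added for the
    intervention arm only.
    """
    doses_total = cohort.doses_per_year * cohort.horizon_years
    dsum = discount_sum(cohort.horizon_years, cohort.discount_rate)

    admin_cost_per_year = (
        np.asarray(admin_time_minutes, dtype=float)
        / 60.0
        * nurse_rate_per_hour
        * cohort.doses_per_year
    )
    error_cost_per_year = dose_outcome.expected_error_cost * cohort.doses_per_year
    qaly_per_year = dose_outcome.expected_qaly_decrement * cohort.doses_per_year

    cost = (admin_cost_per_year + error_cost_per_year) * dsum
    if user_testing_cost is not None:
        cost = cost + user_testing_cost
    return ArmResult(
        total_pades=dose_outcome.p_pade * doses_total,
        moderate_severe_pades=dose_outcome.p_moderate_severe_pade * doses_total,
        total_qaly_decrement=qaly_per_year * dsum,
        health_system_cost=cost,
        cohort=cohort,
    )


def incremental(current: ArmResult, user: ArmResult, wtp: float) -> IncrementalResult:
    """Incremental outcomes (current minus user) at a willingness-to-pay."""
    if current.cohort != user.cohort:
        raise ValueError("arms were computed on different cohort settings")
    delta_q = current.total_qaly_decrement - user.total_qaly_decrement
    ics = current.health_system_cost - user.health_system_cost
    return IncrementalResult(
        delta_pades=current.total_pades - user.total_pades,
        delta_mod_severe_pades=current.moderate_severe_pades - user.moderate_severe_pades,
        delta_qaly_decrement=delta_q,
        incremental_cost_saving=ics,
        nmb_at_wtp=wtp * delta_q + ics,
        wtp=float(wtp),
    )
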