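"""Per-dose decision tree for medicines administration errors.

Each administered dose passes through four chance nodes:

1. error type — no error, or one of 11 guideline-related error types;
2. detection — a prepared dose may be double-checked and the error
   caught before administration (probability ``1 - p_undetected``);
3. harm — an undetected error may still cause no harm (``p_no_harm``);
4. severity — a harmful undetected error (a preventable adverse drug
   event, pADE) is minor, moderate or severe, with error-type-specific
   conditional probabilities.

Detected errors incur only the detection/correction cost; pADEs incur a
severity-specific treatment cost and QALY decrement.  All functions
accept batched draws (leading axes broadcast).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .params import N_ERROR_TYPES, SEVERITY_LABELS, ParameterDraw

__all__ = ["DoseOutcome", "TreePath", "enumerate_paths", "expected_dose_outcome", "N_PATHS"]

#: 1 no-error path + 11 error types x (detected, undetected-no-harm, 3 severities)
N_PATHS = 1 + N_ERROR_TYPES * 5


class TreePath(NamedTuple):
    label: str
    probability: float
    cost: float
    qaly_decrement: float


@dataclass
class DoseOutcome:
    """Expected per-dose event probabilities, cost and QALY decrement."""

    p_no_error: np.ndarray
    p_detected_error: np.ndarray
    p_undetected_no_harm: np.ndarray
    p_pade_by_severity: np.ndarray  # (..., 3): minor, moderate, severe
    expected_error_cost: np.ndarray  # GBP/dose, excl. administration time
    expected_qaly_decrement: np.ndarray  # QALYs/dose

    @property
    def p_pade(self) -> np.ndarray:
        return self.p_pade_by_severity.sum(axis=-1)

    @property
    def p_moderate_severe_pade(self) -> np.ndarray:
        return self.p_pade_by_severity[..., 1:].sum(axis=-1)

    def total_probability(self) -> np.ndarray:
        return (
            self.p_no_error
            + self.p_detected_error
            + self.p_undetected_no_harm
            + self.p_pade
        )


def enumerate_paths(draw: ParameterDraw, arm: str) -> list[TreePath]:
    """List every terminal path of the tree for a scalar draw.

    Returns 56 paths with their probability, cost and QALY decrement;
    probabilities sum to 1.  Intended for audit (CSV export) and as the
    exhaustive oracle for :func:`expected_dose_outcome`.
    """
    a = draw.arm(arm)
    node1 = np.asarray(a.node1, dtype=float)
    if node1.ndim != 1:
        raise ValueError("enumerate_paths requires a scalar (unbatched) draw")
    sev = np.asarray(a.severity, dtype=float)
    p_und = float(draw.p_undetected)
    p_nh = float(draw.p_no_harm)
    cost_det = float(draw.cost_detected)
    paths = [TreePath("no_error", float(node1[0]), 0.0, 0.0)]
    for i in range(N_ERROR_TYPES):
        p_i = float(node1[i + 1])
        t = f"error_type_{i + 1}"
        paths.append(TreePath(f"{t}:detected", p_i * (1.0 - p_und), cost_det, 0.0))
        paths.append(TreePath(f"{t}:undetected_no_harm", p_i * p_und * p_nh, 0.0, 0.0))
        for s, name in enumerate(SEVERITY_LABELS):
            paths.append(
                TreePath(
                    f"{t}:pade_{name}",
                    p_i * p_und * (1.0 - p_nh) * float(sev[i, s]),
                    float(draw.cost_pade[..., s]),
                    float(draw.qaly_decrement[..., s]),
                )
            )
    return paths


def expected_dose_outcome(draw: ParameterDraw, arm: str) -> DoseOutcome:
    """Aggregate the tree into per-dose expectations for one arm.

    Equals the probability-weighted sum over :func:`enumerate_paths`
    exactly; implemented in closed form so it vectorises over batched
    draws.
    """
    a = draw.arm(arm)
    node1 = np.asarray(a.node1, dtype=float)
    error_probs = node1[..., 1:]  # (..., 11)
    p_error = error_probs.sum(axis=-1)
    p_und = np.asarray(draw.p_undetected, dtype=float)
    p_nh = np.asarray(draw.p_no_harm, dtype=float)

    p_detected = p_error * (1.0 - p_und)
    p_und_no_harm = p_error * p_und * p_nh
    # severity mix of harmful undetected errors: node-1 weights x node-4 triples
    type_sev = np.einsum("...i,...is->...s", error_probs, a.severity)
    p_pade_sev = (p_und * (1.0 - p_nh))[..., np.newaxis] * type_sev

    cost = p_detected * draw.cost_detected + np.einsum(
        "...s,...s->...", p_pade_sev, draw.cost_pade
    )
    qaly = np.einsum("...s,...s->...", p_pade_sev, draw.qaly_decrement)
    return DoseOutcome(
        p_no_error=node1[..., 0],
        p_detected_error=p_detected,
        p_undetected_no_harm=p_und_no_harm,
        p_pade_by_severity=p_pade_sev,
        expected_error_cost=cost,
        expected_qaly_decrement=qaly,
    )
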