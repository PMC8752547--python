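"""Sensitivity scenarios as transformations of the base-case configuration.

Built-in scenarios cover the published one-way analyses: shorter/longer
time horizons, a larger annual dose volume, deterministic variants of
the detection and no-harm probabilities, and the lower-risk rescaling in
which the expected undetected-error frequency with current guidelines is
set to 32% of doses (optionally with the relative effect of user-testing
halved).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .params import (
    CohortSpec,
    ConfigError,
    DistributionSpec,
    GuidelineArmSpec,
    ModelConfig,
    SharedSpec,
)
from .psa import PsaResult, run_psa

__all__ = [
    "ScenarioSpec",
    "BUILTIN_SCENARIOS",
    "apply_scenario",
    "rescale_error_frequency",
    "run_scenario_suite",
]

#: shared-distribution names accepted as overrides
_DIST_KEYS = ("p_undetected", "p_no_harm", "cost_detected")
_COHORT_KEYS = ("horizon_years", "doses_per_year", "discount_rate", "wtp")


@dataclass(frozen=True)
class ScenarioSpec:
    """Named set of typed edits to the base-case configuration."""

    name: str
    overrides: Mapping[str, object] = field(default_factory=dict)
    #: rescale the expected undetected-error frequency with current guidelines
    target_undetected_frequency: float | None = None
    #: multiply the relative reduction achieved by user-testing (1 = unchanged)
    effectiveness_multiplier: float = 1.0

    def __post_init__(self):
        for key in self.overrides:
            if key not in _COHORT_KEYS and key not in _DIST_KEYS:
                raise ConfigError(f"scenario {self.name!r}: unknown override key {key!r}")
        if self.target_undetected_frequency is not None and not (
            0 < self.target_undetected_frequency < 1
        ):
            raise ConfigError("target_undetected_frequency must be in (0, 1)")
        if not (0 < self.effectiveness_multiplier <= 1):
            raise ConfigError("effectiveness_multiplier must be in (0, 1]")


def _scaled_arm(arm: GuidelineArmSpec, k: float) -> GuidelineArmSpec:
    """Scale an arm's error-type mass by ``k``, moving freed mass to no-error.

    Severity pseudo-counts scale uniformly, so the conditional severity
    composition of each error type is untouched; the total pseudo-count
    (and hence the Dirichlet's concentration) is preserved.
    """
    n1 = arm.node1
    new_sev = arm.severity * k
    new_errors = n1[1:] * k
    new_no_error = n1.sum() - new_errors.sum()
    node1 = np.concatenate([[new_no_error], new_errors])
    if np.any(node1 < 0) or node1[0] > n1.sum():
        raise ConfigError(f"rescaling factor {k:.4g} pushes probabilities outside [0, 1]")
    return GuidelineArmSpec(
        label=arm.label,
        node1_pseudo_counts=tuple(node1),
        severity_pseudo_counts=tuple(tuple(r) for r in new_sev),
        admin_time=arm.admin_time,
    )


def rescale_error_frequency(
    current: GuidelineArmSpec,
    user: GuidelineArmSpec,
    shared: SharedSpec,
    target_undetected_frequency: float,
    effectiveness_multiplier: float = 1.0,
) -> tuple[GuidelineArmSpec, GuidelineArmSpec]:
    """Rescale both arms to a target expected undetected-error frequency.

    The current arm's error-type probability mass is multiplied by
    ``k = target / (p_error_current * E[p_undetected])`` with the freed
    mass reassigned to the no-error category; the user arm is scaled so
    that its relative reduction in expected undetected-error frequency
    equals the base-case relative reduction times
    ``effectiveness_multiplier``.  Conditional severity compositions are
    unchanged.
    """
    if not (0 < target_undetected_frequency < 1):
        raise ConfigError("target_undetected_frequency must be in (0, 1)")
    if not (0 < effectiveness_multiplier <= 1):
        raise ConfigError("effectiveness_multiplier must be in (0, 1]")
    e_und = float(shared.p_undetected.mean())
    f_current = current.error_mass_fraction * e_und
    f_user = user.error_mass_fraction * e_und
    rel_reduction = 1.0 - f_user / f_current

    k_current = target_undetected_frequency / f_current
    new_f_user = target_undetected_frequency * (
        1.0 - rel_reduction * effectiveness_multiplier
    )
    k_user = (new_f_user / e_und) / user.error_mass_fraction
    return _scaled_arm(current, k_current), _scaled_arm(user, k_user)


def apply_scenario(base: ModelConfig, scenario: ScenarioSpec) -> ModelConfig:
    """Return a new configuration with the scenario's edits applied."""
    cohort_kwargs = {}
    for key in _COHORT_KEYS:
        if key in scenario.overrides:
            cohort_kwargs[key] = scenario.overrides[key]
    cohort = dataclasses.replace(base.cohort, **cohort_kwargs) if cohort_kwargs else base.cohort

    shared = base.shared
    shared_kwargs = {}
    for key in _DIST_KEYS:
        if key in scenario.overrides:
            value = scenario.overrides[key]
            if not isinstance(value, DistributionSpec):
                value = DistributionSpec("deterministic", (float(value),))
            shared_kwargs[key] = value
    if shared_kwargs:
        shared = dataclasses.replace(shared, **shared_kwargs)

    current, user = base.current, base.user
    if scenario.target_undetected_frequency is not None:
        current, user = rescale_error_frequency(
            current,
            user,
            shared,
            scenario.target_undetected_frequency,
            scenario.effectiveness_multiplier,
        )
    return ModelConfig(current=current, user=user, shared=shared, cohort=cohort)


#: Built-in one-way sensitivity scenarios.  Detection variants use the
#: endpoints of the 95% prediction interval behind the base-case
#: detection distribution as deterministic values.
BUILTIN_SCENARIOS: dict[str, ScenarioSpec] = {
    s.name: s
    for s in (
        ScenarioSpec("base"),
        ScenarioSpec("horizon_1y", overrides={"horizon_years": 1}),
        ScenarioSpec("horizon_10y", overrides={"horizon_years": 10}),
        ScenarioSpec("doses_20000", overrides={"doses_per_year": 20000}),
        ScenarioSpec("detection_low", overrides={"p_undetected": 0.655}),
        ScenarioSpec("detection_high", overrides={"p_undetected": 0.918}),
        ScenarioSpec("no_harm_low", overrides={"p_no_harm": 0.75}),
        ScenarioSpec("no_harm_high", overrides={"p_no_harm": 0.99}),
        ScenarioSpec("error_freq_32", target_undetected_frequency=0.32),
        ScenarioSpec(
            "error_freq_32_half_effect",
            target_undetected_frequency=0.32,
            effectiveness_multiplier=0.5,
        ),
    )
}


def run_scenario_suite(
    base: ModelConfig,
    scenarios: Mapping[str, ScenarioSpec],
    n_samples: int = 20000,
    seed: int = 1,
) -> tuple[pd.DataFrame, dict[str, PsaResult]]:
    """Run the PSA for every scenario; one summary row per scenario.

    Each scenario is run with the same seed, so the ``base`` row is
    identical to a standalone base-case run at that seed.
    """
    rows = []
    results: dict[str, PsaResult] = {}
    for name, scenario in scenarios.items():
        config = apply_scenario(base, scenario)
        res = run_psa(config, n_samples=n_samples, seed=seed)
        results[name] = res
        s = res.summary()
        rows.append(
            {
                "scenario": name,
                "mean_delta_mod_severe_pades": s.loc["delta_mod_severe", "mean"],
                "mean_delta_pades": s.loc["delta_pades", "mean"],
                "mean_delta_qaly": s.loc["delta_qaly", "mean"],
                "mean_ics": s.loc["ics", "mean"],
                "ics_ci_lower": s.loc["ics", "ci_lower"],
                "ics_ci_upper": s.loc["ics", "ci_upper"],
                "p_cost_saving": res.p_cost_saving,
                "mean_nmb": s.loc["nmb", "mean"],
                "nmb_ci_lower": s.loc["nmb", "ci_lower"],
                "nmb_ci_upper": s.loc["nmb", "ci_upper"],
                "p_cost_effective": res.p_cost_effective(),
            }
        )
    return pd.DataFrame(rows).set_index("scenario"), results
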