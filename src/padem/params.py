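"""Model input distributions, configuration loading and joint parameter sampling.

The model compares two versions of a written guideline for intravenous
medicines administration ("current" and "user_tested").  Each arm is
described by a Dirichlet distribution over twelve node-1 categories
(no-error plus 11 error types), one conditional severity Dirichlet
(minor / moderate / severe harm) per error type, and a normal
administration-time distribution.  Shared inputs cover error detection,
the probability an undetected error causes no harm, error-related costs
and QALY decrements, the user-testing resource model, staff rates and
the cohort settings (doses per year, horizon, discounting,
willingness-to-pay).

Dirichlet inputs are posteriors from observed multinomial study counts
with a flat pseudo-count prior so that unobserved error types keep a
small non-zero probability.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "DistributionSpec",
    "GuidelineArmSpec",
    "UserTestingSpec",
    "StaffRates",
    "SharedSpec",
    "CohortSpec",
    "ModelConfig",
    "ArmDraw",
    "ParameterDraw",
    "N_ERROR_TYPES",
    "N_SEVERITIES",
    "SEVERITY_LABELS",
    "build_dirichlet_posterior",
    "arm_spec_from_counts",
    "sample_draw",
    "expected_draw",
    "load_config",
    "save_config",
    "base_case_config",
    "base_case_path",
]

N_ERROR_TYPES = 11
N_SEVERITIES = 3
SEVERITY_LABELS = ("minor", "moderate", "severe")

_FAMILIES = ("dirichlet", "beta", "lognormal", "normal", "deterministic")


class ConfigError(ValueError):
    """A model input failed validation."""


@dataclass(frozen=True)
class DistributionSpec:
    """Tagged parametric distribution for one model input.

    Parameters
    ----------
    family
        One of ``dirichlet`` (params are pseudo-counts per category),
        ``beta`` (shape1, shape2), ``lognormal`` (mu, sigma on the
        natural-log scale), ``normal`` (mean, sd) or ``deterministic``
        (single value).
    params
        Distribution parameters, see above.
    truncation
        Optional ``(lower, upper)`` closed interval; samples are clamped
        into it after drawing.  ``None`` entries leave that side open.
    """

    family: str
    params: tuple[float, ...]
    truncation: tuple[float | None, float | None] | None = None

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.family not in _FAMILIES:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "dirichlet":
            if len(p) < 2 or any(a <= 0 for a in p):
                raise ConfigError("dirichlet pseudo-counts must be > 0 (>= 2 categories)")
        elif self.family == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise ConfigError("beta requires two positive shapes")
        elif self.family == "lognormal":
            if len(p) != 2 or p[1] <= 0:
                raise ConfigError("lognormal requires (mu, sigma) with sigma > 0")
        elif self.family == "normal":
            if len(p) != 2 or p[1] < 0:
                raise ConfigError("normal requires (mean, sd) with sd >= 0")
        elif self.family == "deterministic":
            if len(p) != 1:
                raise ConfigError("deterministic requires a single value")
        if self.truncation is not None:
            lo, hi = self.truncation
            if lo is not None and hi is not None and lo > hi:
                raise ConfigError("truncation lower bound exceeds upper bound")
            object.__setattr__(self, "truncation", (lo, hi))

    # -- sampling -----------------------------------------------------

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draw from the distribution, applying any truncation by clamping."""
        if self.family == "dirichlet":
            k = len(self.params)
            shape = (k,) if size is None else tuple(np.atleast_1d(size)) + (k,)
            g = rng.gamma(np.asarray(self.params), size=shape)
            x = g / g.sum(axis=-1, keepdims=True)
        elif self.family == "beta":
            x = rng.beta(self.params[0], self.params[1], size=size)
        elif self.family == "lognormal":
            x = rng.lognormal(self.params[0], self.params[1], size=size)
        elif self.family == "normal":
            x = rng.normal(self.params[0], self.params[1], size=size)
        else:  # deterministic
            x = np.full(size if size is not None else (), self.params[0])
        if self.truncation is not None:
            lo, hi = self.truncation
            x = np.clip(x, lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
        return np.asarray(x, dtype=float)

    def mean(self) -> np.ndarray:
        """Analytic mean of the untruncated distribution.

        Truncation in this model clips only far-tail mass (e.g. the
        detection risk ratio above 1, negative times), so the untruncated
        mean is used as the expected-value input throughout.
        """
        p = self.params
        if self.family == "dirichlet":
            a = np.asarray(p)
            return a / a.sum()
        if self.family == "beta":
            return np.asarray(p[0] / (p[0] + p[1]))
        if self.family == "lognormal":
            return np.asarray(np.exp(p[0] + p[1] ** 2 / 2.0))
        if self.family == "normal":
            return np.asarray(p[0])
        return np.asarray(p[0])

    # -- (de)serialisation --------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"family": self.family, "params": list(self.params)}
        if self.truncation is not None:
            d["truncation"] = list(self.truncation)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        try:
            family = d["family"]
            params = d["params"]
        except KeyError as e:
            raise ConfigError(f"distribution is missing field {e.args[0]!r}") from None
        trunc = d.get("truncation")
        if trunc is not None:
            trunc = tuple(None if v is None else float(v) for v in trunc)
        return cls(family=family, params=tuple(params), truncation=trunc)


def build_dirichlet_posterior(
    observed_counts: Sequence[float], prior_count: float
) -> DistributionSpec:
    """Dirichlet posterior from observed multinomial counts plus a flat prior.

    Fractional counts are allowed (ties in severity assignment produce
    half-counts).  With all-zero observations the posterior is the flat
    prior itself, keeping every category at a small non-zero probability.
    """
    counts = np.asarray(observed_counts, dtype=float)
    if prior_count <= 0:
        raise ConfigError("prior_count must be > 0")
    if np.any(counts < 0):
        raise ConfigError("observed counts must be >= 0")
    return DistributionSpec("dirichlet", tuple(counts + prior_count))


@dataclass(frozen=True)
class GuidelineArmSpec:
    """One guideline arm: node-1 Dirichlet, node-4 severity Dirichlets, time.

    ``node1_pseudo_counts`` has 12 entries (no-error first, then error
    types 1..11); ``severity_pseudo_counts`` is an (11, 3) array of
    (minor, moderate, severe) pseudo-counts whose row sums must equal the
    corresponding node-1 entries — the two are the same study counts
    viewed marginally and jointly.
    """

    label: str
    node1_pseudo_counts: tuple[float, ...]
    severity_pseudo_counts: tuple[tuple[float, float, float], ...]
    admin_time: DistributionSpec

    def __post_init__(self):
        n1 = np.asarray(self.node1_pseudo_counts, dtype=float)
        sev = np.asarray(self.severity_pseudo_counts, dtype=float)
        if n1.shape != (N_ERROR_TYPES + 1,):
            raise ConfigError(
                f"arm {self.label!r}: node-1 vector must have {N_ERROR_TYPES + 1} "
                f"entries, got {n1.shape[0] if n1.ndim == 1 else n1.shape}"
            )
        if sev.shape != (N_ERROR_TYPES, N_SEVERITIES):
            raise ConfigError(
                f"arm {self.label!r}: severity table must be "
                f"{N_ERROR_TYPES}x{N_SEVERITIES}, got {sev.shape}"
            )
        if np.any(n1 <= 0) or np.any(sev <= 0):
            raise ConfigError(f"arm {self.label!r}: pseudo-counts must be > 0")
        if not np.allclose(n1[1:], sev.sum(axis=1), rtol=0, atol=1e-9):
            raise ConfigError(
                f"arm {self.label!r}: node-1 error-type pseudo-counts must equal "
                "the row sums of the severity table"
            )
        object.__setattr__(self, "node1_pseudo_counts", tuple(float(x) for x in n1))
        object.__setattr__(
            self, "severity_pseudo_counts", tuple(tuple(float(x) for x in row) for row in sev)
        )

    @property
    def node1(self) -> np.ndarray:
        return np.asarray(self.node1_pseudo_counts)

    @property
    def severity(self) -> np.ndarray:
        return np.asarray(self.severity_pseudo_counts)

    @property
    def error_mass_fraction(self) -> float:
        """Expected probability that a dose contains an error (node-1 mean)."""
        n1 = self.node1
        return float(n1[1:].sum() / n1.sum())

    def to_dict(self) -> dict:
        return {
            "node1_pseudo_counts": list(self.node1_pseudo_counts),
            "severity_pseudo_counts": [list(r) for r in self.severity_pseudo_counts],
            "admin_time": self.admin_time.to_dict(),
        }


def arm_spec_from_counts(
    label: str,
    no_error_count: float,
    severity_counts: np.ndarray,
    admin_time: DistributionSpec,
    prior_count: float = 0.1,
) -> GuidelineArmSpec:
    """Build an arm spec by Bayesian updating of observed study counts.

    ``severity_counts`` is the (11, 3) table of observed error counts by
    type and severity; ``no_error_count`` the number of error-free doses.
    Each cell (and the no-error category) receives ``prior_count``; node-1
    error-type pseudo-counts are the severity row sums, so the marginal
    and conditional posteriors stay mutually consistent.
    """
    sev = np.asarray(severity_counts, dtype=float)
    if sev.shape != (N_ERROR_TYPES, N_SEVERITIES):
        raise ConfigError(f"severity_counts must be {N_ERROR_TYPES}x{N_SEVERITIES}")
    if no_error_count < 0 or np.any(sev < 0):
        raise ConfigError("observed counts must be >= 0")
    post_sev = sev + prior_count
    node1 = np.concatenate([[no_error_count + prior_count], post_sev.sum(axis=1)])
    return GuidelineArmSpec(
        label=label,
        node1_pseudo_counts=tuple(node1),
        severity_pseudo_counts=tuple(tuple(r) for r in post_sev),
        admin_time=admin_time,
    )


_UT_INTERVIEW_KEYS = ("pilot", "round1", "round2", "round3")
_UT_REVISION_KEYS = ("round1", "round2", "round3")


@dataclass(frozen=True)
class UserTestingSpec:
    """Resource model for the one-off user-testing intervention.

    Interviews involve a pharmacist (tester) and a nurse (participant)
    and are transcribed at a per-spoken-minute rate; analysis time is per
    interview and revision time per round, both pharmacist-only.
    """

    interview_minutes: tuple[DistributionSpec, ...]  # pilot, rounds 1-3
    analysis_minutes: tuple[DistributionSpec, ...]  # pilot, rounds 1-3 (per interview)
    revision_minutes: tuple[DistributionSpec, ...]  # after rounds 1-3 (per round)
    n_pilot: int = 4
    n_per_round: int = 10
    transcription_rate: float = 1.75  # GBP per spoken minute
    training_cost: float = 562.0  # GBP, one-off
    equipment_cost: float = 4.0  # GBP, one-off

    def __post_init__(self):
        if len(self.interview_minutes) != 4 or len(self.analysis_minutes) != 4:
            raise ConfigError("interview/analysis require 4 distributions (pilot, rounds 1-3)")
        if len(self.revision_minutes) != 3:
            raise ConfigError("revision requires 3 distributions (after rounds 1-3)")
        if self.n_pilot < 1 or self.n_per_round < 1:
            raise ConfigError("interview counts must be positive integers")
        if min(self.transcription_rate, self.training_cost, self.equipment_cost) < 0:
            raise ConfigError("rates and costs must be >= 0")

    @property
    def interview_counts(self) -> np.ndarray:
        return np.asarray([self.n_pilot] + [self.n_per_round] * 3, dtype=float)

    def to_dict(self) -> dict:
        return {
            "interview_minutes": {
                k: d.to_dict() for k, d in zip(_UT_INTERVIEW_KEYS, self.interview_minutes)
            },
            "analysis_minutes": {
                k: d.to_dict() for k, d in zip(_UT_INTERVIEW_KEYS, self.analysis_minutes)
            },
            "revision_minutes": {
                k: d.to_dict() for k, d in zip(_UT_REVISION_KEYS, self.revision_minutes)
            },
            "n_pilot": self.n_pilot,
            "n_per_round": self.n_per_round,
            "transcription_rate_per_min": self.transcription_rate,
            "training_cost": self.training_cost,
            "equipment_cost": self.equipment_cost,
        }


@dataclass(frozen=True)
class StaffRates:
    pharmacist_per_hour: float
    nurse_per_hour: float

    def __post_init__(self):
        if self.pharmacist_per_hour <= 0 or self.nurse_per_hour <= 0:
            raise ConfigError("staff rates must be > 0")

    def to_dict(self) -> dict:
        return {
            "pharmacist_per_hour": self.pharmacist_per_hour,
            "nurse_per_hour": self.nurse_per_hour,
        }


@dataclass(frozen=True)
class SharedSpec:
    """Inputs common to both arms: detection, harm, costs, QALYs, staffing."""

    p_undetected: DistributionSpec  # node 2: risk ratio used as probability
    p_no_harm: DistributionSpec  # node 3
    cost_detected: DistributionSpec  # GBP per detected error
    cost_pade: tuple[DistributionSpec, DistributionSpec, DistributionSpec]
    qaly_decrement: tuple[DistributionSpec, DistributionSpec, DistributionSpec]
    staff_rates: StaffRates
    user_testing: UserTestingSpec

    def __post_init__(self):
        if len(self.cost_pade) != N_SEVERITIES or len(self.qaly_decrement) != N_SEVERITIES:
            raise ConfigError("cost_pade and qaly_decrement need exactly three severity levels")

    def to_dict(self) -> dict:
        return {
            "p_undetected": self.p_undetected.to_dict(),
            "p_no_harm": self.p_no_harm.to_dict(),
            "cost_detected": self.cost_detected.to_dict(),
            "cost_pade": {k: d.to_dict() for k, d in zip(SEVERITY_LABELS, self.cost_pade)},
            "qaly_decrement": {
                k: d.to_dict() for k, d in zip(SEVERITY_LABELS, self.qaly_decrement)
            },
            "staff_rates": self.staff_rates.to_dict(),
            "user_testing": self.user_testing.to_dict(),
        }


@dataclass(frozen=True)
class CohortSpec:
    doses_per_year: float = 4000.0
    horizon_years: int = 5
    discount_rate: float = 0.035
    wtp: float = 20000.0  # GBP per QALY

    def __post_init__(self):
        if self.doses_per_year <= 0:
            raise ConfigError("doses_per_year must be > 0")
        if self.horizon_years < 1:
            raise ConfigError("horizon_years must be >= 1")
        if not (0 <= self.discount_rate < 1):
            raise ConfigError("discount_rate must be in [0, 1)")
        if self.wtp < 0:
            raise ConfigError("willingness-to-pay must be >= 0")

    def to_dict(self) -> dict:
        return {
            "doses_per_year": self.doses_per_year,
            "horizon_years": self.horizon_years,
            "discount_rate": self.discount_rate,
            "wtp_per_qaly": self.wtp,
        }


@dataclass(frozen=True)
class ModelConfig:
    """Complete model configuration: both arms, shared inputs, cohort."""

    current: GuidelineArmSpec
    user: GuidelineArmSpec
    shared: SharedSpec
    cohort: CohortSpec

    def arm(self, label: str) -> GuidelineArmSpec:
        if label == self.current.label:
            return self.current
        if label == self.user.label:
            return self.user
        raise KeyError(f"unknown arm {label!r}")

    def to_dict(self) -> dict:
        return {
            "arms": {
                self.current.label: self.current.to_dict(),
                self.user.label: self.user.to_dict(),
            },
            "shared": self.shared.to_dict(),
            "cohort": self.cohort.to_dict(),
        }


# ---------------------------------------------------------------------------
# Joint draws
# ---------------------------------------------------------------------------


@dataclass
class ArmDraw:
    """Arm-specific sampled values; leading axes are batch dimensions."""

    node1: np.ndarray  # (..., 12) probabilities
    severity: np.ndarray  # (..., 11, 3) conditional severity probabilities
    admin_minutes: np.ndarray  # (...)


@dataclass
class ParameterDraw:
    """One joint realisation (or a batch) of every stochastic model input."""

    current: ArmDraw
    user: ArmDraw
    p_undetected: np.ndarray
    p_no_harm: np.ndarray
    cost_detected: np.ndarray
    cost_pade: np.ndarray  # (..., 3)
    qaly_decrement: np.ndarray  # (..., 3)
    ut_interview_minutes: np.ndarray  # (..., 4)
    ut_analysis_minutes: np.ndarray  # (..., 4)
    ut_revision_minutes: np.ndarray  # (..., 3)

    def arm(self, label: str) -> ArmDraw:
        if label in ("current", "current_guidelines"):
            return self.current
        if label in ("user", "user_tested"):
            return self.user
        raise KeyError(f"unknown arm {label!r}")


def _sample_arm(spec: GuidelineArmSpec, rng: np.random.Generator, size) -> ArmDraw:
    node1 = DistributionSpec("dirichlet", spec.node1_pseudo_counts).sample(rng, size=size)
    shape = (N_ERROR_TYPES, N_SEVERITIES)
    if size is not None:
        shape = tuple(np.atleast_1d(size)) + shape
    g = rng.gamma(spec.severity, size=shape)
    sev = g / g.sum(axis=-1, keepdims=True)
    admin = np.clip(spec.admin_time.sample(rng, size=size), 0.0, None)
    return ArmDraw(node1=node1, severity=sev, admin_minutes=admin)


def _stack(specs: Iterable[DistributionSpec], rng, size) -> np.ndarray:
    return np.stack([s.sample(rng, size=size) for s in specs], axis=-1)


def sample_draw(
    config: ModelConfig, rng: np.random.Generator, size=None
) -> ParameterDraw:
    """Draw one joint realisation (``size=None``) or a batch of them.

    Shared inputs are sampled once per realisation and reused by both
    arms (common random numbers); arm-specific Dirichlets and times are
    sampled independently per arm.  Probabilities drawn from unbounded
    families are clamped into [0, 1]; times and QALY decrements into
    [0, inf).  The sampling order is fixed, so a given generator state
    always yields the same draw.
    """
    shared = config.shared
    p_und = np.clip(shared.p_undetected.sample(rng, size=size), 0.0, 1.0)
    p_nh = np.clip(shared.p_no_harm.sample(rng, size=size), 0.0, 1.0)
    cost_det = np.clip(shared.cost_detected.sample(rng, size=size), 0.0, None)
    cost_pade = np.clip(_stack(shared.cost_pade, rng, size), 0.0, None)
    qdec = np.clip(_stack(shared.qaly_decrement, rng, size), 0.0, None)
    ut = shared.user_testing
    ut_int = np.clip(_stack(ut.interview_minutes, rng, size), 0.0, None)
    ut_ana = np.clip(_stack(ut.analysis_minutes, rng, size), 0.0, None)
    ut_rev = np.clip(_stack(ut.revision_minutes, rng, size), 0.0, None)
    current = _sample_arm(config.current, rng, size)
    user = _sample_arm(config.user, rng, size)
    return ParameterDraw(
        current=current,
        user=user,
        p_undetected=p_und,
        p_no_harm=p_nh,
        cost_detected=cost_det,
        cost_pade=cost_pade,
        qaly_decrement=qdec,
        ut_interview_minutes=ut_int,
        ut_analysis_minutes=ut_ana,
        ut_revision_minutes=ut_rev,
    )


def _mean_arm(spec: GuidelineArmSpec) -> ArmDraw:
    sev = spec.severity
    return ArmDraw(
        node1=DistributionSpec("dirichlet", spec.node1_pseudo_counts).mean(),
        severity=sev / sev.sum(axis=-1, keepdims=True),
        admin_minutes=spec.admin_time.mean(),
    )


def expected_draw(config: ModelConfig) -> ParameterDraw:
    """Deterministic draw with every input at its analytic mean."""
    shared = config.shared
    return ParameterDraw(
        current=_mean_arm(config.current),
        user=_mean_arm(config.user),
        p_undetected=shared.p_undetected.mean(),
        p_no_harm=shared.p_no_harm.mean(),
        cost_detected=shared.cost_detected.mean(),
        cost_pade=np.stack([d.mean() for d in shared.cost_pade], axis=-1),
        qaly_decrement=np.stack([d.mean() for d in shared.qaly_decrement], axis=-1),
        ut_interview_minutes=np.stack(
            [d.mean() for d in shared.user_testing.interview_minutes], axis=-1
        ),
        ut_analysis_minutes=np.stack(
            [d.mean() for d in shared.user_testing.analysis_minutes], axis=-1
        ),
        ut_revision_minutes=np.stack(
            [d.mean() for d in shared.user_testing.revision_minutes], axis=-1
        ),
    )


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------


def _require(d: Mapping, key: str, where: str):
    if key not in d:
        raise ConfigError(f"missing field {key!r} in {where}")
    return d[key]


def _arm_from_dict(label: str, d: Mapping) -> GuidelineArmSpec:
    arm = GuidelineArmSpec(
        label=label,
        node1_pseudo_counts=tuple(_require(d, "node1_pseudo_counts", f"arm {label}")),
        severity_pseudo_counts=tuple(
            tuple(r) for r in _require(d, "severity_pseudo_counts", f"arm {label}")
        ),
        admin_time=DistributionSpec.from_dict(_require(d, "admin_time", f"arm {label}")),
    )
    # configuration files hold study posteriors built with a 0.1 prior per
    # cell, so every pseudo-count must respect that floor
    if np.any(arm.node1 < 0.1 - 1e-12) or np.any(arm.severity < 0.1 - 1e-12):
        raise ConfigError(f"arm {label!r}: pseudo-counts must be >= 0.1 (prior floor)")
    return arm


def _shared_from_dict(d: Mapping) -> SharedSpec:
    ut = _require(d, "user_testing", "shared")
    iv = _require(ut, "interview_minutes", "user_testing")
    an = _require(ut, "analysis_minutes", "user_testing")
    rv = _require(ut, "revision_minutes", "user_testing")
    user_testing = UserTestingSpec(
        interview_minutes=tuple(
            DistributionSpec.from_dict(_require(iv, k, "interview_minutes"))
            for k in _UT_INTERVIEW_KEYS
        ),
        analysis_minutes=tuple(
            DistributionSpec.from_dict(_require(an, k, "analysis_minutes"))
            for k in _UT_INTERVIEW_KEYS
        ),
        revision_minutes=tuple(
            DistributionSpec.from_dict(_require(rv, k, "revision_minutes"))
            for k in _UT_REVISION_KEYS
        ),
        n_pilot=int(ut.get("n_pilot", 4)),
        n_per_round=int(ut.get("n_per_round", 10)),
        transcription_rate=float(ut.get("transcription_rate_per_min", 1.75)),
        training_cost=float(ut.get("training_cost", 562.0)),
        equipment_cost=float(ut.get("equipment_cost", 4.0)),
    )
    cp = _require(d, "cost_pade", "shared")
    qd = _require(d, "qaly_decrement", "shared")
    sr = _require(d, "staff_rates", "shared")
    return SharedSpec(
        p_undetected=DistributionSpec.from_dict(_require(d, "p_undetected", "shared")),
        p_no_harm=DistributionSpec.from_dict(_require(d, "p_no_harm", "shared")),
        cost_detected=DistributionSpec.from_dict(_require(d, "cost_detected", "shared")),
        cost_pade=tuple(
            DistributionSpec.from_dict(_require(cp, k, "cost_pade")) for k in SEVERITY_LABELS
        ),
        qaly_decrement=tuple(
            DistributionSpec.from_dict(_require(qd, k, "qaly_decrement"))
            for k in SEVERITY_LABELS
        ),
        staff_rates=StaffRates(
            pharmacist_per_hour=float(_require(sr, "pharmacist_per_hour", "staff_rates")),
            nurse_per_hour=float(_require(sr, "nurse_per_hour", "staff_rates")),
        ),
        user_testing=user_testing,
    )


def config_from_dict(d: Mapping) -> ModelConfig:
    arms = _require(d, "arms", "config")
    if set(arms) != {"current", "user_tested"}:
        raise ConfigError("config must define exactly the arms 'current' and 'user_tested'")
    cohort_d = _require(d, "cohort", "config")
    cohort = CohortSpec(
        doses_per_year=float(_require(cohort_d, "doses_per_year", "cohort")),
        horizon_years=int(_require(cohort_d, "horizon_years", "cohort")),
        discount_rate=float(_require(cohort_d, "discount_rate", "cohort")),
        wtp=float(_require(cohort_d, "wtp_per_qaly", "cohort")),
    )
    return ModelConfig(
        current=_arm_from_dict("current", arms["current"]),
        user=_arm_from_dict("user_tested", arms["user_tested"]),
        shared=_shared_from_dict(_require(d, "shared", "config")),
        cohort=cohort,
    )


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return config_from_dict(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def base_case_path() -> Path:
    """Path of the bundled base-case configuration."""
    return Path(importlib.resources.files("padem").joinpath("data/base_case.yaml"))


def base_case_config() -> ModelConfig:
    """The bundled base-case configuration (all printed study inputs)."""
    return load_config(base_case_path())
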