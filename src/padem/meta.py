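"""Random-effects meta-analysis of double-checking trials.

The detection input of the decision tree is the risk ratio of a
medication administration error remaining after a nurse double-check.
Trials report 2x2 tables (errors / administrations with and without
double-checking).  Pooling uses the DerSimonian-Laird estimator; the
95% prediction interval — the plausible risk ratio in a new setting,
incorporating between-trial heterogeneity — uses a t(k-2) multiplier
around the pooled log risk ratio with variance ``se^2 + tau^2``, and is
converted into the lognormal input distribution of the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .params import DistributionSpec

__all__ = [
    "TrialTable",
    "REResult",
    "pool_random_effects",
    "pool_log_effects",
    "to_lognormal_spec",
    "read_trials_csv",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class TrialTable:
    """One two-arm trial: error counts over administrations per arm."""

    label: str
    events_checked: float
    n_checked: float
    events_unchecked: float
    n_unchecked: float

    def __post_init__(self):
        for events, n in (
            (self.events_checked, self.n_checked),
            (self.events_unchecked, self.n_unchecked),
        ):
            if n <= 0:
                raise ValueError(f"trial {self.label!r}: arm size must be > 0")
            if not (0 <= events <= n):
                raise ValueError(f"trial {self.label!r}: events must lie in [0, n]")

    def log_rr_and_variance(self) -> tuple[float, float]:
        """Log risk ratio (checked vs unchecked) and its sampling variance.

        A continuity correction of 0.5 is added to all four cells when
        any cell of the 2x2 table is zero.
        """
        a, n1, c, n2 = (
            self.events_checked,
            self.n_checked,
            self.events_unchecked,
            self.n_unchecked,
        )
        cells = (a, n1 - a, c, n2 - c)
        if min(cells) == 0:
            a, c = a + 0.5, c + 0.5
            n1, n2 = n1 + 1.0, n2 + 1.0
        log_rr = np.log((a / n1) / (c / n2))
        var = 1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2
        return float(log_rr), float(var)


@dataclass(frozen=True)
class REResult:
    """DerSimonian-Laird pooled estimate with heterogeneity and intervals."""

    pooled_log_rr: float
    se_pooled: float
    tau_squared: float
    ci95: tuple[float, float]  # risk-ratio scale
    pi95: tuple[float, float]  # risk-ratio scale, 95% prediction interval
    k: int
    q_statistic: float
    prediction_interval_reliable: bool


def pool_random_effects(trials: list[TrialTable]) -> REResult:
    """Pool trial risk ratios with the DerSimonian-Laird estimator.

    Between-trial variance tau^2 comes from the Q statistic (floored at
    zero); the prediction interval uses a t distribution with k-2
    degrees of freedom.  With exactly two trials the prediction interval
    is undefined (zero degrees of freedom) and is returned infinite with
    ``prediction_interval_reliable=False``.
    """
    if len(trials) < 2:
        raise ValueError("random-effects pooling requires at least two trials")
    yv = [t.log_rr_and_variance() for t in trials]
    return pool_log_effects([y for y, _ in yv], [v for _, v in yv])


def pool_log_effects(log_effects, variances) -> REResult:
    """DerSimonian-Laird pooling of per-trial log effects and variances."""
    y = np.asarray(log_effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = y.size
    if k < 2:
        raise ValueError("random-effects pooling requires at least two trials")

    w = 1.0 / v
    fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - fixed) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    ci = (np.exp(pooled - _Z95 * se), np.exp(pooled + _Z95 * se))

    reliable = k >= 3
    if reliable:
        t_mult = float(stats.t.ppf(0.975, df=k - 2))
        half = t_mult * np.sqrt(tau2 + se**2)
        pi = (np.exp(pooled - half), np.exp(pooled + half))
    else:
        pi = (0.0, np.inf)
    return REResult(
        pooled_log_rr=pooled,
        se_pooled=se,
        tau_squared=float(tau2),
        ci95=ci,
        pi95=pi,
        k=k,
        q_statistic=q,
        prediction_interval_reliable=reliable,
    )


def to_lognormal_spec(result: REResult, truncate_at_one: bool = True) -> DistributionSpec:
    """Convert a pooled result into the model's lognormal detection input.

    ``mu`` is the pooled log risk ratio; ``sigma`` is the prediction
    interval width on the log scale divided by 2 x 1.96, so the implied
    ``exp(mu +/- 1.96 sigma)`` interval reproduces the prediction
    interval.  A degenerate interval yields a deterministic spec.  Since
    the value is used as a probability, draws are truncated at 1 by
    default.
    """
    lo, hi = result.pi95
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo <= 0:
        raise ValueError("prediction interval must be finite with positive bounds")
    sigma = (np.log(hi) - np.log(lo)) / (2.0 * _Z95)
    if sigma == 0.0:
        return DistributionSpec("deterministic", (float(np.exp(result.pooled_log_rr)),))
    trunc = (None, 1.0) if truncate_at_one else None
    return DistributionSpec(
        "lognormal", (result.pooled_log_rr, float(sigma)), truncation=trunc
    )


def read_trials_csv(path: str | Path) -> list[TrialTable]:
    """Read trial 2x2 tables from CSV.

    Expected columns: label, events_checked, n_checked, events_unchecked,
    n_unchecked.
    """
    frame = pd.read_csv(path)
    required = {"label", "events_checked", "n_checked", "events_unchecked", "n_unchecked"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trial CSV is missing columns: {sorted(missing)}")
    return [
        TrialTable(
            label=str(row.label),
            events_checked=float(row.events_checked),
            n_checked=float(row.n_checked),
            events_unchecked=float(row.events_unchecked),
            n_unchecked=float(row.n_unchecked),
        )
        for row in frame.itertuples()
    ]
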