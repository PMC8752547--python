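"""Monte Carlo probabilistic sensitivity analysis (PSA).

Each iteration draws one joint realisation of every model input, pushes
it through the per-dose decision tree and the cohort economics for both
arms, and records incremental outcomes.  Shared inputs (detection,
no-harm, costs, QALY decrements, user-testing durations) use common
random numbers across arms within an iteration; arm-specific Dirichlets
and administration times are drawn independently per arm.

Summaries are empirical: means, 2.5/97.5 percentile credible intervals
(linear interpolation), exceedance probabilities and the
cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import arm_totals, incremental, user_testing_cost
from .params import ModelConfig, sample_draw
from .tree import expected_dose_outcome

__all__ = ["PsaResult", "CeacCurve", "run_psa", "ceac", "ce_plane_export", "convergence_check"]

#: outcome columns summarised with mean and credible interval
_SUMMARY_COLS = (
    "delta_pades",
    "delta_mod_severe",
    "delta_qaly",
    "ics",
    "nmb",
    "ut_cost",
    "pades_current",
    "pades_user",
    "modsev_current",
    "modsev_user",
    "qaly_current",
    "qaly_user",
    "cost_current",
    "cost_user",
)


@dataclass
class PsaResult:
    """Per-iteration outcomes of one PSA run plus run metadata."""

    iterations: pd.DataFrame
    wtp: float
    seed: int
    n: int

    @property
    def p_cost_saving(self) -> float:
        """Fraction of iterations in which user-testing saves money."""
        return float((self.iterations["ics"] > 0).mean())

    def p_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of iterations with positive net monetary benefit."""
        if wtp is None or wtp == self.wtp:
            return float((self.iterations["nmb"] > 0).mean())
        nmb = wtp * self.iterations["delta_qaly"] + self.iterations["ics"]
        return float((nmb > 0).mean())

    def summary(self) -> pd.DataFrame:
        """Mean and 95% credible interval for every outcome column."""
        it = self.iterations
        rows = {}
        for col in _SUMMARY_COLS:
            lo, hi = np.percentile(it[col], [2.5, 97.5])
            rows[col] = {"mean": it[col].mean(), "ci_lower": lo, "ci_upper": hi}
        return pd.DataFrame(rows).T

    def summary_dict(self) -> dict:
        """Headline outputs as a JSON-serialisable dictionary."""
        s = self.summary()
        out = {
            col: {
                "mean": float(s.loc[col, "mean"]),
                "ci95": [float(s.loc[col, "ci_lower"]), float(s.loc[col, "ci_upper"])],
            }
            for col in _SUMMARY_COLS
        }
        out["p_cost_saving"] = self.p_cost_saving
        out["p_cost_effective"] = self.p_cost_effective()
        out["p_fewer_pades"] = float((self.iterations["delta_pades"] > 0).mean())
        out["p_fewer_mod_severe_pades"] = float(
            (self.iterations["delta_mod_severe"] > 0).mean()
        )
        out["p_fewer_qaly_decrements"] = float((self.iterations["delta_qaly"] > 0).mean())
        out["wtp"] = self.wtp
        out["seed"] = self.seed
        out["n_samples"] = self.n
        return out


@dataclass
class CeacCurve:
    """Probability user-testing is cost-effective across willingness-to-pay."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "p_cost_effective": self.probability})


def run_psa(config: ModelConfig, n_samples: int = 20000, seed: int = 1) -> PsaResult:
    """Run the Monte Carlo PSA; fully reproducible from the seed."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    draw = sample_draw(config, rng, size=n_samples)

    out_c = expected_dose_outcome(draw, "current")
    out_u = expected_dose_outcome(draw, "user_tested")
    ut_cost = user_testing_cost(draw, config.shared.user_testing, config.shared.staff_rates)
    nurse = config.shared.staff_rates.nurse_per_hour
    res_c = arm_totals(out_c, draw.current.admin_minutes, config.cohort, nurse)
    res_u = arm_totals(
        out_u, draw.user.admin_minutes, config.cohort, nurse, user_testing_cost=ut_cost
    )
    inc = incremental(res_c, res_u, config.cohort.wtp)

    iterations = pd.DataFrame(
        {
            "delta_pades": inc.delta_pades,
            "delta_mod_severe": inc.delta_mod_severe_pades,
            "delta_qaly": inc.delta_qaly_decrement,
            "ics": inc.incremental_cost_saving,
            "nmb": inc.nmb_at_wtp,
            "ut_cost": ut_cost,
            "pades_current": res_c.total_pades,
            "pades_user": res_u.total_pades,
            "modsev_current": res_c.moderate_severe_pades,
            "modsev_user": res_u.moderate_severe_pades,
            "qaly_current": res_c.total_qaly_decrement,
            "qaly_user": res_u.total_qaly_decrement,
            "cost_current": res_c.health_system_cost,
            "cost_user": res_u.health_system_cost,
        }
    )
    return PsaResult(iterations=iterations, wtp=config.cohort.wtp, seed=seed, n=n_samples)


def ceac(result: PsaResult, wtp_grid) -> CeacCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid.

    At each grid point the per-iteration net monetary benefit is
    recomputed as ``wtp * delta_qaly + ics``; the curve reports the
    fraction of iterations where it is positive.  The value at wtp = 0
    therefore equals the probability of cost-saving, and the limit for
    large wtp approaches the probability of any QALY gain.
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("wtp grid must be non-empty and non-negative")
    dq = result.iterations["delta_qaly"].to_numpy()
    ics = result.iterations["ics"].to_numpy()
    nmb = grid[:, np.newaxis] * dq[np.newaxis, :] + ics[np.newaxis, :]
    return CeacCurve(wtp=grid, probability=(nmb > 0).mean(axis=1))


def ce_plane_export(result: PsaResult, path: str | Path) -> float:
    """Write per-iteration cost-effectiveness plane points to CSV.

    Columns are the incremental QALY gain (current-minus-user decrement
    difference) and the incremental cost (negative of the cost-saving).
    Returns the fraction of iterations in the dominant quadrant (QALYs
    gained and money saved).
    """
    it = result.iterations
    frame = pd.DataFrame(
        {
            "incremental_qaly_gain": it["delta_qaly"],
            "incremental_cost": -it["ics"],
        }
    )
    frame.to_csv(path, index=False)
    dominant = (it["delta_qaly"] > 0) & (it["ics"] > 0)
    return float(dominant.mean())


def convergence_check(
    result: PsaResult,
    block_size: int = 500,
    tolerance: float = 0.01,
    columns: tuple[str, ...] = ("nmb", "ics", "delta_pades"),
) -> tuple[pd.DataFrame, bool]:
    """Running-mean convergence diagnostic for the headline outcomes.

    The running mean of each outcome is recorded every ``block_size``
    iterations.  The run is flagged converged when, over the final
    quarter of the series, each outcome's running-mean range is below
    ``tolerance`` times the magnitude of its final mean.
    """
    n = result.n
    if n < 2 * block_size:
        raise ValueError("need at least two blocks of iterations")
    idx = np.arange(block_size, n + 1, block_size)
    series = {}
    stable = True
    for col in columns:
        x = result.iterations[col].to_numpy()
        running = np.cumsum(x)[idx - 1] / idx
        series[col] = running
        tail = running[3 * len(running) // 4 :]
        final = running[-1]
        denom = abs(final) if final != 0 else 1.0
        if (tail.max() - tail.min()) >= tolerance * denom:
            stable = False
    frame = pd.DataFrame(series, index=pd.Index(idx, name="iteration"))
    return frame, stable
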