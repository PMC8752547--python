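"""Distribution specs, Dirichlet updating, sampling and configuration I/O."""

import dataclasses

import numpy as np
import pytest
import yaml
from scipy import stats

from padem import (
    ConfigError,
    DistributionSpec,
    build_dirichlet_posterior,
    base_case_path,
    load_config,
    sample_draw,
    save_config,
)
from padem.params import config_from_dict


@pytest.mark.parametrize(
    "family,params",
    [
        ("dirichlet", (1.0, 0.0)),
        ("dirichlet", (1.0,)),
        ("beta", (0.0, 2.0)),
        ("beta", (1.0, 2.0, 3.0)),
        ("lognormal", (0.0, 0.0)),
        ("normal", (0.0, -1.0)),
        ("deterministic", (1.0, 2.0)),
    ],
)
def test_invalid_distribution_params_rejected(family, params):
    with pytest.raises(ConfigError):
        DistributionSpec(family, params)


def test_truncation_bounds_must_be_ordered():
    with pytest.raises(ConfigError):
        DistributionSpec("normal", (0.0, 1.0), truncation=(2.0, 1.0))


class TestDirichletPosterior:
    def test_severity_cells_plus_prior(self):
        spec = build_dirichlet_posterior((5.0, 5.5, 0.0), 0.1)
        assert spec.family == "dirichlet"
        assert spec.params == pytest.approx((5.1, 5.6, 0.1))
        assert sum(spec.params) == pytest.approx(10.8)

    def test_all_zero_observations_give_prior_only_posterior(self):
        spec = build_dirichlet_posterior((0.0, 0.0, 0.0), 0.1)
        assert spec.params == pytest.approx((0.1, 0.1, 0.1))

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigError):
            build_dirichlet_posterior((1.0, -0.5), 0.1)

    def test_posterior_mean_matches_large_sample_monte_carlo(self, base_config, rng):
        # no-error category of the current arm: 26.3 / 136.6
        spec = DistributionSpec("dirichlet", base_config.current.node1_pseudo_counts)
        analytic = spec.mean()
        assert analytic[0] == pytest.approx(26.3 / 136.6)
        draws = spec.sample(rng, size=200_000)
        se = draws[:, 0].std() / np.sqrt(draws.shape[0])
        assert abs(draws[:, 0].mean() - analytic[0]) < 4 * se


class TestSampling:
    def test_same_rng_state_gives_identical_draw(self, base_config):
        d1 = sample_draw(base_config, np.random.default_rng(7))
        d2 = sample_draw(base_config, np.random.default_rng(7))
        np.testing.assert_array_equal(d1.current.node1, d2.current.node1)
        np.testing.assert_array_equal(d1.user.severity, d2.user.severity)
        np.testing.assert_array_equal(d1.p_undetected, d2.p_undetected)
        np.testing.assert_array_equal(d1.ut_revision_minutes, d2.ut_revision_minutes)

    def test_dirichlet_vectors_sum_to_one(self, base_config, rng):
        d = sample_draw(base_config, rng, size=2000)
        np.testing.assert_allclose(d.current.node1.sum(axis=-1), 1.0, atol=1e-12)
        np.testing.assert_allclose(d.user.severity.sum(axis=-1), 1.0, atol=1e-12)

    def test_no_harm_mean_matches_beta_mean(self, base_config, rng):
        d = sample_draw(base_config, rng, size=50_000)
        se = d.p_no_harm.std() / np.sqrt(d.p_no_harm.size)
        assert abs(d.p_no_harm.mean() - 217 / 240) < 3 * se

    def test_undetected_quantiles_match_stated_lognormal(self, base_config, rng):
        # 2.5/97.5% quantiles ~ exp(-0.25 -/+ 1.96 * 0.086) ~ (0.658, 0.922),
        # the printed 95% prediction interval up to rounding
        d = sample_draw(base_config, rng, size=50_000)
        lo, hi = np.percentile(d.p_undetected, [2.5, 97.5])
        assert lo == pytest.approx(np.exp(-0.25 - 1.96 * 0.086), abs=0.005)
        assert hi == pytest.approx(np.exp(-0.25 + 1.96 * 0.086), abs=0.005)
        assert lo == pytest.approx(0.655, abs=0.01)
        assert hi == pytest.approx(0.918, abs=0.01)

    @pytest.mark.parametrize(
        "getter,analytic",
        [
            (lambda d: d.p_undetected, np.exp(-0.25 + 0.086**2 / 2)),
            (lambda d: d.cost_detected, np.exp(-1.29 + 1.10**2 / 2)),
            (lambda d: d.cost_pade[:, 1], np.exp(7.13 + 0.07**2 / 2)),
            (lambda d: d.qaly_decrement[:, 2], 3.50),
            (lambda d: d.current.admin_minutes, 13.3),
        ],
        ids=["p_undetected", "cost_detected", "cost_moderate", "qaly_severe", "admin_time"],
    )
    def test_univariate_moments_match_closed_form(self, base_config, getter, analytic):
        # empirical mean of 1e5 draws within 4 standard errors of the
        # analytic mean (truncation affects only far-tail mass)
        d = sample_draw(base_config, np.random.default_rng(99), size=100_000)
        x = getter(d)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - analytic) < 4 * se

    def test_undetected_clamping_frequency_is_upper_tail_mass(self, base_config):
        # P(lognormal(-0.25, 0.086) > 1) = P(Z > 0.25/0.086) ~ 0.0018
        d = sample_draw(base_config, np.random.default_rng(3), size=200_000)
        freq = (d.p_undetected >= 1.0).mean()
        expected = stats.norm.sf(0.25 / 0.086)
        assert freq == pytest.approx(expected, rel=0.5)

    def test_probabilities_and_amounts_within_bounds(self, base_config, rng):
        d = sample_draw(base_config, rng, size=20_000)
        assert d.p_undetected.max() <= 1.0 and d.p_undetected.min() >= 0.0
        assert d.qaly_decrement.min() >= 0.0
        assert d.current.admin_minutes.min() >= 0.0
        assert d.cost_pade.min() >= 0.0


class TestConfigIO:
    def test_base_case_reproduces_printed_inputs(self, base_config):
        assert base_config.current.node1_pseudo_counts == pytest.approx(
            (26.3, 0.3, 0.3, 10.8, 0.3, 6.3, 27.3, 0.3, 3.3, 33.3, 0.3, 27.8)
        )
        assert base_config.user.node1_pseudo_counts == pytest.approx(
            (67.3, 0.3, 0.3, 4.3, 1.3, 0.3, 48.3, 0.3, 6.3, 11.3, 0.3, 3.3)
        )
        assert base_config.current.severity_pseudo_counts[2] == pytest.approx((5.1, 5.6, 0.1))
        assert base_config.user.severity_pseudo_counts[10] == pytest.approx((0.1, 2.1, 1.1))
        assert base_config.shared.p_no_harm.params == (217.0, 23.0)
        assert base_config.shared.p_undetected.params == (-0.25, 0.086)
        assert base_config.shared.cost_pade[1].params == (7.13, 0.07)
        assert base_config.shared.qaly_decrement[2].params == (3.50, 0.83)
        assert base_config.shared.staff_rates.pharmacist_per_hour == 65.0
        assert base_config.cohort.doses_per_year == 4000
        assert base_config.cohort.discount_rate == 0.035

    def test_round_trip(self, base_config, tmp_path):
        p = tmp_path / "cfg.yaml"
        save_config(base_config, p)
        assert load_config(p) == base_config

    def _raw(self):
        with open(base_case_path()) as fh:
            return yaml.safe_load(fh)

    def test_wrong_node1_length_rejected(self):
        raw = self._raw()
        raw["arms"]["current"]["node1_pseudo_counts"] = raw["arms"]["current"][
            "node1_pseudo_counts"
        ][:11]
        with pytest.raises(ConfigError, match="node-1"):
            config_from_dict(raw)

    def test_inconsistent_severity_triple_rejected(self):
        raw = self._raw()
        raw["arms"]["current"]["severity_pseudo_counts"][2] = [5.1, 5.6, 0.2]
        with pytest.raises(ConfigError, match="row sums"):
            config_from_dict(raw)

    def test_missing_field_rejected(self):
        raw = self._raw()
        del raw["shared"]["p_no_harm"]
        with pytest.raises(ConfigError, match="p_no_harm"):
            config_from_dict(raw)

    def test_prior_floor_enforced_on_load(self):
        raw = self._raw()
        raw["arms"]["current"]["severity_pseudo_counts"][0] = [0.05, 0.1, 0.1]
        raw["arms"]["current"]["node1_pseudo_counts"][1] = 0.25
        with pytest.raises(ConfigError, match="0.1"):
            config_from_dict(raw)
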