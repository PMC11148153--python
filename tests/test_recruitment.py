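import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import smrt
from smrt.recruitment import ModelParams, log_posterior, density_to_index


class TestLogExpectedRecruitment:
    @pytest.mark.parametrize(
        "a, a_dev, q, effort, expected",
        [
            (1.0, 0.0, 0.5, 2.0, 0.0),
            (2.3, 0.4, 0.0, 5.0, 2.7),
            (3.0, -0.2, 1.1, 1.425, 3.0 - 0.2 - 1.1 * 1.425),
        ],
    )
    def test_arithmetic(self, a, a_dev, q, effort, expected):
        assert smrt.log_expected_recruitment(a, a_dev, q, effort) == pytest.approx(expected)


class TestNegbinLogpmf:
    def test_normalizes_to_one(self):
        y = np.arange(10_001)
        total = np.exp(smrt.negbin_logpmf(y, mu=3.0, theta=1.5)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_poisson_limit(self):
        y = np.arange(51)
        nb = smrt.negbin_logpmf(y, mu=5.0, theta=1e8)
        po = stats.poisson.logpmf(y, 5.0)
        assert np.max(np.abs(nb - po)) < 1e-4

    def test_matches_scipy_parameterization(self):
        # NB(mean mu, dispersion theta) == nbinom(n=theta, p=theta/(theta+mu))
        y = np.arange(40)
        for mu, theta in [(0.5, 0.3), (4.0, 2.0), (50.0, 0.5)]:
            ours = smrt.negbin_logpmf(y, mu, theta)
            ref = stats.nbinom.logpmf(y, theta, theta / (theta + mu))
            np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_simulated_variance_matches_formula(self):
        rng = np.random.default_rng(3)
        mu, theta = 4.0, 0.5
        lam = rng.gamma(theta, mu / theta, size=1_000_000)
        draws = rng.poisson(lam)
        assert draws.var() == pytest.approx(mu + mu ** 2 / theta, rel=0.03)

    def test_rejects_invalid_y(self):
        with pytest.raises(ValueError):
            smrt.negbin_logpmf(2.5, 1.0, 1.0)
        with pytest.raises(ValueError):
            smrt.negbin_logpmf(-1, 1.0, 1.0)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "q, effort, expected",
        [(0.0, 1.0, 0.0), (math.log(2), 1.0, 50.0), (1.1087, 1.0, 67.0)],
    )
    def test_values(self, q, effort, expected):
        assert smrt.percent_reduction(q, effort) == pytest.approx(expected, abs=0.05)

    @given(
        q=st.floats(min_value=0.0, max_value=5.0),
        e1=st.floats(min_value=0.0, max_value=2.5),
        e2=st.floats(min_value=0.001, max_value=2.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_multiplicative_survival(self, q, e1, e2):
        p1 = smrt.percent_reduction(q, e1)
        p12 = smrt.percent_reduction(q, e1 + e2)
        assert 0.0 <= p1 < 100.0
        assert p12 >= p1
        # survival under combined effort is the product of survivals
        s1 = 1 - p1 / 100
        s2 = 1 - smrt.percent_reduction(q, e2) / 100
        assert 1 - p12 / 100 == pytest.approx(s1 * s2, abs=1e-12)


class TestAssignAge1:
    @pytest.mark.parametrize(
        "length, month, expected",
        [
            (30, 5, True),
            (30, 6, True),
            (50, 7, True),
            (50, 8, True),
            (70, 9, True),
            (70, 10, True),
            (50, 5, False),
            (30, 7, False),
            (85, 9, False),
            (19.9, 5, False),
        ],
    )
    def test_bands(self, length, month, expected):
        call = smrt.assign_age1(length, month)
        assert call.assessable
        assert call.is_age1 is expected

    @pytest.mark.parametrize("month", [1, 2, 3, 4, 11, 12])
    def test_outside_window_not_assessable(self, month):
        call = smrt.assign_age1(30, month)
        assert not call.is_age1 and not call.assessable

    def test_input_validation(self):
        with pytest.raises(ValueError):
            smrt.assign_age1(0, 6)
        with pytest.raises(ValueError):
            smrt.assign_age1(30, 13)

    def test_surveys_from_lengths_aggregates_density(self):
        rows = [
            dict(stream="A", year=2020, month=6, site="s1", length_mm=30, area_m2=50.0),
            dict(stream="A", year=2020, month=6, site="s1", length_mm=35, area_m2=50.0),
            dict(stream="A", year=2020, month=6, site="s1", length_mm=55, area_m2=50.0),
            dict(stream="A", year=2020, month=3, site="s1", length_mm=30, area_m2=50.0),
        ]
        out = smrt.surveys_from_lengths(pd.DataFrame(rows))
        assert len(out) == 1
        assert out["density_per_m2"].iloc[0] == pytest.approx(2 / 50.0)


class TestIndexConstruction:
    def test_round_half_away(self):
        assert density_to_index(0.0205) == 21
        assert density_to_index(0.0) == 0

    def test_zero_density_rows_kept(self, tiny_dataset):
        assert 0 in tiny_dataset.y

    def test_observation_invariant(self):
        obs = smrt.RecruitmentObservation("A", 2020, "s", 0.012)
        assert obs.index == 12
        with pytest.raises(ValueError):
            smrt.RecruitmentObservation("A", 2020, "s", 0.012, index=13)


def brute_force_log_posterior(params, data, priors):
    """Straight-line reference: scipy distributions, explicit loops."""
    lp = 0.0
    for i in range(data.n_obs):
        g = data.group_of_obs[i]
        s = data.stream_of_group[g]
        mu = math.exp(params.a[s] + params.a_dev[g] - params.q[s] * data.effort_of_group[g])
        lp += stats.nbinom.logpmf(data.y[i], params.theta, params.theta / (params.theta + mu))
    for g in range(data.n_groups):
        lp += stats.norm.logpdf(params.a_dev[g], 0.0, params.sigma_a)
    for s in range(data.n_streams):
        lp += stats.norm.logpdf(params.a[s], priors.a_mean, priors.a_sd)
        lp += stats.halfnorm.logpdf(params.q[s], scale=priors.q_scale)
    lp += stats.halfnorm.logpdf(params.sigma_a, scale=priors.sigma_a_scale)
    lp += stats.halfnorm.logpdf(params.theta, scale=priors.theta_scale)
    return lp


class TestLogPosterior:
    def params_for(self, data, seed=0):
        rng = np.random.default_rng(seed)
        return ModelParams(
            a=rng.normal(2.0, 0.5, data.n_streams),
            a_dev=rng.normal(0.0, 0.3, data.n_groups),
            sigma_a=0.7,
            q=np.abs(rng.normal(0.5, 0.2, data.n_streams)),
            theta=1.3,
        )

    def test_matches_brute_force_oracle(self, tiny_dataset):
        priors = smrt.PriorConfig()
        for seed in range(5):
            params = self.params_for(tiny_dataset, seed)
            ours = log_posterior(params, tiny_dataset, priors)
            ref = brute_force_log_posterior(params, tiny_dataset, priors)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_outside_support_is_minus_inf(self, tiny_dataset):
        params = self.params_for(tiny_dataset)
        params.sigma_a = -0.1
        assert log_posterior(params, tiny_dataset) == -math.inf
        params = self.params_for(tiny_dataset)
        params.theta = 0.0
        assert log_posterior(params, tiny_dataset) == -math.inf
        params = self.params_for(tiny_dataset)
        params.q = params.q.copy()
        params.q[0] = -0.2
        assert log_posterior(params, tiny_dataset) == -math.inf

    def test_signed_q_variant_allows_negative(self, tiny_dataset):
        params = self.params_for(tiny_dataset)
        params.q = params.q.copy()
        params.q[0] = -0.2
        priors = smrt.PriorConfig(q_signed=True)
        assert math.isfinite(log_posterior(params, tiny_dataset, priors))

    def test_duplicate_observation_adds_its_logpmf(self, tiny_dataset):
        import dataclasses

        params = self.params_for(tiny_dataset)
        base = log_posterior(params, tiny_dataset)
        # duplicate the first observation
        dup = dataclasses.replace(
            tiny_dataset,
            y=np.concatenate([tiny_dataset.y[:1], tiny_dataset.y]),
            group_of_obs=np.concatenate(
                [tiny_dataset.group_of_obs[:1], tiny_dataset.group_of_obs]
            ),
            group_offsets=np.searchsorted(
                np.sort(
                    np.concatenate(
                        [tiny_dataset.group_of_obs[:1], tiny_dataset.group_of_obs]
                    )
                ),
                np.arange(tiny_dataset.n_groups),
            ),
        )
        g = tiny_dataset.group_of_obs[0]
        s = tiny_dataset.stream_of_group[g]
        mu = math.exp(
            params.a[s] + params.a_dev[g] - params.q[s] * tiny_dataset.effort_of_group[g]
        )
        extra = smrt.negbin_logpmf(int(tiny_dataset.y[0]), mu, params.theta)
        assert log_posterior(params, dup) == pytest.approx(base + extra, abs=1e-10)

    def test_zero_observations_reduces_to_priors(self, tiny_dataset):
        import dataclasses

        params = self.params_for(tiny_dataset)
        empty = dataclasses.replace(
            tiny_dataset,
            y=np.empty(0, dtype=np.int64),
            group_of_obs=np.empty(0, dtype=np.int64),
            group_offsets=np.zeros(tiny_dataset.n_groups, dtype=np.int64),
        )
        got = log_posterior(params, empty)
        expected = brute_force_log_posterior(params, empty, smrt.PriorConfig())
        assert got == pytest.approx(expected, abs=1e-10)


class TestBuildDataset:
    def test_effort_aligned_to_spawning_year(self, tiny_dataset):
        ds = tiny_dataset
        by_label = {ds.group_label(g): ds.effort_of_group[g] for g in range(ds.n_groups)}
        assert by_label["A,2001"] == pytest.approx(1.425)  # 1425 released in 2000
        assert by_label["A,2002"] == 0.0
        assert by_label["B,2003"] == pytest.approx(0.5)

    def test_unknown_effort_rows_dropped_with_warning(self, caplog):
        surveys = pd.DataFrame(
            [
                dict(stream="A", year=2001, site="a", density_per_m2=0.01),
                dict(stream="A", year=2009, site="b", density_per_m2=0.02),
            ]
        )
        releases = pd.DataFrame(
            [dict(stream="A", spawning_year=2000, sterile_released=100)]
        )
        with caplog.at_level("WARNING", logger="smrt.recruitment"):
            ds = smrt.build_dataset(surveys, releases)
        assert ds.n_obs == 1
        assert any("dropping" in rec.message for rec in caplog.records)

    def test_no_usable_rows_raises(self):
        surveys = pd.DataFrame(
            [dict(stream="A", year=2001, site="a", density_per_m2=0.01)]
        )
        releases = pd.DataFrame(
            [dict(stream="B", spawning_year=2000, sterile_released=100)]
        )
        with pytest.raises(ValueError):
            smrt.build_dataset(surveys, releases)
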