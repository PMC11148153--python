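import math

import numpy as np
import pandas as pd
import pytest

import smrt


@pytest.fixture(scope="session")
def published_seasons():
    return smrt.read_trap_csv(smrt.published_trap_csv())


@pytest.fixture(scope="session")
def published_results(published_seasons):
    return smrt.assess_table(published_seasons)


@pytest.fixture(scope="session")
def pop():
    return smrt.PopulationParams()


def result_for(results, stream, year):
    (hit,) = [r for r in results if r.stream == stream and r.year == year]
    return hit


@pytest.fixture(scope="session")
def default_bundle():
    return smrt.generate_bundle(smrt.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_dataset(default_bundle):
    return smrt.build_dataset(
        default_bundle.larval_surveys, default_bundle.releases
    )


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    """One fit at default sampler settings, shared across tests."""
    return smrt.fit_mcmc(default_dataset)


def make_single_stream_dataset(
    a=4.0, q=0.8, theta=2.0, n_years=8, obs_per_year=10, seed=42, effort_on=1.0
):
    """Small one-stream dataset with alternating release/no-release years and
    no year-to-year process noise (a_dev = 0 in truth)."""
    rng = np.random.default_rng(seed)
    rows = []
    efforts = {}
    for i in range(n_years):
        yr = 2000 + i
        e = effort_on if i % 2 else 0.0
        efforts[yr] = e
        mu = math.exp(a - q * e)
        lam = rng.gamma(theta, mu / theta, size=obs_per_year)
        y = rng.poisson(lam)
        for j, v in enumerate(y):
            rows.append(
                dict(stream="S", year=yr + 1, site=f"{yr}-{j}", density_per_m2=v / 1000)
            )
    surveys = pd.DataFrame(rows)
    releases = pd.DataFrame(
        [
            dict(stream="S", spawning_year=yr, sterile_released=int(e * 1000))
            for yr, e in efforts.items()
        ]
    )
    return smrt.build_dataset(surveys, releases)


def grid_posterior_mean_q(
    dataset, theta, priors, a_range=(2.0, 6.0), q_range=(0.0, 4.0), n=401
):
    """Independent oracle: posterior mean of q on the fixed-effects
    single-stream sub-model, by dense 2-D grid integration."""
    grid_a = np.linspace(*a_range, n)
    grid_q = np.linspace(*q_range, n)
    e_obs = dataset.effort_of_group[dataset.group_of_obs]
    lp = np.empty((grid_a.size, grid_q.size))
    for i, a in enumerate(grid_a):
        mu = np.exp(a - grid_q[:, None] * e_obs[None, :])
        ll = smrt.negbin_logpmf(dataset.y[None, :], mu, theta).sum(axis=1)
        lp[i] = (
            ll
            - 0.5 * ((a - priors.a_mean) / priors.a_sd) ** 2
            - 0.5 * (grid_q / priors.q_scale) ** 2
        )
    w = np.exp(lp - lp.max())
    return float((w.sum(axis=0) * grid_q).sum() / w.sum())


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 streams x 3 years, 4 observations total (dual-oracle fixture)."""
    surveys = pd.DataFrame(
        [
            dict(stream="A", year=2001, site="a1", density_per_m2=0.012),
            dict(stream="A", year=2002, site="a2", density_per_m2=0.0),
            dict(stream="B", year=2001, site="b1", density_per_m2=0.205),
            dict(stream="B", year=2003, site="b2", density_per_m2=0.007),
        ]
    )
    releases = pd.DataFrame(
        [
            dict(stream="A", spawning_year=2000, sterile_released=1425),
            dict(stream="A", spawning_year=2001, sterile_released=0),
            dict(stream="B", spawning_year=2000, sterile_released=0),
            dict(stream="B", spawning_year=2002, sterile_released=500),
        ]
    )
    return smrt.build_dataset(surveys, releases)
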