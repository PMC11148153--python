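"""Hierarchical age-1 recruitment model with release-effort mortality.

The process model for stream ``s`` and survey year ``yr`` is a log-scale
white-noise series with an instantaneous mortality term proportional to
release effort::

    log(A[yr, s]) = a[s] + a_dev[yr, s] - q[s] * E[yr, s]
    a_dev[yr, s] ~ Normal(0, sigma_a)

where ``E`` is sterile males released / 1000 in the *spawning* year
(survey year - 1). Survey observations are integer recruitment indices
(age-1 density per m^2, times 1000, rounded) modelled as negative binomial
with mean ``A`` and overdispersion ``theta`` (variance ``mu + mu^2/theta``).
The release effect is reported as a percent reduction in recruitment,
``100 * (1 - exp(-q * E))``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .trap import round_half_away

__all__ = [
    "RecruitmentObservation",
    "RecruitmentDataset",
    "ModelParams",
    "PriorConfig",
    "log_expected_recruitment",
    "negbin_logpmf",
    "log_posterior",
    "percent_reduction",
    "assign_age1",
    "Age1Call",
    "build_dataset",
    "surveys_from_lengths",
    "density_to_index",
]

logger = logging.getLogger(__name__)


def density_to_index(density: float) -> int:
    """Recruitment index: density (larvae per m^2) * 1000, rounded to integer."""
    if density < 0:
        raise ValueError("density must be >= 0")
    return round_half_away(density * 1000.0)


@dataclass(frozen=True)
class RecruitmentObservation:
    """A single age-1 density survey with its integer index."""

    stream: str
    year: int
    site: str
    density: float
    index: int = -1

    def __post_init__(self) -> None:
        if self.index == -1:
            object.__setattr__(self, "index", density_to_index(self.density))
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.index < 0:
            raise ValueError("index must be >= 0")
        if self.index != density_to_index(self.density):
            raise ValueError("index must equal round(density * 1000)")


# ---------------------------------------------------------------------------
# model math


def log_expected_recruitment(a_s: float, a_dev: float, q_s: float, effort: float):
    """Log-scale expected recruitment index ``a_s + a_dev - q_s * E``."""
    return a_s + a_dev - q_s * effort


def negbin_logpmf(y, mu, theta):
    """Negative binomial log pmf in mean-dispersion form (variance mu + mu^2/theta).

    ``lgamma(y+theta) - lgamma(theta) - lgamma(y+1)
    + theta*log(theta/(theta+mu)) + y*log(mu/(theta+mu))``

    Vectorized over any broadcastable combination of arguments.
    """
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if np.any(yf != np.floor(yf)):
            raise ValueError("y must be integer-valued")
        y = yf
    if np.any(y < 0):
        raise ValueError("y must be >= 0")
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be > 0")
    out = (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )
    return out if out.ndim else float(out)


def percent_reduction(q, effort=1.0):
    """Percent reduction in recruitment at effort ``E``: ``100 * (1 - exp(-q E))``."""
    return 100.0 * (1.0 - np.exp(-np.asarray(q, dtype=float) * effort))


# ---------------------------------------------------------------------------
# age assignment

_AGE1_BANDS = {5: (20.0, 40.0), 6: (20.0, 40.0), 7: (40.0, 60.0), 8: (40.0, 60.0), 9: (60.0, 80.0), 10: (60.0, 80.0)}


class Age1Call(NamedTuple):
    is_age1: bool
    assessable: bool


def assign_age1(length_mm: float, month: int) -> Age1Call:
    """Length-by-month age-1 call for a captured larva.

    Age-1 length bands: 20-40 mm in May/June, 40-60 mm in July/August,
    60-80 mm in September/October (inclusive bounds). Months outside
    May-October cannot be assessed and return ``(False, assessable=False)``.
    """
    if length_mm <= 0:
        raise ValueError("length_mm must be > 0")
    if not 1 <= month <= 12:
        raise ValueError("month must be in 1..12")
    band = _AGE1_BANDS.get(month)
    if band is None:
        return Age1Call(False, False)
    lo, hi = band
    return Age1Call(lo <= length_mm <= hi, True)


# ---------------------------------------------------------------------------
# dataset


@dataclass(frozen=True)
class RecruitmentDataset:
    """Survey indices grouped by stream-year with aligned release effort.

    Observations are stored sorted by (stream, year); ``group_offsets`` and
    ``stream_offsets`` delimit contiguous runs so group/stream likelihood
    sums reduce to ``np.add.reduceat``.
    """

    streams: tuple[str, ...]
    y: np.ndarray                # (nobs,) integer indices, sorted by group
    group_of_obs: np.ndarray     # (nobs,) group id per observation
    stream_of_group: np.ndarray  # (ngroup,) stream id per group
    year_of_group: np.ndarray    # (ngroup,) survey year per group
    effort_of_group: np.ndarray  # (ngroup,) E aligned to spawning year
    group_offsets: np.ndarray    # (ngroup,) start index of each group in y
    stream_offsets: np.ndarray   # (nstream,) start group of each stream

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_groups(self) -> int:
        return self.stream_of_group.size

    @property
    def n_streams(self) -> int:
        return len(self.streams)

    def group_label(self, g: int) -> str:
        return f"{self.streams[self.stream_of_group[g]]},{self.year_of_group[g]}"


def build_dataset(
    surveys: pd.DataFrame,
    releases: pd.DataFrame,
    effort_scale: float = 1000.0,
) -> RecruitmentDataset:
    """Assemble a :class:`RecruitmentDataset` from survey and release tables.

    ``surveys`` needs columns stream, year, site, density_per_m2 (or index).
    ``releases`` needs columns stream, spawning_year, sterile_released; the
    effort for a survey in year ``t`` is the release count of spawning year
    ``t - 1`` divided by ``effort_scale``. Surveys whose spawning-year
    release count is unknown are dropped with a logged warning.
    """
    surveys = surveys.copy()
    if "index" not in surveys.columns:
        if "density_per_m2" not in surveys.columns:
            raise ValueError("surveys need a density_per_m2 or index column")
        surveys["index"] = [density_to_index(d) for d in surveys["density_per_m2"]]

    effort = {
        (str(r.stream), int(r.spawning_year)): float(r.sterile_released) / effort_scale
        for r in releases.itertuples()
    }

    known = []
    for row in surveys.itertuples():
        key = (str(row.stream), int(row.year) - 1)
        if key in effort:
            known.append(True)
        else:
            known.append(False)
    n_drop = len(known) - sum(known)
    if n_drop:
        logger.warning(
            "dropping %d survey rows with unknown spawning-year release effort", n_drop
        )
    surveys = surveys.loc[known]
    if surveys.empty:
        raise ValueError("no survey rows with known release effort")

    surveys = surveys.sort_values(["stream", "year"], kind="stable").reset_index(drop=True)
    streams = tuple(sorted(surveys["stream"].astype(str).unique()))
    s_index = {s: i for i, s in enumerate(streams)}

    group_keys = list(
        dict.fromkeys(zip(surveys["stream"].astype(str), surveys["year"].astype(int)))
    )
    group_keys.sort(key=lambda k: (s_index[k[0]], k[1]))
    g_index = {k: i for i, k in enumerate(group_keys)}

    stream_col = surveys["stream"].astype(str).tolist()
    year_col = surveys["year"].astype(int).tolist()
    order = sorted(
        range(len(surveys)), key=lambda i: g_index[(stream_col[i], year_col[i])]
    )
    surveys = surveys.iloc[order].reset_index(drop=True)

    y = surveys["index"].to_numpy(dtype=np.int64)
    if np.any(y < 0):
        raise ValueError("recruitment indices must be >= 0")
    gids = np.array(
        [g_index[(str(s), int(t))] for s, t in zip(surveys["stream"], surveys["year"])],
        dtype=np.int64,
    )
    stream_of_group = np.array([s_index[k[0]] for k in group_keys], dtype=np.int64)
    year_of_group = np.array([k[1] for k in group_keys], dtype=np.int64)
    effort_of_group = np.array(
        [effort[(k[0], k[1] - 1)] for k in group_keys], dtype=float
    )
    group_offsets = np.searchsorted(gids, np.arange(len(group_keys)))
    stream_offsets = np.searchsorted(stream_of_group, np.arange(len(streams)))
    return RecruitmentDataset(
        streams=streams,
        y=y,
        group_of_obs=gids,
        stream_of_group=stream_of_group,
        year_of_group=year_of_group,
        effort_of_group=effort_of_group,
        group_offsets=group_offsets,
        stream_offsets=stream_offsets,
    )


def surveys_from_lengths(lengths: pd.DataFrame) -> pd.DataFrame:
    """Aggregate length records to per-site age-1 densities.

    ``lengths`` needs columns stream, year, month, site, length_mm, area_m2
    (area per site survey). Rows captured outside the assessable May-October
    window are excluded. Returns a frame with stream, year, site,
    density_per_m2.
    """
    required = {"stream", "year", "month", "site", "length_mm", "area_m2"}
    missing = required - set(lengths.columns)
    if missing:
        raise ValueError(f"length records missing columns: {sorted(missing)}")
    calls = [assign_age1(l, m) for l, m in zip(lengths["length_mm"], lengths["month"])]
    lengths = lengths.assign(
        _age1=[c.is_age1 for c in calls], _ok=[c.assessable for c in calls]
    )
    lengths = lengths[lengths["_ok"]]
    grouped = (
        lengths.groupby(["stream", "year", "site"])
        .agg(n_age1=("_age1", "sum"), area_m2=("area_m2", "first"))
        .reset_index()
    )
    grouped["density_per_m2"] = grouped["n_age1"] / grouped["area_m2"]
    return grouped[["stream", "year", "site", "density_per_m2"]]


# ---------------------------------------------------------------------------
# parameters and priors


@dataclass
class ModelParams:
    """Full parameter vector: per-stream ``a`` and ``q``, per-group ``a_dev``,
    shared ``sigma_a`` and ``theta``."""

    a: np.ndarray        # (nstream,)
    a_dev: np.ndarray    # (ngroup,)
    sigma_a: float
    q: np.ndarray        # (nstream,)
    theta: float


@dataclass(frozen=True)
class PriorConfig:
    """Low-information prior set (reconstruction; the originals are unpublished).

    ``a ~ Normal(a_mean, a_sd)``, ``sigma_a ~ HalfNormal(sigma_a_scale)``,
    ``q ~ HalfNormal(q_scale)`` (or Normal(0, q_scale) when ``q_signed``),
    ``theta ~ HalfNormal(theta_scale)``.
    """

    a_mean: float = 0.0
    a_sd: float = 10.0
    sigma_a_scale: float = 2.0
    q_scale: float = 1.5
    theta_scale: float = 5.0
    q_signed: bool = False

    def __post_init__(self) -> None:
        if min(self.a_sd, self.sigma_a_scale, self.q_scale, self.theta_scale) <= 0:
            raise ValueError("prior scales must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "a_mean": self.a_mean,
            "a_sd": self.a_sd,
            "sigma_a_scale": self.sigma_a_scale,
            "q_scale": self.q_scale,
            "theta_scale": self.theta_scale,
            "q_signed": self.q_signed,
        }


_HALF_NORMAL_CONST = 0.5 * math.log(2.0 / math.pi)


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x < 0:
        return -math.inf
    return _HALF_NORMAL_CONST - math.log(scale) - 0.5 * (x / scale) ** 2


def _normal_logpdf(x, mean, sd):
    return -0.5 * math.log(2.0 * math.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def log_posterior(
    params: ModelParams, data: RecruitmentDataset, priors: PriorConfig = PriorConfig()
) -> float:
    """Unnormalized log posterior density of the full parameter vector.

    Sums the negative-binomial log likelihood over every survey, the
    Normal(0, sigma_a) density of every year deviation, and the prior
    densities. Returns ``-inf`` outside the support.
    """
    a = np.asarray(params.a, dtype=float)
    a_dev = np.asarray(params.a_dev, dtype=float)
    q = np.asarray(params.q, dtype=float)
    if a.shape != (data.n_streams,) or q.shape != (data.n_streams,):
        raise ValueError("a and q must have one entry per stream")
    if a_dev.shape != (data.n_groups,):
        raise ValueError("a_dev must have one entry per stream-year group")
    if params.sigma_a <= 0 or params.theta <= 0:
        return -math.inf
    if not priors.q_signed and np.any(q < 0):
        return -math.inf
    if not (
        np.all(np.isfinite(a)) and np.all(np.isfinite(a_dev)) and np.all(np.isfinite(q))
    ):
        return -math.inf

    s_g = data.stream_of_group
    log_mu_g = a[s_g] + a_dev - q[s_g] * data.effort_of_group
    mu_obs = np.exp(log_mu_g)[data.group_of_obs]
    loglik = float(np.sum(negbin_logpmf(data.y, mu_obs, params.theta)))

    lp = loglik
    lp += float(np.sum(_normal_logpdf(a_dev, 0.0, params.sigma_a)))
    lp += float(np.sum(_normal_logpdf(a, priors.a_mean, priors.a_sd)))
    lp += _half_normal_logpdf(params.sigma_a, priors.sigma_a_scale)
    if priors.q_signed:
        lp += float(np.sum(_normal_logpdf(q, 0.0, priors.q_scale)))
    else:
        lp += float(np.sum([_half_normal_logpdf(v, priors.q_scale) for v in q]))
    lp += _half_normal_logpdf(params.theta, priors.theta_scale)
    return lp if np.isfinite(lp) else -math.inf
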