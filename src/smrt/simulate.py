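"""Seeded synthetic data with the statistical structure the analysis assumes.

Generates adult trap seasons (binomial equal-catchability trapping),
viable-egg outcomes (binomial thinning under the sterile-male ratio), and
overdispersed age-1 larval surveys (the recruitment process model run
generatively), bundled into the exact CSV dialects the assessment and
fitting stages consume. A bundle is produced from a single seeded RNG with
fixed substream ordering (trapping by stream-year, then surveys), so
regeneration with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .trap import PopulationParams, TrapSeason
from .recruitment import log_expected_recruitment

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "simulate_trapping",
    "simulate_eggs",
    "simulate_recruitment",
    "generate_bundle",
]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and survey design for a synthetic study.

    Defaults mirror the published study footprint: three streams followed
    for ten years, no releases in the first four years and ~1000 sterile
    males per release year afterwards, wild runs below ~60 adults, and
    fifteen larval surveys per stream-year (per-year survey counts in the
    source study varied and are not published; this is a stand-in).
    """

    streams: tuple[str, ...] = ("Pigeon", "Sturgeon", "Maple")
    years: tuple[int, ...] = tuple(range(2013, 2023))
    a: Union[float, Mapping[str, float]] = 5.5
    sigma_a: float = 0.8
    q: Union[float, Mapping[str, float]] = 1.1
    theta: float = 0.5
    releases: Optional[Mapping[str, Mapping[int, int]]] = None
    surveys_per_stream_year: int = 15
    n_wild: int = 50
    capture_prob: float = 0.3
    p_female: float = 0.5
    fecundity_mean: float = 51_000.0
    fecundity_sd: float = 12_000.0
    fecundity_range: tuple[float, float] = (3_100.0, 72_000.0)
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("a", "q"):
            value = getattr(self, name)
            if isinstance(value, Mapping):
                missing = set(self.streams) - set(value)
                if missing:
                    raise ValueError(f"{name} missing entries for streams {sorted(missing)}")
                object.__setattr__(
                    self, name, {s: float(value[s]) for s in self.streams}
                )
            else:
                object.__setattr__(
                    self, name, {s: float(value) for s in self.streams}
                )
        if not 0 < self.capture_prob <= 1:
            raise ValueError("capture_prob must be in (0, 1]")
        if self.sigma_a <= 0 or self.theta <= 0:
            raise ValueError("sigma_a and theta must be > 0")
        if self.surveys_per_stream_year < 1 or self.n_wild < 0:
            raise ValueError("invalid design sizes")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def release_schedule(self) -> dict[str, dict[int, int]]:
        """Sterile males released per (stream, spawning year).

        When no explicit schedule is configured, the default releases 0 in
        the first four study years and 1000 in every later year.
        """
        if self.releases is not None:
            return {
                s: {int(y): int(n) for y, n in sched.items()}
                for s, sched in self.releases.items()
            }
        return {
            s: {y: (0 if i < 4 else 1000) for i, y in enumerate(self.years)}
            for s in self.streams
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["streams"] = list(self.streams)
        d["years"] = list(self.years)
        d["a"] = dict(self.a)
        d["q"] = dict(self.q)
        d["releases"] = self.release_schedule()
        d["fecundity_range"] = list(self.fecundity_range)
        return d

    @classmethod
    def from_dict(cls, raw: Mapping) -> "SimulationConfig":
        raw = dict(raw)
        raw.pop("note", None)
        if "streams" in raw:
            raw["streams"] = tuple(raw["streams"])
        if "years" in raw:
            years = raw["years"]
            if isinstance(years, Mapping):
                years = range(int(years["start"]), int(years["end"]) + 1)
            raw["years"] = tuple(int(y) for y in years)
        if "fecundity_range" in raw:
            raw["fecundity_range"] = tuple(raw["fecundity_range"])
        if raw.get("releases") is not None:
            raw["releases"] = {
                s: {int(y): int(n) for y, n in sched.items()}
                for s, sched in raw["releases"].items()
            }
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def population_params(self) -> PopulationParams:
        return PopulationParams(
            p_female=self.p_female,
            mean_fecundity=self.fecundity_mean,
            fecundity_range=self.fecundity_range,
        )


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground truth that produced them."""

    trap_seasons: pd.DataFrame
    larval_surveys: pd.DataFrame
    releases: pd.DataFrame
    truth: dict


def simulate_trapping(
    n_wild: int,
    m_released: int,
    capture_prob: float,
    seed_or_rng,
    p_female: float = 0.5,
    stream: str = "sim",
    year: int = 2000,
) -> TrapSeason:
    """One trap season under equal catchability.

    Every sterile male and every wild adult is captured independently with
    the same probability; captured wild fish are sexed at ``1 - p_female``
    male.
    """
    rng = _as_rng(seed_or_rng)
    recaptured = int(rng.binomial(m_released, capture_prob)) if m_released else None
    wild_captured = int(rng.binomial(n_wild, capture_prob))
    wild_males = int(rng.binomial(wild_captured, 1.0 - p_female))
    return TrapSeason(
        stream=stream,
        year=year,
        sterile_released=m_released,
        sterile_recaptured=recaptured,
        wild_captured=wild_captured,
        wild_males_observed=wild_males,
    )


def simulate_eggs(
    n_wild: int,
    ratio: float,
    pop: PopulationParams,
    seed_or_rng,
    fecundity_sd: float = 12_000.0,
) -> tuple[int, int]:
    """Stochastic viable-egg accounting for one season.

    Females are binomial in the wild run; per-female fecundity is truncated
    Normal(mean, sd) clipped to the configured range; each egg independently
    escapes sterile-male fertilization with probability ``1/ratio`` (the
    table convention, so the expectation matches the deterministic
    accounting). ``ratio=0`` means no sterile males: all eggs stay viable.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    rng = _as_rng(seed_or_rng)
    females = int(rng.binomial(n_wild, pop.p_female))
    lo, hi = pop.fecundity_range
    fec = np.empty(0)
    while fec.size < females:
        batch = rng.normal(pop.mean_fecundity, fecundity_sd, size=max(females, 16))
        batch = batch[(batch >= lo) & (batch <= hi)]
        fec = np.concatenate([fec, batch])
    eggs_before = int(np.round(fec[:females]).sum()) if females else 0
    if ratio == 0:
        return eggs_before, eggs_before
    p_viable = min(1.0, 1.0 / ratio)
    eggs_after = int(rng.binomial(eggs_before, p_viable)) if eggs_before else 0
    return eggs_before, eggs_after


def _negbin_draws(rng, mu, theta, size=None):
    """NB(mean mu, dispersion theta) via the gamma-Poisson mixture."""
    lam = rng.gamma(shape=theta, scale=np.asarray(mu, dtype=float) / theta, size=size)
    return rng.poisson(lam)


def simulate_recruitment(
    config: SimulationConfig, seed_or_rng=None
) -> tuple[pd.DataFrame, dict]:
    """Generate larval survey rows from the recruitment process model.

    For each stream and spawning year draws a year deviation, computes the
    expected index ``exp(a + a_dev - q E)``, and samples
    ``surveys_per_stream_year`` negative-binomial indices, dated to the
    survey year (spawning year + 1). Returns the survey table and the
    realized year deviations.
    """
    rng = _as_rng(config.seed if seed_or_rng is None else seed_or_rng)
    schedule = config.release_schedule()
    rows = []
    a_dev_truth: dict[str, float] = {}
    for stream in config.streams:
        for spawn_year in config.years:
            effort = schedule[stream].get(spawn_year, 0) / 1000.0
            a_dev = float(rng.normal(0.0, config.sigma_a))
            a_dev_truth[f"{stream},{spawn_year + 1}"] = a_dev
            mu = np.exp(
                log_expected_recruitment(
                    config.a[stream], a_dev, config.q[stream], effort
                )
            )
            idx = _negbin_draws(
                rng, mu, config.theta, size=config.surveys_per_stream_year
            )
            for site, k in enumerate(idx, start=1):
                rows.append(
                    {
                        "stream": stream,
                        "year": spawn_year + 1,
                        "month": 6,
                        "site": f"{stream}-{spawn_year + 1}-{site:02d}",
                        "density_per_m2": int(k) / 1000.0,
                    }
                )
    surveys = pd.DataFrame(rows)
    return surveys, {"a_dev": a_dev_truth}


def generate_bundle(
    config: SimulationConfig, out_dir: Union[str, Path, None] = None
) -> SyntheticBundle:
    """Generate a full synthetic study and optionally write its CSV files.

    Substream order is fixed: trap seasons first (streams in config order,
    years ascending), then larval surveys. Writes ``trap_seasons.csv``,
    ``larval_surveys.csv``, ``releases.csv`` and ``truth.json`` when
    ``out_dir`` is given.
    """
    rng = np.random.default_rng(config.seed)
    schedule = config.release_schedule()

    trap_rows = []
    for stream in config.streams:
        for year in config.years:
            season = simulate_trapping(
                n_wild=config.n_wild,
                m_released=schedule[stream].get(year, 0),
                capture_prob=config.capture_prob,
                seed_or_rng=rng,
                p_female=config.p_female,
                stream=stream,
                year=year,
            )
            trap_rows.append(
                {
                    "stream": season.stream,
                    "year": season.year,
                    "sterile_released": season.sterile_released,
                    "sterile_recaptured": season.sterile_recaptured,
                    "wild_captured": season.wild_captured,
                    "wild_males_observed": season.wild_males_observed,
                }
            )
    trap_seasons = pd.DataFrame(trap_rows).astype({"sterile_recaptured": "Int64"})

    surveys, extra_truth = simulate_recruitment(config, rng)

    releases = pd.DataFrame(
        [
            {"stream": s, "spawning_year": y, "sterile_released": n}
            for s, sched in schedule.items()
            for y, n in sorted(sched.items())
        ]
    )

    truth = {
        "config": config.to_dict(),
        "a_dev": extra_truth["a_dev"],
        "notes": {
            "surveys_per_stream_year": "stand-in design; source per-year survey "
            "counts are not published",
        },
    }

    bundle = SyntheticBundle(
        trap_seasons=trap_seasons,
        larval_surveys=surveys,
        releases=releases,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trap_seasons.to_csv(out / "trap_seasons.csv", index=False)
        surveys.to_csv(out / "larval_surveys.csv", index=False)
        releases.to_csv(out / "releases.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return bundle
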