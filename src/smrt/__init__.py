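"""Sterile-male-release suppression analysis.

Adult mark-recapture assessment with viable-egg accounting, a Bayesian
hierarchical age-1 recruitment model with release-effort mortality, and a
seeded synthetic-data generator so the full pipeline runs end to end
without external data.
"""

from importlib.resources import files

from .trap import (
    AssessmentResult,
    PopulationParams,
    TrapSeason,
    assess_table,
    egg_reduction_percent,
    petersen_abundance,
    read_trap_csv,
    sterile_wild_male_ratio,
    viable_eggs_after,
    viable_eggs_before,
)
from .recruitment import (
    Age1Call,
    ModelParams,
    PriorConfig,
    RecruitmentDataset,
    RecruitmentObservation,
    assign_age1,
    build_dataset,
    log_expected_recruitment,
    log_posterior,
    negbin_logpmf,
    percent_reduction,
    surveys_from_lengths,
)
from .mcmc import PosteriorDraws, SamplerConfig, fit_mcmc, split_rhat, summarize_effect
from .simulate import (
    SimulationConfig,
    SyntheticBundle,
    generate_bundle,
    simulate_eggs,
    simulate_recruitment,
    simulate_trapping,
)

__version__ = "0.1.0"


def published_trap_csv():
    """Path to the packaged published trap-season fixture CSV."""
    return files("smrt").joinpath("data/trap_seasons_published.csv")


__all__ = [
    "AssessmentResult",
    "Age1Call",
    "ModelParams",
    "PopulationParams",
    "PosteriorDraws",
    "PriorConfig",
    "RecruitmentDataset",
    "RecruitmentObservation",
    "SamplerConfig",
    "SimulationConfig",
    "SyntheticBundle",
    "TrapSeason",
    "assess_table",
    "assign_age1",
    "build_dataset",
    "egg_reduction_percent",
    "fit_mcmc",
    "generate_bundle",
    "log_expected_recruitment",
    "log_posterior",
    "negbin_logpmf",
    "percent_reduction",
    "petersen_abundance",
    "published_trap_csv",
    "read_trap_csv",
    "simulate_eggs",
    "simulate_recruitment",
    "simulate_trapping",
    "split_rhat",
    "sterile_wild_male_ratio",
    "summarize_effect",
    "surveys_from_lengths",
    "viable_eggs_after",
    "viable_eggs_before",
]
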