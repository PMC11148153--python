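"""Adult assessment from trap counts: mark-recapture abundance and viable-egg accounting.

One row of input describes a single stream-year of trapping: sterile males
released (``M``), sterile males recaptured in assessment traps (``R``), and
wild (non-sterile) captures (``C``). From these the module derives a
Lincoln-Petersen abundance estimate, the realized sterile:wild-male ratio,
and the expected number of viable eggs before and after sterile-male
release, assuming every egg could be fertilized by a different male.

All reported integers use round-half-away-from-zero. Quantities that cannot
be estimated (no release, no recaptures, or no wild captures) are explicit
``None`` markers, never zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "TrapSeason",
    "PopulationParams",
    "AssessmentResult",
    "petersen_abundance",
    "sterile_wild_male_ratio",
    "viable_eggs_before",
    "viable_eggs_after",
    "egg_reduction_percent",
    "assess_table",
    "read_trap_csv",
    "write_assessment_csv",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (1.5 -> 2, -1.5 -> -2)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class TrapSeason:
    """One stream-year of release/recapture/wild-capture counts.

    Parameters
    ----------
    stream, year
        Stream identifier and calendar year of the trapping season.
    sterile_released
        Number of sterile males released (``M``).
    sterile_recaptured
        Sterile males recaptured in traps (``R``). ``None`` when no release
        occurred and no recapture count exists.
    wild_captured
        Wild (non-sterile) captures of both sexes (``C``).
    wild_males_observed
        Optional sexed male count among the wild captures; when present it
        is used as the ratio denominator instead of ``C * (1 - p_female)``.
    abundance_est
        Optional externally derived abundance estimate. Takes precedence
        over the Petersen estimate (used for seasons whose abundance was
        estimated by other survey methods, e.g. no-release years).
    ratio_censored_at
        When the realized ratio was only reported as exceeding a bound
        (e.g. ">40:1"), the numeric bound used for downstream arithmetic.
    ambiguous
        Rows whose published values are internally inconsistent; excluded
        from exact-match testing but still processed.
    """

    stream: str
    year: int
    sterile_released: int
    sterile_recaptured: Optional[int]
    wild_captured: int
    wild_males_observed: Optional[int] = None
    abundance_est: Optional[int] = None
    ratio_censored_at: Optional[float] = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        m, r, c = self.sterile_released, self.sterile_recaptured, self.wild_captured
        if m < 0 or c < 0:
            raise ValueError(f"{self.stream} {self.year}: counts must be >= 0")
        if r is not None:
            if r < 0:
                raise ValueError(f"{self.stream} {self.year}: counts must be >= 0")
            if r > m:
                raise ValueError(
                    f"{self.stream} {self.year}: recaptures ({r}) exceed releases ({m})"
                )
        if self.wild_males_observed is not None:
            if self.wild_males_observed < 0:
                raise ValueError(f"{self.stream} {self.year}: counts must be >= 0")
            if self.wild_males_observed > c:
                raise ValueError(
                    f"{self.stream} {self.year}: observed wild males exceed wild captures"
                )

    @property
    def recaptured(self) -> int:
        """Recapture count with a missing value treated as zero."""
        return 0 if self.sterile_recaptured is None else self.sterile_recaptured


@dataclass(frozen=True)
class PopulationParams:
    """Sex ratio and fecundity assumptions used in the egg accounting."""

    p_female: float = 0.5
    mean_fecundity: float = 51_000.0
    fecundity_range: tuple[float, float] = (3_100.0, 72_000.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_female <= 1.0:
            raise ValueError("p_female must be in [0, 1]")
        lo, hi = self.fecundity_range
        if not lo <= self.mean_fecundity <= hi:
            raise ValueError("mean_fecundity must lie within fecundity_range")


@dataclass(frozen=True)
class AssessmentResult:
    """Derived quantities for one stream-year (``None`` marks not-estimable)."""

    stream: str
    year: int
    abundance_wild: Optional[int]
    ratio_sterile_to_wild_male: float
    ratio_raw: float
    ratio_censored: bool
    eggs_before: Optional[int]
    eggs_after: Optional[int]
    egg_reduction_pct: Optional[float]
    ambiguous: bool = False


def petersen_abundance(trap: TrapSeason) -> Optional[int]:
    """Lincoln-Petersen abundance ``N = C * M / R`` rounded half away from zero.

    Sterile males recaptured at rate ``R/M`` stand in for a marked cohort;
    wild captures ``C`` are scaled up by the inverse capture rate. Returns
    ``None`` (not estimable) when no males were released or none were
    recaptured.
    """
    m, r, c = trap.sterile_released, trap.recaptured, trap.wild_captured
    if m == 0 or r == 0:
        return None
    return round_half_away(c * m / r)


def sterile_wild_male_ratio(
    trap: TrapSeason, pop: PopulationParams = PopulationParams()
) -> float:
    """Realized sterile:wild-male ratio ``R / m``, rounded to the nearest integer.

    ``m`` is the observed wild male count when recorded, otherwise the
    expected male fraction of the wild captures, ``C * (1 - p_female)``.
    Returns ``inf`` when no wild males were seen but sterile recaptures
    occurred, and ``0`` when there were no recaptures.
    """
    r = trap.recaptured
    if r == 0:
        return 0.0
    if trap.wild_males_observed is not None:
        m = float(trap.wild_males_observed)
    else:
        m = trap.wild_captured * (1.0 - pop.p_female)
    if m == 0:
        return math.inf
    return float(round_half_away(r / m))


def viable_eggs_before(abundance: int, pop: PopulationParams = PopulationParams()) -> int:
    """Expected viable eggs absent sterile males: ``abundance * p_female * fecundity``."""
    if abundance < 0:
        raise ValueError("abundance must be >= 0")
    return round_half_away(abundance * pop.p_female * pop.mean_fecundity)


def viable_eggs_after(eggs_before: int, ratio: float, convention: str = "table") -> int:
    """Viable eggs remaining once sterile males at ratio ``r`` absorb matings.

    The default ``"table"`` convention divides by ``r`` (each egg fertilized
    by a male drawn from the sterile+wild pool at the realized ratio, as the
    published accounting does); ``"random-mating"`` divides by ``r + 1``, the
    probability that a random male is fertile.
    """
    if eggs_before < 0 or ratio < 0:
        raise ValueError("eggs_before and ratio must be >= 0")
    if convention not in ("table", "random-mating"):
        raise ValueError(f"unknown convention {convention!r}")
    if ratio == 0:
        return eggs_before
    divisor = ratio if convention == "table" else ratio + 1.0
    return round_half_away(eggs_before / divisor)


def egg_reduction_percent(ratio: float) -> float:
    """Percent reduction in viable eggs at sterile:wild ratio ``r``: ``100 * (1 - 1/r)``."""
    if ratio < 1:
        raise ValueError("egg_reduction_percent requires ratio >= 1")
    return 100.0 * (1.0 - 1.0 / ratio)


def _assess_one(
    trap: TrapSeason, pop: PopulationParams, convention: str
) -> AssessmentResult:
    r = trap.recaptured
    if r == 0:
        ratio_raw = 0.0
    elif trap.wild_males_observed is not None:
        ratio_raw = math.inf if trap.wild_males_observed == 0 else r / trap.wild_males_observed
    else:
        m = trap.wild_captured * (1.0 - pop.p_female)
        ratio_raw = math.inf if m == 0 else r / m

    censored = False
    if trap.ratio_censored_at is not None and (
        math.isinf(ratio_raw) or ratio_raw > trap.ratio_censored_at
    ):
        ratio = float(trap.ratio_censored_at)
        censored = True
    elif math.isinf(ratio_raw):
        ratio = math.inf
    else:
        ratio = float(round_half_away(ratio_raw))

    if trap.abundance_est is not None:
        abundance: Optional[int] = trap.abundance_est
    elif trap.sterile_released == 0 or r == 0 or trap.wild_captured == 0:
        abundance = None
    else:
        abundance = petersen_abundance(trap)

    if abundance is None:
        before = after = None
        reduction = None
    else:
        before = viable_eggs_before(abundance, pop)
        if trap.sterile_released == 0 or ratio == 0:
            after = before
        elif math.isinf(ratio):
            after = 0
        else:
            after = viable_eggs_after(before, ratio, convention)
        reduction = 100.0 * (1.0 - after / before) if before > 0 else None

    return AssessmentResult(
        stream=trap.stream,
        year=trap.year,
        abundance_wild=abundance,
        ratio_sterile_to_wild_male=ratio,
        ratio_raw=ratio_raw,
        ratio_censored=censored,
        eggs_before=before,
        eggs_after=after,
        egg_reduction_pct=reduction,
        ambiguous=trap.ambiguous,
    )


def assess_table(
    seasons: Sequence[TrapSeason],
    pop: PopulationParams = PopulationParams(),
    convention: str = "table",
) -> list[AssessmentResult]:
    """Run the full assessment chain over a batch of trap seasons.

    Raises on duplicate (stream, year) keys. Not-estimable seasons propagate
    ``None`` through abundance and both egg columns.
    """
    keys = [(t.stream, t.year) for t in seasons]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate stream-year keys: {dupes}")
    return [_assess_one(t, pop, convention) for t in seasons]


_TRAP_COLUMNS = {
    "stream",
    "year",
    "sterile_released",
    "sterile_recaptured",
    "wild_captured",
}


def read_trap_csv(path) -> list[TrapSeason]:
    """Read ``trap_seasons.csv`` (``#`` comment lines allowed) into TrapSeason rows."""
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    missing = _TRAP_COLUMNS - set(df.columns)
    if missing:
        raise ValueError(f"trap CSV missing required columns: {sorted(missing)}")

    def _opt_int(row, col):
        if col not in row or pd.isna(row[col]):
            return None
        return int(row[col])

    seasons = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            seasons.append(
                TrapSeason(
                    stream=str(row["stream"]),
                    year=int(row["year"]),
                    sterile_released=int(row["sterile_released"]),
                    sterile_recaptured=_opt_int(row, "sterile_recaptured"),
                    wild_captured=int(row["wild_captured"]),
                    wild_males_observed=_opt_int(row, "wild_males_observed"),
                    abundance_est=_opt_int(row, "abundance_est"),
                    ratio_censored_at=(
                        None
                        if "ratio_censored_at" not in row or pd.isna(row["ratio_censored_at"])
                        else float(row["ratio_censored_at"])
                    ),
                    ambiguous=bool(row.get("ambiguous", False))
                    and not pd.isna(row.get("ambiguous")),
                )
            )
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"trap CSV row {i + 2}: {exc}") from exc
    return seasons


def results_to_frame(results: Sequence[AssessmentResult]) -> pd.DataFrame:
    """Tabulate assessment results; ``None`` markers become NaN cells."""
    return pd.DataFrame(
        {
            "stream": [x.stream for x in results],
            "year": [x.year for x in results],
            "abundance_wild": [x.abundance_wild for x in results],
            "ratio_sterile_to_wild_male": [
                x.ratio_sterile_to_wild_male for x in results
            ],
            "ratio_censored": [x.ratio_censored for x in results],
            "eggs_before": [x.eggs_before for x in results],
            "eggs_after": [x.eggs_after for x in results],
            "egg_reduction_pct": [x.egg_reduction_pct for x in results],
            "ambiguous": [x.ambiguous for x in results],
        }
    ).astype(
        {
            "abundance_wild": "Int64",
            "eggs_before": "Int64",
            "eggs_after": "Int64",
        }
    )


def write_assessment_csv(results: Sequence[AssessmentResult], path) -> None:
    results_to_frame(results).to_csv(path, index=False, na_rep="")
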