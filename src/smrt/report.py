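"""Assembly of human-readable assessment and effect reports.

Reports are deterministic functions of their inputs: regenerating a report
from identical files yields byte-identical output (run metadata such as
timestamps lives in the side-car metadata JSON, never in the report).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = ["build_report", "render_assessment_section", "render_effect_section"]


def _fmt_int(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return "NA"
    return f"{int(value):,}"


def render_assessment_section(assessment: pd.DataFrame) -> str:
    """Markdown egg-accounting table plus the release-year reduction range."""
    lines = [
        "## Adult assessment and viable-egg accounting",
        "",
        "| Stream | Year | Abundance (wild) | Sterile:wild male | Eggs before | Eggs after | Reduction (%) |",
        "|---|---|---|---|---|---|---|",
    ]
    for row in assessment.itertuples():
        ratio = row.ratio_sterile_to_wild_male
        if pd.isna(ratio):
            ratio_txt = "NA"
        elif getattr(row, "ratio_censored", False):
            ratio_txt = f">{int(ratio)}:1"
        elif math.isinf(ratio):
            ratio_txt = "inf"
        else:
            ratio_txt = f"{int(ratio)}:1"
        red = row.egg_reduction_pct
        red_txt = "NA" if pd.isna(red) else f"{red:.1f}"
        lines.append(
            "| {} | {} | {} | {} | {} | {} | {} |".format(
                row.stream,
                row.year,
                _fmt_int(row.abundance_wild),
                ratio_txt,
                _fmt_int(row.eggs_before),
                _fmt_int(row.eggs_after),
                red_txt,
            )
        )

    released = assessment[
        (assessment["ratio_sterile_to_wild_male"] > 0)
        & assessment["egg_reduction_pct"].notna()
    ]
    lines.append("")
    if len(released):
        lo = math.floor(released["egg_reduction_pct"].min())
        hi = math.floor(released["egg_reduction_pct"].max())
        lines.append(
            f"Estimated reduction in viable eggs across release years: "
            f"{lo}-{hi}% (n = {len(released)} stream-years)."
        )
    else:
        lines.append("No release-year egg reductions are estimable from the input.")
    lines.append("")
    return "\n".join(lines)


def render_effect_section(summary: dict) -> str:
    """Markdown per-stream percent-reduction summary from a fit's summary JSON."""
    effort = summary.get("effort", 1.0)
    lines = [
        "## Modelled reduction in age-1 recruitment",
        "",
        f"Expected percent reduction per {int(effort * 1000)} sterile males "
        "released (posterior median and 95% credible interval):",
        "",
    ]
    for stream, stats in summary["effect"].items():
        lines.append(
            "- {}: {:.0f}% (95% CrI: {:.1f}-{:.1f}%)".format(
                stream, stats["median"], stats["ci_lower"], stats["ci_upper"]
            )
        )
    rhat = summary.get("rhat")
    if rhat:
        finite = [v for v in rhat.values() if v is not None and not math.isnan(v)]
        if finite:
            lines.append("")
            lines.append(
                "Convergence: split-R-hat range {:.3f}-{:.3f} over {} parameters.".format(
                    min(finite), max(finite), len(finite)
                )
            )
    lines.append("")
    return "\n".join(lines)


def build_report(
    assessment_csv, posterior_summary_json: Optional[str] = None
) -> str:
    """Assemble the full markdown report from pipeline artifacts on disk."""
    assessment = pd.read_csv(assessment_csv, comment="#")
    required = {"stream", "year", "egg_reduction_pct", "ratio_sterile_to_wild_male"}
    missing = required - set(assessment.columns)
    if missing:
        raise ValueError(f"assessment CSV missing columns: {sorted(missing)}")
    parts = ["# Sterile-male-release suppression report", ""]
    parts.append(render_assessment_section(assessment))
    if posterior_summary_json is not None:
        with open(posterior_summary_json) as fh:
            summary = json.load(fh)
        if "effect" not in summary:
            raise ValueError("posterior summary JSON missing 'effect' section")
        parts.append(render_effect_section(summary))
    return "\n".join(parts)
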