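"""End-to-end pipeline and report assembly.

Drives, per analyte x sex: iterated Tukey cleaning -> yearly subgroup
summaries -> regression-tree cut proposal -> Harris-Boyd / Lahti refinement
-> per-bin indirect fit with bootstrap CIs, and assembles the rows of an
age- and sex-specific reference-interval table with a full decision audit.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cleaning import clean_table
from .estimation import RIEstimate, bootstrap_ci
from .partitioning import (
    DEFAULT_MIN_LEAF,
    RECOMMENDED_BIN_N,
    AgePartition,
    fit_age_tree,
    refine_partition,
)

__all__ = [
    "ReportRow",
    "format_age_label",
    "parse_age_label",
    "run_pipeline",
    "report_to_frame",
    "render_text_table",
]

log = logging.getLogger(__name__)

_MONTHS_RE = re.compile(r"^(\d+) mths$")
_YEARS_RE = re.compile(r"^(\d+) yrs$")


def format_age_label(lo_months: int, hi_months: int | None) -> str:
    """Render a half-open month interval as a human age label.

    Bounds under a year are shown in months, whole years in years; the upper
    bound is shown inclusively ("[3, 12)" -> "3 mths-11 mths", "[12, 108)"
    -> "1 yrs-8 yrs").  ``hi_months=None`` means open-ended: "10 yrs-".
    """
    if hi_months is not None and lo_months >= hi_months:
        raise ValueError(f"invalid interval [{lo_months}, {hi_months})")

    def lo_part(m: int) -> str:
        return f"{m} mths" if (m < 12 or m % 12) else f"{m // 12} yrs"

    if hi_months is None:
        return f"{lo_part(lo_months)}–"
    last = hi_months - 1
    if last < 12 or hi_months % 12:
        hi_part = f"{last} mths"
    else:
        hi_part = f"{hi_months // 12 - 1} yrs"
    return f"{lo_part(lo_months)}–{hi_part}"


def parse_age_label(label: str) -> tuple[int, int | None]:
    """Inverse of :func:`format_age_label`."""
    parts = label.split("–")
    if len(parts) != 2:
        raise ValueError(f"unparseable age label: {label!r}")
    lo_s, hi_s = parts

    def parse_lo(s: str) -> int:
        if m := _MONTHS_RE.match(s):
            return int(m.group(1))
        if m := _YEARS_RE.match(s):
            return int(m.group(1)) * 12
        raise ValueError(f"unparseable age bound: {s!r}")

    lo = parse_lo(lo_s)
    if hi_s == "":
        return lo, None
    if m := _MONTHS_RE.match(hi_s):
        return lo, int(m.group(1)) + 1
    if m := _YEARS_RE.match(hi_s):
        return lo, (int(m.group(1)) + 1) * 12
    raise ValueError(f"unparseable age bound: {hi_s!r}")


@dataclass
class ReportRow:
    """One age x sex cell of the reference-interval report."""

    analyte: str
    sex: str
    age_label: str
    age_lo_months: int
    age_hi_months: int
    n: int
    estimate: RIEstimate
    flags: str = ""


def run_pipeline(
    records: pd.DataFrame,
    seed: int = 0,
    B: int = 200,
    min_leaf: int = DEFAULT_MIN_LEAF,
    max_depth: int = 2,
) -> tuple[list[ReportRow], dict[tuple[str, str], AgePartition]]:
    """Full indirect reference-interval pipeline on a long-format table.

    Records need columns ``analyte, sex, age_months, value``.  Sex is always
    a hard partition; within each analyte x sex the data are cleaned, age
    cuts are proposed and refined, and each final bin receives an indirect
    fit with ``B`` bootstrap replicates.  Analyte x sex strata too small to
    split (< 2 * min_leaf) fall back to a single flagged bin.  Deterministic
    given the seed.

    Returns the report rows plus the per-stratum partitions (with audits).
    """
    kept, removed = clean_table(records)
    if len(removed):
        log.info("cleaning removed %d of %d records", len(removed), len(records))

    rows: list[ReportRow] = []
    partitions: dict[tuple[str, str], AgePartition] = {}
    ss = np.random.SeedSequence(seed)

    analytes = sorted(kept["analyte"].unique())
    for analyte in analytes:
        for sex in ("M", "F"):
            stratum = kept[(kept["analyte"] == analyte) & (kept["sex"] == sex)]
            if stratum.empty:
                continue
            ages = stratum["age_months"].to_numpy()
            values = stratum["value"].to_numpy(dtype=float)

            if values.size < 2 * min_leaf:
                part = AgePartition(
                    analyte=analyte,
                    sex=sex,
                    bins=[(int(ages.min()), int(ages.max()) + 1)],
                )
                fallback = True
            else:
                cuts = fit_age_tree(
                    ages, values, max_depth=max_depth, min_leaf=min_leaf
                )
                part = refine_partition(
                    ages,
                    values,
                    cuts,
                    min_leaf=min_leaf,
                    max_depth=max_depth,
                    analyte=analyte,
                    sex=sex,
                )
                fallback = False
            partitions[(analyte, sex)] = part

            for lo, hi in part.bins:
                sel = values[(ages >= lo) & (ages < hi)]
                label = format_age_label(lo, hi)
                # derive a per-bin bootstrap seed deterministically
                bin_seed = int(
                    np.random.default_rng(
                        ss.spawn(1)[0]
                    ).integers(0, 2**31 - 1)
                )
                est = bootstrap_ci(sel, B=B, seed=bin_seed, bin_label=label)
                flags = []
                if sel.size < RECOMMENDED_BIN_N:
                    flags.append(f"n<{RECOMMENDED_BIN_N}")
                if fallback:
                    flags.append("single-bin-fallback")
                rows.append(
                    ReportRow(
                        analyte=analyte,
                        sex=sex,
                        age_label=label,
                        age_lo_months=lo,
                        age_hi_months=hi,
                        n=int(sel.size),
                        estimate=est,
                        flags=";".join(flags),
                    )
                )
    return rows, partitions


def report_to_frame(rows: list[ReportRow]) -> pd.DataFrame:
    """Tabulate report rows (full precision) for CSV output."""
    return pd.DataFrame(
        {
            "analyte": [r.analyte for r in rows],
            "sex": [r.sex for r in rows],
            "age": [r.age_label for r in rows],
            "age_lo_months": [r.age_lo_months for r in rows],
            "age_hi_months": [r.age_hi_months for r in rows],
            "n": [r.n for r in rows],
            "median": [r.estimate.median for r in rows],
            "median_ci_lo": [r.estimate.ci_median[0] for r in rows],
            "median_ci_hi": [r.estimate.ci_median[1] for r in rows],
            "lower": [r.estimate.lower for r in rows],
            "lower_ci_lo": [r.estimate.ci_lower[0] for r in rows],
            "lower_ci_hi": [r.estimate.ci_lower[1] for r in rows],
            "upper": [r.estimate.upper for r in rows],
            "upper_ci_lo": [r.estimate.ci_upper[0] for r in rows],
            "upper_ci_hi": [r.estimate.ci_upper[1] for r in rows],
            "lambda": [r.estimate.lam for r in rows],
            "flags": [r.flags for r in rows],
        }
    )


def render_text_table(rows: list[ReportRow]) -> str:
    """Human-readable report: limits with 95% CIs, rounded to 2 decimals."""

    def fmt(x: float, ci: tuple[float, float]) -> str:
        return f"{x:.2f} ({ci[0]:.2f}, {ci[1]:.2f})"

    header = (
        "Analyte Sex Age               n      "
        "Median (95%CI)          Lower limit (95%CI)     Upper limit (95%CI)"
    )
    lines = [header, "-" * len(header)]
    for r in rows:
        e = r.estimate
        lines.append(
            f"{r.analyte:<7} {r.sex:<3} {r.age_label:<17} {r.n:<6} "
            f"{fmt(e.median, e.ci_median):<23} "
            f"{fmt(e.lower, e.ci_lower):<23} "
            f"{fmt(e.upper, e.ci_upper):<23}"
            + (f"  [{r.flags}]" if r.flags else "")
        )
    return "\n".join(lines)
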