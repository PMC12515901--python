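"""Quantile convention and iterated Tukey outlier removal.

Outlier cleaning is applied per analyte x sex x whole-year age cell before
any partitioning: Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR) are computed,
values strictly outside are dropped, and the process repeats on the surviving
values until a pass removes nothing.

A single quantile convention is fixed here and reused by every other module
(Lahti limits, subgroup summaries, the robust sigma of the indirect fit):
linear interpolation of order statistics at rank h = (n - 1) * p + 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CleanResult",
    "compute_quantile",
    "tukey_fences",
    "iterative_tukey_clean",
    "clean_table",
    "CellTooSmallError",
]

log = logging.getLogger(__name__)

#: Tukey's standard fence multiplier.
TUKEY_K = 1.5

#: Below this cell size fences are too unstable to act on; cells are passed
#: through uncleaned with a warning.
MIN_CELL_SIZE = 8


class CellTooSmallError(ValueError):
    """Raised when a cell has too few values for Tukey fences (n < 8)."""


def compute_quantile(values, p: float) -> float:
    """Quantile of ``values`` at probability ``p``.

    Sorts ascending to x(1..n) and linearly interpolates at rank
    h = (n - 1) * p + 1, so p=0 gives the minimum and p=1 the maximum.
    This is the classic "type 7" convention and the single one used
    throughout the package.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("compute_quantile: empty input")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"compute_quantile: p={p} outside [0, 1]")
    return float(np.quantile(arr, p, method="linear"))


def tukey_fences(values) -> tuple[float, float]:
    """Lower and upper Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR).

    Raises
    ------
    CellTooSmallError
        If fewer than 8 values are supplied; the caller should keep the
        cell uncleaned.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < MIN_CELL_SIZE:
        raise CellTooSmallError(
            f"tukey_fences: n={arr.size} < {MIN_CELL_SIZE}, too small to clean"
        )
    q1 = compute_quantile(arr, 0.25)
    q3 = compute_quantile(arr, 0.75)
    iqr = q3 - q1
    return (q1 - TUKEY_K * iqr, q3 + TUKEY_K * iqr)


@dataclass
class CleanResult:
    """Outcome of one iterated Tukey clean of a single cell.

    ``kept`` and ``removed`` partition the input as multisets; ``kept`` is a
    fixed point of one further Tukey pass.  ``removed_iteration[i]`` is the
    1-based pass on which ``removed[i]`` fell outside the fences.
    """

    kept: np.ndarray
    removed: np.ndarray
    removed_iteration: np.ndarray
    n_iterations: int
    fences_per_iteration: list[tuple[float, float]] = field(default_factory=list)


def iterative_tukey_clean(values) -> CleanResult:
    """Repeat Tukey fencing until no value falls strictly outside.

    Values exactly on a fence are kept (conservative removal).  Cells with
    fewer than 8 values are returned untouched after a logged warning.
    Termination is guaranteed: each pass either removes at least one value
    or ends the loop, and the quartiles always lie inside the fences so the
    kept set can never empty.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("iterative_tukey_clean: empty input")

    kept = arr
    removed_parts: list[np.ndarray] = []
    removed_iters: list[np.ndarray] = []
    fences: list[tuple[float, float]] = []
    iteration = 0
    while True:
        iteration += 1
        try:
            lo, hi = tukey_fences(kept)
        except CellTooSmallError:
            if iteration == 1:
                log.warning(
                    "cell of n=%d too small to clean; passed through", kept.size
                )
            break
        fences.append((lo, hi))
        outside = (kept < lo) | (kept > hi)
        if not outside.any():
            break
        removed_parts.append(kept[outside])
        removed_iters.append(np.full(int(outside.sum()), iteration))
        kept = kept[~outside]

    assert kept.size > 0, "Tukey cleaning removed every value"
    removed = (
        np.concatenate(removed_parts) if removed_parts else np.empty(0, dtype=float)
    )
    removed_iteration = (
        np.concatenate(removed_iters) if removed_iters else np.empty(0, dtype=int)
    )
    return CleanResult(
        kept=kept,
        removed=removed,
        removed_iteration=removed_iteration,
        n_iterations=iteration,
        fences_per_iteration=fences,
    )


def clean_table(
    records: pd.DataFrame, value_col: str = "value"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean a long-format measurement table cell by cell.

    Cells are analyte x sex x whole-year age (``age_months // 12``).  Returns
    ``(kept, removed)`` where ``removed`` carries an ``iteration`` column with
    the Tukey pass on which each record was dropped.  Cells below the minimum
    size pass through untouched.
    """
    required = {"analyte", "sex", "age_months", value_col}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"clean_table: missing columns {sorted(missing)}")

    kept_idx: list[np.ndarray] = []
    removed_idx: list[np.ndarray] = []
    removed_iter: list[np.ndarray] = []
    year = records["age_months"] // 12
    for _, cell in records.groupby(["analyte", "sex", year], sort=False):
        vals = cell[value_col].to_numpy(dtype=float)
        res = iterative_tukey_clean(vals)
        if res.removed.size == 0:
            kept_idx.append(cell.index.to_numpy())
            continue
        # map removed values back to row indices (multiset-safe: pop matches)
        idx = cell.index.to_numpy()
        order = np.argsort(vals, kind="stable")
        sorted_vals = vals[order]
        taken = np.zeros(vals.size, dtype=bool)
        rem_rows = []
        rem_iters = []
        for v, it in zip(res.removed, res.removed_iteration):
            j = int(np.searchsorted(sorted_vals, v))
            while taken[order[j]] or sorted_vals[j] != v:
                j += 1
            taken[order[j]] = True
            rem_rows.append(idx[order[j]])
            rem_iters.append(int(it))
        removed_idx.append(np.asarray(rem_rows))
        removed_iter.append(np.asarray(rem_iters))
        kept_idx.append(idx[~taken])

    kept = records.loc[np.concatenate(kept_idx)].sort_index()
    if removed_idx:
        removed = records.loc[np.concatenate(removed_idx)].copy()
        removed["iteration"] = np.concatenate(removed_iter)
        removed = removed.sort_index()
    else:
        removed = records.iloc[0:0].copy()
        removed["iteration"] = np.empty(0, dtype=int)
    return kept, removed
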