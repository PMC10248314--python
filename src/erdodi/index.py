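"""Aggregation of recoded failure levels into the Erdodi Index.

The index value is the unweighted sum of the k component levels
(range 0 to 3k) and is trichotomized into *Pass*, *Borderline* and
*Fail* by the battery's band parameters.  Borderline rows keep their
label; dichotomous downstream analyses exclude them explicitly.

:func:`enumerate_fail_combinations` exhaustively scans level-vector
space and serves as a brute-force oracle for combinatorial claims about
the banding (e.g. how many liberal-cutoff failures it takes to reach
the Fail range).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cutoffs import BatteryConfig, MissingComponentError, recode_score

logger = logging.getLogger(__name__)

__all__ = [
    "Band",
    "EIResult",
    "ei_total",
    "classify_total",
    "score_cohort",
    "enumerate_fail_combinations",
]


class Band(str, Enum):
    PASS = "Pass"
    BORDERLINE = "Borderline"
    FAIL = "Fail"


@dataclass(frozen=True)
class EIResult:
    """Per-examinee index outcome: levels, total, and band label."""

    levels: tuple[int, ...]
    total: int
    band: Band


def ei_total(levels: Sequence[int] | np.ndarray) -> int:
    """Sum a vector of component failure levels (each in 0..3)."""
    arr = np.asarray(levels)
    if arr.size == 0:
        raise ValueError("empty level vector")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError(f"non-integer levels: {levels!r}")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 3:
        raise ValueError(f"levels out of range 0..3: {levels!r}")
    return int(arr.sum())


def classify_total(total: int, battery: BatteryConfig) -> Band:
    """Trichotomize an index total into Pass / Borderline / Fail."""
    total = int(total)
    if not (0 <= total <= 3 * battery.k):
        raise ValueError(
            f"total {total} outside 0..{3 * battery.k} for k={battery.k}"
        )
    if total <= battery.pass_max:
        return Band.PASS
    if total <= battery.borderline_max:
        return Band.BORDERLINE
    return Band.FAIL


def score_result(levels: Sequence[int], battery: BatteryConfig) -> EIResult:
    """Bundle levels, total and band for one examinee."""
    total = ei_total(levels)
    return EIResult(tuple(int(v) for v in levels), total, classify_total(total, battery))


def score_cohort(
    cohort: pd.DataFrame, battery: BatteryConfig
) -> pd.DataFrame:
    """Recode and aggregate every row of a cohort table.

    Returns a copy of ``cohort`` with one ``level_<component>`` column
    per battery component plus ``ei_total`` and ``ei_band``.  Under
    ``missing_policy="error"`` any missing or NaN component score
    raises, naming the row and component; under ``"complete_case"``
    incomplete rows are dropped and the count logged.
    """
    missing_cols = [
        c for c in battery.component_names if c not in cohort.columns
    ]
    if missing_cols:
        raise MissingComponentError(
            f"cohort lacks component column(s): {missing_cols}"
        )
    if cohort.empty:
        out = cohort.copy()
        for name in battery.component_names:
            out[f"level_{name}"] = pd.Series(dtype=np.int64)
        out["ei_total"] = pd.Series(dtype=np.int64)
        out["ei_band"] = pd.Series(dtype=object)
        return out

    scores = cohort[list(battery.component_names)]
    incomplete = scores.isna().any(axis=1)
    if incomplete.any():
        if battery.missing_policy == "error":
            row = cohort.index[incomplete][0]
            comp = scores.loc[row].isna().idxmax()
            raise MissingComponentError(
                f"row {row!r}: missing score for component {comp!r}"
            )
        n_drop = int(incomplete.sum())
        logger.info(
            "complete_case: dropped %d of %d rows with missing components",
            n_drop,
            len(cohort),
        )
        cohort = cohort.loc[~incomplete]
        scores = scores.loc[~incomplete]

    out = cohort.copy()
    levels = np.empty((len(cohort), battery.k), dtype=np.int64)
    for j, spec in enumerate(battery.components):
        col = scores[spec.name].to_numpy(dtype=float)
        levels[:, j] = [recode_score(v, spec) for v in col]
        out[f"level_{spec.name}"] = levels[:, j]
    totals = levels.sum(axis=1)
    out["ei_total"] = totals
    out["ei_band"] = [classify_total(t, battery).value for t in totals]
    return out


def enumerate_fail_combinations(
    battery: BatteryConfig, *, max_k: int = 10
) -> dict:
    """Exhaustively enumerate all ``4**k`` level vectors.

    Returns a summary with

    ``min_level1_only_components_for_fail``
        the smallest number of components failed at level 1 (all others
        at 0) whose total reaches the Fail band, or ``None`` if no such
        vector fails;
    ``min_level2_only_components_for_fail``
        same with failures all at level 2;
    ``band_counts``
        a ``{Band: count}`` tally over every enumerated vector.
    """
    k = battery.k
    if k > max_k:
        raise ValueError(f"k={k} too large for exhaustive 4^k enumeration")
    band_counts = {b: 0 for b in Band}
    min_l1: int | None = None
    min_l2: int | None = None
    for vec in itertools.product(range(4), repeat=k):
        band = classify_total(sum(vec), battery)
        band_counts[band] += 1
        if band is Band.FAIL:
            nz = [v for v in vec if v]
            if nz and all(v == 1 for v in nz):
                if min_l1 is None or len(nz) < min_l1:
                    min_l1 = len(nz)
            if nz and all(v == 2 for v in nz):
                if min_l2 is None or len(nz) < min_l2:
                    min_l2 = len(nz)
    return {
        "min_level1_only_components_for_fail": min_l1,
        "min_level2_only_components_for_fail": min_l2,
        "band_counts": band_counts,
    }
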