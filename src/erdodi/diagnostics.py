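"""Signal-detection evaluation of scalar validity indices.

Evaluates any scalar score (an aggregate validity index, a single PVT
trial, an embedded indicator) against any dichotomous criterion:
confusion counts and derived rates at a cutoff, cutoff sweeps, the
Mann-Whitney AUC with a Hanley-McNeil confidence interval, multivariate
base rates of failure, cross-range likelihood ratios, and the effect
size conventions used in performance-validity research (Cohen's *d*
with the average-variance denominator; phi-squared).

All computation is at full precision; display rounding lives in
:mod:`erdodi.formatting`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .index import Band

__all__ = [
    "FailDirection",
    "ConfusionCounts",
    "ClassificationMetrics",
    "AucEstimate",
    "RangeBrTable",
    "confusion_at_cutoff",
    "classification_metrics",
    "base_rate_fail",
    "roc_sweep",
    "auc_mann_whitney",
    "likelihood_ratio",
    "range_br_analysis",
    "lr_profile_vs_zero",
    "cohens_d",
    "phi_squared",
    "chi2_rxc",
]


class FailDirection(str, Enum):
    """Whether scores at-or-above or at-or-below the cutoff fail."""

    AT_OR_ABOVE = "at_or_above"
    AT_OR_BELOW = "at_or_below"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ClassificationMetrics:
    """Rates derived from a confusion table.

    ``occ`` is overall correct classification, (TP + TN) / N;
    ``br_fail`` is the base rate of failure, (TP + FP) / N — the
    proportion of the whole sample flagged at the cutoff, which upper
    bounds the false-positive rate.
    """

    sensitivity: float
    specificity: float
    occ: float
    br_fail: float


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_negative: int


def _fails(scores: np.ndarray, cutoff: float, direction: FailDirection) -> np.ndarray:
    direction = FailDirection(direction)
    if direction is FailDirection.AT_OR_ABOVE:
        return scores >= cutoff
    return scores <= cutoff


def confusion_at_cutoff(
    scores: Sequence[float],
    truth: Sequence[bool],
    cutoff: float,
    fail_direction: FailDirection | str = FailDirection.AT_OR_ABOVE,
) -> ConfusionCounts:
    """Tabulate predicted failures at a cutoff against criterion truth.

    The fail condition is inclusive of the cutoff (>= or <=, per
    ``fail_direction``); ties with the cutoff always count as fails.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {t.shape}")
    if s.size == 0:
        raise ValueError("empty input")
    pred = _fails(s, cutoff, fail_direction)
    return ConfusionCounts(
        tp=int(np.sum(pred & t)),
        fp=int(np.sum(pred & ~t)),
        tn=int(np.sum(~pred & ~t)),
        fn=int(np.sum(~pred & t)),
    )


def classification_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Sensitivity, specificity, OCC and BR_Fail from confusion counts."""
    if counts.n_positive == 0:
        raise ZeroDivisionError("no criterion-positive cases: sensitivity undefined")
    if counts.n_negative == 0:
        raise ZeroDivisionError("no criterion-negative cases: specificity undefined")
    n = counts.n
    return ClassificationMetrics(
        sensitivity=counts.tp / counts.n_positive,
        specificity=counts.tn / counts.n_negative,
        occ=(counts.tp + counts.tn) / n,
        br_fail=(counts.tp + counts.fp) / n,
    )


def base_rate_fail(
    scores: Sequence[float],
    cutoff: float,
    fail_direction: FailDirection | str = FailDirection.AT_OR_ABOVE,
) -> float:
    """Proportion of all scores failing the cutoff (no criterion needed)."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty input")
    return float(_fails(s, cutoff, fail_direction).mean())


def roc_sweep(
    scores: Sequence[float],
    truth: Sequence[bool],
    cutoffs: Sequence[float],
    fail_direction: FailDirection | str = FailDirection.AT_OR_ABOVE,
) -> pd.DataFrame:
    """Classification accuracy across a ladder of cutoffs.

    One row per cutoff with columns ``cutoff, br_fail, sensitivity,
    specificity, occ``; as the cutoff grows more conservative,
    sensitivity is non-increasing and specificity non-decreasing.
    """
    if len(list(cutoffs)) == 0:
        raise ValueError("empty cutoff list")
    rows = []
    for c in cutoffs:
        counts = confusion_at_cutoff(scores, truth, c, fail_direction)
        m = classification_metrics(counts)
        rows.append(
            {
                "cutoff": c,
                "br_fail": m.br_fail,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "occ": m.occ,
            }
        )
    return pd.DataFrame(rows)


def auc_mann_whitney(
    scores: Sequence[float],
    truth: Sequence[bool],
    fail_direction: FailDirection | str = FailDirection.AT_OR_ABOVE,
    *,
    alpha: float = 0.05,
) -> AucEstimate:
    """Area under the ROC curve via the Mann-Whitney statistic.

    AUC is the probability that a random criterion-positive case scores
    more extreme in the failure direction than a random negative case,
    with ties credited one half.  The standard error and the normal
    confidence interval follow Hanley & McNeil's approximation, with
    the interval truncated to [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {t.shape}")
    pos = s[t]
    neg = s[~t]
    n1, n2 = pos.size, neg.size
    if n1 == 0 or n2 == 0:
        raise ValueError("need at least one positive and one negative case")
    if FailDirection(fail_direction) is FailDirection.AT_OR_BELOW:
        pos, neg = -pos, -neg
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc = float(u) / (n1 * n2)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n1 - 1) * (q1 - auc**2)
        + (n2 - 1) * (q2 - auc**2)
    ) / (n1 * n2)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return AucEstimate(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        n_positive=n1,
        n_negative=n2,
    )


def likelihood_ratio(br_numerator: float, br_denominator: float) -> float:
    """Ratio of two base rates of criterion failure (same scale)."""
    if br_denominator <= 0:
        raise ZeroDivisionError("likelihood ratio undefined: zero denominator")
    return float(br_numerator) / float(br_denominator)


@dataclass(frozen=True)
class RangeBrTable:
    """Band-wise base rates of criterion failure and their ratios.

    ``br`` has one row per criterion and columns Pass/Borderline/Fail
    (criterion failure rate within each index band, as proportions);
    ``lr`` holds the likelihood ratios Borderline/Pass, Fail/Borderline
    and Fail/Pass per criterion plus a ``Mean LR`` summary row; ``n``
    counts examinees per band.
    """

    br: pd.DataFrame
    lr: pd.DataFrame
    n: dict

    @property
    def mean_lr(self) -> pd.Series:
        return self.lr.loc["Mean LR"]


_BAND_ORDER = [Band.PASS.value, Band.BORDERLINE.value, Band.FAIL.value]


def range_br_analysis(
    bands: Sequence[Band | str],
    criterion_fails: Mapping[str, Sequence[bool]],
) -> RangeBrTable:
    """Base rate of criterion failure across the index bands.

    For each criterion, the proportion failing within the Pass,
    Borderline and Fail bands of the index, plus the likelihood ratios
    B/P, F/B and F/P and their unweighted means across criteria.  A
    criterion vector may contain NaN for examinees it was not
    administered to; those rows are excluded for that criterion only.
    """
    band_vals = np.array([Band(b).value for b in bands], dtype=object)
    n_by_band = {b: int(np.sum(band_vals == b)) for b in _BAND_ORDER}
    empty = [b for b, c in n_by_band.items() if c == 0]
    if empty:
        raise ValueError(f"empty band(s): {empty}")
    br_rows = {}
    for name, fails in criterion_fails.items():
        f = np.asarray(fails, dtype=float)
        if f.shape != band_vals.shape:
            raise ValueError(f"criterion {name!r} not aligned with bands")
        row = {}
        for b in _BAND_ORDER:
            vals = f[band_vals == b]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                raise ValueError(f"criterion {name!r}: no cases in band {b}")
            row[b] = float(vals.mean())
        br_rows[name] = row
    br = pd.DataFrame.from_dict(br_rows, orient="index")[_BAND_ORDER]
    lr = pd.DataFrame(
        {
            "B/P": br[Band.BORDERLINE.value] / br[Band.PASS.value],
            "F/B": br[Band.FAIL.value] / br[Band.BORDERLINE.value],
            "F/P": br[Band.FAIL.value] / br[Band.PASS.value],
        }
    )
    lr.loc["Mean LR"] = lr.mean()
    return RangeBrTable(br=br, lr=lr, n=n_by_band)


def lr_profile_vs_zero(
    values: Sequence[int],
    criterion_fails: Mapping[str, Sequence[bool]],
    max_value: int | None = None,
) -> pd.DataFrame:
    """Likelihood of criterion failure per index value, relative to 0.

    For each index value v, LR(v) = BR_Fail(cases with value v) /
    BR_Fail(cases with value 0), per criterion.  Values above
    ``max_value`` are pooled into the top row (as ``>=max_value``).
    """
    v = np.asarray(values, dtype=int)
    rows = {}
    if max_value is not None:
        v = np.minimum(v, max_value)
    for name, fails in criterion_fails.items():
        f = np.asarray(fails, dtype=float)
        base = f[(v == 0) & ~np.isnan(f)]
        if base.size == 0 or base.mean() == 0:
            raise ValueError(f"criterion {name!r}: zero baseline at value 0")
        b0 = base.mean()
        rows[name] = {
            val: float(np.nanmean(f[v == val]) / b0)
            for val in np.unique(v)
        }
    return pd.DataFrame(rows)


def cohens_d(
    mean1: float, sd1: float, mean2: float, sd2: float, *, pooled_df: bool = False,
    n1: int | None = None, n2: int | None = None,
) -> float:
    """Standardized mean difference between two groups.

    Default denominator is the square root of the unweighted average of
    the two variances, the convention under which the published
    between-band contrasts reproduce.  ``pooled_df=True`` uses the
    df-weighted pooled SD instead (requires ``n1`` and ``n2``).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if pooled_df:
        if n1 is None or n2 is None or n1 < 2 or n2 < 2:
            raise ValueError("pooled_df=True requires group sizes n1, n2 >= 2")
        denom = np.sqrt(
            ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        )
    else:
        denom = np.sqrt((sd1**2 + sd2**2) / 2.0)
    return float(abs(mean1 - mean2) / denom)


def phi_squared(chi2: float, n: int) -> float:
    """Phi-squared effect size for a contingency table: chi^2 / N."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(chi2) / float(n)


def chi2_rxc(counts: Sequence[Sequence[float]]) -> float:
    """Pearson chi-squared statistic on an r x c table (no correction)."""
    table = np.asarray(counts, dtype=float)
    if np.any(table < 0):
        raise ValueError("negative cell counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    stat, _, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat)
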