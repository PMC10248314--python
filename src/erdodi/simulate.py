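"""Synthetic mixed clinical/forensic cohort generator.

No clinical data ship with this package, so end-to-end behaviour is
exercised on simulated cohorts that reproduce the statistical structure
the index model assumes: a latent credibility state (credible vs
non-credible responding) drives correlated deficits across the embedded
indicators, while the free-standing criterion PVTs are imperfectly
coupled to that state through per-test sensitivity/specificity.

The generative model, per examinee *i* and component *j*:

* latent state ``noncredible_i ~ Bernoulli(prevalence)``;
* deficit severity ``z_ij = sqrt(rho) * f_i + sqrt(1-rho) * e_ij`` with
  ``f_i, e_ij ~ N(0, 1)`` — a single shared factor induces the
  inter-indicator correlation;
* raw score ``= mu_j + s * sigma_j * m_i * z_ij + s * delta_j * sigma_j
  * noncredible_i`` where ``s`` points toward the failure direction,
  ``delta_j`` is the non-credible mean shift in credible-SD units and
  ``m_i`` inflates the SD of non-credible responders (invalid
  performance is reliably associated with inflated within-group
  variability);
* scores are then snapped to the instrument's granularity grid and
  clipped to its valid range;
* each criterion PVT fails with probability ``sensitivity`` for
  non-credible examinees and ``1 - specificity`` for credible ones.

Defaults emulate a referral cohort of 452 adults with ~20% non-credible
responders and criterion base rates of failure in the 17%-24% range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cutoffs import BatteryConfig, ComponentSpec, Direction
from .index import Band, score_cohort
from .diagnostics import (
    FailDirection,
    auc_mann_whitney,
    classification_metrics,
    confusion_at_cutoff,
    range_br_analysis,
)

__all__ = [
    "ComponentDistribution",
    "SimulationParams",
    "DEFAULT_COMPONENT_DISTRIBUTIONS",
    "DEFAULT_CRITERION_OPERATING",
    "simulate_cohort",
    "recovery_report",
]


@dataclass(frozen=True)
class ComponentDistribution:
    """Credible-state score distribution on a component's native scale."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")


#: Credible-state locations/spreads for the default EI-5 battery.
#: ACSS components center at 10 (SD 3) by construction of the metric;
#: raw-score components center in the healthy-normal range of each
#: instrument with mild clinical spread.
DEFAULT_COMPONENT_DISTRIBUTIONS: dict[str, ComponentDistribution] = {
    "CD": ComponentDistribution(mean=9.5, sd=3.0),
    "RCFT_Copy": ComponentDistribution(mean=32.0, sd=3.0),
    "FMS_WCST": ComponentDistribution(mean=1.2, sd=1.4),
    "RDS": ComponentDistribution(mean=9.5, sd=2.0),
    "RH_CVLT": ComponentDistribution(mean=14.5, sd=1.8),
}

#: Per-criterion (sensitivity, specificity) against the latent state.
#: With 20% prevalence these imply criterion base rates of failure of
#: roughly 24% (WMT), 18% (MSVT) and 17% (NV-MSVT).
DEFAULT_CRITERION_OPERATING: dict[str, tuple[float, float]] = {
    "wmt": (0.80, 0.90),
    "msvt": (0.72, 0.95),
    "nvmsvt": (0.70, 0.96),
}

_REFERRAL_SOURCES = ("IME", "Clinical", "M-LEG", "W-COM", "Other")
_REFERRAL_PROBS = (0.458, 0.302, 0.095, 0.088, 0.057)
_POSITIVE_INCENTIVE = frozenset({"IME", "M-LEG", "W-COM"})


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic-cohort generative model.

    ``noncredible_shift`` is in credible-state SD units toward each
    component's failure direction; ``sd_multiplier`` inflates the score
    spread of non-credible responders; ``inter_component_correlation``
    is the shared-factor correlation of deficit severity across
    indicators.
    """

    n: int = 452
    prevalence: float = 0.20
    noncredible_shift: float = 2.0
    sd_multiplier: float = 1.5
    inter_component_correlation: float = 0.3
    component_distributions: Mapping[str, ComponentDistribution] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_DISTRIBUTIONS)
    )
    criterion_operating: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CRITERION_OPERATING)
    )
    tomm1: ComponentDistribution = ComponentDistribution(mean=47.5, sd=2.5)
    wmt_subscale: ComponentDistribution = ComponentDistribution(mean=96.0, sd=3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if not (0.0 <= self.inter_component_correlation < 1.0):
            raise ValueError("inter_component_correlation must be in [0, 1)")
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be positive")
        for name, (sens, spec) in self.criterion_operating.items():
            if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
                raise ValueError(
                    f"criterion {name!r}: sens/spec must be probabilities"
                )


def _snap(values: np.ndarray, spec: ComponentSpec) -> np.ndarray:
    lo, hi = spec.valid_range
    if spec.granularity:
        values = np.round(values / spec.granularity) * spec.granularity
    return np.clip(values, lo, hi)


def _correlated_severity(
    rng: np.random.Generator, n: int, m: int, rho: float
) -> np.ndarray:
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, m))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique


def simulate_cohort(
    params: SimulationParams | None = None,
    battery: BatteryConfig | None = None,
) -> pd.DataFrame:
    """Draw a synthetic cohort table; deterministic given ``params.seed``.

    Columns: one raw-score column per battery component; ``wmt_fail``,
    ``msvt_fail``, ``nvmsvt_fail`` (0/1 at standard cutoffs); ``tomm1``
    (integer 0-50); ``wmt_ir``/``wmt_dr``/``wmt_cns`` (subscale
    percentages); ``referral`` and ``incentive`` covariates; and the
    latent ``noncredible`` truth flag (simulation only — absent from
    real cohorts by definition).
    """
    if params is None:
        params = SimulationParams()
    if battery is None:
        from .io import default_battery

        battery = default_battery()
    missing = [
        c.name
        for c in battery.components
        if c.name not in params.component_distributions
    ]
    if missing:
        raise ValueError(
            f"no credible-state distribution for component(s): {missing}"
        )
    rng = np.random.default_rng(params.seed)
    n = params.n
    noncredible = rng.random(n) < params.prevalence
    mult = np.where(noncredible, params.sd_multiplier, 1.0)

    # embedded indicators: shared-factor severity + shift toward failure
    k = battery.k
    z = _correlated_severity(rng, n, k, params.inter_component_correlation)
    data: dict[str, np.ndarray] = {}
    for j, spec in enumerate(battery.components):
        dist = params.component_distributions[spec.name]
        sign = 1.0 if spec.direction is Direction.HIGH_FAILS else -1.0
        raw = (
            dist.mean
            + sign * dist.sd * mult * z[:, j]
            + sign * params.noncredible_shift * dist.sd * noncredible
        )
        data[spec.name] = _snap(raw, spec)

    # criterion PVTs: Bernoulli given the latent state
    for name, (sens, spec_) in params.criterion_operating.items():
        p_fail = np.where(noncredible, sens, 1.0 - spec_)
        data[f"{name}_fail"] = (rng.random(n) < p_fail).astype(int)

    # TOMM-1 trial 1 (0-50 correct, low scores fail)
    z_t = _correlated_severity(rng, n, 1, params.inter_component_correlation)[:, 0]
    tomm = (
        params.tomm1.mean
        - params.tomm1.sd * mult * z_t
        - params.noncredible_shift * params.tomm1.sd * noncredible
    )
    data["tomm1"] = np.clip(np.round(tomm), 0, 50).astype(int)

    # WMT main subscales (percent correct, 2.5% grid of a 40-item scale)
    z_w = _correlated_severity(rng, n, 3, params.inter_component_correlation)
    for col, idx in (("wmt_ir", 0), ("wmt_dr", 1), ("wmt_cns", 2)):
        v = (
            params.wmt_subscale.mean
            - params.wmt_subscale.sd * mult * z_w[:, idx]
            - params.noncredible_shift * params.wmt_subscale.sd * noncredible
        )
        data[col] = np.clip(np.round(v / 2.5) * 2.5, 0.0, 100.0)

    referral = rng.choice(_REFERRAL_SOURCES, size=n, p=_REFERRAL_PROBS)
    data["referral"] = referral
    data["incentive"] = np.isin(referral, list(_POSITIVE_INCENTIVE)).astype(int)
    data["noncredible"] = noncredible.astype(int)
    return pd.DataFrame(data)


def recovery_report(
    cohort: pd.DataFrame, battery: BatteryConfig | None = None
) -> dict:
    """Score a simulated cohort and evaluate recovery of the truth.

    Runs the full pipeline (recode -> aggregate -> band) and reports the
    index's AUC against the latent credibility state, sensitivity and
    specificity of the standard Fail cutoff (Borderline rows excluded,
    as in dichotomous criterion grouping), and band-wise criterion
    base rates of failure with their likelihood-ratio table.
    """
    if battery is None:
        from .io import default_battery

        battery = default_battery()
    if "noncredible" not in cohort.columns:
        raise ValueError("cohort lacks the latent 'noncredible' truth flag")
    scored = score_cohort(cohort, battery)
    truth = scored["noncredible"].astype(bool).to_numpy()
    totals = scored["ei_total"].to_numpy()

    auc = auc_mann_whitney(totals, truth, FailDirection.AT_OR_ABOVE)
    dich = scored["ei_band"] != Band.BORDERLINE.value
    counts = confusion_at_cutoff(
        totals[dich], truth[dich], battery.fail_min, FailDirection.AT_OR_ABOVE
    )
    metrics = classification_metrics(counts)

    criterion_cols = [c for c in scored.columns if c.endswith("_fail")]
    criterion = {
        c.removesuffix("_fail").upper(): scored[c].astype(bool).to_numpy()
        for c in criterion_cols
    }
    ranges = range_br_analysis(scored["ei_band"], criterion)
    prevalence_by_band = (
        scored.groupby("ei_band", observed=True)["noncredible"].mean().to_dict()
    )
    return {
        "n": len(scored),
        "auc_vs_truth": auc,
        "fail_cutoff": battery.fail_min,
        "sensitivity_vs_truth": metrics.sensitivity,
        "specificity_vs_truth": metrics.specificity,
        "band_counts": scored["ei_band"].value_counts().to_dict(),
        "range_br": ranges,
        "noncredible_prevalence_by_band": prevalence_by_band,
    }
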