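"""Criterion groupings from free-standing performance validity tests.

The reference standard is built from three Green-family PVTs (WMT,
MSVT, NV-MSVT), each consumed as a dichotomous Pass/Fail outcome at
its standard cutoff.  The composite (G-3) treats zero failures as an
overall Pass, exactly one failure as indeterminate (excluded from
dichotomous grouping), and two or more failures as an overall Fail.

Also provided: the WMT three-way classification computed from its main
subscale percentages (the only criterion rule published in enough
detail to compute), a configurable G-3 dichotomy (>=1 or >=2 failures),
and the joint two-classifier outcome used for incremental-validity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .index import Band

__all__ = [
    "G3Label",
    "G3Outcome",
    "JointOutcome",
    "TOMM1_FAIL_CUTOFF",
    "g3_outcome",
    "g3_dichotomy",
    "wmt_trichotomize",
    "joint_outcome",
]

#: Default TOMM-1 failure cutoff (fail at or below); published use also
#: includes <=43 — see the methods note for the discrepancy.
TOMM1_FAIL_CUTOFF = 42


class G3Label(str, Enum):
    PASS = "Pass"
    INDETERMINATE = "Indeterminate"
    FAIL = "Fail"


class JointOutcome(str, Enum):
    PASSED_BOTH = "passed_both"
    MIXED = "mixed"
    FAILED_BOTH = "failed_both"


@dataclass(frozen=True)
class G3Outcome:
    n_fails: int
    label: G3Label


def g3_outcome(fail_flags: Sequence[bool]) -> G3Outcome:
    """Aggregate the three criterion PVT outcomes into the G-3.

    Pass = zero failures; a single failure is indeterminate (a lone PVT
    failure is insufficient to call the profile invalid); >=2 failures
    is an overall Fail.
    """
    flags = [bool(f) for f in fail_flags]
    if len(flags) != 3:
        raise ValueError(f"expected exactly 3 PVT flags, got {len(flags)}")
    n = sum(flags)
    if n == 0:
        label = G3Label.PASS
    elif n == 1:
        label = G3Label.INDETERMINATE
    else:
        label = G3Label.FAIL
    return G3Outcome(n, label)


def g3_dichotomy(fail_flags: Sequence[bool], min_fails: int) -> bool:
    """Dichotomous G-3 fail: at least ``min_fails`` of 3 PVTs failed."""
    if min_fails not in (1, 2, 3):
        raise ValueError(f"min_fails must be 1, 2 or 3, got {min_fails}")
    flags = [bool(f) for f in fail_flags]
    if len(flags) != 3:
        raise ValueError(f"expected exactly 3 PVT flags, got {len(flags)}")
    return sum(flags) >= min_fails


def wmt_trichotomize(
    ir: float, dr: float, cns: float, cutoff: float = 85.0
) -> Band:
    """Three-way WMT outcome from its main subscale percentages.

    Pass: IR, DR and CNS all above ``cutoff``; Borderline: at least one
    subscale exactly at the cutoff and none below ("Warning" in the
    test manual); Fail: at least one subscale below the cutoff.
    Inputs are compared at one-decimal precision, matching how subscale
    percentages are reported.
    """
    vals = []
    for label, v in (("IR", ir), ("DR", dr), ("CNS", cns)):
        v = float(v)
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"WMT {label} = {v} outside [0, 100]")
        vals.append(round(v, 1))
    cutoff = round(float(cutoff), 1)
    if any(v < cutoff for v in vals):
        return Band.FAIL
    if any(v == cutoff for v in vals):
        return Band.BORDERLINE
    return Band.PASS


def joint_outcome(g3_label: G3Label | str, ei_band: Band | str) -> JointOutcome:
    """Joint grouping of the G-3 and index outcomes.

    Both inputs must already be dichotomous (indeterminate G-3 and
    Borderline index rows are excluded upstream).
    """
    g3 = G3Label(g3_label)
    ei = Band(ei_band)
    if g3 is G3Label.INDETERMINATE or ei is Band.BORDERLINE:
        raise ValueError(
            f"joint outcome needs dichotomous inputs, got ({g3}, {ei})"
        )
    g3_fail = g3 is G3Label.FAIL
    ei_fail = ei is Band.FAIL
    if g3_fail and ei_fail:
        return JointOutcome.FAILED_BOTH
    if g3_fail or ei_fail:
        return JointOutcome.MIXED
    return JointOutcome.PASSED_BOTH
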