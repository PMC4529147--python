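"""Stress-reactivity screening from salivary cortisol panels.

Group membership is decided purely by the rank of the peak post-stress
sample (C2) within the cohort: strictly above the 75th percentile rank is
"high", strictly below the 25th is "low", and a band around the median
(40th-60th by default) is "medium"; everyone else is unassigned, mirroring
an ex-ante screening design that keeps only clearly separated participants.
A participant is a cortisol responder when the stress-induced increase
(C2 - C0) reaches 1.1 nmol/l.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CohortSizeError
from .types import CortisolProfile

RESPONDER_THRESHOLD_NMOL_L = 1.1


@dataclass(frozen=True)
class ReactivityAssignment:
    participant_id: str
    c2_nmol_l: float
    cortisol_increase: float
    group: str  # "low" | "medium" | "high" | "unassigned"
    responder: bool


def percentile_ranks(values) -> np.ndarray:
    """Percentile rank in (0, 100] of each value; tied values share the rank
    of their common value (the proportion of observations <= it)."""
    v = np.asarray(values, dtype=float)
    srt = np.sort(v)
    ranks = np.searchsorted(srt, v, side="right")
    return 100.0 * ranks / v.size


def responder_status(
    profile: CortisolProfile, threshold: float = RESPONDER_THRESHOLD_NMOL_L
) -> bool:
    """Whether the stress-induced increase (C2 - C0) reaches the threshold.

    The bound is inclusive: an increase exactly at threshold qualifies.
    """
    return profile.increase >= threshold


def assign_reactivity_groups(
    profiles: Sequence[CortisolProfile],
    high_pct: float = 75.0,
    low_pct: float = 25.0,
    mid_band: tuple[float, float] = (40.0, 60.0),
    responder_threshold: float = RESPONDER_THRESHOLD_NMOL_L,
) -> list[ReactivityAssignment]:
    """Classify a cohort into low/medium/high reactivity groups by C2 rank.

    A C2 percentile rank strictly above ``high_pct`` maps to "high",
    strictly below ``low_pct`` to "low", and inside
    ``(mid_band[0], mid_band[1]]`` to "medium"; anything else (including a
    fully degenerate cohort where every C2 is identical) is "unassigned".
    Rank-based cuts make the labels invariant under any strictly increasing
    rescaling of the concentration axis.
    """
    if len(profiles) < 4:
        raise CohortSizeError(
            f"need at least 4 profiles for percentile screening, got {len(profiles)}"
        )
    if not (low_pct <= mid_band[0] < mid_band[1] <= high_pct):
        raise CohortSizeError("mid_band must nest inside (low_pct, high_pct)")

    c2 = np.array([p.c2 for p in profiles], dtype=float)
    degenerate = np.ptp(c2) == 0.0
    if degenerate:
        warnings.warn(
            "all C2 values identical; no participant strictly exceeds any "
            "percentile cut, leaving everyone unassigned",
            stacklevel=2,
        )
    ranks = percentile_ranks(c2)

    out = []
    for profile, r in zip(profiles, ranks):
        if degenerate:
            group = "unassigned"
        elif r > high_pct:
            group = "high"
        elif r < low_pct:
            group = "low"
        elif mid_band[0] < r <= mid_band[1]:
            group = "medium"
        else:
            group = "unassigned"
        out.append(
            ReactivityAssignment(
                participant_id=profile.participant_id,
                c2_nmol_l=profile.c2,
                cortisol_increase=profile.increase,
                group=group,
                responder=responder_status(profile, responder_threshold),
            )
        )
    return out
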