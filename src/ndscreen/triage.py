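"""Hit triage: occupancy tiers, kinetic-shape flags, hit calling.

Fragments are binned per surface by percent occupancy into four tiers —
reference binder (< 0%), no binder [0, 50)%, binder [50, 300]% and
super-stoichiometric binder (> 300%) — with both binder boundaries read as
inclusive. Fragments whose sensorgrams are not fragment-like are flagged:
small molecules should associate and dissociate within seconds, so a large
residual late in dissociation or a persistent positive slope late in the
contact phase marks a likely aspecific interaction; strong binding to the
reference surface in excess of the active channel marks a reference binder.
A fragment is a hit iff its tier is binder and it carries no flags; flags
are recorded for every tier but only reject binder-tier fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import Sensorgram
from .exceptions import ValidationError
from .preprocess import ReportPoint, baseline_level

__all__ = [
    "Tier", "Flag", "TriageThresholds", "TriageResult",
    "classify", "flag_kinetics", "call_hits",
]


class Tier(str, Enum):
    REFERENCE_BINDER = "reference_binder"
    NO_BINDER = "no_binder"
    BINDER = "binder"
    SUPER_STOICHIOMETRIC = "super_stoichiometric"


class Flag(str, Enum):
    SLOW_DISSOCIATION = "slow_dissociation"
    RISING_ASSOCIATION = "rising_association"
    REFERENCE_CHANNEL_BINDING = "reference_channel_binding"


@dataclass(frozen=True)
class TriageThresholds:
    """Tunable thresholds of the kinetic-shape flags.

    f_diss
        Flag slow dissociation when the mean response over the last
        ``diss_tail_s`` seconds of dissociation exceeds ``f_diss`` times the
        report point (only for report points above ``r_min`` RU).
    f_slope
        Flag a rising association when the least-squares slope over the last
        half of the contact window, projected over the remaining half of the
        contact time, exceeds ``f_slope`` times the report point.
    f_ref
        Flag reference-channel binding when the reference channel's report
        point exceeds ``f_ref`` times the reference surface's expected
        100%-occupancy response *and* exceeds the active channel's raw
        (pre-subtraction) report point — i.e. the reference binds more than
        the active surface, beyond what shared membrane partitioning (which
        reference subtraction cancels) explains.
    """

    f_diss: float = 0.2
    f_slope: float = 0.2
    r_min: float = 1.0
    f_ref: float = 0.5
    diss_tail_s: float = 5.0


@dataclass
class TriageResult:
    """Tier, flags and hit decision for one fragment on one surface."""

    analyte_id: str
    channel_id: str
    occupancy_pct: float
    tier: Tier
    flags: frozenset[Flag] = frozenset()

    @property
    def hit(self) -> bool:
        return self.tier is Tier.BINDER and not self.flags


def classify(occupancy_pct: float, lo: float = 50.0, hi: float = 300.0) -> Tier:
    """Occupancy tier; boundaries ``lo`` and ``hi`` belong to the binder tier."""
    if not math.isfinite(occupancy_pct):
        raise ValueError(f"occupancy must be finite, got {occupancy_pct}")
    if occupancy_pct < 0:
        return Tier.REFERENCE_BINDER
    if occupancy_pct < lo:
        return Tier.NO_BINDER
    if occupancy_pct <= hi:
        return Tier.BINDER
    return Tier.SUPER_STOICHIOMETRIC


def flag_kinetics(
    sg: Sensorgram,
    rp: ReportPoint,
    ref_sg: Optional[Sensorgram],
    thresholds: TriageThresholds = TriageThresholds(),
    ref_occ100_ru: Optional[float] = None,
    active_raw_ru: Optional[float] = None,
    baseline_window_s: float = 5.0,
) -> frozenset[Flag]:
    """Kinetic-shape flags for one corrected sensorgram.

    Parameters
    ----------
    sg : Sensorgram
        Reference-subtracted active-channel trace (dissociation phase must
        be present).
    rp : ReportPoint
        Corrected report point belonging to ``sg``.
    ref_sg : Sensorgram or None
        Raw reference-channel trace; ``None`` disables the reference flag.
    ref_occ100_ru : float, optional
        Expected response of the reference surface at 100% occupancy by this
        analyte (``Mw_analyte * capture_ref / Mw_ref``); required for the
        reference flag.
    active_raw_ru : float, optional
        Raw (pre-subtraction) active-channel report point; the reference
        flag requires the reference signal to exceed it.
    """
    if sg.dissociation_time <= 0:
        raise ValidationError(
            f"cycle {sg.cycle_index} channel {sg.channel_id}: flags need a "
            "dissociation phase"
        )
    flags: set[Flag] = set()
    base = baseline_level(sg, baseline_window_s)

    # slow dissociation: tail of the dissociation phase still elevated
    tail = sg.window_mean(sg.t_diss_end - thresholds.diss_tail_s,
                          sg.t_diss_end) - base
    if rp.value > thresholds.r_min and tail > thresholds.f_diss * rp.value:
        flags.add(Flag.SLOW_DISSOCIATION)

    # rising association: late-contact slope projected over the remaining
    # contact time is a large fraction of the report point
    half = sg.t_inject_start + sg.contact_time / 2.0
    mask = (sg.time >= half) & (sg.time <= sg.t_inject_end)
    if mask.sum() >= 3:
        slope = float(np.polyfit(sg.time[mask], sg.response[mask], 1)[0])
        projected = slope * (sg.contact_time / 2.0)
        if (rp.value > thresholds.r_min
                and projected > thresholds.f_slope * rp.value):
            flags.add(Flag.RISING_ASSOCIATION)

    # reference binding: significant reference signal in excess of the active
    if ref_sg is not None and ref_occ100_ru is not None:
        ref_rp = extract_ref_level(ref_sg, rp.window, baseline_window_s)
        threshold = thresholds.f_ref * ref_occ100_ru
        exceeds_active = (active_raw_ru is None) or (ref_rp > active_raw_ru)
        if ref_rp > threshold and exceeds_active:
            flags.add(Flag.REFERENCE_CHANNEL_BINDING)

    return frozenset(flags)


def extract_ref_level(ref_sg: Sensorgram, window: tuple[float, float],
                      baseline_window_s: float = 5.0) -> float:
    """Baseline-anchored reference-channel level over the report window."""
    base = baseline_level(ref_sg, baseline_window_s)
    t_a, t_b = window
    return ref_sg.window_mean(ref_sg.t_inject_start + t_a,
                              ref_sg.t_inject_start + t_b) - base


def call_hits(
    results: Sequence[TriageResult],
) -> tuple[set[str], pd.DataFrame]:
    """Hit set plus a tier-accounting table for one surface.

    The accounting table mirrors the usual screen summary: counts per tier,
    the number (and percentage, rounded to integer percent) of binder-tier
    fragments rejected for flags, and the hit count (binders minus flagged
    binders).
    """
    seen: set[tuple[str, str]] = set()
    for res in results:
        key = (res.analyte_id, res.channel_id)
        if key in seen:
            raise ValidationError(
                f"duplicate triage result for {res.analyte_id!r} on "
                f"{res.channel_id!r}"
            )
        seen.add(key)

    tier_counts = {tier: 0 for tier in Tier}
    for res in results:
        tier_counts[res.tier] += 1
    binders = [res for res in results if res.tier is Tier.BINDER]
    rejected = [res for res in binders if res.flags]
    hits = {res.analyte_id for res in binders if not res.flags}
    n_binders = len(binders)
    pct_rejected = (100.0 * len(rejected) / n_binders) if n_binders else 0.0
    table = pd.DataFrame(
        {
            "count": [
                tier_counts[Tier.REFERENCE_BINDER],
                tier_counts[Tier.NO_BINDER],
                tier_counts[Tier.BINDER],
                tier_counts[Tier.SUPER_STOICHIOMETRIC],
                len(rejected),
                len(hits),
            ],
        },
        index=pd.Index(
            [
                "reference_binder", "no_binder", "binder",
                "super_stoichiometric", "rejected_binder", "hits",
            ],
            name="classified_as",
        ),
    )
    table["pct_of_binders"] = ""
    table.loc["rejected_binder", "pct_of_binders"] = str(int(round(pct_rejected)))
    return hits, table
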