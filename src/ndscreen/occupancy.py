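"""Mw-normalized percent occupancy and control-based decay normalization.

Percent occupancy converts a corrected SPR response into the average number
of analyte molecules bound per captured particle, times 100:

    occupancy% = 100 * (R / Mw_analyte) / (capture_level / Mw_target)

since RU is proportional to bound mass, ``R / Mw_analyte`` is proportional
to moles of analyte and ``capture_level / Mw_target`` to moles of captured
particle. 100% therefore means one analyte per particle on average; negative
values arise when the reference channel bound more than the active surface.

Long screens lose captured target (His-tag leaching off a Ni-chelate chip),
so responses are rescaled with periodic control injections of a well-behaved
tool compound: the control response is an activity proxy for the surface,
and every sample response is multiplied by first-control / interpolated-
control at its cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .exceptions import DataQualityError
from .preprocess import ReportPoint

__all__ = ["OccupancyResult", "occupancy", "stoichiometry", "decay_normalize"]


@dataclass
class OccupancyResult:
    """Per (analyte, surface) occupancy with its provenance."""

    analyte_id: str
    channel_id: str
    corrected_response: float
    scale_factor: float
    occupancy_pct: float


def occupancy(
    corrected_response: float,
    mw_analyte: float,
    capture_level: float,
    mw_target: float,
) -> float:
    """Percent occupancy of the captured particle by the analyte.

    Parameters are the corrected report point (RU), the analyte Mw (Da), the
    run-start capture level (RU) and the captured-particle Mw (Da). The
    result may be negative (reference binders).
    """
    if not mw_analyte > 0:
        raise ValueError("mw_analyte must be > 0")
    if not mw_target > 0:
        raise ValueError("mw_target must be > 0")
    if not capture_level > 0:
        raise ValueError("capture_level must be > 0")
    return 100.0 * (corrected_response / mw_analyte) / (capture_level / mw_target)


def stoichiometry(occupancy_pct: float) -> float:
    """Average analyte molecules bound per captured particle."""
    return occupancy_pct / 100.0


def decay_normalize(
    rp_series: Sequence[ReportPoint],
    controls: Sequence[ReportPoint],
) -> tuple[list[ReportPoint], list[float]]:
    """Rescale sample report points for capture decay using control injections.

    The control response is interpolated linearly in cycle index between
    flanking controls (nearest control beyond the ends); the scale factor at
    cycle i is ``R_control(first) / R_control_interp(i)`` and each sample
    value is multiplied by it. Requires >= 2 controls spanning the samples;
    a non-positive control response means the surface is dead.

    Returns the normalized report points and the per-sample scale factors.
    """
    if len(controls) < 2:
        raise DataQualityError(
            "decay normalization requires >= 2 control injections, got "
            f"{len(controls)}"
        )
    anchors = sorted((c.cycle_index, c.value) for c in controls)
    if any(v <= 0 for _, v in anchors):
        bad = [c for c, v in anchors if v <= 0]
        raise DataQualityError(
            "control response <= 0 RU at cycle(s) "
            + ", ".join(map(str, bad))
            + ": surface appears dead"
        )
    cycles = np.array([c for c, _ in anchors], dtype=float)
    values = np.array([v for _, v in anchors], dtype=float)
    first = values[0]
    normalized: list[ReportPoint] = []
    scales: list[float] = []
    for rp in rp_series:
        interp = float(np.interp(rp.cycle_index, cycles, values))
        scale = first / interp
        scales.append(scale)
        normalized.append(ReportPoint(rp.cycle_index, rp.channel_id,
                                      rp.value * scale, rp.window))
    return normalized, scales
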