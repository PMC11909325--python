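"""Sensorgram corrections: double referencing and solvent correction.

Raw traces become corrected report points in a fixed order:

1. **Reference subtraction** — pointwise subtraction of the designated
   reference channel's trace (empty chip for empty-ND and protein-only
   surfaces, a same-lipid empty ND for protein-ND surfaces), interpolated
   onto the active grid where grids differ.
2. **Report-point extraction** — mean response over a late-contact window
   (default: last 25% of the contact time, ending 1 s before injection end),
   relative to the mean of the 5 s pre-injection baseline.
3. **Blank correction** — subtraction of the linear-in-cycle-index
   interpolation between the flanking running-buffer blank injections.
4. **Solvent correction** — subtraction of a quadratic calibration curve,
   fitted to matched DMSO-titration cycles, evaluated at the reference
   channel's bulk report point; compensates the residual bulk offset left by
   sample-vs-running-buffer DMSO mismatch over crowded surfaces.

Each step is linear, so the whole pipeline is linear in the trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import Sensorgram
from .exceptions import AlignmentError, ConfigError, FitError, NdscreenError
from .exceptions import ValidationError

__all__ = [
    "ReportPoint", "SolventCurve", "reference_subtract", "extract_report_point",
    "default_report_window", "blank_correct", "fit_solvent_correction",
    "apply_solvent_correction",
]


@dataclass
class ReportPoint:
    """A baseline-anchored binding level read from one sensorgram.

    ``window`` is (t_a, t_b) in seconds relative to injection start.
    """

    cycle_index: int
    channel_id: str
    value: float
    window: tuple[float, float]


@dataclass
class SolventCurve:
    """Quadratic mapping reference-channel bulk response (RU) -> correction (RU).

    ``coefficients`` are (c2, c1, c0) for ``c2 x^2 + c1 x + c0``;
    ``calibration_range`` is the abscissa span of the fitted points.
    Evaluating outside the range warns and extrapolates.
    """

    coefficients: tuple[float, float, float]
    calibration_range: tuple[float, float]
    residual_norm: float = 0.0

    def __call__(self, reference_bulk: float) -> float:
        lo, hi = self.calibration_range
        if not lo <= reference_bulk <= hi:
            warnings.warn(
                f"solvent correction evaluated at {reference_bulk:.3g} RU, "
                f"outside calibration range [{lo:.3g}, {hi:.3g}] RU; "
                "extrapolating",
                stacklevel=2,
            )
        c2, c1, c0 = self.coefficients
        return c2 * reference_bulk ** 2 + c1 * reference_bulk + c0


def reference_subtract(active: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Subtract the reference trace from the active trace, pointwise.

    The reference is linearly interpolated onto the active grid if the grids
    differ; the active sensorgram's phase markers are preserved. Raises
    :class:`AlignmentError` for mismatched cycles or non-overlapping spans.
    """
    if active.cycle_index != reference.cycle_index:
        raise AlignmentError(
            f"cannot reference-subtract cycle {active.cycle_index} against "
            f"cycle {reference.cycle_index}"
        )
    if (reference.time[-1] < active.time[0]
            or reference.time[0] > active.time[-1]):
        raise AlignmentError(
            f"cycle {active.cycle_index}: active ({active.channel_id}) and "
            f"reference ({reference.channel_id}) time spans do not overlap"
        )
    ref_on_active = np.interp(active.time, reference.time, reference.response)
    return Sensorgram(
        cycle_index=active.cycle_index,
        channel_id=active.channel_id,
        time=active.time.copy(),
        response=active.response - ref_on_active,
        t_inject_start=active.t_inject_start,
        t_inject_end=active.t_inject_end,
        t_diss_end=active.t_diss_end,
    )


def default_report_window(contact_time: float, frac: float = 0.25,
                          end_offset_s: float = 1.0) -> tuple[float, float]:
    """Window (s, relative to injection start) for a steady-state report point."""
    t_b = contact_time - end_offset_s
    t_a = contact_time * (1.0 - frac)
    if not t_a < t_b:
        raise ConfigError(
            f"degenerate report window for contact time {contact_time} s: "
            f"[{t_a}, {t_b}]"
        )
    return (t_a, t_b)


def baseline_level(sg: Sensorgram, baseline_window_s: float = 5.0) -> float:
    """Mean response over the ``baseline_window_s`` seconds before injection."""
    return sg.window_mean(sg.t_inject_start - baseline_window_s,
                          np.nextafter(sg.t_inject_start, -np.inf))


def extract_report_point(
    sg: Sensorgram,
    window: tuple[float, float],
    baseline_window_s: float = 5.0,
) -> ReportPoint:
    """Baseline-anchored mean response over ``window`` (relative to injection).

    The window must lie inside the association phase.
    """
    t_a, t_b = window
    if not (0 <= t_a < t_b <= sg.contact_time):
        raise ValidationError(
            f"cycle {sg.cycle_index} channel {sg.channel_id}: report window "
            f"[{t_a}, {t_b}] s outside association phase "
            f"(contact {sg.contact_time} s)"
        )
    base = baseline_level(sg, baseline_window_s)
    value = sg.window_mean(sg.t_inject_start + t_a, sg.t_inject_start + t_b)
    return ReportPoint(
        cycle_index=sg.cycle_index,
        channel_id=sg.channel_id,
        value=value - base,
        window=(t_a, t_b),
    )


def _interp_by_cycle(cycle: int, anchors: Sequence[tuple[int, float]]) -> float:
    """Piecewise-linear interpolation in cycle index; nearest beyond the ends."""
    cycles = np.array([c for c, _ in anchors], dtype=float)
    values = np.array([v for _, v in anchors], dtype=float)
    return float(np.interp(cycle, cycles, values))


def blank_correct(
    report_points: Sequence[ReportPoint],
    blanks: Sequence[ReportPoint],
) -> list[ReportPoint]:
    """Subtract interpolated blank responses from sample report points.

    Each sample report point loses the linear-in-cycle-index interpolation
    between its flanking blanks; samples before the first (after the last)
    blank use the nearest blank. With a single blank the subtraction is that
    constant. No blanks at all is a configuration error.
    """
    if not blanks:
        raise ConfigError("blank correction requires at least one blank "
                          "injection")
    anchors = sorted((b.cycle_index, b.value) for b in blanks)
    out = []
    for rp in report_points:
        correction = _interp_by_cycle(rp.cycle_index, anchors)
        out.append(ReportPoint(rp.cycle_index, rp.channel_id,
                               rp.value - correction, rp.window))
    return out


def fit_solvent_correction(
    calibration: Sequence[tuple[float, float]],
    min_points: int = 5,
) -> SolventCurve:
    """Least-squares quadratic through (reference bulk RU, residual RU) pairs.

    Needs at least ``min_points`` pairs with distinct abscissae; a
    rank-deficient design raises :class:`FitError`.
    """
    if len(calibration) < min_points:
        raise FitError(
            f"solvent correction needs >= {min_points} calibration points, "
            f"got {len(calibration)}"
        )
    x = np.array([p[0] for p in calibration], dtype=float)
    y = np.array([p[1] for p in calibration], dtype=float)
    if np.unique(x).size < min_points:
        raise FitError("solvent calibration abscissae must be distinct")
    design = np.column_stack([x ** 2, x, np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 3:
        raise FitError("solvent calibration design is rank deficient")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return SolventCurve(
        coefficients=(float(coef[0]), float(coef[1]), float(coef[2])),
        calibration_range=(float(x.min()), float(x.max())),
        residual_norm=float(np.linalg.norm(resid)),
    )


def apply_solvent_correction(
    rp: ReportPoint,
    curve: SolventCurve,
    reference_bulk: float,
) -> ReportPoint:
    """Subtract ``curve(reference_bulk)`` from the report-point value."""
    return ReportPoint(rp.cycle_index, rp.channel_id,
                       rp.value - curve(reference_bulk), rp.window)
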