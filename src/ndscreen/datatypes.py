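"""Core record types for an SPR fragment-screening run.

A screen is a sequence of injection *cycles*. Each cycle injects one analyte
(a fragment, a tool compound, a fluconazole-like control, a running-buffer
blank, or a DMSO solvent-calibration sample) over all flow channels of the
sensor chip. Each channel carries a *surface*: an empty chip, an empty lipid
nanodisc (ND), the target protein alone, or the protein embedded in an ND.
The instrument reports one time/response trace (a *sensorgram*, in response
units RU) per cycle per channel.

These dataclasses are deliberately thin: arrays stay numpy, tables stay
pandas, and the invariants that matter for downstream arithmetic are enforced
at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .exceptions import ValidationError


class Role(str, Enum):
    """What an injection cycle contains."""

    FRAGMENT = "fragment"
    TOOL_COMPOUND = "tool_compound"
    BLANK = "blank"
    SOLVENT_CORRECTION = "solvent_correction"
    CONTROL = "control"


class CapturedSpecies(str, Enum):
    """What is immobilized on a flow channel."""

    EMPTY_CHIP = "empty_chip"
    EMPTY_ND = "empty_nd"
    PROTEIN = "protein"
    PROTEIN_ND = "protein_nd"


class Lipid(str, Enum):
    """Phospholipid used to assemble the nanodisc bilayer (NONE = no lipid)."""

    POPC = "POPC"
    DMPC = "DMPC"
    DPPC = "DPPC"
    DPHPC = "DPhPC"
    NONE = "none"


#: roles that carry an actual analyte and therefore need a molecular weight
ANALYTE_ROLES = frozenset({Role.FRAGMENT, Role.TOOL_COMPOUND, Role.CONTROL})


@dataclass(frozen=True)
class InjectionRecord:
    """One sample-sheet row: what was injected in one cycle.

    Parameters
    ----------
    cycle_index : int
        1-based position in the run; strictly increasing across a run.
    analyte_id : str
        Identifier of the injected species ("blank" / "solvent" for buffer cycles).
    role : Role
    mw : float or None
        Analyte molecular weight, Da. Required (> 0) for analyte roles.
    clogp : float or None
        Computed octanol-water partition coefficient; may be absent for
        blanks and solvent-calibration cycles.
    concentration : float
        Injected concentration, µM. Zero for blanks.
    dmso_pct : float
        DMSO content of the sample, % v/v.
    contact_time : float
        Association (injection) duration, s.
    dissociation_time : float
        Dissociation duration after injection end, s.
    """

    cycle_index: int
    analyte_id: str
    role: Role
    mw: Optional[float]
    clogp: Optional[float]
    concentration: float
    dmso_pct: float
    contact_time: float
    dissociation_time: float

    def __post_init__(self) -> None:
        if self.cycle_index < 1:
            raise ValidationError(f"cycle_index must be >= 1, got {self.cycle_index}")
        if self.role in ANALYTE_ROLES:
            if self.mw is None or not self.mw > 0:
                raise ValidationError(
                    f"cycle {self.cycle_index} ({self.analyte_id}): role "
                    f"{self.role.value!r} requires mw > 0, got {self.mw}"
                )
        if self.concentration < 0:
            raise ValidationError(
                f"cycle {self.cycle_index}: concentration must be >= 0, "
                f"got {self.concentration}"
            )
        if self.role is Role.BLANK and self.concentration != 0:
            raise ValidationError(
                f"cycle {self.cycle_index}: blank injections must have "
                f"concentration 0, got {self.concentration}"
            )
        if self.contact_time <= 0 or self.dissociation_time < 0:
            raise ValidationError(
                f"cycle {self.cycle_index}: contact_time must be > 0 and "
                "dissociation_time >= 0"
            )


@dataclass(frozen=True)
class SurfaceDefinition:
    """What is captured on one flow channel.

    ``reference_channel`` names the channel whose trace is subtracted from
    this one (empty chip for empty NDs and for the protein without ND; a
    same-lipid empty ND for protein-ND surfaces). A channel that is itself
    a reference must have ``reference_channel = None`` — chained referencing
    is not allowed.
    """

    channel_id: str
    captured_species: CapturedSpecies
    lipid: Lipid
    mw_target: Optional[float]
    capture_level: float
    reference_channel: Optional[str] = None

    def __post_init__(self) -> None:
        if self.captured_species is not CapturedSpecies.EMPTY_CHIP:
            if self.mw_target is None or not self.mw_target > 0:
                raise ValidationError(
                    f"channel {self.channel_id}: mw_target > 0 required for "
                    f"captured species {self.captured_species.value!r}"
                )
        lipid_free = self.captured_species in (
            CapturedSpecies.EMPTY_CHIP,
            CapturedSpecies.PROTEIN,
        )
        if lipid_free != (self.lipid is Lipid.NONE):
            raise ValidationError(
                f"channel {self.channel_id}: lipid must be 'none' iff the "
                f"captured species is empty_chip or protein "
                f"(got {self.captured_species.value!r} / {self.lipid.value!r})"
            )
        if self.capture_level < 0:
            raise ValidationError(
                f"channel {self.channel_id}: capture_level must be >= 0"
            )

    @property
    def has_lipid(self) -> bool:
        return self.lipid is not Lipid.NONE

    @property
    def has_protein(self) -> bool:
        return self.captured_species in (
            CapturedSpecies.PROTEIN,
            CapturedSpecies.PROTEIN_ND,
        )


@dataclass
class Sensorgram:
    """One injection cycle's trace on one flow channel.

    ``time`` is seconds on the cycle clock (strictly increasing, grids may
    differ between cycles); ``response`` is RU. The three phase markers
    delimit baseline / association / dissociation:
    ``t_inject_start < t_inject_end <= t_diss_end``, all inside the grid span.
    """

    cycle_index: int
    channel_id: str
    time: np.ndarray
    response: np.ndarray
    t_inject_start: float
    t_inject_end: float
    t_diss_end: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.response.shape:
            raise ValidationError(
                f"cycle {self.cycle_index} channel {self.channel_id}: time and "
                "response must be 1-D arrays of equal length"
            )
        if self.time.size < 2 or not np.all(np.diff(self.time) > 0):
            raise ValidationError(
                f"cycle {self.cycle_index} channel {self.channel_id}: time grid "
                "must be strictly increasing"
            )
        if not (self.t_inject_start < self.t_inject_end <= self.t_diss_end):
            raise ValidationError(
                f"cycle {self.cycle_index} channel {self.channel_id}: require "
                "t_inject_start < t_inject_end <= t_diss_end"
            )
        if self.t_inject_start < self.time[0] or self.t_diss_end > self.time[-1]:
            raise ValidationError(
                f"cycle {self.cycle_index} channel {self.channel_id}: phase "
                "markers outside the time grid span"
            )

    @property
    def contact_time(self) -> float:
        return self.t_inject_end - self.t_inject_start

    @property
    def dissociation_time(self) -> float:
        return self.t_diss_end - self.t_inject_end

    def window_mean(self, t_a: float, t_b: float) -> float:
        """Mean response over the closed time interval [t_a, t_b]."""
        mask = (self.time >= t_a) & (self.time <= t_b)
        if not mask.any():
            raise ValidationError(
                f"cycle {self.cycle_index} channel {self.channel_id}: no samples "
                f"in window [{t_a}, {t_b}] s"
            )
        return float(self.response[mask].mean())
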