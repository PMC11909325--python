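"""Synthetic SPR screen generator with known ground truth.

The simulator emulates a fragment screen against a membrane protein captured
in lipid nanodiscs (NDs), alongside empty-ND control surfaces, producing the
same sample-sheet / sensorgram / surface dialects the analysis consumes plus
a ground-truth table of every noiseless signal component.

Signal model per cycle per channel, in RU:

* **Specific 1:1 binding** (protein-bearing surfaces, analytes with a
  specific site): pseudo-first-order Langmuir association
  ``R(t) = R_eq (1 - exp(-(kon C + koff) t))`` with
  ``R_eq = Rmax C / (K_D + C)``, ``K_D = koff/kon``, and exponential
  dissociation ``R(t) = R_0 exp(-koff t)``. ``Rmax`` scales with the captured
  level and the analyte/particle mass ratio (one site per particle).
* **Membrane partitioning** (lipid-bearing surfaces): treated as
  instantaneous relative to the 20 s contact; a square pulse
  ``R_mem = kappa_lipid 10^(beta cLogP) C (capture/1000)`` — log-linear in
  hydrophobicity, linear in concentration (tens of fragments per ND is far
  from bilayer saturation, so no saturation term).
* **Capture leaching**: the captured level decays exponentially over the
  wall-clock duration of the screen (His-tag capture slowly washing off a
  Ni-chelate surface).
* **DMSO bulk offset** during injection, proportional to the sample-vs-running
  -buffer DMSO mismatch and reduced on crowded surfaces by an excluded-volume
  factor (the origin of the residual that solvent correction removes).
* **Gaussian noise** per time point.
* **Planted pathologies**: ``slow_dissociation`` scales koff down 100x,
  ``rising_association`` adds a linear ramp during contact on protein
  surfaces, ``reference_sticker`` adds a square pulse on reference channels
  only.

All randomness flows from single seeds; equal seeds give identical screens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    CapturedSpecies,
    InjectionRecord,
    Lipid,
    Role,
    Sensorgram,
    SurfaceDefinition,
)
from .exceptions import ConfigError, NdscreenError, ValidationError

__all__ = [
    "Pathology", "FragmentSpec", "SimConfig", "InjectionProtocol",
    "SimulatedScreen", "langmuir_response", "partition_response",
    "capture_decay", "generate_library", "simulate_screen", "default_surfaces",
    "DEFAULT_LEACH_RATE",
]

#: Default capture-leach rate: 30% loss over a 34 h screen.
DEFAULT_LEACH_RATE = -math.log(0.7) / (34 * 3600.0)

#: Running-buffer DMSO content, % v/v.
RUNNING_BUFFER_DMSO_PCT = 1.0


class Pathology(str, Enum):
    NONE = "none"
    SLOW_DISSOCIATION = "slow_dissociation"
    RISING_ASSOCIATION = "rising_association"
    REFERENCE_STICKER = "reference_sticker"


@dataclass(frozen=True)
class FragmentSpec:
    """Ground-truth description of one library fragment.

    ``true_kd`` (µM) is the specific-site dissociation constant, or ``None``
    for fragments with no specific protein site. ``true_kon`` is in
    1/(µM·s). Mw obeys the rule-of-three bound (<= 300 Da); cLogP may exceed
    3 for the lipophilic tail of a real library.
    """

    analyte_id: str
    mw: float
    clogp: float
    true_kd: Optional[float]
    true_kon: float
    pathology: Pathology = Pathology.NONE

    def __post_init__(self) -> None:
        if not 100.0 <= self.mw <= 300.0:
            raise ValidationError(
                f"{self.analyte_id}: fragment Mw must lie in [100, 300] Da"
            )
        if self.true_kd is not None and not self.true_kd > 0:
            raise ValidationError(f"{self.analyte_id}: true_kd must be > 0")
        if not self.true_kon > 0:
            raise ValidationError(f"{self.analyte_id}: true_kon must be > 0")


@dataclass
class SimConfig:
    """Simulator tunables; defaults are the study conditions.

    kappa_lipid : RU µM^-1 per 1000 RU capture, ordered POPC > DPPC > DPhPC
        > DMPC so the DMPC membrane binds 65% less than POPC (inside the
        observed 40-80% band).
    beta_clogp : slope of the log-linear hydrophobicity factor 10^(beta cLogP).
    leach_rate : 1/s; default = 30% capture loss over 34 h.
    noise_sigma : RU, per time point.
    dmso_bulk_per_pct : RU of bulk signal per % v/v DMSO mismatch.
    excluded_volume_per_ru : bulk-exclusion per RU of capture (dimensionless);
        the per-channel factor is ``min(0.5, value * capture_level)``. A dict
        ``ref_excluded_volume_factor`` may instead pin factors per channel.
    ramp_ru_per_s : slope of the rising-association pathology.
    sticker_ru : flat pulse the reference_sticker pathology adds on
        reference channels.
    cycle_duration_s : wall-clock spacing of cycles (sets how much leaching
        accrues per cycle).
    dt_s, baseline_s, tail_s : trace grid step, pre-injection baseline span,
        post-dissociation tail span.
    """

    kappa_lipid: dict[Lipid, float] = field(default_factory=lambda: {
        Lipid.POPC: 1.0e-3,
        Lipid.DPPC: 0.8e-3,
        Lipid.DPHPC: 0.7e-3,
        Lipid.DMPC: 0.35e-3,
    })
    beta_clogp: float = 0.5
    leach_rate: float = DEFAULT_LEACH_RATE
    noise_sigma: float = 0.1
    dmso_bulk_per_pct: float = 100.0
    excluded_volume_per_ru: float = 3.0e-5
    ref_excluded_volume_factor: Optional[dict[str, float]] = None
    ramp_ru_per_s: float = 0.3
    sticker_ru: float = 5.0
    cycle_duration_s: float = 360.0
    dt_s: float = 0.5
    baseline_s: float = 10.0
    tail_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.kappa_lipid.values()):
            raise ConfigError("kappa_lipid entries must be >= 0")
        if self.noise_sigma < 0 or self.leach_rate < 0:
            raise ConfigError("noise_sigma and leach_rate must be >= 0")

    def excluded_volume(self, surface: SurfaceDefinition) -> float:
        if self.ref_excluded_volume_factor is not None:
            return self.ref_excluded_volume_factor.get(surface.channel_id, 0.0)
        return min(0.5, self.excluded_volume_per_ru * surface.capture_level)


@dataclass
class InjectionProtocol:
    """Injection plan: what gets injected, at what cadence.

    The default mirrors a two-concentration fragment screen: each series
    opens with a blank and a control injection, runs the library with a
    blank every 5 fragments and a control every 10, and closes with a blank
    and a control. Five solvent-calibration cycles (0.7-1.8% v/v DMSO)
    precede everything.
    """

    concentrations: tuple[float, ...] = (250.0, 500.0)
    contact_time: float = 20.0
    dissociation_time: float = 40.0
    blank_every: int = 5
    control_every: int = 10
    control_id: str = "fluconazole"
    control_mw: float = 306.3
    control_clogp: float = 0.4
    control_concentration: float = 100.0
    control_kd: float = 15.0
    control_kon: float = 0.05
    solvent_points: tuple[float, ...] = (0.7, 0.975, 1.25, 1.525, 1.8)
    sample_dmso_range: tuple[float, float] = (0.9, 1.15)


@dataclass
class SimulatedScreen:
    """Everything one simulated screen produced."""

    sample_sheet: list[InjectionRecord]
    sensorgrams: list[Sensorgram]
    surfaces: list[SurfaceDefinition]
    truth: pd.DataFrame
    config: SimConfig
    protocol: InjectionProtocol


# ---------------------------------------------------------------------------
# elementary response models


def langmuir_response(
    t: Union[float, np.ndarray],
    C: float,
    kon: float,
    koff: float,
    rmax: float,
    phase: str = "association",
    r0: Optional[float] = None,
) -> Union[float, np.ndarray]:
    """1:1 Langmuir response at time ``t`` (s) into the given phase.

    Association: ``R(t) = R_eq (1 - exp(-(kon C + koff) t))`` with
    ``R_eq = rmax C / (K_D + C)`` and ``K_D = koff / kon``.
    Dissociation: ``R(t) = r0 exp(-koff t)`` (``r0`` required).
    Units: C in µM, kon in 1/(µM s), koff in 1/s, responses in RU.
    """
    if C < 0 or kon <= 0 or koff < 0 or rmax < 0:
        raise ValueError("langmuir_response requires C >= 0, kon > 0, "
                         "koff >= 0, rmax >= 0")
    t = np.asarray(t, dtype=float)
    if phase == "association":
        kd = koff / kon
        req = 0.0 if (C == 0 and kd == 0) else rmax * C / (kd + C)
        rate = kon * C + koff
        out = req * (1.0 - np.exp(-rate * t))
    elif phase == "dissociation":
        if r0 is None:
            raise ValueError("dissociation phase requires r0 (response at "
                             "injection end)")
        out = r0 * np.exp(-koff * t)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return float(out) if out.ndim == 0 else out


def partition_response(
    C: float,
    clogp: float,
    lipid: Lipid,
    capture_level: float,
    cfg: SimConfig,
) -> float:
    """Equilibrium membrane-partition signal, RU.

    ``R_mem = kappa_lipid * 10^(beta * cLogP) * C * (capture_level / 1000)``
    — zero for lipid-free surfaces, strictly increasing in C, cLogP and
    kappa.
    """
    if C < 0:
        raise ValueError("concentration must be >= 0")
    if lipid is Lipid.NONE:
        return 0.0
    if lipid not in cfg.kappa_lipid:
        raise ConfigError(f"no kappa_lipid entry for lipid {lipid.value!r}")
    kappa = cfg.kappa_lipid[lipid]
    return kappa * 10.0 ** (cfg.beta_clogp * clogp) * C * (capture_level / 1000.0)


def capture_decay(
    t: Union[float, np.ndarray], r0: float, leach_rate: float
) -> Union[float, np.ndarray]:
    """Captured level after ``t`` seconds of leaching: ``r0 exp(-leach_rate t)``."""
    if r0 < 0:
        raise ValueError("r0 must be >= 0")
    out = r0 * np.exp(-leach_rate * np.asarray(t, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# library generation


def generate_library(
    n: int = 140,
    seed: int = 0,
    clogp_mean: float = 1.3,
    clogp_sd: float = 1.0,
    frac_pathological: float = 0.05,
    frac_binders: float = 0.10,
    binder_occupancy_range: tuple[float, float] = (60.0, 95.0),
    binder_reference_concentration: float = 500.0,
) -> list[FragmentSpec]:
    """Draw a reproducible fragment library with planted ground truth.

    Mw is uniform on [100, 300] Da; cLogP is normal(clogp_mean, clogp_sd)
    truncated to [-2, 4]. ``round(frac_pathological * n)`` fragments receive
    pathologies (cycled through the three kinds); ``round(frac_binders * n)``
    of the remaining clean fragments get a specific protein site whose K_D is
    chosen so that the saturating 1:1 occupancy at
    ``binder_reference_concentration`` (µM) falls uniformly inside
    ``binder_occupancy_range`` (percent, one site per particle).

    Slow-dissociation pathologies carry an aspecific site with deliberately
    slow intrinsic kinetics (kon 0.01-0.02 1/(µM s), K_D 26-100 µM) so that
    the 100x koff reduction leaves a visible dissociation residual.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= frac_pathological <= 1:
        raise ValueError("frac_pathological must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mw = rng.uniform(100.0, 300.0, size=n)
    clogp = np.empty(n)
    todo = np.arange(n)
    while todo.size:  # truncated normal by resampling
        draw = rng.normal(clogp_mean, clogp_sd, size=todo.size)
        if clogp_sd == 0:
            draw = np.full(todo.size, np.clip(clogp_mean, -2.0, 4.0))
        ok = (draw >= -2.0) & (draw <= 4.0)
        clogp[todo[ok]] = draw[ok]
        todo = todo[~ok]

    order = rng.permutation(n)
    n_path = int(round(frac_pathological * n))
    path_idx = order[:n_path]
    kinds = [Pathology.SLOW_DISSOCIATION, Pathology.RISING_ASSOCIATION,
             Pathology.REFERENCE_STICKER]
    pathology = {int(i): kinds[k % 3] for k, i in enumerate(path_idx)}

    n_bind = int(round(frac_binders * n))
    clean = [int(i) for i in order[n_path:]]
    binder_idx = set(clean[:n_bind])

    lo, hi = binder_occupancy_range
    specs: list[FragmentSpec] = []
    width = len(str(n))
    for i in range(n):
        kd: Optional[float] = None
        kon = float(rng.uniform(0.02, 0.1))
        patho = pathology.get(i, Pathology.NONE)
        if i in binder_idx:
            occ = float(rng.uniform(lo, hi))
            kd = binder_reference_concentration * (100.0 - occ) / occ
        elif patho is Pathology.SLOW_DISSOCIATION:
            kd = float(rng.uniform(26.0, 100.0))
            kon = float(rng.uniform(0.01, 0.02))
        specs.append(
            FragmentSpec(
                analyte_id=f"F{i + 1:0{width}d}",
                mw=float(mw[i]),
                clogp=float(clogp[i]),
                true_kd=kd,
                true_kon=kon,
                pathology=patho,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# surfaces and screen assembly


def default_surfaces(
    nd_mw: float = 150_000.0,
    protein_nd_mw: float = 200_000.0,
) -> list[SurfaceDefinition]:
    """Seven-channel layout of the default simulated screen.

    Channel 1 is the empty-chip reference for the four empty-ND surfaces
    (POPC, DPPC, DPhPC, DMPC; captures in the 4000-6500 RU range); channel 6
    carries the protein reconstituted in a DMPC ND and is referenced against
    a dedicated same-lipid empty ND on channel 7 captured to the same level.
    """
    return [
        SurfaceDefinition("ch1", CapturedSpecies.EMPTY_CHIP, Lipid.NONE,
                          None, 0.0, None),
        SurfaceDefinition("ch2", CapturedSpecies.EMPTY_ND, Lipid.POPC,
                          nd_mw, 6500.0, "ch1"),
        SurfaceDefinition("ch3", CapturedSpecies.EMPTY_ND, Lipid.DPPC,
                          nd_mw, 6000.0, "ch1"),
        SurfaceDefinition("ch4", CapturedSpecies.EMPTY_ND, Lipid.DPHPC,
                          nd_mw, 5500.0, "ch1"),
        SurfaceDefinition("ch5", CapturedSpecies.EMPTY_ND, Lipid.DMPC,
                          nd_mw, 4500.0, "ch1"),
        SurfaceDefinition("ch6", CapturedSpecies.PROTEIN_ND, Lipid.DMPC,
                          protein_nd_mw, 5000.0, "ch7"),
        SurfaceDefinition("ch7", CapturedSpecies.EMPTY_ND, Lipid.DMPC,
                          nd_mw, 5000.0, None),
    ]


@dataclass(frozen=True)
class _Analyte:
    """Internal analyte record for non-fragment injections (controls)."""

    analyte_id: str
    mw: float
    clogp: float
    true_kd: Optional[float]
    true_kon: float
    pathology: Pathology = Pathology.NONE


@dataclass(frozen=True)
class _PlannedCycle:
    role: Role
    fragment: Optional[FragmentSpec]
    concentration: float
    dmso_pct: float


def _build_plan(
    library: Sequence[FragmentSpec],
    protocol: InjectionProtocol,
    rng: np.random.Generator,
) -> list[_PlannedCycle]:
    lo, hi = protocol.sample_dmso_range
    plan: list[_PlannedCycle] = []
    for pct in protocol.solvent_points:
        plan.append(_PlannedCycle(Role.SOLVENT_CORRECTION, None, 0.0, pct))
    blank = _PlannedCycle(Role.BLANK, None, 0.0, RUNNING_BUFFER_DMSO_PCT)
    control = _PlannedCycle(Role.CONTROL, None, protocol.control_concentration,
                            RUNNING_BUFFER_DMSO_PCT)
    for conc in protocol.concentrations:
        plan.append(blank)
        plan.append(control)
        count = 0
        for frag in library:
            plan.append(
                _PlannedCycle(Role.FRAGMENT, frag, conc,
                              float(rng.uniform(lo, hi)))
            )
            count += 1
            if count % protocol.blank_every == 0:
                plan.append(blank)
            if count % protocol.control_every == 0:
                plan.append(control)
        if count % protocol.blank_every != 0:
            plan.append(blank)
        if count % protocol.control_every != 0:
            plan.append(control)
    return plan


def _specific_trace(
    t_assoc: np.ndarray,
    t_diss: np.ndarray,
    C: float,
    frag: FragmentSpec,
    rmax: float,
    contact_time: float,
) -> tuple[np.ndarray, np.ndarray]:
    koff = frag.true_kon * frag.true_kd
    if frag.pathology is Pathology.SLOW_DISSOCIATION:
        koff /= 100.0
    assoc = langmuir_response(t_assoc, C, frag.true_kon, koff, rmax,
                              phase="association")
    r_end = float(langmuir_response(contact_time, C, frag.true_kon, koff,
                                    rmax, phase="association"))
    diss = langmuir_response(t_diss, C, frag.true_kon, koff, rmax,
                             phase="dissociation", r0=r_end)
    return np.asarray(assoc), np.asarray(diss)


def simulate_screen(
    library: Sequence[FragmentSpec],
    surfaces: Sequence[SurfaceDefinition],
    cfg: Optional[SimConfig] = None,
    protocol: Optional[InjectionProtocol] = None,
) -> SimulatedScreen:
    """Simulate a full screen and return sheet, traces and ground truth.

    The ground-truth table holds, per (fragment, analysed surface,
    concentration), the noiseless no-leach signal components at the
    default report-point convention (mean over the last quarter of the
    contact window, ending 1 s before injection end) and the resulting true
    percent occupancy after ideal referencing.
    """
    cfg = cfg or SimConfig()
    protocol = protocol or InjectionProtocol()
    if not library:
        raise ValidationError("library must not be empty")
    surf_list = list(surfaces)
    by_id = {sd.channel_id: sd for sd in surf_list}
    for sd in surf_list:
        if sd.reference_channel is not None and sd.reference_channel not in by_id:
            raise ValidationError(
                f"surface {sd.channel_id} references unknown channel "
                f"{sd.reference_channel!r}"
            )
        if sd.has_lipid and sd.lipid not in cfg.kappa_lipid:
            raise ConfigError(f"no kappa_lipid entry for {sd.lipid.value!r}")
    referenced = {sd.reference_channel for sd in surf_list
                  if sd.reference_channel is not None}

    rng = np.random.default_rng(cfg.seed)
    plan = _build_plan(library, protocol, rng)

    # shared grid geometry
    span = cfg.baseline_s + protocol.contact_time + protocol.dissociation_time + cfg.tail_s
    t = np.arange(0.0, span + 0.5 * cfg.dt_s, cfg.dt_s)
    t_is = cfg.baseline_s
    t_ie = t_is + protocol.contact_time
    t_de = t_ie + protocol.dissociation_time
    inj = (t >= t_is) & (t < t_ie)
    dis = t >= t_ie
    t_assoc = t[inj] - t_is
    t_diss = t[dis] - t_ie

    # the control is a tool compound, not a fragment (Ro3 bounds don't apply)
    control_frag = _Analyte(
        analyte_id=protocol.control_id,
        mw=protocol.control_mw,
        clogp=protocol.control_clogp,
        true_kd=protocol.control_kd,
        true_kon=protocol.control_kon,
        pathology=Pathology.NONE,
    )

    records: list[InjectionRecord] = []
    sensorgrams: list[Sensorgram] = []
    for i, cyc in enumerate(plan):
        cycle_index = i + 1
        t_wall = i * cfg.cycle_duration_s
        frag = cyc.fragment if cyc.role is Role.FRAGMENT else (
            control_frag if cyc.role is Role.CONTROL else None)
        analyte_id = (frag.analyte_id if frag is not None
                      else ("blank" if cyc.role is Role.BLANK else "solvent"))
        records.append(
            InjectionRecord(
                cycle_index=cycle_index,
                analyte_id=analyte_id,
                role=cyc.role,
                mw=None if frag is None else frag.mw,
                clogp=None if frag is None else frag.clogp,
                concentration=cyc.concentration,
                dmso_pct=cyc.dmso_pct,
                contact_time=protocol.contact_time,
                dissociation_time=protocol.dissociation_time,
            )
        )
        for sd in surf_list:
            resp = np.zeros_like(t)
            cap = (capture_decay(t_wall, sd.capture_level, cfg.leach_rate)
                   if sd.captured_species is not CapturedSpecies.EMPTY_CHIP
                   else 0.0)
            if frag is not None:
                if sd.has_protein and frag.true_kd is not None:
                    rmax = cap * frag.mw / sd.mw_target
                    assoc, diss = _specific_trace(
                        t_assoc, t_diss, cyc.concentration, frag, rmax,
                        protocol.contact_time)
                    resp[inj] += assoc
                    resp[dis] += diss
                if sd.has_lipid and cyc.concentration > 0:
                    resp[inj] += partition_response(
                        cyc.concentration, frag.clogp, sd.lipid, cap, cfg)
                if (frag.pathology is Pathology.RISING_ASSOCIATION
                        and sd.has_protein):
                    resp[inj] += cfg.ramp_ru_per_s * t_assoc
                if (frag.pathology is Pathology.REFERENCE_STICKER
                        and sd.channel_id in referenced):
                    resp[inj] += cfg.sticker_ru
            mismatch = cyc.dmso_pct - RUNNING_BUFFER_DMSO_PCT
            if mismatch != 0.0:
                resp[inj] += (cfg.dmso_bulk_per_pct * mismatch
                              * (1.0 - cfg.excluded_volume(sd)))
            if cfg.noise_sigma > 0:
                resp += rng.normal(0.0, cfg.noise_sigma, size=resp.size)
            sensorgrams.append(
                Sensorgram(cycle_index=cycle_index, channel_id=sd.channel_id,
                           time=t.copy(), response=resp,
                           t_inject_start=t_is, t_inject_end=t_ie,
                           t_diss_end=t_de)
            )

    truth = _ground_truth(library, surf_list, cfg, protocol,
                          t_assoc, protocol.contact_time)
    return SimulatedScreen(
        sample_sheet=records, sensorgrams=sensorgrams, surfaces=surf_list,
        truth=truth, config=cfg, protocol=protocol,
    )


def _ground_truth(
    library: Sequence[FragmentSpec],
    surfaces: Sequence[SurfaceDefinition],
    cfg: SimConfig,
    protocol: InjectionProtocol,
    t_assoc: np.ndarray,
    contact: float,
) -> pd.DataFrame:
    """Noiseless, no-leach components at the default report-point window."""
    by_id = {sd.channel_id: sd for sd in surfaces}
    win_lo = contact * 0.75
    win_hi = contact - 1.0
    wmask = (t_assoc >= win_lo) & (t_assoc <= win_hi)
    rows = []
    for frag in library:
        for sd in surfaces:
            if sd.reference_channel is None:
                continue
            ref = by_id[sd.reference_channel]
            for conc in protocol.concentrations:
                specific = 0.0
                if sd.has_protein and frag.true_kd is not None:
                    rmax = sd.capture_level * frag.mw / sd.mw_target
                    assoc, _ = _specific_trace(t_assoc, np.empty(0), conc,
                                               frag, rmax, contact)
                    specific = float(np.asarray(assoc)[wmask].mean())
                part = (partition_response(conc, frag.clogp, sd.lipid,
                                           sd.capture_level, cfg)
                        if sd.has_lipid else 0.0)
                ref_part = (partition_response(conc, frag.clogp, ref.lipid,
                                               ref.capture_level, cfg)
                            if ref.has_lipid else 0.0)
                ramp = 0.0
                if (frag.pathology is Pathology.RISING_ASSOCIATION
                        and sd.has_protein):
                    ramp = float(cfg.ramp_ru_per_s * t_assoc[wmask].mean())
                sticker_ref = (cfg.sticker_ru
                               if frag.pathology is Pathology.REFERENCE_STICKER
                               else 0.0)
                net = specific + part + ramp - ref_part - sticker_ref
                occ = (100.0 * (net / frag.mw)
                       / (sd.capture_level / sd.mw_target))
                rows.append({
                    "analyte_id": frag.analyte_id,
                    "channel_id": sd.channel_id,
                    "concentration_um": conc,
                    "specific_ru": specific,
                    "partition_ru": part,
                    "ref_partition_ru": ref_part,
                    "ramp_ru": ramp,
                    "sticker_ref_ru": sticker_ref,
                    "true_occupancy_pct": occ,
                    "pathology": frag.pathology.value,
                    "is_specific_binder": bool(
                        sd.has_protein and frag.true_kd is not None
                        and frag.pathology is Pathology.NONE),
                })
    return pd.DataFrame(rows)
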