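"""Analysis configuration: every tunable has a named key and a default.

The on-disk format is a flat ``key = value`` text file (``#`` comments and
blank lines allowed). Unknown keys are rejected so typos fail loudly; values
are cast to the type of the default.
"""

from __future__ import annotations

import os
from typing import Any, Mapping, Optional

from .exceptions import ConfigError

#: Defaults for every analysis tunable.
#:
#: report_window_frac / report_window_end_offset_s
#:     Report point = mean over the last ``frac`` of the contact time, ending
#:     ``end_offset`` s before injection end (steady-state read of a "squared"
#:     fragment sensorgram).
#: baseline_window_s
#:     Pre-injection baseline averaged over this many seconds before injection
#:     start; the report point is relative to it.
#: tier_binder_lo / tier_binder_hi
#:     Percent-occupancy boundaries of the binder tier. Both boundaries are
#:     inclusive for the binder tier: occupancy < 0 -> reference binder,
#:     [0, lo) -> no binder, [lo, hi] -> binder, > hi -> super-stoichiometric.
#: f_diss, f_slope, r_min, f_ref, diss_tail_s
#:     Kinetic-shape flag thresholds; see :mod:`ndscreen.triage`.
#: occupancy_mw_basis
#:     "particle" uses the full captured-particle Mw in the occupancy formula;
#:     "protein" is the alternative convention (protein-only Mw).
#: hit_concentration_um
#:     Screening concentration at which hits are called (primary screen).
#: control_kd_lo / control_kd_hi
#:     Acceptable K_D window (µM) for the control-compound QC fit.
#: rank_include_reference_binders
#:     Whether negative-occupancy fragments stay in rank comparisons.
#: solvent_min_points
#:     Minimum number of distinct solvent-calibration points.
DEFAULT_CONFIG: dict[str, Any] = {
    "report_window_frac": 0.25,
    "report_window_end_offset_s": 1.0,
    "baseline_window_s": 5.0,
    "tier_binder_lo": 50.0,
    "tier_binder_hi": 300.0,
    "f_diss": 0.2,
    "f_slope": 0.2,
    "r_min": 1.0,
    "f_ref": 0.5,
    "diss_tail_s": 5.0,
    "occupancy_mw_basis": "particle",
    "hit_concentration_um": 500.0,
    "control_kd_lo": 10.0,
    "control_kd_hi": 20.0,
    "rank_include_reference_binders": True,
    "solvent_min_points": 5,
}


def _cast(key: str, raw: str, like: Any) -> Any:
    try:
        if isinstance(like, bool):
            low = raw.strip().lower()
            if low in ("true", "1", "yes", "on"):
                return True
            if low in ("false", "0", "no", "off"):
                return False
            raise ValueError(raw)
        if isinstance(like, int):
            return int(raw)
        if isinstance(like, float):
            return float(raw)
        return raw.strip()
    except ValueError as exc:
        raise ConfigError(f"config key {key!r}: cannot parse value {raw!r}") from exc


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Raise :class:`ConfigError` on out-of-range or inconsistent values."""
    for key in DEFAULT_CONFIG:
        if key not in cfg:
            raise ConfigError(f"missing config key {key!r}")
    if not 0 < cfg["report_window_frac"] <= 1:
        raise ConfigError("report_window_frac must be in (0, 1]")
    if cfg["report_window_end_offset_s"] < 0:
        raise ConfigError("report_window_end_offset_s must be >= 0")
    if cfg["baseline_window_s"] <= 0:
        raise ConfigError("baseline_window_s must be > 0")
    if not cfg["tier_binder_lo"] < cfg["tier_binder_hi"]:
        raise ConfigError("tier boundaries require tier_binder_lo < tier_binder_hi")
    if cfg["tier_binder_lo"] < 0:
        raise ConfigError("tier_binder_lo must be >= 0 (negative occupancy is the "
                          "reference-binder tier)")
    for key in ("f_diss", "f_slope", "f_ref"):
        if cfg[key] < 0:
            raise ConfigError(f"{key} must be >= 0")
    if cfg["r_min"] < 0:
        raise ConfigError("r_min must be >= 0")
    if cfg["occupancy_mw_basis"] not in ("particle", "protein"):
        raise ConfigError("occupancy_mw_basis must be 'particle' or 'protein'")
    if not cfg["control_kd_lo"] <= cfg["control_kd_hi"]:
        raise ConfigError("control K_D window requires control_kd_lo <= control_kd_hi")
    if cfg["solvent_min_points"] < 3:
        raise ConfigError("solvent_min_points must be >= 3 (quadratic fit)")


def load_config(path: Optional[str] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> dict[str, Any]:
    """Return the full configuration: defaults, then file, then overrides.

    Parameters
    ----------
    path : str, optional
        ``key = value`` text file; unknown keys raise :class:`ConfigError`.
    overrides : mapping, optional
        Programmatic overrides applied last (values used as-is).
    """
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.split("#", 1)[0].strip()
                if not stripped:
                    continue
                if "=" not in stripped:
                    raise ConfigError(
                        f"{path}:{lineno}: expected 'key = value', got {line!r}"
                    )
                key, raw = (part.strip() for part in stripped.split("=", 1))
                if key not in DEFAULT_CONFIG:
                    raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
                cfg[key] = _cast(key, raw, DEFAULT_CONFIG[key])
    if overrides:
        for key, value in overrides.items():
            if key not in DEFAULT_CONFIG:
                raise ConfigError(f"unknown config key {key!r}")
            cfg[key] = value
    validate_config(cfg)
    return cfg


def save_config(cfg: Mapping[str, Any], path: str) -> None:
    """Write a configuration as a flat key = value file."""
    with open(path, "w") as fh:
        for key in DEFAULT_CONFIG:
            fh.write(f"{key} = {cfg[key]}\n")
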