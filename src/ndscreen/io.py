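"""Reading and writing the plain-text screen formats.

Three delimited text (CSV) dialects, all with header rows:

sample sheet
    ``cycle_index, analyte_id, role, mw, clogp, concentration_uM, dmso_pct,
    contact_time_s, dissociation_time_s`` — one row per injection cycle.
sensorgrams
    ``cycle, channel, time_s, response_RU`` — one row per time point, plus a
    phase-marker sidecar ``cycle, t_inject_start, t_inject_end, t_diss_end``
    (markers are per cycle; all channels of a cycle share them). The sidecar
    path defaults to ``<data path minus extension>.markers.csv``.
surfaces
    ``channel_id, captured_species, lipid, mw_target, capture_level,
    reference_channel``.

No attempt is made to parse proprietary instrument exports; converting an
instrument export into these dialects is the extension point
(:func:`convert_instrument_export` is a documented stub).

Values round-trip through text at better than 1e-9 via ``%.12g`` formatting.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

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
from .exceptions import FormatError, ValidationError

_FLOAT_FMT = "%.12g"

SAMPLE_SHEET_COLUMNS = [
    "cycle_index", "analyte_id", "role", "mw", "clogp",
    "concentration_uM", "dmso_pct", "contact_time_s", "dissociation_time_s",
]
SENSORGRAM_COLUMNS = ["cycle", "channel", "time_s", "response_RU"]
MARKER_COLUMNS = ["cycle", "t_inject_start", "t_inject_end", "t_diss_end"]
SURFACE_COLUMNS = [
    "channel_id", "captured_species", "lipid", "mw_target",
    "capture_level", "reference_channel",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what}: missing mandatory column {col!r}")


def _optional_float(raw, what: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"{what}: cannot parse number {raw!r}") from exc


def default_markers_path(data_path: str) -> str:
    stem, _ = os.path.splitext(data_path)
    return stem + ".markers.csv"


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path: str) -> list[InjectionRecord]:
    """Parse a sample sheet into :class:`InjectionRecord` rows in cycle order.

    Raises
    ------
    FormatError
        Missing mandatory column, or unparseable numeric fields (reported
        with their row numbers).
    ValidationError
        Duplicated cycle indices (listed in the message) or violated record
        invariants.
    """
    df = pd.read_csv(path, dtype=str, comment="#", skipinitialspace=True)
    _require_columns(df, SAMPLE_SHEET_COLUMNS, f"sample sheet {path}")

    records: list[InjectionRecord] = []
    bad_rows: list[str] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based + header row
        try:
            role = Role(str(row["role"]).strip())
            rec = InjectionRecord(
                cycle_index=int(str(row["cycle_index"]).strip()),
                analyte_id=str(row["analyte_id"]).strip(),
                role=role,
                mw=_optional_float(row["mw"], "mw"),
                clogp=_optional_float(row["clogp"], "clogp"),
                concentration=float(row["concentration_uM"]),
                dmso_pct=float(row["dmso_pct"]),
                contact_time=float(row["contact_time_s"]),
                dissociation_time=float(row["dissociation_time_s"]),
            )
        except (ValueError, FormatError) as exc:
            bad_rows.append(f"row {rownum}: {exc}")
            continue
        records.append(rec)
    if bad_rows:
        raise FormatError(
            f"sample sheet {path}: unparseable rows:\n  " + "\n  ".join(bad_rows)
        )

    cycles = [rec.cycle_index for rec in records]
    seen: set[int] = set()
    dupes = sorted({c for c in cycles if c in seen or seen.add(c)})
    if dupes:
        raise ValidationError(
            f"sample sheet {path}: duplicate cycle_index value(s): "
            + ", ".join(map(str, dupes))
        )
    records.sort(key=lambda rec: rec.cycle_index)
    return records


def write_sample_sheet(records: Iterable[InjectionRecord], path: str) -> None:
    rows = [
        {
            "cycle_index": rec.cycle_index,
            "analyte_id": rec.analyte_id,
            "role": rec.role.value,
            "mw": "" if rec.mw is None else _FLOAT_FMT % rec.mw,
            "clogp": "" if rec.clogp is None else _FLOAT_FMT % rec.clogp,
            "concentration_uM": _FLOAT_FMT % rec.concentration,
            "dmso_pct": _FLOAT_FMT % rec.dmso_pct,
            "contact_time_s": _FLOAT_FMT % rec.contact_time,
            "dissociation_time_s": _FLOAT_FMT % rec.dissociation_time,
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sensorgrams


def read_sensorgrams(path: str, markers_path: Optional[str] = None) -> list[Sensorgram]:
    """Read a sensorgram set: one :class:`Sensorgram` per (cycle, channel).

    Time grids need not be shared across cycles. Non-monotone time within a
    (cycle, channel) group raises :class:`FormatError` naming the group.
    """
    if markers_path is None:
        markers_path = default_markers_path(path)
    df = pd.read_csv(path)
    _require_columns(df, SENSORGRAM_COLUMNS, f"sensorgram file {path}")
    mk = pd.read_csv(markers_path)
    _require_columns(mk, MARKER_COLUMNS, f"marker file {markers_path}")
    markers = {
        int(row["cycle"]): (
            float(row["t_inject_start"]),
            float(row["t_inject_end"]),
            float(row["t_diss_end"]),
        )
        for _, row in mk.iterrows()
    }

    out: list[Sensorgram] = []
    for (cycle, channel), grp in df.groupby(["cycle", "channel"], sort=True):
        cycle = int(cycle)
        t = grp["time_s"].to_numpy(dtype=float)
        r = grp["response_RU"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise FormatError(
                f"sensorgram file {path}: time not strictly increasing for "
                f"cycle {cycle}, channel {channel}"
            )
        if cycle not in markers:
            raise FormatError(
                f"marker file {markers_path}: no phase markers for cycle {cycle}"
            )
        t_is, t_ie, t_de = markers[cycle]
        out.append(
            Sensorgram(
                cycle_index=cycle, channel_id=str(channel), time=t, response=r,
                t_inject_start=t_is, t_inject_end=t_ie, t_diss_end=t_de,
            )
        )
    out.sort(key=lambda sg: (sg.cycle_index, sg.channel_id))
    return out


def write_sensorgrams(sensorgrams: Iterable[Sensorgram], path: str,
                      markers_path: Optional[str] = None) -> None:
    if markers_path is None:
        markers_path = default_markers_path(path)
    sgs = sorted(sensorgrams, key=lambda sg: (sg.cycle_index, sg.channel_id))
    frames = []
    marker_rows = {}
    for sg in sgs:
        frames.append(
            pd.DataFrame(
                {
                    "cycle": sg.cycle_index,
                    "channel": sg.channel_id,
                    "time_s": sg.time,
                    "response_RU": sg.response,
                }
            )
        )
        marker_rows[sg.cycle_index] = {
            "cycle": sg.cycle_index,
            "t_inject_start": sg.t_inject_start,
            "t_inject_end": sg.t_inject_end,
            "t_diss_end": sg.t_diss_end,
        }
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(list(marker_rows.values()), columns=MARKER_COLUMNS).to_csv(
        markers_path, index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# surfaces


def read_surfaces(path: str) -> list[SurfaceDefinition]:
    """Read surface definitions and validate the referencing layout."""
    df = pd.read_csv(path, dtype=str, comment="#", skipinitialspace=True)
    _require_columns(df, SURFACE_COLUMNS, f"surface file {path}")
    surfaces: list[SurfaceDefinition] = []
    for _, row in df.iterrows():
        ref = row["reference_channel"]
        ref = None if (pd.isna(ref) or str(ref).strip().lower() in ("", "none")) else str(ref).strip()
        surfaces.append(
            SurfaceDefinition(
                channel_id=str(row["channel_id"]).strip(),
                captured_species=CapturedSpecies(str(row["captured_species"]).strip()),
                lipid=Lipid(str(row["lipid"]).strip()),
                mw_target=_optional_float(row["mw_target"], "mw_target"),
                capture_level=float(row["capture_level"]),
                reference_channel=ref,
            )
        )
    validate_surface_layout(surfaces)
    return surfaces


def validate_surface_layout(surfaces: Sequence[SurfaceDefinition]) -> None:
    by_id = {sd.channel_id: sd for sd in surfaces}
    if len(by_id) != len(surfaces):
        raise ValidationError("duplicate channel_id in surface definitions")
    for sd in surfaces:
        if sd.reference_channel is None:
            continue
        ref = by_id.get(sd.reference_channel)
        if ref is None:
            raise ValidationError(
                f"channel {sd.channel_id}: unknown reference channel "
                f"{sd.reference_channel!r}"
            )
        if ref.reference_channel is not None:
            raise ValidationError(
                f"channel {sd.channel_id}: reference channel {ref.channel_id} "
                "must itself have reference_channel = none"
            )


def write_surfaces(surfaces: Iterable[SurfaceDefinition], path: str) -> None:
    rows = [
        {
            "channel_id": sd.channel_id,
            "captured_species": sd.captured_species.value,
            "lipid": sd.lipid.value,
            "mw_target": "" if sd.mw_target is None else _FLOAT_FMT % sd.mw_target,
            "capture_level": _FLOAT_FMT % sd.capture_level,
            "reference_channel": sd.reference_channel or "none",
        }
        for sd in surfaces
    ]
    pd.DataFrame(rows, columns=SURFACE_COLUMNS).to_csv(path, index=False)


def convert_instrument_export(path: str) -> list[Sensorgram]:
    """Stub extension point for proprietary instrument exports.

    There is no open interchange standard for SPR traces. To analyze real
    instrument data, export it to the columnar dialect documented in this
    module (one row per cycle/channel/time point plus a marker sidecar) and
    use :func:`read_sensorgrams`; or subclass this function for a specific
    vendor export.
    """
    raise NotImplementedError(
        "proprietary instrument exports are not parsed; convert to the "
        "documented columnar dialect (see ndscreen.io module docstring)"
    )
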