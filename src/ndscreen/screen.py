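"""The screen-analysis model: raw screen in, triaged hits out.

:class:`ScreenAnalysis` is the package's central modelling object, in the
model/results idiom: it is constructed from the three screen inputs (sample
sheet, sensorgram set, surface definitions) plus a configuration, and
``fit()`` runs the full pipeline —

    reference subtraction -> report points -> blank correction ->
    solvent correction -> control-based decay normalization ->
    percent occupancy -> tier classification + kinetic flags -> hit calls

— returning a :class:`ScreenResults` that carries the occupancy and triage
tables, a per-cycle corrections log, per-surface accounting, and the
cross-surface comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, load_config, validate_config
from .datatypes import (
    CapturedSpecies,
    InjectionRecord,
    Role,
    Sensorgram,
    SurfaceDefinition,
)
from .exceptions import ConfigError, DataQualityError, ValidationError
from .io import read_sample_sheet, read_sensorgrams, read_surfaces
from .occupancy import decay_normalize, occupancy
from .preprocess import (
    ReportPoint,
    blank_correct,
    default_report_window,
    extract_report_point,
    fit_solvent_correction,
    reference_subtract,
)
from .stats import mann_whitney, rank_compare, spearman, venn
from .triage import (
    Tier,
    TriageResult,
    TriageThresholds,
    call_hits,
    classify,
    extract_ref_level,
    flag_kinetics,
)

__all__ = ["ScreenAnalysis", "ScreenResults", "ScreenComparison"]

_SAMPLE_ROLES = (Role.FRAGMENT, Role.TOOL_COMPOUND, Role.CONTROL)


@dataclass
class ScreenComparison:
    """Cross-surface comparison statistics.

    pairwise : per surface pair, Spearman r_s of fragment occupancies and a
        two-sided Mann-Whitney test of their distributions.
    clogp_rs : per surface, Spearman r_s of occupancy vs fragment cLogP.
    hit_venn : disjoint-region decomposition of the per-surface hit sets
        (None when more than four surfaces were compared).
    ranks : paired-rank data of every surface against the reference surface.
    """

    pairwise: pd.DataFrame
    clogp_rs: pd.DataFrame
    hit_venn: Optional[Any]
    ranks: Any
    reference: str

    def summary(self) -> str:
        lines = ["Cross-surface comparison", "========================", ""]
        lines.append(f"reference surface: {self.reference}")
        lines.append("")
        lines.append("pairwise (fragment occupancy):")
        lines.append(self.pairwise.to_string(index=False,
                                             float_format=lambda v: f"{v:.4g}"))
        lines.append("")
        lines.append("occupancy vs cLogP:")
        lines.append(self.clogp_rs.to_string(index=False,
                                             float_format=lambda v: f"{v:.4g}"))
        if self.hit_venn is not None:
            lines.append("")
            lines.append("hit overlap (membership pattern over "
                         f"{list(self.hit_venn.names)}):")
            for pattern, ids in sorted(self.hit_venn.regions.items(),
                                       reverse=True):
                tag = "".join("1" if p else "0" for p in pattern)
                lines.append(f"  {tag}: {len(ids):3d}  "
                             f"{sorted(ids)[:6]}{'...' if len(ids) > 6 else ''}")
        return "\n".join(lines)


class ScreenAnalysis:
    """Model object for one SPR fragment screen.

    Parameters
    ----------
    sample_sheet : list of InjectionRecord
        The injection cycles, in cycle order.
    sensorgrams : list of Sensorgram
        One trace per (cycle, channel) covering every channel in
        ``surfaces``.
    surfaces : list of SurfaceDefinition
        Channel layout; surfaces with a ``reference_channel`` are analysed,
        the rest serve as references.
    config : mapping, optional
        Analysis tunables; missing keys take their defaults
        (:data:`ndscreen.config.DEFAULT_CONFIG`).
    """

    def __init__(
        self,
        sample_sheet: Sequence[InjectionRecord],
        sensorgrams: Sequence[Sensorgram],
        surfaces: Sequence[SurfaceDefinition],
        config: Optional[Mapping[str, Any]] = None,
    ) -> None:
        self.records = sorted(sample_sheet, key=lambda r: r.cycle_index)
        if len({r.cycle_index for r in self.records}) != len(self.records):
            raise ValidationError("duplicate cycle_index in sample sheet")
        self.surfaces = {sd.channel_id: sd for sd in surfaces}
        self.traces: dict[tuple[int, str], Sensorgram] = {
            (sg.cycle_index, sg.channel_id): sg for sg in sensorgrams
        }
        cfg = dict(DEFAULT_CONFIG)
        if config:
            for key, value in config.items():
                if key not in cfg:
                    raise ConfigError(f"unknown config key {key!r}")
                cfg[key] = value
        validate_config(cfg)
        self.config = cfg

    @classmethod
    def from_files(
        cls,
        sample_sheet: str,
        sensorgrams: str,
        surfaces: str,
        config: Optional[str] = None,
        markers: Optional[str] = None,
    ) -> "ScreenAnalysis":
        return cls(
            read_sample_sheet(sample_sheet),
            read_sensorgrams(sensorgrams, markers),
            read_surfaces(surfaces),
            load_config(config),
        )

    # ------------------------------------------------------------------
    def _trace(self, cycle: int, channel: str) -> Sensorgram:
        try:
            return self.traces[(cycle, channel)]
        except KeyError:
            raise ValidationError(
                f"no sensorgram for cycle {cycle}, channel {channel!r}"
            ) from None

    def _analyse_surface(self, sd: SurfaceDefinition) -> pd.DataFrame:
        """Run corrections for one active surface; one row per cycle."""
        cfg = self.config
        ref_sd = self.surfaces[sd.reference_channel]
        rows: list[dict[str, Any]] = []
        for rec in self.records:
            sg_a = self._trace(rec.cycle_index, sd.channel_id)
            sg_r = self._trace(rec.cycle_index, ref_sd.channel_id)
            corrected = reference_subtract(sg_a, sg_r)
            window = default_report_window(
                rec.contact_time,
                cfg["report_window_frac"],
                cfg["report_window_end_offset_s"],
            )
            rp = extract_report_point(corrected, window,
                                      cfg["baseline_window_s"])
            raw = extract_report_point(sg_a, window, cfg["baseline_window_s"])
            ref_bulk = extract_ref_level(sg_r, window, cfg["baseline_window_s"])
            rows.append({
                "cycle_index": rec.cycle_index,
                "analyte_id": rec.analyte_id,
                "role": rec.role,
                "concentration_um": rec.concentration,
                "mw": rec.mw,
                "clogp": rec.clogp,
                "window": window,
                "raw_ru": raw.value,
                "ref_bulk_ru": ref_bulk,
                "refsub_ru": rp.value,
                "corrected_sg": corrected,
                "ref_sg": sg_r,
            })
        df = pd.DataFrame(rows)

        # solvent calibration from the DMSO-titration cycles
        calib = df[df["role"] == Role.SOLVENT_CORRECTION]
        curve = None
        if len(calib) >= cfg["solvent_min_points"]:
            curve = fit_solvent_correction(
                list(zip(calib["ref_bulk_ru"], calib["refsub_ru"])),
                min_points=cfg["solvent_min_points"],
            )
        self._solvent_curves[sd.channel_id] = curve

        # blank correction over all analyte cycles
        is_sample = df["role"].isin(_SAMPLE_ROLES)
        blanks = [
            ReportPoint(int(r.cycle_index), sd.channel_id, r.refsub_ru,
                        r.window)
            for r in df[df["role"] == Role.BLANK].itertuples()
        ]
        sample_rps = [
            ReportPoint(int(r.cycle_index), sd.channel_id, r.refsub_ru,
                        r.window)
            for r in df[is_sample].itertuples()
        ]
        blanked = blank_correct(sample_rps, blanks)
        df["blank_ru"] = np.nan
        df.loc[is_sample, "blank_ru"] = [rp.value for rp in blanked]

        # solvent correction at the sample's reference bulk
        df["solvent_ru"] = df["blank_ru"]
        if curve is not None:
            df.loc[is_sample, "solvent_ru"] = [
                v - curve(x) for v, x in zip(df.loc[is_sample, "blank_ru"],
                                             df.loc[is_sample, "ref_bulk_ru"])
            ]

        # control-based decay normalization on protein-bearing surfaces
        df["scale_factor"] = 1.0
        df["final_ru"] = df["solvent_ru"]
        if sd.has_protein:
            controls = [
                ReportPoint(int(r.cycle_index), sd.channel_id, r.solvent_ru,
                            r.window)
                for r in df[df["role"] == Role.CONTROL].itertuples()
            ]
            targets_mask = df["role"].isin((Role.FRAGMENT, Role.TOOL_COMPOUND))
            targets = [
                ReportPoint(int(r.cycle_index), sd.channel_id, r.solvent_ru,
                            r.window)
                for r in df[targets_mask].itertuples()
            ]
            normalized, scales = decay_normalize(targets, controls)
            df.loc[targets_mask, "final_ru"] = [rp.value for rp in normalized]
            df.loc[targets_mask, "scale_factor"] = scales
        return df

    def fit(self) -> "ScreenResults":
        """Run the full correction/occupancy/triage pipeline."""
        cfg = self.config
        active = [sd for sd in self.surfaces.values()
                  if sd.reference_channel is not None]
        if not active:
            raise ValidationError("no surface has a reference channel; "
                                  "nothing to analyse")
        self._solvent_curves: dict[str, Any] = {}
        thresholds = TriageThresholds(
            f_diss=cfg["f_diss"], f_slope=cfg["f_slope"],
            r_min=cfg["r_min"], f_ref=cfg["f_ref"],
            diss_tail_s=cfg["diss_tail_s"],
        )

        occ_rows: list[dict[str, Any]] = []
        triage_rows: list[dict[str, Any]] = []
        log_rows: list[dict[str, Any]] = []
        for sd in active:
            ref_sd = self.surfaces[sd.reference_channel]
            df = self._analyse_surface(sd)
            for r in df.itertuples():
                log_rows.append({
                    "cycle_index": r.cycle_index,
                    "surface": sd.channel_id,
                    "analyte_id": r.analyte_id,
                    "role": r.role.value,
                    "raw_ru": r.raw_ru,
                    "after_reference_subtraction_ru": r.refsub_ru,
                    "after_blank_ru": r.blank_ru,
                    "after_solvent_ru": r.solvent_ru,
                    "scale_factor": r.scale_factor,
                    "final_ru": r.final_ru,
                })
                if r.role not in (Role.FRAGMENT, Role.TOOL_COMPOUND):
                    continue
                occ = occupancy(r.final_ru, r.mw, sd.capture_level,
                                sd.mw_target)
                occ_rows.append({
                    "analyte_id": r.analyte_id,
                    "surface": sd.channel_id,
                    "concentration_um": r.concentration_um,
                    "corrected_ru": r.final_ru,
                    "scale_factor": r.scale_factor,
                    "occupancy_pct": occ,
                    "clogp": r.clogp,
                    "mw": r.mw,
                })
                if r.role is not Role.FRAGMENT:
                    continue
                tier = classify(occ, cfg["tier_binder_lo"],
                                cfg["tier_binder_hi"])
                if ref_sd.mw_target is not None and ref_sd.capture_level > 0:
                    ref100 = r.mw * ref_sd.capture_level / ref_sd.mw_target
                else:  # empty-chip reference: scale by the active surface
                    ref100 = r.mw * sd.capture_level / sd.mw_target
                rp_obj = ReportPoint(int(r.cycle_index), sd.channel_id,
                                     r.solvent_ru, r.window)
                flags = flag_kinetics(
                    r.corrected_sg, rp_obj, r.ref_sg,
                    thresholds=thresholds, ref_occ100_ru=ref100,
                    active_raw_ru=r.raw_ru,
                    baseline_window_s=cfg["baseline_window_s"],
                )
                triage_rows.append({
                    "analyte_id": r.analyte_id,
                    "surface": sd.channel_id,
                    "concentration_um": r.concentration_um,
                    "occupancy_pct": occ,
                    "tier": tier.value,
                    "flags": ",".join(sorted(f.value for f in flags)),
                    "hit": int(tier is Tier.BINDER and not flags),
                })

        return ScreenResults(
            model=self,
            occupancy=pd.DataFrame(occ_rows),
            triage=pd.DataFrame(triage_rows),
            corrections_log=pd.DataFrame(log_rows),
            solvent_curves=dict(self._solvent_curves),
        )


@dataclass
class ScreenResults:
    """Fitted screen: occupancy and triage tables plus diagnostics.

    occupancy
        One row per (analyte, surface, concentration) with the corrected
        response, decay scale factor and percent occupancy.
    triage
        One row per (fragment, surface, concentration) with tier, flags and
        the per-row hit decision.
    corrections_log
        One row per (cycle, surface) tracking the response through every
        correction.
    """

    model: ScreenAnalysis
    occupancy: pd.DataFrame
    triage: pd.DataFrame
    corrections_log: pd.DataFrame
    solvent_curves: dict[str, Any] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def _hit_conc(self, concentration: Optional[float]) -> float:
        if concentration is not None:
            return concentration
        return float(self.model.config["hit_concentration_um"])

    def triage_at(self, concentration: Optional[float] = None) -> pd.DataFrame:
        conc = self._hit_conc(concentration)
        out = self.triage[self.triage["concentration_um"] == conc]
        if out.empty:
            raise ValidationError(
                f"no triage rows at concentration {conc} uM"
            )
        return out

    def hit_sets(self, concentration: Optional[float] = None
                 ) -> dict[str, set[str]]:
        """Per-surface hit sets at the hit-calling concentration."""
        df = self.triage_at(concentration)
        return {
            surface: set(grp.loc[grp["hit"] == 1, "analyte_id"])
            for surface, grp in df.groupby("surface")
        }

    def accounting(self, concentration: Optional[float] = None) -> pd.DataFrame:
        """Tier/hit accounting table, one column per surface."""
        df = self.triage_at(concentration)
        columns = {}
        for surface, grp in df.groupby("surface"):
            results = [
                TriageResult(
                    analyte_id=row.analyte_id,
                    channel_id=surface,
                    occupancy_pct=row.occupancy_pct,
                    tier=Tier(row.tier),
                    flags=frozenset(row.flags.split(",")) if row.flags
                    else frozenset(),
                )
                for row in grp.itertuples()
            ]
            _, table = call_hits(results)
            col = table["count"].astype(object)
            pct = table.loc["rejected_binder", "pct_of_binders"]
            col.loc["rejected_binder"] = f"{col.loc['rejected_binder']} ({pct})"
            columns[surface] = col
        return pd.DataFrame(columns)

    def occupancy_matrix(self, concentration: Optional[float] = None,
                         fragments_only: bool = True) -> pd.DataFrame:
        """Fragments x surfaces occupancy pivot at one concentration."""
        conc = self._hit_conc(concentration)
        df = self.occupancy[self.occupancy["concentration_um"] == conc]
        if fragments_only:
            frag_ids = set(self.triage["analyte_id"])
            df = df[df["analyte_id"].isin(frag_ids)]
        return df.pivot(index="analyte_id", columns="surface",
                        values="occupancy_pct")

    # ------------------------------------------------------------------
    def compare(
        self,
        reference: Optional[str] = None,
        concentration: Optional[float] = None,
        surfaces: Optional[Sequence[str]] = None,
    ) -> ScreenComparison:
        """Cross-surface rank, distribution and hit-overlap comparison."""
        cfg = self.model.config
        mat = self.occupancy_matrix(concentration)
        if surfaces is not None:
            mat = mat[list(surfaces)]
        include_ref_binders = cfg["rank_include_reference_binders"]
        if reference is None:
            reference = str(mat.columns[0])

        pair_rows = []
        cols = list(mat.columns)
        for i, sa in enumerate(cols):
            for sb in cols[i + 1:]:
                sub = mat[[sa, sb]].dropna()
                if not include_ref_binders:
                    sub = sub[(sub[sa] >= 0) & (sub[sb] >= 0)]
                mw = mann_whitney(sub[sa].to_numpy(), sub[sb].to_numpy())
                pair_rows.append({
                    "surface_a": sa,
                    "surface_b": sb,
                    "spearman_rs": spearman(sub[sa], sub[sb]),
                    "mw_u": mw.u,
                    "mw_p": mw.p_two_sided,
                    "n": len(sub),
                })
        clogp = (
            self.occupancy.drop_duplicates("analyte_id")
            .set_index("analyte_id")["clogp"]
        )
        clogp_rows = []
        for s in cols:
            sub = mat[s].dropna()
            if not include_ref_binders:
                sub = sub[sub >= 0]
            cl = clogp.reindex(sub.index)
            ok = cl.notna()
            clogp_rows.append({
                "surface": s,
                "spearman_rs": spearman(sub[ok], cl[ok]),
                "n": int(ok.sum()),
            })

        hit_sets = self.hit_sets(concentration)
        hit_sets = {s: hit_sets.get(s, set()) for s in cols}
        hit_venn = venn(hit_sets) if len(cols) <= 4 else None

        occ_maps = {
            s: mat[s].dropna().to_dict() for s in cols
        }
        ranks = rank_compare(occ_maps, reference)

        return ScreenComparison(
            pairwise=pd.DataFrame(pair_rows),
            clogp_rs=pd.DataFrame(clogp_rows),
            hit_venn=hit_venn,
            ranks=ranks,
            reference=reference,
        )

    # ------------------------------------------------------------------
    def summary(self) -> str:
        conc = self._hit_conc(None)
        lines = [
            "SPR fragment-screen analysis",
            "============================",
            f"cycles analysed:   {self.corrections_log['cycle_index'].nunique()}",
            f"surfaces analysed: {sorted(self.occupancy['surface'].unique())}",
            f"hit calling at:    {conc:g} uM",
            "",
            "Tier accounting:",
            self.accounting().to_string(),
            "",
            "Hits per surface:",
        ]
        for surface, hits in sorted(self.hit_sets().items()):
            lines.append(f"  {surface}: {len(hits)}")
        return "\n".join(lines)

    def to_csv(self, out_dir: str) -> list[str]:
        """Write occupancy, triage, accounting and corrections-log tables."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        written = []
        for name, df, index in (
            ("occupancy.csv", self.occupancy, False),
            ("triage.csv", self.triage, False),
            ("accounting.csv", self.accounting(), True),
            ("corrections_log.csv", self.corrections_log, False),
        ):
            path = os.path.join(out_dir, name)
            df.to_csv(path, index=index, float_format="%.9g")
            written.append(path)
        return written
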