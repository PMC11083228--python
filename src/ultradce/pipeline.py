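"""End-to-end orchestration: prep -> fits -> summaries -> statistics.

`run_patient` takes one dynamic series with its masks through baseline
estimation, concentration conversion, AIF extraction, kinetic and
empirical-model fitting, and ROI summarization. `run_cohort` runs the
four statistical analyses with the Benjamini–Hochberg family correction
on an assembled cohort table. Failures are soft at the voxel and ROI
level (validity masks, dropped summaries) and hard for missing inputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emm import fit_emm_volume
from .errors import UltraDceError, AccountingError
from .io import DynamicSeries, ParameterMap, RoiMask
from .kinetics import DEFAULT_START, fit_2cu_volume
from .prep import compute_baseline, extract_aif, to_concentration
from .ranges import ANALYSIS_PARAMETERS
from .stats import DEFAULT_BH_Q, StatsResult, run_all_stats
from .summarize import CohortRecord, assemble_cohort, summarize_roi

__all__ = ["RunConfig", "PatientResult", "run_patient", "run_cohort",
           "apply_exclusions"]


@dataclass
class RunConfig:
    """Tunable pipeline constants; defaults are the standard protocol.

    R
        Concentration scale 1/(r1*T10); 1.0 when no T1 map exists.
    window_s
        Early-enhancement analysis window from bolus arrival, seconds.
    weight_policy
        Uptake-phase weighting for the empirical models.
    """

    R: float = 1.0
    window_s: float = 120.0
    weight_policy: str = "max120_peak"
    start_2cu: tuple[float, float, float] = DEFAULT_START
    fit_t0: bool = False
    emm_models: str = "both"
    bh_q: float = DEFAULT_BH_Q
    equal_var_ttests: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.start_2cu, list):
            cfg.start_2cu = tuple(cfg.start_2cu)
        return cfg

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PatientResult:
    maps: dict[str, ParameterMap]
    records: list[CohortRecord]
    arrival_frame: int
    manifest: dict = field(default_factory=dict)


def run_patient(
    series: DynamicSeries,
    artery: RoiMask,
    rois: list[tuple[RoiMask, dict]],
    config: RunConfig | None = None,
    patient_id: str = "P000",
    fit_mask: np.ndarray | None = None,
) -> PatientResult:
    """Full single-patient analysis.

    ``rois`` pairs each tissue ROI mask with its metadata dict
    (roi_id, roi_type, zone, pirads, gg). ``fit_mask`` optionally
    restricts voxelwise fitting (default: the union of the tissue
    ROIs, which is all the statistics need).
    """
    config = config or RunConfig()
    if artery is None:
        raise UltraDceError("artery mask is required for AIF extraction")

    # Prep: arrival from the raw artery signal, then baseline and
    # concentration on the whole volume.
    artery_signal = series.data[artery.data].mean(axis=0)
    from .prep import detect_arrival

    arrival = detect_arrival(artery_signal)
    s0 = compute_baseline(series, arrival)
    conc = to_concentration(series, s0, R=config.R, arrival_frame=arrival)
    aif = extract_aif(conc, artery)

    if fit_mask is None:
        fit_mask = np.zeros(series.spatial_shape, dtype=bool)
        for roi, _ in rois:
            fit_mask |= roi.data

    maps = fit_2cu_volume(conc, aif, window_s=config.window_s,
                          start=config.start_2cu, fit_t0=config.fit_t0,
                          voxel_mask=fit_mask)
    maps.update(fit_emm_volume(conc, arrival, window_s=config.window_s,
                               policy=config.weight_policy,
                               models=config.emm_models,
                               voxel_mask=fit_mask))

    records = []
    for roi, meta in rois:
        rec = CohortRecord(
            patient_id=patient_id,
            roi_id=meta["roi_id"],
            roi_type=meta["roi_type"],
            zone=meta["zone"],
            pirads=int(meta["pirads"]),
            gg=str(meta["gg"]),
        )
        for name in ANALYSIS_PARAMETERS:
            if name in maps:
                rec.summaries[name] = summarize_roi(maps[name], roi)
        records.append(rec)

    manifest = {
        "patient_id": patient_id,
        "arrival_frame": int(arrival),
        "aif_voxels": aif.source_voxel_count,
        "config": asdict(config),
    }
    return PatientResult(maps=maps, records=records, arrival_frame=arrival,
                         manifest=manifest)


def run_cohort(
    table_or_records: pd.DataFrame | list[CohortRecord],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> StatsResult:
    """Cohort statistics on an assembled table (or list of records).

    Emits the zone-comparison, two-way ANOVA and grade-group tables
    (plus Tukey post-hoc tables and the BH family) as CSV when
    ``out_dir`` is given. Analyses that lack data are skipped with NaN
    p-values rather than failing the run.
    """
    config = config or RunConfig()
    if isinstance(table_or_records, list):
        table, drops = assemble_cohort(table_or_records)
    else:
        table, drops = table_or_records, []
    if table["patient_id"].nunique() < 2:
        raise UltraDceError("cohort statistics need at least 2 patients")

    present = tuple(p for p in ANALYSIS_PARAMETERS
                    if (table["parameter"] == p).any())
    result = run_all_stats(table, parameters=present, bh_q=config.bh_q,
                           equal_var=config.equal_var_ttests)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.zone_table.to_csv(out / "zone_comparison.csv", index=False)
        result.twoway_table.to_csv(out / "twoway_anova.csv", index=False)
        result.gg_table.to_csv(out / "grade_group.csv", index=False)
        result.bh_family.to_csv(out / "bh_family.csv", index=False)
        for key, df in result.tukey.items():
            df.to_csv(out / f"tukey_{key.replace(':', '_')}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump({"config": asdict(config), "dropped": drops,
                       "n_rows": int(len(table))}, fh, indent=2)
    return result


def apply_exclusions(screened: int, exclusion_counts: list[int]) -> int:
    """Cohort accounting: screened minus the exclusion counts.

    Raises AccountingError if any count is negative or the exclusions
    exceed the screened total.
    """
    if screened < 0 or any(c < 0 for c in exclusion_counts):
        raise AccountingError("counts must be nonnegative")
    remaining = screened - sum(exclusion_counts)
    if remaining < 0:
        raise AccountingError(
            f"exclusions ({sum(exclusion_counts)}) exceed screened ({screened})"
        )
    return remaining
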