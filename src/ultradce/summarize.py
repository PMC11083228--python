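"""ROI summaries and cohort table assembly.

Values are masked before averaging: only voxels inside the ROI *and*
flagged valid in the parameter map (in-range, converged fit) enter the
mean and standard deviation. An ROI can therefore end up empty for one
parameter while remaining usable for the others; empty summaries are
dropped from the cohort table and logged, which is how a subject can be
absent from the analyses of one parameter only.

The ROI-level mean is the unit of analysis downstream; the standard
deviation uses the n-1 (sample) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridMismatchError, UltraDceError
from .io import ParameterMap, RoiMask

__all__ = ["RoiSummary", "CohortRecord", "summarize_roi", "assemble_cohort"]

VALID_ROI_TYPES = ("lesion", "normal")
VALID_ZONES = ("PZ", "TZ")  # TZ includes the central zone
VALID_PIRADS = (1, 3, 4, 5)  # normal-appearing tissue is assigned PI-RADS 1
VALID_GG = ("neg", "1", "2", "3", "4")


@dataclass(frozen=True)
class RoiSummary:
    """Mean/SD of one parameter over the valid voxels of one ROI."""

    parameter: str
    mean: float  # NaN when empty
    sd: float  # NaN when n_valid < 2
    n_valid: int
    n_total: int

    @property
    def empty(self) -> bool:
        return self.n_valid == 0


@dataclass
class CohortRecord:
    """One ROI with its labels and per-parameter summaries."""

    patient_id: str
    roi_id: str
    roi_type: str  # lesion | normal
    zone: str  # PZ | TZ
    pirads: int
    gg: str  # neg | 1 | 2 | 3 | 4
    summaries: dict[str, RoiSummary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.roi_type not in VALID_ROI_TYPES:
            raise UltraDceError(f"unknown roi_type '{self.roi_type}'")
        if self.zone not in VALID_ZONES:
            raise UltraDceError(f"unknown zone '{self.zone}'")
        if self.pirads not in VALID_PIRADS:
            raise UltraDceError(f"PI-RADS must be one of {VALID_PIRADS}")
        if self.roi_type == "normal" and self.pirads != 1:
            raise UltraDceError("normal-appearing ROIs carry PI-RADS 1")
        if self.roi_type == "lesion" and self.pirads == 1:
            raise UltraDceError("lesion ROIs carry PI-RADS 3, 4 or 5")
        if self.gg not in VALID_GG:
            raise UltraDceError(f"grade group must be one of {VALID_GG}")


def summarize_roi(pmap: ParameterMap, roi: RoiMask) -> RoiSummary:
    """Masked-then-averaged summary of one parameter map over one ROI."""
    if pmap.values.shape != roi.data.shape:
        raise GridMismatchError("parameter map and ROI grids differ")
    sel = roi.data & pmap.valid
    vals = pmap.values[sel]
    n_valid = int(sel.sum())
    mean = float(vals.mean()) if n_valid >= 1 else float("nan")
    sd = float(vals.std(ddof=1)) if n_valid >= 2 else float("nan")
    return RoiSummary(parameter=pmap.name, mean=mean, sd=sd,
                      n_valid=n_valid, n_total=roi.n_voxels)


def assemble_cohort(
    records: list[CohortRecord],
) -> tuple[pd.DataFrame, list[dict]]:
    """Build the long-format cohort table, one row per (ROI, parameter).

    Empty summaries (no valid voxels for that parameter in that ROI)
    are dropped and reported in the returned drop log; the ROI's other
    parameters are unaffected. Duplicate (roi, parameter) pairs raise.
    """
    rows: list[dict] = []
    drops: list[dict] = []
    seen: set[tuple[str, str]] = set()
    for rec in records:
        for param, s in rec.summaries.items():
            key = (rec.roi_id, param)
            if key in seen:
                raise UltraDceError(
                    f"duplicate summary for roi '{rec.roi_id}', "
                    f"parameter '{param}'"
                )
            seen.add(key)
            if s.empty:
                drops.append({
                    "patient_id": rec.patient_id, "roi_id": rec.roi_id,
                    "parameter": param,
                    "reason": "no voxels within the credible value range",
                })
                continue
            rows.append({
                "patient_id": rec.patient_id,
                "roi_id": rec.roi_id,
                "roi_type": rec.roi_type,
                "zone": rec.zone,
                "pirads": rec.pirads,
                "gg": rec.gg,
                "parameter": param,
                "mean": s.mean,
                "sd": s.sd,
                "n_valid": s.n_valid,
            })
    columns = ["patient_id", "roi_id", "roi_type", "zone", "pirads", "gg",
               "parameter", "mean", "sd", "n_valid"]
    table = pd.DataFrame(rows, columns=columns)
    return table, drops
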