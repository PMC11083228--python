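"""Bolus preparation: baseline, concentration conversion, AIF, analysis window.

The signal model is the linearized low-concentration approximation

    C(t) = R * (S(t) - S0) / S0

with R = 1/(r1 * T10) collapsing relaxivity and native T1 into one
scale factor. Without a T1 map, R defaults to 1, i.e. identical native
T1 is assumed for lesions and healthy tissue; concentrations are then
unitless relative enhancements. Negative concentrations from noise are
kept, not clipped — clipping would bias fits near baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DetectionError, EmptyRoiError, WindowError
from .io import DynamicSeries, RoiMask

__all__ = [
    "ConcentrationSeries",
    "Aif",
    "detect_arrival",
    "compute_baseline",
    "to_concentration",
    "extract_aif",
    "cut_window",
]

#: Frames excluded from the start of every baseline window (scanner
#: signal has not reached steady state in the first two frames).
BASELINE_SKIP = 2

#: Bolus arrival trigger: first frame exceeding baseline mean by this
#: many baseline standard deviations.
ARRIVAL_NSD = 5.0

#: Minimum number of baseline frames before a trigger is trusted; with
#: fewer the baseline SD is degenerate and noise alone would trigger.
MIN_BASELINE_FRAMES = 3


@dataclass
class ConcentrationSeries:
    """4D contrast-agent concentration on the acquisition grid."""

    data: np.ndarray
    dt_seconds: float
    arrival_frame: int | None = None
    valid: np.ndarray | None = None  # 3D; False where S0 <= 0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[3]


@dataclass
class Aif:
    """Arterial input function: mean concentration over an artery ROI.

    Used as measured — no amplitude correction, scaling or dispersion
    correction is applied, so fitted kinetic parameters inherit the
    AIF's (unknown) scale.
    """

    values: np.ndarray
    dt_seconds: float
    arrival_frame: int
    source_voxel_count: int = 0

    def __len__(self) -> int:
        return len(self.values)

    def windowed(self, duration_s: float) -> tuple[np.ndarray, np.ndarray]:
        """AIF over the analysis window, time re-origined at arrival."""
        return cut_window(self.values, self.arrival_frame, duration_s,
                          self.dt_seconds)


def detect_arrival(curve: np.ndarray) -> int:
    """Detect the bolus-arrival frame of a signal or concentration curve.

    Scans for the first frame ``k`` whose value exceeds the running
    baseline (frames ``2..k-1``) mean by ``ARRIVAL_NSD`` baseline
    standard deviations, sustained for two consecutive frames (a single
    noise spike must not trigger). At least ``MIN_BASELINE_FRAMES``
    baseline frames are required before a trigger counts, and the SD is
    floored at a small fraction of the curve's dynamic range so a
    near-constant baseline cannot trigger on numerical noise. If the
    threshold never fires, falls back to the start of the global
    upslope (steepest frame-to-frame rise, walked back to the last
    frame at or below the pre-rise baseline mean).

    Raises
    ------
    DetectionError
        If the curve is flat (no excursion at all).
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 1 or len(curve) < 8:
        raise DetectionError("arrival detection needs a 1D curve of >= 8 frames")
    rng = float(curve.max() - curve.min())
    if rng == 0.0:
        raise DetectionError("flat curve: no bolus excursion")
    sd_floor = 1e-6 * rng

    start = BASELINE_SKIP + MIN_BASELINE_FRAMES
    for k in range(start, len(curve) - 1):
        base = curve[BASELINE_SKIP:k]
        mu = base.mean()
        sd = max(base.std(ddof=1), sd_floor)
        thr = mu + ARRIVAL_NSD * sd
        if curve[k] > thr and curve[k + 1] > thr:
            return k

    # Fallback: steepest upslope, walked back to baseline level.
    diffs = np.diff(curve)
    j = int(np.argmax(diffs)) + 1  # frame where the steepest rise lands
    base = curve[BASELINE_SKIP:max(j, BASELINE_SKIP + 1)]
    mu = base.mean()
    k = j
    while k - 1 > BASELINE_SKIP and curve[k - 1] > mu:
        k -= 1
    return max(k, BASELINE_SKIP + 1)


def compute_baseline(series: DynamicSeries, arrival: int) -> np.ndarray:
    """Per-voxel pre-contrast signal S0.

    Mean over frames ``2..arrival-1``: the first two timepoints are
    excluded and the window ends with the final frame before contrast
    arrival.
    """
    if arrival <= BASELINE_SKIP:
        raise WindowError(
            f"arrival frame {arrival} leaves no baseline after skipping "
            f"the first {BASELINE_SKIP} frames"
        )
    return series.data[..., BASELINE_SKIP:arrival].mean(axis=-1)


def to_concentration(
    series: DynamicSeries,
    s0: np.ndarray,
    R: float = 1.0,
    arrival_frame: int | None = None,
) -> ConcentrationSeries:
    """Convert signal to concentration, ``C = R (S - S0) / S0``.

    Voxels with nonpositive baseline are flagged invalid (their
    concentration is set to NaN) rather than raising.
    """
    s0 = np.asarray(s0, dtype=float)
    valid = s0 > 0
    safe = np.where(valid, s0, 1.0)
    conc = R * (series.data - safe[..., None]) / safe[..., None]
    conc[~valid] = np.nan
    return ConcentrationSeries(
        data=conc,
        dt_seconds=series.dt_seconds,
        arrival_frame=arrival_frame,
        valid=valid,
        affine=series.affine,
    )


def extract_aif(conc: ConcentrationSeries, artery: RoiMask) -> Aif:
    """Mean concentration curve over the artery ROI, with arrival frame.

    No rescaling or amplitude correction is applied.
    """
    if artery.data.shape != conc.spatial_shape:
        raise EmptyRoiError(
            "artery mask grid does not match concentration series"
        )
    voxels = conc.data[artery.data]  # (n_voxels, t)
    if voxels.size == 0:
        raise EmptyRoiError("artery mask has no voxels")
    values = voxels.mean(axis=0)
    arrival = detect_arrival(values)
    return Aif(
        values=values,
        dt_seconds=conc.dt_seconds,
        arrival_frame=arrival,
        source_voxel_count=int(artery.data.sum()),
    )


def cut_window(
    curve: np.ndarray,
    arrival: int,
    duration_s: float,
    dt_seconds: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the analysis window from a 1D curve.

    Returns frames ``arrival .. arrival + floor(duration_s/dt)``
    (inclusive, truncated at the end of the series) together with the
    time grid in seconds re-origined to 0 at arrival.
    """
    curve = np.asarray(curve, dtype=float)
    n_post = int(np.floor(duration_s / dt_seconds))
    stop = min(arrival + n_post + 1, len(curve))
    window = curve[arrival:stop]
    times = np.arange(len(window)) * dt_seconds
    return window, times
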