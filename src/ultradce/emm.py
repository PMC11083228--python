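"""Empirical mathematical models of early enhancement, plus time to peak.

Two curve-shape models are fitted per voxel to the concentration time
course, with no biophysical assumptions and no AIF:

* exponential uptake, ``C(t) = A (1 - exp(-alpha (t - t0)))`` for
  t >= t0 and 0 before — amplitude A, enhancement rate alpha, arrival
  time t0;
* sigmoidal uptake, ``C(t) = A0 * Phi((t - A1) / A2)`` with Phi the
  standard normal CDF — plateau amplitude A0, center time A1 (reported
  relative to the arrival reference T0 as A1 - T0) and slope width A2.

The sigmoid is the integral of a Gaussian; it is normalized so that A0
is the plateau amplitude and A2 a width in time units, the only reading
under which "amplitude" and "slope" keep their meaning.

The time axis is in dynamics (frame counts), matching the units the
parameters are reported in; 1 dynamic = dt seconds.

Fitting is weighted nonlinear least squares with binary weights: 1 over
the uptake phase, 0 afterwards, to keep wash-out from distorting the
uptake fit. The default cutoff is the later of 120 s and the peak of
enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr

from .errors import DomainError, FitError
from .io import ParameterMap
from .prep import ConcentrationSeries, cut_window
from .ranges import in_range, unit_of

__all__ = [
    "ExpEmmParams",
    "SigmoidEmmParams",
    "CurveShape",
    "exp_emm_curve",
    "sigmoid_emm_curve",
    "build_weights",
    "initial_estimates_exp",
    "initial_estimates_sigmoid",
    "fit_exp_emm",
    "fit_sigmoid_emm",
    "compute_ttp",
    "fit_emm_volume",
]

#: Minimum uptake-phase duration for the weight vector, seconds.
UPTAKE_MIN_S = 120.0


@dataclass(frozen=True)
class ExpEmmParams:
    a: float  # amplitude, concentration units
    alpha: float  # enhancement rate, dynamics^-1
    t0: float  # arrival time, dynamics


@dataclass(frozen=True)
class SigmoidEmmParams:
    a0: float  # plateau amplitude, concentration units
    a1: float  # center time, dynamics
    a2: float  # slope width, dynamics
    t0_ref: float = 0.0  # arrival reference, dynamics

    @property
    def a1_minus_t0(self) -> float:
        return self.a1 - self.t0_ref


@dataclass(frozen=True)
class CurveShape:
    ttp: int  # time to peak, dynamics


def exp_emm_curve(p: ExpEmmParams, times: np.ndarray) -> np.ndarray:
    """Exponential uptake curve; zero before onset t0."""
    t = np.asarray(times, dtype=float)
    dt = t - p.t0
    return np.where(dt >= 0, p.a * (1.0 - np.exp(-p.alpha * np.maximum(dt, 0.0))), 0.0)


def sigmoid_emm_curve(p: SigmoidEmmParams, times: np.ndarray) -> np.ndarray:
    """Gaussian-integral (sigmoid) uptake curve, plateau A0."""
    if p.a2 <= 0:
        raise DomainError("sigmoid slope width A2 must be positive")
    t = np.asarray(times, dtype=float)
    return p.a0 * ndtr((t - p.a1) / p.a2)


def build_weights(
    curve: np.ndarray,
    dt_seconds: float,
    policy: str = "max120_peak",
) -> np.ndarray:
    """Binary uptake-phase weights for the windowed curve.

    Policies
    --------
    ``fixed_120s``  — 1 for frames with time <= 120 s from window start.
    ``to_peak``     — 1 up to and including the (earliest) peak frame.
    ``max120_peak`` — the later of the two cutoffs (default): weights
    are 1 for at least the first 120 s of the window, or to the peak of
    enhancement when it comes later.

    The result is always a contiguous prefix of ones.
    """
    curve = np.asarray(curve, dtype=float)
    n = len(curve)
    last_120 = min(int(np.floor(UPTAKE_MIN_S / dt_seconds)), n - 1)
    peak = int(np.argmax(curve))
    if policy == "fixed_120s":
        cutoff = last_120
    elif policy == "to_peak":
        cutoff = peak
    elif policy == "max120_peak":
        cutoff = max(last_120, peak)
    else:
        raise DomainError(f"unknown weight policy '{policy}'")
    w = np.zeros(n)
    w[: cutoff + 1] = 1.0
    return w


def _plateau_estimate(curve: np.ndarray, weights: np.ndarray) -> float:
    """Mean of the last 10% of the weighted (uptake-phase) frames."""
    nw = int(weights.sum())
    tail = max(1, int(np.ceil(0.1 * nw)))
    return float(curve[:nw][-tail:].mean())


def _crossing_time(curve: np.ndarray, level: float) -> float | None:
    """First (linearly interpolated) time the curve reaches ``level``."""
    above = np.nonzero(curve >= level)[0]
    if len(above) == 0:
        return None
    k = int(above[0])
    if k == 0:
        return 0.0
    c0, c1 = curve[k - 1], curve[k]
    if c1 == c0:
        return float(k)
    return float(k - 1 + (level - c0) / (c1 - c0))


def initial_estimates_exp(
    curve: np.ndarray, weights: np.ndarray, arrival: float = 0.0
) -> tuple[ExpEmmParams, bool]:
    """Starting estimates from the baseline and ending signal.

    Returns (params, degenerate_flag); the flag is set for flat curves,
    where defaults are returned instead of data-driven estimates.
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) < 5:
        raise FitError("initial estimates need >= 5 frames")
    a = _plateau_estimate(curve, weights)
    if not np.isfinite(a) or a <= 0 or np.ptp(curve) == 0:
        return ExpEmmParams(a=1.0, alpha=0.1, t0=arrival), True
    t_half = _crossing_time(curve, 0.5 * a)
    if t_half is None or t_half <= arrival:
        return ExpEmmParams(a=a, alpha=0.1, t0=arrival), True
    alpha = float(np.log(2.0) / (t_half - arrival))
    alpha = min(max(alpha, 1e-3), 1.0)
    return ExpEmmParams(a=a, alpha=alpha, t0=arrival), False


def initial_estimates_sigmoid(
    curve: np.ndarray, weights: np.ndarray, t0_ref: float = 0.0
) -> tuple[SigmoidEmmParams, bool]:
    """Starting estimates for the sigmoid model.

    A1 is the half-amplitude crossing time; A2 the 10–90% rise time
    divided by 2.563 (the 10–90% span of a unit-width normal CDF).
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) < 5:
        raise FitError("initial estimates need >= 5 frames")
    a0 = _plateau_estimate(curve, weights)
    if not np.isfinite(a0) or a0 <= 0 or np.ptp(curve) == 0:
        return SigmoidEmmParams(a0=1.0, a1=len(curve) / 4, a2=5.0,
                                t0_ref=t0_ref), True
    t50 = _crossing_time(curve, 0.5 * a0)
    t10 = _crossing_time(curve, 0.1 * a0)
    t90 = _crossing_time(curve, 0.9 * a0)
    if t50 is None:
        return SigmoidEmmParams(a0=a0, a1=len(curve) / 4, a2=5.0,
                                t0_ref=t0_ref), True
    if t10 is not None and t90 is not None and t90 > t10:
        a2 = (t90 - t10) / 2.563
    else:
        a2 = max(len(curve) / 10.0, 1.0)
    return SigmoidEmmParams(a0=a0, a1=t50, a2=max(a2, 0.1), t0_ref=t0_ref), False


def _weighted_fit(residual_fn, x0, lo, hi):
    sol = least_squares(residual_fn, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    return sol


def fit_exp_emm(
    curve: np.ndarray,
    weights: np.ndarray,
    dt_seconds: float | None = None,
    start: ExpEmmParams | None = None,
) -> tuple[ExpEmmParams, float]:
    """Weighted bounded least-squares fit of the exponential model.

    Times are frame indices (dynamics). Only frames with weight 1 enter
    the fit; at least 4 are required. Returns (params, weighted SSR).
    Validity against the credible range (alpha in (0, 1]) is applied by
    the caller, not here.
    """
    curve = np.asarray(curve, dtype=float)
    weights = np.asarray(weights, dtype=float)
    sel = weights > 0
    if sel.sum() < 4:
        raise FitError("exponential fit needs >= 4 weighted frames")
    t = np.arange(len(curve), dtype=float)[sel]
    y = curve[sel]
    if start is None:
        start, _ = initial_estimates_exp(curve, weights)

    def residuals(theta):
        return exp_emm_curve(ExpEmmParams(*theta), t) - y

    n = len(curve)
    x0 = [max(start.a, 1e-6), min(max(start.alpha, 1e-4), 5.0),
          min(max(start.t0, 0.0), n - 1.0)]
    sol = _weighted_fit(residuals, x0, [0.0, 1e-6, 0.0], [np.inf, 5.0, float(n)])
    p = ExpEmmParams(a=sol.x[0], alpha=sol.x[1], t0=sol.x[2])
    return p, float(2 * sol.cost)


def fit_sigmoid_emm(
    curve: np.ndarray,
    weights: np.ndarray,
    t0_ref: float = 0.0,
    start: SigmoidEmmParams | None = None,
) -> tuple[SigmoidEmmParams, float]:
    """Weighted bounded least-squares fit of the sigmoid model."""
    curve = np.asarray(curve, dtype=float)
    weights = np.asarray(weights, dtype=float)
    sel = weights > 0
    if sel.sum() < 4:
        raise FitError("sigmoid fit needs >= 4 weighted frames")
    t = np.arange(len(curve), dtype=float)[sel]
    y = curve[sel]
    if start is None:
        start, _ = initial_estimates_sigmoid(curve, weights, t0_ref=t0_ref)

    def residuals(theta):
        return SigmoidEmmParams(theta[0], theta[1], theta[2]).a0 * ndtr(
            (t - theta[1]) / theta[2]
        ) - y

    n = len(curve)
    x0 = [max(start.a0, 1e-6), start.a1, max(start.a2, 0.05)]
    sol = _weighted_fit(residuals, x0, [0.0, -float(n), 0.01],
                        [np.inf, 2.0 * n, 10.0 * n])
    p = SigmoidEmmParams(a0=sol.x[0], a1=sol.x[1], a2=sol.x[2], t0_ref=t0_ref)
    return p, float(2 * sol.cost)


def compute_ttp(curve: np.ndarray, arrival: int = 0) -> CurveShape:
    """Time to peak concentration, in dynamics after ``arrival``.

    Ties break to the earliest maximum. For a curve already windowed at
    arrival, pass arrival=0 (the default).
    """
    curve = np.asarray(curve, dtype=float)
    if len(curve) == 0:
        raise FitError("empty curve")
    peak = int(np.argmax(curve[arrival:]))  # argmax returns first maximum
    return CurveShape(ttp=peak)


_EMM_MAPS = ("a", "alpha", "t0", "a0", "a1_minus_t0", "a2", "ttp")


def fit_emm_volume(
    conc: ConcentrationSeries,
    arrival: int,
    window_s: float = 120.0,
    policy: str = "max120_peak",
    models: str = "both",
    voxel_mask: np.ndarray | None = None,
) -> dict[str, ParameterMap]:
    """Voxelwise EMM fits and TTP over the early-enhancement window.

    Returns maps named a, alpha, t0 (exponential), a0, a1_minus_t0, a2
    (sigmoid) and ttp, each with Table-of-credible-ranges validity.
    ``models`` selects "exp", "sigmoid" or "both".
    """
    shape = conc.spatial_shape
    want_exp = models in ("exp", "both")
    want_sig = models in ("sigmoid", "both")
    names = ["ttp"]
    if want_exp:
        names += ["a", "alpha", "t0"]
    if want_sig:
        names += ["a0", "a1_minus_t0", "a2"]
    values = {name: np.full(shape, np.nan) for name in names}
    ok = {name: np.zeros(shape, dtype=bool) for name in names}

    if voxel_mask is None:
        voxel_mask = np.ones(shape, dtype=bool)
    if conc.valid is not None:
        voxel_mask = voxel_mask & conc.valid

    for idx in np.argwhere(voxel_mask):
        i, j, k = idx
        curve, _ = cut_window(conc.data[i, j, k], arrival, window_s,
                              conc.dt_seconds)
        if not np.isfinite(curve).all() or np.ptp(curve) == 0:
            continue
        w = build_weights(curve, conc.dt_seconds, policy=policy)
        values["ttp"][i, j, k] = compute_ttp(curve).ttp
        ok["ttp"][i, j, k] = True
        if want_exp:
            try:
                pe, _ = fit_exp_emm(curve, w)
            except FitError:
                pe = None
            if pe is not None:
                for name, val in (("a", pe.a), ("alpha", pe.alpha),
                                  ("t0", pe.t0)):
                    values[name][i, j, k] = val
                    ok[name][i, j, k] = bool(in_range(name, np.array(val)))
        if want_sig:
            try:
                ps, _ = fit_sigmoid_emm(curve, w)
            except FitError:
                ps = None
            if ps is not None:
                for name, val in (("a0", ps.a0),
                                  ("a1_minus_t0", ps.a1_minus_t0),
                                  ("a2", ps.a2)):
                    values[name][i, j, k] = val
                    ok[name][i, j, k] = bool(in_range(name, np.array(val)))

    return {
        name: ParameterMap(name=name, values=values[name], valid=ok[name],
                           unit=unit_of(name))
        for name in names
    }
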