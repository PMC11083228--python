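"""Two-compartment uptake (2CU) model: forward curves, fitting, conversions.

The 2CU model describes early enhancement as a plasma compartment with
flow Fp feeding unidirectional extraction PS into the extravascular
extracellular space (back-flux neglected, valid within the first ~2 min
of enhancement). Its tissue impulse response is biexponential,

    I(tau) = alpha_plus + alpha_minus * exp(-beta_minus * tau),  tau >= 0,

and the tissue concentration is the causal convolution I * AIF. The
biexponential parameters map one-to-one onto the physiological triple
(vp, PS, Fp):

    Fp = alpha_plus + alpha_minus
    E  = alpha_plus / Fp            (extraction fraction)
    PS = Fp * E / (1 - E)
    vp = (Fp + PS) / beta_minus

equivalently I(tau) = Fp * [E + (1-E) exp(-tau/MTTp)] with plasma mean
transit time MTTp = vp/(PS+Fp) = 1/beta_minus. Derived quantities:
Tc = vp/Fp (capillary transit time), Ktrans = E*Fp (= alpha_plus).

All rates are per minute and times in minutes. Fitting minimizes the
sum of squared residuals over the early-enhancement window with loose
positivity bounds; the physiological ranges are applied afterwards as
validity masks, not as optimizer constraints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .errors import DomainError, GridMismatchError
from .io import ParameterMap
from .prep import Aif, ConcentrationSeries
from .ranges import in_range, unit_of

__all__ = [
    "BiexpParams",
    "TwoCUParams",
    "Derived2CU",
    "FitDiagnostics",
    "biexp_to_physio",
    "physio_to_biexp",
    "derive_secondary",
    "forward_2cu",
    "forward_2cu_physio",
    "fit_2cu_voxel",
    "fit_2cu_volume",
    "DEFAULT_START",
    "OPTIMIZER_BOUNDS",
]

#: Printed starting estimates; they correspond to Fp=0.4 min^-1,
#: PS=0.4 min^-1, vp=0.2.
DEFAULT_START = (0.2, 0.2, 4.0)

#: Loose positivity bounds used by the optimizer; the physiological
#: ranges are applied post hoc as validity masks.
OPTIMIZER_BOUNDS = ((0.0, 0.0, 1e-3), (20.0, 20.0, 100.0))


@dataclass(frozen=True)
class BiexpParams:
    """Biexponential impulse-response parameters (rates in min^-1)."""

    alpha_plus: float
    alpha_minus: float
    beta_minus: float
    t0: float = 0.0  # bolus delay, minutes

    def __post_init__(self) -> None:
        if self.alpha_plus < 0 or self.alpha_minus < 0:
            raise DomainError("alpha_plus and alpha_minus must be >= 0")
        if self.beta_minus <= 0:
            raise DomainError("beta_minus must be > 0")
        if self.t0 < 0:
            raise DomainError("t0 must be >= 0")


@dataclass(frozen=True)
class TwoCUParams:
    """Physiological 2CU parameters: vp (mL/mL), PS and Fp (min^-1)."""

    vp: float
    ps: float
    fp: float


@dataclass(frozen=True)
class Derived2CU:
    """Secondary parameters derived from (vp, PS, Fp)."""

    mttp: float  # plasma mean transit time, min
    tc: float  # capillary transit time, min
    e: float  # extraction fraction
    ktrans: float  # volume transfer constant, min^-1


@dataclass
class FitDiagnostics:
    ssr: float
    converged: bool
    n_iterations: int = 0


def biexp_to_physio(b: BiexpParams) -> TwoCUParams:
    """Convert biexponential to physiological parameters.

    Raises
    ------
    DomainError
        If alpha_minus = 0 (extraction fraction 1, infinite PS) or both
        amplitudes vanish (degenerate response).
    """
    fp = b.alpha_plus + b.alpha_minus
    if fp <= 0:
        raise DomainError("degenerate response: alpha_plus = alpha_minus = 0")
    if b.alpha_minus == 0:
        raise DomainError("alpha_minus = 0 implies infinite PS")
    e = b.alpha_plus / fp
    if e >= 1.0:  # float underflow of alpha_minus/fp
        raise DomainError("extraction fraction at 1: PS diverges")
    ps = fp * e / (1.0 - e)
    vp = (fp + ps) / b.beta_minus
    return TwoCUParams(vp=vp, ps=ps, fp=fp)


def physio_to_biexp(p: TwoCUParams, t0: float = 0.0) -> BiexpParams:
    """Inverse conversion; round-trips with :func:`biexp_to_physio`."""
    if p.fp <= 0 or p.vp <= 0:
        raise DomainError("Fp and vp must be positive")
    if p.ps < 0:
        raise DomainError("PS must be >= 0")
    e = p.ps / (p.ps + p.fp)
    alpha_plus = e * p.fp
    alpha_minus = p.fp - alpha_plus
    beta_minus = (p.fp + p.ps) / p.vp
    return BiexpParams(alpha_plus, alpha_minus, beta_minus, t0)


def derive_secondary(p: TwoCUParams) -> Derived2CU:
    """MTTp, Tc, E and Ktrans from the physiological triple."""
    if p.fp <= 0:
        raise DomainError("Fp = 0: capillary transit time undefined")
    denom = p.ps + p.fp
    e = p.ps / denom
    return Derived2CU(
        mttp=p.vp / denom,
        tc=p.vp / p.fp,
        e=e,
        ktrans=e * p.fp,
    )


def _check_uniform(times_min: np.ndarray) -> float:
    times_min = np.asarray(times_min, dtype=float)
    if len(times_min) < 2:
        raise GridMismatchError("time grid needs at least 2 points")
    steps = np.diff(times_min)
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-12) or dt <= 0:
        raise GridMismatchError("time grid must be uniform and increasing")
    return float(dt)


def _conv_exp_exact(beta: float, aif: np.ndarray, dt: float) -> np.ndarray:
    """Exact convolution of ``exp(-beta t)`` with a piecewise-linear AIF.

    Recursion over frames: ``y[k] = E y[k-1] + segment integral`` with
    ``E = exp(-beta dt)`` and the segment integral evaluated in closed
    form for a linear AIF segment. Exact up to the piecewise-linear
    representation of the AIF, so the discretization error does not
    grow with beta the way a sampled trapezoidal convolution's does.
    """
    n = len(aif)
    E = np.exp(-beta * dt)
    # closed-form weights for the left/right endpoint of each segment
    c_left = (1.0 - E) / beta - (dt / beta - (1.0 - E) / beta**2) / dt
    c_right = (dt / beta - (1.0 - E) / beta**2) / dt
    # IIR form y[k] = E y[k-1] + c_left aif[k-1] + c_right aif[k],
    # corrected so that y[0] = 0 (causality).
    z = lfilter([c_right, c_left], [1.0, -E], aif)
    return z - c_right * aif[0] * E ** np.arange(n)


def _cumtrapz(aif: np.ndarray, dt: float) -> np.ndarray:
    """Running integral of a piecewise-linear AIF (trapezoid, exact)."""
    out = np.zeros(len(aif))
    out[1:] = np.cumsum(0.5 * dt * (aif[1:] + aif[:-1]))
    return out


def forward_2cu(
    b: BiexpParams, aif: Aif | np.ndarray, times_min: np.ndarray
) -> np.ndarray:
    """Tissue concentration curve of the 2CU model on a uniform grid.

    Causal convolution of the delayed impulse response with the AIF,
    treating the AIF as piecewise linear between frames: the constant
    term integrates by the (then exact) trapezoidal rule and the
    exponential term by an exact recursive closed form. A nonzero
    bolus delay t0 shifts the zero-delay solution by linear
    interpolation on the grid.
    """
    times_min = np.asarray(times_min, dtype=float)
    dt = _check_uniform(times_min)
    aif_vals = aif.values if isinstance(aif, Aif) else np.asarray(aif, float)
    if len(aif_vals) != len(times_min):
        raise GridMismatchError("AIF and time grid lengths differ")
    c0 = (b.alpha_plus * _cumtrapz(aif_vals, dt)
          + b.alpha_minus * _conv_exp_exact(b.beta_minus, aif_vals, dt))
    if b.t0 == 0.0:
        return c0
    rel = times_min - times_min[0]
    return np.interp(rel - b.t0, rel, c0, left=0.0)


def forward_2cu_physio(
    p: TwoCUParams, aif: Aif | np.ndarray, times_min: np.ndarray, t0: float = 0.0
) -> np.ndarray:
    """Forward curve from the residue-function form Fp[E + (1-E)e^(-t/MTTp)].

    Mathematically identical to :func:`forward_2cu` through the
    parameter mapping; kept separate so the two parameterizations can
    be cross-checked.
    """
    d = derive_secondary(p)
    times_min = np.asarray(times_min, dtype=float)
    dt = _check_uniform(times_min)
    aif_vals = aif.values if isinstance(aif, Aif) else np.asarray(aif, float)
    c0 = p.fp * (d.e * _cumtrapz(aif_vals, dt)
                 + (1.0 - d.e) * _conv_exp_exact(1.0 / d.mttp, aif_vals, dt))
    if t0 == 0.0:
        return c0
    rel = times_min - times_min[0]
    return np.interp(rel - t0, rel, c0, left=0.0)


def fit_2cu_voxel(
    curve: np.ndarray,
    aif_values: np.ndarray,
    times_min: np.ndarray,
    start: tuple[float, float, float] = DEFAULT_START,
    bounds: tuple[tuple, tuple] = OPTIMIZER_BOUNDS,
    fit_t0: bool = False,
    t0_max_min: float = 0.0,
) -> tuple[BiexpParams, FitDiagnostics]:
    """Bounded least-squares fit of the biexponential 2CU form to one voxel.

    Parameters are started from ``start`` (default: the standard
    starting estimates). When ``fit_t0`` is set, the bolus delay is
    fitted over [0, t0_max_min]; otherwise t0 is fixed at 0, assuming
    both tissue curve and AIF were re-origined at the detected arrival.

    A curve that is identically zero (or non-finite) returns the start
    with ``converged=False``.
    """
    curve = np.asarray(curve, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    finite = np.isfinite(curve)
    if not finite.all() or not np.any(curve != 0):
        b = BiexpParams(*start)
        return b, FitDiagnostics(ssr=float(np.nansum(curve**2)), converged=False)

    aif_values = np.asarray(aif_values, dtype=float)

    if fit_t0:
        def residuals(theta):
            b = BiexpParams(theta[0], theta[1], theta[2], theta[3])
            return forward_2cu(b, aif_values, times_min) - curve

        x0 = [*start, 0.0]
        lo = [*bounds[0], 0.0]
        hi = [*bounds[1], max(t0_max_min, 1e-6)]
    else:
        def residuals(theta):
            b = BiexpParams(theta[0], theta[1], theta[2], 0.0)
            return forward_2cu(b, aif_values, times_min) - curve

        x0, lo, hi = list(start), list(bounds[0]), list(bounds[1])

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    t0 = sol.x[3] if fit_t0 else 0.0
    b = BiexpParams(sol.x[0], sol.x[1], sol.x[2], t0)
    diag = FitDiagnostics(
        ssr=float(2 * sol.cost), converged=bool(sol.success),
        n_iterations=int(sol.nfev),
    )
    return b, diag


_MAP_ORDER = ("vp", "ps", "fp", "mttp", "tc", "e", "ktrans")


def fit_2cu_volume(
    conc: ConcentrationSeries,
    aif: Aif,
    window_s: float = 120.0,
    start: tuple[float, float, float] = DEFAULT_START,
    fit_t0: bool = False,
    voxel_mask: np.ndarray | None = None,
) -> dict[str, ParameterMap]:
    """Voxelwise 2CU fit over the early-enhancement window.

    Returns seven parameter maps (vp, ps, fp, mttp, tc, e, ktrans).
    Each map's validity mask is True where the voxel had a usable
    baseline, the fit converged, the conversion to physiological
    parameters was defined, and the value lies inside its credible
    range. Out-of-range or degenerate voxels are masked, never fatal.

    ``voxel_mask`` restricts fitting to a subset of voxels (e.g. a
    prostate bounding box); others are left invalid.
    """
    from .prep import cut_window

    arrival = conc.arrival_frame
    if arrival is None:
        arrival = aif.arrival_frame
    aif_win, times_s = aif.windowed(window_s)
    times_min = times_s / 60.0

    shape = conc.spatial_shape
    values = {name: np.full(shape, np.nan) for name in _MAP_ORDER}
    ok = {name: np.zeros(shape, dtype=bool) for name in _MAP_ORDER}

    if voxel_mask is None:
        voxel_mask = np.ones(shape, dtype=bool)
    if conc.valid is not None:
        voxel_mask = voxel_mask & conc.valid

    for idx in np.argwhere(voxel_mask):
        i, j, k = idx
        curve, _ = cut_window(conc.data[i, j, k], arrival, window_s,
                              conc.dt_seconds)
        n = min(len(curve), len(aif_win))
        b, diag = fit_2cu_voxel(curve[:n], aif_win[:n], times_min[:n],
                                start=start, fit_t0=fit_t0,
                                t0_max_min=10 * conc.dt_seconds / 60.0)
        if not diag.converged:
            continue
        try:
            p = biexp_to_physio(b)
            d = derive_secondary(p)
        except DomainError:
            continue
        vox = {"vp": p.vp, "ps": p.ps, "fp": p.fp, "mttp": d.mttp,
               "tc": d.tc, "e": d.e, "ktrans": d.ktrans}
        for name, val in vox.items():
            values[name][i, j, k] = val
            ok[name][i, j, k] = bool(in_range(name, np.array(val)))

    return {
        name: ParameterMap(name=name, values=values[name], valid=ok[name],
                           unit=unit_of(name))
        for name in _MAP_ORDER
    }
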