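"""Synthetic phantoms and cohorts with known ground truth.

Every analysis stage in the package is testable without any acquired
data: this module generates (a) bolus-shaped arterial input functions,
(b) single-voxel signal curves driven by the forward kinetic and
empirical models with seeded noise, (c) small 4D digital phantoms with
artery and tissue regions, and (d) ROI-level cohort tables with
controllable group effects, emulating a study of 25 patients with 35
lesions (plus 35 paired normal-appearing ROIs) acquired at 1.695 s per
dynamic over 150 dynamics.

The fast-path cohort generator draws ROI-level parameter means directly
from a location-shift model (baseline + per-level effect in SD units +
Gaussian noise) because the statistics operate on ROI means and do not
need voxel data. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, GridMismatchError
from .io import DynamicSeries, RoiMask
from .kinetics import BiexpParams, TwoCUParams, forward_2cu, physio_to_biexp
from .emm import ExpEmmParams, SigmoidEmmParams, exp_emm_curve, sigmoid_emm_curve
from .prep import Aif

__all__ = [
    "AifSpec",
    "Region",
    "PhantomSpec",
    "CohortSpec",
    "make_aif",
    "simulate_voxel",
    "make_phantom",
    "make_cohort",
    "null_cohort",
    "BASELINE_MEANS",
    "DEFAULT_PIRADS_EFFECTS",
    "DEFAULT_GG_EFFECTS",
    "DEFAULT_ZONE_EFFECTS",
]

#: Acquisition defaults emulated throughout: 1.695 s per dynamic,
#: 150 dynamics (~4 min 14 s).
DT_SECONDS = 1.695
N_DYNAMICS = 150


@dataclass(frozen=True)
class AifSpec:
    """Shape specification for a synthetic arterial input function.

    The gamma-variate form ``a (t-ta)^b exp(-(t-ta)/c)`` (zero before
    arrival ``ta``) is the standard first-pass bolus shape; the
    amplitude is normalized so the peak equals ``peak_amplitude``.
    ``recirculation`` adds a dispersed second pass plus a steady-state
    plateau.
    """

    model: str = "gamma_variate"  # gamma_variate | boxcar | impulse
    arrival_s: float = 25.0
    peak_amplitude: float = 5.0
    shape_b: float = 2.0  # gamma-variate exponent
    shape_c_s: float = 4.0  # gamma-variate decay, seconds
    boxcar_duration_s: float = 30.0
    recirculation: bool = False

    def __post_init__(self) -> None:
        if self.shape_b < 0 or self.shape_c_s <= 0:
            raise DomainError("gamma-variate shape parameters must be positive")
        if self.peak_amplitude < 0:
            raise DomainError("peak amplitude must be nonnegative")


@dataclass
class Region:
    """A homogeneous phantom region: a mask plus its ground-truth model."""

    name: str
    mask: np.ndarray  # 3D bool
    model: str  # 2cu | exp_emm | sigmoid_emm
    params: object  # TwoCUParams | BiexpParams | ExpEmmParams | SigmoidEmmParams


@dataclass
class PhantomSpec:
    """Specification for a small 4D digital phantom."""

    shape: tuple[int, int, int] = (16, 16, 4)
    dt_seconds: float = DT_SECONDS
    n_dynamics: int = N_DYNAMICS
    aif: AifSpec = field(default_factory=AifSpec)
    regions: list[Region] = field(default_factory=list)
    artery_mask: np.ndarray | None = None
    s0: float = 100.0
    noise_sd_rel: float = 0.0  # noise SD relative to baseline signal
    noise_model: str = "gaussian"  # gaussian | rician
    R: float = 1.0
    seed: int = 0


@dataclass
class CohortSpec:
    """Effect-model specification for a fast-path ROI-level cohort.

    The composition defaults emulate the study cohort: 25 patients, 35
    lesions (29 peripheral zone, 6 transition zone; PI-RADS 3/4/5 in
    4/21/10; grade group neg/1/2/3/4 in 11/6/9/5/4) with one paired
    normal-appearing ROI per lesion.

    Effects are monotone location shifts per category level in units of
    the within-group SD: a lesion of PI-RADS p contributes
    ``pirads_effects[param] * level(p)`` SDs, with level(normal)=0 and
    level(3,4,5)=1,2,3; grade-group and zone effects are analogous.
    """

    n_patients: int = 25
    lesions_per_patient: tuple[int, ...] = (1,) * 16 + (2,) * 8 + (3,)
    n_pz: int = 29  # lesions in the peripheral zone (rest are TZ)
    pirads_counts: dict[int, int] = field(
        default_factory=lambda: {3: 4, 4: 21, 5: 10})
    gg_counts: dict[str, int] = field(
        default_factory=lambda: {"neg": 11, "1": 6, "2": 9, "3": 5, "4": 4})
    baselines: dict[str, float] = field(
        default_factory=lambda: dict(BASELINE_MEANS))
    noise_frac: float = 0.30  # within-group SD as a fraction of baseline
    pirads_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PIRADS_EFFECTS))
    gg_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GG_EFFECTS))
    zone_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_EFFECTS))
    seed: int = 0

    @property
    def n_lesions(self) -> int:
        return int(sum(self.lesions_per_patient))


#: Plausible ROI-mean magnitudes for normal peripheral zone, used as the
#: cohort baseline for each analysis parameter.
BASELINE_MEANS: dict[str, float] = {
    "vp": 1.761, "ps": 0.108, "fp": 1.363, "mttp": 1.439, "tc": 1.534,
    "e": 0.0861, "ktrans": 0.0938, "alpha": 0.0723,
    "a1_minus_t0": 16.671, "a2": 15.071, "ttp": 35.0,
}

#: Signed per-level shifts (SD units) emulating the observed pattern:
#: flow, extraction and enhancement rate rise with suspicion category
#: while transit and rise times shorten; vp, PS and Ktrans carry no
#: effect.
DEFAULT_PIRADS_EFFECTS: dict[str, float] = {
    "fp": 1.0, "mttp": -1.0, "tc": -1.0, "e": 1.0, "alpha": 1.0,
    "a1_minus_t0": -1.0, "a2": -1.0, "ttp": -1.0,
}

#: Grade-group shifts, same parameters, slightly weaker.
DEFAULT_GG_EFFECTS: dict[str, float] = {
    "fp": 0.8, "mttp": -0.8, "tc": -0.8, "e": 0.8, "alpha": 0.8,
    "a1_minus_t0": -0.8, "a2": -0.8, "ttp": -0.8,
}

#: Zone shifts (TZ relative to PZ): plasma flow and enhancement rate
#: are higher in the transition zone.
DEFAULT_ZONE_EFFECTS: dict[str, float] = {"fp": 1.0, "alpha": 1.5}


def make_aif(
    spec: AifSpec,
    n_dynamics: int = N_DYNAMICS,
    dt_seconds: float = DT_SECONDS,
) -> Aif:
    """Deterministic AIF on the acquisition grid.

    Zero before arrival; the impulse model concentrates unit area
    (1 on the minutes axis) in a single frame.
    """
    t = np.arange(n_dynamics) * dt_seconds
    arrival_frame = int(np.ceil(spec.arrival_s / dt_seconds))
    values = np.zeros(n_dynamics)
    if spec.model == "impulse":
        dt_min = dt_seconds / 60.0
        values[arrival_frame] = 1.0 / dt_min
    elif spec.model == "boxcar":
        on = (t >= spec.arrival_s) & (t < spec.arrival_s + spec.boxcar_duration_s)
        values[on] = spec.peak_amplitude
    elif spec.model == "gamma_variate":
        tau = t - spec.arrival_s
        pos = tau > 0
        g = np.zeros(n_dynamics)
        g[pos] = tau[pos] ** spec.shape_b * np.exp(-tau[pos] / spec.shape_c_s)
        peak = g.max()
        if peak > 0:
            g *= spec.peak_amplitude / peak
        if spec.recirculation:
            tau2 = t - spec.arrival_s - 20.0
            pos2 = tau2 > 0
            g2 = np.zeros(n_dynamics)
            g2[pos2] = tau2[pos2] ** spec.shape_b * np.exp(
                -tau2[pos2] / (3.0 * spec.shape_c_s))
            if g2.max() > 0:
                g2 *= 0.25 * spec.peak_amplitude / g2.max()
            plateau = 0.1 * spec.peak_amplitude * (1 - np.exp(
                -np.maximum(tau, 0) / 30.0))
            g = g + g2 + np.where(pos, plateau, 0.0)
        values = g
    else:
        raise DomainError(f"unknown AIF model '{spec.model}'")
    return Aif(values=values, dt_seconds=dt_seconds,
               arrival_frame=arrival_frame, source_voxel_count=0)


def _truth_concentration(
    model: str, params, aif: Aif, n_dynamics: int, dt_seconds: float
) -> np.ndarray:
    """Noise-free concentration curve on the full acquisition grid."""
    t_dyn = np.arange(n_dynamics, dtype=float)  # dynamics axis for EMMs
    if model == "2cu":
        b = params if isinstance(params, BiexpParams) else physio_to_biexp(params)
        times_min = t_dyn * dt_seconds / 60.0
        return forward_2cu(b, aif.values[:n_dynamics], times_min)
    if model == "exp_emm":
        return exp_emm_curve(params, t_dyn)
    if model == "sigmoid_emm":
        return sigmoid_emm_curve(params, t_dyn)
    raise DomainError(f"unknown truth model '{model}'")


def simulate_voxel(
    model: str,
    params,
    aif: Aif,
    n_dynamics: int = N_DYNAMICS,
    dt_seconds: float = DT_SECONDS,
    s0: float = 100.0,
    noise_sd_rel: float = 0.0,
    noise_model: str = "gaussian",
    R: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One synthetic signal curve: forward model, signal inversion, noise.

    The concentration curve is inverted through the linearized signal
    model ``S = S0 (1 + C/R)`` and corrupted with noise of SD
    ``noise_sd_rel * S0`` (Gaussian by default; Rician available, which
    matters only at very low SNR). Reproducible given the seed.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    conc = _truth_concentration(model, params, aif, n_dynamics, dt_seconds)
    signal = s0 * (1.0 + conc / R)
    sd = noise_sd_rel * s0
    if sd == 0:
        return signal
    if noise_model == "gaussian":
        return signal + rng.normal(0.0, sd, size=signal.shape)
    if noise_model == "rician":
        re = signal + rng.normal(0.0, sd, size=signal.shape)
        im = rng.normal(0.0, sd, size=signal.shape)
        return np.hypot(re, im)
    raise DomainError(f"unknown noise model '{noise_model}'")


def make_phantom(
    spec: PhantomSpec,
) -> tuple[DynamicSeries, dict[str, RoiMask], Aif, pd.DataFrame]:
    """Build a 4D phantom series with artery and tissue regions.

    Returns (series, masks, ground-truth AIF, truth table). The artery
    region carries the AIF concentration converted to signal; tissue
    regions follow their forward models; everything else is flat
    baseline. Region masks (including the artery) must be pairwise
    disjoint.
    """
    rng = np.random.default_rng(spec.seed)
    aif = make_aif(spec.aif, spec.n_dynamics, spec.dt_seconds)

    occupancy = np.zeros(spec.shape, dtype=int)
    if spec.artery_mask is not None:
        occupancy += spec.artery_mask.astype(int)
    for reg in spec.regions:
        if reg.mask.shape != spec.shape:
            raise GridMismatchError(f"region '{reg.name}' mask shape mismatch")
        occupancy += reg.mask.astype(int)
    if (occupancy > 1).any():
        raise GridMismatchError("phantom regions overlap")

    data = np.empty((*spec.shape, spec.n_dynamics))
    flat = spec.s0 * np.ones(spec.n_dynamics)
    data[...] = flat  # background
    curves: dict[str, np.ndarray] = {}
    if spec.artery_mask is not None:
        curves["artery"] = spec.s0 * (1.0 + aif.values / spec.R)
        data[spec.artery_mask.astype(bool)] = curves["artery"]
    truth_rows = []
    for reg in spec.regions:
        conc = _truth_concentration(reg.model, reg.params, aif,
                                    spec.n_dynamics, spec.dt_seconds)
        data[reg.mask.astype(bool)] = spec.s0 * (1.0 + conc / spec.R)
        truth_rows.append({"region": reg.name, "model": reg.model,
                           "params": reg.params,
                           "n_voxels": int(reg.mask.sum())})

    sd = spec.noise_sd_rel * spec.s0
    if sd > 0:
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, sd, size=data.shape)
        elif spec.noise_model == "rician":
            re = data + rng.normal(0.0, sd, size=data.shape)
            im = rng.normal(0.0, sd, size=data.shape)
            data = np.hypot(re, im)
        else:
            raise DomainError(f"unknown noise model '{spec.noise_model}'")

    series = DynamicSeries(data=data, dt_seconds=spec.dt_seconds)
    masks: dict[str, RoiMask] = {}
    if spec.artery_mask is not None:
        masks["artery"] = RoiMask(data=spec.artery_mask, label="artery")
    for reg in spec.regions:
        masks[reg.name] = RoiMask(data=reg.mask, label="lesion")
    truth = pd.DataFrame(truth_rows)
    return series, masks, aif, truth


def _pirads_level(pirads: int) -> int:
    return {1: 0, 3: 1, 4: 2, 5: 3}[pirads]


def _gg_level(gg: str) -> int:
    return 0 if gg == "neg" else int(gg)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Fast-path cohort table: ROI-level parameter means with labels.

    One lesion ROI and one paired normal-appearing ROI (same patient
    and zone) per lesion. For each parameter the ROI mean is drawn as

        baseline + (zone + PI-RADS + GG shifts) * sd + Normal(0, sd)

    with ``sd = noise_frac * |baseline|``. Returns the long-format
    cohort table used by the statistics module.
    """
    rng = np.random.default_rng(spec.seed)
    n_lesions = spec.n_lesions
    if sum(spec.pirads_counts.values()) != n_lesions:
        raise DomainError("PI-RADS counts must sum to the lesion count")
    if sum(spec.gg_counts.values()) != n_lesions:
        raise DomainError("grade-group counts must sum to the lesion count")
    if not 0 <= spec.n_pz <= n_lesions:
        raise DomainError("n_pz out of range")

    zones = np.array(["PZ"] * spec.n_pz + ["TZ"] * (n_lesions - spec.n_pz))
    pirads = np.concatenate(
        [np.full(n, p) for p, n in spec.pirads_counts.items()])
    ggs = np.concatenate(
        [np.full(n, g, dtype=object) for g, n in spec.gg_counts.items()])
    rng.shuffle(zones)
    rng.shuffle(pirads)
    rng.shuffle(ggs)

    rois = []  # (patient, roi_id, roi_type, zone, pirads, gg)
    lesion_idx = 0
    for pat, n_les in enumerate(spec.lesions_per_patient[: spec.n_patients]):
        pid = f"P{pat:03d}"
        for j in range(n_les):
            z = zones[lesion_idx]
            rois.append((pid, f"{pid}_L{j}", "lesion", z,
                         int(pirads[lesion_idx]), str(ggs[lesion_idx])))
            rois.append((pid, f"{pid}_N{j}", "normal", z, 1, "neg"))
            lesion_idx += 1

    params = sorted(spec.baselines)
    rows = []
    for param in params:
        base = spec.baselines[param]
        sd = spec.noise_frac * abs(base)
        eff_p = spec.pirads_effects.get(param, 0.0)
        eff_g = spec.gg_effects.get(param, 0.0)
        eff_z = spec.zone_effects.get(param, 0.0)
        for pid, roi_id, roi_type, zone, prd, gg in rois:
            shift = eff_z * sd * (zone == "TZ")
            if roi_type == "lesion":
                shift += eff_p * sd * _pirads_level(prd)
                shift += eff_g * sd * _gg_level(gg)
            value = base + shift + rng.normal(0.0, sd)
            rows.append({
                "patient_id": pid, "roi_id": roi_id, "roi_type": roi_type,
                "zone": zone, "pirads": prd, "gg": gg,
                "parameter": param, "mean": value,
                "sd": sd, "n_valid": 1,
            })
    return pd.DataFrame(rows)


def null_cohort(spec: CohortSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Cohort with every effect set to zero — the calibration null."""
    spec = spec or CohortSpec()
    spec = replace(spec, pirads_effects={}, gg_effects={}, zone_effects={},
                   seed=seed)
    return make_cohort(spec)
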