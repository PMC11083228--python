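"""Physiologically credible parameter ranges used to mask fitted values.

Each entry maps a parameter name to (low, high, low_inclusive,
high_inclusive, unit). Values outside the range are flagged invalid in
parameter maps and excluded from ROI summaries; the fit itself is not
constrained to these ranges. Parameters with no stated range (EMM
amplitudes and arrival times, TTP) are always considered in-range.

Units: kinetic parameters are in min^-1 / min / dimensionless; the
empirical-model time parameters are in dynamics (frame counts).
"""

from __future__ import annotations

import math

import numpy as np

#: (low, high, low_inclusive, high_inclusive, unit)
PARAMETER_RANGES: dict[str, tuple[float, float, bool, bool, str]] = {
    "vp": (0.0, 10.0, True, True, "mL/mL"),
    "ps": (0.0, 10.0, False, True, "min^-1"),
    "fp": (0.0, 10.0, True, True, "min^-1"),
    "tc": (0.0, 5.0, True, False, "min"),
    "mttp": (0.0, 5.0, True, False, "min"),
    "e": (0.0, 1.0, True, True, "dimensionless"),
    "ktrans": (0.0, 10.0, True, True, "min^-1"),
    "a": (-math.inf, math.inf, False, False, "concentration"),
    "alpha": (0.0, 1.0, False, True, "dynamics^-1"),
    "t0": (-math.inf, math.inf, False, False, "dynamics"),
    "a0": (-math.inf, math.inf, False, False, "concentration"),
    "a1_minus_t0": (0.0, 100.0, False, True, "dynamics"),
    "a2": (0.0, 100.0, False, True, "dynamics"),
    "ttp": (-math.inf, math.inf, False, False, "dynamics"),
}

#: Parameters entering the statistical analyses (amplitudes and arrival
#: times show negligible spatial contrast and are excluded).
ANALYSIS_PARAMETERS: tuple[str, ...] = (
    "vp", "ps", "fp", "mttp", "tc", "e", "ktrans",
    "alpha", "a1_minus_t0", "a2", "ttp",
)


def unit_of(name: str) -> str:
    return PARAMETER_RANGES[name][4]


def in_range(name: str, values: np.ndarray) -> np.ndarray:
    """Elementwise validity of ``values`` for parameter ``name``.

    NaN and infinite values are always invalid.
    """
    low, high, lo_inc, hi_inc, _ = PARAMETER_RANGES[name]
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    ok &= (values >= low) if lo_inc else (values > low)
    ok &= (values <= high) if hi_inc else (values < high)
    return ok
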