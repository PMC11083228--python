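"""Cohort statistics: zone t-test, two-way and one-way ANOVA, Tukey, BH.

Four principal analyses are run for each parameter on the ROI-level
means of the cohort table:

1. Welch t-test between normal-appearing peripheral (PZ) and
   transition/central (TZ) zones.
2. Two-way ANOVA over all ROIs with prostate zone (2 levels) and
   PI-RADS category (4 levels: normal-appearing = 1, then 3, 4, 5) as
   main effects — no interaction, Type II sums of squares, which is the
   appropriate decomposition for this heavily unbalanced design and
   yields exactly one p-value per factor.
3. Welch t-test of biopsy grade group negative vs positive (GG >= 1),
   peripheral-zone lesions only.
4. One-way ANOVA across five grade-group levels, peripheral zone only,
   with normal-appearing ROIs folded into the GG-negative level.

Parameters flagged significant in an ANOVA get Tukey HSD post-hoc
pairwise comparisons (Tukey–Kramer for unequal group sizes). The
ANOVA p-values — 2 factors x 11 parameters from the two-way table plus
11 from the one-way table, 33 in all — form a single Benjamini–Hochberg
family controlling the false discovery rate at q; the t-test families
are reported uncorrected.

Degenerate inputs fail soft: zero-variance data yields p = 1 with a
flag rather than an exception, so one flat parameter cannot kill a
cohort run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError
from .ranges import ANALYSIS_PARAMETERS

__all__ = [
    "StatsResult",
    "zone_ttest",
    "twoway_anova",
    "biopsy_ttest",
    "oneway_anova_gg",
    "tukey_hsd",
    "bh_correct",
    "run_all_stats",
    "gg_five_level",
]

DEFAULT_BH_Q = 0.05


@dataclass
class StatsResult:
    """Collected analysis tables for one cohort."""

    zone_table: pd.DataFrame  # parameter, mean_pz, mean_tz, p
    twoway_table: pd.DataFrame  # parameter, p_zone, p_pirads, BH flags
    gg_table: pd.DataFrame  # parameter, p_ttest, p_anova, BH flag
    tukey: dict[str, pd.DataFrame] = field(default_factory=dict)
    bh_family: pd.DataFrame | None = None


def _welch(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> float:
    """Two-sample t-test p-value with zero-variance conventions.

    When both groups have zero variance the test statistic is
    undefined; by convention p = 1 for equal means (no evidence of a
    difference) and p = 0 for unequal means (deterministic difference).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(p)


def _param_slice(table: pd.DataFrame, parameter: str) -> pd.DataFrame:
    sub = table[table["parameter"] == parameter]
    if sub.empty:
        raise InsufficientDataError(f"no rows for parameter '{parameter}'")
    return sub


def zone_ttest(
    table: pd.DataFrame, parameter: str, equal_var: bool = False
) -> float:
    """Normal-appearing PZ vs TZ comparison of one parameter's ROI means."""
    sub = _param_slice(table, parameter)
    sub = sub[sub["roi_type"] == "normal"]
    pz = sub.loc[sub["zone"] == "PZ", "mean"].to_numpy()
    tz = sub.loc[sub["zone"] == "TZ", "mean"].to_numpy()
    if len(pz) < 2 or len(tz) < 2:
        raise InsufficientDataError(
            f"zone t-test for '{parameter}' needs >= 2 normal ROIs per zone"
        )
    return _welch(pz, tz, equal_var=equal_var)


def twoway_anova(
    table: pd.DataFrame, parameter: str
) -> tuple[float, float, bool]:
    """Main-effects two-way ANOVA (zone + PI-RADS), Type II SS.

    Returns (p_zone, p_pirads, zero_variance_flag). All ROIs enter;
    normal-appearing tissue carries PI-RADS category 1.
    """
    sub = _param_slice(table, parameter)
    if sub["zone"].nunique() < 2 or sub["pirads"].nunique() < 2:
        raise InsufficientDataError(
            f"two-way ANOVA for '{parameter}' needs >= 2 levels per factor"
        )
    y = sub["mean"].to_numpy(float)
    if np.var(y) == 0:
        return 1.0, 1.0, True
    df = pd.DataFrame({
        "value": y,
        "zone": pd.Categorical(sub["zone"]),
        "pirads": pd.Categorical(sub["pirads"]),
    })
    model = smf.ols("value ~ C(zone) + C(pirads)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    return (
        float(aov.loc["C(zone)", "PR(>F)"]),
        float(aov.loc["C(pirads)", "PR(>F)"]),
        False,
    )


def biopsy_ttest(
    table: pd.DataFrame, parameter: str, equal_var: bool = False
) -> float:
    """GG-negative vs GG-positive lesions, peripheral zone only."""
    sub = _param_slice(table, parameter)
    sub = sub[(sub["roi_type"] == "lesion") & (sub["zone"] == "PZ")]
    neg = sub.loc[sub["gg"] == "neg", "mean"].to_numpy()
    pos = sub.loc[sub["gg"] != "neg", "mean"].to_numpy()
    if len(neg) < 2 or len(pos) < 2:
        raise InsufficientDataError(
            f"biopsy t-test for '{parameter}' needs both GG classes"
        )
    return _welch(neg, pos, equal_var=equal_var)


def gg_five_level(sub: pd.DataFrame) -> pd.Series:
    """Five-level grade grouping: normal-appearing ROIs and GG-negative
    biopsies share the 'neg' level; positive biopsies keep their GG."""
    return sub.apply(
        lambda r: "neg" if r["roi_type"] == "normal" or r["gg"] == "neg"
        else str(r["gg"]),
        axis=1,
    )


def oneway_anova_gg(
    table: pd.DataFrame, parameter: str
) -> tuple[float, bool]:
    """One-way ANOVA across five GG levels, peripheral zone only.

    Returns (p, zero_variance_flag).
    """
    sub = _param_slice(table, parameter)
    sub = sub[sub["zone"] == "PZ"]
    levels = gg_five_level(sub)
    groups = [
        sub.loc[levels == lev, "mean"].to_numpy(float)
        for lev in sorted(levels.unique())
    ]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise InsufficientDataError(
            f"one-way GG ANOVA for '{parameter}' needs >= 2 levels with "
            f">= 2 observations"
        )
    concat = np.concatenate(groups)
    if np.var(concat) == 0:
        return 1.0, True
    f, p = sps.f_oneway(*groups)
    return float(p), False


def tukey_hsd(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey–Kramer adjusted pairwise comparisons.

    Returns a table with columns group1, group2, meandiff, p_adj,
    reject. With two groups this reduces to the pooled-variance t-test.
    """
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise InsufficientDataError("Tukey HSD needs >= 2 groups")
    res = pairwise_tukeyhsd(np.asarray(values, float), groups, alpha=alpha)
    df = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )
    df = df.rename(columns={"p-adj": "p_adj"})
    df["p_adj"] = res.pvalues
    return df[["group1", "group2", "meandiff", "p_adj", "reject"]]


def bh_correct(
    p_values: np.ndarray, q: float = DEFAULT_BH_Q
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up over one family of p-values.

    Returns (reject_flags, adjusted_p). Controls the false discovery
    rate at level q for independent or positively dependent tests.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def run_all_stats(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = ANALYSIS_PARAMETERS,
    bh_q: float = DEFAULT_BH_Q,
    equal_var: bool = False,
    run_tukey: bool = True,
) -> StatsResult:
    """Run the four analyses per parameter and the BH family correction.

    Parameters absent from the table, or with too few groups, are
    skipped for the affected analysis (NaN in the output tables). The
    BH family is the concatenation of the two-way factor p-values and
    the one-way GG p-values across parameters.
    """
    zone_rows, two_rows, gg_rows = [], [], []
    for param in parameters:
        sub = table[table["parameter"] == param]
        norm = sub[sub["roi_type"] == "normal"]
        mean_pz = norm.loc[norm["zone"] == "PZ", "mean"].mean()
        mean_tz = norm.loc[norm["zone"] == "TZ", "mean"].mean()
        try:
            p_zone_t = zone_ttest(table, param, equal_var=equal_var)
        except InsufficientDataError:
            p_zone_t = np.nan
        zone_rows.append({"parameter": param, "mean_pz": mean_pz,
                          "mean_tz": mean_tz, "p": p_zone_t})

        try:
            pz2, pp2, _ = twoway_anova(table, param)
        except InsufficientDataError:
            pz2, pp2 = np.nan, np.nan
        two_rows.append({"parameter": param, "p_zone": pz2, "p_pirads": pp2})

        try:
            p_bt = biopsy_ttest(table, param, equal_var=equal_var)
        except InsufficientDataError:
            p_bt = np.nan
        try:
            p_gg, _ = oneway_anova_gg(table, param)
        except InsufficientDataError:
            p_gg = np.nan
        gg_rows.append({"parameter": param, "p_ttest": p_bt, "p_anova": p_gg})

    zone_table = pd.DataFrame(zone_rows)
    twoway_table = pd.DataFrame(two_rows)
    gg_table = pd.DataFrame(gg_rows)

    # One BH family across all ANOVA p-values (2 x n_params two-way
    # factors + n_params one-way GG tests).
    family = []
    for _, r in twoway_table.iterrows():
        family.append(("twoway_zone", r["parameter"], r["p_zone"]))
        family.append(("twoway_pirads", r["parameter"], r["p_pirads"]))
    for _, r in gg_table.iterrows():
        family.append(("oneway_gg", r["parameter"], r["p_anova"]))
    fam = pd.DataFrame(family, columns=["analysis", "parameter", "p"])
    known = fam["p"].notna().to_numpy()
    reject = np.zeros(len(fam), dtype=bool)
    p_adj = np.full(len(fam), np.nan)
    if known.any():
        rej, adj = bh_correct(fam.loc[known, "p"].to_numpy(), q=bh_q)
        reject[known] = rej
        p_adj[known] = adj
    fam["p_adjusted"] = p_adj
    fam["significant"] = reject

    def _flag(analysis, param):
        row = fam[(fam["analysis"] == analysis) & (fam["parameter"] == param)]
        return bool(row["significant"].iloc[0]) if len(row) else False

    twoway_table["sig_zone"] = [
        _flag("twoway_zone", p) for p in twoway_table["parameter"]]
    twoway_table["sig_pirads"] = [
        _flag("twoway_pirads", p) for p in twoway_table["parameter"]]
    gg_table["sig_anova"] = [
        _flag("oneway_gg", p) for p in gg_table["parameter"]]

    result = StatsResult(zone_table=zone_table, twoway_table=twoway_table,
                         gg_table=gg_table, bh_family=fam)

    if run_tukey:
        for _, r in twoway_table.iterrows():
            if r["sig_pirads"]:
                sub = table[table["parameter"] == r["parameter"]]
                result.tukey[f"pirads:{r['parameter']}"] = tukey_hsd(
                    sub["mean"].to_numpy(), sub["pirads"].to_numpy())
        for _, r in gg_table.iterrows():
            if r["sig_anova"]:
                sub = table[(table["parameter"] == r["parameter"])
                            & (table["zone"] == "PZ")]
                result.tukey[f"gg:{r['parameter']}"] = tukey_hsd(
                    sub["mean"].to_numpy(),
                    gg_five_level(sub).to_numpy())
    return result
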