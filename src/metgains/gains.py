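"""Check-relative yield and annual genetic-gain regression.

A line's predicted yield (BLUP plus mean site effect) is expressed
relative to the mean predicted yield of the long-term checks present in
its own trial series:

``GYC = (BLUP - MeanGY) / MeanGY * 100``

so the checks anchor cross-year comparison and their own mean GYC is
identically zero within every analysis unit.  The top decile of
non-check entries by GYC — the highest-yielding lines (HYLs) — is
selected within each series-by-environment-class unit; ordinary least
squares of the pooled HYL GYC values on the series index estimates the
annual rate of gain, in % per year and, via the class's mean check
yield, in kg/ha per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GainsError

GYC_COLUMNS = ["genotype_id", "series", "class", "gyc_pct", "predicted_yield_t_ha", "is_check", "is_hyl"]


@dataclass
class GainFit:
    """Annual gain estimate for one environment class."""

    class_label: str
    slope_pct_per_year: float
    slope_kg_per_ha_year: float
    intercept: float
    r_squared: float
    p_value_slope: float
    n_points: int
    mean_check_yield_t_ha: float
    hyl_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "class": self.class_label,
            "slope_pct": self.slope_pct_per_year,
            "slope_kg": self.slope_kg_per_ha_year,
            "intercept": self.intercept,
            "r2": self.r_squared,
            "p": self.p_value_slope,
            "n": self.n_points,
            "mean_check_yield_t_ha": self.mean_check_yield_t_ha,
            "hyl_ids": list(self.hyl_ids),
        }


def compute_gyc(
    blups: pd.DataFrame, check_ids, series: int, class_label: str
) -> pd.DataFrame:
    """Express predicted yields relative to the checks of one unit.

    ``blups`` is the blup_table output (genotype_id, is_check,
    predicted_yield_t_ha); ``check_ids`` are the checks present in this
    series per the check roster.  Only checks actually in the table are
    used for the mean.
    """
    present = [c for c in check_ids if c in set(blups["genotype_id"])]
    if not present:
        raise GainsError(f"no check present in series {series}, class {class_label}")
    mean_gy = float(
        blups.loc[blups["genotype_id"].isin(present), "predicted_yield_t_ha"].mean()
    )
    if mean_gy <= 0:
        raise GainsError(
            f"non-positive check mean yield ({mean_gy:.3f}) in series {series}, class {class_label}"
        )
    out = blups.copy()
    out["gyc_pct"] = (out["predicted_yield_t_ha"] - mean_gy) / mean_gy * 100.0
    out["series"] = series
    out["class"] = class_label
    out["is_check"] = out["genotype_id"].isin(present) | out["is_check"].astype(bool)
    out["is_hyl"] = False
    return out[GYC_COLUMNS]


def select_hyl(records: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Flag the top ``fraction`` of non-check entries by GYC.

    Selection is within each (series, class) unit; the count is
    ``ceil(fraction * n_noncheck)``; ties are broken by genotype_id so
    the flagged set is deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise GainsError(f"fraction must be in (0, 1], got {fraction}")
    out = records.copy()
    out["is_hyl"] = False
    for (_, _), idx in out.groupby(["series", "class"], sort=False).groups.items():
        unit = out.loc[idx]
        nonchecks = unit[~unit["is_check"].astype(bool)]
        n_take = math.ceil(fraction * len(nonchecks))
        top = nonchecks.sort_values(
            ["gyc_pct", "genotype_id"], ascending=[False, True], kind="stable"
        ).head(n_take)
        out.loc[top.index, "is_hyl"] = True
    return out


def gain_regression(
    records: pd.DataFrame, class_label: str, per_series_mean: bool = False
) -> GainFit:
    """OLS of HYL GYC on series index for one environment class.

    By default each HYL line contributes one point (per-line mode); with
    ``per_series_mean`` the series-mean GYC values are regressed
    instead.  The %/yr slope converts to kg/ha/yr through the class's
    mean check predicted yield.
    """
    recs = records[(records["class"] == class_label) & records["is_hyl"]]
    if recs["series"].nunique() < 2:
        raise GainsError(
            f"gain regression for {class_label} needs >= 2 distinct series, "
            f"found {recs['series'].nunique()}"
        )
    if per_series_mean:
        pts = recs.groupby("series")["gyc_pct"].mean().reset_index()
        x, y = pts["series"].to_numpy(float), pts["gyc_pct"].to_numpy(float)
    else:
        x = recs["series"].to_numpy(dtype=float)
        y = recs["gyc_pct"].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    r2 = 0.0 if np.var(y) == 0 else float(res.rvalue**2)
    checks = records[(records["class"] == class_label) & records["is_check"].astype(bool)]
    mean_check = float(checks["predicted_yield_t_ha"].mean())
    slope_pct = float(res.slope)
    # kg/ha/yr = %/yr of the check yield; 1 t/ha = 1000 kg/ha
    slope_kg = slope_pct / 100.0 * mean_check * 1000.0
    return GainFit(
        class_label=class_label,
        slope_pct_per_year=slope_pct,
        slope_kg_per_ha_year=slope_kg,
        intercept=float(res.intercept),
        r_squared=r2,
        p_value_slope=float(res.pvalue) if not math.isnan(res.pvalue) else 1.0,
        n_points=len(x),
        mean_check_yield_t_ha=mean_check,
        hyl_ids=sorted(recs["genotype_id"].unique()),
    )


def plot_gain(records: pd.DataFrame, fit: GainFit, ax=None):
    """Scatter of HYL GYC by series with the fitted gain line (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    recs = records[(records["class"] == fit.class_label) & records["is_hyl"]]
    ax.scatter(recs["series"], recs["gyc_pct"], s=12, alpha=0.6)
    xs = np.array(sorted(recs["series"].unique()), dtype=float)
    ax.plot(xs, fit.intercept + fit.slope_pct_per_year * xs, color="k")
    ax.set_xlabel("trial series (year index)")
    ax.set_ylabel("GYC (% of check yield)")
    ax.set_title(
        f"{fit.class_label}: {fit.slope_pct_per_year:.2f} %/yr, R$^2$={fit.r_squared:.2f}"
    )
    return ax
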