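"""Cohort- and cluster-level descriptive summaries.

Receipt-by-gestational-age tables (the fraction of infants receiving each
component on at least one day, with survival), postmenstrual-age time curves
of component administration among infants still in care, per-cluster
proportion histograms and normalised-stay timelines, and the size of the
theoretically possible pattern space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import COMPONENTS
from .errors import DataError


def receipt_by_ga(infants: pd.DataFrame, nutrition_any: pd.DataFrame,
                  ga_range=range(22, 32)) -> pd.DataFrame:
    """Percentage of infants receiving each component on >= 1 day, by GA week.

    ``nutrition_any`` holds per-infant booleans (component received on at
    least one day); rows for empty GA strata are omitted.  The Total row is
    the pooled computation over all infants, not a mean of strata.
    """
    ga = pd.to_numeric(infants["ga_weeks"], errors="coerce")
    survival = 100.0 * (1.0 - pd.to_numeric(infants["mortality"], errors="coerce"))
    rows = []
    for week in ga_range:
        mask = ga == week
        if not mask.any():
            continue
        rec = 100.0 * nutrition_any[mask.to_numpy()].mean(axis=0)
        rows.append([week, int(mask.sum())] + list(rec) + [survival[mask].mean()])
    rec = 100.0 * nutrition_any.mean(axis=0)
    rows.append(["Total", len(infants)] + list(rec) + [survival.mean()])
    return pd.DataFrame(rows, columns=["ga_weeks", "n"] + COMPONENTS
                        + ["survival"]).set_index("ga_weeks")


def component_time_curves(complete_daily: pd.DataFrame, infants: pd.DataFrame,
                          min_ga: int = 23) -> pd.DataFrame:
    """Per postmenstrual week: fraction of infants in care receiving each
    component, stratified by gestational-age group.

    The denominator at each postmenstrual week counts infants still in care
    that week; the numerator counts those receiving the component on at
    least one day of that week.  The lowest GA stratum (22 weeks) is
    excluded by default because of its small size.
    """
    ga = pd.to_numeric(infants["ga_weeks"], errors="coerce")
    d = complete_daily.merge(ga.rename("ga_weeks_adm"), left_on="infant_id",
                             right_index=True, how="inner")
    d = d[d["ga_weeks_adm"] >= min_ga]
    d["pm_week"] = (d["ga_weeks_adm"] * 7 + d["postnatal_day"]) // 7
    grouped = d.groupby(["ga_weeks_adm", "pm_week"])
    denominators = grouped["infant_id"].nunique()
    rows = []
    for (ga_w, pm_w), grp in grouped:
        denom = denominators.loc[(ga_w, pm_w)]
        rec = grp.groupby("infant_id")[COMPONENTS].max().sum(axis=0) / denom
        rows.append([ga_w, pm_w, denom] + list(rec))
    return pd.DataFrame(rows, columns=["ga_weeks", "pm_week", "n_in_care"]
                        + COMPONENTS)


def pattern_histograms(nutrition: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Per-component proportion histograms: an exact-zero bin plus ``n_bins``
    width-0.1 bins over (0, 1].  Masses sum to 1 per component."""
    if len(nutrition) == 0:
        raise DataError("at least one infant is required")
    out = {}
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    for comp in COMPONENTS:
        values = nutrition[comp].to_numpy(dtype=float)
        zero = float(np.mean(values == 0.0))
        pos = values[values > 0.0]
        hist, _ = np.histogram(pos, bins=edges)
        out[comp] = [zero] + list(hist / len(values))
    labels = ["0"] + [f"({edges[i]:.1f},{edges[i + 1]:.1f}]" for i in range(n_bins)]
    return pd.DataFrame(out, index=pd.Index(labels, name="bin"))


def pattern_timelines(complete_daily: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Mean administration of each component over normalised stay time.

    Day ``d`` of a stay spanning days ``0..T-1`` falls into bin
    ``floor(n_bins * d / T)`` (last day clamped).  A bin value of 1 means
    every infant received the component on every day in that bin.
    """
    if complete_daily.empty:
        raise DataError("at least one infant-day is required")
    d = complete_daily.copy()
    grp = d.groupby("infant_id")["postnatal_day"]
    first = grp.transform("min")
    length = grp.transform("max") - first + 1
    rel = d["postnatal_day"] - first
    d["bin"] = np.minimum((n_bins * rel // length).astype(int), n_bins - 1)
    per_infant = d.groupby(["infant_id", "bin"])[COMPONENTS].mean()
    return per_infant.groupby("bin").mean().reindex(range(n_bins))


def count_pattern_space(n_components: int = 6, los: int = 49,
                        include_endpoint: bool = False) -> int:
    """Number of distinct per-component day-count combinations for a stay.

    With ``los`` admissible day-count values per component the count is
    ``los ** n_components`` (for six components over a 49-day stay this is
    13,841,287,201, about 13.8 billion).  ``include_endpoint`` switches to
    ``(los + 1) ** n_components``, counting both endpoints of 0..los.
    """
    if n_components < 1 or los < 1:
        raise DataError("n_components and los must be positive")
    base = los + 1 if include_endpoint else los
    return int(base) ** int(n_components)
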