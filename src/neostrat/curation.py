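"""Registry curation: one complete record per infant per day.

Converts the episodic admission table and the daily event table into derived
admission variables, outcome variables and the N x 6 proportion-of-days
nutrition encoding:

* episodic constants are resolved by last-observation-carried-forward over
  episodes ordered by admission time;
* daily entries sharing a midnight-normalised timestamp (unit transfers) are
  merged by taking the union of non-missing events;
* day entries with any missing nutrition field are removed;
* each infant's clock is reset to zero at the first daily entry, with
  postnatal age carried from the recorded birth time;
* length of stay is the difference between the last and first day in care,
  and the nutrition encoding divides per-component day-counts by the number
  of retained complete days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COMPONENTS, ADMISSION_VARS, OUTCOME_VARS
from .errors import DataError
from .lms import LMSReference

logger = logging.getLogger(__name__)

_LOCF_FIELDS = [
    "birth_time", "ga_weeks", "birth_weight_g", "sex", "antenatal_steroids",
    "resuscitation", "apgar1", "apgar5", "apgar10", "imd_decile", "smoking",
    "discharge_destination", "severe_nec",
]


def read_episodes(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["admission_time", "birth_time"])


def read_daily(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["timestamp"])


def locf_episodic(episodes: pd.DataFrame) -> pd.DataFrame:
    """Resolve per-infant admission constants by LOCF over time-ordered episodes.

    For each variable the last non-missing value wins; an all-missing variable
    stays missing (the infant is excluded later if it is required).  Episodes
    sharing an identical admission time keep their input order, so the last
    row wins the tie (logged).
    """
    eps = episodes.copy()
    eps["_order"] = np.arange(len(eps))
    dup = eps.duplicated(subset=["infant_id", "admission_time"], keep=False)
    if dup.any():
        logger.warning("LOCF tie-break: %d episodes share an admission time; "
                       "stable input order used, last row wins", int(dup.sum()))
    eps = eps.sort_values(["infant_id", "admission_time", "_order"], kind="stable")
    grouped = eps.groupby("infant_id", sort=True)
    fields = [c for c in _LOCF_FIELDS if c in eps.columns]
    adm = grouped[fields].last()          # last() skips missing values
    adm["region"] = grouped["region"].last()
    adm["n_regions"] = grouped["region"].nunique(dropna=True)
    adm["n_episodes"] = grouped.size()
    if "birth_time" in adm.columns:
        adm["birth_year"] = pd.to_datetime(adm["birth_time"]).dt.year
    return adm


def merge_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows with equal (infant, day) by the union of non-missing events.

    Binary fields take the logical OR over non-missing entries and stay
    missing only if missing everywhere; continuous fields take the maximum of
    the non-missing entries.  Idempotent.
    """
    d = daily.copy()
    d["timestamp"] = pd.to_datetime(d["timestamp"]).dt.normalize()
    agg_cols = [c for c in COMPONENTS + ["weight_g", "respiratory_support"]
                if c in d.columns]
    merged = (d.groupby(["infant_id", "timestamp"], as_index=False, sort=True)
                [agg_cols].max())
    return merged


def drop_incomplete_days(daily: pd.DataFrame) -> pd.DataFrame:
    """Remove day entries with any missing nutrition field."""
    complete = daily.dropna(subset=COMPONENTS)
    n_dropped = len(daily) - len(complete)
    if n_dropped:
        logger.info("dropped %d incomplete day entries (%.1f%%)",
                    n_dropped, 100 * n_dropped / len(daily))
    return complete.reset_index(drop=True)


def _with_postnatal_day(complete: pd.DataFrame,
                        birth_time: pd.Series) -> pd.DataFrame:
    """Attach the postnatal day: age in days from birth to each entry.

    The first entry resets the infant's clock; where the birth time is
    unrecorded the first entry is taken as day zero.
    """
    out = complete.copy()
    birth = out["infant_id"].map(birth_time)
    first = out.groupby("infant_id")["timestamp"].transform("min")
    birth = birth.fillna(first)
    out["postnatal_day"] = (out["timestamp"] - pd.to_datetime(birth)).dt.days
    return out


def compute_los(complete: pd.DataFrame) -> pd.Series:
    """Length of stay: last minus first retained day, per infant."""
    if complete.empty:
        return pd.Series(dtype=int, name="los")
    days = complete.groupby("infant_id")["postnatal_day"]
    return (days.max() - days.min()).rename("los")


def encode_proportions(complete: pd.DataFrame,
                       denominator: str = "complete_days") -> pd.DataFrame:
    """Per-infant proportion-of-days encoding (the N x 6 nutrition matrix).

    ``denominator="complete_days"`` divides day-counts by the number of
    retained complete days (entries <= 1 by construction, the default);
    ``denominator="los"`` divides by the last-minus-first day span.
    Zero-denominator infants are excluded.
    """
    if denominator not in ("complete_days", "los"):
        raise DataError(f"unknown denominator convention: {denominator}")
    grouped = complete.groupby("infant_id")
    counts = grouped[COMPONENTS].sum()
    if denominator == "complete_days":
        denom = grouped.size()
    else:
        denom = compute_los(complete)
    keep = denom > 0
    if not keep.all():
        logger.info("excluded %d infants with zero encoding denominator",
                    int((~keep).sum()))
    matrix = counts[keep].div(denom[keep], axis=0)
    matrix.columns = COMPONENTS
    return matrix


def derive_outcomes(admission: pd.DataFrame, complete: pd.DataFrame,
                    reference: LMSReference) -> pd.DataFrame:
    """Derive the seven outcome variables per infant from the curated trajectory.

    Mortality comes from the LOCF discharge destination; chronic lung disease
    (BPD) from the respiratory-support flag on the day postmenstrual age
    reaches 36 weeks; maternal milk at discharge from the last two days in
    care; the 36-week weight z-score from the recorded weight on that day via
    the LMS reference.  BPD and the 36-week measures are NA for infants who
    died before 36 weeks postmenstrual age; a survivor discharged earlier has
    BPD 0 and a missing 36-week z-score with a reason code.
    """
    grouped = complete.groupby("infant_id")
    first_day = grouped["postnatal_day"].min()
    last_day = grouped["postnatal_day"].max()
    out = pd.DataFrame(index=admission.index)
    out["mortality"] = (admission["discharge_destination"] == "death").astype(float)
    out["severe_nec"] = pd.to_numeric(admission["severe_nec"], errors="coerce")
    out["los"] = (last_day - first_day).reindex(admission.index)

    ga = pd.to_numeric(admission["ga_weeks"], errors="coerce")
    d36 = 36 * 7 - 7 * ga

    # maternal milk on either of the last two days in care
    tail_limit = complete["infant_id"].map(last_day) - 1
    tail = complete[complete["postnatal_day"] >= tail_limit]
    mm_tail = tail.groupby("infant_id")["MM"].max()
    out["mm_at_discharge"] = mm_tail.reindex(admission.index)

    death_day = out["los"] + first_day.reindex(admission.index)
    died_before_36 = (out["mortality"] == 1) & (death_day < d36)

    # rows on the 36-week postmenstrual-age day
    row_d36 = complete["infant_id"].map(d36)
    at36 = complete[complete["postnatal_day"] == row_d36]
    resp36 = (at36.groupby("infant_id")["respiratory_support"].max()
              if "respiratory_support" in at36.columns else pd.Series(dtype=float))
    w36_weight = (at36.groupby("infant_id")["weight_g"].max()
                  if "weight_g" in at36.columns else pd.Series(dtype=float))

    in_window = (d36 >= first_day.reindex(admission.index)) & \
                (d36 <= last_day.reindex(admission.index))
    resp36 = resp36.reindex(admission.index)
    bpd = pd.Series(np.nan, index=admission.index)
    bpd[in_window & resp36.notna()] = resp36[in_window & resp36.notna()]
    discharged_early = (~in_window) & (d36 > last_day.reindex(admission.index))
    bpd[discharged_early & (out["mortality"] == 0)] = 0.0
    bpd[died_before_36] = np.nan
    out["bpd"] = bpd

    w36 = pd.Series(np.nan, index=admission.index)
    reason = pd.Series("ok", index=admission.index)
    w36_weight = w36_weight.reindex(admission.index)
    measurable = in_window & w36_weight.notna() & ~died_before_36
    if measurable.any():
        sub = admission.loc[measurable]
        z = [reference.zscore(w36_weight.loc[i], sub.loc[i, "sex"],
                              ga.loc[i], int(d36.loc[i]))
             for i in sub.index]
        w36.loc[measurable] = z
    reason[died_before_36] = "died_before_36w"
    reason[(~died_before_36) & discharged_early] = "discharged_before_36w"
    reason[(~died_before_36) & ~discharged_early & ~measurable] = "day_missing"
    w36[died_before_36] = np.nan
    out["w36_zscore"] = w36
    out["w36_reason"] = reason
    out["w36dz"] = out["w36_zscore"] - pd.to_numeric(admission.get("bw_zscore"),
                                                     errors="coerce")
    out["in_care_at_36w"] = (in_window & ~died_before_36).astype(int)
    return out


def apply_cohort_filters(infants: pd.DataFrame,
                         birth_window=("2012-01-01", "2018-07-01"),
                         max_ga_weeks: int = 32) -> tuple[pd.DataFrame, dict]:
    """Retain very-preterm infants with in-window births, single-region care
    and at least one complete day; returns (filtered, exclusion counts)."""
    ga = pd.to_numeric(infants["ga_weeks"], errors="coerce")
    birth = pd.to_datetime(infants["birth_time"])
    lo, hi = pd.Timestamp(birth_window[0]), pd.Timestamp(birth_window[1])
    keep_ga = ga < max_ga_weeks
    keep_window = (birth >= lo) & (birth < hi)
    keep_region = infants["n_regions"] <= 1
    keep_days = infants["complete_days"].fillna(0) > 0
    keep = keep_ga & keep_window & keep_region & keep_days
    exclusions = {
        "ga_out_of_range": int((~keep_ga).sum()),
        "birth_out_of_window": int((~keep_window).sum()),
        "multi_region_care": int((~keep_region).sum()),
        "no_complete_days": int((~keep_days).sum()),
        "retained": int(keep.sum()),
    }
    if int((~keep).sum()):
        logger.info("cohort filters: %s", exclusions)
    return infants[keep].copy(), exclusions


@dataclass
class CuratedCohort:
    """Curated per-infant table plus the nutrition encoding matrix."""

    infants: pd.DataFrame             # admission + outcome + region, by infant
    nutrition: pd.DataFrame           # N x 6 proportion-of-days matrix
    exclusions: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        return self.nutrition.to_numpy(dtype=float)


def curate(episodes: pd.DataFrame, daily: pd.DataFrame,
           reference: LMSReference | None = None,
           denominator: str = "complete_days",
           birth_window=("2012-01-01", "2018-07-01")) -> CuratedCohort:
    """Run the full curation stage and return the analysis-ready cohort."""
    if reference is None:
        reference = LMSReference.synthetic()
    adm = locf_episodic(episodes)
    merged = merge_daily(daily)
    complete = drop_incomplete_days(merged)
    complete = _with_postnatal_day(complete, adm["birth_time"])

    # birth-weight z-score from the LMS reference at day zero
    bw = pd.to_numeric(adm.get("birth_weight_g"), errors="coerce")
    bw_z = [reference.zscore(bw.loc[i], adm.loc[i, "sex"], adm.loc[i, "ga_weeks"], 0)
            if np.isfinite(bw.loc[i]) and pd.notna(adm.loc[i, "sex"])
            and pd.notna(adm.loc[i, "ga_weeks"]) else np.nan
            for i in adm.index]
    adm["bw_zscore"] = bw_z

    outcomes = derive_outcomes(adm, complete, reference)
    infants = adm.drop(columns=["severe_nec"], errors="ignore").join(outcomes)
    infants["complete_days"] = complete.groupby("infant_id").size().reindex(infants.index)
    infants, exclusions = apply_cohort_filters(infants, birth_window=birth_window)

    nutrition = encode_proportions(
        complete[complete["infant_id"].isin(infants.index)], denominator=denominator)
    nutrition = nutrition.reindex(infants.index).dropna()
    infants = infants.loc[nutrition.index]
    keep_cols = ([c for c in ADMISSION_VARS if c in infants.columns]
                 + ["region", "birth_time", "n_regions", "n_episodes",
                    "complete_days", "in_care_at_36w", "w36_reason"]
                 + [c for c in OUTCOME_VARS if c in infants.columns])
    return CuratedCohort(infants=infants[keep_cols], nutrition=nutrition,
                         exclusions=exclusions)
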