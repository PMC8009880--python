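import itertools

import numpy as np
import pandas as pd
import pytest

import neostrat as ns
from neostrat.constants import COMPONENTS
from neostrat.curation import _with_postnatal_day, derive_outcomes
from neostrat.lms import LMSReference


def _episodes(rows):
    cols = ["infant_id", "admission_time", "region", "ga_weeks", "birth_time",
            "sex", "birth_weight_g", "discharge_destination", "severe_nec"]
    out = pd.DataFrame(rows, columns=cols[:len(rows[0])])
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    out["admission_time"] = pd.to_datetime(out["admission_time"])
    return out


class TestLocf:
    def test_last_non_missing_wins(self):
        eps = _episodes([
            ("a", "2015-01-01", "North", 28.0),
            ("a", "2015-02-01", "North", 29.0),
            ("a", "2015-03-01", "North", np.nan),
        ])
        adm = ns.locf_episodic(eps)
        assert adm.loc["a", "ga_weeks"] == 29.0

    def test_single_episode_passthrough(self):
        adm = ns.locf_episodic(_episodes([("a", "2015-01-01", "South", 30.0)]))
        assert adm.loc["a", "ga_weeks"] == 30.0
        assert adm.loc["a", "n_regions"] == 1

    def test_all_missing_stays_missing(self):
        eps = _episodes([("a", "2015-01-01", "South", np.nan),
                         ("a", "2015-02-01", "South", np.nan)])
        assert np.isnan(ns.locf_episodic(eps).loc["a", "ga_weeks"])

    def test_identical_timestamps_last_input_row_wins(self):
        eps = _episodes([("a", "2015-01-01", "South", 27.0),
                         ("a", "2015-01-01", "South", 31.0)])
        assert ns.locf_episodic(eps).loc["a", "ga_weeks"] == 31.0

    def test_multi_region_counted(self):
        eps = _episodes([("a", "2015-01-01", "South", 27.0),
                         ("a", "2015-02-01", "London", np.nan)])
        assert ns.locf_episodic(eps).loc["a", "n_regions"] == 2


def _daily(rows):
    out = pd.DataFrame(rows, columns=["infant_id", "timestamp"] + COMPONENTS)
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    return out


class TestMergeDaily:
    def test_union_of_partial_records(self):
        d = _daily([
            ("a", "2015-01-02", 1, np.nan, np.nan, np.nan, np.nan, np.nan),
            ("a", "2015-01-02", np.nan, np.nan, np.nan, 1, np.nan, np.nan),
        ])
        merged = ns.merge_daily(d)
        assert len(merged) == 1
        assert merged.loc[0, "MM"] == 1 and merged.loc[0, "FM"] == 1
        assert np.isnan(merged.loc[0, "HDM"])

    def test_single_row_unchanged(self):
        d = _daily([("a", "2015-01-02", 1, 0, 0, 0, 1, 0)])
        merged = ns.merge_daily(d)
        assert merged[COMPONENTS].iloc[0].tolist() == [1, 0, 0, 0, 1, 0]

    @pytest.mark.parametrize("v1,v2", list(itertools.product([0.0, 1.0, np.nan],
                                                             repeat=2)))
    def test_or_semantics_exhaustive_two_rows(self, v1, v2):
        """Union semantics verified against the exhaustive 2-row truth table:
        OR over non-missing entries; missing only if missing in both."""
        d = _daily([("a", "2015-01-02", v1, 0, 0, 0, 0, 0),
                    ("a", "2015-01-02", v2, 0, 0, 0, 0, 0)])
        got = ns.merge_daily(d).loc[0, "MM"]
        present = [v for v in (v1, v2) if not np.isnan(v)]
        expected = max(present) if present else np.nan
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_idempotent(self, small_cohort):
        _, _, daily, _ = small_cohort
        once = ns.merge_daily(daily)
        twice = ns.merge_daily(once)
        pd.testing.assert_frame_equal(once, twice)


class TestDropIncompleteDays:
    def test_row_with_missing_field_removed(self):
        d = _daily([("a", "2015-01-02", 1, np.nan, 0, 0, 0, 0),
                    ("a", "2015-01-03", 1, 0, 0, 0, 0, 0)])
        kept = ns.drop_incomplete_days(d)
        assert len(kept) == 1

    def test_complete_table_unchanged(self, small_cohort):
        _, _, daily, _ = small_cohort
        merged = ns.merge_daily(daily)
        assert len(ns.drop_incomplete_days(merged)) == len(merged)

    def test_retained_fraction_binomial(self, small_cohort):
        """With per-field missingness rate r, a day survives with prob (1-r)^6."""
        _, _, daily, _ = small_cohort
        merged = ns.merge_daily(daily)
        injected = ns.inject_missingness(merged, 0.1, seed=21)
        frac = len(ns.drop_incomplete_days(injected)) / len(merged)
        assert abs(frac - 0.9 ** 6) < 0.02


class TestLosAndEncoding:
    def test_los_is_span_of_days(self):
        d = _daily([("a", "2015-01-04", 1, 0, 0, 0, 0, 0),
                    ("a", "2015-02-22", 1, 0, 0, 0, 0, 0)])
        d = _with_postnatal_day(d, pd.Series(dtype="datetime64[ns]"))
        assert ns.compute_los(d).loc["a"] == 49

    def test_single_day_is_zero(self):
        d = _daily([("a", "2015-01-04", 1, 0, 0, 0, 0, 0)])
        d = _with_postnatal_day(d, pd.Series(dtype="datetime64[ns]"))
        assert ns.compute_los(d).loc["a"] == 0

    def test_planted_stay_recovered(self, small_curated, small_cohort):
        _, _, _, truth = small_cohort
        los = small_curated.infants["los"]
        assert (los == truth.day_counts.loc[los.index, "los"]).all()

    def test_half_days_encode_to_half(self):
        rows = [("a", f"2015-01-{d:02d}", 1 if d <= 25 else 0, 0, 0, 0, 1, 0)
                for d in range(1, 31)]
        d = _with_postnatal_day(_daily(rows), pd.Series(dtype="datetime64[ns]"))
        enc = ns.encode_proportions(d)
        assert enc.loc["a", "MM"] == pytest.approx(25 / 30)
        assert enc.loc["a", "PN"] == 1.0
        assert enc.loc["a", "HDM"] == 0.0

    def test_entries_in_unit_interval(self, small_curated):
        values = small_curated.nutrition.to_numpy()
        assert values.min() >= 0.0 and values.max() <= 1.0

    def test_round_trip_exact(self, small_curated, small_cohort):
        """Missingness-free curation reproduces planted day-counts exactly."""
        _, _, _, truth = small_cohort
        dc = truth.day_counts.loc[small_curated.nutrition.index]
        expected = dc[COMPONENTS].div(dc["n_days"], axis=0)
        assert (small_curated.nutrition == expected).to_numpy().all()


class TestOutcomes:
    def test_mm_on_final_day_counts_as_discharge_mm(self):
        ref = LMSReference.synthetic(max_postnatal_day=60)
        rows = [("a", f"2015-01-{d:02d}", 1 if d == 10 else 0, 0, 0, 0, 0, 0)
                for d in range(1, 11)]
        daily = _with_postnatal_day(_daily(rows), pd.Series(dtype="datetime64[ns]"))
        adm = pd.DataFrame({"ga_weeks": [28], "sex": [0],
                            "discharge_destination": ["home"],
                            "severe_nec": [0], "bw_zscore": [0.0]},
                           index=pd.Index(["a"], name="infant_id"))
        out = derive_outcomes(adm, daily, ref)
        assert out.loc["a", "mm_at_discharge"] == 1

    def test_death_before_36_weeks_nulls_bpd_and_w36(self, small_curated,
                                                     small_cohort):
        _, _, _, truth = small_cohort
        infants = small_curated.infants
        died_early = (infants["mortality"] == 1) & \
                     (infants["ga_weeks"] * 7 + infants["los"] < 36 * 7)
        assert died_early.any()
        assert infants.loc[died_early, "bpd"].isna().all()
        assert infants.loc[died_early, "w36_zscore"].isna().all()
        assert infants.loc[died_early, "w36dz"].isna().all()

    def test_w36dz_is_difference_of_zscores(self, small_curated):
        infants = small_curated.infants
        defined = infants["w36dz"].notna()
        assert defined.any()
        np.testing.assert_allclose(
            infants.loc[defined, "w36dz"],
            infants.loc[defined, "w36_zscore"] - infants.loc[defined, "bw_zscore"])

    def test_outcomes_match_planted_truth(self, small_curated, small_cohort):
        _, _, _, truth = small_cohort
        infants = small_curated.infants
        planted = truth.outcomes.loc[infants.index]
        assert (infants["mortality"] == planted["mortality"]).all()
        assert (infants["severe_nec"] == planted["severe_nec"]).all()
        assert (infants["mm_at_discharge"] == planted["mm_at_discharge"]).all()
        both = infants["w36_zscore"].notna()
        assert (both == planted["w36_zscore"].notna()).all()
        np.testing.assert_allclose(infants.loc[both, "w36_zscore"],
                                   planted.loc[both, "w36_zscore"], atol=1e-9)


class TestCohortFilters:
    def _infants(self, **overrides):
        base = {"ga_weeks": 28, "birth_time": pd.Timestamp("2015-06-01"),
                "n_regions": 1, "complete_days": 40}
        base.update(overrides)
        return pd.DataFrame([base], index=["a"])

    def test_ga_32_excluded(self):
        kept, excl = ns.apply_cohort_filters(self._infants(ga_weeks=32))
        assert len(kept) == 0 and excl["ga_out_of_range"] == 1

    def test_multi_region_excluded(self):
        kept, excl = ns.apply_cohort_filters(self._infants(n_regions=2))
        assert len(kept) == 0 and excl["multi_region_care"] == 1

    def test_out_of_window_birth_excluded(self):
        kept, _ = ns.apply_cohort_filters(
            self._infants(birth_time=pd.Timestamp("2018-09-01")))
        assert len(kept) == 0

    def test_all_eligible_synthetic_cohort_untouched(self, small_curated):
        assert small_curated.exclusions["retained"] == 400
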