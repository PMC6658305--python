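import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from pvfever.config import AnalysisConfig
from pvfever import episodes as ep
from pvfever.simulate import build_cascade_fixture
from oracles import grid_episode, random_reading_set


class TestImputeLinear:
    def test_midpoint_of_a_segment(self):
        curve = ep.impute_linear([0.0, 6.0], [37.0, 39.0])
        assert curve(3.0) == pytest.approx(38.0)

    def test_exact_at_every_reading(self):
        t = np.array([1.0, 4.0, 9.5, 20.0])
        y = np.array([36.9, 38.4, 37.1, 36.6])
        curve = ep.impute_linear(t, y)
        assert np.allclose(curve(t), y)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            ep.impute_linear([1.0], [37.0])
        with pytest.raises(ValueError):
            ep.impute_linear([1.0, 1.0], [37.0, 38.0])  # unresolved tie
        curve = ep.impute_linear([1.0, 5.0], [37.0, 38.0])
        with pytest.raises(ValueError):
            curve(0.5)  # no extrapolation


class TestWindowReadings:
    def test_half_open_window_and_tie_collapse(self, config):
        t = np.array([0.0, 0.0, 5.0, 5.0, 48.0, 48.5])
        y = np.array([39.0, 38.0, 37.0, 38.6, 37.5, 39.0])
        tw, yw, n_collapsed = ep.window_readings(t, y, config)
        # vaccination-instant and beyond-window readings removed,
        # duplicate at 5.0 collapsed to its maximum
        assert tw.tolist() == [5.0, 48.0]
        assert yw.tolist() == [38.6, 37.5]
        assert n_collapsed == 1


class TestExtractEpisode:
    def test_simple_rise_and_fall(self, config):
        """Crossings by exact linear inversion: (0,37),(6,39),(12,37) puts
        onset at 3 h, offset at 9 h, duration 6 h, Tmax 39."""
        epi = ep.extract_episode([0.0, 6.0, 12.0], [37.0, 39.0, 37.0], config)
        assert epi.onset_time_h == pytest.approx(3.0)
        assert epi.offset_time_h == pytest.approx(9.0)
        assert epi.duration_h == pytest.approx(6.0)
        assert epi.tmax_c == pytest.approx(39.0)
        assert not epi.onset_censored

    def test_first_reading_already_febrile_censors_onset(self, config):
        epi = ep.extract_episode([2.0, 5.0, 10.0], [38.5, 39.0, 37.5], config)
        assert epi.onset_censored
        assert epi.onset_time_h == pytest.approx(2.0)
        assert epi.offset_time_h == pytest.approx(25.0 / 3.0)
        assert epi.duration_h == pytest.approx(25.0 / 3.0 - 2.0)

    def test_no_fever_and_unresolved_fever_yield_none(self, config):
        assert ep.extract_episode([1.0, 5.0, 9.0], [37.0, 37.9, 37.5], config) is None
        # still febrile at the final reading: offset unobserved
        assert ep.extract_episode([1.0, 5.0, 9.0], [37.0, 39.0, 38.4], config) is None

    def test_subthreshold_dip_is_spanned(self, config):
        """Onset is the first upward crossing and offset the last downward
        crossing, so a dip below threshold in between lies inside the
        episode."""
        t = [0.0, 4.0, 8.0, 12.0, 16.0]
        y = [37.0, 39.0, 37.5, 38.8, 37.0]
        epi = ep.extract_episode(t, y, config)
        assert epi.onset_time_h == pytest.approx(2.0)
        assert epi.offset_time_h == pytest.approx(12.0 + 4.0 * 0.8 / 1.8)
        assert epi.tmax_c == pytest.approx(39.0)

    def test_exact_threshold_at_last_febrile_reading(self, config):
        epi = ep.extract_episode([0.0, 4.0, 8.0], [37.0, 38.0, 37.0], config)
        assert epi.offset_time_h == pytest.approx(4.0)
        assert epi.tmax_c == pytest.approx(38.0)

    @settings(max_examples=60, deadline=None)
    @given(hst.integers(0, 10_000), hst.integers(0, 60))
    def test_collinear_reading_insertion_is_a_no_op(self, seed, pick):
        """Adding a reading that lies exactly on an existing segment leaves
        the extracted episode unchanged."""
        rng = np.random.default_rng(seed)
        times, temps = random_reading_set(rng)
        seg = pick % (len(times) - 1)
        tm = (times[seg] + times[seg + 1]) / 2.0
        ym = float(np.interp(tm, times, temps))
        t2 = np.insert(times, seg + 1, tm)
        y2 = np.insert(temps, seg + 1, ym)
        a = ep.extract_episode(times, temps)
        b = ep.extract_episode(t2, y2)
        if a is None:
            assert b is None
        else:
            assert b.onset_time_h == pytest.approx(a.onset_time_h, abs=1e-9)
            assert b.offset_time_h == pytest.approx(a.offset_time_h, abs=1e-9)
            assert b.tmax_c == a.tmax_c

    def test_matches_dense_grid_oracle(self, config):
        """Exact crossing inversion agrees with a 0.001 h brute-force grid
        scan on random reading sets."""
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(200):
            times, temps = random_reading_set(rng)
            mine = ep.extract_episode(times, temps, config)
            ref = grid_episode(times, temps)
            assert (mine is None) == (ref is None)
            if mine is None:
                continue
            onset_ref, offset_ref, censored_ref = ref
            assert mine.onset_censored == censored_ref
            assert abs(mine.onset_time_h - onset_ref) <= 0.002
            assert abs(mine.offset_time_h - offset_ref) <= 0.002
            n_checked += 1
        assert n_checked > 50


class TestCascade:
    def test_single_vaccination_selection(self):
        ev = pd.DataFrame({
            "child_id": ["a", "a", "b", "b", "b", "c", "d"],
            "vaccine": ["DTaP", "MMR", "polio", "polio", "Hib", "DTaP", "MMR"],
            "time_iso8601": ["2016-01-01T09:00", "2016-01-01T15:00",   # same-day pair
                             "2016-02-01T09:00", "2016-03-01T09:00",   # different days
                             "2016-03-01T12:00",                        # pairs with previous
                             "2016-04-01T09:00", "2016-05-01T09:00"],
        })
        kept = ep.select_single_vaccinations(ev)
        assert len(kept) == 3
        assert set(kept["child_id"]) == {"b", "c", "d"}
        # a combination vaccine alone on its day counts as single
        assert "DTaP" in set(kept["vaccine"])

    def test_cascade_counts_on_constructed_fixture(self):
        events, readings, doses, expected = build_cascade_fixture()
        _, counts = ep.apply_cascade(events, readings, doses,
                                     AnalysisConfig(min_records_per_vaccine=5))
        assert counts == expected

    def test_cascade_is_monotone(self, fitted_results):
        c = fitted_results.cascade_counts
        ordered = [c[k] for k in ep.CASCADE_STAGES]
        assert all(a >= b for a, b in zip(ordered, ordered[1:]))

    def test_vaccine_minimum_exclusion(self):
        events, readings, doses, _ = build_cascade_fixture()
        records, counts = ep.apply_cascade(events, readings, doses,
                                           AnalysisConfig(min_records_per_vaccine=5))
        # the 4 BCG survivors fall below the per-vaccine minimum of 5
        assert "BCG" not in set(records["vaccine"])
        assert counts["vaccine_min_records"] == counts["onset_offset"] - 4

    def test_episode_invariants_on_cohort(self, fitted_results, config):
        r = fitted_results.records
        assert (r["onset_h"] >= 0).all()
        assert (r["onset_h"] <= r["offset_h"]).all()
        assert (r["offset_h"] <= config.window_hours).all()
        assert np.allclose(r["duration_h"], r["offset_h"] - r["onset_h"])
        assert (r["tmax_c"] >= config.fever_threshold).all()


class TestSummarizeCohort:
    def test_empty_cohort_gives_empty_table(self, config):
        table = ep.summarize_cohort(pd.DataFrame(columns=["child_id", "vaccine"]),
                                    pd.DataFrame(columns=["child_id", "time_h", "temp_c"]),
                                    config)
        assert table.empty and "age_median" in table.columns

    def test_singleton_record(self, config):
        records = pd.DataFrame([dict(
            child_id="a", vaccine="DTaP", age_months=12.0, weight_kg=9.0,
            sex="male", antipyretic_flag=True, n_readings=5)])
        readings = pd.DataFrame({"child_id": ["a"] * 5,
                                 "time_h": [1.0, 2, 3, 4, 5],
                                 "temp_c": [37.0, 38, 39, 38, 37]})
        table = ep.summarize_cohort(records, readings, config)
        row = table.iloc[0]
        assert row["n_records"] == 1 and row["n_children"] == 1
        assert row["age_sd"] == 0.0 and row["male_pct"] == 100.0
        assert row["antipyretic_pct"] == 100.0

    def test_sex_fraction_matches_generator(self, fitted_results):
        """The cohort table's Total male share reproduces the programmed
        60% within binomial error."""
        total = fitted_results.table1.set_index("vaccine").loc["Total"]
        assert abs(total["male_pct"] - 60.0) < 4.0
        assert total["n_records"] == len(fitted_results.records)
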