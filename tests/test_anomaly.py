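"""Temperature-anomaly metric: baselines, aggregation, extremes, population."""

import calendar

import numpy as np
import pandas as pd
import pytest

from anomort.anomaly import (
    _count_episodes,
    aggregate_to_state,
    compute_anomalies,
    compute_long_term_means,
    extreme_measures,
    interpolate_population,
    mean_absolute_anomaly,
)
from anomort.errors import ValidationError


def _temps(records):
    return pd.DataFrame(records, columns=["unit_id", "year", "month", "temp"])


class TestLongTermMeans:
    @pytest.mark.parametrize(
        "years_temps, expected",
        [({2001: 10.0, 2002: 12.0, 2003: 14.0}, 12.0), ({2001: 20.5}, 20.5)],
    )
    def test_arithmetic_mean_over_years(self, years_temps, expected):
        df = _temps([("A", y, 7, t) for y, t in years_temps.items()])
        means = compute_long_term_means(df)
        assert means.loc[0, "mean_temp"] == pytest.approx(expected)

    def test_38_year_gaussian_series_matches_direct_summation(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(15.0, 2.0, size=38)
        df = _temps([("A", 1980 + i, 1, v) for i, v in enumerate(vals)])
        m = compute_long_term_means(df).loc[0, "mean_temp"]
        assert m == pytest.approx(vals.sum() / 38)        # direct summation
        assert abs(m - 15.0) < 3 * 2.0 / np.sqrt(38)

    def test_duplicate_and_missing_records_error(self):
        dup = _temps([("A", 2001, 1, 5.0), ("A", 2001, 1, 6.0)])
        with pytest.raises(ValidationError):
            compute_long_term_means(dup)
        gap = _temps([("A", 2001, 1, np.nan)])
        with pytest.raises(ValidationError) as e:
            compute_long_term_means(gap)
        assert e.value.gaps  # offending records are listed


class TestAnomalies:
    def test_subtraction_and_zero_mean(self):
        df = _temps([("A", y, 7, t) for y, t in [(2001, 10.0), (2002, 12.0), (2003, 14.0)]])
        means = compute_long_term_means(df)
        a = compute_anomalies(df, means)
        assert list(a["anomaly"]) == pytest.approx([-2.0, 0.0, 2.0])

    def test_constant_series_gives_zero(self):
        df = _temps([("A", y, 3, 7.7) for y in range(2000, 2010)])
        a = compute_anomalies(df, compute_long_term_means(df))
        assert np.allclose(a["anomaly"], 0.0)

    def test_self_consistent_input_sums_to_zero_per_unit_month(self):
        rng = np.random.default_rng(3)
        recs = [
            (u, y, m, float(rng.normal(10 + m, 2)))
            for u in ("A", "B")
            for y in range(2000, 2011)
            for m in range(1, 13)
        ]
        df = _temps(recs)
        a = compute_anomalies(df, compute_long_term_means(df))
        sums = a.groupby(["unit_id", "month"])["anomaly"].sum()
        assert np.all(np.abs(sums.to_numpy()) < 1e-9)

    def test_uncovered_unit_month_errors_with_pair_named(self):
        df = _temps([("A", 2001, 1, 5.0)])
        means = pd.DataFrame({"unit_id": ["A"], "month": [2], "mean_temp": [5.0]})
        with pytest.raises(ValidationError) as e:
            compute_anomalies(df, means)
        assert ("A", 1) in e.value.gaps


class TestStateAggregation:
    def _mapping(self, counties, state="X"):
        return pd.DataFrame({"unit_id": counties, "state": state})

    def test_population_weighted_mean(self):
        anoms = pd.DataFrame(
            {"unit_id": ["c1", "c2"], "year": 2000, "month": 1, "anomaly": [1.0, 2.0]}
        )
        w = pd.DataFrame({"unit_id": ["c1", "c2"], "population": [1000.0, 3000.0]})
        out = aggregate_to_state(anoms, w, self._mapping(["c1", "c2"]))
        assert out.loc[0, "anomaly"] == pytest.approx(1.75)

    def test_equal_anomalies_are_invariant(self):
        anoms = pd.DataFrame(
            {"unit_id": list("abcd"), "year": 2000, "month": 6, "anomaly": 0.37}
        )
        w = pd.DataFrame({"unit_id": list("abcd"), "population": [1.0, 10, 100, 3]})
        out = aggregate_to_state(anoms, w, self._mapping(list("abcd")))
        assert out.loc[0, "anomaly"] == pytest.approx(0.37)

    def test_matches_bruteforce_loop_and_weight_rescaling(self):
        rng = np.random.default_rng(7)
        counties = [f"c{i}" for i in range(5)]
        anoms = pd.DataFrame(
            [(c, 2000, m, rng.normal()) for c in counties for m in (1, 2)],
            columns=["unit_id", "year", "month", "anomaly"],
        )
        pops = rng.uniform(10, 1e5, 5)
        w = pd.DataFrame({"unit_id": counties, "population": pops})
        out = aggregate_to_state(anoms, w, self._mapping(counties)).set_index("month")
        for m in (1, 2):
            sub = anoms[anoms["month"] == m].set_index("unit_id")
            expect = sum(pops[i] * sub.loc[c, "anomaly"] for i, c in enumerate(counties))
            expect /= pops.sum()
            assert out.loc[m, "anomaly"] == pytest.approx(expect)
        w10 = w.assign(population=w["population"] * 10)  # uniform rescaling
        out10 = aggregate_to_state(anoms, w10, self._mapping(counties))
        assert np.allclose(out10["anomaly"], out.reset_index()["anomaly"])

    def test_zero_weights_and_missing_mapping_error(self):
        anoms = pd.DataFrame(
            {"unit_id": ["c1"], "year": 2000, "month": 1, "anomaly": [1.0]}
        )
        w0 = pd.DataFrame({"unit_id": ["c1"], "population": [0.0]})
        with pytest.raises(ValidationError):
            aggregate_to_state(anoms, w0, self._mapping(["c1"]))
        w = pd.DataFrame({"unit_id": ["c1"], "population": [5.0]})
        with pytest.raises(ValidationError):
            aggregate_to_state(anoms, w, self._mapping(["c9"]))


class TestMeanAbsoluteAnomaly:
    def test_examples_and_median(self):
        df = pd.DataFrame(
            [("A", y, 1, a) for y, a in [(2000, -2.0), (2001, 0.0), (2002, 2.0)]]
            + [("A", y, 2, 0.0) for y in (2000, 2001, 2002)],
            columns=["unit_id", "year", "month", "anomaly"],
        )
        per, med = mean_absolute_anomaly(df)
        per = per.set_index("month")["mean_abs_anomaly"]
        assert per.loc[1] == pytest.approx(4.0 / 3.0)
        assert per.loc[2] == 0.0
        assert med == pytest.approx((4.0 / 3.0 + 0.0) / 2)

    def test_matches_direct_loop_and_is_nonnegative(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            [("A", 2000 + y, m, rng.normal()) for y in range(8) for m in range(1, 13)],
            columns=["unit_id", "year", "month", "anomaly"],
        )
        per, _ = mean_absolute_anomaly(df)
        for _, row in per.iterrows():
            vals = df[(df["month"] == row["month"])]["anomaly"].abs().to_numpy()
            assert row["mean_abs_anomaly"] == pytest.approx(vals.mean())
            assert row["mean_abs_anomaly"] >= 0


def _episodes_oracle(flags, min_len=3):
    runs, n = [], 0
    for f in list(flags) + [0]:
        if f:
            n += 1
        else:
            runs.append(n)
            n = 0
    return sum(1 for r in runs if r >= min_len)


class TestExtremeMeasures:
    def _daily(self, unit, year, month, temps):
        days = pd.date_range(f"{year}-{month:02d}-01", periods=len(temps), freq="D")
        return pd.DataFrame({"unit_id": unit, "date": days, "temp": temps})

    def test_episode_counting_examples(self):
        assert _count_episodes(np.array([1, 1, 1, 0, 1, 1] + [0] * 24, bool)) == 1
        assert _count_episodes(np.array([1, 1, 0, 1, 1, 0] * 5, bool)) == 0

    def test_episode_count_matches_runlength_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            flags = rng.uniform(size=rng.integers(28, 32)) < 0.3
            assert _count_episodes(flags) == _episodes_oracle(flags)
            assert _count_episodes(flags) <= flags.sum() // 3

    def test_measures_match_direct_scan(self):
        rng = np.random.default_rng(21)
        frames = []
        for year in (2001, 2002, 2003):
            n = calendar.monthrange(year, 6)[1]
            frames.append(self._daily("A", year, 6, rng.normal(20, 3, n)))
        daily = pd.concat(frames, ignore_index=True)
        out = extreme_measures(daily, quantile=0.9)
        out = out.set_index(["year", "measure"])["value"]

        daily["year"] = pd.to_datetime(daily["date"]).dt.year
        per_year_p90 = daily.groupby("year")["temp"].quantile(0.9)
        threshold = daily["temp"].quantile(0.9)
        for year in (2001, 2002, 2003):
            sub = daily[daily["year"] == year].sort_values("date")
            n = len(sub)
            assert out.loc[(year, "p90_anomaly")] == pytest.approx(
                per_year_p90.loc[year] - per_year_p90.mean()
            )
            flags = (sub["temp"] > threshold).to_numpy()
            assert out.loc[(year, "days_above_p90")] == pytest.approx(
                flags.sum() * 30.0 / n
            )
            assert out.loc[(year, "episodes_above_p90")] == pytest.approx(
                _episodes_oracle(flags) * 30.0 / n
            )

    def test_missing_days_error(self):
        daily = self._daily("A", 2001, 6, np.arange(10.0))  # June has 30 days
        with pytest.raises(ValidationError) as e:
            extreme_measures(daily)
        assert e.value.gaps[0][:3] == ("A", 2001, 6)


class TestInterpolatePopulation:
    def test_midpoint_and_anchor_values(self):
        annual = pd.DataFrame(
            {"unit_id": "A", "year": [2000, 2001], "population": [1200.0, 1212.0]}
        )
        out = interpolate_population(annual).set_index(["year", "month"])
        assert out.loc[(2001, 1), "population"] == pytest.approx(1206.0)
        assert out.loc[(2000, 7), "population"] == pytest.approx(1200.0)  # anchors exact
        assert out.loc[(2001, 7), "population"] == pytest.approx(1212.0)

    def test_constant_counts_give_constant_series(self):
        annual = pd.DataFrame(
            {"unit_id": "A", "year": [2000, 2001, 2002], "population": 500.0}
        )
        out = interpolate_population(annual)
        assert np.allclose(out["population"], 500.0)

    def test_matches_two_point_line_formula_with_extrapolation(self):
        annual = pd.DataFrame(
            {"unit_id": "A", "year": [2000, 2001, 2002], "population": [100.0, 160.0, 130.0]}
        )
        out = interpolate_population(annual)
        anchors_x = np.array([2000, 2001, 2002]) * 12 + 7
        anchors_y = np.array([100.0, 160.0, 130.0])
        for _, row in out.iterrows():
            x = row["year"] * 12 + row["month"]
            if x <= anchors_x[1]:
                x0, x1, y0, y1 = anchors_x[0], anchors_x[1], anchors_y[0], anchors_y[1]
            else:
                x0, x1, y0, y1 = anchors_x[1], anchors_x[2], anchors_y[1], anchors_y[2]
            expect = y0 + (y1 - y0) * (x - x0) / (x1 - x0)
            assert row["population"] == pytest.approx(expect)
        # interior months lie between the bracketing anchors
        interior = out[(out["year"] == 2000) & (out["month"] >= 7) | (out["year"] == 2001) & (out["month"] <= 7)]
        assert interior["population"].between(99.999, 160.001).all()

    def test_single_year_warns_and_is_constant(self):
        annual = pd.DataFrame({"unit_id": "A", "year": [2000], "population": [42.0]})
        with pytest.warns(UserWarning):
            out = interpolate_population(annual)
        assert np.allclose(out["population"], 42.0)
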