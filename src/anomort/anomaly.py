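"""Anomalous-temperature exposure metrics.

The exposure of interest is the *temperature anomaly*: the deviation of a
spatial unit's mean temperature in a given calendar month and year from that
unit-month's long-term average over the analysis period.  A unit with a
higher but inter-annually stable temperature in some month therefore has
smaller anomalies than a colder but more variable one.

All functions operate on long-format :class:`pandas.DataFrame` objects:

``temps``
    columns ``unit_id, year, month, temp`` (monthly mean temperature, deg C)
``daily``
    columns ``unit_id, date, temp`` (daily mean temperature, deg C)
``anoms``
    columns ``unit_id, year, month, anomaly``
``population``
    columns ``unit_id, year[, month][, stratum columns...], population``
"""

from __future__ import annotations

import calendar
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "compute_long_term_means",
    "compute_anomalies",
    "aggregate_to_state",
    "mean_absolute_anomaly",
    "extreme_measures",
    "interpolate_population",
]


def _check_monthly_frame(temps: pd.DataFrame, value_col: str = "temp") -> None:
    required = {"unit_id", "year", "month", value_col}
    missing = required - set(temps.columns)
    if missing:
        raise ValidationError(f"monthly frame missing columns: {sorted(missing)}")
    bad_month = temps.loc[~temps["month"].isin(range(1, 13))]
    if len(bad_month):
        raise ValidationError(
            "month values outside 1..12",
            gaps=bad_month[["unit_id", "year", "month"]].to_records(index=False).tolist(),
        )
    dup = temps.duplicated(subset=["unit_id", "year", "month"])
    if dup.any():
        raise ValidationError(
            "duplicate (unit_id, year, month) records",
            gaps=temps.loc[dup, ["unit_id", "year", "month"]]
            .to_records(index=False)
            .tolist(),
        )
    if temps[value_col].isna().any():
        gaps = temps.loc[temps[value_col].isna(), ["unit_id", "year", "month"]]
        raise ValidationError(
            f"missing {value_col} values (no imputation is performed)",
            gaps=gaps.to_records(index=False).tolist(),
        )


def compute_long_term_means(temps: pd.DataFrame) -> pd.DataFrame:
    """Long-term average temperature per (unit, calendar month).

    Returns a frame with columns ``unit_id, month, mean_temp`` where
    ``mean_temp`` is the arithmetic mean over all years present for that
    unit-month.
    """
    _check_monthly_frame(temps)
    out = (
        temps.groupby(["unit_id", "month"], as_index=False, sort=True)["temp"]
        .mean()
        .rename(columns={"temp": "mean_temp"})
    )
    return out


def compute_anomalies(temps: pd.DataFrame, means: pd.DataFrame) -> pd.DataFrame:
    """Subtract the unit-month long-term mean from each monthly temperature.

    Every (unit, month) present in ``temps`` must be covered by ``means``;
    an uncovered pair is an error (never silently dropped).
    """
    _check_monthly_frame(temps)
    merged = temps.merge(means, on=["unit_id", "month"], how="left", validate="m:1")
    uncovered = merged["mean_temp"].isna()
    if uncovered.any():
        gaps = (
            merged.loc[uncovered, ["unit_id", "month"]]
            .drop_duplicates()
            .to_records(index=False)
            .tolist()
        )
        raise ValidationError("no long-term mean for (unit, month) pairs", gaps=gaps)
    merged["anomaly"] = merged["temp"] - merged["mean_temp"]
    return merged[["unit_id", "year", "month", "anomaly"]]


def aggregate_to_state(
    county_anoms: pd.DataFrame,
    weights: pd.DataFrame,
    county_to_state: pd.DataFrame,
) -> pd.DataFrame:
    """Population-weighted aggregation of county anomalies to the state level.

    Parameters
    ----------
    county_anoms
        Long frame ``unit_id, year, month, anomaly`` at county level.
    weights
        Population weights ``unit_id, year, month, population`` (total,
        all-stratum population; time-varying weights are supported and are
        matched on (unit, year, month)).  A frame with only ``unit_id,
        population`` is accepted for time-constant weights.
    county_to_state
        Two columns ``unit_id, state`` mapping each county to exactly one
        state.

    Returns the state-level anomaly frame ``unit_id, year, month, anomaly``
    where ``unit_id`` now holds state labels and the anomaly is
    ``sum_c w_c a_c / sum_c w_c`` within each (state, year, month).
    """
    if set(county_to_state.columns) < {"unit_id", "state"}:
        raise ValidationError("county_to_state needs columns unit_id, state")
    if county_to_state["unit_id"].duplicated().any():
        raise ValidationError("a county maps to more than one state")

    df = county_anoms.merge(county_to_state[["unit_id", "state"]], on="unit_id", how="left")
    unmapped = df["state"].isna()
    if unmapped.any():
        raise ValidationError(
            "counties without a state mapping",
            gaps=sorted(df.loc[unmapped, "unit_id"].unique().tolist()),
        )

    if {"year", "month"} <= set(weights.columns):
        df = df.merge(
            weights[["unit_id", "year", "month", "population"]],
            on=["unit_id", "year", "month"],
            how="left",
            validate="m:1",
        )
    else:
        df = df.merge(weights[["unit_id", "population"]], on="unit_id", how="left", validate="m:1")
    if df["population"].isna().any():
        gaps = df.loc[df["population"].isna(), ["unit_id", "year", "month"]]
        raise ValidationError(
            "missing population weight for county records",
            gaps=gaps.drop_duplicates().to_records(index=False).tolist(),
        )
    if (df["population"] < 0).any():
        raise ValidationError("negative population weights")

    def _wmean(g: pd.DataFrame) -> float:
        wsum = g["population"].sum()
        if wsum <= 0:
            raise ValidationError(
                f"all-zero population weights in state {g.name[0]!r}, "
                f"year {g.name[1]}, month {g.name[2]}"
            )
        return float(np.dot(g["anomaly"], g["population"]) / wsum)

    out = (
        df.groupby(["state", "year", "month"], sort=True)[["anomaly", "population"]]
        .apply(_wmean)
        .rename("anomaly")
        .reset_index()
        .rename(columns={"state": "unit_id"})
    )
    return out[["unit_id", "year", "month", "anomaly"]]


def mean_absolute_anomaly(anoms: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Average size of anomaly per unit-month, and its median across all.

    For each (unit, month) the mean of ``|anomaly|`` over years is the
    "average size of anomaly", a measure of how variable temperatures are
    around their local long-term mean.  The second return value is the
    median of these values taken across all unit-months.
    """
    _check_monthly_frame(anoms, value_col="anomaly")
    per = (
        anoms.assign(absa=anoms["anomaly"].abs())
        .groupby(["unit_id", "month"], as_index=False, sort=True)["absa"]
        .mean()
        .rename(columns={"absa": "mean_abs_anomaly"})
    )
    return per, float(per["mean_abs_anomaly"].median())


# ---------------------------------------------------------------------------
# Extreme-anomaly sensitivity measures
# ---------------------------------------------------------------------------

def _count_episodes(flags: np.ndarray, min_len: int = 3) -> int:
    """Number of maximal runs of True of length >= min_len."""
    n = 0
    run = 0
    for f in flags:
        if f:
            run += 1
        else:
            if run >= min_len:
                n += 1
            run = 0
    if run >= min_len:
        n += 1
    return n


def extreme_measures(daily: pd.DataFrame, quantile: float = 0.9) -> pd.DataFrame:
    """Three extreme-anomaly measures from daily mean temperatures.

    Per (unit, year, month):

    ``p90_anomaly``
        the month's empirical ``quantile`` (default 90th percentile) of daily
        means minus the long-term average of that unit-month's percentiles
        across years (deg C);
    ``days_above_p90``
        number of days above the unit-month *long-term* percentile threshold
        (the percentile of all daily values pooled across years for that
        calendar month), normalised to a 30-day month (x 30 / days in month);
    ``episodes_above_p90``
        number of maximal episodes of >= 3 consecutive days above that
        threshold, with the same month-length normalisation.

    Percentiles use the linear-interpolation quantile estimator.  Months with
    missing days are an error.

    Returns a long frame ``unit_id, year, month, measure, value``.
    """
    required = {"unit_id", "date", "temp"}
    if required - set(daily.columns):
        raise ValidationError(f"daily frame needs columns {sorted(required)}")
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(subset=["unit_id", "date"]).any():
        raise ValidationError("duplicate (unit_id, date) records")
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month

    # completeness: every (unit, year, month) must have all calendar days
    sizes = df.groupby(["unit_id", "year", "month"]).size()
    gaps = []
    for (u, y, m), n in sizes.items():
        ndays = calendar.monthrange(int(y), int(m))[1]
        if n != ndays:
            gaps.append((u, int(y), int(m), int(n), ndays))
    if gaps:
        raise ValidationError("months with missing days (unit, year, month, have, need)", gaps=gaps)

    rows = []
    for (u, m), g in df.groupby(["unit_id", "month"], sort=True):
        # per-year percentile of daily means within the month
        per_year = g.groupby("year")["temp"].quantile(quantile)
        longterm_p = per_year.mean()
        # long-term threshold: percentile of all pooled daily values
        threshold = g["temp"].quantile(quantile)
        for y, gy in g.groupby("year"):
            ndays = len(gy)
            adj = 30.0 / ndays
            flags = (gy.sort_values("date")["temp"] > threshold).to_numpy()
            rows.append((u, int(y), int(m), "p90_anomaly", float(per_year.loc[y] - longterm_p)))
            rows.append((u, int(y), int(m), "days_above_p90", float(flags.sum() * adj)))
            rows.append(
                (u, int(y), int(m), "episodes_above_p90", float(_count_episodes(flags) * adj))
            )
    return pd.DataFrame(rows, columns=["unit_id", "year", "month", "measure", "value"])


def interpolate_population(annual: pd.DataFrame) -> pd.DataFrame:
    """Monthly population via linear interpolation with July anchors.

    Each yearly count is assigned to July of its year; months between two
    Julys lie on the straight line joining them, and months before the first
    (after the last) July are linearly extrapolated from the nearest two
    anchors.  A single-year series yields a constant with a warning.

    ``annual`` has columns ``unit_id, year, population`` plus any extra
    stratum columns (e.g. ``sex``, ``age_group``), which are carried through.
    Returns the same grouping columns with ``year, month, population``.
    """
    required = {"unit_id", "year", "population"}
    if required - set(annual.columns):
        raise ValidationError(f"annual population needs columns {sorted(required)}")
    group_cols = ["unit_id"] + [
        c for c in annual.columns if c not in {"unit_id", "year", "population"}
    ]
    out_frames = []
    for key, g in annual.groupby(group_cols, sort=True):
        g = g.sort_values("year")
        years = g["year"].to_numpy()
        pops = g["population"].to_numpy(dtype=float)
        # anchor x: month index of July (month 7) of each year
        xa = years * 12 + 7
        y0, y1 = int(years.min()), int(years.max())
        months = np.arange(y0 * 12 + 1, y1 * 12 + 13)
        if len(years) == 1:
            warnings.warn(
                f"single-year population for {key!r}; using a constant monthly series",
                stacklevel=2,
            )
            vals = np.full(len(months), pops[0])
        else:
            vals = np.interp(months, xa, pops)
            # np.interp clamps outside the anchor range; extrapolate linearly
            # from the nearest two anchors instead
            lo = months < xa[0]
            hi = months > xa[-1]
            if lo.any():
                slope = (pops[1] - pops[0]) / (xa[1] - xa[0])
                vals[lo] = pops[0] + slope * (months[lo] - xa[0])
            if hi.any():
                slope = (pops[-1] - pops[-2]) / (xa[-1] - xa[-2])
                vals[hi] = pops[-1] + slope * (months[hi] - xa[-1])
        f = pd.DataFrame(
            {
                "year": (months - 1) // 12,
                "month": (months - 1) % 12 + 1,
                "population": vals,
            }
        )
        if not isinstance(key, tuple):
            key = (key,)
        for col, val in zip(group_cols, key):
            f[col] = val
        out_frames.append(f[group_cols + ["year", "month", "population"]])
    return pd.concat(out_frames, ignore_index=True)
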