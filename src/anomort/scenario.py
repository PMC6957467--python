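"""Warm-year excess-death scenarios.

Converts fitted monthly anomaly coefficients into additional annual deaths
under a stylised year in which every month in every state is a uniform
+delta deg C warmer than its long-term average.  The excess relative risk
(ERR) in month m is ``exp(gamma_m * delta) - 1``: the proportional change
in the death rate relative to baseline, so that multiplying observed
reference-year death counts by the ERR yields *additional* (possibly
negative) deaths.  All aggregations are computed within each posterior draw
before percentile extraction, so credible intervals of sums respect
parameter correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .inference import credible_interval

__all__ = ["excess_relative_risk", "excess_deaths", "percent_change", "ScenarioResult"]


def excess_relative_risk(gamma_draws: np.ndarray, delta: float) -> np.ndarray:
    """Per-draw excess relative risk ``exp(gamma * delta) - 1``.

    ``gamma_draws`` is (n_draws, 12) (or any trailing shape); the result has
    the same shape.  ``delta=0`` gives identically zero.
    """
    gamma_draws = np.asarray(gamma_draws, dtype=float)
    if not np.isfinite(delta):
        raise ValidationError("delta must be finite")
    return np.expm1(gamma_draws * delta)


@dataclass
class ScenarioResult:
    """Excess deaths under a uniform +delta deg C year.

    ``cell_draws`` holds per-draw excess deaths on the (stratum, month)
    grid: shape (n_strata, 12, n_draws), with ``strata`` the corresponding
    stratum key frame.  ``tables`` maps a grouping name ("injury_type",
    "sex", "age_group", "month", "total") to a summary DataFrame with
    posterior mean and 95% credible interval; summaries are deterministic
    functions of the draws, aggregated within draw first.
    """

    delta: float
    strata: pd.DataFrame
    cell_draws: np.ndarray
    tables: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.cell_draws.shape[2]

    def total_draws(self) -> np.ndarray:
        """Per-draw net total excess deaths (sum over strata and months)."""
        return self.cell_draws.sum(axis=(0, 1))

    def summary(self, by: str | None = None) -> pd.DataFrame:
        if by is None:
            by = "total"
        return self.tables[by]


def _summarise(groups: pd.Series, draws_2d: np.ndarray, level: float = 0.95) -> pd.DataFrame:
    """Aggregate (n_rows, n_draws) within draw by group, then summarise."""
    df = []
    for g in pd.unique(groups):
        mask = (groups == g).to_numpy()
        agg = draws_2d[mask].sum(axis=0)
        lo, hi = credible_interval(agg, level)
        df.append((g, float(agg.mean()), lo, hi))
    return pd.DataFrame(df, columns=["level", "mean", "lo95", "hi95"])


def excess_deaths(
    observed: pd.DataFrame,
    err_draws,
    *,
    delta: float,
    reference_year: int | None = None,
) -> ScenarioResult:
    """Additional annual deaths under a uniformly +delta deg C warm year.

    Parameters
    ----------
    observed
        StratifiedCounts restricted to (or containing) the reference year:
        columns ``state, year, month, deaths`` plus any of ``injury_type,
        sex, age_group``.  Reference-year counts enter as fixed constants
        (their Poisson uncertainty is not propagated).
    err_draws
        Either an (n_draws, 12) array of monthly ERR draws applied to every
        stratum, or a dict mapping stratum key tuples (values of the
        stratum columns, in column order) to such arrays.
    delta
        The scenario's uniform anomaly in deg C (recorded in the result).
    reference_year
        Year to restrict ``observed`` to; defaults to the maximum year
        present.  Absence of the reference year is an error.

    Per draw, the excess for a stratum-month is ``sum_states deaths_obs *
    ERR_month``; aggregations by injury type, sex, age group, month and the
    grand total are computed within draw and then summarised (posterior
    mean, 95% credible interval).
    """
    if "deaths" not in observed.columns:
        raise ValidationError("observed counts need a 'deaths' column")
    year_col = observed["year"] if "year" in observed.columns else None
    if reference_year is None:
        if year_col is None:
            raise ValidationError("observed counts need a 'year' column")
        reference_year = int(year_col.max())
    obs = observed[observed["year"] == reference_year]
    if not len(obs):
        raise ValidationError(f"reference year {reference_year} absent from observed counts")

    strat_cols = [c for c in ("injury_type", "sex", "age_group") if c in obs.columns]
    monthly = (
        obs.groupby(strat_cols + ["month"], as_index=False, sort=True)["deaths"].sum()
    )
    strata = (
        monthly[strat_cols].drop_duplicates().reset_index(drop=True)
        if strat_cols
        else pd.DataFrame({"stratum": ["all"]})
    )

    # death counts on the (stratum, month) grid
    n_s = len(strata)
    D = np.zeros((n_s, 12))
    for i, row in strata.iterrows():
        if strat_cols:
            mask = np.logical_and.reduce(
                [monthly[c] == row[c] for c in strat_cols]
            )
            sub = monthly[mask]
        else:
            sub = monthly
        D[i, sub["month"].to_numpy() - 1] = sub["deaths"].to_numpy()

    def _err_for(i):
        if isinstance(err_draws, dict):
            key = tuple(strata.iloc[i][c] for c in strat_cols)
            try:
                e = err_draws[key]
            except KeyError:
                raise ValidationError(f"no ERR draws for stratum {key}") from None
        else:
            e = err_draws
        e = np.asarray(e, dtype=float)
        if e.ndim == 1:
            e = e[:, None]
        if e.shape[1] == 1:
            e = np.repeat(e, 12, axis=1)
        return e  # (n_draws, 12)

    e0 = _err_for(0)
    n_draws = e0.shape[0]
    cell = np.empty((n_s, 12, n_draws))
    for i in range(n_s):
        e = _err_for(i)
        if e.shape[0] != n_draws:
            raise ValidationError("ERR draw counts differ across strata")
        cell[i] = D[i][:, None] * e.T  # (12, n_draws)

    res = ScenarioResult(delta=float(delta), strata=strata, cell_draws=cell)

    flat = cell.reshape(n_s * 12, n_draws)
    month_of_row = pd.Series(np.tile(np.arange(1, 13), n_s))
    res.tables["month"] = _summarise(month_of_row, flat)
    for c in strat_cols:
        groups = pd.Series(np.repeat(strata[c].to_numpy(), 12))
        res.tables[c] = _summarise(groups, flat)
    tot = res.total_draws()
    lo, hi = credible_interval(tot)
    res.tables["total"] = pd.DataFrame(
        [("total", float(tot.mean()), lo, hi)], columns=["level", "mean", "lo95", "hi95"]
    )
    return res


def percent_change(
    err_draws,
    observed: pd.DataFrame,
    *,
    reference_year: int | None = None,
) -> pd.DataFrame:
    """Per-stratum percentage change in death rates under the scenario.

    Per draw: ``100 * sum_m deaths_m * ERR_m / sum_m deaths_m``, the
    death-weighted average ERR over months, summarised as posterior mean and
    95% credible interval.  Strata with zero observed deaths are reported as
    missing (NaN) rather than a value.
    """
    if reference_year is None:
        reference_year = int(observed["year"].max())
    obs = observed[observed["year"] == reference_year]
    if not len(obs):
        raise ValidationError(f"reference year {reference_year} absent from observed counts")
    strat_cols = [c for c in ("injury_type", "sex", "age_group") if c in obs.columns]
    monthly = obs.groupby(strat_cols + ["month"], as_index=False, sort=True)["deaths"].sum()
    strata = (
        monthly[strat_cols].drop_duplicates().reset_index(drop=True)
        if strat_cols
        else pd.DataFrame({"stratum": ["all"]})
    )
    rows = []
    for i, row in strata.iterrows():
        if strat_cols:
            mask = np.logical_and.reduce([monthly[c] == row[c] for c in strat_cols])
            sub = monthly[mask]
            key = tuple(row[c] for c in strat_cols)
        else:
            sub = monthly
            key = ("all",)
        d = np.zeros(12)
        d[sub["month"].to_numpy() - 1] = sub["deaths"].to_numpy()
        if isinstance(err_draws, dict):
            e = np.asarray(err_draws[key], dtype=float)
        else:
            e = np.asarray(err_draws, dtype=float)
        if d.sum() == 0:
            rows.append(key + (np.nan, np.nan, np.nan))
            continue
        pc = 100.0 * (e @ d) / d.sum()
        lo, hi = credible_interval(pc)
        rows.append(key + (float(pc.mean()), lo, hi))
    cols = (strat_cols or ["stratum"]) + ["mean", "lo95", "hi95"]
    return pd.DataFrame(rows, columns=cols)
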