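"""Descriptive surfaces: stratum death counts and age-standardised rates.

Direct age standardisation: a weighted average of age-specific death rates
with the weights of a fixed standard population, reported per 100,000.
The default standard is the US 2000 standard population collapsed to the
model's ten age groups; it is configurable because different analyses use
different standards.  Rates computed over monthly cells are annualised
(x 12) so monthly and annual groupings are on the same scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["AGE_GROUPS", "us2000_standard", "age_standardized_rate", "stratum_counts"]

#: The analysis age groups: 0-4, ten-year groups to 84, then 85+.
AGE_GROUPS = [
    "0-4", "5-14", "15-24", "25-34", "35-44",
    "45-54", "55-64", "65-74", "75-84", "85+",
]

# US 2000 standard million collapsed to the ten analysis age groups.
_US2000 = {
    "0-4": 69135, "5-14": 145565, "15-24": 138647, "25-34": 135573,
    "35-44": 162613, "45-54": 134834, "55-64": 87247, "65-74": 66037,
    "75-84": 44841, "85+": 15508,
}


def us2000_standard() -> pd.DataFrame:
    """Default standard population: US 2000, as weights summing to 1."""
    df = pd.DataFrame(
        {"age_group": list(_US2000), "weight": np.array(list(_US2000.values()), float)}
    )
    df["weight"] /= df["weight"].sum()
    return df


def _check_standard(std: pd.DataFrame) -> pd.DataFrame:
    if {"age_group", "weight"} - set(std.columns):
        raise ValidationError("standard population needs columns age_group, weight")
    if (std["weight"] < 0).any():
        raise ValidationError("standard weights must be non-negative")
    total = std["weight"].sum()
    if not np.isclose(total, 1.0):
        std = std.assign(weight=std["weight"] / total)
    return std


def age_standardized_rate(
    counts: pd.DataFrame,
    std: pd.DataFrame | None = None,
    by: tuple[str, ...] = ("injury_type", "sex", "month"),
    *,
    annualize: bool = True,
) -> pd.DataFrame:
    """Directly age-standardised death rates per 100,000.

    ``counts`` is a StratifiedCounts frame with ``age_group, deaths,
    population`` (person-months when cells are monthly).  For each group in
    ``by``, age-specific rates are computed as total deaths over total
    population within the group, then combined as
    ``sum_a w_a * rate_a * 100000``; missing standard age groups are
    zero-filled in deaths but a zero population with non-zero weight is an
    error.  With ``annualize`` (default) monthly rates are multiplied by 12.
    """
    std = _check_standard(std if std is not None else us2000_standard())
    need = {"age_group", "deaths", "population"} | set(by)
    if need - set(counts.columns):
        raise ValidationError(f"counts missing columns {sorted(need - set(counts.columns))}")

    agg = counts.groupby(list(by) + ["age_group"], as_index=False, sort=True).agg(
        deaths=("deaths", "sum"), population=("population", "sum")
    )
    rows = []
    for key, g in agg.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        merged = std.merge(g, on="age_group", how="left")
        merged["deaths"] = merged["deaths"].fillna(0.0)
        bad = (merged["weight"] > 0) & (
            merged["population"].isna() | (merged["population"] <= 0)
        )
        if bad.any():
            raise ValidationError(
                f"zero/absent population for weighted age groups "
                f"{merged.loc[bad, 'age_group'].tolist()} in group {key}"
            )
        rate = float(
            np.sum(merged["weight"] * merged["deaths"] / merged["population"]) * 1e5
        )
        if annualize:
            rate *= 12.0
        rows.append(key + (rate,))
    return pd.DataFrame(rows, columns=list(by) + ["rate_per_100k"])


def stratum_counts(
    counts: pd.DataFrame, by: tuple[str, ...] = ("injury_type", "sex", "age_group")
) -> pd.DataFrame:
    """Exact death totals by stratum, with shares of the grand total."""
    if "deaths" not in counts.columns:
        raise ValidationError("counts need a 'deaths' column")
    out = counts.groupby(list(by), as_index=False, sort=True)["deaths"].sum()
    grand = out["deaths"].sum()
    out["share_pct"] = 100.0 * out["deaths"] / grand if grand else 0.0
    return out
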