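"""The anomalous-temperature metric, from monthly temperatures to state series.

Builds six counties of synthetic monthly temperatures over 38 years,
computes each county-month's long-term baseline and anomaly series,
aggregates counties to two states with population weights, and summarises
how large anomalies typically are.
"""

import numpy as np
import pandas as pd

from anomort import (
    aggregate_to_state,
    compute_anomalies,
    compute_long_term_means,
    mean_absolute_anomaly,
)

rng = np.random.default_rng(0)

# monthly mean temperatures: a seasonal cycle plus county offsets and
# winter-heavy interannual variability
counties = [f"c{i}" for i in range(6)]
records = []
for i, c in enumerate(counties):
    for year in range(1980, 2018):
        for month in range(1, 13):
            season = 12.0 - 10.0 * np.cos(2 * np.pi * (month - 7) / 12)
            sd = 2.2 if month in (12, 1, 2) else 0.8
            records.append((c, year, month, season + i + rng.normal(0, sd)))
temps = pd.DataFrame(records, columns=["unit_id", "year", "month", "temp"])

means = compute_long_term_means(temps)
anoms = compute_anomalies(temps, means)

mapping = pd.DataFrame({"unit_id": counties, "state": ["N"] * 3 + ["S"] * 3})
weights = pd.DataFrame({"unit_id": counties,
                        "population": [9e5, 3e5, 1e5, 7e5, 5e5, 2e5]})
state_anoms = aggregate_to_state(anoms, weights, mapping)

per_unit_month, median_size = mean_absolute_anomaly(state_anoms)
winter = per_unit_month[per_unit_month["month"] == 1]["mean_abs_anomaly"].mean()
summer = per_unit_month[per_unit_month["month"] == 8]["mean_abs_anomaly"].mean()

print(f"state-month anomaly records: {len(state_anoms)}")
print(f"median average anomaly size: {median_size:.2f} degC")
print(f"mean |anomaly| January: {winter:.2f} degC, August: {summer:.2f} degC")
# The median is the typical deviation a state experiences from its own
# long-term month norm; winter months are noisier than summer ones, which
# is the variability pattern the month-specific model terms absorb.
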