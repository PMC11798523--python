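"""Compute the three windowed predictors from a daily station export.

ex1 = mean daily minimum, 1 Dec - 28/29 Feb (winter chilling);
ex2 = mean daily mean, 1-31 Mar (spring forcing);
ex3 = mean daily mean, 1-10 Apr (late forcing).
Here the daily series is synthetic, written to CSV and read back exactly
as a real station file would be.
"""

import tempfile
from dataclasses import replace
from pathlib import Path

from phenossm import (
    compute_predictors,
    default_study_config,
    read_temperature_csv,
    simulate_dataset,
)
from phenossm.io import write_temperature_csv

cfg = replace(default_study_config(seed=5), years=(2000, 2009), daily_mode=True)
ds = simulate_dataset(cfg)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "station.csv"
    write_temperature_csv(ds.daily_series, path)
    series = read_temperature_csv(path)
    print(f"read {len(series)} daily records from {path.name}")

table = compute_predictors(series, (2000, 2009))
print("\nper-year predictors (degC):")
print(table.round(2).to_string(index=False))
print("\nex1 averages 90 or 91 days depending on leap February; "
      "a year outside station coverage would simply get NaN")
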