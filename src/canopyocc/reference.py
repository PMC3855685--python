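"""Published reference model-selection tables.

Two AICc model tables from a published Red-naped Sapsucker occupancy
study in northern Idaho mixed-conifer forest, used as recomputation
fixtures: one for the satellite (large-footprint waveform) LiDAR
candidate set (26 models, n = 73 sites) and one for the airborne
(discrete-return) candidate set (13 models, n = 82 sites). Each row is a
delta(AICc) <= 6 model with its coefficient estimates (blank = covariate
absent), df (= number of parameters K), logLik, AICc, delta, and printed
weight. The AICc/delta/weight columns can be recomputed from logLik, df
and n, which is what the validation suite does.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_table", "REFERENCE_TABLES"]

REFERENCE_TABLES = {
    "glas": {"file": "glas_model_table.csv", "n_sites": 73},
    "airborne": {"file": "airborne_model_table.csv", "n_sites": 82},
}


def load_reference_table(which: str) -> tuple[pd.DataFrame, int]:
    """Return (model table, number of survey sites) for 'glas' or 'airborne'."""
    try:
        meta = REFERENCE_TABLES[which]
    except KeyError:
        raise KeyError(f"unknown reference table {which!r}; "
                       f"choose from {sorted(REFERENCE_TABLES)}") from None
    src = resources.files("canopyocc.data").joinpath(meta["file"])
    with resources.as_file(src) as path:
        df = pd.read_csv(path)
    df["model"] = df["model"].astype(str)
    return df, meta["n_sites"]
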