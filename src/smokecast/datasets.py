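"""Bundled reference data.

The single bundled table is the published 2018-vs-2016 wildfire-season
summary for British Columbia's 16 Health Service Delivery Areas: census
population, population-weighted seasonal mean PM2.5 from the provincial
exposure model for both years, and reliever-inhaler dispensation totals.
It is used for worked examples and for checking the population-weighting
arithmetic against printed provincial values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_bc_hsda_summary"]


def load_bc_hsda_summary() -> pd.DataFrame:
    """The 16-row BC HSDA summary for the 2018 smoke season (one row per HSDA)."""
    with resources.files("smokecast.data").joinpath(
            "bc_hsda_summary_2018.csv").open() as f:
        return pd.read_csv(f, dtype={"hsda_id": str})
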