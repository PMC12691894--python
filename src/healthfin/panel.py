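"""Panel data model, CSV input/output, and run configuration.

The universal input is a long-format country-year panel of twelve
indicators: six health-spending measures (out-of-pocket, voluntary and
compulsory expenditure, each as USD per capita and as % of GDP) and six
outcomes (healthy life expectancy total/male/female in years; infant
mortality total/male/female per 1000 live births).

Long format (one row per country-year-indicator) is the canonical storage;
wide CSVs (one column per indicator) are melted on read. Values are written
with 10 significant digits so a write-read round trip is lossless at that
precision.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Recognised indicator codes, in canonical column order.
INDICATORS = (
    "oop_pc", "oop_gdp",
    "vol_pc", "vol_gdp",
    "comp_pc", "comp_gdp",
    "hale_total", "hale_male", "hale_female",
    "im_total", "im_male", "im_female",
)

#: The six spending indicators, grouped by financing mechanism.
SPENDING_GROUPS = {
    "oop": ("oop_pc", "oop_gdp"),
    "voluntary": ("vol_pc", "vol_gdp"),
    "compulsory": ("comp_pc", "comp_gdp"),
}

_PCT_GDP = {"oop_gdp", "vol_gdp", "comp_gdp"}
_HALE = {"hale_total", "hale_male", "hale_female"}


class PanelValidationError(ValueError):
    """Raised when a panel violates the data-model invariants."""


class SchemaError(ValueError):
    """Raised when an input file lacks a mandatory column."""


@dataclasses.dataclass
class RunConfig:
    """Tunable parameters of the full pipeline.

    Defaults reproduce the reference analysis: exponential weighting slope
    ``lam`` = 1.5, four financing clusters, three outcome tiers, K-means with
    50 random starts and 100 Lloyd iterations, a TOPSIS success threshold of
    70, and Türkiye as the distance-ranking reference.
    """

    lam: float = 1.5
    k_financing: int = 4
    k_outcome: int = 3
    nstart: int = 50
    max_iter: int = 100
    seed: int = 0
    success_threshold: float = 70.0
    reference_country: str = "Türkiye"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.k_financing < 2 or self.k_outcome < 2:
            raise ValueError("cluster counts must be >= 2")
        if self.nstart < 1 or self.max_iter < 1:
            raise ValueError("nstart and max_iter must be >= 1")
        if not 0 <= self.success_threshold <= 100:
            raise ValueError("success_threshold must lie in [0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, allow_unicode=True)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel invariants and return the panel sorted canonically.

    Raises :class:`PanelValidationError` on duplicate (country, year,
    indicator) keys, unknown indicator codes, or out-of-range values
    (% GDP outside [0, 100]; HALE outside (0, 100); negative spending or
    mortality). NaN values are allowed and handled downstream.
    """
    required = {"country", "year", "indicator", "value"}
    missing = required - set(panel.columns)
    if missing:
        raise SchemaError(f"panel is missing columns: {sorted(missing)}")

    bad = set(panel["indicator"]) - set(INDICATORS)
    if bad:
        raise PanelValidationError(f"unknown indicators: {sorted(bad)}")

    keys = panel[["country", "year", "indicator"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise PanelValidationError(
            f"duplicate key: ({dup['country']}, {dup['year']}, {dup['indicator']})"
        )

    vals = panel["value"].to_numpy(dtype=float)
    ind = panel["indicator"].to_numpy()
    obs = ~np.isnan(vals)
    pct = np.isin(ind, list(_PCT_GDP)) & obs
    if ((vals[pct] < 0) | (vals[pct] > 100)).any():
        raise PanelValidationError("% GDP indicator outside [0, 100]")
    hale = np.isin(ind, list(_HALE)) & obs
    if ((vals[hale] <= 0) | (vals[hale] >= 100)).any():
        raise PanelValidationError("HALE indicator outside (0, 100)")
    other = obs & ~pct & ~hale
    if (vals[other] < 0).any():
        raise PanelValidationError("negative per-capita or mortality value")

    out = panel.copy()
    out["year"] = out["year"].astype(int)
    return out.sort_values(["country", "year", "indicator"], ignore_index=True)


def read_panel(path: str | Path, schema: str = "long") -> pd.DataFrame:
    """Read a country-year panel CSV and return a validated long panel.

    ``schema='long'`` expects columns country, year, indicator, value;
    ``schema='wide'`` expects country, year plus one column per indicator
    and melts to long form. Non-numeric values raise a parse error naming
    the offending data row (1-based, excluding the header).
    """
    if schema not in ("long", "wide"):
        raise ValueError(f"schema must be 'long' or 'wide', got {schema!r}")
    df = pd.read_csv(path)

    if schema == "long":
        missing = {"country", "year", "indicator", "value"} - set(df.columns)
        if missing:
            raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
        value_cols = ["value"]
        long = df
    else:
        missing = {"country", "year"} - set(df.columns)
        if missing:
            raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
        value_cols = [c for c in df.columns if c in INDICATORS]
        if not value_cols:
            raise SchemaError("wide panel has no recognised indicator columns")
        long = None

    for col in value_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise PanelValidationError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at data row {row}"
            )
        df[col] = coerced

    if long is None:
        long = df.melt(
            id_vars=["country", "year"],
            value_vars=value_cols,
            var_name="indicator",
            value_name="value",
        )
    return validate_panel(long)


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    """Write a long panel to CSV with 10-significant-digit values."""
    validate_panel(panel).to_csv(path, index=False, float_format="%.10g")


def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read a 3-D embedding table with columns country, V1, V2, V3.

    Returns a DataFrame indexed by country with exactly the file's
    coordinate values; extra columns are passed through unchanged.
    """
    df = pd.read_csv(path)
    needed = {"country", "V1", "V2", "V3"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(
            f"coordinate table must have 3 dimensions (country, V1, V2, V3); "
            f"missing {sorted(missing)}"
        )
    return df.set_index("country")


def load_reference_coordinates() -> pd.DataFrame:
    """Load the packaged 3-D MDS coordinates of the 38 OECD health systems.

    The table carries the published embedding of the time-weighted
    2000-2021 spending profiles (columns V1-V3), each country's Euclidean
    distance to the Türkiye reference point, and the published 4-cluster
    financing typology (1 = High-Public-Spending, 2 = Balanced
    High-Expenditure, 3 = Moderate/Emerging, 4 = US Voluntary-Dominant).
    """
    ref = importlib.resources.files("healthfin.data") / "oecd_mds_coordinates.csv"
    with importlib.resources.as_file(ref) as p:
        return read_coordinates(p)
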