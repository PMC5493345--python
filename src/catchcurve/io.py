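"""Reading and writing the tabular interchange formats.

Length records travel as UTF-8 CSV with a header and one row per measured
individual: species, site, regime, ma_id, fishing_ground, year, length_mm.
Fit tables and comparison tables are tidy CSVs mirroring the in-memory
dataclasses.
"""

from __future__ import annotations

import pandas as pd

from . import design

RECORD_COLUMNS = [
    "species", "site", "regime", "ma_id", "fishing_ground", "year", "length_mm",
]

__all__ = ["RECORD_COLUMNS", "read_length_records", "write_length_records",
           "validate_records", "fits_table", "comparisons_table"]


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"length-record table missing columns: {missing}")
    if not (df["length_mm"] > 0).all():
        raise ValueError("length_mm must be positive")
    bad = ~df["regime"].isin(design.REGIMES)
    if bad.any():
        raise ValueError(
            f"unknown regimes {sorted(df.loc[bad, 'regime'].unique())}; "
            f"expected {design.REGIMES}"
        )
    nt_with_ma = (df["regime"] == design.NT) & df["ma_id"].notna()
    if nt_with_ma.any():
        raise ValueError("no-take records must not carry a management-area id")
    return df


def read_length_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ma_id": "string", "fishing_ground": "string"})
    return validate_records(df)


def write_length_records(df: pd.DataFrame, path) -> None:
    validate_records(df[RECORD_COLUMNS])
    df[RECORD_COLUMNS].to_csv(path, index=False)


def fits_table(fits: dict) -> pd.DataFrame:
    """Per-group fit table: group keys + z, se_z, ci, r2, recruit_age, ..."""
    rows = []
    for key, fit in fits.items():
        row = {"group": key if isinstance(key, str) else "|".join(map(str, key))}
        row.update(fit.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def comparisons_table(comparisons: list[dict]) -> pd.DataFrame:
    """Tidy comparison table: design, term, f, df_num, df_den, p."""
    return pd.DataFrame(
        comparisons, columns=["design", "term", "f", "df_num", "df_den", "p"]
    )
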