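"""Phenotype records: daily germination counts plus day-10 seedling measures.

One experimental unit is an accession x treatment x replicate germination box.
Records are carried as a validated :class:`pandas.DataFrame` (one row per
unit) rather than per-row objects; the schema below is the exchange contract
with the CSV on disk.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "KEY_COLUMNS",
    "TREATMENTS",
    "read_phenotype_csv",
    "validate_phenotypes",
    "write_phenotype_csv",
]

KEY_COLUMNS = ["accession", "treatment", "replicate"]
COUNT_COLUMNS = [f"n_day{i}" for i in range(1, 11)]
MEASUREMENT_COLUMNS = [
    "shoot_length_cm",
    "root_length_cm",
    "fresh_weight_mg",
    "dry_weight_mg",
]
TREATMENTS = ("control", "salinity")

_REQUIRED = KEY_COLUMNS + ["seeds_sown"] + COUNT_COLUMNS


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a phenotype frame in place-safe fashion.

    Enforces the schema invariants: unique (accession, treatment, replicate)
    keys, the closed two-treatment design, non-negative integer counts, and
    daily counts summing to at most the seeds sown. Measurement columns are
    optional and may hold missing values.
    """
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required columns: {missing}")
    df = df.copy()
    df["accession"] = df["accession"].astype(str)
    df["treatment"] = df["treatment"].astype(str)

    bad_treat = sorted(set(df["treatment"]) - set(TREATMENTS))
    if bad_treat:
        raise ValueError(
            f"treatment labels outside {set(TREATMENTS)}: {bad_treat}"
        )

    dup = df.duplicated(KEY_COLUMNS)
    if dup.any():
        keys = df.loc[dup, KEY_COLUMNS].to_records(index=False).tolist()
        raise ValueError(f"duplicated (accession, treatment, replicate) keys: {keys}")

    for col in ["replicate", "seeds_sown"] + COUNT_COLUMNS:
        values = pd.to_numeric(df[col], errors="raise")
        if (values < 0).any() or not np.allclose(values, values.round()):
            raise ValueError(f"column {col} must hold non-negative integers")
        df[col] = values.astype(int)
    if (df["seeds_sown"] < 1).any():
        raise ValueError("seeds_sown must be >= 1 for every record")

    total = df[COUNT_COLUMNS].sum(axis=1)
    over = total > df["seeds_sown"]
    if over.any():
        row = df.index[over][0]
        key = tuple(df.loc[row, KEY_COLUMNS])
        raise ValueError(
            f"daily counts sum to {total[row]} > seeds_sown {df.loc[row, 'seeds_sown']}"
            f" for record {key}"
        )

    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        else:
            df[col] = pd.to_numeric(df[col], errors="raise")
    lengths = df[["shoot_length_cm", "root_length_cm"]].to_numpy(dtype=float)
    if np.nanmin(lengths, initial=0.0) < 0:
        raise ValueError("seedling lengths must be >= 0")
    both = df["fresh_weight_mg"].notna() & df["dry_weight_mg"].notna()
    if (df.loc[both, "dry_weight_mg"] > df.loc[both, "fresh_weight_mg"]).any():
        raise ValueError("dry weight exceeds fresh weight in at least one record")
    return df[_REQUIRED + MEASUREMENT_COLUMNS]


def read_phenotype_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the daily-germination phenotype CSV."""
    return validate_phenotypes(pd.read_csv(path))


def write_phenotype_csv(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df).to_csv(path, index=False)
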