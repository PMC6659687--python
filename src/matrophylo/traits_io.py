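"""Species-by-trait tables.

Traits are carried as a pandas DataFrame indexed by species, with binary
reproductive/sexual-selection columns coded 0/1 (NaN = missing) and
continuous columns (matrotrophy index ``mi``, ``gonopodium_ratio``,
``ssd_index``).  Multiple population rows per species are averaged, as is
standard practice when species-level values are assembled from
population-level measurements.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BINARY_TRAITS = (
    "internal_fertilization",
    "viviparity",
    "placentotrophy",
    "superfetation",
    "courtship",
    "dichromatism",
    "ornamentation",
)
CONTINUOUS_TRAITS = ("mi", "gonopodium_ratio", "ssd_index")
MISSING_TOKENS = ("NA", "", "?", "na", "NaN", "nan")

__all__ = ["read_trait_table", "BINARY_TRAITS", "CONTINUOUS_TRAITS",
           "sexual_selection_index_column"]


def _to_numeric(series: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & ~series.astype(str).str.strip().isin(MISSING_TOKENS)
    if bad.any():
        logger.warning("column %s: %d unparseable cells set to missing",
                       column, int(bad.sum()))
    return out


def read_trait_table(path, sep: str | None = None,
                     drop_species: list[str] | None = None) -> pd.DataFrame:
    """Read a delimited trait table with a mandatory ``species`` column.

    ``NA``, empty strings and ``?`` are treated as missing.  Rows sharing a
    species name (population-level records) are averaged; binary columns are
    averaged only when consistent, otherwise set missing with a warning.
    ``drop_species`` removes listed species (e.g. duplicate populations kept
    under distinct names) before averaging.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python",
                     na_values=list(MISSING_TOKENS), keep_default_na=True,
                     dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    if "species" not in df.columns:
        raise ValueError(f"{path}: trait table must contain a 'species' column")
    df["species"] = df["species"].astype(str).str.strip()
    if drop_species:
        df = df[~df["species"].isin(set(drop_species))]

    value_cols = [c for c in df.columns if c not in ("species", "population")]
    for c in value_cols:
        df[c] = _to_numeric(df[c], c)

    for c in BINARY_TRAITS:
        if c in df.columns:
            bad = df[c].notna() & ~df[c].isin([0.0, 1.0])
            if bad.any():
                logger.warning("column %s: %d non-binary values set to missing",
                               c, int(bad.sum()))
                df.loc[bad, c] = np.nan

    grouped = df.groupby("species", sort=True)[value_cols].mean()
    # binary columns that disagree across populations of one species are
    # unusable as a species-level 0/1 score
    for c in BINARY_TRAITS:
        if c in grouped.columns:
            mixed = grouped[c].notna() & ~grouped[c].isin([0.0, 1.0])
            if mixed.any():
                logger.warning("species with conflicting %s across populations "
                               "set to missing: %s", c,
                               sorted(grouped.index[mixed]))
                grouped.loc[mixed, c] = np.nan
    grouped.index.name = "species"
    return grouped


def sexual_selection_index_column(traits: pd.DataFrame) -> pd.Series:
    """Sum of courtship + dichromatism + ornamentation (0-3), NaN if any missing."""
    from .scoring import sexual_selection_index

    vals = {}
    for sp, row in traits.iterrows():
        vals[sp] = sexual_selection_index(
            row.get("courtship", np.nan),
            row.get("dichromatism", np.nan),
            row.get("ornamentation", np.nan),
        )
    out = pd.Series(vals, name="sexual_selection_index", dtype=float)
    out.index.name = "species"
    return out
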