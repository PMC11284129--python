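"""Delimited-text and SAS-transport table input.

Analysis tables are plain delimited text (comma or tab, by extension).
`read_sas_transport` adapts a SAS XPT release file (the distribution
format of US national examination surveys) onto the package's column
dictionary through a user-supplied mapping, so real release files can
feed the same pipeline as synthetic tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def apply_column_map(df: pd.DataFrame, column_map: Mapping[str, str]) -> pd.DataFrame:
    """Rename source columns to the pipeline dictionary; keep only mapped ones.

    ``column_map`` maps source column names to pipeline names.  Raises
    if a mapped source column is absent.
    """
    missing = set(column_map) - set(df.columns)
    if missing:
        raise KeyError(f"source columns not found in table: {sorted(missing)}")
    return df[list(column_map)].rename(columns=dict(column_map))


def read_sas_transport(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a SAS XPT file, optionally mapping columns to pipeline names."""
    df = pd.read_sas(Path(path), format="xport")
    if column_map is not None:
        df = apply_column_map(df, column_map)
    return df
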