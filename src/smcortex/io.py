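"""Delimited-text readers/writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

LOCALIZATION_COLUMNS = ["frame", "x_um", "y_um", "z_um", "intensity"]
PROFILE_COLUMNS = ["cell_id", "x_um", "intensity_au"]
NODE_COLUMNS = ["node_id", "t_s", "intensity_au", "cell_length_um"]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _read(path: str | Path, required: list[str], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table {path} is missing columns {missing}")
    return df


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Localization table: frame, x_um, y_um, z_um, intensity[, event_id]."""
    return _read(path, ["frame", "x_um", "y_um"], "localization")


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Gradient profile table: cell_id, x_um, intensity_au."""
    return _read(path, PROFILE_COLUMNS, "profile")


def read_node_series(path: str | Path) -> pd.DataFrame:
    """Node time-series table: node_id, t_s, intensity_au, cell_length_um."""
    return _read(path, NODE_COLUMNS, "node series")
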