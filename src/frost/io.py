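"""Tabular I/O: comma-delimited UTF-8 tables, NA token "NA".

Every reader validates the header against its schema and names the
missing column on failure; writers emit a header row and the shared NA
convention so all stage outputs round-trip.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .community import CommunityMatrix
from .errors import InputError
from .thermogram import ThermogramTrace

NA_TOKEN = "NA"

TRACE_COLUMNS = ["species_id", "leaf_id", "time_s", "temp_C"]
DAMAGE_COLUMNS = ["species_id", "leaf_id", "treatment", "fv_fm"]
TRAIT_REQUIRED = ["species_id"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    frame = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False,
                        encoding="utf-8")
    for col in required:
        if col not in frame.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    return frame


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep=NA_TOKEN, encoding="utf-8")


def read_traces(path: str | Path) -> list[ThermogramTrace]:
    """Long-format cooling traces → validated per-leaf trace objects."""
    frame = _read_csv(path, TRACE_COLUMNS)
    traces = []
    for (species_id, leaf_id), grp in frame.groupby(
            ["species_id", "leaf_id"], sort=True):
        traces.append(ThermogramTrace.from_samples(
            str(leaf_id), str(species_id),
            grp["time_s"].to_numpy(float), grp["temp_C"].to_numpy(float)))
    return traces


def read_damage_records(path: str | Path) -> pd.DataFrame:
    frame = _read_csv(path, DAMAGE_COLUMNS)
    bad = frame[~frame["fv_fm"].between(0, 1)]
    if len(bad):
        raise InputError(f"{path}: fv_fm outside [0, 1] at line(s) "
                         f"{(bad.index + 2).tolist()}")
    return frame


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, TRAIT_REQUIRED)


def read_community(path: str | Path) -> CommunityMatrix:
    """Wide matrix: plot_id, altitude_m, then one cover column per species."""
    frame = _read_csv(path, ["plot_id", "altitude_m"])
    return CommunityMatrix.from_wide_frame(frame)
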