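"""CSV readers and writers for datasets, person-period tables and study output.

Wide subject files use the dialect: comma-separated, UTF-8, header row
``id,x,m,e1..eJ``; a missing (post-event) indicator is an empty cell.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .simulator import MISSING, SimulatedDataset

__all__ = [
    "write_dataset_csv",
    "read_dataset_csv",
    "write_person_period_csv",
    "write_bootstrap_draws_csv",
]

PathLike = Union[str, Path]


def write_dataset_csv(data: SimulatedDataset, path: PathLike) -> None:
    """Write a dataset as wide subject CSV (missing entries become empty cells)."""
    data.validate()
    cols = {"id": np.arange(data.n), "x": np.asarray(data.x, int),
            "m": np.asarray(data.m, float)}
    events = np.asarray(data.events)
    for j in range(data.J):
        col = events[:, j].astype(object)
        col[events[:, j] == MISSING] = None
        cols[f"e{j + 1}"] = col
    pd.DataFrame(cols).to_csv(path, index=False, na_rep="")


def read_dataset_csv(path: PathLike) -> SimulatedDataset:
    """Read a wide subject CSV back into a :class:`SimulatedDataset`.

    Empty event cells are interpreted as missing.  The structural
    invariants (at most one event per row, missing only after it) are
    validated and violations raise ``ValueError`` naming the row.
    """
    # round_trip parsing so a write/read cycle reproduces m bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    event_cols = sorted(
        (c for c in df.columns if c.startswith("e") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not event_cols:
        raise ValueError(f"{path}: no event columns e1..eJ found")
    expected = [f"e{j}" for j in range(1, len(event_cols) + 1)]
    if event_cols != expected:
        raise ValueError(f"{path}: event columns must be consecutive e1..eJ")
    for col in ("x", "m"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    events = df[event_cols].to_numpy(float)
    coded = np.where(np.isnan(events), MISSING, events).astype(np.int8)
    data = SimulatedDataset(
        x=df["x"].to_numpy(np.int8),
        m=df["m"].to_numpy(float),
        events=coded,
    )
    data.validate()
    return data


def write_person_period_csv(table: pd.DataFrame, path: PathLike) -> None:
    """Tidy long-format export with columns id, j, event, x, m."""
    table[["id", "j", "event", "x", "m"]].to_csv(path, index=False)


def write_bootstrap_draws_csv(draws: np.ndarray, path: PathLike, name: str = "ab") -> None:
    """Single-column audit dump of the bootstrap draws."""
    pd.DataFrame({name: np.asarray(draws, float)}).to_csv(path, index=False)
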