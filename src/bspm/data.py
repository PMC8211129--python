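"""Trajectory containers and plain-text I/O.

Analyses operate on sets of registered trials: a J x Q matrix whose rows are
trials (or subjects, or gait cycles) and whose columns are the Q nodes of a
time-normalised movement (conventionally Q = 101, i.e. 0-100% of the cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrajectorySet", "TrajectoryParseError", "read_trajectories",
           "write_trajectories", "node_to_pct"]


class TrajectoryParseError(ValueError):
    """A trajectory file failed validation; the message names the offending
    row and column (1-based, header excluded)."""


def node_to_pct(node: int, q: int) -> float:
    """Percent of movement time for a 1-based node index on a Q-node field."""
    return 100.0 * (node - 1) / (q - 1)


@dataclass(frozen=True)
class TrajectorySet:
    """A J x Q matrix of registered trials of one variable.

    Values carry the units of the measured variable (degrees, N, ...).
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"trajectory matrix must be 2-D, got shape {arr.shape}")
        if arr.shape[1] < 3:
            raise ValueError(f"need at least 3 nodes, got {arr.shape[1]}")
        if arr.shape[0] < 1:
            raise ValueError("need at least one trial")
        if not np.isfinite(arr).all():
            j, q = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at trial {j + 1}, node {q + 1}"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def pct(self) -> np.ndarray:
        """Node positions in percent of movement time (0 ... 100)."""
        return np.linspace(0.0, 100.0, self.n_nodes)

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.values.std(axis=0, ddof=1)


def _has_header(first_line: str, delimiter: str) -> bool:
    for tok in first_line.strip().split(delimiter):
        tok = tok.strip()
        if not tok:
            continue
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_trajectories(path, delimiter: str | None = None,
                      label: str | None = None) -> TrajectorySet:
    """Read a rectangular trial matrix from a CSV/TSV file.

    Rows are trials, columns are nodes; an optional single header row of
    node labels is detected and skipped.  Ragged rows, non-numeric cells
    and missing values raise :class:`TrajectoryParseError` naming the
    offending coordinates.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if delimiter is None:
        delimiter = "\t" if "\t" in first else ","
    header = 0 if _has_header(first, delimiter) else None
    try:
        df = pd.read_csv(path, sep=delimiter, header=header,
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TrajectoryParseError(f"{path}: {exc}") from exc

    raw = df.to_numpy()
    numeric = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(df.iloc[:, j], errors="coerce").to_numpy()
        numeric[:, j] = col
    bad = np.argwhere(~np.isfinite(numeric))
    if bad.size:
        i, j = bad[0]
        raise TrajectoryParseError(
            f"{path}: missing or non-numeric value at row {i + 1}, "
            f"column {j + 1}"
        )
    return TrajectorySet(values=numeric, label=label or path.stem)


def write_trajectories(tset: TrajectorySet, path, delimiter: str = ",") -> None:
    """Write a trial matrix as delimited text (full float precision, so a
    write-read round trip reproduces the values bit for bit)."""
    np.savetxt(path, tset.values, delimiter=delimiter, fmt="%.17g")
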