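"""Readers and writers for PLUMED-dialect COLVAR and HILLS text files.

Both formats are whitespace-separated numeric tables with a single header
line ``#! FIELDS time <column names...>``.  A COLVAR file carries one frame
of collective-variable (CV) values per row; a HILLS file carries one
deposited Gaussian kernel per row, with columns
``time <centers> <sigmas> height biasf``.

Only the FIELDS header is interpreted; other ``#!`` metadata lines are
preserved on read as a list of raw strings and ignored otherwise.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ColvarData", "read_colvar", "write_colvar", "read_hills", "write_hills"]


@dataclass
class ColvarData:
    """A parsed COLVAR table: column names (excluding ``time``), the time
    column, and the value matrix of shape ``(n_frames, n_columns)``."""

    names: list[str]
    time: np.ndarray
    values: np.ndarray
    extra_header: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (self.time.size, len(self.names)):
            raise ValueError(
                f"value matrix {self.values.shape} inconsistent with "
                f"{self.time.size} times x {len(self.names)} names"
            )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def _parse_table(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    header: list[str] | None = None
    extra: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                tokens = line.split()
                if len(tokens) >= 2 and tokens[1] == "FIELDS":
                    header = tokens[2:]
                else:
                    extra.append(line)
                continue
            if line.startswith("#"):
                continue
            rows.append([float(t) for t in line.split()])
    if header is None:
        raise ValueError(f"{path}: missing '#! FIELDS' header line")
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(header))
    return header, data, extra


def read_colvar(path: str | Path) -> ColvarData:
    """Read a COLVAR-dialect file.  The first FIELDS column must be ``time``."""
    header, data, extra = _parse_table(path)
    if header[0] != "time":
        raise ValueError(f"{path}: first FIELDS column must be 'time', got {header[0]!r}")
    return ColvarData(names=header[1:], time=data[:, 0], values=data[:, 1:], extra_header=extra)


def write_colvar(path: str | Path, names: list[str], values: np.ndarray,
                 time: np.ndarray | None = None) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if time is None:
        time = np.arange(values.shape[0], dtype=float)
    time = np.asarray(time, dtype=float)
    if values.shape != (time.size, len(names)):
        raise ValueError("shape mismatch between names, time and values")
    buf = io.StringIO()
    buf.write("#! FIELDS time " + " ".join(names) + "\n")
    table = np.column_stack([time, values])
    np.savetxt(buf, table, fmt="%.10g")
    Path(path).write_text(buf.getvalue())


def read_hills(path: str | Path) -> dict[str, np.ndarray | list[str]]:
    """Read a HILLS-dialect file into arrays of kernel parameters.

    Returns a dict with keys ``cv_names`` (list of the biased CV names),
    ``time``, ``centers`` ``(n, d)``, ``sigmas`` ``(n, d)``, ``heights``
    ``(n,)`` and ``biasf`` ``(n,)``.
    """
    header, data, _ = _parse_table(path)
    if header[0] != "time" or header[-1] != "biasf" or header[-2] != "height":
        raise ValueError(f"{path}: HILLS header must be 'time <centers> <sigmas> height biasf'")
    cv_cols = header[1:-2]
    if len(cv_cols) % 2 != 0:
        raise ValueError(f"{path}: center/sigma columns unpaired: {cv_cols}")
    d = len(cv_cols) // 2
    names = cv_cols[:d]
    for name, sig in zip(names, cv_cols[d:]):
        if sig != f"sigma_{name}":
            raise ValueError(f"{path}: expected sigma_{name}, got {sig}")
    return {
        "cv_names": names,
        "time": data[:, 0],
        "centers": data[:, 1:1 + d],
        "sigmas": data[:, 1 + d:1 + 2 * d],
        "heights": data[:, 1 + 2 * d],
        "biasf": data[:, 2 + 2 * d],
    }


def write_hills(path: str | Path, cv_names: list[str], time: np.ndarray,
                centers: np.ndarray, sigmas: np.ndarray, heights: np.ndarray,
                biasf: float | np.ndarray) -> None:
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    sigmas = np.atleast_2d(np.asarray(sigmas, dtype=float))
    n = centers.shape[0]
    biasf = np.broadcast_to(np.asarray(biasf, dtype=float), (n,))
    header = (["time"] + list(cv_names) + [f"sigma_{c}" for c in cv_names]
              + ["height", "biasf"])
    buf = io.StringIO()
    buf.write("#! FIELDS " + " ".join(header) + "\n")
    table = np.column_stack([np.asarray(time, float), centers, sigmas,
                             np.asarray(heights, float), biasf])
    # %.17g keeps float64 round-trips bit-exact for frozen-bias serialization
    np.savetxt(buf, table, fmt="%.17g")
    Path(path).write_text(buf.getvalue())
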