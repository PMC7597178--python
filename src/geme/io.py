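"""Delimited-text readers and writers for networks and time series.

Networks are small dense matrices (n up to a few hundred), so plain
comma- or tab-separated text is the interchange format.  Files may carry an
optional header row and label column with node names.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .embedding import PointSet
from .exceptions import ValidationError
from .network import SYMMETRY_TOL, WeightedNetwork

#: output precision: 10 significant digits, reproducible across platforms
FLOAT_FMT = "%.10g"


def _sniff_delimiter(first_line: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if "," in first_line else "\t" if "\t" in first_line else " "


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_table(
    path: str | os.PathLike, delimiter: str | None
) -> tuple[list[list[str]], str]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"empty input file: {path}")
    delim = _sniff_delimiter(lines[0], delimiter)
    rows = [
        [tok for tok in (ln.split(delim) if delim != " " else ln.split())]
        for ln in lines
    ]
    rows = [[tok.strip() for tok in row if tok.strip() != ""] for row in rows]
    return rows, delim


def _parse_numeric(rows: list[list[str]], path: str) -> np.ndarray:
    width = len(rows[0])
    data = np.empty((len(rows), width))
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValidationError(
                f"{path}: ragged rows ({len(row)} fields on row {i + 1}, "
                f"expected {width})"
            )
        for j, tok in enumerate(row):
            if not _is_number(tok):
                raise ValidationError(
                    f"{path}: non-numeric cell {tok!r} at row {i + 1}, "
                    f"column {j + 1}"
                )
            data[i, j] = float(tok)
    return data


def read_adjacency(
    path: str | os.PathLike,
    delimiter: str | None = None,
    has_labels: bool | None = None,
) -> WeightedNetwork:
    """Read a dense symmetric adjacency matrix from delimited text.

    ``has_labels=None`` auto-detects a header row plus leading label column
    (present when the top-left region is non-numeric).  Asymmetry within
    ``SYMMETRY_TOL`` is averaged away; larger asymmetry is an error.
    """
    rows, _ = _read_table(path, delimiter)
    if has_labels is None:
        has_labels = len(rows) > 1 and (
            not _is_number(rows[1][0]) or len(rows[0]) == len(rows[1]) - 1
        )
    labels: tuple[str, ...] = ()
    if has_labels:
        header = rows[0]
        body = rows[1:]
        # header may or may not include a corner cell above the label column
        labels = tuple(header[-len(body) :])
        rows = [r[1:] for r in body]
    data = _parse_numeric(rows, str(path))
    if data.shape[0] != data.shape[1]:
        raise ValidationError(
            f"{path}: matrix is not square (shape {data.shape[0]}x{data.shape[1]})"
        )
    asym = np.abs(data - data.T).max() if data.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValidationError(
            f"{path}: asymmetry {asym:g} exceeds tolerance {SYMMETRY_TOL:g}"
        )
    return WeightedNetwork(data, labels)


def write_adjacency(
    net: WeightedNetwork, path: str | os.PathLike, delimiter: str = ","
) -> None:
    """Write a network as delimited text with a header row and label column."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(("node", *net.node_labels)) + "\n")
        for label, row in zip(net.node_labels, net.weights):
            fh.write(
                delimiter.join((label, *(FLOAT_FMT % v for v in row))) + "\n"
            )


def read_timeseries(
    path: str | os.PathLike,
    delimiter: str | None = None,
    orientation: str = "nodes-in-rows",
) -> np.ndarray:
    """Read a node-by-time matrix from delimited text.

    ``orientation`` declares the file layout; the returned matrix is always
    nodes x time.
    """
    if orientation not in ("nodes-in-rows", "nodes-in-columns"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    rows, _ = _read_table(path, delimiter)
    if not _is_number(rows[0][0]):
        rows = rows[1:]  # tolerate a header line
        if not rows:
            raise ValidationError(f"{path}: no numeric rows")
    data = _parse_numeric(rows, str(path))
    return data if orientation == "nodes-in-rows" else data.T


def write_coordinates(
    points: PointSet,
    node_labels: tuple[str, ...],
    path: str | os.PathLike,
    delimiter: str = ",",
) -> None:
    """Write embedded coordinates, one row per node: label, x1 .. xk."""
    coords = points.coordinates
    with open(path, "w") as fh:
        fh.write(
            delimiter.join(("node", *(f"x{i + 1}" for i in range(points.k)))) + "\n"
        )
        for j, label in enumerate(node_labels):
            fh.write(
                delimiter.join((label, *(FLOAT_FMT % v for v in coords[:, j])))
                + "\n"
            )
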