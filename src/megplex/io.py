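"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as full (not triangular) labelled TSV, UTF-8, 6 significant
digits by default (raised to 12 for supra/eigenvector artifacts consumed
downstream). Time series are TSV with one header row of region labels and
the sampling frequency in a JSON sidecar (key ``fs_hz``) or in config.
Node sets are one region label per line. All statistical results are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import TimeSeries

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_timeseries",
    "write_timeseries_tsv",
    "read_node_set",
    "write_node_set",
    "read_vector_tsv",
    "write_vector_tsv",
    "write_json",
]

SYMMETRY_ATOL = 1e-9


def write_matrix_tsv(
    path: str | Path,
    matrix: np.ndarray,
    labels: list[str],
    sig_digits: int = 6,
) -> None:
    """Write a labelled square matrix as TSV (header row + index column)."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError(f"matrix is not square: {matrix.shape}")
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for a {n}x{n} matrix")
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format=f"%.{sig_digits}g")


def read_matrix_tsv(
    path: str | Path, repair: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Read a labelled square matrix from TSV.

    Row and column labels must match. Asymmetry up to ``1e-9`` is
    symmetrized silently by averaging; beyond that an error names the worst
    cell, unless ``repair=True``, which symmetrizes with a warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square"
        )
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise ValueError(
            f"{path}: row labels differ from column labels "
            f"(first mismatch: {next((r, c) for r, c in zip(rows, cols) if r != c)})"
        )
    try:
        matrix = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix entries: {exc}") from exc
    asym = np.abs(matrix - matrix.T)
    worst = float(asym.max()) if asym.size else 0.0
    if worst > SYMMETRY_ATOL:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        msg = (
            f"{path}: matrix asymmetric beyond {SYMMETRY_ATOL:g} at cell "
            f"({rows[i]}, {cols[j]}): |{matrix[i, j]:g} - {matrix[j, i]:g}| "
            f"= {worst:g}"
        )
        if not repair:
            raise ValueError(msg)
        warnings.warn(msg + "; symmetrizing by averaging", stacklevel=2)
    matrix = (matrix + matrix.T) / 2.0
    return matrix, rows


def write_timeseries_tsv(
    path: str | Path, ts: TimeSeries, sig_digits: int = 8
) -> None:
    """Write a recording as TSV (regions in columns) plus a ``.json``
    sidecar carrying ``fs_hz``."""
    df = pd.DataFrame(ts.samples, columns=ts.region_labels)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{sig_digits}g")
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(json.dumps({"fs_hz": ts.fs}) + "\n")


def read_timeseries(path: str | Path, fs: float | None = None) -> TimeSeries:
    """Read a recording from TSV (one header row of region labels) or a
    ``.npy`` array container.

    The sampling frequency comes from ``fs`` or from a ``<path>.json``
    sidecar with key ``fs_hz``.
    """
    path = Path(path)
    if fs is None:
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: sampling frequency not given and sidecar "
                f"{sidecar.name} not found"
            )
        fs = float(json.loads(sidecar.read_text())["fs_hz"])
    if path.suffix == ".npy":
        samples = np.load(path)
        return TimeSeries(samples=samples, fs=fs)
    df = pd.read_csv(path, sep="\t")
    return TimeSeries(
        samples=df.to_numpy(dtype=float),
        fs=fs,
        region_labels=[str(c) for c in df.columns],
    )


def read_node_set(path: str | Path) -> list[str]:
    """One region label per line; blank lines and ``#`` comments ignored."""
    labels = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            labels.append(line)
    if not labels:
        raise ValueError(f"{path}: node-set file contains no labels")
    return labels


def write_node_set(path: str | Path, labels: list[str]) -> None:
    Path(path).write_text("\n".join(labels) + "\n")


def write_vector_tsv(
    path: str | Path, values: np.ndarray, labels: list[str],
    column: str = "value", sig_digits: int = 12,
) -> None:
    df = pd.DataFrame({"region": labels, column: np.asarray(values, float)})
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{sig_digits}g")


def read_vector_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 1].to_numpy(dtype=float), [str(x) for x in df.iloc[:, 0]]


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
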