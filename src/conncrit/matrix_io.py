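"""Plain-text connectivity-matrix files.

The on-disk format mirrors public connectivity-matrix databases: one square
numeric matrix per file, whitespace- or comma-delimited, optionally preceded
by a single header line of region labels.  The reader symmetrises by
averaging ``(w_ij + w_ji)/2`` and zeroes the diagonal, logging whenever it
has to repair either.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import MatrixParseError
from .metrics import ConnectivityMatrix

__all__ = ["read_matrix", "write_matrix"]

logger = logging.getLogger("conncrit.matrix_io")


def write_matrix(matrix: ConnectivityMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix as delimited text, with a label header when present."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if matrix.region_labels is not None:
            fh.write(delimiter.join(matrix.region_labels) + "\n")
        for row in matrix.weights:
            fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")


def _tokenize(line: str) -> list[str]:
    line = line.strip()
    if "," in line:
        return [tok.strip() for tok in line.split(",") if tok.strip() != ""]
    return line.split()


def read_matrix(path) -> ConnectivityMatrix:
    """Read a square numeric text matrix, repairing asymmetry and diagonal."""
    path = Path(path)
    raw_lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if not raw_lines:
        raise MatrixParseError(f"{path}: file is empty")
    rows = [_tokenize(ln) for ln in raw_lines]
    labels = None
    try:
        float(rows[0][0])
    except ValueError:
        labels = rows[0]
        rows = rows[1:]
        if not rows:
            raise MatrixParseError(f"{path}: header but no matrix rows")
    n = len(rows)
    parsed = np.empty((n, len(rows[0])))
    for i, toks in enumerate(rows):
        if len(toks) != len(rows[0]):
            raise MatrixParseError(
                f"{path}: row {i + 1} has {len(toks)} columns, expected {len(rows[0])}"
            )
        for j, tok in enumerate(toks):
            try:
                parsed[i, j] = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric cell {tok!r} at row {i + 1}, column {j + 1}"
                ) from None
    if parsed.shape[0] != parsed.shape[1]:
        raise MatrixParseError(
            f"{path}: matrix is not square ({parsed.shape[0]}x{parsed.shape[1]})"
        )
    asym = float(np.max(np.abs(parsed - parsed.T))) if parsed.size else 0.0
    if asym > 0:
        logger.warning(
            "%s: asymmetric by up to %.3g; symmetrising as (w_ij + w_ji)/2",
            path,
            asym,
        )
        parsed = 0.5 * (parsed + parsed.T)
    if np.any(np.diag(parsed) != 0):
        logger.warning("%s: nonzero diagonal; zeroing self-connections", path)
        np.fill_diagonal(parsed, 0.0)
    if labels is not None and len(labels) != parsed.shape[0]:
        raise MatrixParseError(
            f"{path}: {len(labels)} header labels for {parsed.shape[0]} rows"
        )
    return ConnectivityMatrix(weights=parsed, region_labels=labels)
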