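"""Plain-text readers/writers for the formats the pipeline exchanges.

BED3+ for interval sets, two-column chrom.sizes, TSV for cell metadata and
result tables, MatrixMarket (MTX) with row/column index files for
cell-by-feature matrices.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .genome import GenomeLayout, RegionSet


def write_matrix(
    path_prefix: str | Path,
    matrix,
    row_ids: Sequence[str],
    col_ids: Sequence[str],
) -> None:
    """Write ``<prefix>.mtx`` plus ``<prefix>.rows.txt`` / ``<prefix>.cols.txt``."""
    path_prefix = Path(path_prefix)
    X = sp.coo_matrix(matrix)
    scipy.io.mmwrite(str(path_prefix.with_suffix(".mtx")), X)
    path_prefix.with_suffix(".rows.txt").write_text("\n".join(map(str, row_ids)) + "\n")
    path_prefix.with_suffix(".cols.txt").write_text("\n".join(map(str, col_ids)) + "\n")


def read_matrix(path_prefix: str | Path):
    """Read back a matrix written by :func:`write_matrix`."""
    path_prefix = Path(path_prefix)
    X = sp.csr_matrix(scipy.io.mmread(str(path_prefix.with_suffix(".mtx"))))
    rows = path_prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = path_prefix.with_suffix(".cols.txt").read_text().splitlines()
    return X, rows, cols


def write_cells(path: str | Path, cells: pd.DataFrame) -> None:
    cells.to_csv(path, sep="\t", index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dar_bed(path: str | Path, dars: pd.DataFrame) -> None:
    """DARs as BED6+: chrom, start, end, peak_id, -log10 adjusted p, direction."""
    import numpy as np

    out = dars[["chrom", "start", "end", "peak_id"]].copy()
    out["score"] = -np.log10(np.maximum(dars["adjusted_p"], 1e-300))
    out["direction"] = dars["direction"]
    out.to_csv(path, sep="\t", header=False, index=False)


__all__ = [
    "GenomeLayout", "RegionSet",
    "write_matrix", "read_matrix", "write_cells", "read_cells",
    "write_table", "read_table", "write_dar_bed",
]
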