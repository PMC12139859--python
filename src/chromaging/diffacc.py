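"""Proportion-based differential accessibility between age groups.

Accessibility is binarized per cell, so a peak's signal in a group of cells
is the fraction of cells in which it is detected.  Differential testing
between a young and an old group uses a two-sided two-proportion z-test with
pooled variance on those detection fractions, followed by Benjamini-Hochberg
adjustment across all peaks tested in the same comparison family
(conventionally one (cell_type, region, sex) combination).

Filtering follows the standard practice for sparse single-nucleus data:
peaks must be detected in at least 1% of cells in either age group, exceed a
minimum |log2 fold change| (0.25 for the permissive set, 0.5 for the strict
set), and pass adjusted p < 0.01.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .genome import ConfigError


def pseudobulk_fractions(
    matrix,
    cells: pd.DataFrame,
    group_by: str | Sequence[str],
    groups: Sequence | None = None,
) -> pd.DataFrame:
    """Per-peak detection fraction within each metadata group.

    Parameters
    ----------
    matrix
        Binary (or binarizable: any nonzero entry counts as detected)
        cell-by-peak matrix, dense or sparse, rows aligned with ``cells``.
    cells
        Per-cell metadata; must contain every ``group_by`` key.
    group_by
        Metadata key(s) defining the groups.
    groups
        Optional explicit group levels.  Levels with zero cells are
        reported with ``n_cells = 0`` and missing (NaN) fractions rather
        than zeros.

    Returns
    -------
    Long-format frame with columns ``peak_id`` (positional index if the
    matrix has no column names), ``group``, ``n_cells``,
    ``accessible_fraction``.
    """
    keys = [group_by] if isinstance(group_by, str) else list(group_by)
    for k in keys:
        if k not in cells.columns:
            raise ConfigError(f"unknown group key {k!r}")
    if matrix.shape[0] != len(cells):
        raise ConfigError("matrix rows and cell table rows differ")

    label = cells[keys[0]].astype(object) if len(keys) == 1 else \
        pd.Series(list(zip(*(cells[k] for k in keys))), index=cells.index, dtype=object)
    levels = list(pd.unique(label)) if groups is None else list(groups)

    X = matrix
    if sp.issparse(X):
        X = (X != 0).astype(np.int64)
    else:
        X = (np.asarray(X) != 0).astype(np.int64)

    n_peaks = X.shape[1]
    peak_ids = np.arange(n_peaks)
    out = []
    lab = label.to_numpy()
    for lev in levels:
        mask = np.array([x == lev for x in lab])
        n = int(mask.sum())
        if n == 0:
            frac = np.full(n_peaks, np.nan)
        else:
            det = np.asarray(X[mask].sum(axis=0)).ravel()
            frac = det / n
        out.append(pd.DataFrame({
            "peak_id": peak_ids,
            "group": [lev] * n_peaks,
            "n_cells": n,
            "accessible_fraction": frac,
        }))
    return pd.concat(out, ignore_index=True)


def test_differential_accessibility(
    fractions: pd.DataFrame,
    young,
    old,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Two-proportion z-test of old vs. young detection fractions per peak.

    ``log2_fold_change = log2((p_old + eps) / (p_young + eps))`` with
    ``eps`` defaulting to ``1 / (n_young + n_old)``.  The p-value is a
    two-sided pooled-variance two-proportion z-test; peaks where either
    group has fewer than 2 cells are skipped with a warning.  Adjusted
    p-values are Benjamini-Hochberg over the tested peaks; callers testing
    several (cell_type, region, sex) families should call once per family.
    Direction is the sign of the fold change; exact zeros get ``"none"``
    and belong to neither direction set.
    """
    wide_f = fractions.pivot(index="peak_id", columns="group", values="accessible_fraction")
    wide_n = fractions.pivot(index="peak_id", columns="group", values="n_cells")
    for g in (young, old):
        if g not in wide_f.columns:
            raise ConfigError(f"group {g!r} not present in fraction table")

    n1 = wide_n[young].to_numpy(dtype=float)
    n2 = wide_n[old].to_numpy(dtype=float)
    p1 = wide_f[young].to_numpy(dtype=float)
    p2 = wide_f[old].to_numpy(dtype=float)

    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    if not ok.all():
        warnings.warn(f"skipping {int((~ok).sum())} peaks with a group of < 2 cells")
    n1, n2, p1, p2 = n1[ok], n2[ok], p1[ok], p2[ok]
    peak_ids = wide_f.index.to_numpy()[ok]
    if pseudocount is None:
        eps = 1.0 / (n1 + n2)
    else:
        if pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")
        eps = np.full_like(p1, float(pseudocount))

    lfc = np.log2((p2 + eps) / (p1 + eps))
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p2 - p1) / np.sqrt(var), 0.0)
    pval = 2 * norm.sf(np.abs(z))
    adj = multipletests(pval, method="fdr_bh")[1] if len(pval) else pval

    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    return pd.DataFrame({
        "peak_id": peak_ids,
        "frac_young": p1,
        "frac_old": p2,
        "n_young": n1.astype(int),
        "n_old": n2.astype(int),
        "log2_fold_change": lfc,
        "p_value": pval,
        "adjusted_p": adj,
        "direction": direction,
    })


def filter_dars(
    table: pd.DataFrame,
    fractions: pd.DataFrame | None = None,
    min_detect: float = 0.01,
    min_abs_lfc: float = 0.25,
    max_adj_p: float = 0.01,
) -> pd.DataFrame:
    """Detection, effect-size and significance filters on a differential table.

    Keeps peaks detected in at least ``min_detect`` of cells in either
    group, with ``|log2FC| >= min_abs_lfc`` and ``adjusted_p < max_adj_p``.
    Both conventional fold-change thresholds (0.25 permissive, 0.5 strict)
    are supported through ``min_abs_lfc``.  Detection fractions are taken
    from ``table`` itself (``frac_young``/``frac_old``) or from a separate
    fraction table.
    """
    if min_detect < 0 or min_abs_lfc < 0 or max_adj_p <= 0:
        raise ConfigError("thresholds must be positive")
    t = table.copy()
    if "frac_young" in t.columns and "frac_old" in t.columns:
        max_frac = np.maximum(t["frac_young"], t["frac_old"])
    elif fractions is not None:
        mx = fractions.groupby("peak_id")["accessible_fraction"].max()
        max_frac = t["peak_id"].map(mx).to_numpy()
    else:
        raise ConfigError("need detection fractions in table or a fraction table")
    keep = (
        (max_frac >= min_detect)
        & (t["log2_fold_change"].abs() >= min_abs_lfc)
        & (t["adjusted_p"] < max_adj_p)
    )
    return t.loc[keep].reset_index(drop=True)
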