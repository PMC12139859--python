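"""Cell-type composition across ages: weighted proportions and trend tests.

Samples are replicate-level biological units (region x sex x replicate at
one age).  Proportions are per-sample cell-type fractions; the default
"equal-sample" weighting gives every sample at an age the same weight, so
large regions do not dominate cross-sample averages.  Age trends are tested
per cell type with a two-sided Wilcoxon rank-sum test on the per-sample
proportions (exact by enumeration for small tie-free groups, normal
approximation with tie correction otherwise).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .genome import ConfigError

SAMPLE_KEYS = ("region", "sex", "replicate", "age")


def weighted_proportions(
    cells: pd.DataFrame,
    weight_scheme: str = "equal-sample",
    sample_keys: Sequence[str] = SAMPLE_KEYS,
) -> pd.DataFrame:
    """Per-sample cell-type proportions with sampling weights.

    Every cell type observed anywhere is reported in every sample (zero
    proportion when absent), so declines to absence remain testable.
    ``weight_scheme``:

    - ``"equal-sample"``: each sample weighs ``1 / (number of samples at its age)``;
    - ``"by-cell-count"``: each sample weighs its share of cells at its age.
    """
    sample_keys = list(sample_keys)
    if weight_scheme not in ("equal-sample", "by-cell-count"):
        raise ConfigError(f"unknown weight scheme {weight_scheme!r}")
    counts = (
        cells.groupby(sample_keys + ["cell_type"], observed=True)
        .size().rename("n_cells").reset_index()
    )
    # complete the (sample x cell type) grid with zeros
    samples = counts[sample_keys].drop_duplicates()
    grid = samples.merge(pd.DataFrame({"cell_type": cells["cell_type"].unique()}), how="cross")
    counts = grid.merge(counts, on=sample_keys + ["cell_type"], how="left").fillna({"n_cells": 0})
    counts["n_cells"] = counts["n_cells"].astype(int)

    totals = counts.groupby(sample_keys)["n_cells"].transform("sum")
    empty = totals == 0
    if empty.any():
        warnings.warn("dropping empty samples")
        counts = counts.loc[~empty]
        totals = totals.loc[~empty]
    counts["proportion"] = counts["n_cells"] / totals

    n_samples_per_age = samples.groupby("age").size()
    if weight_scheme == "equal-sample":
        counts["weight"] = counts["age"].map(1.0 / n_samples_per_age)
    else:
        age_totals = counts.groupby("age")["n_cells"].transform("sum")
        counts["weight"] = totals / age_totals
    return counts.reset_index(drop=True)


def mean_proportions_by_age(props: pd.DataFrame) -> pd.DataFrame:
    """Weighted mean proportion per (cell type, age)."""
    def wmean(g: pd.DataFrame) -> float:
        return float(np.average(g["proportion"], weights=g["weight"]))
    out = (
        props.groupby(["cell_type", "age"])[["proportion", "weight"]]
        .apply(wmean).rename("mean_proportion").reset_index()
    )
    return out


def test_age_trend(
    props: pd.DataFrame,
    cell_type: str | None = None,
    ages: tuple[int, int] = (2, 18),
    exact_max_n: int = 12,
) -> pd.DataFrame:
    """Two-sided rank-sum test of proportion change between two ages.

    Exact enumeration when both groups have at most ``exact_max_n`` samples
    and there are no ties; tie-corrected normal approximation otherwise.
    Direction is the sign of the old-minus-young median difference.
    """
    young, old = ages
    cts = [cell_type] if cell_type is not None else sorted(props["cell_type"].unique())
    rows = []
    for ct in cts:
        sub = props.loc[props["cell_type"] == ct]
        x = sub.loc[sub["age"] == young, "proportion"].to_numpy(dtype=float)
        y = sub.loc[sub["age"] == old, "proportion"].to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ConfigError(f"need >= 2 samples per age group for {ct!r}")
        ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        exact = (not ties) and max(len(x), len(y)) <= exact_max_n
        res = mannwhitneyu(y, x, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
        diff = float(np.median(y) - np.median(x))
        rows.append({
            "cell_type": ct,
            "n_young": len(x), "n_old": len(y),
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "direction": "decrease" if diff < 0 else ("increase" if diff > 0 else "none"),
            "median_young": float(np.median(x)),
            "median_old": float(np.median(y)),
            "exact": exact,
        })
    return pd.DataFrame(rows)
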