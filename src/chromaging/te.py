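"""Pseudo-bulk TE-subfamily quantification and an age-differential test.

Single-cell counts are summed over (cell type, age, replicate) groups into
bulk-like profiles, normalized with median-of-ratios size factors, and
tested for age differences by permuting replicate age labels.  The
permutation test is exhaustive over distinct label splits when few exist,
Monte-Carlo with the +1 correction otherwise.  With very few replicates the
per-feature permutation p-value has a coarse floor (2/6 at 2v2, 2/70 at
4v4); the pooled mode standardizes the statistic and pools the permutation
null across features (SAM-style) for finer resolution.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from ._util import rng_for
from .genome import ConfigError


def aggregate_pseudobulk(
    matrix,
    cells: pd.DataFrame,
    keys: Sequence[str] = ("cell_type", "age", "replicate"),
    feature_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Sum cell-by-feature counts within each metadata group.

    Returns a features x groups frame (columns are a MultiIndex over
    ``keys``).  The grand total is conserved exactly; cells with missing
    metadata in any key raise an error naming them.
    """
    keys = list(keys)
    for k in keys:
        if k not in cells.columns:
            raise ConfigError(f"unknown group key {k!r}")
    if matrix.shape[0] != len(cells):
        raise ConfigError("matrix rows and cell table rows differ")
    missing = cells.loc[cells[keys].isna().any(axis=1)]
    if len(missing):
        ids = missing["cell_id"].tolist() if "cell_id" in missing else missing.index.tolist()
        raise ConfigError(f"cells missing metadata for {keys}: {ids[:10]}")

    labels = pd.MultiIndex.from_frame(cells[keys])
    codes, uniques = pd.factorize(labels, sort=True)
    n_groups = len(uniques)
    X = matrix.tocsr() if sp.issparse(matrix) else np.asarray(matrix)
    onehot = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_groups, len(codes)),
    )
    agg = onehot @ X
    agg = np.asarray(agg.todense()) if sp.issparse(agg) else np.asarray(agg)
    if feature_ids is None:
        feature_ids = [f"feature_{j}" for j in range(matrix.shape[1])]
    out = pd.DataFrame(agg.T, index=pd.Index(feature_ids, name="feature_id"),
                       columns=pd.MultiIndex.from_tuples(uniques, names=keys))
    return out.astype(np.int64)


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per group (column).

    Each feature's reference is its geometric mean across groups; a group's
    factor is the median ratio to that reference over features with a
    nonzero geometric mean, rescaled so the median factor is 1 (identical
    columns give all-1 factors; one doubled column among equals gets factor
    2).  Groups with all-zero counts are invalid.
    """
    if (counts.sum(axis=0) == 0).any():
        bad = counts.columns[counts.sum(axis=0) == 0].tolist()
        raise ConfigError(f"groups with all-zero counts: {bad}")
    log = np.log(counts.to_numpy(dtype=float))
    with np.errstate(divide="ignore"):
        ref = log.mean(axis=1)  # -inf for features with any zero
    usable = np.isfinite(ref)
    if not usable.any():
        raise ConfigError("no feature has a nonzero count in every group")
    ratios = np.exp(log[usable] - ref[usable, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.median(factors)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def test_te_differential(
    counts: pd.DataFrame,
    young_cols: Sequence,
    old_cols: Sequence,
    n_permutations: int = 10_000,
    seed: int = 0,
    pool_features: bool = False,
    exhaustive_limit: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Permutation test of old vs. young normalized pseudo-bulk counts.

    ``log2_fold_change`` compares size-factor-normalized replicate means
    (+``pseudocount`` before the log).  The per-feature statistic is the
    difference of mean ``log2(normalized + pseudocount)`` between ages; its
    null comes from permuting which replicates are labelled old — all
    ``C(n, k)`` distinct splits when there are at most ``exhaustive_limit``,
    otherwise ``n_permutations`` Monte-Carlo draws with the +1 correction.
    With ``pool_features=True`` the statistic is standardized by its pooled
    replicate standard deviation (plus a median-based floor) and compared
    against the permutation null pooled across all features, giving much
    finer p-value resolution at small replicate counts.  Adjusted p-values
    are Benjamini-Hochberg across features.
    """
    young_cols, old_cols = list(young_cols), list(old_cols)
    if len(young_cols) < 2 or len(old_cols) < 2:
        raise ConfigError("need >= 2 replicates per age group")
    cols = young_cols + old_cols
    sub = counts[cols]
    factors = size_factors_median_of_ratios(sub)
    norm = sub.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    logn = np.log2(norm + pseudocount)

    n, k = len(cols), len(old_cols)
    old_mask = np.zeros(n, dtype=bool)
    old_mask[len(young_cols):] = True

    lfc = np.log2(norm[:, old_mask].mean(axis=1) + pseudocount) \
        - np.log2(norm[:, ~old_mask].mean(axis=1) + pseudocount)

    def stat(mask: np.ndarray) -> np.ndarray:
        return logn[:, mask].mean(axis=1) - logn[:, ~mask].mean(axis=1)

    all_splits = list(combinations(range(n), k))
    exhaustive = len(all_splits) <= exhaustive_limit or pool_features
    if exhaustive and len(all_splits) <= max(exhaustive_limit, 5000):
        masks = []
        for split in all_splits:
            m = np.zeros(n, dtype=bool)
            m[list(split)] = True
            masks.append(m)
        monte_carlo = False
    else:
        rng = rng_for(seed, "te_permutation")
        masks = []
        for _ in range(n_permutations):
            m = np.zeros(n, dtype=bool)
            m[rng.choice(n, size=k, replace=False)] = True
            masks.append(m)
        monte_carlo = True

    perm = np.stack([stat(m) for m in masks])  # (n_perm, n_features)
    obs = stat(old_mask)

    if pool_features:
        sd = np.sqrt(
            logn[:, old_mask].var(axis=1, ddof=1) / old_mask.sum()
            + logn[:, ~old_mask].var(axis=1, ddof=1) / (~old_mask).sum()
        )
        s0 = np.median(sd[sd > 0]) if (sd > 0).any() else 1.0
        t_obs = np.abs(obs) / (sd + s0)
        # permutation sds: recompute per split for exchangeability
        t_perm = []
        for m, row in zip(masks, perm):
            sd_m = np.sqrt(
                logn[:, m].var(axis=1, ddof=1) / m.sum()
                + logn[:, ~m].var(axis=1, ddof=1) / (~m).sum()
            )
            t_perm.append(np.abs(row) / (sd_m + s0))
        pool = np.concatenate(t_perm)
        tol = 1e-12
        order = np.sort(pool)
        ge = len(pool) - np.searchsorted(order, t_obs - tol, side="left")
        pval = (1 + ge) / (1 + len(pool))
    else:
        tol = 1e-12
        ge = (np.abs(perm) >= np.abs(obs)[None, :] - tol).sum(axis=0)
        if monte_carlo:
            pval = (1 + ge) / (1 + len(masks))
        else:
            pval = ge / len(masks)
    pval = np.minimum(1.0, pval)

    adj = multipletests(pval, method="fdr_bh")[1] if len(pval) else pval
    return pd.DataFrame({
        "feature_id": counts.index,
        "log2_fold_change": lfc,
        "p_value": pval,
        "adjusted_p": adj,
    })
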