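"""Cluster label transfer by profile correlation and confidence-gated voting.

Two procedures used to carry reference cell-type labels onto query data:

1. profile correlation — z-score each gene across all cells, average within
   clusters, and assign each query cluster the label of its most Pearson-
   correlated reference cluster (on the shared-gene intersection);
2. subcluster refinement of per-cell predictions — within each subcluster,
   keep only high-confidence cells (score strictly above a cutoff, default
   0.85) and assign the modal label to the whole subcluster when it wins a
   strict majority, dropping ambiguous subclusters; and the consistency
   rule that labels a subcluster only when one label covers strictly more
   than 80% of its cells.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .genome import ConfigError


def cluster_mean_zscore(
    expr: pd.DataFrame, clusters: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Mean z-scored expression profile of each cluster.

    Genes are z-scored across all cells jointly, then averaged within
    clusters.  Zero-variance genes are excluded and listed in
    ``result.attrs["excluded_genes"]``.
    """
    if expr.shape[0] < 2 or expr.shape[1] == 0:
        raise ConfigError("need an expression matrix with >= 2 cells and >= 1 gene")
    clusters = pd.Series(clusters)
    clusters = clusters.reindex(expr.index)
    if clusters.isna().any():
        raise ConfigError("every cell needs a cluster assignment")

    X = expr.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    excluded = list(expr.columns[~keep])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} constant genes from profiles")
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    zdf = pd.DataFrame(Z, index=expr.index, columns=expr.columns[keep])
    profiles = zdf.groupby(clusters).mean()
    profiles.index.name = "cluster_id"
    profiles.attrs["excluded_genes"] = excluded
    return profiles


def correlate_and_assign(
    query: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Assign each query cluster the label of its most correlated reference cluster.

    Pearson correlation on the shared-gene intersection (sorted gene ids);
    exact ties for the maximum leave the query cluster unassigned (NaN).
    """
    shared = sorted(set(query.columns) & set(reference.columns))
    if len(shared) < 2:
        raise ConfigError(f"need >= 2 shared genes, found {len(shared)}")
    q = query[shared].to_numpy(dtype=float)
    r = reference[shared].to_numpy(dtype=float)

    qc = q - q.mean(axis=1, keepdims=True)
    rc = r - r.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(qc, axis=1, keepdims=True)
    rn = np.linalg.norm(rc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qc / qn) @ (rc / rn).T  # query x reference

    rows = []
    for i, qid in enumerate(query.index):
        c = corr[i]
        best = np.nanmax(c)
        winners = np.flatnonzero(c == best)
        if len(winners) != 1 or not np.isfinite(best):
            rows.append({"query_cluster": qid, "assigned_label": None,
                         "correlation": float(best) if np.isfinite(best) else np.nan})
        else:
            rows.append({"query_cluster": qid,
                         "assigned_label": reference.index[winners[0]],
                         "correlation": float(best)})
    return pd.DataFrame(rows)


def refine_subcluster_labels(
    preds: pd.DataFrame,
    score_min: float = 0.85,
    majority_min: float = 0.5,
    rule: str = "strict",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confidence-gated majority vote per subcluster.

    Within each subcluster only cells with ``score > score_min`` vote.  Under
    ``rule="strict"`` the modal label must exceed ``majority_min`` of the
    high-confidence cells to be assigned to *all* cells of the subcluster;
    under ``rule="plurality"`` the modal label wins unless tied.  Subclusters
    with no high-confidence cells, tied modes, or (strict rule) no strict
    majority are dropped.

    Returns ``(assignments, dropped)``: per-cell final labels for kept
    subclusters, and a per-subcluster report of why the rest were removed.
    """
    if rule not in ("strict", "plurality"):
        raise ConfigError("rule must be 'strict' or 'plurality'")
    for col in ("cell_id", "subcluster_id", "predicted_label", "score"):
        if col not in preds.columns:
            raise ConfigError(f"predictions need column {col!r}")

    assignments = []
    dropped = []
    for sub_id, sub in preds.groupby("subcluster_id", sort=True):
        hi = sub.loc[sub["score"] > score_min]
        if len(hi) == 0:
            dropped.append({"subcluster_id": sub_id, "reason": "no high-confidence cells"})
            continue
        votes = hi["predicted_label"].value_counts()
        top = votes.iloc[0]
        tied = (votes == top).sum() > 1
        share = top / len(hi)
        if tied:
            dropped.append({"subcluster_id": sub_id, "reason": "tied modal labels"})
            continue
        if rule == "strict" and not share > majority_min:
            dropped.append({"subcluster_id": sub_id,
                            "reason": f"modal share {share:.3f} <= {majority_min}"})
            continue
        label = votes.index[0]
        assignments.append(pd.DataFrame({
            "cell_id": sub["cell_id"],
            "subcluster_id": sub_id,
            "final_label": label,
            "modal_share": share,
            "n_high_confidence": len(hi),
        }))
    out = pd.concat(assignments, ignore_index=True) if assignments else pd.DataFrame(
        columns=["cell_id", "subcluster_id", "final_label", "modal_share", "n_high_confidence"])
    return out, pd.DataFrame(dropped, columns=["subcluster_id", "reason"])


def consistency_assign(
    preds: pd.DataFrame, consistency_min: float = 0.80
) -> pd.DataFrame:
    """Label a subcluster only when one label covers strictly > ``consistency_min`` of its cells.

    All cells vote (no confidence gate).  Subclusters failing the rule are
    returned with a null label and ``needs_manual=True``.
    """
    for col in ("cell_id", "subcluster_id", "predicted_label"):
        if col not in preds.columns:
            raise ConfigError(f"predictions need column {col!r}")
    rows = []
    for sub_id, sub in preds.groupby("subcluster_id", sort=True):
        votes = sub["predicted_label"].value_counts()
        share = votes.iloc[0] / len(sub)
        tied = (votes == votes.iloc[0]).sum() > 1
        ok = share > consistency_min and not tied
        rows.append({
            "subcluster_id": sub_id,
            "label": votes.index[0] if ok else None,
            "top_share": float(share),
            "n_cells": len(sub),
            "needs_manual": not ok,
        })
    return pd.DataFrame(rows)
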