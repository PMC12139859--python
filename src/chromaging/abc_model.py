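"""Activity-By-Contact (ABC) scoring of element-gene links.

For a gene g with candidate elements E(g), each element e gets

    ABC(e, g) = A_e * C_{e,g} / sum_{e' in E(g)} A_{e'} * C_{e',g}

where A is the element's activity (here chromatin-accessibility signal, or
any precomputed activity column) and C its normalized contact frequency
with the gene's promoter.  Scores over a gene's candidates sum to one
whenever any candidate has positive A*C; genes with a zero denominator
yield no links.  Candidates default to elements whose midpoint lies within
a fixed window of the gene's transcription start site (strand-aware).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import ConfigError, RegionSet


def tss_positions(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware transcription start site: ``start`` on '+', ``end - 1`` on '-'."""
    if "strand" in genes.columns:
        tss = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    else:
        tss = genes["start"].to_numpy()
    return pd.Series(tss, index=genes.index, name="tss")


def candidate_elements(
    peaks: RegionSet,
    genes: pd.DataFrame,
    window_bp: int = 5_000_000,
) -> dict[str, list[str]]:
    """Candidate elements per gene: peak midpoint strictly within ``window_bp`` of the TSS.

    ``peaks`` needs a ``name`` column of element ids; ``genes`` needs
    ``gene_id``, ``chrom``, ``start``, ``end`` and optionally ``strand``.
    """
    if window_bp <= 0:
        raise ConfigError("window_bp must be positive")
    if "name" not in peaks.df.columns:
        raise ConfigError("peaks need a 'name' column of element ids")
    pk = peaks.df
    mid = (pk["start"].to_numpy() + pk["end"].to_numpy()) / 2.0
    tss = tss_positions(genes).to_numpy()

    out: dict[str, list[str]] = {}
    for chrom, gsub in genes.groupby("chrom", sort=False):
        pmask = (pk["chrom"] == chrom).to_numpy()
        pm = mid[pmask]
        names = pk.loc[pmask, "name"].to_numpy()
        order = np.argsort(pm, kind="stable")
        pm_sorted, names_sorted = pm[order], names[order]
        for gid, t in zip(gsub["gene_id"], tss[gsub.index.to_numpy()]):
            lo = np.searchsorted(pm_sorted, t - window_bp, side="right")
            hi = np.searchsorted(pm_sorted, t + window_bp, side="left")
            out[gid] = list(names_sorted[lo:hi])
    for gid in genes["gene_id"]:
        out.setdefault(gid, [])
    return out


def abc_scores(
    activities: Mapping[str, float] | pd.Series,
    contacts: pd.DataFrame,
    candidates: Mapping[str, Sequence[str]],
    threshold: float | None = None,
) -> pd.DataFrame:
    """ABC score table over (element, gene) pairs.

    ``activities`` maps element id to activity A >= 0; ``contacts`` is a
    long-format frame with ``element_id``, ``gene_id``, ``contact`` (C >= 0;
    absent pairs count as 0).  Returns links sorted by gene then descending
    score; ``threshold`` drops links scoring below it.
    """
    act = pd.Series(activities, dtype=float)
    if (act < 0).any():
        raise ConfigError("negative activity values")
    if (contacts["contact"] < 0).any():
        raise ConfigError("negative contact values")
    cmap = {(e, g): c for e, g, c in
            zip(contacts["element_id"], contacts["gene_id"], contacts["contact"])}

    rows = []
    for gene, elems in candidates.items():
        if len(elems) == 0:
            continue
        a = np.array([act.get(e, 0.0) for e in elems], dtype=float)
        c = np.array([cmap.get((e, gene), 0.0) for e in elems], dtype=float)
        prod = a * c
        denom = prod.sum()
        if denom <= 0:
            continue
        score = prod / denom
        for e, ai, ci, s in zip(elems, a, c, score):
            if threshold is not None and s < threshold:
                continue
            rows.append({"element_id": e, "gene_id": gene,
                         "activity": ai, "contact": ci, "abc_score": s})
    out = pd.DataFrame(rows, columns=["element_id", "gene_id", "activity", "contact", "abc_score"])
    return out.sort_values(["gene_id", "abc_score"], ascending=[True, False],
                           kind="stable").reset_index(drop=True)
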