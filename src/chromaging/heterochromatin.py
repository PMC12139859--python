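"""Overlap and enrichment statistics for repressive (H3K9me3-like) domains.

Ties differential regions and hotspots to constitutive heterochromatin:
any-bp interval overlap flags, enrichment of region sets in domains against
a genome-coverage null (closed-form binomial upper tail plus a
length-preserving permutation test), the up/down direction split of DARs
inside vs. outside domains with an exact 2x2 association test, and the
biotype composition (lncRNA / pseudogene share) of top-ranked
differential genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from scipy.stats import binom, hypergeom

from ._util import intervals_overlap_any, rng_for
from .genome import ConfigError, GenomeLayout, RegionSet


@dataclass
class EnrichmentResult:
    n_total: int
    n_overlapping: int
    observed_fraction: float
    genome_coverage_fraction: float
    enrichment_ratio: float
    binomial_p: float
    permutation_p: float | None
    n_permutations: int
    defined: bool = True


def overlap_flags(
    regions: RegionSet, domains: RegionSet, use_midpoint: bool = False
) -> pd.DataFrame:
    """Per-region overlap flag and overlapped bp against a domain set.

    A region overlaps iff the intersection is at least 1 bp (half-open
    arithmetic); with ``use_midpoint=True`` only the region midpoint is
    tested (useful for wide hotspot bins).  Rows follow the input order.
    """
    if len(regions) and len(domains) and not (regions.chroms & domains.chroms):
        raise ConfigError("region and domain chromosome namespaces do not intersect")
    n = len(regions)
    out = pd.DataFrame({"overlaps": np.zeros(n, dtype=bool),
                        "overlap_bp": np.zeros(n, dtype=np.int64)})
    if n == 0 or len(domains) == 0:
        return out

    rdf = regions.df.copy()
    if use_midpoint:
        mid = (rdf["start"] + rdf["end"]) // 2
        rdf = rdf.assign(start=mid, end=mid + 1)
    q = pd.DataFrame({
        "Chromosome": rdf["chrom"], "Start": rdf["start"], "End": rdf["end"],
        "_ridx": np.arange(n),
    })
    d = domains.merged().df.rename(
        columns={"chrom": "Chromosome", "start": "Start", "end": "End"})
    joined = pr.PyRanges(q).join(pr.PyRanges(d), report_overlap=True)
    if len(joined) == 0:
        return out
    jdf = joined.df
    bp = jdf.groupby("_ridx")["Overlap"].sum()
    out.loc[bp.index, "overlap_bp"] = bp.to_numpy()
    out["overlaps"] = out["overlap_bp"] > 0
    if use_midpoint:
        out["overlap_bp"] = 0  # bp is meaningless in midpoint mode
    return out


def domain_enrichment(
    regions: RegionSet,
    domains: RegionSet,
    layout: GenomeLayout,
    n_permutations: int = 1000,
    seed: int = 0,
    use_midpoint: bool = False,
) -> EnrichmentResult:
    """Enrichment of a region set in domains relative to genome coverage.

    ``enrichment_ratio`` is the observed overlapping fraction divided by the
    domains' genome-coverage fraction.  ``binomial_p`` is the closed-form
    upper tail ``P(X >= k | n, coverage)``; ``permutation_p`` re-places each
    region uniformly on its own chromosome (length preserved) and uses the
    upper tail with the +1/(n+1) correction.  Set ``n_permutations=0`` to
    skip the permutation test.
    """
    n_total = len(regions)
    if n_total == 0:
        raise ConfigError("n_total must be > 0")
    coverage = domains.total_bp / layout.total_bp
    if coverage == 0:
        return EnrichmentResult(n_total, 0, 0.0, 0.0, float("nan"), float("nan"),
                                None, 0, defined=False)

    flags = overlap_flags(regions, domains, use_midpoint=use_midpoint)
    k = int(flags["overlaps"].sum())
    obs_frac = k / n_total
    binom_p = float(binom.sf(k - 1, n_total, coverage))

    perm_p = None
    if n_permutations > 0:
        rng = rng_for(seed, "domain_enrichment")
        dom_arrays = domains.by_chrom_arrays()
        counts = np.zeros(n_permutations, dtype=np.int64)
        for chrom, sub in regions.df.groupby("chrom", sort=True):
            chrom_len = layout.length_of(chrom)
            lengths = (sub["end"] - sub["start"]).to_numpy()
            if use_midpoint:
                lengths = np.ones_like(lengths)
            ds, de = dom_arrays.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            hi = np.maximum(1, chrom_len - lengths + 1)
            starts = (rng.random((n_permutations, len(sub))) * hi).astype(np.int64)
            ov = intervals_overlap_any(starts.ravel(), (starts + lengths).ravel(), ds, de)
            counts += ov.reshape(n_permutations, -1).sum(axis=1)
        perm_p = float((1 + (counts >= k).sum()) / (n_permutations + 1))

    return EnrichmentResult(
        n_total=n_total, n_overlapping=k, observed_fraction=obs_frac,
        genome_coverage_fraction=coverage, enrichment_ratio=obs_frac / coverage,
        binomial_p=binom_p, permutation_p=perm_p, n_permutations=n_permutations,
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact association p for the table [[a, b], [c, d]].

    Conditional on the margins, the first cell follows a hypergeometric law;
    the two-sided p sums the probabilities of all tables at most as likely
    as the observed one (with a small tolerance for floating ties).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ConfigError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def direction_split(
    dars: pd.DataFrame,
    domains: RegionSet,
    by: str | None = "cell_type",
) -> pd.DataFrame:
    """Up/down x inside/outside-domain 2x2 split per stratum.

    Returns one row per stratum (``by`` column, or a single ``"all"`` row)
    with counts ``up_in, down_in, up_out, down_out``, the up-fractions
    inside and outside domains, and a two-sided exact association p-value.
    DARs with direction ``"none"`` are excluded from both direction sets.
    """
    d = dars.loc[dars["direction"].isin(["up", "down"])].reset_index(drop=True)
    flags = overlap_flags(RegionSet(d[["chrom", "start", "end"]]), domains)["overlaps"] \
        if len(d) else pd.Series(dtype=bool)
    strata = d[by] if (by is not None and by in d.columns) else pd.Series(["all"] * len(d))

    rows = []
    for stratum in (pd.unique(strata) if len(d) else ["all"]):
        m = (strata == stratum).to_numpy() if len(d) else np.zeros(0, dtype=bool)
        up = (d.loc[m, "direction"] == "up").to_numpy() if len(d) else np.zeros(0, dtype=bool)
        inside = flags.to_numpy()[m] if len(d) else np.zeros(0, dtype=bool)
        a = int((up & inside).sum()); b = int((~up & inside).sum())
        c = int((up & ~inside).sum()); e = int((~up & ~inside).sum())
        rows.append({
            by or "stratum": stratum,
            "up_in": a, "down_in": b, "up_out": c, "down_out": e,
            "up_fraction_in": a / (a + b) if a + b else np.nan,
            "up_fraction_out": c / (c + e) if c + e else np.nan,
            "fisher_p": fisher_exact_2x2(a, b, c, e),
        })
    return pd.DataFrame(rows)


def biotype_top_composition(
    ranked_genes: pd.DataFrame,
    biotypes: Mapping[str, str] | pd.Series,
    top_n: int = 100,
    target_biotypes: Sequence[str] = ("lncRNA", "pseudogene"),
    pre_ranked: bool = False,
) -> pd.DataFrame:
    """Biotype make-up of the top up- and down-regulated genes.

    ``ranked_genes`` needs ``gene_id`` and ``log2_fold_change`` (direction
    comes from its sign) and, unless ``pre_ranked``, ``adjusted_p``; within
    each direction genes are ranked by ascending adjusted p, ties broken by
    descending |log2FC| then gene id.  Genes absent from the biotype map
    count as ``"unknown"``.  Returns one row per (direction, biotype) with
    ``count``, ``fraction`` and an ``is_target`` flag; target fraction per
    direction is the sum of fractions where ``is_target``.
    """
    if isinstance(biotypes, pd.Series):
        biotypes = biotypes.to_dict()
    g = ranked_genes.copy()
    g["direction"] = np.where(g["log2_fold_change"] > 0, "up",
                              np.where(g["log2_fold_change"] < 0, "down", "none"))
    rows = []
    for direction in ("up", "down"):
        sub = g.loc[g["direction"] == direction].copy()
        if top_n > len(sub):
            raise ConfigError(
                f"top_n={top_n} exceeds the {len(sub)} {direction}-regulated genes")
        if not pre_ranked:
            sub["_abs_lfc"] = sub["log2_fold_change"].abs()
            sub = sub.sort_values(
                ["adjusted_p", "_abs_lfc", "gene_id"],
                ascending=[True, False, True], kind="stable")
        top = sub.head(top_n)
        bt = top["gene_id"].map(lambda x: biotypes.get(x, "unknown"))
        counts = bt.value_counts()
        for biotype, cnt in counts.items():
            rows.append({
                "direction": direction, "biotype": biotype,
                "count": int(cnt), "fraction": cnt / top_n,
                "is_target": biotype in set(target_biotypes),
            })
    return pd.DataFrame(rows)


def target_fraction(composition: pd.DataFrame, direction: str) -> float:
    """Summed fraction of target biotypes (e.g. lncRNA + pseudogene) in one direction."""
    sub = composition.loc[(composition["direction"] == direction) & composition["is_target"]]
    return float(sub["fraction"].sum())
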