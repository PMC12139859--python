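"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generators emulate a multi-region single-nucleus chromatin-accessibility
study of the aging mouse brain: a multi-chromosome genome carrying broad
repressive (heterochromatin-like) domains, transposable-element copies and
annotated genes; peak sets with uniform background differentially accessible
regions (DARs) plus planted clustered DARs; per-cell binary accessibility
with age-group-specific probabilities; cell-type compositions that decline
with age (progenitor-like populations falling from a few percent to near
zero); negative-binomial TE-subfamily count matrices; and reference/query
cluster expression profiles with controllable noise and label confusion.

Every generator is deterministic given :class:`SimConfig` (one global seed,
split into named sub-streams so adding a generator never perturbs another).
All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._util import (
    complement_intervals,
    points_in_intervals,
    rng_for,
    sample_positions_in_intervals,
)
from .genome import ConfigError, GenomeLayout, RegionSet

AGES = (2, 9, 18)  # months

_DEFAULT_TE_SUBFAMILIES = (
    "IAPLTR3-int", "IAPEz-int", "L1Md_A", "L1Md_T", "B2_Mm2", "MMERVK10C-int",
    "RLTR10-int", "ETnERV-int", "MERVL-int", "ORR1A0",
)

_DEFAULT_COMPOSITION: dict[str, tuple[float, float, float]] = {
    # proportions at 2, 9, 18 months; progenitor-like populations decline
    "DG progenitor": (0.03, 0.005, 0.0001),
    "IOL": (0.02, 0.008, 0.001),
    "OB-STR-CTX Inh IMN": (0.04, 0.02, 0.01),
    "Oligo NN": (0.25, 0.26, 0.27),
    "DG Glut": (0.30, 0.30, 0.30),
    "D12 MSN": (0.36, 0.407, 0.4189),
}


@dataclass(frozen=True)
class HotspotSpec:
    """A planted cluster of DARs: ``n_dars`` placed within ``span_bp`` around ``center_bp``."""

    chrom: str
    center_bp: int
    span_bp: int
    n_dars: int


@dataclass(frozen=True)
class CompositionSpec:
    """Cell-type proportions per age, and the replicate structure of samples."""

    proportions: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COMPOSITION)
    )
    ages: tuple[int, ...] = AGES
    regions: tuple[str, ...] = ("AHC", "PHC", "FC", "ENT")
    n_replicates: int = 2
    cells_per_sample: int = 250

    def validate(self) -> None:
        for i, age in enumerate(self.ages):
            total = sum(p[i] for p in self.proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"proportions at age {age} sum to {total}, not 1")
        for ct, props in self.proportions.items():
            if any(not (0 <= p <= 1) for p in props):
                raise ConfigError(f"proportion outside [0,1] for {ct}")
        if self.n_replicates < 1 or self.cells_per_sample < 1:
            raise ConfigError("need >=1 replicate and >=1 cell per sample")


@dataclass(frozen=True)
class AccessibilitySpec:
    """Per-peak per-age-group Bernoulli accessibility probabilities.

    Baseline probabilities are drawn uniformly from ``base_prob_range``;
    ``n_differential`` randomly chosen peaks have their old-age probability
    scaled by ``2**effect_log2fc`` (9-month cells get the geometric midpoint).
    Explicit per-age probability vectors can be supplied via ``probs``.
    """

    base_prob_range: tuple[float, float] = (0.02, 0.30)
    n_differential: int = 0
    effect_log2fc: float = 1.0
    probs: Mapping[int, Sequence[float]] | None = None

    def validate(self) -> None:
        lo, hi = self.base_prob_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("base_prob_range must satisfy 0 <= lo <= hi <= 1")
        if self.probs is not None:
            for age, p in self.probs.items():
                arr = np.asarray(p, dtype=float)
                if ((arr < 0) | (arr > 1)).any():
                    raise ConfigError(f"accessibility probability outside [0,1] at age {age}")


@dataclass(frozen=True)
class TESpec:
    """TE-subfamily negative-binomial count model."""

    n_subfamilies: int = 500
    mean_range: tuple[float, float] = (10.0, 200.0)
    dispersion: float = 0.1
    n_differential: int = 20
    fold_change: float = 4.0

    def validate(self) -> None:
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.n_differential > self.n_subfamilies:
            raise ConfigError("n_differential exceeds n_subfamilies")


@dataclass(frozen=True)
class LabelSpec:
    """Reference/query cluster-profile generator parameters."""

    n_clusters: int = 20
    n_genes: int = 200
    noise_sd: float = 0.1
    confusion_rate: float = 0.0

    def validate(self) -> None:
        if self.n_clusters < 2 or self.n_genes < 2:
            raise ConfigError("need n_clusters >= 2 and n_genes >= 2")
        if not (0 <= self.confusion_rate <= 1):
            raise ConfigError("confusion_rate must be in [0,1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with one global seed."""

    seed: int = 0
    n_chroms: int = 5
    chrom_length_bp: int = 20_000_000
    n_peaks: int = 2_000
    peak_width_bp: int = 500
    n_background_dars: int = 30_000
    planted_hotspots: tuple[HotspotSpec, ...] = ()
    domain_coverage_fraction: float = 0.03
    domain_block_bp: int = 250_000
    domain_dar_enrichment: float = 1.0
    dar_width_bp: int = 500
    up_fraction: float = 0.5
    domain_dars_up_fraction: float | None = None
    # DAR effect-size mixture: |log2FC| = offset + Exponential(scale).  The
    # background population spans the hotspot stage's |log2FC| > 1 filter
    # (most DARs are modest; only the strong tail counts toward density),
    # while planted hotspot DARs are uniformly strong.
    background_lfc_offset: float = 0.25
    background_lfc_scale: float = 0.15
    hotspot_lfc_offset: float = 1.2
    hotspot_lfc_scale: float = 0.5
    n_genes: int = 2_000
    n_te_copies: int = 2_000
    composition: CompositionSpec = field(default_factory=CompositionSpec)
    accessibility: AccessibilitySpec = field(default_factory=AccessibilitySpec)
    te: TESpec = field(default_factory=TESpec)
    labels: LabelSpec = field(default_factory=LabelSpec)

    def validate(self) -> None:
        if self.n_chroms < 1 or self.chrom_length_bp < 1:
            raise ConfigError("need at least one chromosome of positive length")
        if not (0 <= self.domain_coverage_fraction < 1):
            raise ConfigError("domain_coverage_fraction must be in [0, 1)")
        if self.domain_dar_enrichment < 0:
            raise ConfigError("domain_dar_enrichment must be >= 0")
        if not (0 <= self.up_fraction <= 1):
            raise ConfigError("up_fraction must be in [0,1]")
        if self.domain_dars_up_fraction is not None and not (0 <= self.domain_dars_up_fraction <= 1):
            raise ConfigError("domain_dars_up_fraction must be in [0,1]")
        self.composition.validate()
        self.accessibility.validate()
        self.te.validate()
        self.labels.validate()

    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chroms))
        return GenomeLayout(names, (self.chrom_length_bp,) * self.n_chroms)


# ---------------------------------------------------------------------------
# genome-level annotation


def simulate_genome(config: SimConfig) -> tuple[GenomeLayout, RegionSet, RegionSet, pd.DataFrame]:
    """Genome layout, repressive domains, TE copies, and gene annotation.

    Domains are fixed-length non-overlapping blocks whose total length is the
    requested fraction of the genome (up to block rounding).  Genes carry a
    ``biotype`` column including ``lncRNA`` and ``pseudogene``.
    """
    config.validate()
    layout = config.layout()
    domains = _place_domains(layout, config)
    tes = _place_tes(layout, config)
    genes = _place_genes(layout, config)
    return layout, domains, tes, genes


def _place_domains(layout: GenomeLayout, config: SimConfig) -> RegionSet:
    rng = rng_for(config.seed, "domains")
    block = config.domain_block_bp
    target_bp = config.domain_coverage_fraction * layout.total_bp
    n_blocks = int(round(target_bp / block))
    empty = pd.DataFrame({"chrom": pd.Series(dtype=str),
                          "start": pd.Series(dtype=np.int64),
                          "end": pd.Series(dtype=np.int64)})
    if n_blocks == 0:
        return RegionSet(empty, layout)
    chrom_p = np.array(layout.chrom_lengths, dtype=float)
    chrom_p /= chrom_p.sum()
    chrom_idx = rng.choice(len(layout.chrom_names), size=n_blocks, p=chrom_p)
    rows: list[tuple[str, int, int]] = []
    for ci in range(len(layout.chrom_names)):
        k = int((chrom_idx == ci).sum())
        if k == 0:
            continue
        length = layout.chrom_lengths[ci]
        if k * block > length:
            raise ConfigError("domain blocks do not fit on chromosome")
        placed: list[int] = []
        tries = 0
        while len(placed) < k:
            s = int(rng.integers(0, length - block + 1))
            if all(abs(s - q) >= block for q in placed):
                placed.append(s)
            tries += 1
            if tries > 1000 * k:
                raise ConfigError("could not place non-overlapping domains; lower coverage")
        for s in sorted(placed):
            rows.append((layout.chrom_names[ci], s, s + block))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), layout)


def _place_tes(layout: GenomeLayout, config: SimConfig) -> RegionSet:
    rng = rng_for(config.seed, "tes")
    n = config.n_te_copies
    chrom_p = np.array(layout.chrom_lengths, dtype=float)
    chrom_p /= chrom_p.sum()
    ci = rng.choice(len(layout.chrom_names), size=n, p=chrom_p)
    width = 300
    starts = np.array([rng.integers(0, layout.chrom_lengths[c] - width) for c in ci])
    sub = rng.choice(_DEFAULT_TE_SUBFAMILIES, size=n)
    df = pd.DataFrame({
        "chrom": [layout.chrom_names[c] for c in ci],
        "start": starts,
        "end": starts + width,
        "subfamily": sub,
    })
    return RegionSet(df, layout)


def _place_genes(layout: GenomeLayout, config: SimConfig) -> pd.DataFrame:
    rng = rng_for(config.seed, "genes")
    n = config.n_genes
    chrom_p = np.array(layout.chrom_lengths, dtype=float)
    chrom_p /= chrom_p.sum()
    ci = rng.choice(len(layout.chrom_names), size=n, p=chrom_p)
    widths = rng.integers(1_000, 100_000, size=n)
    starts = np.array([
        rng.integers(0, max(1, layout.chrom_lengths[c] - w)) for c, w in zip(ci, widths)
    ])
    biotype = rng.choice(["protein_coding", "lncRNA", "pseudogene"], size=n, p=[0.7, 0.2, 0.1])
    strand = rng.choice(["+", "-"], size=n)
    return pd.DataFrame({
        "gene_id": [f"gene_{i:05d}" for i in range(n)],
        "chrom": [layout.chrom_names[c] for c in ci],
        "start": starts,
        "end": starts + widths,
        "strand": strand,
        "biotype": biotype,
    })


# ---------------------------------------------------------------------------
# DARs


def simulate_dars(layout: GenomeLayout, domains: RegionSet, config: SimConfig) -> pd.DataFrame:
    """Background DARs (uniform, with domain enrichment) plus planted hotspot clusters.

    Background DARs fall inside repressive domains with probability
    ``coverage * domain_dar_enrichment`` (capped at 1), uniformly within the
    chosen stratum, and outside planted hotspot spans.  Each planted hotspot
    contributes exactly its ``n_dars`` within its span.  The returned table
    carries synthetic effect sizes: background DARs draw |log2FC| from a
    shifted exponential spanning the hotspot stage's |log2FC| > 1 filter
    (only the strong tail contributes to hotspot density), planted DARs are
    uniformly strong; p-values (1e-8..1e-3) all pass the p < 0.01 filter,
    as befits regions already called differential.
    """
    config.validate()
    rng = rng_for(config.seed, "dars")
    w = config.dar_width_bp
    for hs in config.planted_hotspots:
        if hs.chrom not in layout.chrom_names:
            raise ConfigError(f"planted hotspot on unknown chromosome {hs.chrom!r}")
        length = layout.length_of(hs.chrom)
        lo, hi = hs.center_bp - hs.span_bp // 2, hs.center_bp + hs.span_bp // 2
        if lo < 0 or hi > length:
            raise ConfigError("planted hotspot span extends outside chromosome")
        if hs.n_dars * w > hs.span_bp:
            raise ConfigError("n_dars exceeds hotspot span capacity at minimum spacing")

    dom_arrays = domains.by_chrom_arrays()
    span_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for hs in config.planted_hotspots:
        lo = hs.center_bp - hs.span_bp // 2
        span_by_chrom.setdefault(hs.chrom, []).append((lo, lo + hs.span_bp))

    chroms: list[str] = []
    mids: list[np.ndarray] = []
    in_domain: list[np.ndarray] = []
    planted: list[np.ndarray] = []

    # planted clusters
    for hs in config.planted_hotspots:
        lo = hs.center_bp - hs.span_bp // 2
        m = sample_positions_in_intervals(
            np.array([lo + w // 2]), np.array([lo + hs.span_bp - w + w // 2 + 1]), hs.n_dars, rng
        )
        chroms.append(hs.chrom)
        mids.append(m)
        ds, de = dom_arrays.get(hs.chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        in_domain.append(points_in_intervals(m, ds, de))
        planted.append(np.ones(hs.n_dars, dtype=bool))

    # background
    coverage = domains.total_bp / layout.total_bp if layout.total_bp else 0.0
    p_in = min(1.0, coverage * config.domain_dar_enrichment) if coverage > 0 else 0.0
    n_bg = config.n_background_dars
    n_in = int(rng.binomial(n_bg, p_in)) if 0 < p_in < 1 else (n_bg if p_in >= 1 else 0)
    n_out = n_bg - n_in

    def stratum_arrays(inside: bool) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for i, chrom in enumerate(layout.chrom_names):
            ds, de = dom_arrays.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
            if inside:
                ss, ee = ds.copy(), de.copy()
            else:
                ss, ee = complement_intervals(ds, de, layout.chrom_lengths[i])
            # remove planted spans from the stratum
            for lo, hi in span_by_chrom.get(chrom, []):
                keep_s, keep_e = [], []
                for s, e in zip(ss, ee):
                    if e <= lo or s >= hi:
                        keep_s.append(s); keep_e.append(e)
                    else:
                        if s < lo:
                            keep_s.append(s); keep_e.append(lo)
                        if e > hi:
                            keep_s.append(hi); keep_e.append(e)
                ss, ee = np.array(keep_s, np.int64), np.array(keep_e, np.int64)
            if len(ss):
                out[chrom] = (ss, ee)
        return out

    for inside, n_strat in ((True, n_in), (False, n_out)):
        if n_strat == 0:
            continue
        strat = stratum_arrays(inside)
        if not strat:
            raise ConfigError("empty placement stratum for background DARs")
        names = sorted(strat)
        weights = np.array([(strat[c][1] - strat[c][0]).sum() for c in names], dtype=float)
        weights /= weights.sum()
        counts = rng.multinomial(n_strat, weights)
        for c, k in zip(names, counts):
            if k == 0:
                continue
            ss, ee = strat[c]
            # sample midpoints so the full DAR width stays inside the chromosome
            m = sample_positions_in_intervals(ss, ee, int(k), rng)
            m = np.clip(m, w // 2, layout.length_of(c) - w + w // 2)
            chroms.append(c)
            mids.append(m)
            in_domain.append(np.full(int(k), inside))
            planted.append(np.zeros(int(k), dtype=bool))

    chrom_col = np.concatenate([np.repeat(c, len(m)) for c, m in zip(chroms, mids)]) \
        if mids else np.empty(0, dtype=object)
    mid = np.concatenate(mids) if mids else np.empty(0, dtype=np.int64)
    dom_flag = np.concatenate(in_domain) if in_domain else np.empty(0, dtype=bool)
    planted_flag = np.concatenate(planted) if planted else np.empty(0, dtype=bool)

    n = len(mid)
    if config.domain_dars_up_fraction is None:
        p_up = np.full(n, config.up_fraction)
    else:
        p_up = np.where(dom_flag, config.domain_dars_up_fraction, config.up_fraction)
    up = rng.random(n) < p_up
    lfc_mag = np.where(
        planted_flag,
        config.hotspot_lfc_offset + rng.exponential(config.hotspot_lfc_scale, size=n),
        config.background_lfc_offset + rng.exponential(config.background_lfc_scale, size=n),
    )
    lfc = np.where(up, lfc_mag, -lfc_mag)
    pval = 10.0 ** rng.uniform(-8, -3, size=n)

    start = mid - w // 2
    df = pd.DataFrame({
        "peak_id": [f"dar_{i:06d}" for i in range(n)],
        "chrom": chrom_col,
        "start": start,
        "end": start + w,
        "log2_fold_change": lfc,
        "p_value": pval,
        "adjusted_p": np.minimum(1.0, pval * 1.5),
        "direction": np.where(up, "up", "down"),
        "in_domain": dom_flag,
        "planted": planted_flag,
    })
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# peaks, cells, accessibility


def simulate_peaks(layout: GenomeLayout, config: SimConfig) -> RegionSet:
    """Uniformly placed fixed-width candidate peaks with stable identifiers."""
    config.validate()
    rng = rng_for(config.seed, "peaks")
    w = config.peak_width_bp
    chrom_p = np.array(layout.chrom_lengths, dtype=float)
    chrom_p /= chrom_p.sum()
    ci = rng.choice(len(layout.chrom_names), size=config.n_peaks, p=chrom_p)
    starts = np.array([rng.integers(0, layout.chrom_lengths[c] - w) for c in ci])
    df = pd.DataFrame({
        "chrom": [layout.chrom_names[c] for c in ci],
        "start": starts,
        "end": starts + w,
        "name": [f"peak_{i:05d}" for i in range(config.n_peaks)],
    })
    return RegionSet(df.sort_values(["chrom", "start"], kind="stable"), layout)


def simulate_cells(
    layout: GenomeLayout, peaks: RegionSet, config: SimConfig
) -> tuple[pd.DataFrame, sp.csr_matrix]:
    """Per-cell metadata and a binary cell-by-peak accessibility matrix.

    Cells are drawn per (age, region, replicate) sample with multinomial
    cell-type composition; matrix entries are Bernoulli with the configured
    per-peak, per-age-group probability.
    """
    config.validate()
    comp = config.composition
    rng = rng_for(config.seed, "cells")
    mrng = rng_for(config.seed, "matrix")

    cell_types = list(comp.proportions)
    rows = []
    for ai, age in enumerate(comp.ages):
        props = np.array([comp.proportions[ct][ai] for ct in cell_types], dtype=float)
        for region in comp.regions:
            for rep in range(1, comp.n_replicates + 1):
                sex = "M" if rep % 2 == 1 else "F"
                counts = rng.multinomial(comp.cells_per_sample, props)
                for ct, k in zip(cell_types, counts):
                    rows.extend((ct, age, sex, region, rep) for _ in range(int(k)))
    cells = pd.DataFrame(rows, columns=["cell_type", "age", "sex", "region", "replicate"])
    cells.insert(0, "cell_id", [f"cell_{i:06d}" for i in range(len(cells))])

    n_peaks = len(peaks)
    probs = _age_probs(config, n_peaks)
    blocks = []
    order = []
    for age in comp.ages:
        idx = np.flatnonzero(cells["age"].to_numpy() == age)
        order.append(idx)
        p = probs[age]
        block_rows = []
        for chunk in np.array_split(idx, max(1, len(idx) // 1000)):
            if not len(chunk):
                continue
            block_rows.append(sp.csr_matrix(
                (mrng.random((len(chunk), n_peaks)) < p).astype(np.int8)
            ))
        blocks.append(sp.vstack(block_rows) if block_rows else sp.csr_matrix((0, n_peaks), dtype=np.int8))
    X = sp.vstack(blocks).tocsr()
    perm = np.argsort(np.concatenate(order), kind="stable")
    X = X[perm]
    return cells, X


def _age_probs(config: SimConfig, n_peaks: int) -> dict[int, np.ndarray]:
    spec = config.accessibility
    ages = config.composition.ages
    if spec.probs is not None:
        out = {}
        for age in ages:
            arr = np.asarray(spec.probs[age], dtype=float)
            if arr.shape != (n_peaks,):
                raise ConfigError("explicit probability vector length != number of peaks")
            out[age] = arr
        return out
    prng = rng_for(config.seed, "peak_probs")
    base = prng.uniform(*spec.base_prob_range, size=n_peaks)
    diff_idx = prng.choice(n_peaks, size=min(spec.n_differential, n_peaks), replace=False)
    fold = 2.0 ** spec.effect_log2fc
    out = {}
    for age in ages:
        p = base.copy()
        if age == max(ages):
            p[diff_idx] = np.minimum(1.0, base[diff_idx] * fold)
        elif age not in (min(ages), max(ages)):
            p[diff_idx] = np.minimum(1.0, base[diff_idx] * fold ** 0.5)
        out[age] = p
    return out


def simulate_te_counts(
    cells: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Cell-by-TE-subfamily negative-binomial counts with planted age effects.

    Returns ``(info, counts, subfamily_names)`` where ``info`` lists each
    subfamily's baseline mean and whether it is a planted age-differential
    one (old-age cells scaled by ``fold_change``).
    """
    config.validate()
    spec = config.te
    rng = rng_for(config.seed, "te_counts")
    n_sub = spec.n_subfamilies
    means = rng.uniform(*spec.mean_range, size=n_sub)
    diff_idx = rng.choice(n_sub, size=spec.n_differential, replace=False)
    is_diff = np.zeros(n_sub, dtype=bool)
    is_diff[diff_idx] = True
    old_age = max(config.composition.ages)
    ages = cells["age"].to_numpy()
    mu = np.tile(means, (len(cells), 1))
    mu[np.ix_(ages == old_age, diff_idx)] *= spec.fold_change
    if spec.dispersion > 0:
        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, mu * spec.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    names = [f"TE_{i:04d}" for i in range(n_sub)]
    info = pd.DataFrame({
        "subfamily": names,
        "baseline_mean": means,
        "age_differential": is_diff,
        "fold_change": np.where(is_diff, spec.fold_change, 1.0),
    })
    return info, counts, names


# ---------------------------------------------------------------------------
# label-transfer profiles


def simulate_label_profiles(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Reference and query cluster profiles plus the true query->reference map.

    Query profiles equal their source reference profile plus Gaussian noise
    (sd ``noise_sd``); with probability ``confusion_rate`` a query cluster is
    generated from a different, randomly chosen reference cluster.
    """
    config.validate()
    spec = config.labels
    rng = rng_for(config.seed, "labels")
    k, g = spec.n_clusters, spec.n_genes
    genes = [f"g{j:04d}" for j in range(g)]
    ref_ids = [f"ref_{i:02d}" for i in range(k)]
    query_ids = [f"query_{i:02d}" for i in range(k)]
    ref = rng.normal(0.0, 1.0, size=(k, g))
    true_map: dict[str, str] = {}
    query = np.empty_like(ref)
    for i in range(k):
        src = i
        if rng.random() < spec.confusion_rate:
            others = [j for j in range(k) if j != i]
            src = int(rng.choice(others))
        true_map[query_ids[i]] = ref_ids[src]
        noise = rng.normal(0.0, spec.noise_sd, size=g) if spec.noise_sd > 0 else 0.0
        query[i] = ref[src] + noise
    ref_df = pd.DataFrame(ref, index=ref_ids, columns=genes)
    query_df = pd.DataFrame(query, index=query_ids, columns=genes)
    return ref_df, query_df, true_map
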