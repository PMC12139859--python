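"""Gaussian-density hotspot statistic for clustered accessibility change.

The genome is partitioned into fixed-width bins (default 100 kb), each bin
counts the differentially accessible regions (DARs) whose midpoint falls in
it (after effect-size and significance filtering, default p < 0.01 and
|log2FC| > 1), the counts are smoothed per chromosome with a windowed
Gaussian kernel (default 20-bin window, ~2 Mb span), and hotspots are the
runs of adjacent bins whose smoothed score exceeds a top-quantile threshold
(default the top 1%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import intervals_overlap_any
from .genome import BinTrack, ConfigError, GenomeLayout, RegionSet


@dataclass
class HotspotCall:
    """One merged run of above-threshold bins."""

    chrom: str
    start: int
    end: int
    peak_score: float
    n_dars: int | None = None
    overlaps_domain: bool | None = None


def bin_genome(layout: GenomeLayout, bin_width: int = 100_000) -> BinTrack:
    """An all-zero track with ``ceil(length / bin_width)`` bins per chromosome."""
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    return BinTrack(layout, bin_width)


def count_dars_per_bin(
    dars: pd.DataFrame,
    track: BinTrack,
    direction: str = "both",
    lfc_min: float = 1.0,
    p_max: float = 0.01,
) -> BinTrack:
    """Count qualifying DARs per bin; each DAR increments the bin holding its midpoint.

    Qualifying means ``p_value < p_max`` and ``|log2_fold_change| > lfc_min``,
    optionally restricted to one direction (``"up"``, ``"down"``, ``"both"``).
    """
    if direction not in ("up", "down", "both"):
        raise ConfigError("direction must be 'up', 'down' or 'both'")
    layout = track.layout
    unknown = sorted(set(dars["chrom"]) - set(layout.chrom_names))
    if unknown:
        raise ConfigError(f"DARs on chromosomes absent from layout: {unknown}")

    sel = (dars["p_value"] < p_max) & (dars["log2_fold_change"].abs() > lfc_min)
    if direction != "both":
        sel &= dars["direction"] == direction
    sub = dars.loc[sel]

    values = track.values.copy()
    offsets = dict(zip(layout.chrom_names, track.offsets))
    nbins = dict(zip(layout.chrom_names, track.n_bins_per_chrom))
    for chrom, grp in sub.groupby("chrom", sort=False):
        mid = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2)
        b = np.minimum(mid // track.bin_width, nbins[chrom] - 1)
        np.add.at(values, offsets[chrom] + b, 1.0)
    return track.copy_with(values)


def gaussian_kernel(window_bins: int, tails: float = 2.5) -> np.ndarray:
    """Symmetric Gaussian weights on ``j in [-window_bins//2, window_bins//2]``.

    ``w(j) = exp(-0.5 * (tails * j / (window_bins / 2))**2)``; ``tails``
    sets how many kernel standard deviations the half-window spans.
    """
    if window_bins < 1:
        raise ConfigError("window_bins must be >= 1")
    half = window_bins // 2
    j = np.arange(-half, half + 1, dtype=float)
    return np.exp(-0.5 * (tails * j / (window_bins / 2.0)) ** 2)


def gaussian_smooth(track: BinTrack, window_bins: int = 20, tails: float = 2.5) -> BinTrack:
    """Per-chromosome windowed Gaussian smoothing with edge renormalization.

    At every position the kernel weights over in-bounds bins are renormalized
    to sum to one, so a constant track maps to itself and interior mass is
    conserved.  A window wider than a chromosome is effectively truncated
    (with a warning).
    """
    kernel = gaussian_kernel(window_bins, tails)
    out = np.empty_like(track.values)
    for chrom, sl in track.per_chrom():
        v = track.values[sl]
        if window_bins + 1 > len(v):
            warnings.warn(f"smoothing window exceeds {chrom} ({len(v)} bins); kernel truncated")
        half = len(kernel) // 2  # centered slice works even when the kernel
        num = np.convolve(v, kernel)[half:half + len(v)]  # outsizes the chromosome
        den = np.convolve(np.ones_like(v), kernel)[half:half + len(v)]
        out[sl] = num / den
    return track.copy_with(out)


def hotspot_threshold(
    track: BinTrack,
    quantile: float = 0.99,
    abs_threshold: float | None = None,
    nonzero_bins_only: bool = False,
) -> float:
    """Score cutoff: the genome-wide quantile (over bins of chromosomes that
    carry any signal), raised to ``abs_threshold`` if one is given."""
    if not (0 < quantile < 1):
        raise ConfigError("quantile must be in (0, 1)")
    vals = []
    for _, sl in track.per_chrom():
        v = track.values[sl]
        if np.any(v != 0):
            vals.append(v)
    pool = np.concatenate(vals) if vals else track.values
    if nonzero_bins_only:
        nz = pool[pool != 0]
        pool = nz if len(nz) else pool
    thr = float(np.quantile(pool, quantile))
    if abs_threshold is not None:
        thr = max(thr, float(abs_threshold))
    return thr


def call_hotspots(
    track: BinTrack,
    quantile: float = 0.99,
    abs_threshold: float | None = None,
    domains: RegionSet | None = None,
    raw_track: BinTrack | None = None,
    nonzero_bins_only: bool = False,
) -> list[HotspotCall]:
    """Merge runs of bins whose smoothed score is strictly above the threshold.

    ``overlaps_domain`` is filled when ``domains`` is given (any-bp overlap);
    ``n_dars`` is the raw count inside the call when ``raw_track`` (the
    unsmoothed count track) is given.
    """
    thr = hotspot_threshold(track, quantile, abs_threshold, nonzero_bins_only)
    above = track.values > thr
    if not above.any():
        warnings.warn("no bins exceed the hotspot threshold (flat track?)")
        return []

    dom_arrays = domains.by_chrom_arrays() if domains is not None else None
    calls: list[HotspotCall] = []
    for chrom, sl in track.per_chrom():
        mask = above[sl]
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        run_breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[0], run_breaks + 1])
        run_ends = np.concatenate([run_breaks, [len(idx) - 1]])
        chrom_len = track.layout.length_of(chrom)
        for a, b in zip(run_starts, run_ends):
            first, last = idx[a], idx[b]
            start = first * track.bin_width
            end = min((last + 1) * track.bin_width, chrom_len)
            score = float(track.values[sl][first:last + 1].max())
            n_dars = None
            if raw_track is not None:
                n_dars = int(round(raw_track.values[sl][first:last + 1].sum()))
            overlaps = None
            if dom_arrays is not None:
                ds, de = dom_arrays.get(chrom, (np.empty(0), np.empty(0)))
                overlaps = bool(intervals_overlap_any(
                    np.array([start]), np.array([end]), ds, de)[0])
            calls.append(HotspotCall(chrom, int(start), int(end), score, n_dars, overlaps))
    return calls


def hotspots_to_frame(calls: list[HotspotCall]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "peak_score", "n_dars", "overlaps_domain"]
    return pd.DataFrame([{c: getattr(h, c) for c in cols} for h in calls], columns=cols)
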