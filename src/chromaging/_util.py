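"""Seeded random streams and interval-sampling helpers shared by the generators."""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """A named, reproducible random stream derived from one global seed.

    Each stream is keyed by a CRC of its name, so adding a new generator
    does not perturb draws from existing ones.
    """
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def sample_positions_in_intervals(
    starts: np.ndarray, ends: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` positions uniformly from the union of half-open intervals."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    lengths = ends - starts
    if len(lengths) == 0 or lengths.sum() <= 0:
        if n == 0:
            return np.empty(0, dtype=np.int64)
        raise ValueError("cannot sample from an empty interval union")
    cum = np.concatenate([[0], np.cumsum(lengths)])
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    return starts[idx] + (u - cum[idx])


def complement_intervals(
    starts: np.ndarray, ends: np.ndarray, chrom_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Complement of sorted, merged intervals within ``[0, chrom_length)``."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    bounds_s = np.concatenate([[0], ends])
    bounds_e = np.concatenate([starts, [chrom_length]])
    keep = bounds_e > bounds_s
    return bounds_s[keep], bounds_e[keep]


def points_in_intervals(
    points: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Boolean membership of points in a union of sorted merged intervals."""
    points = np.asarray(points)
    if len(starts) == 0:
        return np.zeros(points.shape, dtype=bool)
    idx = np.searchsorted(starts, points, side="right") - 1
    ok = idx >= 0
    out = np.zeros(points.shape, dtype=bool)
    out[ok] = points[ok] < np.asarray(ends)[idx[ok]]
    return out


def intervals_overlap_any(
    q_starts: np.ndarray, q_ends: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """For query intervals, whether each overlaps (>=1 bp) any merged interval."""
    q_starts = np.asarray(q_starts)
    q_ends = np.asarray(q_ends)
    if len(starts) == 0:
        return np.zeros(q_starts.shape, dtype=bool)
    # first merged interval ending strictly after the query start
    idx = np.searchsorted(np.asarray(ends), q_starts, side="right")
    ok = idx < len(starts)
    out = np.zeros(q_starts.shape, dtype=bool)
    out[ok] = np.asarray(starts)[idx[ok]] < q_ends[ok]
    return out
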