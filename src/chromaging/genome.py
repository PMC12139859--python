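"""Coordinate frame, interval sets, and binned genome tracks.

All coordinates are 0-based, half-open (``[start, end)``), the BED
convention.  :class:`GenomeLayout` fixes the chromosome namespace for a
dataset; :class:`RegionSet` holds genomic intervals with arbitrary extra
columns; :class:`BinTrack` carries one number per fixed-width genome bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """An invalid configuration or input parameterization."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ConfigError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ConfigError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ConfigError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", tuple(self.chrom_names))
        object.__setattr__(self, "chrom_lengths", tuple(int(l) for l in self.chrom_lengths))

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths))

    @property
    def lengths(self) -> Mapping[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
        return cls(tuple(df["chrom"].astype(str)), tuple(int(x) for x in df["length"]))

    def to_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")


class RegionSet:
    """A set of genomic intervals with per-interval attribute columns.

    Wraps a :class:`pandas.DataFrame` that must contain ``chrom``,
    ``start``, ``end``; any further columns are carried along.  Input
    order is preserved.
    """

    REQUIRED = ("chrom", "start", "end")

    def __init__(self, df: pd.DataFrame, layout: GenomeLayout | None = None):
        df = pd.DataFrame(df).reset_index(drop=True).copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ConfigError(f"RegionSet requires column {col!r}")
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and ((df["start"] < 0).any() or (df["end"] <= df["start"]).any()):
            raise ConfigError("intervals must satisfy 0 <= start < end")
        if layout is not None:
            bad = set(df["chrom"]) - set(layout.chrom_names)
            if bad:
                raise ConfigError(f"regions on chromosomes absent from layout: {sorted(bad)}")
            lens = df["chrom"].map(layout.lengths)
            if (df["end"] > lens).any():
                raise ConfigError("intervals extend past chromosome ends")
        self.df = df
        self.layout = layout

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals on {self.df['chrom'].nunique()} chromosomes)"

    @property
    def chroms(self) -> set[str]:
        return set(self.df["chrom"].unique())

    def merged(self) -> "RegionSet":
        """Union of the intervals: sorted, non-overlapping (bookended runs joined)."""
        if not len(self.df):
            return RegionSet(self.df[list(self.REQUIRED)], self.layout)
        rows = []
        for chrom, sub in self.df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), self.layout)

    @property
    def total_bp(self) -> int:
        m = self.merged().df
        return int((m["end"] - m["start"]).sum())

    def by_chrom_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Merged ``{chrom: (starts, ends)}`` arrays for fast membership queries."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.merged().df.groupby("chrom", sort=True):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    @classmethod
    def from_bed(cls, path: str | Path, layout: GenomeLayout | None = None,
                 extra_names: Iterable[str] = ()) -> "RegionSet":
        names = ["chrom", "start", "end", *extra_names]
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, : len(names)]
        df.columns = names[: df.shape[1]]
        return cls(df, layout)

    def to_bed(self, path: str | Path, extra_cols: Iterable[str] = ()) -> None:
        cols = ["chrom", "start", "end", *extra_cols]
        self.df[cols].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class BinTrack:
    """One numeric value per fixed-width bin, ordered by (chromosome, bin index).

    The last bin of each chromosome may be short (``ceil(length / bin_width)``
    bins per chromosome).
    """

    layout: GenomeLayout
    bin_width: int
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        n = self.n_bins_total
        if self.values is None:
            self.values = np.zeros(n, dtype=float)
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (n,):
                raise ConfigError(f"values must have length {n}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError("track values must be finite")

    @property
    def n_bins_per_chrom(self) -> tuple[int, ...]:
        return tuple(math.ceil(l / self.bin_width) for l in self.layout.chrom_lengths)

    @property
    def n_bins_total(self) -> int:
        return sum(self.n_bins_per_chrom)

    @property
    def offsets(self) -> np.ndarray:
        """Start offset of each chromosome in the concatenated value vector."""
        return np.concatenate([[0], np.cumsum(self.n_bins_per_chrom)])[:-1]

    def per_chrom(self) -> Iterator[tuple[str, slice]]:
        off = 0
        for name, n in zip(self.layout.chrom_names, self.n_bins_per_chrom):
            yield name, slice(off, off + n)
            off += n

    def chrom_values(self, chrom: str) -> np.ndarray:
        for name, sl in self.per_chrom():
            if name == chrom:
                return self.values[sl]
        raise KeyError(chrom)

    def copy_with(self, values: np.ndarray) -> "BinTrack":
        return BinTrack(self.layout, self.bin_width, np.asarray(values, dtype=float))

    def bin_bounds(self, chrom: str, idx: int) -> tuple[int, int]:
        """Genomic [start, end) of a bin; the terminal bin is clipped."""
        length = self.layout.length_of(chrom)
        start = idx * self.bin_width
        return start, min(start + self.bin_width, length)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, sl in self.per_chrom():
                vals = self.values[sl]
                for i, v in enumerate(vals):
                    s, e = self.bin_bounds(chrom, i)
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
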