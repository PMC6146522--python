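"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates are 1-based inclusive (the VCF convention);
BED-style 0-based half-open coordinates are converted at the I/O
boundary and never appear internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Fixed nucleotide ordering for every 4-vector in the package.
BASES = ("A", "C", "G", "T")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass
class VariantTable:
    """A multi-sample table of SNV sites with per-sample read counts.

    ``data`` holds one row per site with columns ``chrom``, ``pos``,
    ``ref``, ``alt`` plus, for every sample ``s`` in ``sample_ids``,
    integer columns ``{s}_ref_count`` and ``{s}_alt_count``.
    """

    data: pd.DataFrame
    sample_ids: list[str]
    genome_spec: dict[str, int] | None = None

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "ref", "alt"]
        for col in required:
            if col not in self.data.columns:
                raise FormatError(f"variant table missing column {col!r}")
        for s in self.sample_ids:
            for suffix in ("ref_count", "alt_count"):
                col = f"{s}_{suffix}"
                if col not in self.data.columns:
                    raise FormatError(
                        f"variant table missing counts for sample {s!r} "
                        f"(column {col!r})"
                    )
        dup = self.data.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = self.data.loc[dup.idxmax()]
            raise FormatError(
                f"duplicated site {row['chrom']}:{row['pos']} in variant table"
            )
        self.data = self.data.sort_values(
            ["chrom", "pos"], kind="stable"
        ).reset_index(drop=True)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def depth(self, sample: str) -> np.ndarray:
        """Per-site read depth (ref + alt) for one sample."""
        return (
            self.data[f"{sample}_ref_count"].to_numpy()
            + self.data[f"{sample}_alt_count"].to_numpy()
        )

    def vaf(self, sample: str) -> np.ndarray:
        """Per-site variant allele frequency; NaN where depth is zero."""
        alt = self.data[f"{sample}_alt_count"].to_numpy(dtype=float)
        depth = self.depth(sample).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(depth > 0, alt / depth, np.nan)
        return out

    def positions_by_chromosome(self) -> dict[str, np.ndarray]:
        """Sorted site positions grouped by chromosome."""
        return {
            str(chrom): grp["pos"].to_numpy()
            for chrom, grp in self.data.groupby("chrom", sort=True)
        }

    def subset(self, keep: np.ndarray) -> "VariantTable":
        return VariantTable(
            self.data.loc[keep].reset_index(drop=True),
            list(self.sample_ids),
            self.genome_spec,
        )


@dataclass
class RegionMask:
    """Exclusion regions: genomic intervals plus whole chromosomes.

    Intervals are stored 1-based inclusive. Overlapping input intervals
    are merged; membership queries are unaffected by the merge.
    """

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    excluded_chromosomes: set[str] = field(default_factory=set)

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int]],
        excluded_chromosomes: Iterable[str] = (),
    ) -> "RegionMask":
        """Build a mask from 1-based inclusive (chrom, start, end) triples."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start < 1 or end < start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[list[int]] = []
            for start, end in ivs:
                if out and start <= out[-1][1] + 1:
                    out[-1][1] = max(out[-1][1], end)
                else:
                    out.append([start, end])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        return cls(merged, set(map(str, excluded_chromosomes)))

    def contains(self, chrom: str | Sequence[str], pos: int | np.ndarray) -> np.ndarray:
        """Vectorised membership: is each (chrom, pos) excluded?"""
        chrom_arr = np.atleast_1d(np.asarray(chrom, dtype=object))
        pos_arr = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        if chrom_arr.size == 1 and pos_arr.size > 1:
            chrom_arr = np.repeat(chrom_arr, pos_arr.size)
        out = np.zeros(pos_arr.size, dtype=bool)
        for c in np.unique(chrom_arr):
            sel = chrom_arr == c
            if str(c) in self.excluded_chromosomes:
                out[sel] = True
                continue
            ivs = self.intervals.get(str(c))
            if ivs is None or not len(ivs):
                continue
            # merged intervals are disjoint & sorted: binary search on starts
            idx = np.searchsorted(ivs[:, 0], pos_arr[sel], side="right") - 1
            hit = (idx >= 0) & (pos_arr[sel] <= ivs[np.clip(idx, 0, None), 1])
            out[sel] = hit
        return out


@dataclass
class BaseCountMatrix:
    """Per-position, per-sample nucleotide read counts.

    ``counts`` has shape ``(n_positions, n_samples, 4)`` in A, C, G, T
    order. ``positions`` is a DataFrame with columns ``chrom``, ``pos``
    aligned with axis 0; ``samples`` labels axis 1.
    """

    counts: np.ndarray
    positions: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise ValueError("counts must have shape (positions, samples, 4)")
        if self.counts.shape[0] != len(self.positions):
            raise ValueError("positions do not match counts axis 0")
        if self.counts.shape[1] != len(self.samples):
            raise ValueError("samples do not match counts axis 1")
        if (self.counts < 0).any():
            raise ValueError("negative nucleotide counts")

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0]

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def total_count(self) -> np.ndarray:
        """TC: reads per (position, sample)."""
        return self.counts.sum(axis=2)

    def major_count(self) -> np.ndarray:
        """MC: reads supporting the most frequent base per (position, sample)."""
        return self.counts.max(axis=2)

    def background_count(self) -> np.ndarray:
        """BC = TC - MC: reads disagreeing with the major base."""
        return self.total_count() - self.major_count()

    def select_samples(self, samples: Sequence[str]) -> np.ndarray:
        idx = [self.sample_index(s) for s in samples]
        return self.counts[:, idx, :]


@dataclass
class SimulationTruth:
    """Ground truth recorded by the synthetic-data generators.

    Sufficient to score sensitivity/precision of every downstream stage
    without re-deriving anything from the simulated observations.
    """

    planted_hotspots: list[tuple[str, int, int]] = field(default_factory=list)
    shifted_sites: list[tuple[str, int]] = field(default_factory=list)
    planted_variants: list[tuple[int, tuple[str, ...], float]] = field(
        default_factory=list
    )
    per_position_error: np.ndarray | None = None


@dataclass
class Hotspot:
    """A called cluster of SNVs.

    ``m`` counts member inter-SNV distances with exponential-model
    p < alpha_distance, ``n`` the tolerated larger gaps; ``p_value`` is
    the hypergeometric upper tail for drawing ``m`` significant
    distances in ``n + m`` draws from the genome-wide pool.
    """

    chrom: str
    start: int
    end: int
    site_count: int
    m: int
    n: int
    p_value: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PermutationScheme:
    """One split of the single-cell panel into reference pair + test set."""

    reference_pair: tuple[str, ...]
    test_set: tuple[str, ...]
    is_case: bool

    @property
    def label(self) -> str:
        return "+".join(self.reference_pair)


def genome_spec_from_mapping(spec: Mapping[str, int]) -> dict[str, int]:
    out = {}
    for chrom, length in spec.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        out[str(chrom)] = length
    return out
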