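"""Mutation-hotspot calling from inter-SNV distances.

The model: if SNV sites arrive along the genome as a Poisson process,
the distance x between adjacent sites is exponential, and

    P(x) = 1 - exp(-lambda * x),    lambda = 1 / xbar,

with xbar the mean adjacent-site distance genome-wide, is the
probability of seeing a gap at most x. Distances with P(x) < 0.01 are
"significant" (unusually short). A hotspot is a maximal run-length
block of significant distances allowing a bounded number of
non-significant gaps, and its significance is the hypergeometric upper
tail of drawing that many significant distances from the genome-wide
pool of distances.

Distances are computed within chromosomes only; a chromosome with k
sites contributes k - 1 distances, so s sites spread over c occupied
chromosomes give s - c distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .containers import Hotspot

log = logging.getLogger(__name__)

__all__ = [
    "DistanceModel",
    "inter_snv_distances",
    "fit_distance_model",
    "hypergeometric_tail",
    "call_hotspots",
]


@dataclass
class DistanceModel:
    """Fitted exponential model of adjacent-SNV distances.

    ``distances`` concatenates per-chromosome adjacent-site distances in
    chromosome-sorted, position-sorted order (the order RLE clustering
    consumes); ``chrom_of`` labels each distance with its chromosome.
    """

    positions: dict[str, np.ndarray]
    distances: np.ndarray
    chrom_of: np.ndarray
    xbar: float
    lam: float
    p_exp: np.ndarray
    alpha_distance: float = 0.01

    @property
    def a(self) -> int:
        """Total number of adjacent-pair distances genome-wide."""
        return int(self.distances.size)

    @property
    def b(self) -> int:
        """Number of distances with exponential p below ``alpha_distance``."""
        return int((self.p_exp < self.alpha_distance).sum())


def inter_snv_distances(
    positions: Mapping[str, Sequence[int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Distances between consecutive sites within each chromosome.

    Never crosses chromosome boundaries. Returns (distances, chrom_of)
    in chromosome-sorted order, positions sorted within chromosome.
    """
    dists: list[np.ndarray] = []
    chroms: list[np.ndarray] = []
    for chrom in sorted(positions):
        pos = np.asarray(positions[chrom], dtype=np.int64)
        pos = np.sort(pos)
        if pos.size >= 2:
            d = np.diff(pos)
            dists.append(d)
            chroms.append(np.full(d.size, chrom, dtype=object))
    if not dists:
        log.info("fewer than 2 sites on every chromosome: no distances")
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=object)
    return np.concatenate(dists), np.concatenate(chroms)


def fit_distance_model(
    positions: Mapping[str, Sequence[int]], alpha_distance: float = 0.01
) -> DistanceModel:
    """Fit lambda = 1/xbar genome-wide and score every distance.

    xbar is the mean over all adjacent-pair distances in the genome
    (one pooled fit, not per chromosome).
    """
    pos_sorted = {
        str(c): np.sort(np.asarray(p, dtype=np.int64))
        for c, p in positions.items()
    }
    distances, chrom_of = inter_snv_distances(pos_sorted)
    if distances.size == 0:
        return DistanceModel(
            pos_sorted, distances, chrom_of, np.nan, np.nan,
            np.empty(0), alpha_distance,
        )
    xbar = float(distances.mean())
    if xbar <= 0:
        raise ValueError(
            "all adjacent distances are zero; duplicate positions upstream"
        )
    lam = 1.0 / xbar
    p_exp = 1.0 - np.exp(-lam * distances.astype(float))
    return DistanceModel(
        pos_sorted, distances, chrom_of, xbar, lam, p_exp, alpha_distance
    )


def hypergeometric_tail(a: int, b: int, n: int, m: int) -> float:
    """Upper tail P(X >= m) for X hypergeometric(a, b, n + m).

    A candidate hotspot containing m significant and n non-significant
    distances is scored against drawing n + m distances at random from
    the genome-wide pool of a distances of which b are significant.
    Computed in log space via log-gamma binomial coefficients, summing
    the upper tail directly (accurate for very small p).
    """
    a, b, n, m = int(a), int(b), int(n), int(m)
    if not (0 <= b <= a):
        raise ValueError(f"need 0 <= b <= a, got a={a}, b={b}")
    if n < 0 or m < 1:
        raise ValueError(f"need n >= 0 and m >= 1, got n={n}, m={m}")
    draws = n + m
    if draws > a:
        raise ValueError(f"draw size n + m = {draws} exceeds a = {a}")

    def log_comb(nn: int, kk: np.ndarray) -> np.ndarray:
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    lo = max(m, draws - (a - b))
    hi = min(draws, b)
    if lo > hi:
        return 0.0
    i = np.arange(lo, hi + 1)
    log_terms = log_comb(b, i) + log_comb(a - b, draws - i) - log_comb(a, draws)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def _greedy_blocks(
    flags: np.ndarray, min_m: int, max_gap_n: int
) -> list[tuple[int, int, int, int]]:
    """Maximal significant blocks in a boolean distance sequence.

    Returns (i, j, m, n) inclusive index ranges. A block starts and
    ends on a significant distance, contains at most ``max_gap_n``
    non-significant distances and at least ``min_m`` significant ones.
    Blocks are grown greedily left to right: from each candidate start
    the block absorbs whole non-significant runs while the gap budget
    allows, which makes emitted blocks maximal and non-overlapping.
    """
    n_flags = len(flags)
    blocks: list[tuple[int, int, int, int]] = []
    k = 0
    while k < n_flags:
        if not flags[k]:
            k += 1
            continue
        i = k
        t = k
        gaps = 0
        while True:
            while t + 1 < n_flags and flags[t + 1]:
                t += 1
            j = t
            g = t + 1
            gap_len = 0
            while g + gap_len < n_flags and not flags[g + gap_len]:
                gap_len += 1
            if (
                gap_len == 0
                or g + gap_len >= n_flags
                or gaps + gap_len > max_gap_n
            ):
                break
            gaps += gap_len
            t = g + gap_len
        m = (j - i + 1) - gaps
        if m >= min_m:
            blocks.append((i, j, m, gaps))
            k = j + 1
        else:
            # a start later inside the leading run can only shrink m,
            # so resume the scan after that run
            t2 = i
            while t2 + 1 < n_flags and flags[t2 + 1]:
                t2 += 1
            k = t2 + 1
    return blocks


def call_hotspots(
    model: DistanceModel,
    min_m: int = 5,
    max_gap_n: int = 1,
    max_length: int = 100_000,
) -> list[Hotspot]:
    """Call hotspots by run-length clustering of significant distances.

    Per chromosome, the boolean sequence (p_exp < alpha_distance) is
    segmented into maximal blocks with >= ``min_m`` significant
    distances and <= ``max_gap_n`` gaps; blocks spanning more than
    ``max_length`` bp are discarded. Each surviving block is annotated
    with the hypergeometric upper-tail p-value against the genome-wide
    distance pool (a = total distances, b = significant distances).
    """
    if model.a == 0:
        return []
    a, b = model.a, model.b
    sig = model.p_exp < model.alpha_distance
    hotspots: list[Hotspot] = []
    offset = 0
    for chrom in sorted(model.positions):
        pos = model.positions[chrom]
        n_d = max(pos.size - 1, 0)
        if n_d == 0:
            continue
        flags = sig[offset : offset + n_d]
        for i, j, m, gaps in _greedy_blocks(flags, min_m, max_gap_n):
            start = int(pos[i])
            end = int(pos[j + 1])
            if end - start > max_length:
                continue
            hotspots.append(
                Hotspot(
                    chrom=chrom,
                    start=start,
                    end=end,
                    site_count=j - i + 2,
                    m=m,
                    n=gaps,
                    p_value=hypergeometric_tail(a, b, gaps, m),
                )
            )
        offset += n_d
    return hotspots
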