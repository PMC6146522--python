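"""Synthetic data with the statistical structure the analysis assumes.

Three generators mirror the three data modalities of the study design:

* SNV positions as a homogeneous Poisson process with optional planted
  high-rate clusters (so inter-SNV distances are exponential outside
  clusters);
* paired parental/derived read counts with binomially sampled alternate
  alleles, a subset of sites getting a higher allele frequency in the
  derived sample;
* deep single-cell nucleotide count matrices with position-specific
  sequencing-error rates and optionally planted group-specific variants.

Each generator takes an integer seed (or an existing Generator) and is
byte-reproducible for a given seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    BASES,
    BaseCountMatrix,
    SimulationTruth,
    VariantTable,
    genome_spec_from_mapping,
)

__all__ = [
    "simulate_snv_positions",
    "simulate_paired_counts",
    "simulate_base_count_matrix",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_depths(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    mean: float,
    dispersion: float,
) -> np.ndarray:
    """Over-dispersed integer depths with floor 1.

    Gamma-Poisson mixture (negative-binomial-like): ``dispersion`` is
    the gamma shape; variance = mean + mean^2/dispersion. Large
    dispersion approaches plain Poisson.
    """
    if mean <= 0:
        raise ValueError("mean depth must be positive")
    if dispersion <= 0:
        raise ValueError("depth dispersion must be positive")
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=shape)
    depths = rng.poisson(lam)
    return np.maximum(depths, 1)


def simulate_snv_positions(
    genome_spec: Mapping[str, int],
    background_rate: float,
    hotspot_specs: Sequence[tuple[str, int, int, float]] = (),
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, np.ndarray], SimulationTruth]:
    """Draw SNV positions as a Poisson process with planted clusters.

    Outside planted intervals sites arrive at ``background_rate`` per
    bp; inside an interval the rate is multiplied by that interval's
    rate multiplier. Positions are integer, sorted, deduplicated.

    Parameters
    ----------
    genome_spec : chromosome name -> length in bp.
    background_rate : expected SNVs per bp outside clusters.
    hotspot_specs : (chrom, start, end, multiplier) with 1-based
        inclusive bounds; intervals must not overlap; multiplier >= 1.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    spec = genome_spec_from_mapping(genome_spec)
    by_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in spec}
    for chrom, start, end, mult in hotspot_specs:
        chrom = str(chrom)
        if chrom not in spec:
            raise ValueError(f"hotspot on unknown chromosome {chrom!r}")
        if not (1 <= start <= end <= spec[chrom]):
            raise ValueError(f"hotspot {chrom}:{start}-{end} outside genome")
        if mult < 1:
            raise ValueError("hotspot rate multiplier must be >= 1")
        by_chrom[chrom].append((int(start), int(end), float(mult)))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping hotspot intervals on {chrom}")

    rng = _rng(seed)
    positions: dict[str, np.ndarray] = {}
    truth = SimulationTruth(
        planted_hotspots=[
            (c, s, e) for c, ivs in by_chrom.items() for s, e, _ in ivs
        ]
    )
    for chrom in sorted(spec):
        length = spec[chrom]
        n_bg = rng.poisson(background_rate * length)
        pos = rng.integers(1, length + 1, size=n_bg)
        extra = []
        for start, end, mult in by_chrom[chrom]:
            span = end - start + 1
            n_extra = rng.poisson(background_rate * (mult - 1.0) * span)
            extra.append(rng.integers(start, end + 1, size=n_extra))
        if extra:
            pos = np.concatenate([pos] + extra)
        positions[chrom] = np.unique(pos)
    return positions, truth


def simulate_paired_counts(
    positions: Mapping[str, np.ndarray],
    depth_law: tuple[float, float] = (100.0, 10.0),
    base_vaf: float = 0.1,
    shifted_fraction: float = 0.0,
    shifted_vaf: float = 0.5,
    sample_ids: tuple[str, str] = ("2D", "SP4"),
    seed: int | np.random.Generator = 0,
) -> tuple[VariantTable, SimulationTruth]:
    """Simulate parental/derived read counts at the given SNV positions.

    Every site carries the variant at ``base_vaf`` in both samples; a
    random ``shifted_fraction`` of sites instead has allele frequency
    ``shifted_vaf`` in the derived sample, emulating expansion of a
    variant-carrying subpopulation. Per site per sample, total depth is
    drawn from the over-dispersed ``depth_law = (mean, dispersion)``
    and the alternate count is binomial(depth, that sample's VAF).
    """
    if not 0 < base_vaf <= 1:
        raise ValueError("base_vaf must be in (0, 1]")
    if not base_vaf <= shifted_vaf <= 1:
        raise ValueError("shifted_vaf must be in [base_vaf, 1]")
    if not 0 <= shifted_fraction <= 1:
        raise ValueError("shifted_fraction must be in [0, 1]")
    rng = _rng(seed)
    parental, derived = sample_ids

    chroms: list[str] = []
    pos_all: list[np.ndarray] = []
    for chrom in sorted(positions):
        p = np.asarray(positions[chrom], dtype=np.int64)
        chroms.extend([chrom] * p.size)
        pos_all.append(p)
    pos_arr = (
        np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
    )
    n = pos_arr.size

    shifted = rng.random(n) < shifted_fraction
    vaf_parental = np.full(n, base_vaf)
    vaf_derived = np.where(shifted, shifted_vaf, base_vaf)

    mean, dispersion = depth_law
    data = {"chrom": chroms, "pos": pos_arr, "ref": "N", "alt": "N"}
    bases = np.array(BASES)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    data["ref"] = bases[ref_idx]
    data["alt"] = bases[alt_idx]
    for sample, vaf in ((parental, vaf_parental), (derived, vaf_derived)):
        depth = _draw_depths(rng, (n,), mean, dispersion)
        alt = rng.binomial(depth, vaf)
        data[f"{sample}_ref_count"] = depth - alt
        data[f"{sample}_alt_count"] = alt
    table = VariantTable(pd.DataFrame(data), [parental, derived])
    truth = SimulationTruth(
        shifted_sites=[
            (c, int(p)) for c, p, s in zip(chroms, pos_arr, shifted) if s
        ]
    )
    return table, truth


def simulate_base_count_matrix(
    n_positions: int,
    n_test: int = 3,
    n_ref: int = 2,
    depth_law: tuple[float, float] = (4000.0, 20.0),
    error_law: tuple[float, float] = (0.005, 2000.0),
    planted_variants: Sequence[tuple[int, Sequence[str], float]] = (),
    dropout: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[BaseCountMatrix, SimulationTruth]:
    """Simulate a deep-coverage single-cell nucleotide count matrix.

    Samples are named ``T1..Tk`` (test group, putative stem cells) and
    ``R1..Rj`` (reference group). At every position one base is the
    true major allele; each sample's background count is
    binomial(TC, e_pos) with a per-position error probability e_pos
    drawn once from a Beta distribution with the given (mean, nu)
    (nu = a + b concentration) and shared across samples — sequencing
    error is position-specific, not cell-specific. Background reads
    split uniformly over the three non-major bases.

    ``planted_variants`` entries (position index, sample names,
    fraction) add a true second allele at that fraction in those
    samples. ``dropout`` optionally zeroes one of the two alleles of a
    planted heterozygous site per sample with that probability,
    emulating whole-genome-amplification allele dropout (off by
    default).
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    mean_err, nu = error_law
    if not 0 <= mean_err < 0.5:
        raise ValueError("mean error must be in [0, 0.5)")
    rng = _rng(seed)
    samples = [f"T{i + 1}" for i in range(n_test)] + [
        f"R{i + 1}" for i in range(n_ref)
    ]
    n_samples = len(samples)

    if mean_err == 0:
        err = np.zeros(n_positions)
    else:
        a = mean_err * nu
        b = (1 - mean_err) * nu
        err = rng.beta(a, b, size=n_positions)
        err = np.clip(err, 0.0, 0.499)

    major_idx = rng.integers(0, 4, size=n_positions)
    alt_of: dict[int, int] = {}
    planted_map: dict[tuple[int, int], float] = {}
    for pos_idx, who, frac in planted_variants:
        if not 0 < frac <= 1:
            raise ValueError("planted allele fraction must be in (0, 1]")
        if not 0 <= pos_idx < n_positions:
            raise ValueError(f"planted position index {pos_idx} out of range")
        if pos_idx not in alt_of:
            alt_of[pos_idx] = (major_idx[pos_idx] + rng.integers(1, 4)) % 4
        for s in who:
            planted_map[(pos_idx, samples.index(s))] = float(frac)

    mean_depth, dispersion = depth_law
    tc = _draw_depths(rng, (n_positions, n_samples), mean_depth, dispersion)
    counts = np.zeros((n_positions, n_samples, 4), dtype=np.int64)

    # background errors: BC ~ Binomial(TC, e), split over non-major bases
    bc = rng.binomial(tc, err[:, None])
    for pi in range(n_positions):
        others = [b for b in range(4) if b != major_idx[pi]]
        for si in range(n_samples):
            split = rng.multinomial(bc[pi, si], [1 / 3] * 3)
            counts[pi, si, others] = split
            counts[pi, si, major_idx[pi]] = tc[pi, si] - bc[pi, si]

    for (pi, si), frac in planted_map.items():
        ai, mi = alt_of[pi], major_idx[pi]
        f = frac
        if dropout > 0 and rng.random() < dropout:
            # WGA dropout: one allele of the het site vanishes
            f = 0.0 if rng.random() < 0.5 else 1.0
        alt_reads = rng.binomial(tc[pi, si], f)
        alt_reads = min(alt_reads, counts[pi, si, mi])
        counts[pi, si, mi] -= alt_reads
        counts[pi, si, ai] += alt_reads

    positions = pd.DataFrame(
        {"chrom": "sim", "pos": np.arange(1, n_positions + 1, dtype=np.int64)}
    )
    matrix = BaseCountMatrix(counts, positions, samples)
    truth = SimulationTruth(
        planted_variants=[
            (int(pi), tuple(who), float(frac))
            for pi, who, frac in planted_variants
        ],
        per_position_error=err,
    )
    return matrix, truth
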