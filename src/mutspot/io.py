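"""Readers and writers for the plain-text formats the pipeline touches.

Variant tables come in as TSV (or VCF with per-sample allele depths),
region masks as BED3+, nucleotide counts as long-format TSV. All output
is tab-separated UTF-8 with a single ``#``-prefixed header line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    BASES,
    BaseCountMatrix,
    FormatError,
    Hotspot,
    RegionMask,
    VariantTable,
)

log = logging.getLogger(__name__)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def read_variant_table(path: str | Path, format: str = "tsv") -> VariantTable:
    """Read a multi-sample variant table from TSV or VCF.

    TSV needs columns ``chrom``, ``pos``, ``ref``, ``alt`` and, per
    sample ``s``, ``{s}_ref_count`` and ``{s}_alt_count``. VCF needs
    per-sample allele depths (``AD`` format field); only the first
    alternate allele is used. Coordinates are 1-based on return.
    """
    if format == "vcf":
        return _read_variant_vcf(path)
    if format != "tsv":
        raise ValueError(f"unknown variant table format {format!r}")
    df = _read_tsv(path)
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sample_ids = sorted(
        {
            c[: -len("_ref_count")]
            for c in df.columns
            if c.endswith("_ref_count")
        }
    )
    if not sample_ids:
        raise FormatError(f"{path}: no per-sample *_ref_count columns found")
    for s in sample_ids:
        alt_col = f"{s}_alt_count"
        if alt_col not in df.columns:
            raise FormatError(f"{path}: sample {s!r} has no {alt_col!r} column")
    count_cols = [f"{s}_{k}" for s in sample_ids for k in ("ref_count", "alt_count")]
    for col in count_cols:
        vals = df[col]
        if vals.isna().any():
            raise FormatError(f"{path}: missing counts in column {col!r}")
        if (vals < 0).any():
            raise FormatError(f"{path}: negative counts in column {col!r}")
        df[col] = vals.astype(np.int64)
    df["pos"] = df["pos"].astype(np.int64)
    if not df[["chrom", "pos"]].equals(
        df[["chrom", "pos"]].sort_values(["chrom", "pos"])
    ):
        log.warning("%s: sites not sorted; sorting by (chrom, pos)", path)
    return VariantTable(df, sample_ids)


def _read_variant_vcf(path: str | Path) -> VariantTable:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows = []
    for var in vcf:
        depths = var.format("AD")
        if depths is None:
            raise FormatError(
                f"{path}: {var.CHROM}:{var.POS} has no AD (allele depth) field"
            )
        row = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0] if var.ALT else ".",
        }
        for s, ad in zip(sample_ids, depths):
            if ad[0] < 0 or (len(ad) > 1 and ad[1] < 0):
                raise FormatError(
                    f"{path}: missing allele depths for sample {s!r} at "
                    f"{var.CHROM}:{var.POS}"
                )
            row[f"{s}_ref_count"] = int(ad[0])
            row[f"{s}_alt_count"] = int(ad[1]) if len(ad) > 1 else 0
        rows.append(row)
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt"]
        + [f"{s}_{k}" for s in sample_ids for k in ("ref_count", "alt_count")]
    )
    return VariantTable(df, sample_ids)


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    df = table.data.copy()
    df = df.rename(columns={"chrom": "#chrom"})
    df.to_csv(path, sep="\t", index=False)


def read_region_mask(
    path: str | Path, excluded_chromosomes: Iterable[str] = ()
) -> RegionMask:
    """Read exclusion intervals from a BED3+ file.

    BED is 0-based half-open; intervals are stored 1-based inclusive to
    match variant coordinates (BED ``99 200`` covers positions 100-200).
    """
    intervals: list[tuple[str, int, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if start0 < 0 or end0 <= start0:
                raise FormatError(
                    f"{path}:{lineno}: invalid BED interval {start0}-{end0}"
                )
            intervals.append((chrom, start0 + 1, end0))
    return RegionMask.from_intervals(intervals, excluded_chromosomes)


def read_base_counts(path: str | Path) -> BaseCountMatrix:
    """Read a long-format nucleotide count TSV into a dense matrix.

    Expects columns ``chrom``, ``pos``, ``sample``, ``A``, ``C``, ``G``,
    ``T``. Positions not covered by every sample (absent row or zero
    total count) are dropped, with the dropped count logged: downstream
    error-rate estimation requires coverage in all cells.
    """
    df = _read_tsv(path)
    needed = ["chrom", "pos", "sample"] + list(BASES)
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    for b in BASES:
        if (df[b] < 0).any():
            raise FormatError(f"{path}: negative count in column {b!r}")
        df[b] = df[b].astype(np.int64)
    samples = sorted(df["sample"].astype(str).unique())
    wide = df.pivot_table(
        index=["chrom", "pos"],
        columns="sample",
        values=list(BASES),
        aggfunc="sum",
        fill_value=0,
    )
    n_pos_all = len(wide)
    counts = np.zeros((n_pos_all, len(samples), 4), dtype=np.int64)
    for bi, b in enumerate(BASES):
        for si, s in enumerate(samples):
            if (b, s) in wide.columns:
                counts[:, si, bi] = wide[(b, s)].to_numpy()
    covered = (counts.sum(axis=2) > 0).all(axis=1)
    dropped = int((~covered).sum())
    if dropped:
        log.info(
            "%s: dropped %d position(s) not covered by all %d samples",
            path,
            dropped,
            len(samples),
        )
    positions = wide.index.to_frame(index=False).loc[covered].reset_index(drop=True)
    positions.columns = ["chrom", "pos"]
    return BaseCountMatrix(counts[covered], positions, samples)


def write_base_counts(matrix: BaseCountMatrix, path: str | Path) -> None:
    rows = []
    for pi in range(matrix.n_positions):
        chrom = matrix.positions.iloc[pi]["chrom"]
        pos = matrix.positions.iloc[pi]["pos"]
        for si, s in enumerate(matrix.samples):
            rows.append(
                [chrom, pos, s] + [int(v) for v in matrix.counts[pi, si]]
            )
    out = pd.DataFrame(rows, columns=["#chrom", "pos", "sample"] + list(BASES))
    out.to_csv(path, sep="\t", index=False)


def write_hotspots(
    hotspots: Sequence[Hotspot], bed_path: str | Path, tsv_path: str | Path
) -> None:
    """Write called hotspots as a BED file plus a TSV report.

    BED is 0-based half-open, so a hotspot spanning 1-based positions
    1001-1318 becomes ``chrom<TAB>1000<TAB>1318``.
    """
    with open(bed_path, "w", encoding="utf-8") as fh:
        for h in hotspots:
            fh.write(f"{h.chrom}\t{h.start - 1}\t{h.end}\n")
    rows = [
        {
            "chrom": h.chrom,
            "start": h.start,
            "end": h.end,
            "length": h.length,
            "site_count": h.site_count,
            "m": h.m,
            "n": h.n,
            "p_value": h.p_value,
        }
        for h in hotspots
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length", "site_count", "m", "n", "p_value"
        ],
    )
    df = df.rename(columns={"chrom": "#chrom"})
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")


def read_hotspots(tsv_path: str | Path) -> list[Hotspot]:
    df = _read_tsv(tsv_path)
    return [
        Hotspot(
            chrom=str(r["chrom"]),
            start=int(r["start"]),
            end=int(r["end"]),
            site_count=int(r["site_count"]),
            m=int(r["m"]),
            n=int(r["n"]),
            p_value=float(r["p_value"]),
        )
        for _, r in df.iterrows()
    ]
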