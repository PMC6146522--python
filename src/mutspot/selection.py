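"""Site filtering and selection of SNVs with increased allele frequency.

The selection rule compares the parental sample against the derived
sample at every site with a two-sided Fisher exact test on the 2x2
ref/alt read-count table, and keeps sites with p < alpha *and* a strict
VAF increase (parental VAF < derived VAF). The test is non-directional;
direction is a separate filter, so under a null with no true shifts
about half of the sites passing the p threshold also pass direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RegionMask, VariantTable

log = logging.getLogger(__name__)

__all__ = [
    "apply_site_filters",
    "fisher_vaf_test",
    "select_increased_sites",
    "SelectionResult",
]


@dataclass
class SelectionResult:
    """Outcome of the VAF-increase test at one site."""

    chrom: str
    pos: int
    fisher_p: float
    vaf_parental: float
    vaf_derived: float
    direction_ok: bool
    selected: bool
    evaluable: bool = True


def apply_site_filters(
    table: VariantTable,
    mask: RegionMask | None = None,
    depth_min: int = 10,
    depth_max: int = 200,
) -> tuple[VariantTable, dict[str, int]]:
    """Remove masked-region sites and sites outside the depth window.

    Depth is ref + alt per sample; a site is removed if *any* sample
    falls outside ``[depth_min, depth_max]`` (the stricter per-sample
    reading of the depth rule). Returns the filtered table and the
    number of sites removed by each filter (a site failing both is
    counted under the region filter, which is applied first).
    """
    keep = np.ones(table.n_sites, dtype=bool)
    removed = {"region": 0, "depth": 0}
    if mask is not None and table.n_sites:
        in_mask = mask.contains(
            table.data["chrom"].to_numpy(dtype=object),
            table.data["pos"].to_numpy(),
        )
        removed["region"] = int(in_mask.sum())
        keep &= ~in_mask
    if table.n_sites:
        depth_ok = np.ones(table.n_sites, dtype=bool)
        for s in table.sample_ids:
            d = table.depth(s)
            depth_ok &= (d >= depth_min) & (d <= depth_max)
        removed["depth"] = int((keep & ~depth_ok).sum())
        keep &= depth_ok
    if removed["region"] or removed["depth"]:
        log.info(
            "site filters removed %d region / %d depth of %d sites",
            removed["region"],
            removed["depth"],
            table.n_sites,
        )
    return table.subset(keep), removed


def fisher_vaf_test(
    ref_a: int, alt_a: int, ref_b: int, alt_b: int
) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[ref_a, alt_a], [ref_b, alt_b]].

    Returns NaN when either sample has zero depth (the site is
    unevaluable, not significant).
    """
    if ref_a + alt_a == 0 or ref_b + alt_b == 0:
        return float("nan")
    _, p = stats.fisher_exact(
        [[ref_a, alt_a], [ref_b, alt_b]], alternative="two-sided"
    )
    return float(p)


def select_increased_sites(
    table: VariantTable,
    parental: str,
    derived: str,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """Test every site for a significant VAF increase parental -> derived.

    Returns a DataFrame with one row per site: ``fisher_p``,
    per-sample VAFs, ``direction_ok`` (strict VAF increase),
    ``evaluable`` (both samples covered) and ``selected``
    (p < alpha and direction_ok). Unevaluable sites are never selected.
    """
    for s in (parental, derived):
        if s not in table.sample_ids:
            raise KeyError(f"sample {s!r} not in table")
    ref_a = table.data[f"{parental}_ref_count"].to_numpy()
    alt_a = table.data[f"{parental}_alt_count"].to_numpy()
    ref_b = table.data[f"{derived}_ref_count"].to_numpy()
    alt_b = table.data[f"{derived}_alt_count"].to_numpy()

    n = table.n_sites
    pvals = np.ones(n)
    evaluable = (ref_a + alt_a > 0) & (ref_b + alt_b > 0)
    idx = np.nonzero(evaluable)[0]
    # scipy >= 1.10 vectorises the conditional-odds-ratio machinery only
    # per call; loop over evaluable sites with the exact test.
    for i in idx:
        _, pvals[i] = stats.fisher_exact(
            [[ref_a[i], alt_a[i]], [ref_b[i], alt_b[i]]]
        )
    pvals = np.where(evaluable, pvals, np.nan)

    vaf_a = table.vaf(parental)
    vaf_b = table.vaf(derived)
    direction = evaluable & (vaf_a < vaf_b)
    selected = evaluable & (pvals < alpha) & direction
    n_uneval = int((~evaluable).sum())
    if n_uneval:
        log.info("%d site(s) unevaluable (zero depth) and excluded", n_uneval)
    return pd.DataFrame(
        {
            "chrom": table.data["chrom"],
            "pos": table.data["pos"],
            "fisher_p": pvals,
            "vaf_parental": vaf_a,
            "vaf_derived": vaf_b,
            "direction_ok": direction,
            "evaluable": evaluable,
            "selected": selected,
        }
    )
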