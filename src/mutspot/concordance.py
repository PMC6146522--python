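"""Genomic concordance between single-cell groups.

Given deep per-position nucleotide counts for a small panel of single
cells split into a test group (putative stem cells) and a reference
group, this module quantifies whether the two groups differ
genetically:

* base weights (per-position A/C/G/T read fractions), their pairwise
  Pearson correlation and Euclidean genetic distance across cells;
* a position error rate (PER) estimated from the reference cells,
  inflated by a Gaussian-quantile standard-error term;
* an exact binomial upper-tail test (PBC) of the test group's pooled
  background count against that corrected error probability, with a
  Bonferroni-style family threshold;
* a permutation scheme over all reference-pair relabelings and the
  case-permutation ratio CPR = NP_case / (NP_perm + NP_case), which
  sits near 0.5 when the grouping carries no genetic signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BaseCountMatrix, PermutationScheme

log = logging.getLogger(__name__)

__all__ = [
    "base_weights",
    "pairwise_weight_correlation",
    "inter_intra_group_test",
    "genetic_distance",
    "gaussian_quantile",
    "position_error_rate",
    "ErrorModel",
    "pbc_test",
    "significance_threshold",
    "enumerate_permutations",
    "cpr_curve",
    "concordance_analysis",
    "ConcordanceResult",
]


def base_weights(counts: np.ndarray) -> np.ndarray:
    """Per-position base weights: counts / total, in A, C, G, T order.

    ``counts`` is (..., 4); positions with zero total count get NaN
    weights (they should have been dropped when the matrix was read).
    """
    counts = np.asarray(counts, dtype=float)
    tc = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(tc > 0, counts / tc, np.nan)
    return w


def pairwise_weight_correlation(
    matrix: BaseCountMatrix, sample_a: str, sample_b: str
) -> float:
    """Pearson r between two samples' concatenated base-weight vectors.

    Each sample contributes a vector of 4 x n_positions weights over
    the positions covered in both samples; r is NaN when either vector
    has zero variance.
    """
    ia, ib = matrix.sample_index(sample_a), matrix.sample_index(sample_b)
    wa = base_weights(matrix.counts[:, ia, :])
    wb = base_weights(matrix.counts[:, ib, :])
    ok = ~(np.isnan(wa).any(axis=1) | np.isnan(wb).any(axis=1))
    if ok.sum() < 2:
        raise ValueError("need >= 2 positions covered in both samples")
    xa, xb = wa[ok].ravel(), wb[ok].ravel()
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    return float(stats.pearsonr(xa, xb).statistic)


def inter_intra_group_test(
    inter: Sequence[float], intra: Sequence[float]
) -> float:
    """Two-tailed two-sample t-test p comparing inter- vs intra-group values."""
    inter = np.asarray(inter, dtype=float)
    intra = np.asarray(intra, dtype=float)
    if inter.size < 2 or intra.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(inter) == 0 and np.ptp(intra) == 0:
        return 1.0 if inter.mean() == intra.mean() else float("nan")
    res = stats.ttest_ind(inter, intra)
    return float(res.pvalue)


def genetic_distance(w1: np.ndarray, w2: np.ndarray) -> float | np.ndarray:
    """Euclidean distance between two base-weight 4-vectors.

    d = sqrt(sum_n (w1_n - w2_n)^2) over n in {A, C, G, T}; ranges from
    0 (identical composition) to sqrt(2) (disjoint single bases). The
    square is taken per component: summing the differences first is
    identically zero because each weight vector sums to one.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    d = np.sqrt(((w1 - w2) ** 2).sum(axis=-1))
    return float(d) if d.ndim == 0 else d


def gaussian_quantile(order: float) -> float:
    """Standard normal inverse CDF (e.g. 0.95 -> 1.64)."""
    if not 0 < order < 1:
        raise ValueError("quantile order must be in (0, 1)")
    return float(stats.norm.ppf(order))


@dataclass
class ErrorModel:
    """Position-specific background-error model from the reference cells.

    ``per`` is the pooled background fraction sum(BC)/sum(TC) over
    reference cells; ``p0 = per + c * sqrt(per / tc_ref)`` (clamped to
    [0, 1]) inflates it by ``c`` standard errors at the coverage scale
    ``tc_ref`` of a single cell (the mean reference TC by default;
    ``tc_mode='sum'`` uses the summed TC instead). ``tc_ref_sum``
    (total reference reads) feeds the zero-error floor applied at test
    time.
    """

    per: np.ndarray
    tc_ref: np.ndarray
    tc_ref_sum: np.ndarray
    p0: np.ndarray
    c: float = 1.64


def position_error_rate(
    matrix: BaseCountMatrix,
    reference_samples: Sequence[str],
    c: float = 1.64,
    tc_mode: str = "mean",
) -> ErrorModel:
    """Estimate the per-position error rate from the reference cells.

    PER = sum(BC) / sum(TC) pooled over reference samples at each
    position; the corrected null probability is
    p0 = min(1, PER + c * sqrt(PER / TC_ref)).
    """
    if tc_mode not in ("mean", "sum"):
        raise ValueError("tc_mode must be 'mean' or 'sum'")
    idx = [matrix.sample_index(s) for s in reference_samples]
    sub = matrix.counts[:, idx, :]
    tc = sub.sum(axis=2)
    if (tc == 0).any():
        raise ValueError("reference samples must cover every position")
    bc = tc - sub.max(axis=2)
    tc_sum = tc.sum(axis=1).astype(float)
    per = bc.sum(axis=1) / tc_sum
    tc_ref = tc.mean(axis=1) if tc_mode == "mean" else tc_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = per + c * np.sqrt(per / tc_ref)
    p0 = np.clip(np.where(per > 0, p0, 0.0), 0.0, 1.0)
    return ErrorModel(per=per, tc_ref=tc_ref, tc_ref_sum=tc_sum, p0=p0, c=c)


def significance_threshold(alpha: float, n_sites: int) -> float:
    """Bonferroni-style per-site threshold alpha / n_sites."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return alpha / n_sites


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (counts are non-negative here)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


def pbc_test(
    matrix: BaseCountMatrix,
    test_samples: Sequence[str],
    error_model: ErrorModel,
) -> np.ndarray:
    """Exact binomial upper-tail p per position for the test group.

    Successes and trials are the test group's mean background and
    total counts, rounded to the nearest integer (exact binomial tests
    need integer counts); the null probability is the corrected ``p0``,
    floored at 1 / (total reference reads + 1) so that a zero estimated
    error rate cannot declare any background count impossible. Returns
    P(X >= successes), 1.0 when the background count is zero; NaN for
    positions with zero trials.
    """
    idx = [matrix.sample_index(s) for s in test_samples]
    sub = matrix.counts[:, idx, :]
    tc = sub.sum(axis=2)
    bc = tc - sub.max(axis=2)
    k = len(idx)
    successes = _round_half_up(bc.sum(axis=1) / k)
    trials = _round_half_up(tc.sum(axis=1) / k)

    floor = 1.0 / (error_model.tc_ref_sum + 1.0)
    p_used = np.maximum(error_model.p0, floor)
    n_floored = int(((error_model.p0 < floor) & (successes > 0)).sum())
    if n_floored:
        log.info(
            "error floor bound at %d position(s) with zero estimated PER",
            n_floored,
        )
    pbc = np.full(matrix.n_positions, np.nan)
    ok = trials > 0
    if (~ok).any():
        log.info("%d position(s) with zero trials skipped", int((~ok).sum()))
    # P(X >= s | n, p) = sf(s - 1); matches an exact one-sided
    # binomial test with alternative 'greater'
    pbc[ok] = stats.binom.sf(successes[ok] - 1, trials[ok], p_used[ok])
    return pbc


def enumerate_permutations(
    samples: Sequence[str], case_reference_pair: Sequence[str]
) -> list[PermutationScheme]:
    """All C(5,2) = 10 reference-pair splits of a 5-sample panel.

    Each unordered pair of samples forms a reference set and induces
    the complementary test set; the split matching
    ``case_reference_pair`` is flagged as the case, leaving 9
    permutation schemes.
    """
    ids = list(dict.fromkeys(map(str, samples)))
    if len(ids) != len(list(samples)):
        raise ValueError("sample ids must be distinct")
    case = frozenset(map(str, case_reference_pair))
    if len(case) != 2 or not case <= set(ids):
        raise ValueError("case reference pair must be 2 of the sample ids")
    schemes = []
    for pair in combinations(ids, 2):
        ref = tuple(pair)
        test = tuple(s for s in ids if s not in pair)
        schemes.append(
            PermutationScheme(
                reference_pair=ref,
                test_set=test,
                is_case=frozenset(ref) == case,
            )
        )
    assert sum(s.is_case for s in schemes) == 1
    return schemes


def cpr_curve(
    pvalues: Mapping[str, np.ndarray],
    case_label: str,
    thresholds: np.ndarray,
) -> pd.DataFrame:
    """Case-permutation ratio across a grid of p-value thresholds.

    ``pvalues`` maps scheme labels to per-position p arrays over a
    common position set. For each threshold t, NP = number of positions
    with p < t per scheme, and for each non-case scheme
    CPR = NP_case / (NP_scheme + NP_case); rows where both counts are
    zero carry CPR = NaN (undefined, not 0.5). Returns a tidy frame
    with columns threshold, scheme, np_case, np_perm, cpr.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    if case_label not in pvalues:
        raise KeyError(f"case label {case_label!r} not in pvalues")
    sizes = {len(np.asarray(v)) for v in pvalues.values()}
    if len(sizes) != 1:
        raise ValueError("all schemes must cover the same positions")
    case_p = np.asarray(pvalues[case_label], dtype=float)
    rows = []
    for t in thresholds:
        np_case = int(np.nansum(case_p < t))
        for label, p in pvalues.items():
            if label == case_label:
                continue
            np_perm = int(np.nansum(np.asarray(p, dtype=float) < t))
            denom = np_case + np_perm
            cpr = np_case / denom if denom > 0 else np.nan
            rows.append(
                {
                    "threshold": float(t),
                    "scheme": label,
                    "np_case": np_case,
                    "np_perm": np_perm,
                    "cpr": cpr,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ConcordanceResult:
    """Bundle of everything the concordance pipeline computes."""

    correlations: pd.DataFrame
    inter_intra_p: float
    distance_mean: float
    pbc: dict[str, np.ndarray]
    schemes: list[PermutationScheme]
    family_threshold: float
    flagged: dict[str, int]
    cpr: pd.DataFrame

    @property
    def case_label(self) -> str:
        return next(s.label for s in self.schemes if s.is_case)


def concordance_analysis(
    matrix: BaseCountMatrix,
    reference_samples: Sequence[str],
    test_samples: Sequence[str],
    alpha_family: float = 0.001,
    c_order: float = 0.95,
    thresholds: np.ndarray | None = None,
    tc_mode: str = "mean",
) -> ConcordanceResult:
    """Run the full concordance pipeline on one count matrix.

    Computes pairwise base-weight correlations with the inter/intra
    group t-test, mean genetic distance over all sample pairs and
    positions, the PBC test for the case grouping and every
    permutation scheme, flagged-position counts at the Bonferroni
    family threshold, and the CPR curve.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 0.1, 101)
    samples = list(matrix.samples)
    groups = {s: "test" for s in test_samples}
    groups.update({s: "ref" for s in reference_samples})

    rows, inter, intra = [], [], []
    dists = []
    weights = base_weights(matrix.counts)
    for i, a in enumerate(samples):
        for bs in samples[i + 1 :]:
            r = pairwise_weight_correlation(matrix, a, bs)
            kind = "intra" if groups.get(a) == groups.get(bs) else "inter"
            rows.append({"sample_a": a, "sample_b": bs, "r": r, "kind": kind})
            (intra if kind == "intra" else inter).append(r)
            d = genetic_distance(
                weights[:, matrix.sample_index(a), :],
                weights[:, matrix.sample_index(bs), :],
            )
            dists.append(np.nanmean(d))
    corr_df = pd.DataFrame(rows)
    inter_intra_p = inter_intra_group_test(inter, intra)

    c = gaussian_quantile(c_order)
    schemes = enumerate_permutations(samples, reference_samples)
    pbc: dict[str, np.ndarray] = {}
    for scheme in schemes:
        model = position_error_rate(
            matrix, scheme.reference_pair, c=c, tc_mode=tc_mode
        )
        pbc[scheme.label] = pbc_test(matrix, scheme.test_set, model)

    family_threshold = significance_threshold(alpha_family, matrix.n_positions)
    flagged = {
        label: int(np.nansum(p < family_threshold)) for label, p in pbc.items()
    }
    case_label = next(s.label for s in schemes if s.is_case)
    cpr = cpr_curve(pbc, case_label, thresholds)
    return ConcordanceResult(
        correlations=corr_df,
        inter_intra_p=inter_intra_p,
        distance_mean=float(np.mean(dists)),
        pbc=pbc,
        schemes=schemes,
        family_threshold=family_threshold,
        flagged=flagged,
        cpr=cpr,
    )
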