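"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive: exact rational arithmetic and
exhaustive enumeration, sharing no code with the implementation paths
they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_tail_exact(a: int, b: int, n: int, m: int) -> Fraction:
    """P(X >= m), X ~ Hypergeom(a, b, n + m), by exact rational summation."""
    draws = n + m
    num = 0
    for i in range(m, min(draws, b) + 1):
        if draws - i > a - b:
            continue
        num += comb(b, i) * comb(a - b, draws - i)
    return Fraction(num, comb(a, draws))


def fisher_two_sided_exact(
    ref_a: int, alt_a: int, ref_b: int, alt_b: int
) -> Fraction:
    """Two-sided Fisher p by enumerating all tables with fixed margins.

    Sums the hypergeometric probabilities of every table at most as
    probable as the observed one. A relative tie tolerance of 1e-7
    (the conventional guard for floating-point ties in the reference
    implementations) is applied in exact rational form.
    """
    r1, r2 = ref_a + alt_a, ref_b + alt_b
    c1 = ref_a + ref_b
    total = r1 + r2

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(total, c1))

    obs = pmf(ref_a)
    cutoff = obs * Fraction(10**7 + 1, 10**7)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(
        (pmf(k) for k in range(lo, hi + 1) if pmf(k) <= cutoff),
        Fraction(0),
    )


def binom_upper_tail_exact(k: int, n: int, p: Fraction) -> Fraction:
    """P(X >= k), X ~ Binomial(n, p), via the exact lower-tail complement."""
    if k <= 0:
        return Fraction(1)
    lower = sum(
        Fraction(comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k)
    )
    return 1 - lower


def brute_blocks(
    flags: list[bool], min_m: int, max_gap_n: int
) -> list[tuple[int, int, int, int]]:
    """Exhaustive left-to-right scan for maximal significant blocks.

    From each start index, scan every window to find the longest one
    that starts and ends on a significant flag, has <= max_gap_n
    non-significant flags and >= min_m significant ones; emit it and
    resume past its end. Index-level; independent of run-length
    encoding.
    """
    blocks: list[tuple[int, int, int, int]] = []
    s, n = 0, len(flags)
    while s < n:
        if not flags[s]:
            s += 1
            continue
        best = None
        m = gaps = 0
        for e in range(s, n):
            if flags[e]:
                m += 1
            else:
                gaps += 1
            if gaps > max_gap_n:
                break
            if flags[e] and m >= min_m:
                best = (s, e, m, gaps)
        if best is not None:
            blocks.append(best)
            s = best[1] + 1
        else:
            s += 1
    return blocks


def mask_membership_brute(
    intervals: list[tuple[str, int, int]],
    excluded: set[str],
    chrom: str,
    pos: int,
) -> bool:
    """Per-position linear scan over raw (possibly overlapping) intervals."""
    if chrom in excluded:
        return True
    return any(c == chrom and s <= pos <= e for c, s, e in intervals)


def norm_ppf_acklam(p: float) -> float:
    """Standard normal inverse CDF via Acklam's rational approximation.

    Independent of scipy; absolute error < 1.15e-9 on (0, 1).
    """
    import math

    a = [-3.969683028665376e+01, 2.209460984245205e+02,
         -2.759285104469687e+02, 1.383577518672690e+02,
         -3.066479806614716e+01, 2.506628277459239e+00]
    b = [-5.447609879822406e+01, 1.615858368580409e+02,
         -1.556989798598866e+02, 6.680131188771972e+01,
         -1.328068155288572e+01]
    c = [-7.784894002430293e-03, -3.223964580411365e-01,
         -2.400758277161838e+00, -2.549732539343734e+00,
         4.374664141464968e+00, 2.938163982698783e+00]
    d = [7.784695709041462e-03, 3.224671290700398e-01,
         2.445134137142996e+00, 3.754408661907416e+00]
    p_low, p_high = 0.02425, 1 - 0.02425
    if p < p_low:
        q = math.sqrt(-2 * math.log(p))
        return (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q
                + c[5]) / ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1)
    if p > p_high:
        return -norm_ppf_acklam(1 - p)
    q = p - 0.5
    r = q * q
    return (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r
            + a[5]) * q / (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r
            + b[4]) * r + 1)
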