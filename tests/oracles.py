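"""Independent brute-force oracles used to pin down conventions.

Everything here is deliberately written in plain Python (no numpy/scipy)
and independently of the package implementation: full sorts, explicit
index arithmetic, exact combinatorics via math.comb.
"""

from __future__ import annotations

import math
from fractions import Fraction


def _rank_index(q: float, n: int, cap_upper: bool) -> int:
    """1-based ascending nearest-rank index; exact-integer products detected
    via Fraction so 0.95*20 counts as the exact rank 19."""
    x = Fraction(q).limit_denominator(10**6) * n
    if x.denominator == 1:
        k = int(x)
    else:
        k = math.ceil(x)
        if cap_upper:
            k = min(k, n - 1)
    return max(k, 1)


def erc_oracle(read_counts, min_coverage=8, quantile=0.25):
    """Top-quantile genotype: descending sort, value at 1-based ceil(q*N)."""
    counts = sorted(read_counts, reverse=True)
    n = len(counts)
    if n < min_coverage:
        return None
    return counts[math.ceil(quantile * n) - 1]


def trim_oracle(values, q_low=0.05, q_high=0.95):
    """Nearest-rank percentile bounds and the retained values (order kept)."""
    ordered = sorted(values)
    n = len(ordered)
    p_low = ordered[_rank_index(q_low, n, cap_upper=False) - 1]
    p_high = ordered[_rank_index(q_high, n, cap_upper=True) - 1]
    kept = [v for v in values if p_low <= v <= p_high]
    return kept, p_low, p_high


def population_sd_oracle(values):
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / n)


def trimmed_rdi_oracle(values, q_low=0.05, q_high=0.95):
    kept, _, _ = trim_oracle(values, q_low, q_high)
    return population_sd_oracle(kept)


def hypergeom_pmf(k, K, n, N):
    """P[X = k] drawing n from a universe of N with K successes."""
    return math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)


def fisher_two_sided_oracle(k, K, n, N):
    """Two-sided Fisher p: sum of hypergeometric outcomes no more likely
    than the observed table (standard small-p-inclusion definition)."""
    observed = hypergeom_pmf(k, K, n, N)
    total = 0.0
    for kk in range(max(0, n + K - N), min(n, K) + 1):
        p = hypergeom_pmf(kk, K, n, N)
        if p <= observed * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, pvalues[i] * m / (pos + 1))
        adjusted[i] = running_min
    return adjusted


def pearson_oracle(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sx = math.sqrt(sum((x - mx) ** 2 for x in xs))
    sy = math.sqrt(sum((y - my) ** 2 for y in ys))
    return cov / (sx * sy)
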