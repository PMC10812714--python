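"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's vectorized code paths: exhaustive
enumeration for the HWE exact test, scalar symbol-by-symbol evaluation
of the published variance-components formulas, pairwise-difference
counting for π, and exact rational arithmetic for Tajima's constants.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def hwe_exact_enum(n_AA: int, n_Aa: int, n_aa: int) -> Fraction:
    """Exact HWE p-value by exhaustive enumeration with rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    configs = []
    for h in range(rare % 2, rare + 1, 2):
        aa = (rare - h) // 2
        AA = n - aa - h
        weight = Fraction(math.factorial(n), math.factorial(AA) * math.factorial(h) * math.factorial(aa)) * 2**h
        configs.append((h, weight))
    total = sum(w for _, w in configs)
    probs = {h: Fraction(w, total) for h, w in configs}
    p_obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= p_obs)


def wc_components_scalar(counts_a, counts_b):
    """Two-population W-C (1984) a, b, c from genotype counts, plain floats."""
    def stats(c):
        n = sum(c)
        p = (2 * c[2] + c[1]) / (2 * n)
        h = c[1] / n
        return n, p, h

    n1, p1, h1 = stats(counts_a)
    n2, p2, h2 = stats(counts_b)
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def reynolds_locus_scalar(counts_a, counts_b):
    """Reynolds-Weir-Cockerham (1983) per-locus numerator/denominator,
    summing explicitly over both alleles."""
    def stats(c):
        n = sum(c)
        p = (2 * c[2] + c[1]) / (2 * n)
        return n, p

    n1, p1 = stats(counts_a)
    n2, p2 = stats(counts_b)
    x1 = [p1, 1 - p1]
    x2 = [p2, 1 - p2]
    diff = sum((a - b) ** 2 for a, b in zip(x1, x2)) / 2
    al1 = 1 - sum(x * x for x in x1)
    al2 = 1 - sum(x * x for x in x2)
    shared = (n1 * al1 + n2 * al2) / (4 * n1 * n2 * (n1 + n2 - 1))
    num = diff - (n1 + n2) * shared
    den = diff + (4 * n1 * n2 - n1 - n2) * shared
    return num, den


def pi_pairwise_counting(dosages: np.ndarray, window_length: int) -> float:
    """Window π per bp by counting differences over all pairs of allele
    copies at each site (complete data only)."""
    total = 0.0
    for site in dosages:
        copies = []
        for d in site:
            copies.extend([1] * int(d) + [0] * (2 - int(d)))
        n = len(copies)
        if n < 2:
            continue
        diffs = sum(abs(a - b) for a, b in combinations(copies, 2))
        total += diffs / (n * (n - 1) / 2)
    return total / window_length


def tajimas_d_rational(site_freq_counts: list[tuple[int, int]]) -> float:
    """Tajima's D from (minor copies, total copies) per segregating site,
    constants and numerator in exact rational arithmetic (one shared n)."""
    ns = {n for _, n in site_freq_counts}
    assert len(ns) == 1, "oracle assumes a single copy count"
    n = ns.pop()
    s = len(site_freq_counts)
    if s == 0:
        return float("nan")
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = sum(
        Fraction(n, n - 1) * 2 * Fraction(k, n) * (1 - Fraction(k, n))
        for k, _ in site_freq_counts
    )
    num = pi - Fraction(s, 1) / a1
    var = e1 * s + e2 * s * (s - 1)
    return float(num) / math.sqrt(float(var))


def pearson_r2_scalar(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy * sxy / (sxx * syy)
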