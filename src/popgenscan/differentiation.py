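"""Pairwise population differentiation.

Implements the Weir–Cockerham (1984) two-population diploid
variance-components estimator of F_ST — per-site components a (among
populations), b (among individuals within populations) and c (within
individuals) — and the Reynolds–Weir–Cockerham (1983) coancestry
estimator behind Reynolds' genetic distance D = −ln(1 − θ_R).

Genome-wide F_ST is the ratio of sums Σa / Σ(a+b+c); window-level
scanning (see :mod:`popgenscan.sweep`) instead averages per-site θ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class SiteFstComponents:
    a: float
    b: float
    c: float
    theta: float  # NaN when a+b+c <= 0


def _counts_to_stats(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float, float]:
    """(n diploids, alt frequency, observed het frequency) from counts."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 0.0, np.nan, np.nan
    p = (2 * n_aa + n_Aa) / (2.0 * n)
    h = n_Aa / float(n)
    return float(n), p, h


def wc_fst_site(
    counts_a: tuple[int, int, int], counts_b: tuple[int, int, int]
) -> SiteFstComponents:
    """Per-site W–C components from (hom-ref, het, hom-alt) counts of two
    populations. Requires ≥2 non-missing diploid calls in each."""
    n1, p1, h1 = _counts_to_stats(*counts_a)
    n2, p2, h2 = _counts_to_stats(*counts_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 diploid calls at the site")
    a, b, c = _wc_components(
        np.array([n1]), np.array([p1]), np.array([h1]),
        np.array([n2]), np.array([p2]), np.array([h2]),
    )
    denom = a[0] + b[0] + c[0]
    theta = a[0] / denom if denom > 0 else np.nan
    return SiteFstComponents(float(a[0]), float(b[0]), float(c[0]), float(theta))


def _wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorized two-population W–C (1984) a, b, c per site."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar)
    c = hbar / 2.0
    return a, b, c


def _pop_site_stats(gm: GenotypeMatrix, popmap: PopulationMap, pop_or_samples):
    if isinstance(pop_or_samples, str):
        samples = popmap.samples_in(pop_or_samples)
    else:
        samples = list(pop_or_samples)
    values = gm.values[:, gm.columns_for(samples)]
    called = values != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, values, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = (values == 1).sum(axis=1) / n
    return n, p, h


def site_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a,
    pop_b,
) -> pd.DataFrame:
    """Per-locus W–C components and θ for two populations (or explicit
    sample lists). Sites with <2 calls in either group, or monomorphic
    across both, get θ = NaN; components are NaN where undefined."""
    n1, p1, h1 = _pop_site_stats(gm, popmap, pop_a)
    n2, p2, h2 = _pop_site_stats(gm, popmap, pop_b)
    ok = (n1 >= 2) & (n2 >= 2)
    a = np.full(gm.n_loci, np.nan)
    b = np.full(gm.n_loci, np.nan)
    c = np.full(gm.n_loci, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        av, bv, cv = _wc_components(n1[ok], p1[ok], h1[ok], n2[ok], p2[ok], h2[ok])
    a[ok], b[ok], c[ok] = av, bv, cv
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(denom > 0, a / denom, np.nan)
    return pd.DataFrame({"a": a, "b": b, "c": c, "theta": theta})


def global_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop_a,
    pop_b,
    loci: np.ndarray | None = None,
) -> float:
    """Genome-wide ratio-of-sums θ = Σa / Σ(a+b+c) over usable loci."""
    comp = site_fst(gm, popmap, pop_a, pop_b)
    if loci is not None:
        comp = comp.iloc[loci]
    denom = comp["a"] + comp["b"] + comp["c"]
    usable = denom.notna() & (denom != 0)
    if not usable.any():
        raise ValueError("no usable loci for F_ST")
    return float(comp.loc[usable, "a"].sum() / denom[usable].sum())


def _reynolds_terms(gm, popmap, pop_a, pop_b):
    n1, p1, _ = _pop_site_stats(gm, popmap, pop_a)
    n2, p2, _ = _pop_site_stats(gm, popmap, pop_b)
    ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 2)
    n1, p1, n2, p2 = n1[ok], p1[ok], n2[ok], p2[ok]
    # biallelic: sum over alleles of (x1u - x2u)^2 = 2 (p1-p2)^2;
    # alpha_i = 1 - sum_u x_iu^2 = 2 p_i q_i
    diff2 = (p1 - p2) ** 2  # already the halved allele-sum
    al1 = 2.0 * p1 * (1.0 - p1)
    al2 = 2.0 * p2 * (1.0 - p2)
    shared = (n1 * al1 + n2 * al2) / (4.0 * n1 * n2 * (n1 + n2 - 1.0))
    num = diff2 - (n1 + n2) * shared
    den = diff2 + (4.0 * n1 * n2 - n1 - n2) * shared
    return num, den


def reynolds_theta(gm: GenotypeMatrix, popmap: PopulationMap, pop_a, pop_b) -> float:
    """Ratio-of-sums coancestry θ_R (Reynolds–Weir–Cockerham 1983)."""
    num, den = _reynolds_terms(gm, popmap, pop_a, pop_b)
    total = den.sum()
    if total <= 0:
        raise ValueError("no usable loci for Reynolds' distance")
    return float(num.sum() / total)


def reynolds_distance(gm: GenotypeMatrix, popmap: PopulationMap, pop_a, pop_b) -> float:
    """Reynolds' genetic distance D = −ln(1 − θ_R); negative θ_R is
    truncated to 0 and θ_R = 1 yields +inf."""
    theta_r = reynolds_theta(gm, popmap, pop_a, pop_b)
    theta_r = max(theta_r, 0.0)
    if theta_r >= 1.0:
        return float("inf")
    return float(-np.log(1.0 - theta_r))


def pairwise_matrix(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Square table in popmap order: W–C F_ST below the diagonal,
    Reynolds' D above, empty diagonal. Negative global θ is clamped to 0
    for display (the raw value is recoverable via :func:`global_fst`)."""
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    mat = pd.DataFrame(np.nan, index=pops, columns=pops, dtype=float)
    for i, pa in enumerate(pops):
        for j, pb in enumerate(pops):
            if i > j:
                mat.iloc[i, j] = max(global_fst(gm, popmap, pa, pb), 0.0)
            elif i < j:
                mat.iloc[i, j] = reynolds_distance(gm, popmap, pa, pb)
    return mat
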