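"""LD decay and effective-population-size estimation.

Pairwise LD is the squared Pearson correlation (r²) of unphased allele
dosages at two loci on the same contig, over samples non-missing at
both. Mean r² per 20-kb distance bin out to 1 Mb gives the decay curve;
each bin inverts the drift–recombination expectation
E(r²) = (1 + 4·Ne·c)⁻¹ to an effective size Ne at t = 1/(2c)
generations ago, with the bin midpoint mapped to a recombination
fraction c via a constant cM/Mb rate. An optional Sved-style
sample-size correction subtracts 1/(2n) from the observed mean r²
before inversion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap, VariantTable

_EPS = 1e-12


def pair_r2(
    gm: GenotypeMatrix,
    vt: VariantTable,
    popmap: PopulationMap | None = None,
    pop: str | None = None,
    max_distance: int = 1_000_000,
    min_separation_snps: int = 0,
    max_pairs_per_locus: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """All (optionally subsampled) same-contig locus pairs within
    ``max_distance`` bp with their dosage r².

    ``min_separation_snps`` skips pairs closer than that many loci apart
    in SNP order. ``max_pairs_per_locus`` caps (by seeded subsampling)
    the partners drawn per left locus to bound the quadratic cost.
    Zero-variance (monomorphic) pairs are skipped.
    """
    if pop is not None:
        if popmap is None:
            raise ValueError("popmap required when pop is given")
        cols = gm.columns_for(popmap.samples_in(pop))
        values = gm.values[:, cols]
    else:
        values = gm.values
    chrom = vt.chrom
    pos = vt.pos.astype(np.int64)
    rng = np.random.default_rng(seed)

    vals = values.astype(np.float64)
    miss = values == MISSING
    vals[miss] = np.nan

    # enumerate candidate partners per left locus with searchsorted on the
    # contig-local position array (positions are sorted within a contig)
    chunks_i: list[np.ndarray] = []
    chunks_j: list[np.ndarray] = []
    n = gm.n_loci
    start = 0
    while start < n:
        stop = start
        while stop < n and chrom[stop] == chrom[start]:
            stop += 1
        cpos = pos[start:stop]
        hi = np.searchsorted(cpos, cpos + max_distance, side="right")
        for k in range(stop - start):
            lo = k + 1 + min_separation_snps
            count = hi[k] - lo
            if count <= 0:
                continue
            if max_pairs_per_locus is not None and count > max_pairs_per_locus:
                js = np.sort(
                    rng.choice(count, size=max_pairs_per_locus, replace=False)
                ) + lo
            else:
                js = np.arange(lo, hi[k])
            chunks_i.append(np.full(len(js), start + k, dtype=np.int64))
            chunks_j.append(js + start)
        start = stop

    ii = np.concatenate(chunks_i) if chunks_i else np.empty(0, dtype=np.int64)
    jj = np.concatenate(chunks_j) if chunks_j else np.empty(0, dtype=np.int64)
    r2 = np.empty(len(ii))
    # chunked pairwise-complete Pearson r^2
    chunk = 200_000
    for lo in range(0, len(ii), chunk):
        hi = min(lo + chunk, len(ii))
        x = vals[ii[lo:hi]]
        y = vals[jj[lo:hi]]
        ok = ~np.isnan(x) & ~np.isnan(y)
        m = ok.sum(axis=1).astype(float)
        xs = np.where(ok, x, 0.0)
        ys = np.where(ok, y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = xs.sum(axis=1) / m
            my = ys.sum(axis=1) / m
            sxy = (np.where(ok, (x - mx[:, None]) * (y - my[:, None]), 0.0)).sum(axis=1)
            sxx = (np.where(ok, (x - mx[:, None]) ** 2, 0.0)).sum(axis=1)
            syy = (np.where(ok, (y - my[:, None]) ** 2, 0.0)).sum(axis=1)
            r2[lo:hi] = np.where(
                (sxx > 0) & (syy > 0) & (m >= 2), (sxy**2) / (sxx * syy), np.nan
            )
    keep = ~np.isnan(r2)
    return pd.DataFrame(
        {
            "i": ii[keep],
            "j": jj[keep],
            "distance": (pos[jj[keep]] - pos[ii[keep]]),
            "r2": r2[keep],
        }
    )


def bin_decay(
    pairs: pd.DataFrame, bin_width: int = 20_000, max_distance: int = 1_000_000
) -> pd.DataFrame:
    """Mean r² per contiguous distance bin [k·w, (k+1)·w); empty bins are
    reported with n_pairs = 0 and NaN mean."""
    if len(pairs) == 0:
        raise ValueError("no LD pairs to bin")
    n_bins = int(np.ceil(max_distance / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    which = np.clip(
        np.searchsorted(edges, pairs["distance"].to_numpy(), side="right") - 1,
        0,
        n_bins - 1,
    )
    sums = np.bincount(which, weights=pairs["r2"].to_numpy(), minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "n_pairs": counts,
            "mean_r2": means,
        }
    )


def estimate_ne(
    bins: pd.DataFrame,
    n_samples: int,
    alpha: float = 1.0,
    sample_size_correction: bool = True,
    cM_per_Mb: float = 1.0,
) -> pd.DataFrame:
    """Invert E(r²) = (1 + 4·Ne·c)⁻¹ per distance bin.

    c is the bin-midpoint distance converted to Morgans at ``cM_per_Mb``;
    Ne = (1/r²_adj − alpha) / (4c) and t = 1/(2c) generations ago. With
    the correction on, r²_adj = mean_r2 − 1/(2·n_samples) (floored at a
    tiny positive ε). Bins yielding Ne ≤ 0 are flagged undefined and
    excluded.
    """
    usable = bins[(bins["n_pairs"] > 0) & bins["mean_r2"].notna()]
    rows = []
    for b in usable.itertuples(index=False):
        mid = (b.bin_start + b.bin_end) / 2.0
        c = mid * cM_per_Mb * 1e-8  # bp -> Morgans
        if c <= 0:
            continue
        r2a = b.mean_r2 - (1.0 / (2.0 * n_samples) if sample_size_correction else 0.0)
        r2a = max(r2a, _EPS)
        ne = (1.0 / r2a - alpha) / (4.0 * c)
        t = 1.0 / (2.0 * c)
        rows.append((t, ne, c, bool(ne > 0)))
    df = pd.DataFrame(rows, columns=["t", "ne", "c", "defined"])
    return df[df["defined"]].drop(columns="defined").reset_index(drop=True)
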