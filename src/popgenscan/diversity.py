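"""Per-population genetic-diversity statistics.

All statistics run over the *filtered* locus set so values are
comparable across populations: P_N is the fraction of that set
segregating within the population, H_O/H_E are means over loci with at
least one non-missing call in the population, and F_IS is the
method-of-moments heterozygote-deficit coefficient averaged over
individuals. Expected heterozygosity uses the small-sample correction
2p̂q̂·2n/(2n−1) with n the number of non-missing diploid calls at the
locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap, VariantTable


@dataclass
class DiversitySummary:
    population: str
    n_samples: int
    n_variants: int
    pn: float
    ho: float
    he: float
    mean_maf: float
    fis: float


def _pop_values(gm: GenotypeMatrix, popmap: PopulationMap, pop: str) -> np.ndarray:
    samples = popmap.samples_in(pop)
    if not samples:
        raise ValueError(f"population {pop!r} has no samples")
    return gm.values[:, gm.columns_for(samples)]


def _freq_and_n(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus alt-allele frequency and non-missing diploid count."""
    called = values != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, values, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
    return p, n


def pop_variant_count(gm: GenotypeMatrix, popmap: PopulationMap, pop: str) -> int:
    """Loci carrying at least one alt allele among the population's calls."""
    values = _pop_values(gm, popmap, pop)
    alt_present = (np.where(values == MISSING, 0, values) > 0).any(axis=1)
    return int(alt_present.sum())


def prop_polymorphic(gm: GenotypeMatrix, popmap: PopulationMap, pop: str) -> float:
    """P_N: fraction of the filtered locus set segregating within the pop."""
    values = _pop_values(gm, popmap, pop)
    if values.shape[0] == 0:
        raise ValueError("no loci")
    called = values != MISSING
    has_ref = ((values == 0) | (values == 1)).any(axis=1) & called.any(axis=1)
    has_alt = (np.where(called, values, 0) > 0).any(axis=1)
    return float((has_ref & has_alt).mean())


def observed_het(gm: GenotypeMatrix, popmap: PopulationMap, pop: str) -> float:
    values = _pop_values(gm, popmap, pop)
    called = values != MISSING
    n = called.sum(axis=1)
    usable = n > 0
    if not usable.any():
        raise ValueError("no loci with non-missing calls")
    het = (values == 1).sum(axis=1)
    return float((het[usable] / n[usable]).mean())


def _he_per_locus(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unbiased per-locus gene diversity 2p̂q̂·2n/(2n−1); returns (he, usable)."""
    p, n = _freq_and_n(values)
    usable = n > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        he = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
    he = np.where(n == 0, np.nan, he)
    # single diploid call: 2n-1 = 1, formula still defined (2pq*2)
    return he, usable


def expected_het(gm: GenotypeMatrix, popmap: PopulationMap, pop: str) -> float:
    values = _pop_values(gm, popmap, pop)
    he, usable = _he_per_locus(values)
    if not usable.any():
        raise ValueError("no loci with non-missing calls")
    return float(np.nanmean(he[usable]))


def mean_maf(gm: GenotypeMatrix, popmap: PopulationMap, pop: str) -> float:
    """Mean within-population MAF over loci segregating in the full dataset."""
    pooled_p, pooled_n = _freq_and_n(gm.values)
    seg = (pooled_n > 0) & (pooled_p > 0) & (pooled_p < 1)
    if not seg.any():
        raise ValueError("no segregating loci in the dataset")
    values = _pop_values(gm, popmap, pop)[seg]
    p, n = _freq_and_n(values)
    ok = n > 0
    maf = np.minimum(p[ok], 1.0 - p[ok])
    return float(maf.mean())


def fis(
    gm: GenotypeMatrix, popmap: PopulationMap, pop: str
) -> tuple[pd.Series, float]:
    """Per-individual inbreeding F and the population mean F_IS.

    F_i = (O_hom(i) − E_hom(i)) / (L_i − E_hom(i)) with E_hom summed over
    the individual's non-missing loci from population allele frequencies
    (1 − 2p̂q̂·2n/(2n−1)). Individuals with a degenerate denominator are
    excluded with a warning.
    """
    samples = popmap.samples_in(pop)
    if len(samples) < 2:
        raise ValueError("F_IS needs at least 2 samples")
    values = _pop_values(gm, popmap, pop)
    he, _ = _he_per_locus(values)
    exp_hom_site = 1.0 - np.nan_to_num(he, nan=0.0)

    f_vals: dict[str, float] = {}
    for j, sample in enumerate(samples):
        col = values[:, j]
        called = col != MISSING
        l_i = int(called.sum())
        if l_i == 0:
            warnings.warn(f"sample {sample} has no calls; excluded from F_IS", stacklevel=2)
            continue
        o_hom = int(((col == 0) | (col == 2)) [called].sum())
        e_hom = float(exp_hom_site[called].sum())
        denom = l_i - e_hom
        if abs(denom) < 1e-12:
            warnings.warn(
                f"sample {sample}: expected homozygosity equals call count; excluded",
                stacklevel=2,
            )
            continue
        f_vals[sample] = (o_hom - e_hom) / denom
    if not f_vals:
        raise ValueError("no usable individuals for F_IS")
    series = pd.Series(f_vals, name="F")
    return series, float(series.mean())


def per_chromosome_counts(
    vt: VariantTable, contig_lengths: dict[str, int] | None = None
) -> pd.DataFrame:
    """Per-contig SNP counts with contig length (header value or max pos)."""
    df = vt.df
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "n_snps", "length"])
    grouped = df.groupby("chrom", sort=False)
    rows = []
    for chrom, sub in grouped:
        length = (
            contig_lengths.get(chrom, int(sub["pos"].max()))
            if contig_lengths
            else int(sub["pos"].max())
        )
        rows.append((chrom, len(sub), length))
    return pd.DataFrame(rows, columns=["chrom", "n_snps", "length"])


def diversity_table(
    gm: GenotypeMatrix, popmap: PopulationMap, vt: VariantTable | None = None
) -> pd.DataFrame:
    """One summary row per population (population, n, SNPs, PN, HO, HE,
    meanMAF, FIS)."""
    rows = []
    for pop in popmap.populations:
        samples = popmap.samples_in(pop)
        summary = DiversitySummary(
            population=pop,
            n_samples=len(samples),
            n_variants=pop_variant_count(gm, popmap, pop),
            pn=prop_polymorphic(gm, popmap, pop),
            ho=observed_het(gm, popmap, pop),
            he=expected_het(gm, popmap, pop),
            mean_maf=mean_maf(gm, popmap, pop),
            fis=fis(gm, popmap, pop)[1],
        )
        rows.append(summary.__dict__)
    df = pd.DataFrame(rows)
    return df.rename(
        columns={
            "population": "population",
            "n_samples": "n",
            "n_variants": "SNPs",
            "pn": "PN",
            "ho": "HO",
            "he": "HE",
            "mean_maf": "meanMAF",
            "fis": "FIS",
        }
    )
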