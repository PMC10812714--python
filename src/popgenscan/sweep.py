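"""Windowed selective-sweep scan.

The scan contrasts one *test* population against a pooled control
group: per-site Weir–Cockerham θ is averaged over SNPs in 100-kb
windows sliding by 50 kb (windows with fewer than ``min_snps`` usable
sites are dropped), window F_ST is Z-transformed genome-wide, window
nucleotide diversity π (per bp) is computed for each group and
log2(π_control / π_test) formed, and windows in the top tail of *both*
statistics are flagged as joint sweep candidates. Tajima's D per group
per window serves as confirmation: sweep windows in the test population
are expected to show negative D.

Window coordinates are 0-based half-open; VCF positions are 1-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differentiation import site_fst
from .genotypes import MISSING, GenotypeMatrix, PopulationMap, VariantTable


@dataclass
class ScanThresholds:
    quantile: float
    realized_zfst_cutoff: float
    realized_log2ratio_cutoff: float


def make_windows(
    contig_lengths: dict[str, int], size: int = 100_000, step: int = 50_000
) -> pd.DataFrame:
    """Sliding windows fully contained in each contig (start 0, step
    ``step``); columns chrom/start/end, 0-based half-open."""
    if size <= 0:
        raise ValueError("window size must be positive")
    if not (0 < step <= size):
        raise ValueError("step must be in (0, size] (larger steps would leave gaps)")
    rows = []
    for chrom, length in contig_lengths.items():
        start = 0
        while start + size <= length:
            rows.append((chrom, start, start + size))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _sites_in_window(chrom, pos, window) -> np.ndarray:
    """Indices of sites inside a half-open window (pos is 1-based, so a
    site at pos p occupies 0-based coordinate p-1)."""
    mask = chrom == window.chrom
    idx = np.nonzero(mask)[0]
    p0 = pos[idx] - 1
    lo = np.searchsorted(p0, window.start, side="left")
    hi = np.searchsorted(p0, window.end, side="left")
    return idx[lo:hi]


def window_fst(
    site_theta: pd.DataFrame,
    windows: pd.DataFrame,
    min_snps: int = 50,
) -> pd.DataFrame:
    """Mean per-site θ per window (``site_theta`` columns: chrom, pos,
    theta). Windows with fewer than ``min_snps`` usable (defined-θ)
    sites are dropped."""
    chrom = site_theta["chrom"].to_numpy()
    pos = site_theta["pos"].to_numpy()
    theta = site_theta["theta"].to_numpy(dtype=float)
    out = []
    for w in windows.itertuples(index=False):
        idx = _sites_in_window(chrom, pos, w)
        th = theta[idx]
        th = th[~np.isnan(th)]
        if len(th) < min_snps:
            continue
        out.append((w.chrom, w.start, w.end, len(th), float(th.mean())))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "n_snps", "fst_mean"])


def zscore(values: np.ndarray) -> np.ndarray:
    """(x − mean)/sd with sample sd (ddof=1) over all retained windows."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 values to Z-transform")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread: Z-scores undefined")
    return (x - x.mean()) / sd


def _site_pi_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (π̂, allele copies n, segregating flag) within a sample set.

    π̂_site = (n/(n−1))·2p̂q̂ — the mean pairwise difference per site over
    the n non-missing allele copies.
    """
    called = values != MISSING
    n = 2.0 * called.sum(axis=1)
    alt = np.where(called, values, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        pi = (n / (n - 1.0)) * 2.0 * p * (1.0 - p)
    pi = np.where(n >= 2, pi, np.nan)
    seg = (alt > 0) & (alt < n)
    return pi, n, seg


def window_pi(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop,
    windows: pd.DataFrame,
    vt: VariantTable,
) -> pd.Series:
    """Per-window π per bp for one population (or explicit sample list):
    Σ per-site π̂ over the window's variant sites ÷ window length.
    Windows with no usable site data get NaN."""
    samples = popmap.samples_in(pop) if isinstance(pop, str) else list(pop)
    values = gm.values[:, gm.columns_for(samples)]
    pi_site, n, _ = _site_pi_stats(values)
    chrom = vt.chrom
    pos = vt.pos
    out = np.full(len(windows), np.nan)
    for k, w in enumerate(windows.itertuples(index=False)):
        idx = _sites_in_window(chrom, pos, w)
        if len(idx) == 0:
            out[k] = 0.0  # no segregating sites in window: π = 0
            continue
        vals = pi_site[idx]
        if np.isnan(vals).all():
            continue  # no non-missing data: undefined
        out[k] = np.nansum(vals) / (w.end - w.start)
    return pd.Series(out, index=windows.index, name="pi")


def log2_pi_ratio(pi_control: float, pi_test: float) -> float:
    """log2(π_control / π_test); +inf when the test population has zero
    diversity but the control does not, NaN when both are zero."""
    if np.isnan(pi_control) or np.isnan(pi_test):
        return float("nan")
    if pi_test == 0:
        return float("inf") if pi_control > 0 else float("nan")
    if pi_control == 0:
        return float("-inf")
    return float(np.log2(pi_control / pi_test))


def tajima_constants(n: int) -> dict[str, float]:
    """Standard Tajima constants a1,a2,b1,b2,c1,c2,e1,e2 for n allele copies."""
    if n < 3:
        raise ValueError("Tajima's D needs >= 3 allele copies")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_sites(pi_site: np.ndarray, n_copies: np.ndarray, seg: np.ndarray) -> float:
    """Tajima's D from per-site π̂, allele-copy counts and segregating
    flags within one window. S counts segregating sites; π is the window
    total Σπ̂ over those sites; the constants use the rounded mean copy
    count across the window's segregating sites. NaN when S = 0."""
    use = seg & ~np.isnan(pi_site)
    s = int(use.sum())
    if s == 0:
        return float("nan")
    n_mean = int(round(float(n_copies[use].mean())))
    if n_mean < 3:
        return float("nan")
    k = tajima_constants(n_mean)
    pi_total = float(pi_site[use].sum())
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - s / k["a1"]) / math.sqrt(var)


def tajimas_d(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    pop,
    window,
    vt: VariantTable,
) -> float:
    """Tajima's D for one population in one window (half-open interval)."""
    samples = popmap.samples_in(pop) if isinstance(pop, str) else list(pop)
    values = gm.values[:, gm.columns_for(samples)]
    pi_site, n, seg = _site_pi_stats(values)
    idx = _sites_in_window(vt.chrom, vt.pos, window)
    return tajimas_d_from_sites(pi_site[idx], n[idx], seg[idx])


def call_outliers(
    rows: pd.DataFrame, quantile: float = 0.95
) -> tuple[pd.DataFrame, ScanThresholds]:
    """Flag the rank-based top (1−quantile) windows on Z(F_ST) and on the
    log2 π ratio; the joint flag is their conjunction. Ties and the
    count are deterministic: exactly floor((1−q)·W) windows per
    statistic, earlier genomic order winning ties. Realized cutoffs
    (minimum flagged values) are reported."""
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    w = len(rows)
    if w < 20:
        raise ValueError(f"only {w} retained windows; need >= 20 for a top-tail call")
    k = int(math.floor((1.0 - quantile) * w))
    rows = rows.reset_index(drop=True).copy()

    def top_k(col: str) -> np.ndarray:
        vals = rows[col].to_numpy(dtype=float)
        finite_rank = np.where(np.isnan(vals), -np.inf, vals)
        order = np.lexsort((np.arange(w), -finite_rank))
        flags = np.zeros(w, dtype=bool)
        flags[order[:k]] = True
        return flags

    rows["fst_outlier"] = top_k("zfst")
    rows["pi_outlier"] = top_k("log2_ratio")
    rows["joint_outlier"] = rows["fst_outlier"] & rows["pi_outlier"]
    thresholds = ScanThresholds(
        quantile=quantile,
        realized_zfst_cutoff=float(rows.loc[rows["fst_outlier"], "zfst"].min())
        if k
        else float("nan"),
        realized_log2ratio_cutoff=float(rows.loc[rows["pi_outlier"], "log2_ratio"].min())
        if k
        else float("nan"),
    )
    return rows, thresholds


def scan(
    vt: VariantTable,
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    test_pop: str,
    window_size: int = 100_000,
    step: int = 50_000,
    min_snps: int = 50,
    quantile: float = 0.95,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, ScanThresholds]:
    """Run the full window scan: test population vs the pooled remainder.

    Returns the retained-window table (chrom, start, end, n_snps,
    fst_mean, zfst, pi_test, pi_control, log2_ratio, tajd_test,
    tajd_control, outlier flags) and the realized thresholds.
    """
    if test_pop not in popmap.populations:
        raise ValueError(f"test population {test_pop!r} not in population map")
    control = popmap.samples_not_in(test_pop)
    if not control:
        raise ValueError("control group is empty")
    if contig_lengths is None:
        contig_lengths = {
            c: int(vt.df.loc[vt.df["chrom"] == c, "pos"].max())
            for c in vt.df["chrom"].unique()
        }
    windows = make_windows(contig_lengths, window_size, step)

    comp = site_fst(gm, popmap, test_pop, control)
    site_theta = pd.DataFrame(
        {"chrom": vt.chrom, "pos": vt.pos, "theta": comp["theta"].to_numpy()}
    )
    wf = window_fst(site_theta, windows, min_snps=min_snps)
    if len(wf) == 0:
        raise ValueError("no windows retained (check min_snps / window size)")

    retained = windows.merge(wf, on=["chrom", "start", "end"], how="inner")
    retained["zfst"] = zscore(retained["fst_mean"].to_numpy())

    pi_test = window_pi(gm, popmap, test_pop, retained, vt)
    pi_control = window_pi(gm, popmap, control, retained, vt)
    retained["pi_test"] = pi_test.to_numpy()
    retained["pi_control"] = pi_control.to_numpy()
    retained["log2_ratio"] = [
        log2_pi_ratio(c, t)
        for c, t in zip(retained["pi_control"], retained["pi_test"])
    ]
    # both-zero π windows carry no ratio information: drop before ranking
    retained = retained[~retained["log2_ratio"].isna()].reset_index(drop=True)

    test_vals = gm.values[:, gm.columns_for(popmap.samples_in(test_pop))]
    ctrl_vals = gm.values[:, gm.columns_for(control)]
    pi_t, n_t, seg_t = _site_pi_stats(test_vals)
    pi_c, n_c, seg_c = _site_pi_stats(ctrl_vals)
    tajd_test = np.full(len(retained), np.nan)
    tajd_control = np.full(len(retained), np.nan)
    for i, w in enumerate(retained.itertuples(index=False)):
        idx = _sites_in_window(vt.chrom, vt.pos, w)
        tajd_test[i] = tajimas_d_from_sites(pi_t[idx], n_t[idx], seg_t[idx])
        tajd_control[i] = tajimas_d_from_sites(pi_c[idx], n_c[idx], seg_c[idx])
    retained["tajd_test"] = tajd_test
    retained["tajd_control"] = tajd_control

    return call_outliers(retained, quantile=quantile)


def genes_in_windows(windows: pd.DataFrame, gff3_path: str) -> pd.DataFrame:
    """Annotate windows with overlapping gene features from a GFF3.

    Overlap is computed half-open with ≥1 bp shared; gene GFF3
    coordinates (1-based inclusive) are converted accordingly. Output:
    one row per window with any overlap, gene names comma-joined, plus
    zfst / log2_ratio columns when present in ``windows``.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as e:
        raise ValueError(f"malformed GFF3 {gff3_path}: {e}") from e

    genes = []
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", g.attributes.get("ID", [g.id]))[0]
        genes.append((g.seqid, g.start - 1, g.end, name))  # to 0-based half-open
    gdf = pd.DataFrame(genes, columns=["chrom", "gstart", "gend", "gene"])

    rows = []
    for w in windows.itertuples(index=False):
        sub = gdf[
            (gdf["chrom"] == w.chrom) & (gdf["gstart"] < w.end) & (gdf["gend"] > w.start)
        ]
        if len(sub) == 0:
            continue
        row = {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "genes": ",".join(sub["gene"]),
        }
        for col in ("zfst", "log2_ratio"):
            if hasattr(w, col):
                row[col] = getattr(w, col)
        rows.append(row)
    return pd.DataFrame(rows)
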