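"""Genotype data model, VCF/popmap I/O and variant filtering.

The in-memory substrate for every statistic in the package is a pair of
objects: a :class:`VariantTable` (per-locus chrom / 1-based position /
ref / alt) and a :class:`GenotypeMatrix` holding allele dosages — the
number of copies of the alternate allele per diploid call, coded
0 / 1 / 2 with :data:`MISSING` (−1) for uncalled genotypes.

Filtering follows the usual WGS SNP-QC cascade for unphased diploid
data: structural (biallelic SNP, autosome whitelist), mean-depth bounds
when depth is present, per-locus call rate, per-locus missing rate,
pooled minor-allele frequency, and a Hardy–Weinberg exact test on the
pooled genotype counts. Each locus is charged to the first rule it
fails so the removal report is additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

#: Sentinel dosage for an uncalled genotype. Distinct from any valid dosage.
MISSING: int = -1

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class VCFFormatError(ValueError):
    """Raised for malformed VCF input (bad header, non-diploid calls...)."""


@dataclass
class VariantTable:
    """Per-locus site table.

    ``df`` columns: chrom (str), pos (int, 1-based), id (str), ref (str),
    alt (str, comma-joined when multi-allelic), and the convenience flag
    ``biallelic_snp``. Within a contig, positions are strictly increasing.
    An optional ``depth`` column carries the mean per-sample depth.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    def validate(self) -> None:
        df = self.df
        if (df["pos"] < 1).any():
            raise ValueError("VCF positions are 1-based; found pos < 1")
        for _, sub in df.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError("positions within a contig must be strictly increasing")
        same = df["ref"] == df["alt"]
        if same.any():
            raise ValueError("ref and alt alleles must differ")


@dataclass
class GenotypeMatrix:
    """Loci × samples alt-allele dosage matrix (0/1/2, MISSING=-1)."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (loci x samples)")
        if self.values.shape[1] != len(self.sample_ids):
            raise ValueError("column count does not match number of sample ids")
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2, MISSING}")

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def columns_for(self, samples: list[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([idx[s] for s in samples], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e} not present in genotype matrix") from e


@dataclass
class PopulationMap:
    """Sample → population assignment; populations keep first-appearance order."""

    assignments: dict[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop)
        return list(seen)

    def samples_in(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    def samples_not_in(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p != pop]

    def check_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples missing from population map: {missing}")
        absent = [s for s in self.assignments if s not in gm.sample_ids]
        if absent:
            warnings.warn(f"popmap samples absent from VCF: {absent}", stacklevel=2)


@dataclass
class FilterCriteria:
    """Thresholds of the SNP-QC cascade (defaults mirror a typical WGS pipeline:
    MAF > 0.05, missing rate < 0.1, HWE exact p ≥ 1e-5, call rate ≥ 0.90,
    biallelic autosomal SNPs, mean depth in (3, 30) when depth is present)."""

    maf_min: float = 0.05
    max_missing_rate: float = 0.1
    hwe_p_min: float = 1e-5
    min_call_rate: float = 0.90
    biallelic_only: bool = True
    autosomes: list[str] | None = None
    depth_min: float = 3.0
    depth_max: float = 30.0

    def validate(self) -> None:
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 < self.min_call_rate <= 1):
            raise ValueError("min_call_rate must be in (0, 1]")
        if not (self.depth_min < self.depth_max):
            raise ValueError("depth_min must be < depth_max")
        if not (0 <= self.max_missing_rate <= 1):
            raise ValueError("max_missing_rate must be in [0, 1]")


# application order is part of the contract: a locus is charged to the
# first rule it fails.
FILTER_RULES = ("biallelic", "autosome", "depth", "call_rate", "missing", "maf", "hwe")


@dataclass
class FilterReport:
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def __post_init__(self) -> None:
        for rule in FILTER_RULES:
            self.removed.setdefault(rule, 0)

    def check_conservation(self) -> None:
        total = self.n_retained + sum(self.removed.values())
        if total != self.n_input:
            raise AssertionError(
                f"filter report not conserved: {self.n_input} != {total}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["step", "n_loci"])


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str, samples: list[str] | None = None) -> tuple[VariantTable, GenotypeMatrix]:
    """Read a VCF into a site table and dosage matrix.

    Dosage is the count of non-reference alleles per diploid call;
    ``./.`` and ``.|.`` map to MISSING; phased and unphased separators
    are treated identically. Multi-allelic and non-SNP records are
    loaded but flagged (``biallelic_snp`` False) for downstream
    filtering. A per-site mean FORMAT/DP is captured when present.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), samples=samples, gts012=False)
    except Exception as e:  # cyvcf2 raises bare exceptions on bad headers
        raise VCFFormatError(f"cannot parse VCF {path}: {e}") from e

    sample_ids = list(vcf.samples)
    rows = []
    dosages = []
    depths = []
    has_depth = "DP" in {f for f in _format_ids(vcf)}
    for v in vcf:
        gts = v.genotypes  # [[a1, a2, phased], ...]
        row = np.empty(len(sample_ids), dtype=np.int8)
        for j, g in enumerate(gts):
            alleles = g[:-1]
            if len(alleles) != 2:
                raise VCFFormatError(
                    f"non-diploid call for sample {sample_ids[j]} at "
                    f"{v.CHROM}:{v.POS}"
                )
            a1, a2 = alleles
            if a1 < 0 or a2 < 0:
                row[j] = MISSING
            else:
                row[j] = (a1 > 0) + (a2 > 0)
        rows.append(
            (
                v.CHROM,
                v.POS,
                v.ID or ".",
                v.REF,
                ",".join(v.ALT) if v.ALT else ".",
                _is_biallelic_snp(v.REF, v.ALT),
            )
        )
        dosages.append(row)
        if has_depth:
            dp = v.format("DP")
            depths.append(float(np.nanmean(dp)) if dp is not None else np.nan)

    df = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", "biallelic_snp"])
    if has_depth:
        df["depth"] = depths
    gm = GenotypeMatrix(
        np.array(dosages, dtype=np.int8).reshape(len(rows), len(sample_ids)),
        sample_ids,
    )
    return VariantTable(df), gm


def _format_ids(vcf) -> list[str]:
    ids = []
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                ids.append(h["ID"])
        except KeyError:
            continue
    return ids


def _is_biallelic_snp(ref: str, alt: list[str] | None) -> bool:
    if not alt or len(alt) != 1:
        return False
    return len(ref) == 1 and len(alt[0]) == 1 and ref != alt[0]


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    vt: VariantTable,
    gm: GenotypeMatrix,
    path: str,
    contig_lengths: dict[str, int] | None = None,
    extra_header: list[str] | None = None,
) -> str:
    """Write a VCF v4.2 with unphased GT-only calls (MISSING as ``./.``)."""
    if len(vt) != gm.n_loci:
        raise ValueError(
            f"variant table has {len(vt)} loci but matrix has {gm.n_loci} rows"
        )
    lines = ["##fileformat=VCFv4.2"]
    lines += ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if contig_lengths is None and len(vt):
        # declare contigs from the data so readers need not warn
        contig_lengths = {
            str(c): int(sub["pos"].max())
            for c, sub in vt.df.groupby("chrom", sort=False)
        }
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    if extra_header:
        lines += extra_header
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )
    df = vt.df
    chroms = df["chrom"].to_numpy()
    poss = df["pos"].to_numpy()
    ids = df["id"].to_numpy() if "id" in df else np.full(len(df), ".")
    refs = df["ref"].to_numpy()
    alts = df["alt"].to_numpy()
    for i in range(len(df)):
        gts = "\t".join(_GT_CODE[int(d)] for d in gm.values[i])
        lines.append(
            f"{chroms[i]}\t{poss[i]}\t{ids[i]}\t{refs[i]}\t{alts[i]}\t.\t.\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def read_popmap(path: str) -> PopulationMap:
    """Read a two-column (sample, population) whitespace-delimited map."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"popmap line {lineno}: expected 2 columns, got {len(parts)}")
            sample, pop = parts
            if sample in assignments:
                raise ValueError(f"popmap line {lineno}: duplicate sample id {sample!r}")
            assignments[sample] = pop
    if not assignments:
        raise ValueError("popmap contains no samples")
    return PopulationMap(assignments)


def write_popmap(popmap: PopulationMap, path: str) -> str:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")
    return str(path)


# ---------------------------------------------------------------------------
# Statistics used by the filter cascade


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test on one locus.

    Conditional on the observed allele counts, sums the probabilities of
    every heterozygote configuration whose probability does not exceed
    that of the observed one (the standard exact HWE test for biallelic
    SNPs). Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes observed")
    n_a = 2 * n_aa + n_Aa  # one allele's count; symmetry makes the choice moot
    rare = min(n_a, 2 * n - n_a)
    # P(h hets | n, rare) ∝ n! / (((rare-h)/2)! h! ((2n-rare-h)/2)!) * 2^h
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (
        hets * np.log(2.0)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((2 * n - rare - hets) / 2 + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa]
    if len(p_obs) == 0:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _pooled_counts(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (hom-ref, het, hom-alt) counts pooled across samples."""
    n_hom_ref = (values == 0).sum(axis=1)
    n_het = (values == 1).sum(axis=1)
    n_hom_alt = (values == 2).sum(axis=1)
    return n_hom_ref, n_het, n_hom_alt


def apply_filters(
    vt: VariantTable,
    gm: GenotypeMatrix,
    criteria: FilterCriteria | None = None,
) -> tuple[VariantTable, GenotypeMatrix, FilterReport]:
    """Apply the QC cascade in fixed order and itemize removals.

    Order: biallelic SNP → autosome whitelist → mean-depth bounds (only
    when the site table carries depth) → call rate → missing rate →
    pooled MAF → pooled HWE. Removal thresholds are strict in the
    direction that makes a zero/disabled setting an identity filter.
    """
    criteria = criteria or FilterCriteria()
    criteria.validate()
    if len(vt) != gm.n_loci:
        raise ValueError("variant table / genotype matrix size mismatch")

    n_input = len(vt)
    report = FilterReport(n_input=n_input)
    alive = np.ones(n_input, dtype=bool)
    values = gm.values
    df = vt.df

    def charge(rule: str, failing: np.ndarray) -> None:
        hit = alive & failing
        report.removed[rule] = int(hit.sum())
        alive[hit] = False

    if criteria.biallelic_only and n_input:
        charge("biallelic", ~df["biallelic_snp"].to_numpy())
    if criteria.autosomes is not None and n_input:
        charge("autosome", ~df["chrom"].isin(criteria.autosomes).to_numpy())
    if "depth" in df.columns and n_input:
        depth = df["depth"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = ~((depth > criteria.depth_min) & (depth < criteria.depth_max))
        bad &= ~np.isnan(depth)  # sites without depth pass trivially
        charge("depth", bad)

    if n_input:
        called = (values != MISSING).sum(axis=1)
        call_rate = called / gm.n_samples
        charge("call_rate", call_rate < criteria.min_call_rate)
        charge("missing", (1.0 - call_rate) > criteria.max_missing_rate)

        alt_count = np.where(values == MISSING, 0, values).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt_count / (2.0 * called)
        maf = np.minimum(p, 1.0 - p)
        charge("maf", np.nan_to_num(maf, nan=0.0) < criteria.maf_min)

        if criteria.hwe_p_min > 0:
            n0, n1, n2 = _pooled_counts(values)
            hwe_fail = np.zeros(n_input, dtype=bool)
            for i in np.nonzero(alive)[0]:
                if n0[i] + n1[i] + n2[i] == 0:
                    continue
                hwe_fail[i] = hwe_exact_p(int(n0[i]), int(n1[i]), int(n2[i])) < criteria.hwe_p_min
            charge("hwe", hwe_fail)

    report.n_retained = int(alive.sum())
    report.check_conservation()
    vt_out = VariantTable(df.loc[alive].reset_index(drop=True))
    gm_out = GenotypeMatrix(values[alive], list(gm.sample_ids))
    return vt_out, gm_out, report


# ---------------------------------------------------------------------------
# LD pruning and site utilities


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over samples
    non-missing at both loci; NaN when either locus has zero variance."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    xv -= xv.mean()
    yv -= yv.mean()
    sx = (xv * xv).sum()
    sy = (yv * yv).sum()
    if sx == 0 or sy == 0:
        return float("nan")
    r = (xv * yv).sum() / np.sqrt(sx * sy)
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Greedy windowed LD pruning on dosage correlation.

    Successive windows of ``window_snps`` loci advance by ``step_snps``;
    within a window, pairs are scanned in position order and the later
    locus of any pair with r² above the threshold is dropped. Returns
    the sorted indices of retained loci. Deterministic.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")
    n = gm.n_loci
    keep = np.ones(n, dtype=bool)
    start = 0
    while start < n:
        idx = [i for i in range(start, min(start + window_snps, n)) if keep[i]]
        for ai in range(len(idx)):
            i = idx[ai]
            if not keep[i]:
                continue
            for j in idx[ai + 1 :]:
                if not keep[j]:
                    continue
                r2 = dosage_r2(gm.values[i], gm.values[j])
                if not np.isnan(r2) and r2 > r2_threshold:
                    keep[j] = False
        if start + window_snps >= n:
            break
        start += step_snps
    return np.nonzero(keep)[0]


def ts_tv_ratio(vt: VariantTable) -> float:
    """Transition / transversion count ratio over biallelic SNPs.

    Returns ``inf`` when there are transitions but no transversions.
    """
    df = vt.df
    snp = df[df["biallelic_snp"]] if "biallelic_snp" in df else df
    if len(snp) == 0:
        raise ValueError("no SNPs in variant table")
    pairs = list(zip(snp["ref"].str.upper(), snp["alt"].str.upper()))
    ts = sum(1 for p in pairs if p in _TRANSITIONS)
    tv = len(pairs) - ts
    if tv == 0:
        return float("inf")
    return ts / tv


def gc_content(path: str) -> float:
    """Genome-wide GC fraction of a FASTA: (G+C)/(A+C+G+T), case-insensitive,
    ambiguity codes excluded from the denominator."""
    from pyfaidx import Fasta

    gc = 0
    acgt = 0
    fasta = Fasta(str(path))
    for name in fasta.keys():
        seq = str(fasta[name][:]).upper()
        g = seq.count("G")
        c = seq.count("C")
        a = seq.count("A")
        t = seq.count("T")
        gc += g + c
        acgt += a + c + g + t
    if acgt == 0:
        raise ValueError("FASTA contains no unambiguous bases")
    return gc / acgt
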