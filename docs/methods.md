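# Methods

## Data model

All statistics operate on a loci × samples matrix of alternate-allele
dosages (0/1/2, with −1 for missing calls) plus a site table (contig,
1-based position, ref/alt). VCF positions are 1-based; every interval
the package emits (windows, BED, sweep truth) is 0-based half-open.

## Variant QC

Rules are applied in a fixed order — biallelic SNP, autosome whitelist,
mean-depth bounds, call rate, missing rate, pooled MAF, pooled HWE —
and a locus is charged to the *first* rule it fails, so the removal
report is additive (input = retained + Σ removed) and filtering is
idempotent. Defaults: MAF ≥ 0.05, missing rate < 0.1 (equivalently
call rate ≥ 0.90; both rules exist because they are often reported
separately), HWE exact p ≥ 1e-5, mean depth in (3, 30) when the VCF
carries per-sample DP. Boundary semantics are chosen so a zero/disabled
threshold is an identity filter (remove iff MAF < threshold); this
differs only on a measure-zero boundary from the strict "MAF > 0.05"
convention. The HWE test is the standard exact conditional test on
pooled genotype counts (all heterozygote configurations no more
probable than the observed one, given the allele counts), computed with
log-gamma weights and cross-checked against exhaustive rational
enumeration in the tests. Pooling mirrors a single `--hardy`-style pass
over all samples; with structured populations it also removes strong
Wahlund-effect loci, which is the intended behaviour of that
conventional pipeline step.

LD pruning is the usual greedy windowed pass (50 SNPs, step 10,
r² > 0.2 drops the *later* locus of a pair). The drop-the-later
tie-break is deterministic; other implementations may drop the other
member of the pair. Pruning is exposed for structure-analysis
preprocessing but is not part of the sweep pipeline, which needs dense
sites.

## Diversity

P_N, H_O, H_E and mean MAF are averaged over the *full filtered locus
set* (not per-population segregating sets) so values are comparable
across populations. H_E uses the small-sample correction
2p̂q̂·2n/(2n−1) with n the non-missing diploid calls at the locus.
F_IS is method-of-moments: per individual,
F_i = (O_hom − E_hom)/(L_i − E_hom) with E_hom summed over that
individual's non-missing loci from population frequencies; the
population value is the mean of F_i. On simulated data with planted
inbreeding F the estimate recovers F within ±0.05 at 50 diploids ×
10,000 loci (tested).

## Differentiation

Per-site two-population Weir–Cockerham (1984) components a, b, c are
computed from sample sizes, allele frequencies and observed
heterozygote frequencies; sites need ≥2 diploid calls per group and
θ is undefined when a+b+c ≤ 0 (monomorphic sites). The genome-wide
value is the ratio of sums Σa/Σ(a+b+c) — the standard choice for this
estimator — while the window scan averages per-site θ (see below).
Negative per-site θ values are retained in window means; the pairwise
matrix clamps negative global values to 0 for display only.

Reynolds' distance uses the 1983 ratio-of-sums coancestry estimator
(per-locus numerator/denominator with explicit sample-size terms;
derivable as unbiased via E[numerator] = 0 for identical populations
and E[denominator] = 2pq), then D = −ln(1−θ_R) with negative θ_R
truncated to 0 and θ_R = 1 flagged infinite. The shortcut −ln(1−F_ST)
is deliberately not used.

Under the Balding–Nichols model two populations drifted at F from a
common ancestor have pairwise F_ST = F in expectation, which is the
package's parameter-recovery target: at 50+50 diploids and 20,000 loci
the estimate lands within ±0.02 of the planted F and is strictly
monotone over F ∈ {0.01, 0.05, 0.15, 0.30} (tested).

## Sweep scan

Windows of 100 kb slide by 50 kb; only windows fully contained in a
contig are emitted (edge handling is a package choice), and windows
with fewer than 50 usable (defined-θ) sites are dropped. Window F_ST is
the arithmetic mean of per-site θ ("averaged over SNPs"); a
ratio-of-sums variant is available. Z-transformation uses the sample
standard deviation over all retained windows genome-wide.

Per-site π̂ = (n/(n−1))·2p̂q̂ equals the mean pairwise difference over
the n non-missing allele copies (exactly — verified against
pairwise-difference counting at 1e-12); window π is the sum over
variant sites divided by window length in bp. The scan statistic is
log2(π_control/π_test), so positive values mark diversity depletion in
the test population. The control group pools all non-test populations
into one sample set before computing both θ and π. Windows where both
groups have zero π carry no ratio information and are dropped before
ranking.

Outliers are rank-based: exactly floor(0.05·W) windows per statistic
(ties resolved toward earlier genomic order), making the flagged count
deterministic; the realized cutoffs (minimum flagged Z(F_ST) and
log2-ratio) are reported for comparability. The joint set is the
intersection of the two top-5% sets.

Tajima's D per window uses S = segregating sites for the group,
π = the window total of per-site π̂, and the standard constants
a1…e2 evaluated at the rounded mean allele-copy count across the
window's segregating sites (with missing data the copy count varies by
site; averaging then rounding is the package's choice — a per-site
alternative is noted in the code). D is reported as missing when S = 0
so downstream means are not biased toward 0. The implementation is
cross-checked against an exact-rational-arithmetic oracle.

## LD and Ne

r² is the squared Pearson correlation of dosage vectors
(composite/Burrows-style, since genotypes are unphased) over samples
non-missing at both loci, restricted to same-contig pairs within 1 Mb.
An optional minimum pair separation in SNP order (`--min-sep-snps`) and
a seeded per-locus partner cap bound the quadratic cost; subsampling
changes bin means only within Monte-Carlo noise (tested). Decay bins
are 20 kb wide. Each bin inverts E(r²) = (1+4·Ne·c)⁻¹ with c from the
bin midpoint at 1 cM/Mb (configurable), Ne = (1/r²_adj − α)/(4c),
t = 1/(2c); α defaults to 1.0 (mutation-adjusted 2.2 available). The
Sved-style sample-size correction r²_adj = r² − 1/(2n) is on by
default. The inversion is exact: bins synthesized from the model
equation recover Ne to machine precision (tested).

## Simulator

Per locus: ancestral frequency p ~ Uniform(0.05, 0.95); population
frequency p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (p_k = p at F = 0);
genotypes are two Bernoulli(p_k) copies, identical-by-descent with
probability F_sim; missingness is i.i.d.; ref/alt pairs are drawn at a
transition:transversion mix of 2.38, typical of mammalian WGS panels.
Inside sweep intervals the test population's frequency is overridden to
1 − (1−strength)·u, u ~ U(0,1) — near fixation at strength 0.95. The
default configuration is one 10-Mb contig, 50,000 SNPs, a 12-diploid
test population and a 33-diploid control group both at drift F = 0.05,
2% missingness, and five 200-kb sweeps at strength 0.95 — sample sizes
mirroring a realistic small livestock resequencing panel. All draws
come from one PCG64 stream in documented order, so a fixed seed gives
byte-identical output files.

What the simulator does **not** emulate: genuine linkage (sites are
drawn independently, so LD between non-sweep loci sits at the
finite-sample noise floor ≈ 1/(n−1) and the Ne trajectory on simulated
data reflects that floor, not a demographic history — the Ne estimator
is instead validated by the exact forward–inverse identity); a neutral
site-frequency spectrum (the uniform ancestral law over-represents
common variants, which shifts absolute Tajima's D positive genome-wide —
the sweep contrast in D remains valid and is what the scan uses);
sequencing-depth structure; and selection *dynamics* (the sweep is
imposed on frequencies, which is exactly the signature the scan
detects). Passing recovery tests therefore demonstrate estimator
correctness under the stated frequency model, not robustness to every
property of real resequencing data.

## Problem sizes

Recovery tests and the acceptance script use 20,000-locus panels for
F_ST recovery, the 50,000-locus default dataset for the sweep scan, and
a 20,000-locus run for pipeline determinism — sizes at which all
Monte-Carlo tolerances above are comfortably met while the whole
battery runs in a few minutes on one CPU.

## Known limitations

- Only biallelic diploid SNPs; multi-allelic records are loaded but
  filtered, never decomposed.
- The window scan's top-5% rule flags a fixed fraction of windows by
  construction; when sweeps cover more than 5% of the windowed genome
  the joint-outlier set cannot contain them all, so recall against
  broad planted truth saturates at (0.05·W)/truth — enrichment and
  Tajima's D direction are the robust recovery readouts in that regime.
- Reynolds' D and F_ST are the only distance/differentiation measures;
  no Hudson/Nei variants, no bootstrap CIs.
- No haplotype statistics (iHS, XP-EHH) and no phasing; LD is composite
  dosage r².
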