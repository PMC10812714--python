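#!/usr/bin/env python
"""Per-population diversity over the filtered locus set: proportion of
polymorphic loci (P_N), observed/expected heterozygosity, mean MAF and
F_IS, plus per-chromosome SNP counts and the Ts/Tv ratio.

Writes results/diversity.tsv and results/per_chromosome.tsv."""

import argparse

from popgenscan import diversity_table, per_chromosome_counts, read_popmap, read_vcf, ts_tv_ratio
from popgenscan.pipeline import _write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--vcf", default="results/filtered.vcf")
parser.add_argument("--popmap", default="results/data/sim.popmap.tsv")
parser.add_argument("--outdir", default="results")
args = parser.parse_args()

vt, gm = read_vcf(args.vcf)
pm = read_popmap(args.popmap)
pm.check_against(gm)

div = diversity_table(gm, pm, vt)
_write_tsv(div, f"{args.outdir}/diversity.tsv", "diversity over filtered loci")
print(div.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

chrom = per_chromosome_counts(vt)
_write_tsv(chrom, f"{args.outdir}/per_chromosome.tsv", "per-contig counts")
print(f"\nTs/Tv = {ts_tv_ratio(vt):.3f}")
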