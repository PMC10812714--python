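#!/usr/bin/env python
"""Pairwise genome-wide differentiation: ratio-of-sums Weir-Cockerham
F_ST below the diagonal, Reynolds' genetic distance above.

Writes results/pairwise_fst_reynolds.tsv."""

import argparse

from popgenscan import pairwise_matrix, read_popmap, read_vcf
from popgenscan.pipeline import _write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--vcf", default="results/filtered.vcf")
parser.add_argument("--popmap", default="results/data/sim.popmap.tsv")
parser.add_argument("--outdir", default="results")
args = parser.parse_args()

vt, gm = read_vcf(args.vcf)
pm = read_popmap(args.popmap)
mat = pairwise_matrix(gm, pm)
_write_tsv(mat, f"{args.outdir}/pairwise_fst_reynolds.tsv",
           "F_ST below diagonal, Reynolds' D above", index=True)
print("F_ST below diagonal, Reynolds' D above:")
print(mat.to_string(float_format=lambda v: f"{v:.4f}"))
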