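"""Synthetic two-group genotype data with planted selective sweeps.

The generator emulates the statistical structure of a multi-population
WGS SNP panel: an ancestral allele frequency per locus, per-population
frequencies drifted under the Balding–Nichols model
p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F), diploid genotypes with optional
within-population inbreeding (identical-by-descent allele copies with
probability F_sim), i.i.d. missingness, and *sweep* intervals where the
test population's allele frequency is pushed to near fixation
(p_sweep = 1 − (1 − strength)·u, u ~ U(0,1)) — producing exactly the
signature the window scan targets: elevated differentiation and
depleted diversity in the test group.

Balding–Nichols is used because it gives the Weir–Cockerham estimator a
known true value: two populations each drifted at F from a shared
ancestor have pairwise F_ST = F in expectation.

All randomness flows from one numpy Generator (PCG64) in documented
order (positions → substitution types → ancestral frequencies →
per-population frequencies in population order → sweep overrides in
sweep-list order → genotypes population by population → missingness),
so a fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    VariantTable,
    write_popmap,
    write_vcf,
)

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": ["C", "T"], "G": ["C", "T"], "C": ["A", "G"], "T": ["A", "G"]}


@dataclass
class PopulationSpec:
    label: str
    n_individuals: int
    drift_f: float = 0.05
    inbreeding_f: float = 0.0


@dataclass
class SweepSpec:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strength: float = 0.95


@dataclass
class SimConfig:
    seed: int = 0
    contigs: list[tuple[str, int]] = field(default_factory=lambda: [("1", 10_000_000)])
    n_snps: int = 50_000
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [
            PopulationSpec("BG", 12, 0.05, 0.0),
            PopulationSpec("CTRL", 33, 0.05, 0.0),
        ]
    )
    test_population: str = "BG"
    sweeps: list[SweepSpec] = field(
        default_factory=lambda: [
            SweepSpec("1", 1_000_000, 1_200_000, 0.95),
            SweepSpec("1", 3_000_000, 3_200_000, 0.95),
            SweepSpec("1", 5_000_000, 5_200_000, 0.95),
            SweepSpec("1", 7_000_000, 7_200_000, 0.95),
            SweepSpec("1", 9_000_000, 9_200_000, 0.95),
        ]
    )
    missing_rate: float = 0.02
    maf_floor_ancestral: float = 0.05
    ts_tv: float = 2.38  # substitution-type mix typical of mammalian WGS panels

    def validate(self) -> None:
        lengths = dict(self.contigs)
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        if self.test_population not in labels:
            raise ValueError(f"test population {self.test_population!r} not defined")
        for p in self.populations:
            if p.n_individuals < 2:
                raise ValueError(f"population {p.label}: need >= 2 individuals")
            if not (0 <= p.drift_f < 1) or not (0 <= p.inbreeding_f < 1):
                raise ValueError(f"population {p.label}: F values must be in [0, 1)")
        for s in self.sweeps:
            if s.contig not in lengths:
                raise ValueError(f"sweep on unknown contig {s.contig!r}")
            if not (0 <= s.start < s.end <= lengths[s.contig]):
                raise ValueError(f"sweep interval out of contig bounds: {s}")
            if not (0 < s.strength <= 1):
                raise ValueError("sweep strength must be in (0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 < self.maf_floor_ancestral < 0.5):
            raise ValueError("maf_floor_ancestral must be in (0, 0.5)")

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(self.contigs)


@dataclass
class SweepTruth:
    """Ground truth for recovery tests: planted intervals, drift values
    and per-locus ancestral / realized frequencies."""

    sweeps: list[SweepSpec]
    drift_f: dict[str, float]
    ancestral_freq: np.ndarray
    pop_freq: dict[str, np.ndarray]


def simulate(config: SimConfig) -> tuple[VariantTable, GenotypeMatrix, PopulationMap, SweepTruth]:
    """Simulate a dataset in memory (see module docstring for the model)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # positions: distinct uniform sites per contig, proportional to length
    total_len = sum(length for _, length in config.contigs)
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    remaining = config.n_snps
    for idx, (name, length) in enumerate(config.contigs):
        n_here = (
            remaining
            if idx == len(config.contigs) - 1
            else int(round(config.n_snps * length / total_len))
        )
        n_here = min(n_here, remaining)
        remaining -= n_here
        pos = np.sort(rng.choice(length, size=n_here, replace=False)) + 1  # 1-based
        chroms.extend([name] * n_here)
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.array([], dtype=int)
    n_loci = len(pos_all)

    # ref/alt substitution types at a fixed transition:transversion mix
    refs = _BASES[rng.integers(0, 4, size=n_loci)]
    is_ts = rng.random(n_loci) < config.ts_tv / (1.0 + config.ts_tv)
    tv_pick = rng.integers(0, 2, size=n_loci)
    alts = np.array(
        [
            _TRANSITION[r] if t else _TRANSVERSIONS[r][k]
            for r, t, k in zip(refs, is_ts, tv_pick)
        ]
    )

    floor = config.maf_floor_ancestral
    p_anc = rng.uniform(floor, 1.0 - floor, size=n_loci)

    pop_freq: dict[str, np.ndarray] = {}
    for spec in config.populations:
        if spec.drift_f == 0:
            pop_freq[spec.label] = p_anc.copy()
        else:
            f = spec.drift_f
            shape1 = p_anc * (1.0 - f) / f
            shape2 = (1.0 - p_anc) * (1.0 - f) / f
            pop_freq[spec.label] = rng.beta(shape1, shape2)

    # sweep overrides in the test population
    chrom_arr = np.asarray(chroms)
    test = config.test_population
    for s in config.sweeps:
        in_sweep = (chrom_arr == s.contig) & (pos_all - 1 >= s.start) & (pos_all - 1 < s.end)
        k = int(in_sweep.sum())
        u = rng.uniform(0.0, 1.0, size=k)
        pop_freq[test][in_sweep] = 1.0 - (1.0 - s.strength) * u

    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    blocks = []
    for spec in config.populations:
        pk = pop_freq[spec.label][:, None]
        n = spec.n_individuals
        ibd = rng.random((n_loci, n)) < spec.inbreeding_f
        d1 = (rng.random((n_loci, n)) < pk).astype(np.int8)
        d2 = (rng.random((n_loci, n)) < pk).astype(np.int8)
        geno = np.where(ibd, 2 * d1, d1 + d2).astype(np.int8)
        blocks.append(geno)
        for i in range(n):
            sid = f"{spec.label}_{i + 1:02d}"
            sample_ids.append(sid)
            assignments[sid] = spec.label
    values = np.hstack(blocks) if blocks else np.zeros((n_loci, 0), dtype=np.int8)

    if config.missing_rate > 0 and values.size:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = MISSING

    vt = VariantTable(
        pd.DataFrame(
            {
                "chrom": chroms,
                "pos": pos_all,
                "id": ".",
                "ref": refs,
                "alt": alts,
                "biallelic_snp": True,
            }
        )
    )
    gm = GenotypeMatrix(values, sample_ids)
    truth = SweepTruth(
        sweeps=list(config.sweeps),
        drift_f={p.label: p.drift_f for p in config.populations},
        ancestral_freq=p_anc,
        pop_freq=pop_freq,
    )
    return vt, gm, PopulationMap(assignments), truth


def simulate_dataset(
    config: SimConfig, out_prefix: str
) -> tuple[str, str, str]:
    """Simulate and write <prefix>.vcf, <prefix>.popmap.tsv and
    <prefix>.truth.json (+ sweep BED at <prefix>.sweeps.bed).
    Byte-identical for a fixed config and seed."""
    vt, gm, popmap, truth = simulate(config)
    header = [
        f"##source=popgenscan-simulate(seed={config.seed},rng=PCG64)",
    ]
    vcf_path = f"{out_prefix}.vcf"
    write_vcf(vt, gm, vcf_path, contig_lengths=config.contig_lengths, extra_header=header)
    popmap_path = f"{out_prefix}.popmap.tsv"
    write_popmap(popmap, popmap_path)
    truth_path = f"{out_prefix}.truth.json"
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "sweeps": [
                    {"contig": s.contig, "start": s.start, "end": s.end, "strength": s.strength}
                    for s in truth.sweeps
                ],
                "drift_f": truth.drift_f,
                "seed": config.seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    with open(f"{out_prefix}.sweeps.bed", "w") as fh:
        for s in truth.sweeps:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\tsweep_{s.strength}\n")
    return vcf_path, popmap_path, truth_path


def truth_windows(truth: SweepTruth | list[SweepSpec], windows: pd.DataFrame) -> np.ndarray:
    """Boolean flag per window: does it overlap (half-open, ≥1 bp) any
    planted sweep interval?"""
    sweeps = truth.sweeps if isinstance(truth, SweepTruth) else truth
    flags = np.zeros(len(windows), dtype=bool)
    for k, w in enumerate(windows.itertuples(index=False)):
        for s in sweeps:
            if s.contig == w.chrom and w.start < s.end and w.end > s.start:
                flags[k] = True
                break
    return flags
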