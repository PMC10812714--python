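"""End-to-end orchestration: filter → diversity → differentiation →
sweep scan → LD/Ne, with one config and file-based interchange.

Every output table is TSV with a comment header naming the parameters
and package version; a machine-readable manifest records inputs, a
parameter hash and per-stage locus counts. No hidden state crosses
stages, so each stage is independently testable, and a run with a fixed
config (and simulation seed) is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .genotypes import (
    FilterCriteria,
    apply_filters,
    read_popmap,
    read_vcf,
    ts_tv_ratio,
)
from .diversity import diversity_table, per_chromosome_counts
from .differentiation import pairwise_matrix
from .ldne import bin_decay, estimate_ne, pair_r2
from .sweep import genes_in_windows, scan

logger = logging.getLogger("popgenscan")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    test_population: str
    out_prefix: str
    gff3: str | None = None
    fasta: str | None = None
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    window_size: int = 100_000
    step: int = 50_000
    min_snps: int = 50
    quantile: float = 0.95
    ld_max_distance: int = 1_000_000
    ld_bin_width: int = 20_000
    ld_max_pairs_per_locus: int = 20
    ld_alpha: float = 1.0
    ld_sample_size_correction: bool = True
    ld_cm_per_mb: float = 1.0
    ld_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterCriteria(**raw.pop("filter", {}))
        return cls(filter=filt, **raw)

    def validate(self) -> None:
        for label, path in (("vcf", self.vcf), ("popmap", self.popmap)):
            if not os.path.exists(path):
                raise StageError("config", f"{label} file not found: {path}")
        popmap = read_popmap(self.popmap)
        if self.test_population not in popmap.populations:
            raise StageError(
                "config",
                f"test population {self.test_population!r} not in popmap",
                hint=f"available: {popmap.populations}",
            )


def _param_hash(config: RunConfig) -> str:
    # hash analysis parameters only: identical analyses of the same inputs
    # hash identically regardless of where outputs are written
    d = asdict(config)
    d.pop("out_prefix", None)
    for key in ("vcf", "popmap", "gff3", "fasta"):
        if d.get(key):
            d[key] = os.path.basename(d[key])
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: str, params: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# popgenscan {__version__} | {params}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def summarize_overlap(rows: pd.DataFrame) -> dict[str, int]:
    """Counts of fst-only / pi-only / joint outlier windows."""
    fst = rows["fst_outlier"].to_numpy(dtype=bool)
    pi = rows["pi_outlier"].to_numpy(dtype=bool)
    return {
        "fst_only": int((fst & ~pi).sum()),
        "pi_only": int((pi & ~fst).sum()),
        "joint": int((fst & pi).sum()),
    }


def run_all(config: RunConfig) -> dict[str, str]:
    """Run every stage; returns {output name: path}. On stage failure,
    completed outputs remain and an error manifest is written."""
    config.validate()
    prefix = config.out_prefix
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    outputs: dict[str, str] = {}
    manifest: dict[str, object] = {
        "version": __version__,
        "inputs": {
            "vcf": os.path.basename(config.vcf),
            "popmap": os.path.basename(config.popmap),
            "gff3": os.path.basename(config.gff3) if config.gff3 else None,
        },
        "param_hash": _param_hash(config),
        "counts": {},
    }
    counts: dict[str, int] = manifest["counts"]  # type: ignore[assignment]

    def fail(stage: str, exc: Exception, hint: str = "") -> StageError:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        with open(f"{prefix}.manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return StageError(stage, str(exc), hint)

    try:
        vt, gm = read_vcf(config.vcf)
        popmap = read_popmap(config.popmap)
        popmap.check_against(gm)
        counts["input_loci"] = len(vt)
    except StageError:
        raise
    except Exception as e:
        raise fail("read", e, "check VCF/popmap formats") from e

    try:
        vt_f, gm_f, report = apply_filters(vt, gm, config.filter)
        report.check_conservation()
        counts["retained_loci"] = report.n_retained
        path = f"{prefix}.filter_report.tsv"
        _write_tsv(report.to_frame(), path, f"filter={asdict(config.filter)}")
        outputs["filter_report"] = path
        logger.info("filter: %d -> %d loci", len(vt), report.n_retained)
    except Exception as e:
        raise fail("filter", e) from e

    try:
        div = diversity_table(gm_f, popmap, vt_f)
        path = f"{prefix}.diversity.tsv"
        _write_tsv(div, path, "per-population diversity over the filtered locus set")
        outputs["diversity"] = path
        chrom_counts = per_chromosome_counts(vt_f)
        path = f"{prefix}.per_chromosome.tsv"
        tstv = ts_tv_ratio(vt_f)
        _write_tsv(chrom_counts, path, f"ts/tv={tstv:.4g}")
        outputs["per_chromosome"] = path
    except Exception as e:
        raise fail("diversity", e) from e

    try:
        mat = pairwise_matrix(gm_f, popmap)
        path = f"{prefix}.pairwise_fst_reynolds.tsv"
        _write_tsv(mat, path, "W-C F_ST below diagonal, Reynolds' D above", index=True)
        outputs["pairwise"] = path
    except Exception as e:
        raise fail("differentiation", e) from e

    try:
        rows, thresholds = scan(
            vt_f,
            gm_f,
            popmap,
            config.test_population,
            window_size=config.window_size,
            step=config.step,
            min_snps=config.min_snps,
            quantile=config.quantile,
        )
        counts["scan_windows"] = len(rows)
        params = (
            f"test={config.test_population} window={config.window_size} "
            f"step={config.step} min_snps={config.min_snps} q={config.quantile} "
            f"zfst_cutoff={thresholds.realized_zfst_cutoff:.6g} "
            f"log2ratio_cutoff={thresholds.realized_log2ratio_cutoff:.6g}"
        )
        path = f"{prefix}.scan.tsv"
        _write_tsv(rows, path, params)
        outputs["scan"] = path
        bed = rows[rows["joint_outlier"]]
        path = f"{prefix}.joint_outliers.bed"
        with open(path, "w") as fh:
            for w in bed.itertuples(index=False):
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\tjoint\t{w.zfst:.4f}\n")
        outputs["joint_bed"] = path
        overlap = summarize_overlap(rows)
        path = f"{prefix}.overlap.tsv"
        _write_tsv(pd.DataFrame([overlap]), path, params)
        outputs["overlap"] = path
        if config.gff3:
            genes = genes_in_windows(bed, config.gff3)
            path = f"{prefix}.outlier_genes.tsv"
            _write_tsv(genes, path, params)
            outputs["genes"] = path
    except Exception as e:
        raise fail("scan", e, "check window/min_snps against data density") from e

    try:
        n_test = len(popmap.samples_in(config.test_population))
        pairs = pair_r2(
            gm_f,
            vt_f,
            popmap,
            config.test_population,
            max_distance=config.ld_max_distance,
            max_pairs_per_locus=config.ld_max_pairs_per_locus,
            seed=config.ld_seed,
        )
        bins = bin_decay(pairs, config.ld_bin_width, config.ld_max_distance)
        path = f"{prefix}.ld_decay.tsv"
        _write_tsv(
            bins,
            path,
            f"pop={config.test_population} bin={config.ld_bin_width} "
            f"max_dist={config.ld_max_distance}",
        )
        outputs["ld_decay"] = path
        ne = estimate_ne(
            bins,
            n_samples=n_test,
            alpha=config.ld_alpha,
            sample_size_correction=config.ld_sample_size_correction,
            cM_per_Mb=config.ld_cm_per_mb,
        )
        path = f"{prefix}.ne.tsv"
        _write_tsv(ne, path, f"alpha={config.ld_alpha} cM/Mb={config.ld_cm_per_mb}")
        outputs["ne"] = path
    except Exception as e:
        raise fail("ldne", e) from e

    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = f"{prefix}.manifest.json"
    return outputs
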