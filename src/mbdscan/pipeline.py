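"""End-to-end orchestration: simulate -> callpeaks -> annotate -> diff -> enrich.

One plain-text YAML config drives a run; defaults reproduce the study
conditions (300 bp windows, 1% maximum FDR, 20 kbp promoter/3'-flank).
Every stage's outputs are persisted under the output directory together
with a machine-readable run report, and identical config + seeds give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (annotate_peaks, build_feature_index,
                       chromosomal_distribution, feature_proportions)
from .differential import (attach_normalized_difference, classify_differential,
                           global_methylation_summary)
from .enrichment import enrich, focus_genes
from .io import (PEAK_TABLE_COLUMNS, read_bed_reads, read_chrom_sizes,
                 read_gene_models, read_gmt, write_bed_reads, write_peak_table)
from .peaks import MBDScan
from .simulate import (CONTROL, TREATED, SimulationConfig, simulate_landscape,
                       simulate_reads, write_truth)

logger = logging.getLogger("mbdscan")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    # inputs (ignored when simulate = True)
    reads_treated: str | None = None
    reads_control: str | None = None
    chrom_sizes: str | None = None
    genes: str | None = None
    genes_format: str = "gtf"
    gene_sets: str | None = None

    # simulation stage
    simulate: bool = False
    sim_chrom_sizes: dict = field(default_factory=lambda: {"chr1": 1_000_000,
                                                           "chr2": 600_000,
                                                           "chr3": 400_000})
    sim_n_regions: int = 100
    sim_retained_fraction: float = 0.6
    sim_region_length_min: int = 500
    sim_region_length_max: int = 2000
    sim_enrichment_factor: float = 8.0
    sim_n_reads: int = 100_000
    seed: int = 0

    # peak calling
    window_size: int = 300
    step: int = 100
    max_fdr: float = 0.01
    low_coverage_quantile: float = 0.90
    fdr_form: str = "tail"
    require_orientation: bool = False
    wilcoxon_alpha: float = 0.05

    # annotation / differential / enrichment
    flank_size: int = 20_000
    min_overlap_bp: int = 1
    enrich_classes: list = field(default_factory=lambda: ["promoter", "gene_body"])
    enrich_labels: list = field(default_factory=lambda: ["hypo"])

    def validate(self) -> list[str]:
        errors = []
        if self.window_size < 1:
            errors.append("window_size: must be >= 1")
        if not 1 <= self.step <= self.window_size:
            errors.append("step: must satisfy 1 <= step <= window_size")
        if not 0.0 < self.max_fdr <= 1.0:
            errors.append("max_fdr: must be in (0, 1]")
        if not 0.0 < self.low_coverage_quantile <= 1.0:
            errors.append("low_coverage_quantile: must be in (0, 1]")
        if self.fdr_form not in ("tail", "per_count"):
            errors.append("fdr_form: must be 'tail' or 'per_count'")
        if self.flank_size <= 0:
            errors.append("flank_size: must be > 0")
        if self.min_overlap_bp < 1:
            errors.append("min_overlap_bp: must be >= 1")
        if not 0.0 <= self.sim_retained_fraction <= 1.0:
            errors.append("sim_retained_fraction: must be in [0, 1]")
        if self.sim_enrichment_factor < 1:
            errors.append("sim_enrichment_factor: must be >= 1")
        if self.genes_format not in ("gtf", "bed12"):
            errors.append("genes_format: must be 'gtf' or 'bed12'")
        return errors

    def missing_inputs(self) -> list[str]:
        """Input files required at run time (none when simulating)."""
        if self.simulate:
            return []
        return [key for key in ("reads_treated", "reads_control", "chrom_sizes")
                if getattr(self, key) is None]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(path: str | Path) -> RunConfig:
    """Load, type-check and default-fill a YAML run config.

    Unknown keys are rejected; an empty file yields the full default
    config.  Raises :class:`ConfigError` listing every violation.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    errors = [f"{k}: unknown config key" for k in unknown]
    if errors:
        raise ConfigError(errors)
    try:
        config = RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError([str(exc)]) from exc
    errors = config.validate()
    if errors:
        raise ConfigError(errors)
    return config


def _calls_to_frame(calls, nd_by_call) -> pd.DataFrame:
    rows = []
    for call in calls:
        ap = call.peak
        peak = ap.peak if hasattr(ap, "peak") else ap
        rows.append(
            {
                "chrom": peak.chrom,
                "start": peak.start,
                "end": peak.end,
                "read_count": peak.read_count,
                "fdr": peak.min_window_fdr,
                "normalized_difference": call.normalized_difference,
                "wilcoxon_p": peak.wilcoxon_p,
                "feature_class": getattr(ap, "feature_class", ""),
                "nearest_gene": getattr(ap, "nearest_gene", None) or "",
                "differential_label": call.label,
            }
        )
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and return the run report (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.to_dict(),
                    "stages": {}}
    stage = "setup"
    try:
        missing = config.missing_inputs()
        if missing:
            raise ValueError(f"missing inputs: {', '.join(missing)}")
        with open(out / "config.echo.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

        # --- inputs ---------------------------------------------------
        t0 = time.perf_counter()
        if config.simulate:
            stage = "simulate"
            landscape = simulate_landscape(
                config.sim_chrom_sizes, config.sim_n_regions,
                config.sim_retained_fraction,
                (config.sim_region_length_min, config.sim_region_length_max),
                rng_seed=config.seed,
            )
            write_truth(landscape, out / "truth")
            chrom_sizes = landscape.chrom_sizes
            reads = {}
            for i, cond in enumerate((TREATED, CONTROL)):
                sim_cfg = SimulationConfig(
                    enrichment_factor=config.sim_enrichment_factor,
                    n_reads=config.sim_n_reads,
                    rng_seed=config.seed + 1 + i,
                )
                reads[cond] = simulate_reads(landscape, cond, sim_cfg)
                write_bed_reads(reads[cond], out / f"reads_{cond}.bed")
            report["stages"]["simulate"] = {
                "n_regions_control": len(landscape.regions(CONTROL)),
                "n_regions_treated": len(landscape.regions(TREATED)),
                "n_reads": {c: len(r) for c, r in reads.items()},
                "seconds": round(time.perf_counter() - t0, 3),
            }
        else:
            stage = "load"
            chrom_sizes = read_chrom_sizes(config.chrom_sizes)
            reads = {
                TREATED: read_bed_reads(config.reads_treated),
                CONTROL: read_bed_reads(config.reads_control),
            }
            report["stages"]["load"] = {
                "n_reads": {c: len(r) for c, r in reads.items()},
                "seconds": round(time.perf_counter() - t0, 3),
            }

        # --- peak calling per sample ----------------------------------
        stage = "callpeaks"
        t0 = time.perf_counter()
        results = {}
        for cond in (TREATED, CONTROL):
            res = MBDScan(
                reads[cond], chrom_sizes,
                window_size=config.window_size, step=config.step,
                max_fdr=config.max_fdr,
                low_coverage_quantile=config.low_coverage_quantile,
                fdr_form=config.fdr_form,
                require_orientation=config.require_orientation,
                wilcoxon_alpha=config.wilcoxon_alpha,
            ).fit()
            results[cond] = res
            with open(out / f"null_{cond}.json", "w") as fh:
                json.dump(res.null_model.to_dict() if res.null_model else None,
                          fh, indent=2)
        report["stages"]["callpeaks"] = {
            "n_windows": {c: results[c].track.n_windows for c in results},
            "n_candidates": {c: len(results[c].candidates) for c in results},
            "n_peaks": {c: results[c].n_peaks for c in results},
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # --- annotation -----------------------------------------------
        stage = "annotate"
        t0 = time.perf_counter()
        gene_models = None
        annotated = {}
        if config.genes:
            gene_models = read_gene_models(config.genes, config.genes_format)
            index = build_feature_index(gene_models, config.flank_size,
                                        chrom_sizes=chrom_sizes)
            for cond in (TREATED, CONTROL):
                annotated[cond] = annotate_peaks(results[cond].peaks, index)
            report["stages"]["annotate"] = {
                "n_genes": len(gene_models),
                "class_fractions": {
                    c: feature_proportions(annotated[c])["fractions"]
                    for c in annotated
                },
                "seconds": round(time.perf_counter() - t0, 3),
            }
        else:
            annotated = {c: results[c].peaks for c in results}

        # --- differential ---------------------------------------------
        stage = "diff"
        t0 = time.perf_counter()
        calls = classify_differential(annotated[TREATED], annotated[CONTROL],
                                      config.min_overlap_bp)
        if len(reads[TREATED]) and len(reads[CONTROL]):
            attach_normalized_difference(calls, reads[TREATED], reads[CONTROL],
                                         chrom_sizes)
        summary = global_methylation_summary(calls)
        chrom_dist = chromosomal_distribution(
            {
                TREATED: [c.peak for c in calls
                          if c.sample == "treated" and c.label != "shared"],
                CONTROL: [c.peak for c in calls
                          if c.sample == "control" and c.label != "shared"],
            },
            chromosomes=list(chrom_sizes),
        )
        chrom_dist.to_csv(out / "chromosomal_distribution.tsv", sep="\t")
        for cond, sample in ((TREATED, "treated"), (CONTROL, "control")):
            frame = _calls_to_frame(
                [c for c in calls if c.sample == sample], None
            )
            write_peak_table(frame, out / f"peaks_{cond}")
        report["stages"]["diff"] = {
            "n_hyper": summary["n_hyper"],
            "n_hypo": summary["n_hypo"],
            "n_shared": summary["n_shared"],
            "global_hypomethylation": summary["global_hypomethylation"],
            "seconds": round(time.perf_counter() - t0, 3),
        }

        # --- enrichment -----------------------------------------------
        if config.gene_sets and gene_models:
            stage = "enrich"
            t0 = time.perf_counter()
            sets = read_gmt(config.gene_sets)
            universe = {g.gene_id for g in gene_models}
            focus = focus_genes(calls, config.enrich_classes,
                                config.enrich_labels) & universe
            enr = enrich(focus, sets, universe)
            pd.DataFrame(
                [dataclasses.asdict(r) for r in enr]
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False,
                     float_format="%.6g")
            report["stages"]["enrich"] = {
                "n_focus": len(focus),
                "n_sets": len(sets),
                "top_sets": [
                    {"set_id": r.set_id, "p_value": r.p_value,
                     "adjusted_p": r.adjusted_p}
                    for r in enr[:5]
                ],
                "seconds": round(time.perf_counter() - t0, 3),
            }

        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        logger.error("pipeline stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
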