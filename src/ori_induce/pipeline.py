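"""End-to-end run: simulate (or load) → σ tracks → call origins → annotate.

A run is described by one :class:`RunConfig` (deserialisable from YAML),
executes its stages in order with per-stage logging to stderr, writes every
intermediate artifact as plain text (bedGraph / BED / GFF3 / TSV) into the
output directory, and returns a :class:`RunReport` whose numbers are exactly
recomputable from those artifacts. Runs are deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from .genes import (BinGeneClasses, GeneModel, classify_bins, gene_size_enrichment,
                    genes_hit_by_origins, genic_fraction)
from .genome import GenomeBinning
from .origins import (ClassifierConfig, OriginCall, calls_to_frame,
                      classify_origins, find_peaks, summarize_origins)
from .sigma import SigmaTrack, average_sigma, bin_reads, compute_sigma, smooth_sigma
from .synthetic import SimulationConfig, simulate_eduseq_counts, simulate_genome

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Configuration problems, all collected before raising."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one input mode: ``simulation`` (generate the experiment) or
    explicit read files (``reads_treated`` / ``reads_control`` BED paths —
    replicate lists — plus ``genome_path`` chrom sizes and ``genes_path``).
    """

    outdir: str = "ori_induce_run"
    seed: int = 0
    bin_width_bp: int = 10_000
    target_mean: float = 10.0
    sd_mode: str = "sample"          # "sample" | "poisson"
    sd_scope: str = "genome"         # "genome" | "chromosome"
    smoothing_window_bins: int = 1
    min_score: float | None = None
    replicate_combine: str = "mean_sigma"   # "mean_sigma" | "pooled_counts"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    simulation: SimulationConfig | None = None
    reads_treated: list[str] = field(default_factory=list)
    reads_control: list[str] = field(default_factory=list)
    genome_path: str | None = None
    genes_path: str | None = None

    def config_hash(self) -> str:
        def enc(o: Any):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError
        d = asdict(self)
        d.pop("outdir", None)  # where results go does not change what they are
        blob = json.dumps(d, sort_keys=True, default=enc)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate_config(raw: str | dict) -> RunConfig:
    """Build a RunConfig from YAML text or a dict, collecting *all* errors."""
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"not valid YAML: {exc}"]) from exc
    else:
        data = dict(raw)
    errors: list[str] = []

    def take(d: dict, key: str, default=None):
        return d.pop(key, default)

    classifier_raw = take(data, "classifier", {}) or {}
    simulation_raw = take(data, "simulation", None)
    known = {f for f in RunConfig.__dataclass_fields__
             if f not in ("classifier", "simulation")}
    cfg_kwargs = {}
    for key in list(data):
        if key in known:
            cfg_kwargs[key] = data.pop(key)
    for key in data:
        errors.append(f"unknown config key {key!r}")

    classifier = None
    try:
        classifier = ClassifierConfig(**classifier_raw)
    except (TypeError, ValueError) as exc:
        errors.append(f"classifier: {exc}")
    simulation = None
    if simulation_raw is not None:
        try:
            simulation = SimulationConfig(**simulation_raw)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulation: {exc}")

    bw = cfg_kwargs.get("bin_width_bp", 10_000)
    if not isinstance(bw, int) or bw <= 0:
        errors.append(f"bin_width_bp must be a positive integer, got {bw!r}")
    if cfg_kwargs.get("sd_mode", "sample") not in ("sample", "poisson"):
        errors.append(f"sd_mode must be 'sample' or 'poisson'")
    if cfg_kwargs.get("sd_scope", "genome") not in ("genome", "chromosome"):
        errors.append(f"sd_scope must be 'genome' or 'chromosome'")
    if cfg_kwargs.get("replicate_combine", "mean_sigma") not in (
            "mean_sigma", "pooled_counts"):
        errors.append("replicate_combine must be 'mean_sigma' or 'pooled_counts'")
    win = cfg_kwargs.get("smoothing_window_bins", 1)
    if not isinstance(win, int) or win < 1 or win % 2 == 0:
        errors.append(f"smoothing_window_bins must be an odd integer >= 1, got {win!r}")

    if simulation is None and simulation_raw is None:
        import os
        for key in ("genome_path", "genes_path"):
            path = cfg_kwargs.get(key)
            if not path:
                errors.append(f"{key} is required when no simulation block is given")
            elif not os.path.exists(path):
                errors.append(f"{key}: no such file {path!r}")
        if not cfg_kwargs.get("reads_treated"):
            errors.append("reads_treated is required when no simulation block is given")
        for key in ("reads_treated", "reads_control"):
            for path in cfg_kwargs.get(key) or []:
                import os
                if not os.path.exists(path):
                    errors.append(f"{key}: no such file {path!r}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(classifier=classifier, simulation=simulation, **cfg_kwargs)


@dataclass
class RunReport:
    """Headline numbers of one run; every figure is recomputable from the
    artifacts written next to it."""

    n_constitutive: int
    n_induced_2x: int
    n_induced_4x: int
    total_origins: int
    induced_fraction_percent: float
    genic_fraction_all_percent: float
    genic_fraction_induced_percent: float
    genic_fraction_constitutive_percent: float
    n_hit_genes: int
    hit_gene_mean_length_bp: float
    all_gene_mean_length_bp: float
    gene_size_u: float
    gene_size_pvalue: float
    version: str
    config_hash: str
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "warnings"}
        return pd.DataFrame({"metric": list(d), "value": list(d.values())})

    def to_text(self) -> str:
        lines = ["ori-induce run report", "=" * 22]
        for _, row in self.to_frame().iterrows():
            v = row["value"]
            if isinstance(v, float):
                v = "nan" if np.isnan(v) else f"{v:.4f}"
            lines.append(f"{row['metric']:38s} {v}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines) + "\n"


def _log(stage: str, t0: float) -> None:
    print(f"[ori-induce] {stage}: done in {time.perf_counter() - t0:.2f}s",
          file=sys.stderr)


def _sigma_from_reads(paths: list[str], binning: GenomeBinning, cfg: RunConfig,
                      sample_id: str) -> tuple[SigmaTrack, list[str]]:
    warnings: list[str] = []
    tracks = []
    pooled = np.zeros(binning.n_bins_total, dtype=np.int64)
    for path in paths:
        reads = oio.read_bed_intervals(path)
        binned = bin_reads(reads, binning, min_score=cfg.min_score)
        if binned.n_discarded:
            warnings.append(f"{path}: discarded {binned.n_discarded} of "
                            f"{binned.n_reads} reads")
        if cfg.replicate_combine == "pooled_counts":
            pooled += binned.counts
        else:
            tracks.append(compute_sigma(binned.counts, binning,
                                        sample_id=path, target_mean=cfg.target_mean,
                                        sd_mode=cfg.sd_mode, sd_scope=cfg.sd_scope))
    if cfg.replicate_combine == "pooled_counts":
        track = compute_sigma(pooled, binning, sample_id=sample_id,
                              target_mean=cfg.target_mean, sd_mode=cfg.sd_mode,
                              sd_scope=cfg.sd_scope)
    else:
        track = average_sigma(tracks, sample_id) if len(tracks) > 1 else tracks[0]
    return smooth_sigma(track, cfg.smoothing_window_bins), warnings


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages, write artifacts under ``config.outdir``."""
    import os

    out = config.outdir
    os.makedirs(out, exist_ok=True)
    warnings: list[str] = []

    # -- stage: inputs ------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.simulation is not None:
            sim = config.simulation
            if config.seed != sim.seed:
                from dataclasses import replace
                sim = replace(sim, seed=config.seed)
            binning, genes = simulate_genome(sim)
            counts_t, counts_c, truth = simulate_eduseq_counts(sim, binning, genes)
            oio.write_chrom_sizes(binning.chromosomes, f"{out}/genome.tsv")
            oio.write_gff3(genes, f"{out}/genes.gff3")
            oio.write_bed6(pd.DataFrame(
                dict(chromosome=[g.chromosome for g in genes],
                     start=[g.start for g in genes],
                     end=[g.end for g in genes],
                     name=[g.gene_id for g in genes],
                     score=0, strand=[g.strand for g in genes],
                     biotype=[g.biotype for g in genes])),
                f"{out}/genes.bed")
            oio.write_tsv(truth, f"{out}/truth.tsv")
            oio.write_bedgraph(binning, counts_t, f"{out}/counts_treated.bedGraph")
            oio.write_bedgraph(binning, counts_c, f"{out}/counts_control.bedGraph")
            masked_df = pd.DataFrame(binning.bin_table())
            oio.write_tsv(masked_df[masked_df["masked"]].drop(columns="masked"),
                          f"{out}/masked_bins.tsv")
        else:
            chroms = oio.read_chrom_sizes(config.genome_path)
            binning = GenomeBinning(chroms, config.bin_width_bp)
            genes = oio.read_gene_annotation(config.genes_path)
            counts_t = counts_c = truth = None
    except StageError:
        raise
    except Exception as exc:
        raise StageError("inputs", exc) from exc
    _log("inputs", t0)

    # -- stage: sigma -------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.simulation is not None:
            treated = smooth_sigma(
                compute_sigma(counts_t, binning, sample_id="treated",
                              target_mean=config.target_mean,
                              sd_mode=config.sd_mode, sd_scope=config.sd_scope),
                config.smoothing_window_bins)
            control = smooth_sigma(
                compute_sigma(counts_c, binning, sample_id="control",
                              target_mean=config.target_mean,
                              sd_mode=config.sd_mode, sd_scope=config.sd_scope),
                config.smoothing_window_bins)
        else:
            treated, w = _sigma_from_reads(config.reads_treated, binning,
                                           config, "treated")
            warnings.extend(w)
            control = None
            if config.reads_control:
                control, w = _sigma_from_reads(config.reads_control, binning,
                                               config, "control")
                warnings.extend(w)
        oio.write_bedgraph(binning, treated.sigma, f"{out}/sigma_treated.bedGraph")
        if control is not None:
            oio.write_bedgraph(binning, control.sigma, f"{out}/sigma_control.bedGraph")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("sigma", exc) from exc
    _log("sigma", t0)

    # -- stage: call-origins ------------------------------------------------
    t0 = time.perf_counter()
    try:
        if control is None:
            raise ValueError("no control track: reads_control is required "
                             "to classify origins")
        peaks = find_peaks(treated, config.classifier)
        calls = classify_origins(peaks, treated, control, config.classifier)
        summary = summarize_origins(calls)
        oio.write_bed6(calls_to_frame(calls, binning.bin_width_bp),
                       f"{out}/origins.bed")
        oio.write_tsv(pd.DataFrame(
            dict(origin_class=["constitutive", "induced_2x", "induced_4x", "total"],
                 count=[summary.n_constitutive, summary.n_induced_2x,
                        summary.n_induced_4x, summary.total])),
            f"{out}/origin_summary.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("call-origins", exc) from exc
    _log("call-origins", t0)

    # -- stage: annotate ----------------------------------------------------
    t0 = time.perf_counter()
    try:
        bin_classes = classify_bins(binning, genes)
        rec = pd.DataFrame(binning.bin_table())
        rec["name"] = bin_classes.raw
        oio.write_bed6(rec[["chromosome", "start", "end", "name"]],
                       f"{out}/bin_classes.bed")
        frac_all = genic_fraction(calls, bin_classes)
        frac_ind = genic_fraction(calls, bin_classes,
                                  class_filter=("induced_2x", "induced_4x"))
        frac_con = genic_fraction(calls, bin_classes, class_filter="constitutive")
        hit = genes_hit_by_origins(calls, genes,
                                   class_filter=("induced_2x", "induced_4x"),
                                   bin_width_bp=binning.bin_width_bp)
        coding = [g for g in genes if g.biotype == "protein_coding"]
        if hit and coding:
            enr = gene_size_enrichment(hit, coding)
            enr_row = dict(n_hit=enr.n_hit, n_all=enr.n_all,
                           mean_hit_bp=enr.mean_hit_bp, mean_all_bp=enr.mean_all_bp,
                           u_statistic=enr.u_statistic, pvalue=enr.pvalue,
                           method=enr.test.method)
        else:
            enr = None
            enr_row = dict(n_hit=len(hit), n_all=len(coding),
                           mean_hit_bp=np.nan, mean_all_bp=np.nan,
                           u_statistic=np.nan, pvalue=np.nan, method="undefined")
            warnings.append("gene-size enrichment undefined (no induced hit genes)")
        oio.write_tsv(pd.DataFrame([enr_row]), f"{out}/gene_size_enrichment.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("annotate", exc) from exc
    _log("annotate", t0)

    # -- stage: report ------------------------------------------------------
    t0 = time.perf_counter()
    report = RunReport(
        n_constitutive=summary.n_constitutive,
        n_induced_2x=summary.n_induced_2x,
        n_induced_4x=summary.n_induced_4x,
        total_origins=summary.total,
        induced_fraction_percent=summary.induced_fraction_percent,
        genic_fraction_all_percent=frac_all.percent,
        genic_fraction_induced_percent=frac_ind.percent,
        genic_fraction_constitutive_percent=frac_con.percent,
        n_hit_genes=len(hit),
        hit_gene_mean_length_bp=enr.mean_hit_bp if enr else float("nan"),
        all_gene_mean_length_bp=enr.mean_all_bp if enr else float("nan"),
        gene_size_u=enr.u_statistic if enr else float("nan"),
        gene_size_pvalue=enr.pvalue if enr else float("nan"),
        version=__version__,
        config_hash=config.config_hash(),
        warnings=warnings,
    )
    oio.write_tsv(report.to_frame(), f"{out}/report.tsv", float_format="%.6f")
    oio.write_text(report.to_text(), f"{out}/report.txt")
    _log("report", t0)
    return report
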