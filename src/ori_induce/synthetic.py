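"""Synthetic EdU-seq experiments with known ground truth.

The generator emulates the geometry of nascent-strand sequencing under
hydroxyurea on a toy multi-chromosome genome: flat Poisson background
coverage in 10-kb bins, origins as narrow triangular pileups (HU confines
nascent DNA near the firing site), a masked-bin fraction standing in for
unmappable sequence, and a non-overlapping gene annotation with log-normal
gene lengths. Constitutive origins carry equal signal in the treated and
control libraries; induced origins carry full signal in the treated library
only, plus a calibrated residue in the control library (see
``simulate_eduseq_counts``), so the planted treated:control σ ratio equals
the requested fold.

Everything is driven by one explicit seed: same seed + same config gives
bit-identical genomes, counts and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genes import GeneModel, classify_bins
from .genome import GenomeBinning
from .origins import ClassifierConfig
from .assays import CtRecord, FibreTrack

DEFAULT_KB_PER_UM = 2.59


class CapacityError(ValueError):
    """Requested annotation does not fit in the genome."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic EdU-seq experiment.

    ``induced_fold`` is the target treated:control σ ratio of induced
    origins — a scalar applied to all of them, or one value per induced
    origin. ``induced_genic_bias`` is the probability that an induced origin
    lands in a fully-genic bin; None (default) places origins uniformly per
    base pair over all eligible bins, which by itself makes long genes more
    likely to be hit. ``control_leak``, when set, bypasses the calibrated
    control residue and plants ``peak_amplitude_reads * control_leak`` reads
    at induced origins in the control library.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length_bp: int = 50_000_000
    bin_width_bp: int = 10_000
    background_mean_reads: float = 10.0
    n_constitutive_origins: int = 30
    n_induced_origins: int = 30
    induced_fold: float | tuple = 5.0
    peak_amplitude_reads: float = 800.0
    peak_halfwidth_bins: int = 2
    masked_fraction: float = 0.05
    gene_length_log_mean: float = 10.0
    gene_length_log_sd: float = 1.0
    n_genes: int = 800
    induced_genic_bias: float | None = None
    control_leak: float | None = None
    min_origin_separation_bins: int = 10
    target_mean: float = 10.0

    def __post_init__(self) -> None:
        if self.bin_width_bp <= 0:
            raise ValueError("bin_width_bp must be positive")
        if self.chromosome_length_bp < self.bin_width_bp:
            raise ValueError("chromosome_length_bp must be >= bin_width_bp")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.background_mean_reads < 0:
            raise ValueError("background_mean_reads must be non-negative")
        if self.peak_amplitude_reads <= 0:
            raise ValueError("peak_amplitude_reads must be positive")
        if self.peak_halfwidth_bins < 1:
            raise ValueError("peak_halfwidth_bins must be >= 1")
        if not 0 <= self.masked_fraction <= 1:
            raise ValueError("masked_fraction must be in [0, 1]")
        if self.n_constitutive_origins < 0 or self.n_induced_origins < 0:
            raise ValueError("origin counts must be non-negative")
        for f in self.induced_folds():
            if f <= 0:
                raise ValueError("induced_fold values must be positive")
        if self.induced_genic_bias is not None and not 0 <= self.induced_genic_bias <= 1:
            raise ValueError("induced_genic_bias must be in [0, 1] or None")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")

    def induced_folds(self) -> tuple[float, ...]:
        """Per-induced-origin fold targets."""
        if isinstance(self.induced_fold, (int, float)):
            return (float(self.induced_fold),) * self.n_induced_origins
        folds = tuple(float(f) for f in self.induced_fold)
        if len(folds) != self.n_induced_origins:
            raise ValueError(
                f"induced_fold sequence has {len(folds)} entries for "
                f"{self.n_induced_origins} induced origins")
        return folds

    def chromosomes(self) -> list[tuple[str, int]]:
        return [(f"chr{i + 1}", self.chromosome_length_bp)
                for i in range(self.n_chromosomes)]


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig
                    ) -> tuple[GenomeBinning, list[GeneModel]]:
    """Build the binned toy genome and a non-overlapping gene annotation.

    Masked bins are an i.i.d. Bernoulli(masked_fraction) draw. Gene lengths
    are log-normal; genes are distributed over chromosomes with probability
    proportional to chromosome length and placed uniformly at random without
    overlap (via uniform gap splitting of the remaining free space), so a
    uniformly-chosen base pair falls in a given gene with probability
    proportional to its length.
    """
    rng = np.random.default_rng(config.seed)
    chroms = config.chromosomes()
    binning = GenomeBinning(chroms, config.bin_width_bp)
    masked = rng.random(binning.n_bins_total) < config.masked_fraction
    binning = GenomeBinning(chroms, config.bin_width_bp, masked=masked)

    genes: list[GeneModel] = []
    if config.n_genes > 0:
        lengths = np.rint(rng.lognormal(config.gene_length_log_mean,
                                        config.gene_length_log_sd,
                                        config.n_genes)).astype(np.int64)
        lengths = np.maximum(lengths, 200)  # floor: no sub-200-bp genes
        genome_bp = sum(length for _, length in chroms)
        if int(lengths.sum()) > genome_bp:
            raise CapacityError(
                f"requested {int(lengths.sum())} bp of genes in a "
                f"{genome_bp} bp genome")
        # length-proportional chromosome assignment, retried if a draw
        # overfills one chromosome (cannot happen at moderate gene density)
        probs = np.array([length for _, length in chroms], dtype=float)
        probs /= probs.sum()
        for _ in range(50):
            assignment = rng.choice(len(chroms), size=config.n_genes, p=probs)
            per = [lengths[assignment == i].sum() for i in range(len(chroms))]
            if all(per[i] <= chroms[i][1] for i in range(len(chroms))):
                break
        else:
            raise CapacityError("could not distribute genes over chromosomes; "
                                "annotation too dense")
        gid = 0
        for i, (name, chrom_len) in enumerate(chroms):
            lens = lengths[assignment == i]
            if lens.size == 0:
                continue
            order = rng.permutation(lens.size)
            lens = lens[order]
            free = chrom_len - int(lens.sum())
            cuts = np.sort(rng.uniform(0, free, size=lens.size))
            starts = np.floor(cuts).astype(np.int64) + np.concatenate(
                [[0], np.cumsum(lens[:-1])])
            for s, ln in zip(starts, lens):
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(f"gene_{gid:05d}", name, int(s),
                                       int(s + ln), strand, "protein_coding"))
                gid += 1
        genes.sort(key=lambda g: (g.chromosome, g.start))
    return binning, genes


# ---------------------------------------------------------------------------
# EdU-seq counts
# ---------------------------------------------------------------------------

def _triangular_kernel(halfwidth: int) -> np.ndarray:
    """Weights at offsets -(h-1)..(h-1): 1 at the centre, linear to 0 at ±h."""
    offsets = np.arange(-(halfwidth - 1), halfwidth)
    return 1.0 - np.abs(offsets) / halfwidth


def _add_kernel(lam: np.ndarray, sl: slice, local_bin: int, amplitude: float,
                halfwidth: int) -> None:
    weights = _triangular_kernel(halfwidth) * amplitude
    for off, w in zip(range(-(halfwidth - 1), halfwidth), weights):
        b = local_bin + off
        if 0 <= b < sl.stop - sl.start:
            lam[sl.start + b] += w


def _expected_sd(lam: np.ndarray, unmasked: np.ndarray) -> float:
    """Expected count SD: Poisson within-bin variance + between-bin spread."""
    sub = lam[unmasked]
    return float(np.sqrt(sub.mean() + sub.var()))


def _solve_control_amplitudes(folds: np.ndarray, amplitude: float,
                              background: float, lam_t: np.ndarray,
                              lam_c_base: np.ndarray, unmasked: np.ndarray,
                              kernel_positions: list[tuple[slice, int]],
                              halfwidth: int) -> np.ndarray:
    """Control-side amplitudes making the expected σ ratio equal each fold.

    σ divides each track by its own genome-wide SD, so the treated track
    (which carries the full induced signal) has the larger SD and a plain
    amplitude/fold residue would deflate every ratio by sd_control/sd_treated.
    Solve   (background + amplitude) / sd_t  =  fold * (background + leak) / sd_c
    for the leak of each fold class by fixed-point iteration (sd_c depends on
    the leaks; sd_t does not).
    """
    sd_t = _expected_sd(lam_t, unmasked)
    leaks = amplitude / folds  # starting point: the naive residue
    for _ in range(30):
        lam_c = lam_c_base.copy()
        for (sl, b), leak in zip(kernel_positions, leaks):
            _add_kernel(lam_c, sl, b, leak, halfwidth)
        sd_c = _expected_sd(lam_c, unmasked)
        new = np.maximum((sd_c / sd_t) * (background + amplitude) / folds
                         - background, 0.0)
        if np.allclose(new, leaks, rtol=1e-10, atol=1e-12):
            leaks = new
            break
        leaks = new
    return leaks


def simulate_eduseq_counts(config: SimulationConfig, binning: GenomeBinning,
                           genes: list[GeneModel]
                           ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-bin treated/control read counts with planted origins, plus truth.

    Counts are Poisson around background + triangular origin pileups.
    Constitutive origins add ``peak_amplitude_reads`` to both conditions.
    Induced origins add it to the treated condition only; their control-side
    residue is calibrated so the *expected σ ratio* equals the origin's fold
    (or fixed to ``amplitude * control_leak`` when the override is set).
    Masked bins emit zero reads. The truth table records each origin's bin,
    fold, class under the standard ratio thresholds, and genic context.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    unmasked = ~binning.masked
    folds = np.array(config.induced_folds(), dtype=float)
    halfwidth = config.peak_halfwidth_bins
    margin = halfwidth + 1
    bin_classes = classify_bins(binning, genes) if genes else None

    # eligible bins: unmasked, away from chromosome edges
    eligible: list[tuple[str, int]] = []
    genic_flags: list[bool] = []
    for name in binning.chromosome_names:
        sl = binning.chrom_slice(name)
        n = sl.stop - sl.start
        for b in range(margin, n - margin):
            if unmasked[sl.start + b]:
                eligible.append((name, b))
                genic_flags.append(bool(bin_classes.collapsed_genic[sl.start + b])
                                   if bin_classes is not None else False)

    n_total = config.n_constitutive_origins + config.n_induced_origins
    sep = config.min_origin_separation_bins
    chosen: list[tuple[str, int]] = []
    taken: dict[str, list[int]] = {}

    def free(site: tuple[str, int]) -> bool:
        chrom, b = site
        return all(abs(b - o) >= sep for o in taken.get(chrom, ()))

    def pick(pool_idx: np.ndarray) -> tuple[str, int]:
        pool_idx = rng.permutation(pool_idx)
        for k in pool_idx:
            site = eligible[int(k)]
            if free(site):
                taken.setdefault(site[0], []).append(site[1])
                return site
        raise CapacityError(
            f"could not place {n_total} origins {sep} bins apart; "
            f"genome too small or too masked")

    genic_idx = np.flatnonzero(np.array(genic_flags, dtype=bool))
    nongenic_idx = np.flatnonzero(~np.array(genic_flags, dtype=bool))
    all_idx = np.arange(len(eligible))

    records = []
    for i in range(config.n_constitutive_origins):
        chrom, b = pick(all_idx)
        records.append([f"ori_{len(records):04d}", chrom, b, "constitutive",
                        1.0, False])
    thresholds = ClassifierConfig()
    for i in range(config.n_induced_origins):
        if config.induced_genic_bias is None:
            pool = all_idx
        elif rng.random() < config.induced_genic_bias and genic_idx.size:
            pool = genic_idx
        else:
            pool = nongenic_idx if nongenic_idx.size else all_idx
        chrom, b = pick(pool)
        records.append([f"ori_{len(records):04d}", chrom, b,
                        thresholds.classify_ratio(folds[i]), float(folds[i]),
                        True])

    truth = pd.DataFrame(records, columns=["origin_id", "chromosome",
                                           "bin_index", "true_class", "fold",
                                           "is_induced"])
    truth = truth.astype({"bin_index": np.int64, "fold": float,
                          "is_induced": bool})
    truth["position_bp"] = truth["bin_index"] * binning.bin_width_bp

    # genic context of each origin bin
    inside, gene_ids = [], []
    for chrom, b in zip(truth["chromosome"], truth["bin_index"]):
        g = binning.global_index(chrom, int(b))
        is_genic = bool(bin_classes.collapsed_genic[g]) if bin_classes is not None else False
        inside.append(is_genic)
        gid = None
        if is_genic:
            start = int(b) * binning.bin_width_bp
            centre = start + binning.bin_width_bp // 2
            for gene in genes:
                if gene.chromosome == chrom and gene.start <= centre < gene.end:
                    gid = gene.gene_id
                    break
        gene_ids.append(gid)
    truth["inside_gene"] = inside
    truth["gene_id"] = gene_ids

    # intensity fields
    A = config.peak_amplitude_reads
    bg = config.background_mean_reads
    lam_t = np.where(unmasked, bg, 0.0)
    lam_c_base = np.where(unmasked, bg, 0.0)
    const = truth[~truth["is_induced"]]
    induced = truth[truth["is_induced"]]
    for chrom, b in zip(const["chromosome"], const["bin_index"]):
        sl = binning.chrom_slice(chrom)
        _add_kernel(lam_t, sl, int(b), A, halfwidth)
        _add_kernel(lam_c_base, sl, int(b), A, halfwidth)
    induced_positions = [(binning.chrom_slice(c), int(b))
                         for c, b in zip(induced["chromosome"], induced["bin_index"])]
    for sl, b in induced_positions:
        _add_kernel(lam_t, sl, b, A, halfwidth)

    if induced_positions:
        if config.control_leak is not None:
            leaks = np.full(len(induced_positions), A * config.control_leak)
        else:
            leaks = _solve_control_amplitudes(
                folds, A, bg, lam_t, lam_c_base, unmasked,
                induced_positions, halfwidth)
    else:
        leaks = np.array([])
    lam_c = lam_c_base.copy()
    for (sl, b), leak in zip(induced_positions, leaks):
        _add_kernel(lam_c, sl, b, leak, halfwidth)

    counts_t = rng.poisson(lam_t).astype(np.int64)
    counts_c = rng.poisson(lam_c).astype(np.int64)
    counts_t[binning.masked] = 0
    counts_c[binning.masked] = 0
    return counts_t, counts_c, truth


# ---------------------------------------------------------------------------
# fibre tracks and Ct tables
# ---------------------------------------------------------------------------

def simulate_fibre_tracks(n: int, true_speed_kb_min: float,
                          label_minutes: float = 40.0,
                          noise_sd_um: float = 0.0, seed: int | None = None,
                          condition: str = "sim",
                          kb_per_um: float = DEFAULT_KB_PER_UM
                          ) -> list[FibreTrack]:
    """Fibre tracks whose lengths follow speed * minutes / (kb per µm) plus
    Gaussian measurement noise, truncated at zero."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if true_speed_kb_min < 0:
        raise ValueError("true_speed_kb_min must be non-negative")
    if noise_sd_um < 0:
        raise ValueError("noise_sd_um must be non-negative")
    rng = np.random.default_rng(seed)
    base = true_speed_kb_min * label_minutes / kb_per_um
    lengths = base + rng.normal(0.0, noise_sd_um, size=n) if noise_sd_um > 0 \
        else np.full(n, base)
    lengths = np.maximum(lengths, 0.0)
    return [FibreTrack(f"{condition}_fibre_{i:05d}", float(l), condition)
            for i, l in enumerate(lengths)]


def simulate_ct_table(target_genes: list[str], conditions: list[str],
                      true_fold_changes: dict, calibrator_condition: str,
                      reference_gene: str = "GAPDH", n_replicates: int = 3,
                      noise_sd_ct: float = 0.0, baseline_ct: float = 24.0,
                      reference_ct: float = 18.0, seed: int | None = None
                      ) -> tuple[list[CtRecord], pd.DataFrame]:
    """qPCR wells with Ct = baseline − log2(expression) + noise.

    ``true_fold_changes[gene][condition]`` is that condition's expression of
    the gene relative to the calibrator condition (whose own fold must be 1).
    Every sample gets a reference-gene well. Returns the well records and a
    truth table of the planted folds.
    """
    if calibrator_condition not in conditions:
        raise ValueError(f"calibrator {calibrator_condition!r} not among conditions")
    if reference_gene in target_genes:
        raise ValueError("reference gene cannot also be a target gene")
    for gene in target_genes:
        folds = true_fold_changes.get(gene)
        if folds is None:
            raise ValueError(f"no fold changes given for gene {gene!r}")
        for cond in conditions:
            f = folds.get(cond)
            if f is None or f <= 0:
                raise ValueError(f"need a positive fold for ({gene!r}, {cond!r})")
        if not math.isclose(folds[calibrator_condition], 1.0):
            raise ValueError(f"calibrator fold for {gene!r} must be 1")
    rng = np.random.default_rng(seed)

    def noise() -> float:
        return float(rng.normal(0.0, noise_sd_ct)) if noise_sd_ct > 0 else 0.0

    records: list[CtRecord] = []
    truth_rows = []
    for cond in conditions:
        for rep in range(n_replicates):
            sample = f"{cond}_rep{rep + 1}"
            is_cal = cond == calibrator_condition
            records.append(CtRecord(sample, reference_gene,
                                    reference_ct + noise(),
                                    is_reference=True,
                                    is_calibrator_sample=is_cal))
            for gene in target_genes:
                fold = float(true_fold_changes[gene][cond])
                records.append(CtRecord(sample, gene,
                                        baseline_ct - math.log2(fold) + noise(),
                                        is_reference=False,
                                        is_calibrator_sample=is_cal))
                truth_rows.append([sample, gene, cond, fold])
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "gene", "condition",
                                              "true_fold"])
    return records, truth
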