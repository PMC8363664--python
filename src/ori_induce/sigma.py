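"""Per-bin sigma (σ) tracks from binned nascent-strand read counts.

The σ value of a bin is its read count, depth-normalised so the genome-wide
mean over unmasked bins equals ``target_mean``, then divided by one standard
deviation of those normalised counts. σ is therefore a z-like firing-intensity
score: invariant to library size, comparable between samples, with background
bins near mean/SD and origin bins standing several σ above it.

Read-to-bin assignment is by read midpoint, so every read lands in exactly one
bin and count totals are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBinning


class DegenerateTrackError(ValueError):
    """All unmasked counts equal (zero SD) or zero total — σ undefined."""


@dataclass
class BinnedReads:
    """Raw counts plus the bookkeeping needed for count conservation."""

    counts: np.ndarray
    n_reads: int
    n_discarded_score: int = 0
    n_unknown_chromosome: int = 0
    n_outside_bins: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_discarded_score + self.n_unknown_chromosome + self.n_outside_bins


@dataclass
class SigmaTrack:
    """σ values for one sample on one binning.

    ``sigma`` is NaN on masked bins. ``normalization_constant`` is the factor
    taking raw counts to depth-normalised counts; ``sd_used`` is the standard
    deviation those normalised counts were divided by (a per-chromosome dict
    when ``sd_scope='chromosome'``).
    """

    binning: GenomeBinning
    sample_id: str
    raw_counts: np.ndarray
    sigma: np.ndarray
    normalization_constant: float
    sd_used: float | dict = field(default=0.0)

    def sigma_for(self, chromosome: str) -> np.ndarray:
        return self.sigma[self.binning.chrom_slice(chromosome)]


def bin_reads(reads: pd.DataFrame, binning: GenomeBinning,
              min_score: float | None = None) -> BinnedReads:
    """Count reads per bin by midpoint.

    ``reads`` needs columns chromosome/start/end (0-based half-open) and,
    when ``min_score`` is given, a score column; reads scoring below the
    threshold are discarded, mirroring upstream base-quality filtering.
    Reads on chromosomes absent from the binning, or whose midpoint falls in
    a dropped trailing partial bin, are counted as discarded, not fatal.
    """
    n_reads = len(reads)
    counts = np.zeros(binning.n_bins_total, dtype=np.int64)
    if n_reads == 0:
        return BinnedReads(counts, 0)
    if (reads["start"].to_numpy() < 0).any():
        raise ValueError("negative start coordinate in reads")
    if (reads["start"].to_numpy() >= reads["end"].to_numpy()).any():
        raise ValueError("read interval with start >= end")

    n_score = 0
    if min_score is not None:
        if "score" not in reads.columns:
            raise ValueError("min_score given but reads have no score column")
        score = pd.to_numeric(reads["score"], errors="coerce").to_numpy(dtype=float)
        keep = score >= min_score  # NaN scores fail the comparison → discarded
        n_score = int((~keep).sum())
        reads = reads.loc[keep]

    n_unknown = 0
    n_outside = 0
    width = binning.bin_width_bp
    for chrom, sub in reads.groupby("chromosome", sort=False):
        chrom = str(chrom)
        if chrom not in binning.chromosome_names:
            n_unknown += len(sub)
            continue
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        local = mid // width
        sl = binning.chrom_slice(chrom)
        n_bins = sl.stop - sl.start
        inside = local < n_bins
        n_outside += int((~inside).sum())
        np.add.at(counts, sl.start + local[inside], 1)
    return BinnedReads(counts, n_reads, n_score, n_unknown, n_outside)


def _sigma_one_scope(counts: np.ndarray, unmasked: np.ndarray, target_mean: float,
                     sd_mode: str) -> tuple[np.ndarray, float, float]:
    """σ over one normalisation scope. Returns (sigma, scale, sd)."""
    total = float(counts[unmasked].sum())
    n_unmasked = int(unmasked.sum())
    if n_unmasked < 2:
        raise DegenerateTrackError("need at least 2 unmasked bins")
    if total <= 0:
        raise DegenerateTrackError("zero total count over unmasked bins")
    scale = target_mean * n_unmasked / total
    norm = counts * scale
    if sd_mode == "sample":
        sd = float(np.std(norm[unmasked], ddof=1))
        if sd <= 0:
            raise DegenerateTrackError("all unmasked counts equal; σ undefined")
    elif sd_mode == "poisson":
        # Poisson alternative: SD = sqrt of the mean normalised count.
        sd = float(np.sqrt(np.mean(norm[unmasked])))
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    sigma = np.full(counts.shape, np.nan)
    sigma[unmasked] = norm[unmasked] / sd
    return sigma, scale, sd


def compute_sigma(counts: np.ndarray, binning: GenomeBinning, *,
                  sample_id: str = "sample", target_mean: float = 10.0,
                  sd_mode: str = "sample", sd_scope: str = "genome") -> SigmaTrack:
    """Normalise counts to σ values.

    Counts are scaled so their mean over unmasked bins equals ``target_mean``
    (this makes σ invariant to sequencing depth), then divided by the sample
    standard deviation (denominator n−1) of the scaled counts. ``sd_scope``
    selects whether normalisation and SD are genome-wide (default) or per
    chromosome; ``sd_mode='poisson'`` swaps the empirical SD for
    sqrt(mean normalised count).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (binning.n_bins_total,):
        raise ValueError("counts must have one entry per bin")
    if (counts < 0).any():
        raise ValueError("negative counts")
    unmasked = ~binning.masked
    if sd_scope == "genome":
        sigma, scale, sd = _sigma_one_scope(counts, unmasked, target_mean, sd_mode)
        return SigmaTrack(binning, sample_id, counts, sigma, scale, sd)
    if sd_scope == "chromosome":
        sigma = np.full(counts.shape, np.nan)
        sds: dict[str, float] = {}
        scales: list[float] = []
        for name in binning.chromosome_names:
            sl = binning.chrom_slice(name)
            sub_sigma, scale, sd = _sigma_one_scope(
                counts[sl], unmasked[sl], target_mean, sd_mode)
            sigma[sl] = sub_sigma
            sds[name] = sd
            scales.append(scale)
        return SigmaTrack(binning, sample_id, counts, sigma,
                          float(np.mean(scales)), sds)
    raise ValueError(f"unknown sd_scope {sd_scope!r}")


def smooth_sigma(track: SigmaTrack, window_bins: int = 1) -> SigmaTrack:
    """Centred moving average of σ over unmasked bins, per chromosome.

    Masked bins are excluded from both numerator and denominator and stay
    NaN in the output. ``window_bins`` must be odd; 1 is the identity.
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError(f"window_bins must be odd and >= 1, got {window_bins}")
    if window_bins == 1:
        return track
    half = window_bins // 2
    out = np.full_like(track.sigma, np.nan)
    for name in track.binning.chromosome_names:
        sl = track.binning.chrom_slice(name)
        sig = track.sigma[sl]
        valid = ~np.isnan(sig)
        vals = np.where(valid, sig, 0.0)
        kernel = np.ones(window_bins)
        num = np.convolve(vals, kernel, mode="same")
        den = np.convolve(valid.astype(float), kernel, mode="same")
        sm = np.full(sig.shape, np.nan)
        ok = valid & (den > 0)
        sm[ok] = num[ok] / den[ok]
        out[sl] = sm
    return SigmaTrack(track.binning, track.sample_id, track.raw_counts, out,
                      track.normalization_constant, track.sd_used)


def average_sigma(tracks: list[SigmaTrack], sample_id: str = "mean") -> SigmaTrack:
    """Bin-wise mean σ across replicate tracks sharing one binning."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if not t.binning.same_binning(first.binning):
            raise ValueError("replicate tracks are on different binnings")
    sigma = np.mean([t.sigma for t in tracks], axis=0)
    counts = np.sum([t.raw_counts for t in tracks], axis=0)
    return SigmaTrack(first.binning, sample_id, counts, sigma,
                      float(np.mean([t.normalization_constant for t in tracks])),
                      first.sd_used)
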