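"""Genic/intergenic context of bins and origins, and gene-size enrichment.

A fixed-width bin is *genic* when every base pair of it lies inside the union
of gene spans (any strand), *intergenic* when it overlaps no gene at all, and
*mixed* otherwise. For origin-distribution summaries the mixed class collapses
into intergenic, so "genic" means wholly intragenic firing.

The gene-size question: oncogene-induced origins concentrate in long,
actively transcribed genes. ``genes_hit_by_origins`` collects the
protein-coding genes whose span overlaps an induced origin's bin, and
``gene_size_enrichment`` compares their length distribution against all
protein-coding genes with a two-sided Mann-Whitney test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBinning
from .origins import OriginCall
from .stats import MannWhitneyResult, mann_whitney

RAW_GENIC = "genic"
RAW_INTERGENIC = "intergenic"
RAW_MIXED = "mixed"


@dataclass(frozen=True)
class GeneModel:
    """One gene span, 0-based half-open, isoforms already collapsed."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class BinGeneClasses:
    """Per-bin genic context for a whole binning.

    ``raw`` holds genic/intergenic/mixed per global bin; ``collapsed_genic``
    is True only for fully-genic bins (mixed counts as intergenic).
    """

    binning: GenomeBinning
    raw: np.ndarray            # array of strings
    n_skipped_genes: int = 0

    @property
    def collapsed_genic(self) -> np.ndarray:
        return self.raw == RAW_GENIC

    def counts(self) -> dict[str, int]:
        return {cls: int((self.raw == cls).sum())
                for cls in (RAW_GENIC, RAW_INTERGENIC, RAW_MIXED)}


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted disjoint list."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def classify_bins(binning: GenomeBinning, genes: list[GeneModel]) -> BinGeneClasses:
    """Classify every bin as genic / intergenic / mixed against gene spans.

    Strand is ignored (a bin inside a gene on either strand is genic). Genes
    on chromosomes absent from the binning are skipped with a warning and
    counted in ``n_skipped_genes``. Masked bins are classified like any other
    bin; downstream code decides whether to use them.
    """
    width = binning.bin_width_bp
    covered = np.zeros(binning.n_bins_total, dtype=np.int64)  # genic bp per bin
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    n_skipped = 0
    for g in genes:
        if g.chromosome not in binning.chromosome_names:
            warnings.warn(f"gene {g.gene_id} on unknown chromosome "
                          f"{g.chromosome!r}; skipped", stacklevel=2)
            n_skipped += 1
            continue
        by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
    for chrom, ivals in by_chrom.items():
        sl = binning.chrom_slice(chrom)
        n_bins = sl.stop - sl.start
        span_end = n_bins * width
        for s, e in merge_intervals(ivals):
            s, e = max(0, s), min(e, span_end)
            if s >= e:
                continue
            first, last = s // width, (e - 1) // width
            if first == last:
                covered[sl.start + first] += e - s
                continue
            covered[sl.start + first] += (first + 1) * width - s
            covered[sl.start + last] += e - last * width
            if last - first > 1:
                covered[sl.start + first + 1: sl.start + last] += width
    raw = np.where(covered == width, RAW_GENIC,
                   np.where(covered == 0, RAW_INTERGENIC, RAW_MIXED))
    return BinGeneClasses(binning, raw.astype(object), n_skipped)


def _filter_calls(calls: list[OriginCall], class_filter) -> list[OriginCall]:
    if class_filter is None:
        return list(calls)
    if callable(class_filter):
        return [c for c in calls if class_filter(c)]
    allowed = set(class_filter) if not isinstance(class_filter, str) else {class_filter}
    return [c for c in calls if c.origin_class in allowed]


@dataclass(frozen=True)
class GenicFraction:
    n_genic: int
    n_total: int

    @property
    def undefined(self) -> bool:
        return self.n_total == 0

    @property
    def percent(self) -> float:
        if self.undefined:
            return float("nan")
        return 100.0 * self.n_genic / self.n_total


def genic_fraction(calls: list[OriginCall], bin_classes: BinGeneClasses,
                   class_filter=None) -> GenicFraction:
    """Percentage of (filtered) origins whose bin is fully genic.

    ``class_filter`` may be None (all calls), a class name or collection of
    class names, or a predicate over :class:`OriginCall`. An empty filter
    result gives an undefined (NaN) fraction rather than an error.
    """
    selected = _filter_calls(calls, class_filter)
    genic = bin_classes.collapsed_genic
    n_genic = sum(
        1 for c in selected
        if genic[bin_classes.binning.global_index(c.chromosome, c.bin_index)]
    )
    return GenicFraction(n_genic, len(selected))


def genes_hit_by_origins(calls: list[OriginCall], genes: list[GeneModel],
                         class_filter=None, *, bin_width_bp: int | None = None,
                         require_containment: bool = False) -> list[GeneModel]:
    """Protein-coding genes whose span overlaps a (filtered) origin's bin.

    Overlap means >= 1 bp between the origin's bin and the gene span; with
    ``require_containment`` the bin must lie entirely within the gene.
    ``bin_width_bp`` defaults to the span implied by the calls' positions
    (bin start to start + width); pass it explicitly when calls are synthetic.
    """
    selected = _filter_calls(calls, class_filter)
    out: list[GeneModel] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in selected:
        width = bin_width_bp
        if width is None:
            raise ValueError("bin_width_bp is required")
        by_chrom.setdefault(c.chromosome, []).append(
            (c.position_bp, c.position_bp + width))
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        for s, e in by_chrom.get(g.chromosome, ()):
            if require_containment:
                hit = g.start <= s and e <= g.end
            else:
                hit = s < g.end and g.start < e
            if hit:
                out.append(g)
                break
    return out


@dataclass(frozen=True)
class GeneSizeEnrichment:
    mean_hit_bp: float
    mean_all_bp: float
    n_hit: int
    n_all: int
    test: MannWhitneyResult

    @property
    def u_statistic(self) -> float:
        return self.test.statistic

    @property
    def pvalue(self) -> float:
        return self.test.pvalue


def gene_size_enrichment(hit_genes: list[GeneModel],
                         all_genes: list[GeneModel]) -> GeneSizeEnrichment:
    """Compare gene-length distributions of hit genes vs all genes.

    Returns the two set means (the "dotted lines" of a size-frequency plot)
    and a two-sided Mann-Whitney U test of the hit-gene lengths against the
    full gene set's lengths.
    """
    if not hit_genes or not all_genes:
        raise ValueError("both gene sets must be non-empty")
    hit = np.array([g.length_bp for g in hit_genes], dtype=float)
    ref = np.array([g.length_bp for g in all_genes], dtype=float)
    return GeneSizeEnrichment(float(hit.mean()), float(ref.mean()),
                              len(hit), len(ref), mann_whitney(hit, ref))
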