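"""Origin calling and treated:control ratio classification.

Replication origins are per-chromosome local maxima of the σ track of the
treated (oncogene-activated) sample. Each called origin is then classified
from the ratio of its treated to control σ value:

* ratio > 4          → ``induced_4x``  (strong oncogene-induced firing, 4:1)
* 2 < ratio <= 4     → ``induced_2x``  (moderate induction, 2:1)
* otherwise          → ``constitutive`` (fires comparably in both conditions)

A ratio of exactly 4 falls in the 2:1 class and exactly 2 is constitutive
(the induced thresholds are strict lower bounds). The denominator is floored
at ``control_floor`` so origins with essentially no control signal get a
finite, large ratio instead of a division blow-up — this is the package's
"adjusted" ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sigma import SigmaTrack

CLASS_CONSTITUTIVE = "constitutive"
CLASS_INDUCED_2X = "induced_2x"
CLASS_INDUCED_4X = "induced_4x"
ORIGIN_CLASSES = (CLASS_CONSTITUTIVE, CLASS_INDUCED_2X, CLASS_INDUCED_4X)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds for peak calling and ratio classification."""

    min_sigma: float = 3.0
    ratio_lo: float = 2.0
    ratio_hi: float = 4.0
    control_floor: float = 1.0
    merge_distance_bins: int = 2
    match_tolerance_bins: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.ratio_lo < self.ratio_hi:
            raise ValueError("need 0 < ratio_lo < ratio_hi")
        if self.control_floor <= 0:
            raise ValueError("control_floor must be positive")
        if self.merge_distance_bins < 0 or self.match_tolerance_bins < 0:
            raise ValueError("distances must be non-negative")

    def classify_ratio(self, ratio: float) -> str:
        if ratio > self.ratio_hi:
            return CLASS_INDUCED_4X
        if ratio > self.ratio_lo:
            return CLASS_INDUCED_2X
        return CLASS_CONSTITUTIVE


@dataclass(frozen=True)
class OriginCall:
    chromosome: str
    bin_index: int          # local bin within the chromosome
    position_bp: int        # bin start
    sigma_treated: float
    sigma_control: float
    ratio: float
    origin_class: str

    @property
    def induced(self) -> bool:
        return self.origin_class != CLASS_CONSTITUTIVE


def _peaks_one_chromosome(sigma: np.ndarray, min_sigma: float,
                          merge_distance: int) -> list[int]:
    """Local-maxima scan of one chromosome's σ values (NaN = masked).

    Masked bins are invisible: each unmasked bin is compared against its
    nearest unmasked neighbours. A plateau (maximal run of equal σ) higher
    than both flanking values yields its leftmost bin. Candidates closer than
    ``merge_distance`` bins are merged keeping the higher-σ bin (ties →
    leftmost).
    """
    valid = np.flatnonzero(~np.isnan(sigma))
    if valid.size == 0:
        return []
    vals = sigma[valid]
    candidates: list[int] = []
    i = 0
    n = vals.size
    while i < n:
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        higher_left = i == 0 or vals[i - 1] < vals[i]
        higher_right = j == n - 1 or vals[j + 1] < vals[i]
        if higher_left and higher_right and vals[i] >= min_sigma:
            candidates.append(int(valid[i]))  # leftmost bin of the run
        i = j + 1
    if merge_distance <= 1 or len(candidates) < 2:
        return candidates
    merged: list[int] = []
    group = [candidates[0]]
    for b in candidates[1:]:
        if b - group[-1] < merge_distance:
            group.append(b)
        else:
            merged.append(_best_of(group, sigma))
            group = [b]
    merged.append(_best_of(group, sigma))
    return merged


def _best_of(group: list[int], sigma: np.ndarray) -> int:
    best = group[0]
    for b in group[1:]:
        if sigma[b] > sigma[best]:  # ties keep the leftmost (earlier) bin
            best = b
    return best


def find_peaks(track: SigmaTrack, config: ClassifierConfig | None = None
               ) -> list[tuple[str, int]]:
    """Candidate origin bins: ``(chromosome, local_bin)`` per local σ maximum.

    Peaks never span chromosomes; chromosome-edge bins are compared against
    their single neighbour.
    """
    config = config or ClassifierConfig()
    peaks: list[tuple[str, int]] = []
    for name in track.binning.chromosome_names:
        sig = track.sigma_for(name)
        for b in _peaks_one_chromosome(sig, config.min_sigma,
                                       config.merge_distance_bins):
            peaks.append((name, b))
    return peaks


def classify_origins(peaks: list[tuple[str, int]], treated: SigmaTrack,
                     control: SigmaTrack, config: ClassifierConfig | None = None
                     ) -> list[OriginCall]:
    """Attach control σ, adjusted ratio and class to each peak bin."""
    config = config or ClassifierConfig()
    if not treated.binning.same_binning(control.binning):
        raise ValueError("treated and control tracks are on different binnings")
    width = treated.binning.bin_width_bp
    calls: list[OriginCall] = []
    for chrom, b in peaks:
        g = treated.binning.global_index(chrom, b)
        s_t = float(treated.sigma[g])
        s_c = float(control.sigma[g])
        if np.isnan(s_c):
            s_c = 0.0
        ratio = s_t / max(s_c, config.control_floor)
        calls.append(OriginCall(
            chromosome=chrom, bin_index=b, position_bp=b * width,
            sigma_treated=s_t, sigma_control=s_c, ratio=ratio,
            origin_class=config.classify_ratio(ratio),
        ))
    return calls


def match_origins(calls_a: list[OriginCall], calls_b: list[OriginCall],
                  tolerance_bins: int = 1) -> pd.DataFrame:
    """Greedy nearest-bin pairing of two call sets on one binning.

    Candidate pairs on the same chromosome within ``tolerance_bins`` are taken
    closest-first (ties broken by bin of the first then second set, making the
    result deterministic and symmetric up to that tie-break); each origin
    matches at most once. Unmatched origins appear as rows with NaN on the
    other side.
    """
    pairs = []
    for ia, a in enumerate(calls_a):
        for ib, b in enumerate(calls_b):
            if a.chromosome == b.chromosome and abs(a.bin_index - b.bin_index) <= tolerance_bins:
                pairs.append((abs(a.bin_index - b.bin_index),
                              a.chromosome, a.bin_index, b.bin_index, ia, ib))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    rows = []
    for delta, chrom, bin_a, bin_b, ia, ib in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        a, b = calls_a[ia], calls_b[ib]
        rows.append(dict(chromosome=chrom, bin_a=bin_a, bin_b=bin_b,
                         delta_bin=delta, sigma_a=a.sigma_treated,
                         sigma_b=b.sigma_treated, class_a=a.origin_class,
                         class_b=b.origin_class, matched=True))
    for ia, a in enumerate(calls_a):
        if ia not in used_a:
            rows.append(dict(chromosome=a.chromosome, bin_a=a.bin_index,
                             bin_b=np.nan, delta_bin=np.nan,
                             sigma_a=a.sigma_treated, sigma_b=np.nan,
                             class_a=a.origin_class, class_b=None, matched=False))
    for ib, b in enumerate(calls_b):
        if ib not in used_b:
            rows.append(dict(chromosome=b.chromosome, bin_a=np.nan,
                             bin_b=b.bin_index, delta_bin=np.nan,
                             sigma_a=np.nan, sigma_b=b.sigma_treated,
                             class_a=None, class_b=b.origin_class, matched=False))
    return pd.DataFrame(rows, columns=["chromosome", "bin_a", "bin_b", "delta_bin",
                                       "sigma_a", "sigma_b", "class_a", "class_b",
                                       "matched"])


@dataclass(frozen=True)
class OriginSummary:
    n_constitutive: int
    n_induced_2x: int
    n_induced_4x: int

    @property
    def total(self) -> int:
        return self.n_constitutive + self.n_induced_2x + self.n_induced_4x

    @property
    def n_induced(self) -> int:
        return self.n_induced_2x + self.n_induced_4x

    @property
    def induced_fraction_percent(self) -> float:
        """100 · induced / total; NaN (undefined) when there are no calls."""
        if self.total == 0:
            return float("nan")
        return 100.0 * self.n_induced / self.total


def summarize_origins(calls: list[OriginCall]) -> OriginSummary:
    counts = {c: 0 for c in ORIGIN_CLASSES}
    for call in calls:
        counts[call.origin_class] += 1
    return OriginSummary(counts[CLASS_CONSTITUTIVE], counts[CLASS_INDUCED_2X],
                         counts[CLASS_INDUCED_4X])


def calls_to_frame(calls: list[OriginCall], bin_width_bp: int) -> pd.DataFrame:
    """BED6+ layout: chrom, start, end, origin id, σ_treated, strand, extras."""
    rows = []
    for i, c in enumerate(calls):
        rows.append(dict(chromosome=c.chromosome, start=c.position_bp,
                         end=c.position_bp + bin_width_bp,
                         name=f"origin_{i:05d}", score=round(c.sigma_treated, 4),
                         strand=".", sigma_control=round(c.sigma_control, 4),
                         ratio=round(c.ratio, 4), origin_class=c.origin_class))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "name",
                                       "score", "strand", "sigma_control",
                                       "ratio", "origin_class"])
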