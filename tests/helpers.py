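"""Shared test utilities (imported as a plain module, not via conftest)."""

import numpy as np

from ori_induce import GenomeBinning, SigmaTrack


def make_track(sigma_values, masked=None, chrom_name="chr1",
               bin_width=10_000) -> SigmaTrack:
    """Build a SigmaTrack directly from σ values for peak-caller tests."""
    sigma = np.asarray(sigma_values, dtype=float)
    n = sigma.size
    mask = np.zeros(n, dtype=bool) if masked is None else np.asarray(masked, bool)
    binning = GenomeBinning([(chrom_name, n * bin_width)], bin_width, masked=mask)
    sigma = sigma.copy()
    sigma[mask] = np.nan
    return SigmaTrack(binning, "test", np.zeros(n), sigma, 1.0, 1.0)


def brute_force_peaks(sigma, min_sigma):
    """Independent exhaustive local-maximum scan (no merging).

    For every unmasked bin, compare against the nearest unmasked neighbour on
    each side; plateaus keep their leftmost bin.
    """
    valid = [i for i, v in enumerate(sigma) if not np.isnan(v)]
    peaks = []
    for k, i in enumerate(valid):
        v = sigma[i]
        if v < min_sigma:
            continue
        # walk left past equal values to find the plateau's left flank
        j = k
        while j - 1 >= 0 and sigma[valid[j - 1]] == v:
            j -= 1
        if j != k:
            continue  # not the leftmost bin of its plateau
        left_ok = j == 0 or sigma[valid[j - 1]] < v
        m = k
        while m + 1 < len(valid) and sigma[valid[m + 1]] == v:
            m += 1
        right_ok = m == len(valid) - 1 or sigma[valid[m + 1]] < v
        if left_ok and right_ok:
            peaks.append(i)
    return peaks


def match_calls_to_truth(calls, truth, tolerance_bins=1):
    """Pair planted origins with the closest call within tolerance.

    Returns (n_recovered, n_correct_class) against the truth table.
    """
    by_chrom = {}
    for call in calls:
        by_chrom.setdefault(call.chromosome, []).append(call)
    n_rec = n_correct = 0
    for row in truth.itertuples(index=False):
        best = None
        for call in by_chrom.get(row.chromosome, []):
            if abs(call.bin_index - row.bin_index) <= tolerance_bins:
                if best is None or call.sigma_treated > best.sigma_treated:
                    best = call
        if best is not None:
            n_rec += 1
            n_correct += best.origin_class == row.true_class
    return n_rec, n_correct
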