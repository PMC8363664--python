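"""Truth-matching helper for the acceptance script."""


def match_calls_to_truth(calls, truth, tolerance_bins=1):
    """Pair each planted origin with the closest call within tolerance;
    return (n_recovered, n_correct_class)."""
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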