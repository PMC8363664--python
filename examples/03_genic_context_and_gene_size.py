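"""Where do induced origins fire: genic context and gene-size bias.

Runs a synthetic experiment whose induced origins are placed uniformly per
base pair, classifies every 10-kb bin as genic / intergenic / mixed against
the annotation, reports the genic fraction of the induced origins, and asks
whether the protein-coding genes they hit are longer than average
(two-sided Mann-Whitney on gene lengths).
"""

import ori_induce as oi

cfg = oi.SimulationConfig(seed=23, n_constitutive_origins=30,
                          n_induced_origins=200, n_genes=2_000,
                          gene_length_log_mean=9.2)
binning, genes = oi.simulate_genome(cfg)
counts_t, counts_c, truth = oi.simulate_eduseq_counts(cfg, binning, genes)

treated = oi.compute_sigma(counts_t, binning)
control = oi.compute_sigma(counts_c, binning)
calls = oi.classify_origins(oi.find_peaks(treated), treated, control)

bin_classes = oi.classify_bins(binning, genes)
print("bin classes     :", bin_classes.counts())

induced = ("induced_2x", "induced_4x")
frac = oi.genic_fraction(calls, bin_classes, class_filter=induced)
print(f"genic fraction of induced origins: {frac.percent:.1f}% "
      f"({frac.n_genic}/{frac.n_total})")

hit = oi.genes_hit_by_origins(calls, genes, class_filter=induced,
                              bin_width_bp=binning.bin_width_bp)
enr = oi.gene_size_enrichment(hit, genes)
print(f"hit genes       : {enr.n_hit} of {enr.n_all}")
print(f"mean length     : hit {enr.mean_hit_bp / 1e3:.1f} kb vs "
      f"all {enr.mean_all_bp / 1e3:.1f} kb")
print(f"Mann-Whitney    : U = {enr.u_statistic:.0f}, "
      f"two-sided p = {enr.pvalue:.2e}")

# Even with purely uniform placement, long genes cover more base pairs and
# so are hit more often: the hit-gene mean length exceeds the genome-wide
# mean and the rank test is significant — the length bias that intragenic
# origin analyses must account for.
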