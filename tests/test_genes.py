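"""Genic/intergenic bin classification and gene-size enrichment."""

import itertools

import numpy as np
import pytest
from helpers import make_track
from hypothesis import given, settings
from hypothesis import strategies as st

from ori_induce import (GeneModel, GenomeBinning, OriginCall, classify_bins,
                        gene_size_enrichment, genes_hit_by_origins,
                        genic_fraction, mann_whitney)


def gene(gid, start, end, chrom="chr1", biotype="protein_coding"):
    return GeneModel(gid, chrom, start, end, "+", biotype)


def origin(b, cls="induced_4x", chrom="chr1", width=10_000):
    return OriginCall(chrom, b, b * width, 8.0, 1.0, 8.0, cls)


def brute_force_bin_classes(binning, genes):
    """Per-bp membership scan: the independent oracle for classify_bins."""
    out = []
    for name, _ in binning.chromosomes:
        sl = binning.chrom_slice(name)
        n = sl.stop - sl.start
        w = binning.bin_width_bp
        covered = np.zeros(n * w, dtype=bool)
        for g in genes:
            if g.chromosome == name:
                covered[max(0, g.start):min(n * w, g.end)] = True
        for b in range(n):
            frac = covered[b * w:(b + 1) * w].sum()
            out.append("genic" if frac == w else
                       "intergenic" if frac == 0 else "mixed")
    return np.array(out, dtype=object)


class TestClassifyBins:
    def test_containment_overlap_and_mixed_rules(self, small_binning):
        genes = [gene("g1", 10_000, 45_000)]
        bc = classify_bins(small_binning, genes)
        assert bc.raw[2] == "genic"        # [20k,30k) entirely inside the gene
        assert bc.raw[5] == "intergenic"   # [50k,60k) no overlap
        assert bc.raw[4] == "mixed"        # [40k,50k) straddles the gene end
        assert not bc.collapsed_genic[4]   # mixed collapses to intergenic

    def test_partition_counts_sum_to_total(self, small_binning):
        genes = [gene("g1", 10_000, 45_000), gene("g2", 70_000, 71_000)]
        bc = classify_bins(small_binning, genes)
        assert sum(bc.counts().values()) == small_binning.n_bins_total

    def test_overlapping_genes_are_unioned(self, small_binning):
        # two genes together tile [10k, 30k): bins 1 and 2 fully genic
        genes = [gene("g1", 10_000, 22_000), gene("g2", 18_000, 30_000)]
        bc = classify_bins(small_binning, genes)
        assert bc.raw[1] == "genic" and bc.raw[2] == "genic"

    def test_unknown_chromosome_gene_warned_and_skipped(self, small_binning):
        with pytest.warns(UserWarning, match="unknown chromosome"):
            bc = classify_bins(small_binning, [gene("g1", 0, 5_000, chrom="chr9")])
        assert bc.n_skipped_genes == 1
        assert (bc.raw == "intergenic").all()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_matches_per_bp_oracle_on_random_annotations(self, seed):
        rng = np.random.default_rng(seed)
        binning = GenomeBinning([("chr1", 500_000), ("chr2", 500_000)], 10_000)
        genes = []
        for i in range(50):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            start = int(rng.integers(0, 490_000))
            length = int(rng.integers(1, 60_000))
            genes.append(gene(f"g{i}", start, min(start + length, 500_000),
                              chrom=chrom))
        bc = classify_bins(binning, genes)
        np.testing.assert_array_equal(bc.raw, brute_force_bin_classes(binning, genes))


class TestGenicFraction:
    def test_all_origins_in_genic_bins(self, small_binning):
        bc = classify_bins(small_binning, [gene("g1", 0, 100_000)])
        frac = genic_fraction([origin(2), origin(5)], bc)
        assert frac.percent == 100.0

    def test_two_of_four_induced_in_genic_bins(self, small_binning):
        bc = classify_bins(small_binning, [gene("g1", 0, 20_000)])
        calls = [origin(0), origin(1), origin(5), origin(7)]
        frac = genic_fraction(calls, bc, class_filter=("induced_2x", "induced_4x"))
        assert frac.percent == 50.0

    def test_empty_filter_result_is_undefined_not_fatal(self, small_binning):
        bc = classify_bins(small_binning, [])
        frac = genic_fraction([origin(1, cls="constitutive")], bc,
                              class_filter="induced_4x")
        assert frac.undefined and np.isnan(frac.percent)


class TestGenesHit:
    def test_origin_bin_inside_gene_hits_it(self, small_binning):
        genes = [gene("g1", 5_000, 35_000)]
        hit = genes_hit_by_origins([origin(1)], genes, bin_width_bp=10_000)
        assert [g.gene_id for g in hit] == ["g1"]

    def test_one_bp_overlap_suffices(self):
        genes = [gene("g1", 19_999, 30_000)]
        hit = genes_hit_by_origins([origin(1)], genes, bin_width_bp=10_000)
        assert [g.gene_id for g in hit] == ["g1"]
        # but containment mode rejects the same configuration
        assert genes_hit_by_origins([origin(1)], genes, bin_width_bp=10_000,
                                    require_containment=True) == []

    def test_non_coding_genes_excluded(self):
        genes = [gene("g1", 5_000, 35_000, biotype="lncRNA")]
        assert genes_hit_by_origins([origin(1)], genes, bin_width_bp=10_000) == []

    def test_no_induced_calls_gives_empty_set(self):
        genes = [gene("g1", 5_000, 35_000)]
        calls = [origin(1, cls="constitutive")]
        assert genes_hit_by_origins(calls, genes, bin_width_bp=10_000,
                                    class_filter=("induced_2x", "induced_4x")) == []


def enumeration_mann_whitney(x, y):
    """Oracle: full enumeration of sample assignments with midrank ties."""
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_of(idx_set):
        a = pooled[list(idx_set)]
        b = pooled[[i for i in range(len(pooled)) if i not in idx_set]]
        return sum(1.0 if ai > bi else 0.5 if ai == bi else 0.0
                   for ai in a for bi in b)

    u_obs = u_of(tuple(range(nx)))
    us = np.array([u_of(c) for c in
                   itertools.combinations(range(len(pooled)), nx)])
    p = min(1.0, 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean()))
    return u_obs, p


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1 / 3, abs=1e-12)
        assert res.method == "exact"

    def test_identical_samples_give_p_one(self):
        res = mann_whitney([5, 6, 7], [5, 6, 7])
        assert res.pvalue == 1.0

    @pytest.mark.parametrize("x,y", [
        ([1, 2, 2], [2, 3, 4]),
        ([1, 1, 2, 2], [1, 2, 2, 3]),
        ([1, 3, 5, 7], [2, 4, 6, 8]),
        ([10.5], [1, 2, 3]),
    ])
    def test_exact_path_matches_enumeration_oracle(self, x, y):
        res = mann_whitney(x, y)
        u, p = enumeration_mann_whitney(np.array(x, float), np.array(y, float))
        assert res.statistic == pytest.approx(u)
        assert res.pvalue == pytest.approx(p, abs=1e-12)

    def test_large_samples_use_tie_corrected_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 10, 50).astype(float)
        y = rng.integers(2, 12, 60).astype(float)
        res = mann_whitney(x, y)
        assert res.method == "asymptotic" and 0 < res.pvalue < 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestGeneSizeEnrichment:
    def test_identical_sets_give_p_one(self):
        genes = [gene(f"g{i}", i * 1000, i * 1000 + 500 + i) for i in range(1, 6)]
        enr = gene_size_enrichment(genes, genes)
        assert enr.pvalue == 1.0
        assert enr.mean_hit_bp == enr.mean_all_bp

    def test_means_reported_for_both_sets(self):
        hit = [gene("a", 0, 30_000), gene("b", 40_000, 50_000)]
        ref = hit + [gene("c", 60_000, 62_000), gene("d", 70_000, 74_000)]
        enr = gene_size_enrichment(hit, ref)
        assert enr.mean_hit_bp == pytest.approx(20_000)
        assert enr.mean_all_bp == pytest.approx((30_000 + 10_000 + 2_000 + 4_000) / 4)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            gene_size_enrichment([], [gene("a", 0, 1000)])


class TestLengthBiasProperty:
    def test_hit_probability_nondecreasing_in_gene_length(self):
        """Origins placed uniformly per bp hit long genes more often."""
        from scipy.stats import spearmanr

        from ori_induce import (SimulationConfig, simulate_eduseq_counts,
                                simulate_genome)
        cfg = SimulationConfig(seed=11, n_constitutive_origins=0,
                               n_induced_origins=150, n_genes=400,
                               gene_length_log_mean=9.5, induced_genic_bias=None)
        binning, genes = simulate_genome(cfg)
        _, _, truth = simulate_eduseq_counts(cfg, binning, genes)
        hit_ids = set(truth["gene_id"].dropna())
        lengths = np.array([g.length_bp for g in genes])
        hits = np.array([g.gene_id in hit_ids for g in genes], dtype=float)
        rho, p = spearmanr(lengths, hits)
        assert rho > 0 and p < 0.01
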