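"""Population and pooled-sequencing simulator behaviour."""

import numpy as np
import pytest
from scipy import stats

from bsamap import popsim
from bsamap.genome import Chromosome, GenomeModel


class TestSimulateEmsVariants:
    def test_causal_only(self, small_genome):
        vs = popsim.simulate_ems_variants(
            small_genome, 0, ("chrA", 2_751_259, "G", "T"), seed=1
        )
        assert len(vs) == 1
        assert vs.causal.pos == 2_751_259 and vs.causal.is_causal

    def test_count_order_and_determinism(self, small_genome):
        vs1 = popsim.simulate_ems_variants(
            small_genome, 500, ("chrA", 100, "G", "T"), seed=7
        )
        vs2 = popsim.simulate_ems_variants(
            small_genome, 500, ("chrA", 100, "G", "T"), seed=7
        )
        assert len(vs1) == 501
        assert vs1.variants == vs2.variants
        for chrom in vs1.chroms:
            _, pos = vs1.chrom_index(chrom)
            assert (np.diff(pos) > 0).all()

    def test_causal_out_of_range(self, small_genome):
        with pytest.raises(ValueError, match="outside chromosome"):
            popsim.simulate_ems_variants(
                small_genome, 0, ("chrA", 10_000_001, "G", "T"), seed=1
            )

    @pytest.mark.parametrize(
        "variants",
        [
            [popsim.Variant("c", 1, "G", "T", True), popsim.Variant("c", 1, "G", "A")],
            [popsim.Variant("c", 1, "G", "T", True), popsim.Variant("c", 2, "A", "A")],
            [popsim.Variant("c", 1, "G", "T"), popsim.Variant("c", 2, "G", "A")],
        ],
        ids=["duplicate-position", "ref-equals-alt", "no-causal"],
    )
    def test_invalid_sets_rejected(self, variants):
        with pytest.raises(ValueError):
            popsim.EmsVariantSet(variants)


class TestMakeBc1f2:
    def test_zero_genetic_length_gives_whole_chromosome_segments(self, small_genome):
        vs = popsim.simulate_ems_variants(small_genome, 5, ("chrC", 1000, "G", "T"), seed=3)
        genome0 = GenomeModel(
            tuple(Chromosome(c.name, c.length_bp, 0.0) for c in small_genome.chromosomes)
        )
        pop = popsim.make_bc1f2(vs, 20, genome0, seed=4)
        for ind in pop:
            for pair in ind.haplotypes.values():
                for hap in pair:
                    assert len(hap.ends) == 1

    def test_recessive_segregation_and_genotype_ratio(self, small_genome):
        vs = popsim.simulate_ems_variants(small_genome, 0, ("chrA", 2_000_000, "G", "T"), seed=5)
        pop = popsim.make_bc1f2(vs, 4000, small_genome, seed=6)
        frac = np.mean([i.phenotype == popsim.MUTANT_PHENOTYPE for i in pop])
        assert abs(frac - 0.25) < 0.03  # Monte-Carlo band at n=4000
        geno = [i.genotype_at("chrA", 2_000_000) for i in pop]
        counts = [geno.count(2), geno.count(1), geno.count(0)]
        _, p = stats.chisquare(counts, f_exp=[1000, 2000, 1000])
        assert p > 1e-3
        # phenotype is consistent with the causal genotype at full penetrance
        assert all(
            (i.phenotype == popsim.MUTANT_PHENOTYPE) == (g == 2)
            for i, g in zip(pop, geno)
        )

    def test_mendelian_ratio_stable_across_seeds(self, small_genome):
        # scaled replicate check of 1:2:1 convergence: chi-square GOF should
        # be non-significant at alpha=0.01 in nearly all replicates
        vs = popsim.simulate_ems_variants(small_genome, 0, ("chrB", 4_000_000, "C", "A"), seed=8)
        passes = 0
        for seed in range(10):
            pop = popsim.make_bc1f2(vs, 2000, small_genome, seed=seed)
            geno = [i.genotype_at("chrB", 4_000_000) for i in pop]
            counts = [geno.count(2), geno.count(1), geno.count(0)]
            _, p = stats.chisquare(counts, f_exp=[500, 1000, 500])
            passes += p > 0.01
        assert passes >= 9

    def test_partial_penetrance(self, small_genome):
        vs = popsim.simulate_ems_variants(small_genome, 0, ("chrA", 2_000_000, "G", "T"), seed=5)
        pop = popsim.make_bc1f2(vs, 4000, small_genome, seed=9, penetrance=0.5)
        frac = np.mean([i.phenotype == popsim.MUTANT_PHENOTYPE for i in pop])
        assert abs(frac - 0.125) < 0.03


class TestSelectBulks:
    def test_disjoint_bulks(self, small_pop):
        mut, wt = popsim.select_bulks(small_pop, 20, seed=1)
        assert len(mut) == len(wt) == 20
        assert all(i.phenotype == popsim.MUTANT_PHENOTYPE for i in mut)
        assert all(i.phenotype == popsim.WT_LIKE for i in wt)
        assert not set(map(id, mut)) & set(map(id, wt))

    def test_zero_bulk_size(self, small_pop):
        mut, wt = popsim.select_bulks(small_pop, 0, seed=1)
        assert mut == [] and wt == []

    def test_insufficient_class_named_in_error(self, small_pop):
        wt_only = [i for i in small_pop if i.phenotype == popsim.WT_LIKE]
        with pytest.raises(ValueError, match="mutant_bulk"):
            popsim.select_bulks(wt_only, 5, seed=1)


class TestPooledReads:
    def test_all_homozygous_bulk_error_free_gives_af_one(self, small_genome, small_variants, small_pop):
        causal = small_variants.causal
        homs = [i for i in small_pop if i.genotype_at(causal.chrom, causal.pos) == 2][:10]
        counts = popsim.simulate_pooled_reads(homs, small_variants, 30.0, 0.0, seed=2)
        ci = [i for i, v in enumerate(small_variants) if v.is_causal][0]
        assert counts.alt_count[ci] == counts.depth[ci]

    def test_unselected_bulk_mean_af_near_half(self, small_variants, small_pop):
        counts = popsim.simulate_pooled_reads(small_pop[:100], small_variants, 40.0, 0.0, seed=3)
        keep = counts.depth > 0
        af = counts.alt_count[keep] / counts.depth[keep]
        assert abs(af.mean() - 0.5) < 0.05

    def test_empty_bulk_rejected(self, small_variants):
        with pytest.raises(ValueError, match="empty"):
            popsim.simulate_pooled_reads([], small_variants, 30.0, 0.0, seed=1)

    def test_sampler_matches_binomial_oracle(self):
        # On a zero-recombination chromosome every site shares one carrier
        # pattern, so pooled draws across sites are iid; they must agree in
        # distribution with depth ~ Poisson, alt ~ Binomial(depth, p') where
        # p' is the error-adjusted true allele fraction.
        genome = GenomeModel((Chromosome("chr0", 5_000_000, 0.0),))
        rng = np.random.default_rng(77)
        positions = rng.choice(np.arange(2, 5_000_000), size=4000, replace=False)
        variants = popsim.EmsVariantSet(
            [popsim.Variant("chr0", 1, "G", "T", True)]
            + [popsim.Variant("chr0", int(p), "G", "A") for p in positions]
        )
        pop = popsim.make_bc1f2(variants, 20, genome, seed=13)
        bulk = pop[:20]
        p_true = np.mean([i.genotype_at("chr0", 1) for i in bulk]) / 2
        error = 0.002
        counts = popsim.simulate_pooled_reads(bulk, variants, 32.0, error, seed=14)
        p_adj = p_true * (1 - error) + (1 - p_true) * error
        oracle_depth = rng.poisson(32.0, size=len(variants))
        oracle_alt = rng.binomial(oracle_depth, p_adj)
        _, p = stats.ks_2samp(counts.alt_count, oracle_alt)
        assert p > 0.01


class TestIntrogressionBlock:
    def _counts(self, small_variants, small_pop):
        mut, wt = popsim.select_bulks(small_pop, 20, seed=5)
        return (
            popsim.simulate_pooled_reads(wt, small_variants, 32.0, 0.002, seed=6, label="wt_like_bulk"),
            popsim.simulate_pooled_reads(mut, small_variants, 32.0, 0.002, seed=7, label="mutant_bulk"),
        )

    def test_block_raises_af_in_both_bulks(self, small_genome, small_variants, small_pop):
        counts = self._counts(small_variants, small_pop)
        interval = ("chrB", 1, 8_000_000)
        out = popsim.inject_introgression_block(
            small_variants, counts, interval, 1.0, seed=8, genome=small_genome
        )
        idx, _ = small_variants.chrom_index("chrB")
        for bc in out:
            inside = bc.depth[idx] > 0
            assert (bc.alt_count[idx][inside] == bc.depth[idx][inside]).all()

    def test_empty_interval_is_noop(self, small_genome, small_variants, small_pop):
        counts = self._counts(small_variants, small_pop)
        out = popsim.inject_introgression_block(
            small_variants, counts, ("chrB", 100, 50), 1.0, seed=8, genome=small_genome
        )
        for bc_in, bc_out in zip(counts, out):
            assert (bc_in.alt_count == bc_out.alt_count).all()

    def test_unknown_chromosome_rejected(self, small_genome, small_variants, small_pop):
        counts = self._counts(small_variants, small_pop)
        with pytest.raises(ValueError, match="not in the simulated genome"):
            popsim.inject_introgression_block(
                small_variants, counts, ("chrZ", 1, 10), 1.0, genome=small_genome
            )
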