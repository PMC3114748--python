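import numpy as np
import pytest
from scipy import stats

from ffg import synthetic_cross as sc


class TestSimulateGenome:
    def test_panel_matches_genome_and_density(self):
        genome, panel = sc.simulate_genome(1, [1_000_000], 1e-3, 0.0, seed=1)
        # direct recount of the emitted panel against the emitted sequence
        seq = genome.sequence("chr1")
        for rec in panel:
            assert seq[rec.pos].upper() == rec.ref_allele.upper()
            assert rec.ref_allele.upper() != rec.map_allele.upper()
        assert 850 <= len(panel) <= 1150  # ~Binomial(1e6, 1e-3)

    def test_masked_bases_excluded(self):
        genome, panel = sc.simulate_genome(1, [300_000], 2e-3, 0.4, seed=2)
        seq = genome.sequence("chr1")
        assert any(b.islower() for b in seq)
        for rec in panel:
            assert not seq[rec.pos].islower()

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            sc.simulate_genome(1, [100_000], 0.0, 0.0, seed=1)

    def test_too_sparse_rejected(self):
        # < 2 x bin_size expected SNPs per chromosome
        with pytest.raises(ValueError, match="mapping would be impossible"):
            sc.simulate_genome(1, [100_000], 1e-4, 0.0, seed=1)

    def test_zero_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            sc.simulate_genome(0, [], 1e-3, 0.0, seed=1)

    def test_deterministic(self):
        a = sc.simulate_genome(2, [80_000, 100_000], 1e-3, 0.2, seed=7)
        b = sc.simulate_genome(2, [80_000, 100_000], 1e-3, 0.2, seed=7)
        assert a[0].chromosomes == b[0].chromosomes
        assert a[1].records == b[1].records


class TestApplyEms:
    def test_mean_burden(self):
        # 1 Mb at 1/100kb -> lambda 10; mean over replicates close to 10
        genome, _ = sc.simulate_genome(1, [1_000_000], 1e-3, 0.0, seed=3)
        counts = [
            len(sc.apply_ems(genome, rate=1e-5, seed=s)) for s in range(300)
        ]
        assert np.mean(counts) == pytest.approx(10.0, rel=0.15)

    def test_rate_to_zero_limit(self, small_genome):
        genome, panel = small_genome
        muts = sc.apply_ems(
            genome, rate=1e-12, causal_pos=("chr1", 100_001), seed=4,
            snp_panel=panel,
        )
        assert len(muts) == 1
        assert muts.causal.pos == 100_001

    def test_gc_bias_forced(self):
        gmap = sc.GeneticMap.uniform({"chr1": 3000}, 4.0)
        genome = sc.Genome([("chr1", "GC" * 1500)], gmap)
        muts = sc.apply_ems(genome, rate=1e-2, gc_to_at_bias=1.0, seed=5)
        assert all(m.alt in "AT" for m in muts)

    def test_no_snp_collision(self, small_genome):
        genome, panel = small_genome
        muts = sc.apply_ems(genome, rate=5e-4, seed=6, snp_panel=panel)
        assert not ({(m.chrom, m.pos) for m in muts} & panel.position_set())

    def test_causal_on_snp_rejected(self, small_genome):
        genome, panel = small_genome
        snp = panel.records[0]
        with pytest.raises(ValueError, match="panel SNP"):
            sc.apply_ems(
                genome, causal_pos=(snp.chrom, snp.pos), seed=7, snp_panel=panel
            )

    def test_causal_on_masked_rejected(self):
        genome, panel = sc.simulate_genome(1, [100_000], 2e-3, 0.5, seed=8)
        seq = genome.sequence("chr1")
        masked_pos = next(i for i, b in enumerate(seq) if b.islower())
        with pytest.raises(ValueError, match="masked"):
            sc.apply_ems(genome, causal_pos=("chr1", masked_pos), seed=9)

    def test_exactly_one_causal(self, small_cross):
        _, _, mutations, _, _, _ = small_cross
        assert sum(m.is_causal for m in mutations) == 1


class TestSimulateF2:
    def test_mendelian_segregation(self, small_genome):
        genome, panel = small_genome
        muts = sc.apply_ems(
            genome, rate=1e-12, causal_pos=("chr1", 100_001), seed=20,
            snp_panel=panel,
        )
        f2 = sc.simulate_f2(genome, panel, muts, 10_000, seed=21)
        frac = sum(i.phenotype == "mutant" for i in f2) / len(f2)
        assert abs(frac - 0.25) < 0.015

    def test_one_two_one_genotype_ratio(self, small_genome):
        genome, panel = small_genome
        muts = sc.apply_ems(
            genome, rate=1e-12, causal_pos=("chr1", 100_001), seed=22,
            snp_panel=panel,
        )
        f2 = sc.simulate_f2(genome, panel, muts, 10_000, seed=23)
        dosages = [ind.causal_dosage() for ind in f2]
        obs = [dosages.count(0), dosages.count(1), dosages.count(2)]
        chi2 = stats.chisquare(obs, [2500, 5000, 2500])
        assert chi2.pvalue > 1e-3

    def test_no_crossovers_on_flat_map(self):
        gmap = sc.GeneticMap.uniform({"chr1": 50_000}, 0.0)
        genome = sc.Genome([("chr1", "A" * 25_000 + "G" * 25_000)], gmap)
        panel = sc.SnpPanel([sc.SnpRecord("chr1", 10, "A", "T")])
        muts = sc.MutationSet([sc.Mutation("chr1", 30_000, "G", "A", True)])
        f2 = sc.simulate_f2(genome, panel, muts, 50, seed=24)
        for ind in f2:
            for hap in (ind.haplotype_a, ind.haplotype_b):
                assert len(hap.segments("chr1")) == 1

    def test_unlinked_map_allele_frequency(self):
        genome, panel = sc.simulate_genome(
            2, [100_000, 100_000], 1e-3, 0.0, seed=25, cm_per_mb=20.0
        )
        muts = sc.apply_ems(
            genome, rate=1e-12, causal_pos=("chr1", 50_000), seed=26,
            snp_panel=panel,
        )
        f2 = sc.simulate_f2(genome, panel, muts, 4000, seed=27)
        snp = next(r for r in panel if r.chrom == "chr2")
        n_map = sum(
            hap.origin_at("chr2", snp.pos) == sc.MAP
            for ind in f2
            for hap in (ind.haplotype_a, ind.haplotype_b)
        )
        assert n_map / (2 * len(f2)) == pytest.approx(0.5, abs=0.02)

    def test_segments_tile_chromosome(self, small_cross):
        genome, _, _, f2, _, _ = small_cross
        ind = f2[0]
        for hap in (ind.haplotype_a, ind.haplotype_b):
            segs = hap.segments("chr1")
            assert segs[0][0] == 0
            assert segs[-1][1] == genome.lengths["chr1"]
            for (s1, e1, o1), (s2, e2, o2) in zip(segs, segs[1:]):
                assert e1 == s2 and o1 != o2

    def test_n_f2_validation(self, small_cross):
        genome, panel, mutations, _, _, _ = small_cross
        with pytest.raises(ValueError):
            sc.simulate_f2(genome, panel, mutations, 0, seed=1)


class TestBuildPools:
    def test_pure_pools(self, small_cross):
        _, _, _, _, mutant, wildtype = small_cross
        assert mutant.n == wildtype.n == 60
        assert mutant.is_pure and wildtype.is_pure
        assert all(i.causal_dosage() == 2 for i in mutant.individuals)

    def test_missort_count_exact(self, small_cross):
        _, _, _, f2, _, _ = small_cross
        mutant, wildtype = sc.build_pools(f2, 50, seed=31, missort_rate=0.02)
        # round(0.02 * 50) = 1 swapped individual per pool
        assert sum(i.phenotype == "wildtype" for i in mutant.individuals) == 1
        assert sum(i.phenotype == "mutant" for i in wildtype.individuals) == 1

    def test_insufficient_mutants_error(self, small_cross):
        _, _, _, f2, _, _ = small_cross
        with pytest.raises(ValueError, match="short by"):
            sc.build_pools(f2, 300, seed=32)


class TestSequencePool:
    def test_causal_position_all_alt(self, small_cross):
        genome, panel, mutations, _, mutant, _ = small_cross
        causal = mutations.causal
        cols = sc.sequence_pool(
            mutant, genome, panel, mutations,
            positions={"chr1": np.array([causal.pos])},
            depth=1000, error_rate=0.0, seed=40,
        )
        (col,) = cols
        assert col.pos == causal.pos
        assert np.all(col.bases == causal.alt)

    def test_unlinked_snp_half_map_fraction(self):
        genome, panel = sc.simulate_genome(
            2, [60_000, 60_000], 1e-3, 0.0, seed=41, cm_per_mb=20.0
        )
        muts = sc.apply_ems(
            genome, rate=1e-12, causal_pos=("chr1", 30_000), seed=42,
            snp_panel=panel,
        )
        f2 = sc.simulate_f2(genome, panel, muts, 1200, seed=43)
        mutant, _ = sc.build_pools(f2, 250, seed=44)
        snp = next(r for r in panel if r.chrom == "chr2")
        cols = sc.sequence_pool(
            mutant, genome, panel, muts,
            positions={"chr2": np.array([snp.pos])},
            depth=2000, error_rate=0.0, seed=45,
        )
        (col,) = cols
        frac = np.mean(col.bases == snp.map_allele)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_error_rate_recovered(self, small_cross):
        genome, panel, mutations, _, mutant, _ = small_cross
        # monomorphic position: no SNP, no mutation
        occupied = {p for _, p in panel.position_set()} | {
            m.pos for m in mutations
        }
        pos = next(p for p in range(1000, 2000) if p not in occupied)
        cols = sc.sequence_pool(
            mutant, genome, panel, mutations,
            positions={"chr1": np.array([pos])},
            depth=100_000, error_rate=1e-3, seed=46,
        )
        (col,) = cols
        ref = genome.base("chr1", pos).upper()
        nonref = np.mean(col.bases != ref)
        # binomial expectation: p=1e-3, n~1e5 -> 3 sigma ~ 3e-4
        assert nonref == pytest.approx(1e-3, abs=4e-4)

    def test_coverage_poisson_mean(self, small_cross):
        genome, panel, mutations, _, _, wildtype = small_cross
        cols = sc.sequence_pool(
            wildtype, genome, panel, mutations, depth=15, seed=47
        )
        depths = [c.depth for c in cols]
        assert np.mean(depths) == pytest.approx(15, rel=0.05)

    def test_determinism(self, small_cross):
        genome, panel, mutations, _, mutant, _ = small_cross
        a = sc.sequence_pool(mutant, genome, panel, mutations, depth=5, seed=48)
        b = sc.sequence_pool(mutant, genome, panel, mutations, depth=5, seed=48)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            assert ca.pos == cb.pos
            assert np.array_equal(ca.bases, cb.bases)
            assert np.array_equal(ca.read_starts, cb.read_starts)
            assert np.array_equal(ca.quals, cb.quals)

    def test_empty_pool_rejected(self, small_cross):
        genome, panel, mutations, _, _, _ = small_cross
        empty = sc.Pool("mutant", [])
        with pytest.raises(ValueError, match="empty pool"):
            sc.sequence_pool(empty, genome, panel, mutations, depth=5, seed=1)

    def test_read_start_invariant(self, small_cross):
        genome, panel, mutations, _, mutant, _ = small_cross
        cols = sc.sequence_pool(
            mutant, genome, panel, mutations, depth=8, read_len=35, seed=49
        )
        for col in cols[:50]:
            assert np.all(col.read_starts <= col.pos)
            assert np.all(col.pos < col.read_starts + 35)


class TestAlleleFrequencyCurves:
    """Pool allele frequencies at linked markers vs. the enumeration oracle."""

    @staticmethod
    def oracle(pool, r):
        """Enumerate conditional F2 gamete pairs at recombination r."""
        # gamete: (causal origin, marker origin); 0 = MUT, 1 = MAP
        gametes = {
            (0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2,
            (0, 1): r / 2, (1, 0): r / 2,
        }
        num = den = 0.0
        for (c1, m1), p1 in gametes.items():
            for (c2, m2), p2 in gametes.items():
                is_mut = c1 == 0 and c2 == 0
                if (pool == "mutant") != is_mut:
                    continue
                num += p1 * p2 * (m1 + m2)
                den += p1 * p2 * 2
        return num / den

    @pytest.mark.parametrize("cm_dist", [0.0, 10.0, 30.0])
    def test_simulated_pool_matches_oracle(self, cm_dist):
        length = 800_000
        genome, panel = sc.simulate_genome(
            1, [length], 5e-4, 0.0, seed=50, cm_per_mb=100.0
        )
        causal_pos = 400_000
        muts = sc.apply_ems(
            genome, rate=1e-12, causal_pos=("chr1", causal_pos), seed=51,
            snp_panel=panel,
        )
        f2 = sc.simulate_f2(genome, panel, muts, 6000, seed=52)
        marker = causal_pos + int(cm_dist * 10_000)  # 100 cM/Mb
        d = genome.genetic_map.bp_to_morgans(
            "chr1", marker
        ) - genome.genetic_map.bp_to_morgans("chr1", causal_pos)
        r = sc.haldane_r(float(d))
        for label in ("mutant", "wildtype"):
            members = [i for i in f2 if (i.phenotype == "mutant") == (label == "mutant")]
            n_map = sum(
                h.origin_at("chr1", marker) == sc.MAP
                for i in members
                for h in (i.haplotype_a, i.haplotype_b)
            )
            frac = n_map / (2 * len(members))
            assert frac == pytest.approx(self.oracle(label, r), abs=0.03)


class TestRecombinantFlanks:
    def test_interval_bounds_and_units(self):
        gmap = sc.GeneticMap.uniform({"chr1": 1_000_000}, 100.0)  # 100 cM
        genome = sc.Genome([("chr1", "A" * 1_000_000)], gmap)
        # MAP up to 400k, MUT between the crossovers, MAP after 700k
        hap = sc.Haplotype(
            {"chr1": sc.MAP},
            {"chr1": np.array([400_000, 700_000])},
            {"chr1": 1_000_000},
        )
        hap2 = sc.Haplotype(
            {"chr1": sc.MUT}, {"chr1": np.array([], dtype=np.int64)},
            {"chr1": 1_000_000},
        )
        ind = sc.Individual(hap, hap2, _causal=("chr1", 500_000))
        left, right, cm = sc.recombinant_flank_interval(
            [ind], genome, "chr1", 500_000
        )
        assert (left, right) == (400_000, 700_000)
        assert cm == pytest.approx(30.0)


class TestGeneticMap:
    def test_piecewise_round_trip(self):
        gmap = sc.GeneticMap(
            {
                "chr1": [
                    sc.GeneticMapSegment(0, 100_000, 2.0),
                    sc.GeneticMapSegment(100_000, 300_000, 10.0),
                ]
            }
        )
        for pos in (0, 50_000, 100_000, 123_456, 300_000):
            d = gmap.bp_to_morgans("chr1", pos)
            back = gmap.morgans_to_bp("chr1", d)
            assert float(back) == pytest.approx(pos, abs=1)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sc.GeneticMap({"chr1": [sc.GeneticMapSegment(0, 1000, -1.0)]})

    def test_haldane_limits(self):
        assert sc.haldane_r(0.0) == 0.0
        assert sc.haldane_r(100.0) == pytest.approx(0.5)
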