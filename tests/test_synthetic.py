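"""Generator tests: determinism, Mendelian and Haldane consistency, and
round-trips of the simulated read structure."""

import collections

import numpy as np
import pytest
from scipy import stats

import bsrwalk.synthetic as syn
from bsrwalk.seqwalk import demultiplex, trim_mu_flank, FlankRead

from conftest import make_linked_map


class TestMakeReference:
    def test_genes_disjoint_and_in_bounds(self):
        ref = syn.make_reference([1_000_000], 10, seed=1)
        genes = sorted(ref.genes, key=lambda g: g.start)
        assert len(genes) == 10
        assert all(1 <= g.start <= g.end <= 1_000_000 for g in genes)
        assert all(a.end < b.start for a, b in zip(genes, genes[1:]))
        assert set(ref.sequences[0]) <= set("ACGT")

    def test_same_seed_byte_identical_output(self, tmp_path):
        for tag in ("a", "b"):
            ref = syn.make_reference([50_000], 5, seed=42)
            ref.to_fasta(tmp_path / f"{tag}.fasta")
            ref.to_gff3(tmp_path / f"{tag}.gff3")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="without overlap"):
            syn.make_reference([1_000], 500, seed=0, min_gene_len=100, max_gene_len=100)

    def test_fasta_gff_round_trip(self, tmp_path):
        ref = syn.make_reference([30_000], 4, seed=3)
        ref.to_fasta(tmp_path / "r.fasta")
        ref.to_gff3(tmp_path / "r.gff3")
        back = syn.ReferenceGenome.from_files(tmp_path / "r.fasta", tmp_path / "r.gff3")
        assert back.sequences == ref.sequences
        assert back.genes == ref.genes


class TestGeneticMap:
    def test_monotone(self, small_map):
        for chrom in small_map.chroms:
            bp, cm = small_map.chrom_markers(chrom)
            assert np.all(np.diff(bp) > 0)
            assert np.all(np.diff(cm) >= 0)

    def test_no_suppression_gives_uniform_rate(self):
        ref = syn.make_reference([500_000], 3, seed=5)
        gmap = syn.make_genetic_map(ref, 50, (200_000, 300_000), 1.0, 5.0, seed=6)
        bp, cm = gmap.chrom_markers("chr1")
        rates = np.diff(cm) / (np.diff(bp) / 1e6)
        assert rates == pytest.approx([5.0] * len(rates))

    def test_suppression_factor_sets_slope_ratio(self):
        ref = syn.make_reference([2_000_000], 3, seed=7)
        span = (800_000, 1_200_000)
        gmap = syn.make_genetic_map(ref, 400, span, 0.1, 5.0, seed=8)
        bp, cm = gmap.chrom_markers("chr1")
        pairs_in = (bp[:-1] >= span[0]) & (bp[1:] <= span[1])
        pairs_out = (bp[1:] <= span[0]) | (bp[:-1] >= span[1])
        slope = np.diff(cm) / (np.diff(bp) / 1e6)
        ratio = slope[pairs_in].mean() / slope[pairs_out].mean()
        assert ratio == pytest.approx(0.1, abs=0.02)

    def test_invalid_suppression_rejected(self, small_reference):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                syn.make_genetic_map(small_reference, 10, (1_000, 2_000), bad, 5.0, seed=0)

    def test_tsv_round_trip(self, small_map, tmp_path):
        small_map.to_tsv(tmp_path / "map.tsv")
        back = syn.GeneticMap.from_tsv(tmp_path / "map.tsv")
        assert back.df["pos_bp"].tolist() == small_map.df["pos_bp"].tolist()
        assert back.df["pos_cm"].to_numpy() == pytest.approx(small_map.df["pos_cm"].to_numpy())


class TestF2Simulation:
    def test_causal_genotypes_1_2_1(self):
        gmap = make_linked_map([10.0])
        pop = syn.simulate_f2_population(gmap, ("chr1", 1_000), 4_000, seed=21)
        counts = collections.Counter(pop.causal_genotypes())
        chi2, p = stats.chisquare(
            [counts["mm"], counts["m+"], counts["++"]], [1_000, 2_000, 1_000]
        )
        assert p > 0.001
        # recessive phenotype segregates 3:1
        assert pop.is_mutant().sum() == counts["mm"]

    @pytest.mark.parametrize("d_cm", [1.0, 10.0, 50.0])
    def test_gamete_recombination_matches_haldane(self, d_cm):
        gmap = make_linked_map([d_cm])
        n = 3_000
        pop = syn.simulate_f2_population(gmap, ("chr1", 1_000), n, seed=int(d_cm))
        gametes = pop.origins.reshape(2 * n, -1)
        rec = (gametes[:, 0] != gametes[:, 1]).mean()
        expected = float(syn.haldane_r(d_cm))
        se = np.sqrt(expected * (1 - expected) / (2 * n))
        assert abs(rec - expected) < 3 * se

    def test_zero_distance_means_complete_linkage(self):
        gmap = make_linked_map([0.0])
        pop = syn.simulate_f2_population(gmap, ("chr1", 1_000), 500, seed=2)
        gametes = pop.origins.reshape(1_000, -1)
        assert (gametes[:, 0] == gametes[:, 1]).all()

    def test_invalid_inputs(self):
        gmap = make_linked_map([5.0])
        with pytest.raises(ValueError):
            syn.simulate_f2_population(gmap, ("chr1", 1_000), 0, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_f2_population(gmap, ("chr1", 999), 10, seed=0)

    def test_individual_accessor_consistent(self):
        gmap = make_linked_map([5.0])
        pop = syn.simulate_f2_population(gmap, ("chr1", 1_000), 50, seed=3)
        ind = pop[7]
        n_p1 = sum(int(g[pop.causal_index]) == 0 for g in ind.gametes)
        assert ind.causal_genotype == {2: "mm", 1: "m+", 0: "++"}[n_p1]


@pytest.fixture(scope="module")
def population():
    gmap = make_linked_map([10.0], unlinked=1)
    return syn.simulate_f2_population(gmap, ("chr1", 1_000), 600, seed=31)


@pytest.fixture(scope="module")
def counts_scenario():
    gmap = make_linked_map([10.0], unlinked=1)
    pop = syn.simulate_f2_population(gmap, ("chr1", 1_000), 600, seed=41)
    bulks = syn.phenotype_and_bulk(pop, 123, 123, seed=42)
    return gmap, bulks


class TestBulking:
    def test_default_bulk_sizes(self, population):
        mut, wt = syn.phenotype_and_bulk(population, seed=1)
        assert (mut.n_individuals, wt.n_individuals) == (123, 123)
        assert mut.chromosomes.shape == (246, 3)

    def test_mutant_bulk_is_pure_mm(self, population):
        mut, _ = syn.phenotype_and_bulk(population, seed=2)
        # both chromosomes of every member carry the P1 allele at the causal locus
        assert (mut.chromosomes[:, population.causal_index] == 0).all()

    def test_wt_bulk_genotype_ratio_1_to_2(self):
        # among phenotypically wild-type plants ++ : m+ is 1 : 2
        gmap = make_linked_map([10.0])
        hom, het = 0, 0
        for seed in range(30):
            pop = syn.simulate_f2_population(gmap, ("chr1", 1_000), 600, seed=seed)
            _, wt = syn.phenotype_and_bulk(pop, 123, 123, seed=seed)
            n_p1 = (wt.chromosomes.reshape(123, 2, -1)[:, :, pop.causal_index] == 0).sum(axis=1)
            hom += int((n_p1 == 0).sum())
            het += int((n_p1 == 1).sum())
        frac_hom = hom / (hom + het)
        se = np.sqrt((1 / 3) * (2 / 3) / (hom + het))
        assert abs(frac_hom - 1 / 3) < 3 * se

    def test_deficit_error_names_class(self, population):
        with pytest.raises(ValueError, match="mm individuals"):
            syn.phenotype_and_bulk(population, n_mutant=500, seed=0)


class TestBulkAlleleCounts:
    def test_causal_snp_has_no_p2_reads_at_zero_error(self, counts_scenario):
        gmap, bulks = counts_scenario
        counts = syn.simulate_bulk_allele_counts(bulks, gmap, 50.0, 0.0, seed=43)
        causal = counts[(counts["chrom"] == "chr1") & (counts["pos"] == 1_000)].iloc[0]
        assert causal["mut_alt"] == 0
        assert causal["mut_ref"] > 0

    def test_unlinked_snp_balanced_across_pools(self, counts_scenario):
        gmap, bulks = counts_scenario
        ref = alt = 0
        for seed in range(20):
            counts = syn.simulate_bulk_allele_counts(bulks, gmap, 50.0, 0.0, seed=seed)
            row = counts[counts["chrom"] == "chr2"].iloc[0]
            ref += row["mut_ref"] + row["wt_ref"]
            alt += row["mut_alt"] + row["wt_alt"]
        frac = ref / (ref + alt)
        # bulk chromosome composition is fixed across seeds, so allow its
        # finite-sampling offset (492 chromosomes) on top of read noise
        se = np.sqrt(0.25 / (ref + alt) + 0.25 / 492)
        assert abs(frac - 0.5) < 3 * se

    def test_vanishing_depth_gives_empty_counts(self, counts_scenario):
        gmap, bulks = counts_scenario
        counts = syn.simulate_bulk_allele_counts(bulks, gmap, 1e-4, 0.0, seed=44)
        assert (counts[["mut_ref", "mut_alt", "wt_ref", "wt_alt"]].sum(axis=1) == 0).mean() > 0.99

    def test_rejects_invalid_error_rate(self, counts_scenario):
        gmap, bulks = counts_scenario
        with pytest.raises(ValueError):
            syn.simulate_bulk_allele_counts(bulks, gmap, 10.0, 0.6, seed=0)


class TestSeqwalkLibrary:
    def test_zero_error_round_trip(self, small_reference):
        ins = [syn.Insertion("chr1", 50_000, 1.0)]
        reads, truth = syn.simulate_seqwalk_library(
            small_reference, ins, 40, "GTCGAT", seq_error=0.0, seed=51, library="mutant"
        )
        assigned, unassigned = demultiplex(reads, {"mutant": "GTCGAT"})
        assert unassigned == 0 and len(assigned["mutant"]) == 40
        for read in assigned["mutant"]:
            flank = trim_mu_flank(read, syn.DEFAULT_TIR_TAG, library="mutant")
            assert isinstance(flank, FlankRead)
            expected = small_reference.fetch("chr1", 50_000, 50_000 + len(flank.sequence) - 1)
            assert flank.sequence == expected
        assert truth.insertions["n_reads"].sum() == 40

    def test_read_weights_drive_read_counts(self, small_reference):
        ins = [syn.Insertion("chr1", 20_000, 10.0), syn.Insertion("chr1", 90_000, 1.0)]
        n_heavy = n_light = 0
        for seed in range(10):
            _, truth = syn.simulate_seqwalk_library(
                small_reference, ins, 1_000, "GTCGAT", seq_error=0.0, seed=seed
            )
            n_heavy += truth.insertions["n_reads"].iloc[0]
            n_light += truth.insertions["n_reads"].iloc[1]
        frac = n_heavy / (n_heavy + n_light)
        se = np.sqrt((10 / 11) * (1 / 11) / (n_heavy + n_light))
        assert abs(frac - 10 / 11) < 3 * se

    def test_insertion_outside_reference_rejected(self, small_reference):
        with pytest.raises(ValueError, match="outside"):
            syn.simulate_seqwalk_library(
                small_reference, [syn.Insertion("chr1", 10**9, 1.0)], 10, "GTCGAT"
            )

    def test_fastq_deterministic(self, small_reference, tmp_path):
        from bsrwalk.seqwalk import write_fastq
        ins = [syn.Insertion("chr1", 1_234, 1.0)]
        for tag in ("a", "b"):
            reads, _ = syn.simulate_seqwalk_library(
                small_reference, ins, 25, "CTGCTA", seq_error=0.02, seed=99
            )
            write_fastq(reads, tmp_path / f"{tag}.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
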