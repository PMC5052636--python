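"""Seq-walking tests: demultiplexing, TIR trimming, the length filter
boundary, the toy mapper, binned site calling, control subtraction,
ranking, and end-to-end recovery of planted insertions at zero error."""

import numpy as np
import pytest

import bsrwalk.seqwalk as sw
import bsrwalk.synthetic as syn
from bsrwalk.scan import MappingInterval

TIR = syn.DEFAULT_TIR_TAG


def read(seq, rid="r1"):
    return sw.RawRead(rid, seq, "I" * len(seq))


class TestDemultiplex:
    BARCODES = {"mutant": "GTCGAT", "control": "CTGCTA"}

    def test_assignment_and_barcode_removal(self):
        reads = [read("GTCGAT" + "AAAA", "m"), read("CTGCTA" + "CCCC", "c"),
                 read("TTTTTT" + "GGGG", "x")]
        assigned, unassigned = sw.demultiplex(reads, self.BARCODES)
        assert [r.id for r in assigned["mutant"]] == ["m"]
        assert assigned["mutant"][0].sequence == "AAAA"
        assert [r.id for r in assigned["control"]] == ["c"]
        assert unassigned == 1
        assert sum(map(len, assigned.values())) + unassigned == len(reads)

    def test_near_miss_is_unassigned(self):
        # one substitution in the barcode: exact matching rejects it
        assigned, unassigned = sw.demultiplex([read("GTCGAA" + "AAAA")], self.BARCODES)
        assert unassigned == 1

    def test_duplicate_barcode_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sw.demultiplex([], {"a": "GTCGAT", "b": "GTCGAT"})

    def test_unequal_barcode_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            sw.demultiplex([], {"a": "GTCGAT", "b": "CTG"})


class TestTrimMuFlank:
    def test_exact_tag_round_trip(self):
        flank = "ACGTACGTACGT"
        out = sw.trim_mu_flank(read(TIR + flank), TIR, library="mutant")
        assert isinstance(out, sw.FlankRead)
        assert out.sequence == flank
        assert out.library == "mutant"

    def test_mismatch_threshold(self):
        tag2 = "CC" + TIR[2:]  # 2 substitutions: allowed
        tag3 = "CCC" + TIR[3:]  # 3 substitutions: rejected
        assert isinstance(sw.trim_mu_flank(read(tag2 + "AAAA"), TIR), sw.FlankRead)
        out = sw.trim_mu_flank(read(tag3 + "AAAA"), TIR)
        assert isinstance(out, sw.TrimRejected)
        assert "3 mismatches" in out.reason

    def test_too_short_read_rejected(self):
        out = sw.trim_mu_flank(read(TIR[:10]), TIR)
        assert isinstance(out, sw.TrimRejected)


class TestFilterLength:
    def test_strict_90_bp_boundary(self):
        flanks = [
            sw.FlankRead("a", "m", "A" * 90),
            sw.FlankRead("b", "m", "A" * 91),
        ]
        kept = sw.filter_length(flanks, min_exclusive=90)
        assert [f.id for f in kept] == ["b"]

    def test_empty_input(self):
        assert sw.filter_length([]) == []


@pytest.fixture(scope="module")
def index(small_reference):
    return sw.KmerIndex.from_reference(small_reference)


class TestMapper:
    def test_exact_forward_flank(self, small_reference, index):
        pos = 77_000
        flank = sw.FlankRead("f", "m", small_reference.fetch("chr1", pos, pos + 119))
        hit = sw.map_flank(flank, index)
        assert isinstance(hit, sw.Alignment)
        assert (hit.chrom, hit.pos, hit.strand, hit.mismatches) == ("chr1", pos, "+", 0)

    def test_reverse_complement_same_coordinate(self, small_reference, index):
        pos = 77_000
        seq = small_reference.fetch("chr1", pos, pos + 119)
        hit = sw.map_flank(sw.FlankRead("f", "m", sw.revcomp(seq)), index)
        assert isinstance(hit, sw.Alignment)
        # the reported coordinate is the flank-start base of the original read
        assert (hit.chrom, hit.strand) == ("chr1", "-")
        assert hit.pos == pos + 119

    def test_mismatches_within_budget_still_map(self, small_reference, index):
        pos = 30_000
        seq = list(small_reference.fetch("chr1", pos, pos + 99))
        for i in (40, 70):  # 2 mismatches in 100 bp <= 5%
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        hit = sw.map_flank(sw.FlankRead("f", "m", "".join(seq)), index)
        assert isinstance(hit, sw.Alignment)
        assert hit.pos == pos and hit.mismatches == 2

    def test_foreign_sequence_unmapped(self, index, rng):
        seq = "".join(rng.choice(list("ACGT"), 60))
        out = sw.map_flank(sw.FlankRead("f", "m", seq), index)
        assert isinstance(out, (sw.Unmapped, sw.Multimapped))

    def test_short_flank_unmapped(self, index):
        out = sw.map_flank(sw.FlankRead("f", "m", "ACGT"), index)
        assert isinstance(out, sw.Unmapped)
        assert "shorter than seed" in out.reason

    def test_repeated_segment_multimaps(self):
        core = "ACGTTGCA" * 8  # 64 bp repeated twice in the reference
        ref = syn.ReferenceGenome(
            ["chrR"], ["TTTT" + core + "CCCCCCCCCCCC" + core + "GGGG"], []
        )
        index = sw.KmerIndex.from_reference(ref)
        out = sw.map_flank(sw.FlankRead("f", "m", core), index)
        assert isinstance(out, sw.Multimapped)


class TestSiteCalling:
    def _aln(self, pos, rid="r"):
        return sw.Alignment(rid, "chr1", pos, "+", 0)

    def test_reads_in_one_bin_cluster(self):
        sites = sw.call_sites([self._aln(p) for p in range(104_610_901, 104_611_000, 20)],
                              bin_width=100, library="mutant")
        assert len(sites) == 1
        row = sites.df.iloc[0]
        assert row["bin_start"] == 104_610_901
        assert row["read_count"] == 5

    def test_different_bins_stay_separate(self):
        sites = sw.call_sites([self._aln(150), self._aln(250)], bin_width=100)
        assert sites.df["bin_start"].tolist() == [101, 201]

    def test_multimapped_and_unmapped_excluded(self):
        results = [self._aln(500), sw.Unmapped("u", "x"), sw.Multimapped("m", 2)]
        sites = sw.call_sites(results, bin_width=100)
        assert sites.df["read_count"].sum() == 1

    def test_empty(self):
        assert len(sw.call_sites([], bin_width=100)) == 0


class TestSubtractControl:
    def _table(self, bins, bin_width=100, library="mutant"):
        import pandas as pd
        df = pd.DataFrame(
            {"chrom": "chr1", "bin_start": bins, "read_count": 5, "library": library}
        )
        return sw.SiteTable(df[sw.SiteTable.COLUMNS], bin_width)

    def test_self_subtraction_is_empty(self):
        t = self._table([101, 501, 901])
        assert len(sw.subtract_control(t, t)) == 0

    def test_private_sites_survive(self):
        sample = self._table([101, 5_001])
        control = self._table([101], library="control")
        out = sw.subtract_control(sample, control)
        assert out.df["bin_start"].tolist() == [5_001]

    def test_empty_control_is_identity(self):
        sample = self._table([101, 201])
        out = sw.subtract_control(sample, self._table([]))
        assert out.df["bin_start"].tolist() == [101, 201]

    def test_tolerance_in_bins(self):
        sample = self._table([301])
        near = self._table([201], library="control")  # 1 bin away: removed
        far = self._table([501], library="control")  # 2 bins away: kept
        assert len(sw.subtract_control(sample, near, tolerance=1)) == 0
        assert len(sw.subtract_control(sample, far, tolerance=1)) == 1

    def test_mismatched_bin_widths_rejected(self):
        with pytest.raises(ValueError, match="bin widths"):
            sw.subtract_control(self._table([101]), self._table([101], bin_width=50))


class TestRestrictAndRank:
    INTERVAL = MappingInterval("chr1", 100_000, 150_000, 10.0, 25.0, 15.0, 0)

    def _table(self, rows, bin_width=100):
        import pandas as pd
        df = pd.DataFrame(rows, columns=sw.SiteTable.COLUMNS)
        return sw.SiteTable(df, bin_width)

    def test_highest_read_count_wins(self):
        genes = [syn.Gene("gA", "chr1", 104_550, 104_800, "+")]
        sites = self._table(
            [("chr1", 104_601, 22_945, "mutant"),
             ("chr1", 120_001, 310, "mutant"),
             ("chr1", 140_001, 12, "mutant")]
        )
        report = sw.restrict_and_rank(sites, self.INTERVAL, genes)
        assert isinstance(report, sw.CandidateReport)
        top = report.candidate
        assert top["read_count"] == 22_945
        assert top["gene_id"] == "gA"
        assert report.df["rank"].tolist() == [1, 2, 3]

    def test_all_sites_outside_interval(self):
        sites = self._table([("chr1", 500_001, 99, "mutant")])
        out = sw.restrict_and_rank(sites, self.INTERVAL, [])
        assert isinstance(out, sw.NoCandidate)

    def test_count_tie_broken_by_coordinate(self):
        sites = self._table(
            [("chr1", 130_001, 50, "mutant"), ("chr1", 110_001, 50, "mutant")]
        )
        report = sw.restrict_and_rank(sites, self.INTERVAL, [])
        assert report.candidate["bin_start"] == 110_001


class TestEndToEnd:
    def test_zero_error_recovers_every_planted_site(self, small_reference):
        barcodes = dict(syn.DEFAULT_BARCODES)
        mut_ins = [syn.Insertion("chr1", 20_000, 3.0), syn.Insertion("chr1", 65_432, 1.0),
                   syn.Insertion("chr1", 120_000, 1.0)]
        ctl_ins = [syn.Insertion("chr1", 65_432, 1.0), syn.Insertion("chr1", 180_000, 1.0)]
        reads_m, _ = syn.simulate_seqwalk_library(
            small_reference, mut_ins, 600, barcodes["mutant"], seq_error=0.0,
            seed=71, library="mutant")
        reads_c, _ = syn.simulate_seqwalk_library(
            small_reference, ctl_ins, 400, barcodes["control"], seq_error=0.0,
            seed=72, library="control")
        result = sw.run_seqwalk(reads_m + reads_c, barcodes, TIR, small_reference)

        def bins(table):
            return set(table.df["bin_start"])

        bin_of = lambda p: (p - 1) // 100 * 100 + 1
        # every planted insertion appears at its true bin, nothing else
        assert bins(result.sample_sites) == {bin_of(i.pos) for i in mut_ins}
        assert bins(result.control_sites) == {bin_of(i.pos) for i in ctl_ins}
        # subtraction removes exactly the site shared between libraries
        assert bins(result.candidate_sites) == {bin_of(20_000), bin_of(120_000)}
        # exact accounting at every stage
        result.accounting.check()
        acc = result.accounting
        assert acc.n_input == 1_000 and acc.n_unassigned == 0
        m = acc.libraries["mutant"]
        assert m.n_assigned == 600 == m.n_trimmed + m.n_rejected
        assert m.n_kept == m.n_mapped + m.n_unmapped + m.n_multimapped

    def test_accounting_error_names_stage(self):
        acc = sw.LibraryAccounting("mutant", n_assigned=10, n_trimmed=9, n_rejected=1,
                                   n_kept=8, n_length_filtered=1, n_mapped=8)
        acc.check()
        acc.n_mapped = 7
        with pytest.raises(sw.AccountingError, match="mapping"):
            acc.check()

    def test_fastq_round_trip(self, tmp_path):
        reads = [read("GTCGATACGT", "a"), read("CTGCTAGGGG", "b")]
        sw.write_fastq(reads, tmp_path / "x.fastq")
        back = sw.read_fastq(tmp_path / "x.fastq")
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in reads]
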