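"""Gene filtering, strand assignment, unit-gene meta-profiles, per-gene
log-ratios, and time-course summaries."""

import numpy as np
import pandas as pd
import pytest

import xrseq as x
from xrseq.core import MappedRead, MappedReadSet, XRSeqError
from xrseq.tcr import (
    FLANK_BIN_BP,
    N_BINS,
    N_BODY_BINS,
    N_FLANK_BINS,
    UnitGeneProfile,
    assign_strand,
    body_ts_nts_ratio,
    filter_genes,
    gene_bins,
    log2_ts_nts_per_gene,
    tcr_timecourse,
    unit_gene_profile,
)
from test_simulate import brute_force_filter_ids


class TestFilterGenes:
    def test_length_boundary_half_open(self):
        genes = x.GeneSet(
            [
                x.GeneModel("short", "chr1", 1000, 1999, "+"),
                x.GeneModel("exact", "chr1", 5000, 6000, "+"),
            ]
        )
        result = filter_genes(genes, min_length=1000)
        assert [g.id for g in result.genes] == ["exact"]
        assert result.n_short == 1

    def test_antisense_overlap_excludes_both(self):
        genes = x.GeneSet(
            [
                x.GeneModel("a", "chr1", 1000, 3000, "+"),
                x.GeneModel("b", "chr1", 2000, 4500, "-"),
                x.GeneModel("c", "chr1", 6000, 8000, "+"),
            ]
        )
        result = filter_genes(genes)
        assert [g.id for g in result.genes] == ["c"]
        assert result.n_overlapping == 2

    def test_overlap_tested_against_all_genes(self):
        """A gene overlapped only by a sub-1-kb gene is still excluded: the
        overlap test runs against the full annotation."""
        genes = x.GeneSet(
            [
                x.GeneModel("big", "chr1", 1000, 3000, "+"),
                x.GeneModel("tiny", "chr1", 2900, 3100, "-"),
            ]
        )
        result = filter_genes(genes)
        assert len(result.genes) == 0

    def test_expression_filter_strict_and_missing_logged(self):
        genes = x.GeneSet(
            [
                x.GeneModel("hi", "chr1", 1000, 3000, "+", 11.0),
                x.GeneModel("edge", "chr1", 5000, 7000, "+", 10.0),
                x.GeneModel("none", "chr1", 9000, 11000, "+", None),
            ]
        )
        result = filter_genes(genes, min_rpkm=10.0)
        assert [g.id for g in result.genes] == ["hi"]
        assert result.n_low_expression == 1 and result.n_missing_expression == 1

    def test_matches_brute_force_oracle(self):
        """Sweep-based filter equals the O(n^2) oracle on a random gene set."""
        rng = np.random.default_rng(77)
        genes = []
        for i in range(200):
            start = int(rng.integers(0, 500_000))
            length = int(rng.integers(300, 4000))
            genes.append(
                x.GeneModel(
                    f"g{i}", f"chr{rng.integers(1, 3)}", start, start + length,
                    "+" if rng.random() < 0.5 else "-",
                )
            )
        gs = x.GeneSet(genes)
        result = filter_genes(gs, min_length=1000)
        assert {g.id for g in result.genes} == brute_force_filter_ids(genes)


class TestAssignStrand:
    @pytest.mark.parametrize(
        "read_strand, gene_strand, expected",
        [("-", "+", "TS"), ("+", "+", "NTS"), ("-", "-", "NTS"), ("+", "-", "TS")],
    )
    def test_definition(self, read_strand, gene_strand, expected):
        assert assign_strand(read_strand, gene_strand) == expected

    def test_tcr_factor4_recovery(self, f4_run):
        """With 4x template-strand enhancement, TS counts are ~4x NTS."""
        genes = filter_genes(f4_run.genes).genes
        pg = log2_ts_nts_per_gene(f4_run.reads, genes)
        assert pg.ts_count.sum() / pg.nts_count.sum() == pytest.approx(4.0, rel=0.10)


class TestUnitGeneBinning:
    def test_minus_gene_mirrors_plus(self):
        plus = x.GeneModel("p", "chr1", 10_000, 12_000, "+")
        minus = x.GeneModel("m", "chr1", 10_000, 12_000, "-")
        pos = np.array([8_000, 10_000, 11_000, 11_999, 12_000, 13_999])
        bp, bm = gene_bins(pos, plus), gene_bins(pos, minus)
        assert np.array_equal(bm, N_BINS - 1 - bp)

    def test_body_bin_clamped(self):
        g = x.GeneModel("g", "chr1", 0, 1001, "+")  # length not divisible by 100
        assert gene_bins(np.array([1000]), g)[0] == N_FLANK_BINS + N_BODY_BINS - 1

    def test_single_read_rpkm_by_hand(self):
        """One read at a body-bin midpoint: RPKM = count * 1e9 / (bin_bp * N)."""
        gene = x.GeneSet([x.GeneModel("g", "chr1", 10_000, 11_000, "+")])
        read = MappedReadSet.from_reads(
            [MappedRead("chr1", 10_486, 10_514, "-", "A" * 28, "r0")]
        )  # midpoint 10_500 -> body offset 500 -> bin 25 + 50
        prof = unit_gene_profile(read, gene, total_mapped_reads=1_000)
        expected = 1 * 1e9 / (10.0 * 1_000)  # bin_bp = 1000/100 = 10
        assert prof.ts[75] == pytest.approx(expected)
        nonzero = np.flatnonzero(np.nan_to_num(prof.ts) + np.nan_to_num(prof.nts))
        assert list(nonzero) == [75]

    def test_read_conservation(self, f2_run):
        """Summed per-bin counts equal the number of midpoint-in-window
        assignments, which a brute-force scan reproduces."""
        genes = filter_genes(f2_run.genes).genes
        prof = unit_gene_profile(f2_run.reads, genes, len(f2_run.reads))
        total_binned = int(prof.ts_counts.sum() + prof.nts_counts.sum())
        assert total_binned == prof.n_assignments
        mids = f2_run.reads.midpoints
        brute = sum(
            int(
                np.count_nonzero(
                    (f2_run.reads.chroms == g.chrom)
                    & (mids >= g.start - 2000)
                    & (mids < g.end + 2000)
                )
            )
            for g in genes
        )
        assert total_binned == brute

    def test_strand_flip_swaps_profiles(self, sym_run):
        """Flipping every gene's strand exchanges TS and NTS exactly."""
        genes = filter_genes(sym_run.genes).genes
        flipped = x.GeneSet(
            [
                x.GeneModel(g.id, g.chrom, g.start, g.end,
                            "-" if g.strand == "+" else "+", g.rpkm)
                for g in genes
            ]
        )
        a = unit_gene_profile(sym_run.reads, genes, len(sym_run.reads))
        b = unit_gene_profile(sym_run.reads, flipped, len(sym_run.reads))
        # flipping the strand also mirrors the bin axis (TSS moves ends)
        assert np.allclose(a.ts, b.nts[::-1], equal_nan=True)
        assert np.allclose(a.nts, b.ts[::-1], equal_nan=True)

    def test_symmetric_simulation_profiles_agree(self, sym_run):
        genes = filter_genes(sym_run.genes).genes
        prof = unit_gene_profile(sym_run.reads, genes, len(sym_run.reads),
                                 genome=sym_run.genome)
        assert body_ts_nts_ratio(prof) == pytest.approx(1.0, abs=0.06)


class TestBodyRatio:
    def test_constant_profiles(self):
        ts = np.full(N_BINS, 2.0)
        nts = np.ones(N_BINS)
        prof = UnitGeneProfile(ts, nts, 10, np.full(N_BINS, 10),
                               np.zeros(N_BINS, int), np.zeros(N_BINS, int), 1)
        assert body_ts_nts_ratio(prof) == pytest.approx(2.0)

    def test_zero_nts_undefined(self):
        prof = UnitGeneProfile(np.ones(N_BINS), np.zeros(N_BINS), 1,
                               np.ones(N_BINS, int), np.zeros(N_BINS, int),
                               np.zeros(N_BINS, int), 1)
        assert np.isnan(body_ts_nts_ratio(prof))

    def test_tcr_factor2_recovery(self, f2_run):
        """Cisplatin-default TCR strength: body TS/NTS ~= 2 at 500k reads."""
        genes = filter_genes(f2_run.genes).genes
        prof = unit_gene_profile(f2_run.reads, genes, len(f2_run.reads),
                                 genome=f2_run.genome)
        assert body_ts_nts_ratio(prof) == pytest.approx(2.0, rel=0.10)


class TestLog2PerGene:
    def test_arithmetic(self):
        genes = x.GeneSet([x.GeneModel("g", "chr1", 0, 2000, "+")])
        reads = MappedReadSet.from_reads(
            [MappedRead("chr1", 100 + 30 * i, 128 + 30 * i, "-", "A" * 28, f"t{i}")
             for i in range(31)]
            + [MappedRead("chr1", 110 + 30 * i, 138 + 30 * i, "+", "A" * 28, f"n{i}")
               for i in range(15)]
        )
        pg = log2_ts_nts_per_gene(reads, genes, pseudocount=1)
        assert pg.loc[0, "log2_ratio"] == pytest.approx(1.0)  # log2(32/16)

    def test_zero_counts_give_zero(self):
        genes = x.GeneSet([x.GeneModel("g", "chr1", 0, 2000, "+")])
        pg = log2_ts_nts_per_gene(MappedReadSet.from_reads([]), genes)
        assert pg.loc[0, "log2_ratio"] == 0.0

    def test_pseudocount_positive_required(self):
        genes = x.GeneSet([x.GeneModel("g", "chr1", 0, 2000, "+")])
        with pytest.raises(XRSeqError, match="pseudocount"):
            log2_ts_nts_per_gene(MappedReadSet.from_reads([]), genes, pseudocount=0)

    def test_symmetric_distribution_centered(self, many_genes_sym_run):
        """tcr_factor = 1 over 200 genes: the Log2(TS/NTS) distribution is
        centered at zero (|mean| < 0.05)."""
        run = many_genes_sym_run
        pg = log2_ts_nts_per_gene(run.reads, run.genes)
        assert len(pg) == 200
        assert abs(pg.log2_ratio.mean()) < 0.05

    def test_expression_terciles_monotone(self, lognormal_tcr_run):
        """TS/NTS increases across expression terciles: more transcription,
        stronger template-strand repair."""
        run = lognormal_tcr_run
        genes = filter_genes(run.genes).genes
        pg = log2_ts_nts_per_gene(run.reads, genes)
        rpkm = pd.Series({g.id: g.rpkm for g in genes})
        pg = pg.assign(rpkm=pg.gene_id.map(rpkm))
        pg["tercile"] = pd.qcut(pg.rpkm, 3, labels=[0, 1, 2])
        ratios = [
            grp.ts_count.sum() / grp.nts_count.sum()
            for _, grp in pg.groupby("tercile", observed=True)
        ]
        assert ratios[0] < ratios[1] < ratios[2]


class TestTimeCourse:
    def test_monotone_in_tcr_factor(self, sym_run, f2_run, f4_run):
        """Samples simulated at tcr_factor 1, 2, 4 give strictly increasing
        mean Log2(TS/NTS)."""
        genes = filter_genes(f2_run.genes).genes
        # runs share the config geometry, so one filtered set is comparable
        course = tcr_timecourse(
            [(1.0, sym_run.reads), (2.0, f2_run.reads), (4.0, f4_run.reads)], genes
        )
        m = course.means
        assert m[0] < m[1] < m[2]

    def test_flat_curve_at_constant_factor(self, f2_run):
        """The same factor-2 library at two time points: flat at ~1.0."""
        genes = filter_genes(f2_run.genes).genes
        course = tcr_timecourse([(1.0, f2_run.reads), (2.0, f2_run.reads)], genes)
        assert course.means[0] == course.means[1]
        assert course.means[0] == pytest.approx(1.0, abs=0.15)

    def test_single_sample(self, f2_run):
        genes = filter_genes(f2_run.genes).genes
        course = tcr_timecourse([(0.5, f2_run.reads)], genes)
        assert len(course.table) == 1

    def test_times_must_increase(self, f2_run):
        genes = filter_genes(f2_run.genes).genes
        with pytest.raises(XRSeqError, match="increasing"):
            tcr_timecourse([(2.0, f2_run.reads), (1.0, f2_run.reads)], genes)
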