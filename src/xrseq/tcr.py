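"""Transcription-coupled repair metrics.

The strand asymmetry of excision reads over gene bodies is the readout of
TCR: reads antisense to a gene's annotation derive from repair of its
template (transcribed) strand, reads on the annotated strand from the
non-transcribed strand. Genes are rescaled to a common "unit gene" axis —
25 upstream flank bins (80 bp each, 2 kb), 100 gene-body bins, 25
downstream flank bins — and per-bin RPKM is averaged over genes separately
for TS and NTS. Per-gene Log2(TS/NTS) with a pseudocount summarizes each
gene; its mean over a fixed gene filter tracks TCR strength across
time-course samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneModel, GeneSet, Genome, MappedReadSet, XRSeqError

__all__ = [
    "N_FLANK_BINS",
    "N_BODY_BINS",
    "N_BINS",
    "FLANK_BIN_BP",
    "FilterResult",
    "filter_genes",
    "assign_strand",
    "gene_bins",
    "bin_lengths_bp",
    "valid_bin_mask",
    "UnitGeneProfile",
    "unit_gene_profile",
    "body_ts_nts_ratio",
    "log2_ts_nts_per_gene",
    "TCRTimeCourse",
    "tcr_timecourse",
]

N_FLANK_BINS = 25
N_BODY_BINS = 100
N_BINS = 2 * N_FLANK_BINS + N_BODY_BINS  # 150
FLANK_BIN_BP = 80
FLANK_BP = N_FLANK_BINS * FLANK_BIN_BP  # 2 kb


# ---------------------------------------------------------------------------
# Gene filtering


@dataclass
class FilterResult:
    """Filtered gene set plus exclusion tallies."""

    genes: GeneSet
    n_input: int
    n_overlapping: int
    n_short: int
    n_low_expression: int
    n_missing_expression: int

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)


def filter_genes(
    genes: GeneSet,
    min_length: int = 1000,
    require_nonoverlapping: bool = True,
    min_rpkm: float | None = None,
) -> FilterResult:
    """Standard meta-profile gene filter.

    Keeps genes that (a) do not intersect any *other annotated gene*
    (strand-agnostic, tested against the full input set, including genes
    that fail other filters), (b) are at least *min_length* bp (half-open
    length), and, optionally last, (c) have expression >= *min_rpkm*. Genes
    lacking an expression value when *min_rpkm* is set are excluded and
    counted separately.
    """
    overlapping = genes.overlapping_ids() if require_nonoverlapping else set()
    kept: list[GeneModel] = []
    n_overlap = n_short = n_low = n_missing = 0
    for g in genes:
        if g.id in overlapping:
            n_overlap += 1
            continue
        if g.length < min_length:
            n_short += 1
            continue
        if min_rpkm is not None:
            if g.rpkm is None:
                n_missing += 1
                continue
            if g.rpkm <= min_rpkm:
                n_low += 1
                continue
        kept.append(g)
    return FilterResult(GeneSet(kept), len(genes), n_overlap, n_short, n_low, n_missing)


# ---------------------------------------------------------------------------
# Strand assignment


def assign_strand(read_strand: str, gene_strand: str) -> str:
    """"TS" iff the read maps opposite the gene's annotated strand.

    Excision products carry the sequence of the damaged/repaired strand;
    the template (transcribed) strand is antisense to the mRNA, so a read
    antisense to the gene reports template-strand repair.
    """
    return "TS" if read_strand != gene_strand else "NTS"


# ---------------------------------------------------------------------------
# Unit-gene binning


def gene_bins(positions: np.ndarray, gene: GeneModel) -> np.ndarray:
    """Map genomic positions to unit-gene bins 0..149 (-1 = outside).

    Bin 0 is always the bin 2 kb upstream of the TSS, bin 149 the bin 2 kb
    downstream of the TES, regardless of gene strand. Body bin index is
    floor(100 * offset / gene_length) clamped to [0, 99]; the final base of
    a gene whose length is not divisible by 100 maps to body bin 99.
    """
    m = np.asarray(positions, dtype=np.int64)
    gs, ge, glen = gene.start, gene.end, gene.length
    bins = np.full(len(m), -1, dtype=np.int64)

    up = (m >= gs - FLANK_BP) & (m < gs)
    bins[up] = (m[up] - (gs - FLANK_BP)) // FLANK_BIN_BP
    body = (m >= gs) & (m < ge)
    bins[body] = N_FLANK_BINS + np.minimum(
        N_BODY_BINS - 1, (N_BODY_BINS * (m[body] - gs)) // glen
    )
    down = (m >= ge) & (m < ge + FLANK_BP)
    bins[down] = N_FLANK_BINS + N_BODY_BINS + (m[down] - ge) // FLANK_BIN_BP

    if gene.strand == "-":
        inside = bins >= 0
        bins[inside] = N_BINS - 1 - bins[inside]
    return bins


def bin_lengths_bp(gene: GeneModel) -> np.ndarray:
    """bp represented by each of the 150 bins (flanks 80; body length/100)."""
    out = np.empty(N_BINS, dtype=float)
    out[:N_FLANK_BINS] = FLANK_BIN_BP
    out[N_FLANK_BINS : N_FLANK_BINS + N_BODY_BINS] = gene.length / N_BODY_BINS
    out[N_FLANK_BINS + N_BODY_BINS :] = FLANK_BIN_BP
    return out


def valid_bin_mask(gene: GeneModel, chrom_length: int) -> np.ndarray:
    """False for flank bins that extend off the chromosome (those bins are
    recorded as missing for this gene, not zero-filled)."""
    mask = np.ones(N_BINS, dtype=bool)
    for i in range(N_FLANK_BINS):  # plus-frame upstream flank bins
        if gene.start - FLANK_BP + i * FLANK_BIN_BP < 0:
            b = i if gene.strand == "+" else N_BINS - 1 - i
            mask[b] = False
    for j in range(N_FLANK_BINS):  # plus-frame downstream flank bins
        if gene.end + (j + 1) * FLANK_BIN_BP > chrom_length:
            b = N_FLANK_BINS + N_BODY_BINS + j
            if gene.strand == "-":
                b = N_BINS - 1 - b
            mask[b] = False
    return mask


@dataclass
class UnitGeneProfile:
    """150-bin TS/NTS meta-profile: mean per-bin RPKM across genes.

    ``ts``/``nts`` are the per-bin means over genes with that bin on the
    chromosome (``n_genes_per_bin`` gives the denominator).
    ``ts_counts``/``nts_counts`` are raw summed read counts per bin, kept
    for conservation checks. ``n_double_counted`` tallies read assignments
    beyond the first when flank regions of retained genes overlap.
    """

    ts: np.ndarray
    nts: np.ndarray
    n_genes: int
    n_genes_per_bin: np.ndarray
    ts_counts: np.ndarray
    nts_counts: np.ndarray
    total_mapped_reads: int
    n_assignments: int = 0
    n_double_counted: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(N_BINS),
                "ts_mean_rpkm": self.ts,
                "nts_mean_rpkm": self.nts,
                "n_genes": self.n_genes_per_bin,
            }
        )

    def swapped(self) -> "UnitGeneProfile":
        """TS and NTS exchanged (used by strand-symmetry checks)."""
        return UnitGeneProfile(
            self.nts.copy(),
            self.ts.copy(),
            self.n_genes,
            self.n_genes_per_bin.copy(),
            self.nts_counts.copy(),
            self.ts_counts.copy(),
            self.total_mapped_reads,
            self.n_assignments,
            self.n_double_counted,
        )


def unit_gene_profile(
    reads: MappedReadSet,
    genes: GeneSet,
    total_mapped_reads: int,
    genome: Genome | None = None,
) -> UnitGeneProfile:
    """Build the 150-bin TS/NTS meta-profile.

    Each read is assigned to exactly one bin of each gene whose extended
    region (gene +/- 2 kb) contains its midpoint (floor((start+end)/2));
    overlapping flanks of adjacent retained genes double-count and are
    tallied. Per-gene per-bin RPKM = count * 1e9 / (bin_bp *
    total_mapped_reads); the profile is the arithmetic mean over genes.
    Passing *genome* enables off-chromosome flank-bin masking; without it
    all bins are assumed on-chromosome.
    """
    if len(genes) == 0:
        raise XRSeqError("no genes after filtering; cannot build a unit-gene profile")
    if total_mapped_reads <= 0:
        raise XRSeqError("total_mapped_reads must be positive (RPKM library size)")

    mids = reads.midpoints
    strands = reads.strands
    # per-chromosome sorted midpoint index for fast window queries
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(reads.chroms):
        idx = np.flatnonzero(reads.chroms == chrom)
        by_chrom[str(chrom)] = idx[np.argsort(mids[idx], kind="stable")]

    ts_sum = np.zeros(N_BINS)
    nts_sum = np.zeros(N_BINS)
    n_per_bin = np.zeros(N_BINS, dtype=np.int64)
    ts_counts = np.zeros(N_BINS, dtype=np.int64)
    nts_counts = np.zeros(N_BINS, dtype=np.int64)
    assigned_per_read = np.zeros(len(reads), dtype=np.int32)

    scale = 1e9 / total_mapped_reads
    for g in genes:
        order = by_chrom.get(g.chrom)
        if order is None:
            sel = np.empty(0, dtype=np.int64)
        else:
            sorted_mids = mids[order]
            lo = np.searchsorted(sorted_mids, g.start - FLANK_BP, side="left")
            hi = np.searchsorted(sorted_mids, g.end + FLANK_BP, side="left")
            sel = order[lo:hi]
        bin_bp = bin_lengths_bp(g)
        mask = (
            valid_bin_mask(g, genome.length(g.chrom)) if genome is not None
            else np.ones(N_BINS, dtype=bool)
        )
        if len(sel) > 0:
            bins = gene_bins(mids[sel], g)
            keep = bins >= 0
            sel, bins = sel[keep], bins[keep]
            assigned_per_read[sel] += 1
            is_ts = strands[sel] != g.strand
            ts_c = np.bincount(bins[is_ts], minlength=N_BINS)
            nts_c = np.bincount(bins[~is_ts], minlength=N_BINS)
        else:
            ts_c = np.zeros(N_BINS, dtype=np.int64)
            nts_c = np.zeros(N_BINS, dtype=np.int64)
        ts_counts += ts_c
        nts_counts += nts_c
        ts_sum[mask] += ts_c[mask] * scale / bin_bp[mask]
        nts_sum[mask] += nts_c[mask] * scale / bin_bp[mask]
        n_per_bin += mask

    with np.errstate(invalid="ignore"):
        ts_mean = np.where(n_per_bin > 0, ts_sum / np.maximum(n_per_bin, 1), np.nan)
        nts_mean = np.where(n_per_bin > 0, nts_sum / np.maximum(n_per_bin, 1), np.nan)
    n_assign = int(assigned_per_read.sum())
    n_double = int(assigned_per_read[assigned_per_read > 1].sum() - np.count_nonzero(assigned_per_read > 1))
    return UnitGeneProfile(
        ts_mean,
        nts_mean,
        len(genes),
        n_per_bin,
        ts_counts,
        nts_counts,
        total_mapped_reads,
        n_assign,
        n_double,
    )


def body_ts_nts_ratio(profile: UnitGeneProfile) -> float:
    """Mean TS over the 100 body bins divided by mean NTS (ratio of means,
    robust to near-zero individual bins). NaN when the NTS mean is zero."""
    body = slice(N_FLANK_BINS, N_FLANK_BINS + N_BODY_BINS)
    ts_mean = float(np.nanmean(profile.ts[body]))
    nts_mean = float(np.nanmean(profile.nts[body]))
    if nts_mean == 0:
        return float("nan")
    return ts_mean / nts_mean


# ---------------------------------------------------------------------------
# Per-gene Log2(TS/NTS)


def log2_ts_nts_per_gene(
    reads: MappedReadSet, genes: GeneSet, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene TS/NTS body read counts and log2((ts+c)/(nts+c)).

    Counts use gene-body reads only (midpoint rule, no flanks); one row per
    gene in *genes* (apply no expression filter to plot the distribution
    over all annotated genes). The pseudocount keeps ratios finite;
    ts = nts = 0 gives exactly 0.
    """
    if pseudocount <= 0:
        raise XRSeqError("pseudocount must be > 0 to keep log-ratios finite")
    mids = reads.midpoints
    rows = []
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(reads.chroms):
        idx = np.flatnonzero(reads.chroms == chrom)
        by_chrom[str(chrom)] = idx[np.argsort(mids[idx], kind="stable")]
    for g in genes:
        order = by_chrom.get(g.chrom)
        if order is None:
            ts = nts = 0
        else:
            sorted_mids = mids[order]
            lo = np.searchsorted(sorted_mids, g.start, side="left")
            hi = np.searchsorted(sorted_mids, g.end, side="left")
            sel = order[lo:hi]
            is_ts = reads.strands[sel] != g.strand
            ts = int(np.count_nonzero(is_ts))
            nts = len(sel) - ts
        rows.append(
            {
                "gene_id": g.id,
                "ts_count": ts,
                "nts_count": nts,
                "gene_length": g.length,
                "log2_ratio": float(
                    np.log2((ts + pseudocount) / (nts + pseudocount))
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time course


@dataclass
class TCRTimeCourse:
    """Ordered (time, mean Log2(TS/NTS), n_genes) samples on one gene filter."""

    table: pd.DataFrame  # columns: time, mean_log2_ts_nts, n_genes

    @property
    def times(self) -> np.ndarray:
        return self.table["time"].to_numpy()

    @property
    def means(self) -> np.ndarray:
        return self.table["mean_log2_ts_nts"].to_numpy()


def tcr_timecourse(
    samples: list[tuple[float, MappedReadSet]],
    genes: GeneSet,
    pseudocount: float = 1.0,
) -> TCRTimeCourse:
    """Mean per-gene Log2(TS/NTS) per time point, on one fixed gene filter.

    All samples are analyzed against the same *genes* (the comparability
    contract); times must be strictly increasing.
    """
    if not samples:
        raise XRSeqError("no samples")
    times = [t for t, _ in samples]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise XRSeqError("sample times must be strictly increasing")
    rows = []
    for t, reads in samples:
        per_gene = log2_ts_nts_per_gene(reads, genes, pseudocount)
        rows.append(
            {
                "time": t,
                "mean_log2_ts_nts": float(per_gene["log2_ratio"].mean()),
                "n_genes": len(per_gene),
            }
        )
    return TCRTimeCourse(pd.DataFrame(rows))
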