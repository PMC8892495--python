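"""Sequence-derived expected-damage landscapes.

Repair meta-profiles inherit structure from where lesions *can* form: in an
A/T-rich genome the GpG dinucleotides required for cisplatin crosslinks are
depleted around A/T-rich features (e.g. promoters and terminators), so raw
repair signal dips there even if repair per lesion is uniform. This module
counts damage-motif occurrences per unit-gene bin — the expected-damage
density — and divides observed repair by it, separating sequence-driven
structure from repair-driven structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneSet, Genome, XRSeqError, revcomp
from .tcr import (
    N_BINS,
    UnitGeneProfile,
    bin_lengths_bp,
    gene_bins,
    valid_bin_mask,
)

__all__ = ["SiteDensityProfile", "site_density_profile", "observed_over_expected"]


@dataclass
class SiteDensityProfile:
    """150-bin mean motif sites per bp per gene, split TS/NTS.

    Bin layout is identical to :class:`~xrseq.tcr.UnitGeneProfile`. A motif
    occurrence is assigned TS when the strand carrying it is the template
    strand of the gene (opposite the annotated strand), NTS otherwise, and
    binned by its 5' base.
    """

    ts: np.ndarray
    nts: np.ndarray
    n_genes: int
    n_genes_per_bin: np.ndarray
    motifs: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(N_BINS),
                "ts_sites_per_bp": self.ts,
                "nts_sites_per_bp": self.nts,
                "n_genes": self.n_genes_per_bin,
            }
        )


def _motif_positions(seq_arr: np.ndarray, motif: str, strand: str) -> np.ndarray:
    """Offsets (within seq_arr) of the motif's 5' base on *strand*.

    On the - strand a motif occupying plus offsets [i, i+k) reads as
    revcomp(motif) on the + reference and its 5' base sits at offset i+k-1.
    """
    probe = (motif if strand == "+" else revcomp(motif)).encode("ascii")
    k = len(probe)
    if len(seq_arr) < k:
        return np.empty(0, dtype=np.int64)
    hit = np.ones(len(seq_arr) - k + 1, dtype=bool)
    for j in range(k):
        hit &= seq_arr[j : len(seq_arr) - k + 1 + j] == probe[j : j + 1]
    pos = np.flatnonzero(hit)
    return pos if strand == "+" else pos + k - 1


def site_density_profile(
    genome: Genome, genes: GeneSet, motifs: tuple[str, ...] | list[str]
) -> SiteDensityProfile:
    """Expected-damage density per unit-gene bin.

    Scans both strands of each gene's extended region (gene +/- 2 kb) for
    fixed-length motifs over {A,C,G,T}; each occurrence is binned by its 5'
    base and divided by bin bp, then averaged over genes. Off-chromosome
    flank bins are excluded from the mean (missing, not zero).
    """
    motifs = tuple(m.upper() for m in motifs)
    if not motifs:
        raise XRSeqError("empty motif set")
    for m in motifs:
        if not m or any(b not in "ACGT" for b in m):
            raise XRSeqError(f"motif {m!r} must be a nonempty string over A/C/G/T")
    if len(genes) == 0:
        raise XRSeqError("no genes; cannot build a site-density profile")

    from .tcr import FLANK_BP

    ts_sum = np.zeros(N_BINS)
    nts_sum = np.zeros(N_BINS)
    n_per_bin = np.zeros(N_BINS, dtype=np.int64)

    for g in genes:
        clen = genome.length(g.chrom)
        win_start = max(0, g.start - FLANK_BP)
        win_end = min(clen, g.end + FLANK_BP)
        seq = genome[g.chrom][win_start:win_end]
        seq_arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        bin_bp = bin_lengths_bp(g)
        mask = valid_bin_mask(g, clen)
        for strand in "+-":
            pos_all = [
                _motif_positions(seq_arr, m, strand) + win_start for m in motifs
            ]
            pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
            bins = gene_bins(pos, g)
            bins = bins[bins >= 0]
            counts = np.bincount(bins, minlength=N_BINS)
            is_ts = strand != g.strand  # template strand is antisense to the mRNA
            target = ts_sum if is_ts else nts_sum
            target[mask] += counts[mask] / bin_bp[mask]
        n_per_bin += mask

    ts_mean = np.where(n_per_bin > 0, ts_sum / np.maximum(n_per_bin, 1), np.nan)
    nts_mean = np.where(n_per_bin > 0, nts_sum / np.maximum(n_per_bin, 1), np.nan)
    return SiteDensityProfile(ts_mean, nts_mean, len(genes), n_per_bin, motifs)


def observed_over_expected(
    repair: UnitGeneProfile, expected: SiteDensityProfile
) -> pd.DataFrame:
    """Elementwise observed-repair / expected-site-density per strand class.

    Bins with zero (or missing) expected density are reported as missing
    (NaN), never infinity. Flat ratios indicate purely sequence-driven
    structure in the raw repair profile.
    """
    if len(repair.ts) != N_BINS or len(expected.ts) != N_BINS:
        raise XRSeqError("bin layout mismatch between repair and expected profiles")
    with np.errstate(divide="ignore", invalid="ignore"):
        ts_ratio = np.where(expected.ts > 0, repair.ts / expected.ts, np.nan)
        nts_ratio = np.where(expected.nts > 0, repair.nts / expected.nts, np.nan)
    return pd.DataFrame(
        {
            "bin": np.arange(N_BINS),
            "ts_ratio": ts_ratio,
            "nts_ratio": nts_ratio,
        }
    )
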