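"""Figure conveniences mirroring the standard XR-seq panels.

Figures are side outputs; the TSV tables are the stable machine interface.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .landscape import SiteDensityProfile
from .profiling import BASES, LengthDistribution, PositionFrequencyMatrix
from .tcr import N_BINS, N_BODY_BINS, N_FLANK_BINS, UnitGeneProfile

__all__ = [
    "plot_length_distribution",
    "plot_pfm",
    "plot_unit_gene_profile",
    "plot_landscape_overlay",
]

_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_length_distribution(dist: LengthDistribution, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    fr = dist.fractions
    ax.bar(list(fr), [100 * v for v in fr.values()], color="0.3")
    ax.set_xlabel("excision product length (nt)")
    ax.set_ylabel("percent of total reads")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pfm(pfm: PositionFrequencyMatrix, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(1, pfm.read_length + 1)
    for bi, b in enumerate(BASES):
        ax.plot(x, pfm.freqs[:, bi], label=b, color=_BASE_COLORS[b], lw=1.5)
    ax.set_xlabel("position (5' end = 1)")
    ax.set_ylabel("relative frequency")
    ax.set_title(f"{pfm.read_length}-nt products, n={pfm.n_reads}")
    ax.legend(ncols=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _unit_gene_xticks(ax):
    ax.set_xticks([0, N_FLANK_BINS, N_FLANK_BINS + N_BODY_BINS, N_BINS - 1])
    ax.set_xticklabels(["-2 kb", "TSS", "TES", "+2 kb"])


def plot_unit_gene_profile(profile: UnitGeneProfile, path) -> None:
    """TS in blue, NTS in red, on the 150-bin unit-gene axis."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = np.arange(N_BINS)
    ax.plot(x, profile.ts, color="tab:blue", label="TS")
    ax.plot(x, profile.nts, color="tab:red", label="NTS")
    _unit_gene_xticks(ax)
    ax.set_ylabel("mean RPKM per bin")
    ax.set_title(f"unit gene, n={profile.n_genes} genes")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_landscape_overlay(
    repair: UnitGeneProfile, expected: SiteDensityProfile, path
) -> None:
    """Expected motif density under the observed repair meta-profile."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    x = np.arange(N_BINS)
    ax.plot(x, repair.ts, color="tab:blue", label="repair TS")
    ax.plot(x, repair.nts, color="tab:red", label="repair NTS")
    ax2 = ax.twinx()
    ax2.plot(x, expected.ts, color="tab:blue", ls="--", alpha=0.5, label="sites TS")
    ax2.plot(x, expected.nts, color="tab:red", ls="--", alpha=0.5, label="sites NTS")
    _unit_gene_xticks(ax)
    ax.set_ylabel("mean RPKM per bin")
    ax2.set_ylabel(f"motif sites per bp ({'/'.join(expected.motifs)})")
    ax.legend(loc="upper left", fontsize=8)
    ax2.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
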