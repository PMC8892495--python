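"""Ground-truth simulator for excision-repair sequencing.

Emulates the physical chain behind an XR-seq experiment on a toy genome:

1. **Damage formation.** Lesions form at dinucleotide motifs — GG for
   cisplatin-d(GpG) intrastrand crosslinks, dipyrimidines (TT/TC/CT/CC,
   TT-heaviest) for UV photoproducts (CPD and (6-4)PP) — on either strand.
2. **Transcription-coupled repair.** Lesions on the template strand of an
   annotated gene (the strand complementary to the mRNA) are excised at an
   enhanced rate: the sampling weight of such a site is multiplied by
   ``1 + (tcr_factor - 1) * f(rpkm)`` where ``f`` is a saturating-linear
   function of expression (1 at or above the 95th percentile of RPKM).
3. **Dual-incision geometry.** The excision nuclease cuts ~20 nt 5' and
   6 nt 3' of the lesion, releasing a 24-32 nt oligomer. With read-local
   1-based positions, a length-L cisplatin product carries the lesion's 5'
   base at position L-7 (for L=28: lesion at 21-22, i.e. 20 nt 5' and 6 nt
   3' of the GG). UV photoproducts use an even mixture of registers L-8 and
   L-7, which reproduces both the enriched positions 20-22 of 28-mers and
   the 19-nt 5' / 6-nt 3' incision offsets. A single 2-nt lesion register
   cannot produce a 3-position enrichment window, hence the mixture.
4. **Background.** A configurable fraction of reads are uniform random
   genomic fragments with the same length law and no lesion — setting
   ``background_fraction=1`` emulates a repair-null (XPC knockout-like)
   library of sheared fragments.

Every read is emitted together with a truth record (coordinates, strand,
read-local lesion positions, source gene) so downstream estimators can be
validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    GeneModel,
    GeneSet,
    GeometryError,
    Genome,
    MappedReadSet,
    PlacementError,
    revcomp,
)

__all__ = [
    "DamageType",
    "SimulationConfig",
    "make_genome",
    "place_genes",
    "simulate_excision_reads",
    "impose_at_rich_blocks",
    "simulate",
    "SimulationResult",
    "DEFAULT_LENGTH_WEIGHTS",
    "DAMAGE_MOTIFS",
    "DAMAGE_BASES",
]


class DamageType(str, Enum):
    CPD = "CPD"
    SIX_FOUR = "SIX_FOUR"
    CISPLATIN = "CISPLATIN"


#: Lesion dinucleotide motifs (on the lesion strand) and default relative
#: weights. CPDs form most readily at TT; cisplatin crosslinks GpG.
DAMAGE_MOTIFS: dict[DamageType, dict[str, float]] = {
    DamageType.CPD: {"TT": 0.5, "TC": 0.2, "CT": 0.2, "CC": 0.1},
    DamageType.SIX_FOUR: {"TT": 0.4, "TC": 0.4, "CT": 0.1, "CC": 0.1},
    DamageType.CISPLATIN: {"GG": 1.0},
}

#: Single bases whose per-position frequency is elevated at the lesion.
DAMAGE_BASES: dict[DamageType, tuple[str, ...]] = {
    DamageType.CPD: ("C", "T"),
    DamageType.SIX_FOUR: ("C", "T"),
    DamageType.CISPLATIN: ("G",),
}

#: Default excision-product length laws (support 24-32 nt). UV photoproducts
#: peak at 27 nt, cisplatin at 28 nt; lengths 26-29 predominate.
DEFAULT_LENGTH_WEIGHTS: dict[DamageType, dict[int, float]] = {
    DamageType.CPD: {24: 0.03, 25: 0.07, 26: 0.18, 27: 0.27, 28: 0.20,
                     29: 0.13, 30: 0.07, 31: 0.03, 32: 0.02},
    DamageType.SIX_FOUR: {24: 0.03, 25: 0.07, 26: 0.18, 27: 0.27, 28: 0.20,
                          29: 0.13, 30: 0.07, 31: 0.03, 32: 0.02},
    DamageType.CISPLATIN: {24: 0.02, 25: 0.05, 26: 0.13, 27: 0.20, 28: 0.28,
                           29: 0.18, 30: 0.08, 31: 0.04, 32: 0.02},
}

# Keep lesions this far from chromosome ends so every register fits.
_EDGE_MARGIN = 35


@dataclass
class SimulationConfig:
    """Stated world for one synthetic XR-seq experiment.

    Defaults model a fly-like A/T-rich genome (GC 0.43) at desk scale, a
    cisplatin-strength transcription-coupled repair enhancement of 2 on
    template strands, and damage-type-specific excision length laws.
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    gc_content: float = 0.43
    n_genes: int = 50
    n_short_genes: int = 0          # sub-1-kb genes (fail the length filter)
    n_overlapping_pairs: int = 0    # antisense overlapping pairs (fail the overlap filter)
    gene_length_range: tuple[int, int] = (1_200, 6_000)
    short_gene_length_range: tuple[int, int] = (300, 999)
    intergenic_min: int = 500
    expression_law: tuple = ("lognormal", 3.0, 1.0)  # or ("constant", value), RPKM-like
    damage_type: DamageType = DamageType.CPD
    motif_weights: dict[str, float] | None = None  # default: DAMAGE_MOTIFS[damage_type]
    n_reads: int = 100_000
    tcr_factor: float = 2.0
    length_weights: dict[int, float] | None = None  # default per damage type
    background_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.damage_type, str):
            self.damage_type = DamageType(self.damage_type)
        if self.genome_length < 10_000:
            raise ConfigError("genome_length must be >= 10,000")
        if not (0 < self.gc_content < 1):
            raise ConfigError("gc_content must be strictly between 0 and 1")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.tcr_factor < 0:
            raise ConfigError("tcr_factor must be >= 0")
        if not (0 <= self.background_fraction <= 1):
            raise ConfigError("background_fraction must be in [0, 1]")
        if self.n_genes < self.n_short_genes + 2 * self.n_overlapping_pairs:
            raise ConfigError(
                "n_genes must cover n_short_genes + 2 * n_overlapping_pairs"
            )
        lw = self.resolved_length_weights()
        total = sum(lw.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"length_weights must sum to 1, got {total}")
        if any(not (24 <= L <= 32) for L in lw):
            raise ConfigError("length_weights support must lie within [24, 32]")
        if any(w < 0 for w in lw.values()):
            raise ConfigError("length_weights must be non-negative")

    def resolved_length_weights(self) -> dict[int, float]:
        return dict(
            self.length_weights
            if self.length_weights is not None
            else DEFAULT_LENGTH_WEIGHTS[self.damage_type]
        )

    def resolved_motif_weights(self) -> dict[str, float]:
        w = dict(
            self.motif_weights
            if self.motif_weights is not None
            else DAMAGE_MOTIFS[self.damage_type]
        )
        total = sum(w.values())
        if total <= 0:
            raise ConfigError("motif weights must have positive total")
        return {m: v / total for m, v in w.items()}


def make_genome(config: SimulationConfig) -> Genome:
    """Sample an i.i.d. genome at the configured GC content.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2, so base composition is
    strand-symmetric; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    per_chrom = config.genome_length // config.n_chromosomes
    seqs = {}
    for c in range(config.n_chromosomes):
        n = per_chrom if c < config.n_chromosomes - 1 else (
            config.genome_length - per_chrom * (config.n_chromosomes - 1)
        )
        arr = rng.choice(bases, size=n, p=probs)
        seqs[f"chr{c + 1}"] = arr.tobytes().decode("ascii")
    return Genome(seqs)


def place_genes(genome: Genome, config: SimulationConfig) -> GeneSet:
    """Place stranded genes with expression values on the genome.

    Emits three classes: (a) isolated genes >= 1 kb (pass the standard
    non-overlap + length filter), (b) ``n_short_genes`` isolated sub-1-kb
    genes, and (c) ``n_overlapping_pairs`` antisense overlapping gene pairs.
    Classes (b) and (c) exist to exercise the gene filters downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_regular = config.n_genes - config.n_short_genes - 2 * config.n_overlapping_pairs

    # Job list: each job places one isolated gene or one overlapping pair.
    jobs = (
        ["regular"] * n_regular
        + ["short"] * config.n_short_genes
        + ["pair"] * config.n_overlapping_pairs
    )
    rng.shuffle(jobs)

    cursors = {name: config.intergenic_min for name in genome.names}
    chrom_cycle = list(genome.names)
    genes: list[GeneModel] = []
    gid = 0

    def _next_id() -> str:
        nonlocal gid
        gid += 1
        return f"gene_{gid:04d}"

    def _strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    def _glen(kind: str) -> int:
        lo, hi = (
            config.short_gene_length_range if kind == "short" else config.gene_length_range
        )
        return int(rng.integers(lo, hi + 1))

    for job in jobs:
        placed = False
        for _ in range(len(chrom_cycle)):
            chrom = chrom_cycle[0]
            chrom_cycle.append(chrom_cycle.pop(0))
            cur = cursors[chrom]
            if job == "pair":
                len_a = _glen("regular")
                len_b = _glen("regular")
                start_a = cur
                start_b = start_a + len_a // 2  # antisense partner overlaps gene A
                span_end = max(start_a + len_a, start_b + len_b)
            else:
                glen = _glen(job)
                start_a = cur
                span_end = start_a + glen
            if span_end + config.intergenic_min > genome.length(chrom):
                continue
            if job == "pair":
                s = _strand()
                anti = "-" if s == "+" else "+"
                genes.append(GeneModel(_next_id(), chrom, start_a, start_a + len_a, s))
                genes.append(GeneModel(_next_id(), chrom, start_b, start_b + len_b, anti))
            else:
                genes.append(GeneModel(_next_id(), chrom, start_a, span_end, _strand()))
            cursors[chrom] = span_end + config.intergenic_min + int(rng.integers(0, 500))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"genome of {genome.total_length:,} bp too small to place {config.n_genes} "
                f"genes with intergenic_min={config.intergenic_min}"
            )

    law = config.expression_law
    if law[0] == "lognormal":
        rpkms = rng.lognormal(mean=law[1], sigma=law[2], size=len(genes))
    elif law[0] == "constant":
        rpkms = np.full(len(genes), float(law[1]))
    else:
        raise ConfigError(f"unknown expression_law {law[0]!r}")
    genes = [replace(g, rpkm=float(r)) for g, r in zip(genes, rpkms)]
    return GeneSet(genes)


# ---------------------------------------------------------------------------
# Lesion-site enumeration


def _motif_sites(seq_arr: np.ndarray, motif: str, strand: str) -> np.ndarray:
    """Genomic coordinates of the lesion's 5' base for *motif* on *strand*.

    A motif on the - strand occupying plus coords [i, i+2) reads as
    revcomp(motif) on the + reference; its 5' base (in - orientation) sits
    at plus coordinate i+1.
    """
    probe = motif if strand == "+" else revcomp(motif)
    hits = np.flatnonzero(
        (seq_arr[:-1] == probe[0].encode()) & (seq_arr[1:] == probe[1].encode())
    )
    return hits if strand == "+" else hits + 1


def _expression_scale(genes: GeneSet) -> dict[str, float]:
    """Saturating-linear expression response f(rpkm) = min(rpkm, P95)/P95."""
    rpkms = np.array([g.rpkm if g.rpkm is not None else 0.0 for g in genes])
    if len(rpkms) == 0:
        return {}
    p95 = float(np.percentile(rpkms, 95))
    if p95 <= 0:
        return {g.id: 0.0 for g in genes}
    return {g.id: float(min(g.rpkm or 0.0, p95) / p95) for g in genes}


def simulate_excision_reads(
    genome: Genome, genes: GeneSet, config: SimulationConfig
) -> tuple[MappedReadSet, pd.DataFrame]:
    """Sample excision-product reads and their ground truth.

    Returns the mapped read set and a truth table with one row per read:
    chrom, start, end (0-based half-open), strand, read-local 1-based
    lesion positions ("p,p+1", empty for background), lesion motif, source
    gene id ("." if intergenic), and an is_background flag.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    motif_w = config.resolved_motif_weights()
    length_w = config.resolved_length_weights()
    lengths_support = np.array(sorted(length_w), dtype=np.int64)
    lengths_p = np.array([length_w[int(L)] for L in lengths_support])

    min_L = int(lengths_support[lengths_p > 0].min())
    if config.damage_type is DamageType.CISPLATIN:
        min_register = min_L - 7
    else:
        min_register = min_L - 8
    if min_register < 1:
        raise GeometryError(
            f"length {min_L} too short for the incision register "
            "(lesion would fall outside the read)"
        )

    n_background = int(rng.binomial(config.n_reads, config.background_fraction))
    n_lesion = config.n_reads - n_background

    # --- enumerate lesion sites genome-wide ------------------------------
    site_chrom_idx: list[np.ndarray] = []
    site_pos: list[np.ndarray] = []
    site_strand: list[np.ndarray] = []  # 0 -> '+', 1 -> '-'
    site_weight: list[np.ndarray] = []
    site_motif_idx: list[np.ndarray] = []
    motifs = sorted(motif_w)

    chrom_names = genome.names
    for ci, chrom in enumerate(chrom_names):
        seq = genome[chrom]
        seq_arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
        clen = len(seq)
        for si, strand in enumerate("+-"):
            for mi, motif in enumerate(motifs):
                pos = _motif_sites(seq_arr, motif, strand)
                pos = pos[(pos >= _EDGE_MARGIN) & (pos < clen - _EDGE_MARGIN)]
                if len(pos) == 0:
                    continue
                site_chrom_idx.append(np.full(len(pos), ci, dtype=np.int32))
                site_pos.append(pos.astype(np.int64))
                site_strand.append(np.full(len(pos), si, dtype=np.int8))
                site_weight.append(np.full(len(pos), motif_w[motif]))
                site_motif_idx.append(np.full(len(pos), mi, dtype=np.int8))

    if n_lesion > 0 and not site_pos:
        raise PlacementError(
            f"no {config.damage_type.value} lesion motif sites found in the genome"
        )

    reads_chrom: list[str] = []
    reads_start = np.empty(config.n_reads, dtype=np.int64)
    reads_end = np.empty(config.n_reads, dtype=np.int64)
    reads_strand = np.empty(config.n_reads, dtype=object)
    lesion_pos = np.zeros(config.n_reads, dtype=np.int64)  # 0 => background
    motif_col: list[str] = []
    source_gene: list[str] = []

    if n_lesion > 0:
        chrom_idx = np.concatenate(site_chrom_idx)
        pos5 = np.concatenate(site_pos)
        strand_idx = np.concatenate(site_strand)
        weight = np.concatenate(site_weight)
        motif_idx = np.concatenate(site_motif_idx)

        # TCR: template-strand sites inside gene bodies get an enhanced
        # weight 1 + (tcr_factor - 1) * f(rpkm).
        expr_scale = _expression_scale(genes)
        gene_of_site = np.full(len(pos5), -1, dtype=np.int64)
        gene_list = list(genes)
        for gi, g in enumerate(gene_list):
            ci = chrom_names.index(g.chrom)
            in_gene = (chrom_idx == ci) & (pos5 >= g.start) & (pos5 < g.end)
            template_si = 1 if g.strand == "+" else 0  # template is antisense to mRNA
            on_template = in_gene & (strand_idx == template_si)
            mult = 1.0 + (config.tcr_factor - 1.0) * expr_scale[g.id]
            weight = np.where(on_template, weight * mult, weight)
            # later genes win on (rare) containment by construction genes
            # do not overlap except engineered antisense pairs
            gene_of_site = np.where(in_gene, gi, gene_of_site)

        p = weight / weight.sum()
        picks = rng.choice(len(pos5), size=n_lesion, p=p)
        L = rng.choice(lengths_support, size=n_lesion, p=lengths_p)

        if config.damage_type is DamageType.CISPLATIN:
            register = L - 7
        else:
            register = L - 8 + rng.integers(0, 2, size=n_lesion)  # even {L-8, L-7} mix

        pk_pos5 = pos5[picks]
        pk_strand = strand_idx[picks]
        starts = np.where(
            pk_strand == 0,
            pk_pos5 - (register - 1),
            pk_pos5 + register - L,
        )
        ends = starts + L

        reads_start[:n_lesion] = starts
        reads_end[:n_lesion] = ends
        for i in range(n_lesion):
            reads_chrom.append(chrom_names[chrom_idx[picks[i]]])
            motif_col.append(motifs[motif_idx[picks[i]]])
            gi = gene_of_site[picks[i]]
            source_gene.append(gene_list[gi].id if gi >= 0 else ".")
        reads_strand[:n_lesion] = np.where(pk_strand == 0, "+", "-")
        lesion_pos[:n_lesion] = register

    if n_background > 0:
        clens = np.array([genome.length(c) for c in chrom_names], dtype=np.float64)
        cp = clens / clens.sum()
        bci = rng.choice(len(chrom_names), size=n_background, p=cp)
        bL = rng.choice(lengths_support, size=n_background, p=lengths_p)
        bstart = np.empty(n_background, dtype=np.int64)
        for i in range(n_background):
            bstart[i] = rng.integers(0, clens[bci[i]] - bL[i] + 1)
        reads_start[n_lesion:] = bstart
        reads_end[n_lesion:] = bstart + bL
        reads_strand[n_lesion:] = np.where(
            rng.integers(0, 2, size=n_background) == 0, "+", "-"
        )
        for i in range(n_background):
            reads_chrom.append(chrom_names[bci[i]])
            motif_col.append(".")
            source_gene.append(".")

    # extract sequences (lesion-strand orientation)
    sequences = []
    for i in range(config.n_reads):
        s = genome[reads_chrom[i]][reads_start[i] : reads_end[i]]
        sequences.append(s if reads_strand[i] == "+" else revcomp(s))

    names = [f"read_{i:07d}" for i in range(config.n_reads)]
    reads = MappedReadSet(
        reads_chrom, reads_start, reads_end, reads_strand, sequences, names
    )

    is_background = np.zeros(config.n_reads, dtype=bool)
    is_background[n_lesion:] = True
    lesion_str = [
        "" if is_background[i] else f"{lesion_pos[i]},{lesion_pos[i] + 1}"
        for i in range(config.n_reads)
    ]
    truth = pd.DataFrame(
        {
            "read_id": names,
            "chrom": reads_chrom,
            "start": reads_start,
            "end": reads_end,
            "strand": reads_strand.astype(str),
            "lesion_positions": lesion_str,
            "damage_type": np.where(is_background, ".", config.damage_type.value),
            "motif": motif_col,
            "source_gene": source_gene,
            "is_background": is_background.astype(int),
        }
    )
    return reads, truth


def impose_at_rich_blocks(
    genome: Genome,
    genes: GeneSet,
    gc_content: float = 0.10,
    halfwidth: int = 400,
    seed: int = 0,
) -> Genome:
    """Rewrite +/- *halfwidth* bp around every TSS and TES as A/T-rich sequence.

    Emulates the compositional structure of fly-like promoters/terminators:
    A/T-rich blocks deplete the GG dinucleotides needed for cisplatin
    crosslinks, so raw repair profiles dip there even when repair per lesion
    is uniform. Returns a new genome; the input is not modified.
    """
    if not (0 < gc_content < 1):
        raise ConfigError("gc_content must be strictly between 0 and 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    probs = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    arrs = {
        c: np.frombuffer(genome[c].encode("ascii"), dtype="S1").copy()
        for c in genome.names
    }
    for g in genes:
        for center in (g.start, g.end):
            lo = max(0, center - halfwidth)
            hi = min(genome.length(g.chrom), center + halfwidth)
            arrs[g.chrom][lo:hi] = rng.choice(bases, size=hi - lo, p=probs)
    return Genome({c: a.tobytes().decode("ascii") for c, a in arrs.items()})


@dataclass
class SimulationResult:
    """Everything one synthetic run produces."""

    config: SimulationConfig
    genome: Genome
    genes: GeneSet
    reads: MappedReadSet
    truth: pd.DataFrame


def simulate(config: SimulationConfig) -> SimulationResult:
    """End-to-end synthetic run: genome -> genes -> reads (+truth)."""
    genome = make_genome(config)
    genes = place_genes(genome, config)
    reads, truth = simulate_excision_reads(genome, genes, config)
    return SimulationResult(config, genome, genes, reads, truth)
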