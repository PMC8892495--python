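"""Readers/writers for the standard formats the pipeline touches, plus a
toy-scale unique exact-match mapper for the synthetic path.

All parsers reject malformed records with :class:`~xrseq.core.FormatError`
rather than silently coercing; per-file reject tallies are returned where
records can legitimately be dropped (out-of-bounds reads, multi-mappers).
Gzip is handled transparently by file suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    FormatError,
    GeneModel,
    GeneSet,
    Genome,
    MappedReadSet,
    revcomp,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_bed12",
    "write_gff3",
    "read_expression",
    "write_expression",
    "read_reads_bed",
    "write_reads_bed",
    "write_reads_fasta",
    "RejectTally",
    "map_reads_exact",
    "MapperResult",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Genome:
    """Read a (possibly gzipped) FASTA into a :class:`Genome`; sequences are
    case-folded to uppercase. Duplicate headers are a format error."""
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise FormatError(f"duplicate FASTA header: {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"no FASTA records in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()),
            fh,
            "fasta",
        )


# ---------------------------------------------------------------------------
# Gene annotation (BED12 / GFF3)


def _parse_bed12(path) -> list[GeneModel]:
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: BED needs >= 6 columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end_i <= start_i:
                raise FormatError(f"{path}:{lineno}: end <= start")
            genes.append(GeneModel(name, chrom, start_i, end_i, strand))
    return genes


def _parse_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise FormatError(f"GFF3 gene at {feat.seqid}:{feat.start} has no ID attribute")
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"gene {ids[0]}: strand {feat.strand!r} — a defined strand is required "
                "for TS/NTS assignment"
            )
        # GFF3 is 1-based closed; convert to 0-based half-open.
        genes.append(GeneModel(ids[0], feat.seqid, feat.start - 1, feat.end, feat.strand))
    return genes


def read_annotation(path, dialect: str | None = None) -> GeneSet:
    """Read gene models from BED12 (or BED6) or GFF3.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Genes with undefined strand are rejected: strand is essential for
    transcribed/non-transcribed strand analysis.
    """
    path = Path(path)
    if dialect is None:
        name = path.name.removesuffix(".gz")
        if name.endswith((".gff", ".gff3")):
            dialect = "GFF3"
        elif name.endswith(".bed"):
            dialect = "BED12"
        else:
            raise FormatError(f"cannot infer annotation dialect from {path.name!r}")
    dialect = dialect.upper()
    if dialect in ("BED12", "BED6", "BED"):
        return GeneSet(_parse_bed12(path))
    if dialect == "GFF3":
        return GeneSet(_parse_gff3(path))
    raise FormatError(f"unknown annotation dialect {dialect!r}")


def write_bed12(genes: GeneSet, path) -> None:
    """Write genes as BED12 (single block; thickStart/thickEnd unused)."""
    with _open_text(path, "wt") as fh:
        for g in genes:
            fields = [
                g.chrom,
                str(g.start),
                str(g.end),
                g.id,
                "0",
                g.strand,
                str(g.start),
                str(g.end),
                "0",
                "1",
                f"{g.length},",
                "0,",
            ]
            fh.write("\t".join(fields) + "\n")


def write_gff3(genes: GeneSet, path, source: str = "xrseq") -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        source,
                        "gene",
                        str(g.start + 1),  # 1-based closed
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression table


def read_expression(path) -> dict[str, float]:
    """Read a two-column TSV (gene_id, rpkm) into a dict."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "rpkm" not in cols:
        raise FormatError(f"{path}: expected columns gene_id and rpkm, got {list(df.columns)}")
    out = dict(zip(df[cols["gene_id"]].astype(str), df[cols["rpkm"]].astype(float)))
    if any(v < 0 for v in out.values()):
        raise FormatError(f"{path}: negative RPKM value")
    return out


def write_expression(rpkm: dict[str, float], path) -> None:
    pd.DataFrame({"gene_id": list(rpkm), "rpkm": list(rpkm.values())}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Reads (BED6 + sequences)


@dataclass
class RejectTally:
    """Counts of records dropped by a reader, by reason."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def read_reads_bed(path, genome: Genome) -> tuple[MappedReadSet, RejectTally]:
    """Read BED6 reads and extract sequences from the named strand.

    Sequences are the genomic slice for ``+`` reads and its reverse
    complement for ``-`` reads (lesion-strand orientation). Reads outside
    chromosome bounds are dropped and tallied; an unknown chromosome is a
    hard error naming it.
    """
    rejects = RejectTally()
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    seqs: list[str] = []
    names: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[:6]
            if chrom not in genome:
                raise FormatError(f"{path}:{lineno}: chromosome {chrom!r} not in genome")
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if e <= s:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            if s < 0 or e > genome.length(chrom):
                rejects.add("out_of_bounds")
                continue
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
            strands.append(strand)
            seqs.append(genome.fetch(chrom, s, e, strand))
            names.append(name)
    reads = MappedReadSet(
        chroms,
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(strands, dtype=object),
        seqs,
        names,
    )
    return reads, rejects


def write_reads_bed(reads: MappedReadSet, path) -> None:
    with _open_text(path, "wt") as fh:
        for i in range(len(reads)):
            fh.write(
                f"{reads.chroms[i]}\t{reads.starts[i]}\t{reads.ends[i]}\t"
                f"{reads.names[i]}\t0\t{reads.strands[i]}\n"
            )


def write_reads_fasta(reads: MappedReadSet, path) -> None:
    """Read sequences keyed by read name (lesion-strand orientation)."""
    with _open_text(path, "wt") as fh:
        for i in range(len(reads)):
            fh.write(f">{reads.names[i]}\n{reads.sequences[i]}\n")


# ---------------------------------------------------------------------------
# Toy unique exact-match mapper


@dataclass
class MapperResult:
    reads: MappedReadSet
    n_unmapped: int
    n_multimapped: int


_DEFAULT_GENOME_CAP = 10_000_000
_SEED_LEN = 20


def map_reads_exact(
    genome: Genome,
    sequences: dict[str, str],
    max_genome_size: int = _DEFAULT_GENOME_CAP,
) -> MapperResult:
    """Map read sequences to their unique exact genomic locus.

    A read is reported iff its sequence (or reverse complement) occurs at
    exactly one locus genome-wide; multi-locus and zero-locus reads are
    dropped and tallied. Substring-index based and intended for toy genomes:
    genomes above *max_genome_size* are refused with a pointer to a real
    aligner.

    Parameters
    ----------
    sequences
        Mapping read name -> sequence (>= 20 nt, 5'->3' on the sequenced
        strand).
    """
    from .core import ConfigError

    if genome.total_length > max_genome_size:
        raise ConfigError(
            f"genome of {genome.total_length:,} bp exceeds the toy mapper's cap of "
            f"{max_genome_size:,} bp; use a real aligner (bwa/minimap2) and supply "
            "uniquely-mapped BED"
        )
    for name, seq in sequences.items():
        if len(seq) < _SEED_LEN:
            raise FormatError(f"read {name!r} shorter than {_SEED_LEN} nt")

    # Seed index: 20-mer -> list of (chrom, pos). Collisions resolved by
    # full-sequence extension below.
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        for i in range(len(seq) - _SEED_LEN + 1):
            index.setdefault(seq[i : i + _SEED_LEN], []).append((chrom, i))

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    out_seqs: list[str] = []
    names: list[str] = []
    n_unmapped = 0
    n_multi = 0

    for name, seq in sequences.items():
        seq = seq.upper()
        hits: list[tuple[str, int, str]] = []
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            for chrom, pos in index.get(query[:_SEED_LEN], ()):
                if genome[chrom][pos : pos + len(query)] == query:
                    hits.append((chrom, pos, strand))
                    if len(hits) > 1:
                        break
            if len(hits) > 1:
                break
        if not hits:
            n_unmapped += 1
        elif len(hits) > 1:
            n_multi += 1
        else:
            chrom, pos, strand = hits[0]
            chroms.append(chrom)
            starts.append(pos)
            ends.append(pos + len(seq))
            strands.append(strand)
            out_seqs.append(seq)
            names.append(name)

    reads = MappedReadSet(
        chroms,
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(strands, dtype=object),
        out_seqs,
        names,
    )
    return MapperResult(reads, n_unmapped, n_multi)
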