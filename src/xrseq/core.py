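"""Core containers shared across the pipeline.

Coordinate conventions
----------------------
All genomic intervals are 0-based, half-open ``[start, end)`` — the BED
convention — both internally and on disk.  Read-local positions are 1-based
counted from the 5' end of the excision product (position 1 is the 5'-most
nucleotide), matching how per-position nucleotide frequencies are plotted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "XRSeqError",
    "ConfigError",
    "FormatError",
    "PlacementError",
    "GeometryError",
    "revcomp",
    "Genome",
    "GeneModel",
    "GeneSet",
    "MappedRead",
    "MappedReadSet",
]


class XRSeqError(Exception):
    """Base class for pipeline errors."""


class ConfigError(XRSeqError):
    """Invalid configuration value."""


class FormatError(XRSeqError):
    """Malformed input record; parsers reject rather than coerce."""


class PlacementError(XRSeqError):
    """Synthetic gene placement cannot satisfy its constraints."""


class GeometryError(XRSeqError):
    """Requested lesion register does not fit inside the read."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Genome:
    """Ordered map of chromosome name -> uppercase sequence over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise FormatError("genome has no sequences")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self._seqs:
                raise FormatError(f"duplicate chromosome name: {name!r}")
            if len(seq) == 0:
                raise FormatError(f"chromosome {name!r} has zero length")
            self._seqs[name] = seq.upper()

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        try:
            return self._seqs[name]
        except KeyError:
            raise FormatError(f"chromosome {name!r} not in genome") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def items(self):
        return self._seqs.items()

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def length(self, name: str) -> int:
        return len(self[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on *strand* (5'->3' on that strand)."""
        seq = self[chrom]
        if start < 0 or end > len(seq) or end <= start:
            raise FormatError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds (len {len(seq)})"
            )
        s = seq[start:end]
        return s if strand == "+" else revcomp(s)

    def base_composition(self) -> dict[str, float]:
        """Genome-wide single-base frequencies over A,C,G,T (N excluded)."""
        counts = {b: 0 for b in "ACGT"}
        for seq in self._seqs.values():
            for b in "ACGT":
                counts[b] += seq.count(b)
        total = sum(counts.values())
        if total == 0:
            raise FormatError("genome contains no A/C/G/T bases")
        return {b: c / total for b, c in counts.items()}

    def gc_fraction(self) -> float:
        comp = self.base_composition()
        return comp["G"] + comp["C"]


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene interval with an optional expression value (RPKM)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    rpkm: float | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise FormatError(f"gene {self.id}: end <= start ({self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.id}: strand {self.strand!r} invalid — strand is required "
                "to resolve transcribed vs non-transcribed strand"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Coordinate of the transcription start site (5' gene end)."""
        return self.start if self.strand == "+" else self.end - 1

    def overlaps(self, other: "GeneModel") -> bool:
        """Strand-agnostic interval intersection."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class GeneSet:
    """An ordered collection of genes with overlap queries."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.id))
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate gene ids in gene set")
        self._by_id = {g.id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def overlapping_ids(self) -> set[str]:
        """Ids of genes that intersect at least one other gene (strand-agnostic).

        Sorted sweep per chromosome; O(n log n).
        """
        flagged: set[str] = set()
        active: list[GeneModel] = []
        current_chrom = None
        for g in self.genes:  # already sorted by (chrom, start)
            if g.chrom != current_chrom:
                active = []
                current_chrom = g.chrom
            active = [a for a in active if a.end > g.start]
            for a in active:
                flagged.add(a.id)
                flagged.add(g.id)
            active.append(g)
        return flagged

    def with_expression(self, rpkm: dict[str, float]) -> "GeneSet":
        """Return a copy with RPKM values joined by gene id (missing -> None)."""
        return GeneSet(
            [
                GeneModel(g.id, g.chrom, g.start, g.end, g.strand, rpkm.get(g.id))
                for g in self.genes
            ]
        )


@dataclass(frozen=True)
class MappedRead:
    """A uniquely mapped excision-product read.

    ``sequence`` is in lesion-strand orientation: the genomic slice for a
    ``+`` read, its reverse complement for a ``-`` read.
    """

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class MappedReadSet:
    """Column-oriented set of mapped reads (stranded intervals + sequences)."""

    def __init__(
        self,
        chroms: list[str],
        starts: np.ndarray,
        ends: np.ndarray,
        strands: np.ndarray,
        sequences: list[str],
        names: list[str] | None = None,
    ):
        n = len(chroms)
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=object)
        self.sequences = list(sequences)
        self.names = list(names) if names is not None else [f"read_{i}" for i in range(n)]
        if not (
            len(self.starts) == len(self.ends) == len(self.strands)
            == len(self.sequences) == len(self.names) == n
        ):
            raise ValueError("column length mismatch in MappedReadSet")

    @classmethod
    def from_reads(cls, reads: list[MappedRead]) -> "MappedReadSet":
        return cls(
            [r.chrom for r in reads],
            np.array([r.start for r in reads], dtype=np.int64),
            np.array([r.end for r in reads], dtype=np.int64),
            np.array([r.strand for r in reads], dtype=object),
            [r.sequence for r in reads],
            [r.name for r in reads],
        )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[MappedRead]:
        for i in range(len(self)):
            yield self.read(i)

    def read(self, i: int) -> MappedRead:
        return MappedRead(
            self.chroms[i],
            int(self.starts[i]),
            int(self.ends[i]),
            self.strands[i],
            self.sequences[i],
            self.names[i],
        )

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def subset(self, mask: np.ndarray) -> "MappedReadSet":
        idx = np.flatnonzero(mask)
        return MappedReadSet(
            list(self.chroms[idx]),
            self.starts[idx],
            self.ends[idx],
            self.strands[idx],
            [self.sequences[i] for i in idx],
            [self.names[i] for i in idx],
        )

    def of_length(self, length: int) -> "MappedReadSet":
        return self.subset(self.lengths == length)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "name": self.names,
                "strand": self.strands,
                "sequence": self.sequences,
            }
        )
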