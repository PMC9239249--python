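"""Core domain records: genomes, gene features and alignment hits.

Coordinates are 0-based half-open on the linearized sequence. For genes that
span the origin of a circular genome, ``end`` exceeds the genome length and is
interpreted modulo the length; this keeps every gene a single contiguous
interval internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

VALID_BASES = frozenset("ACGTN")
HALLMARKS = ("VP1", "VP2", "VP3", "VP4", "VP5", "VP8")


@dataclass
class GeneFeature:
    """A single protein-coding gene on a genome.

    ``label`` is one of the hallmark names (VP1..VP8), ``accessory:<cat>``,
    ``unknown`` or a diagnostic label such as ``VP1-duplicate``.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    translation_table: int = 11
    protein: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if self.translation_table not in (11, 4):
            raise ValueError(f"unsupported translation table {self.translation_table}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_hallmark(self) -> bool:
        return self.label in HALLMARKS


@dataclass
class GenomeRecord:
    """One phage contig plus its gene features.

    Gene coordinates live on the linearized sequence; wraparound genes
    (``end > len(sequence)``) are permitted only when ``is_circular``.
    """

    genome_id: str
    sequence: str
    is_circular: bool = True
    source_label: str = ""
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.genome_id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"{self.genome_id}: invalid characters {sorted(bad)}")
        self.sort_genes()
        for g in self.genes:
            if g.start < 0 or g.start >= len(self.sequence):
                raise ValueError(f"{self.genome_id}/{g.gene_id}: start out of range")
            if g.end > len(self.sequence) and not self.is_circular:
                raise ValueError(
                    f"{self.genome_id}/{g.gene_id}: wraparound gene on linear genome"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def sort_genes(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def gc_content(self) -> float:
        s = self.sequence
        acgt = sum(s.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (s.count("G") + s.count("C")) / acgt

    def gene_sequence(self, gene: GeneFeature) -> str:
        """Nucleotide sequence of a gene on the + strand of the linearization,
        reverse-complemented when the gene is on '-'. Handles wraparound."""
        n = len(self.sequence)
        if gene.end <= n:
            nt = self.sequence[gene.start : gene.end]
        else:
            nt = self.sequence[gene.start :] + self.sequence[: gene.end - n]
        if gene.strand == "-":
            nt = reverse_complement(nt)
        return nt

    def find_gene(self, label: str) -> Optional[GeneFeature]:
        for g in self.genes:
            if g.label == label:
                return g
        return None

    def copy(self) -> "GenomeRecord":
        return replace(self, genes=[replace(g) for g in self.genes])


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignmentHit:
    """A pairwise local protein comparison.

    identity: percent identical residues over all alignment columns (gap
    columns included in the denominator).
    coverage: fraction of the shorter protein covered by the alignment.
    """

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    score: float
    significance: float = float("nan")
    aln_len: int = 0
    mismatches: int = 0
    gaps: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def key(self) -> tuple[str, str]:
        return (self.query_id, self.subject_id)


@dataclass
class TaxonAssignment:
    """Per-genome taxonomy call."""

    genome_id: str
    family_id: str  # family name or "SINGLETON"
    genus_id: str
    novel_flag: bool = False
    notes: str = ""

    @property
    def is_singleton(self) -> bool:
        return self.family_id == "SINGLETON"
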