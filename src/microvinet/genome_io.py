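"""Genome and annotation IO: FASTA reading with alphabet normalization,
VP1-anchored linearization of circular genomes, concatemer deduplication and
GFF3 round-tripping (wraparound genes as two-part features sharing an ID)."""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

from .records import GeneFeature, GenomeRecord, VALID_BASES, reverse_complement

log = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_genomes(path: PathLike, circular_default: bool = True) -> list[GenomeRecord]:
    """Read a genome FASTA into GenomeRecords.

    Lowercase is normalized to uppercase; any character outside {A,C,G,T,N}
    (ambiguity codes, stray symbols) is mapped to N with one warning per
    record. Duplicate identifiers are a hard error; an empty file yields an
    empty list with a warning.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate genome identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        n_bad = sum(1 for c in seq if c not in VALID_BASES)
        if n_bad:
            log.warning(
                "%s: %d non-ACGTN characters mapped to N", rec.id, n_bad
            )
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        records.append(
            GenomeRecord(genome_id=rec.id, sequence=seq, is_circular=circular_default)
        )
    if not records:
        log.warning("no FASTA records found in %s", path)
    return records


def write_genomes(genomes: Iterable[GenomeRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.genome_id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")


def rotate_genome(g: GenomeRecord, offset: int) -> GenomeRecord:
    """Rotate a circular genome so the base at ``offset`` becomes position 0.

    Gene coordinates are shifted consistently; genes that come to span the
    origin are stored with end > length.
    """
    if not g.is_circular:
        raise ValueError(f"{g.genome_id}: cannot rotate a linear genome")
    n = len(g.sequence)
    offset %= n
    seq = g.sequence[offset:] + g.sequence[:offset]
    genes = []
    for gene in g.genes:
        start = (gene.start - offset) % n
        genes.append(replace(gene, start=start, end=start + gene.length))
    out = replace(g, sequence=seq, genes=genes)
    out.sort_genes()
    return out


def linearize_at_vp1(g: GenomeRecord) -> GenomeRecord:
    """Rotate a circular genome so its VP1 gene starts at coordinate 0.

    With multiple VP1 labels the lowest-coordinate VP1 anchors (a warning is
    emitted); labeling already demotes extra copies to ``VP1-duplicate``.
    """
    vp1s = [gene for gene in g.genes if gene.label == "VP1"]
    if not vp1s:
        raise ValueError(f"{g.genome_id}: cannot anchor, no VP1 gene")
    if len(vp1s) > 1:
        log.warning("%s: %d VP1 genes, anchoring at lowest coordinate", g.genome_id, len(vp1s))
    anchor = min(vp1s, key=lambda x: (x.start, x.end))
    if anchor.start == 0:
        return g
    return rotate_genome(g, anchor.start)


def smallest_period(s: str) -> int:
    """Length of the smallest string u with s == u * k (k >= 1)."""
    idx = (s + s).find(s, 1)
    if idx != -1 and len(s) % idx == 0:
        return idx
    return len(s)


def dedup_concatemers(g: GenomeRecord) -> GenomeRecord:
    """Collapse an exact tandem-repeat assembly to its single repeat unit.

    MAG assemblies of circular genomes sometimes emit two or more identical
    copies end to end; when the sequence is an exact k-fold repeat (k >= 2)
    the single unit is returned and flagged circular. Near-identical tandem
    copies are deliberately left untouched (logged for manual review).
    Idempotent. Genes falling entirely within the first unit are retained.
    """
    n = len(g.sequence)
    p = smallest_period(g.sequence)
    if p == n:
        return g
    k = n // p
    log.info("%s: exact %d-fold concatemer collapsed to %d nt unit", g.genome_id, k, p)
    genes = [replace(gene) for gene in g.genes if gene.end <= p]
    return replace(g, sequence=g.sequence[:p], is_circular=True, genes=genes)


def normalize_strand(g: GenomeRecord) -> GenomeRecord:
    """Reverse-complement the genome when VP1 lies on '-', flipping all gene
    coordinates, so that VP1 (and after curation every gene) is on '+'."""
    vp1 = g.find_gene("VP1")
    if vp1 is None or vp1.strand == "+":
        return g
    n = len(g.sequence)
    seq = reverse_complement(g.sequence)
    genes = []
    for gene in g.genes:
        # interval [start, end) mod n maps to [n - end mod n position ...)
        start = (n - gene.end) % n
        genes.append(
            replace(
                gene,
                start=start,
                end=start + gene.length,
                strand="+" if gene.strand == "-" else "-",
            )
        )
    out = replace(g, sequence=seq, genes=genes)
    out.sort_genes()
    return out


# ---------------------------------------------------------------------------
# GFF3

_GFF_SOURCE = "microvinet"


def write_annotations(genomes: Iterable[GenomeRecord], path: PathLike) -> None:
    """Write gene features as GFF3 (1-based inclusive coordinates).

    Wraparound genes are emitted as two part-lines sharing one ID; the
    matching reader reassembles them into a single feature with end > length,
    so write → read is lossless.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            n = len(g.sequence)
            fh.write(f"##sequence-region {g.genome_id} 1 {n}\n")
            for gene in g.genes:
                attrs = (
                    f"ID={gene.gene_id};label={gene.label};"
                    f"transl_table={gene.translation_table};circular={int(g.is_circular)}"
                )
                if gene.end <= n:
                    parts = [(gene.start + 1, gene.end)]
                else:
                    parts = [(gene.start + 1, n), (1, gene.end - n)]
                for s1, e1 in parts:
                    fh.write(
                        "\t".join(
                            [
                                g.genome_id,
                                _GFF_SOURCE,
                                "CDS",
                                str(s1),
                                str(e1),
                                ".",
                                gene.strand,
                                "0",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


def read_annotations(path: PathLike, genomes: Iterable[GenomeRecord]) -> list[GenomeRecord]:
    """Attach GFF3 features back onto genome records (inverse of
    :func:`write_annotations`). Two-part features sharing an ID are merged
    into one wraparound gene."""
    by_id = {g.genome_id: replace(g, genes=[]) for g in genomes}
    pending: dict[tuple[str, str], list[tuple[int, int, str, dict]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, s1, e1, _, strand, _, attr_s = f
            if ftype != "CDS" or seqid not in by_id:
                continue
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            key = (seqid, attrs["ID"])
            pending.setdefault(key, []).append((int(s1), int(e1), strand, attrs))
    for (seqid, gene_id), parts in pending.items():
        g = by_id[seqid]
        n = len(g.sequence)
        parts.sort(key=lambda p: p[0])
        if len(parts) == 1:
            s1, e1, strand, attrs = parts[0]
            start, end = s1 - 1, e1
        elif len(parts) == 2:
            # wraparound: [start, n) + [0, tail)
            (head_s, _, strand, attrs) = next(p for p in parts if p[1] == n)
            tail = next(p for p in parts if p[0] == 1)
            start = head_s - 1
            end = n + tail[1]
        else:
            raise ValueError(f"{gene_id}: more than two feature parts")
        g.genes.append(
            GeneFeature(
                gene_id=gene_id,
                start=start,
                end=end,
                strand=strand,
                translation_table=int(attrs.get("transl_table", 11)),
                label=attrs.get("label", "unknown"),
            )
        )
    out = []
    for g in by_id.values():
        g.sort_genes()
        out.append(g)
    return out
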