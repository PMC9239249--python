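"""ORF calling on circular genomes, curation rules and hallmark gene-order
classification.

Microviruses encode all genes on one strand; curation therefore removes any
gene antisense to VP1, rejects genomes missing core hallmarks, and normalizes
the genome so every retained gene sits on '+'. ORFs are called under the
standard bacterial code (table 11) or the Mycoplasma/Spiroplasma code
(table 4, TGA = Trp) because several microvirus hosts use the latter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio.Seq import Seq

from .records import GeneFeature, GenomeRecord, HALLMARKS, reverse_complement
from .genome_io import normalize_strand

log = logging.getLogger(__name__)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = {11: ("TAA", "TAG", "TGA"), 4: ("TAA", "TAG")}


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal open reading frame (coordinates on the forward strand of the
    linearization; ``end`` may exceed the genome length on circular genomes).
    Coordinates include the stop codon."""

    start: int
    end: int
    strand: str
    translation_table: int
    protein: str

    @property
    def length(self) -> int:
        return self.end - self.start


def translate_cds(nt: str, table: int) -> str:
    """Translate a CDS (stop codon included), returning the protein without
    the trailing stop. Codons containing N become X."""
    prot = str(Seq(nt).translate(table=table))
    return prot.rstrip("*")


def _scan_strand(seq: str, n: int, circular: bool, table: int, min_aa: int) -> list[tuple[int, int, str]]:
    """Maximal ORFs on the + strand of ``seq`` (already oriented). Returns
    (start, end, protein) with start in [0, n) and end - start <= n.

    Circular genomes are scanned on the doubled sequence. An ORF may only open
    after a stop codon has been seen in the current frame: anything upstream of
    the first stop is the tail of an ORF that wraps the origin and is captured
    by its downstream copy. Wrapped copies are deduplicated modulo n, which
    makes the resulting ORF set rotation-invariant.
    """
    stops = STOP_CODONS[table]
    scan = seq + seq if circular else seq
    limit = len(scan)
    found: dict[tuple[int, int], str] = {}
    for frame in range(3):
        seen_stop = not circular  # linear: sequence start acts as a boundary
        start: Optional[int] = None
        for p in range(frame, limit - 2, 3):
            codon = scan[p : p + 3]
            if codon in stops:
                if start is not None:
                    end = p + 3
                    length = end - start
                    if length <= n and length // 3 - 1 >= min_aa:
                        key = (start % n, length)
                        if key not in found:
                            found[key] = translate_cds(scan[start:end], table)
                start = None
                seen_stop = True
            elif start is None and seen_stop and codon in START_CODONS:
                start = p
    return [(s, s + length, prot) for (s, length), prot in found.items()]


def call_orfs(g: GenomeRecord, table: int = 11, min_aa: int = 33) -> list[OrfCandidate]:
    """All maximal ORFs on both strands.

    Start codons ATG/GTG/TTG; a maximal ORF runs from the first start codon
    after the preceding in-frame stop to the next stop (which must be
    present). On circular genomes ORFs may span the origin (end > length,
    capped at one full genome). Sorted by (start, end, strand).
    """
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    n = len(g.sequence)
    out: list[OrfCandidate] = []
    for start, end, prot in _scan_strand(g.sequence, n, g.is_circular, table, min_aa):
        out.append(OrfCandidate(start, end, "+", table, prot))
    rc = reverse_complement(g.sequence)
    for s_rc, e_rc, prot in _scan_strand(rc, n, g.is_circular, table, min_aa):
        start = (n - e_rc) % n
        out.append(OrfCandidate(start, start + (e_rc - s_rc), "-", table, prot))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def call_orfs_auto(g: GenomeRecord, min_aa: int = 33, min_orfs: int = 3) -> tuple[list[OrfCandidate], int]:
    """Table-11 calling, retried under the Mycoplasma code when fewer than
    ``min_orfs`` ORFs are found (hosts with reassigned TGA fragment standard
    gene calls). Returns (orfs, table used)."""
    orfs = call_orfs(g, table=11, min_aa=min_aa)
    if len(orfs) >= min_orfs:
        return orfs, 11
    orfs4 = call_orfs(g, table=4, min_aa=min_aa)
    if len(orfs4) > len(orfs):
        log.info("%s: re-called with Mycoplasma code (%d -> %d ORFs)", g.genome_id, len(orfs), len(orfs4))
        return orfs4, 4
    return orfs, 11


def orfs_to_genes(orfs: list[OrfCandidate]) -> list[GeneFeature]:
    return [
        GeneFeature(
            gene_id=f"orf{i:04d}",
            start=o.start,
            end=o.end,
            strand=o.strand,
            translation_table=o.translation_table,
            protein=o.protein,
        )
        for i, o in enumerate(orfs)
    ]


def _circular_overlap(a: GeneFeature, b: GeneFeature, n: int) -> int:
    """Overlap length of two gene intervals on a circle of size n."""

    def spans(g: GeneFeature):
        if g.end <= n:
            return [(g.start, g.end)]
        return [(g.start, n), (0, g.end - n)]

    ov = 0
    for s1, e1 in spans(a):
        for s2, e2 in spans(b):
            ov += max(0, min(e1, e2) - max(s1, s2))
    return ov


def prune_overlapping_unknowns(g: GenomeRecord) -> GenomeRecord:
    """Longest-first greedy selection among unlabeled ORFs.

    Hallmark- and accessory-labeled genes are always kept; an unlabeled ORF is
    dropped when it overlaps an already-kept gene on the same strand.
    Overprinted genes are deliberately not modeled.
    """
    n = len(g.sequence)
    kept = [x for x in g.genes if x.label != "unknown"]
    unknowns = sorted(
        (x for x in g.genes if x.label == "unknown"),
        key=lambda x: (-x.length, x.start, x.gene_id),
    )
    for cand in unknowns:
        if any(
            k.strand == cand.strand and _circular_overlap(cand, k, n) > 0 for k in kept
        ):
            continue
        kept.append(cand)
    out = replace(g, genes=kept)
    out.sort_genes()
    return out


@dataclass
class CurationResult:
    """Outcome of curate_genome: either a curated genome or a structured
    rejection reason of the form ``missing:VP1``."""

    genome: Optional[GenomeRecord]
    rejected: bool = False
    reason: str = ""
    removed_genes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def curate_genome(g: GenomeRecord, require_vp2: bool = False) -> CurationResult:
    """Apply the single-strand and completeness rules.

    1. every gene whose strand differs from VP1's is removed;
    2. the genome is rejected unless VP1 and VP4 are present (and VP2 when
       ``require_vp2``); a VP2-less genome otherwise passes with a
       "Suborder II candidate" warning, since one suborder is defined by the
       absence of a recognizable DNA pilot protein;
    3. the genome is strand-normalized so all retained genes sit on '+'.
    """
    vp1 = g.find_gene("VP1")
    if vp1 is None:
        return CurationResult(None, rejected=True, reason="missing:VP1")
    removed = [x.gene_id for x in g.genes if x.strand != vp1.strand]
    genes = [replace(x) for x in g.genes if x.strand == vp1.strand]
    if removed:
        log.info("%s: removed %d gene(s) antisense to VP1", g.genome_id, len(removed))
    cur = replace(g, genes=genes)
    labels = {x.label for x in cur.genes}
    if "VP4" not in labels:
        return CurationResult(None, rejected=True, reason="missing:VP4", removed_genes=removed)
    warnings = []
    if "VP2" not in labels:
        if require_vp2:
            return CurationResult(None, rejected=True, reason="missing:VP2", removed_genes=removed)
        warnings.append("Suborder II candidate: VP1+VP4 present, VP2 absent")
        log.warning("%s: %s", g.genome_id, warnings[-1])
    cur = normalize_strand(cur)
    return CurationResult(cur, removed_genes=removed, warnings=warnings)


CORE_ORDER_GENES = ("VP1", "VP2", "VP4")


def classify_gene_order(g: GenomeRecord, include_optional: bool = True) -> str:
    """Canonical hallmark order label, e.g. ``"VP1-VP2-VP4"``.

    The circular order of hallmark genes is read 5'->3' starting from VP1, so
    the label is invariant under rotation and (after strand normalization)
    under reverse-complementation of the genome. When a core hallmark is
    missing the label is ``partial:<present set>``. With only the three core
    genes there are exactly two circular classes (VP1-VP2-VP4 and
    VP1-VP4-VP2); optional hallmarks (VP3/VP5/VP8), when present and
    ``include_optional``, extend the label and carry the further gene-order
    variation seen within some families.
    """
    vp1 = g.find_gene("VP1")
    if vp1 is not None and vp1.strand == "-":
        g = normalize_strand(g)
    wanted = set(HALLMARKS) if include_optional else set(CORE_ORDER_GENES)
    marks = [(x.start % len(g.sequence), x.label) for x in g.genes if x.label in wanted]
    present = {label for _, label in marks}
    if not set(CORE_ORDER_GENES) <= present:
        return "partial:" + "+".join(sorted(present & set(CORE_ORDER_GENES)))
    marks.sort()
    labels = [label for _, label in marks]
    i = labels.index("VP1")
    return "-".join(labels[i:] + labels[:i])
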