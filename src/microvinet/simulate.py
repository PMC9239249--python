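"""Synthetic microvirus genome sets with planted taxonomy, reads and
recombination tracts.

The generator emulates the observed envelope of curated microvirus genomes:
3.5-8.3 kb circular genomes, GC 26-65%, all genes on one strand, a hallmark
complement of VP1/VP2/VP4 plus optional VP3/VP5/VP8 and accessory
peptidases/methyltransferases, and six linear arrangements of the core genes.
Protein divergence is applied in amino-acid space along a
family -> genus -> genome tree and back-translated with synonymous-codon
choice honoring a per-family GC target, so AAI bands are controlled directly.
Divergence levels are per-branch substitution fractions; two genomes whose
lineages each carry substitution fraction s from their common ancestor show
pairwise identity of about (1-s)^2 (plus a small back-substitution term).

Defaults plant 5 families x 3 genera x 4 genomes with between-family VP1
identity at random-protein level (<20%), within-family ~35-45% and
within-genus ~75%.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable

from .records import GeneFeature, GenomeRecord

log = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# stop codons in every reading frame on both strands (self-reverse-complement)
STOP_BLOCK = "TTAATTAATTAA"

DEFAULT_DIVERGENCE = {
    "between_family": 1.0,   # >= 1: families drawn independently
    "within_family": 0.30,   # genus-ancestor branch from the family ancestor
    "within_genus": 0.13,    # genome branch from the genus ancestor
}

# mean hallmark/accessory protein lengths (aa); jitter is per family
GENE_LENGTHS = {
    "VP1": 300, "VP2": 120, "VP4": 180, "VP3": 90, "VP5": 60, "VP8": 50,
    "accessory:peptidase": 110, "accessory:methyltransferase": 160,
}
CORE_ORDER = ("VP1", "VP2", "VP4")
OPTIONAL_PROB = {"VP3": 0.5, "VP5": 0.3, "VP8": 0.3,
                 "accessory:peptidase": 0.5, "accessory:methyltransferase": 0.3}


def _codon_table(table: int = 11) -> dict[str, list[str]]:
    fwd = CodonTable.unambiguous_dna_by_id[table].forward_table
    out: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out

CODONS = _codon_table(11)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated genome set."""

    seed: int
    params: dict = field(default_factory=dict)
    family: dict = field(default_factory=dict)    # genome_id -> family label
    genus: dict = field(default_factory=dict)     # genome_id -> genus label
    gene_order: dict = field(default_factory=dict)  # genus label -> core order tuple
    genes: dict = field(default_factory=dict)     # genome_id -> list of gene dicts
    ancestral_proteins: dict = field(default_factory=dict)  # lineage id -> protein
    recombination: list = field(default_factory=list)
    reads: dict = field(default_factory=dict)     # read_id -> genome_id

    def to_json(self) -> str:
        d = asdict(self)
        d["gene_order"] = {k: list(v) for k, v in self.gene_order.items()}
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["gene_order"] = {k: tuple(v) for k, v in d["gene_order"].items()}
        return cls(**d)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate_protein(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(fraction * length) residues (positions drawn
    without replacement). Exact counts rather than per-residue Bernoulli keep
    the configured divergence bands tight even for short proteins."""
    out = list(seq)
    n_mut = int(round(fraction * len(out)))
    for i in rng.choice(len(out), size=min(n_mut, len(out)), replace=False):
        choices = [a for a in AA20 if a != out[i]]
        out[i] = choices[int(rng.integers(19))]
    return "".join(out)


def _codon_weights(codons: Sequence[str], gc: float) -> np.ndarray:
    w = np.array(
        [np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in c]) for c in codons]
    )
    return w / w.sum()


def _back_translate(protein: str, gc: float, rng: np.random.Generator) -> list[str]:
    codons = []
    for aa in protein:
        opts = CODONS[aa]
        codons.append(opts[int(rng.choice(len(opts), p=_codon_weights(opts, gc)))])
    return codons


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _filler(rng: np.random.Generator, length: int, gc: float) -> str:
    """Non-coding filler: stop-codon blocks interleaved with random sequence
    so no spurious ORF of consequence can arise on either strand."""
    parts = []
    total = 0
    while total < length:
        parts.append(STOP_BLOCK)
        parts.append(_random_dna(rng, 9, gc))
        total += len(STOP_BLOCK) + 9
    return "".join(parts)[:length]


def _spacer(rng: np.random.Generator, gc: float) -> str:
    return STOP_BLOCK + _random_dna(rng, int(rng.integers(0, 22)), gc)


def simulate_taxonomy(
    n_families: int = 5,
    genera_per_family: int = 3,
    genomes_per_genus: int = 4,
    divergence: Optional[Mapping[str, float]] = None,
    seed: int = 42,
    length_range: tuple[int, int] = (3500, 8300),
    gc_range: tuple[float, float] = (0.26, 0.65),
    order_permutations: Optional[Mapping[str, Sequence[str]]] = None,
    shared_accessory: Sequence[tuple[int, int]] = (),
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate circular genomes with planted family/genus structure.

    ``order_permutations`` maps genus labels (``famXgY``) to a core gene
    arrangement (a permutation of VP1/VP2/VP4); ``shared_accessory`` lists
    family index pairs that share a planted peptidase at ~74% AAI while their
    VP1 proteins are unrelated. Deterministic for a fixed seed.
    """
    div = dict(DEFAULT_DIVERGENCE)
    if divergence:
        div.update(divergence)
    if not div["between_family"] > div["within_family"] > div["within_genus"]:
        raise ValueError("divergence levels must be strictly ordered")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_families": n_families, "genera_per_family": genera_per_family,
            "genomes_per_genus": genomes_per_genus, "divergence": div,
            "length_range": list(length_range), "gc_range": list(gc_range),
        },
    )
    shared_prot: dict[int, str] = {}
    for fa, fb in shared_accessory:
        prot = shared_prot.get(fa) or shared_prot.get(fb)
        if prot is None:
            prot = _random_protein(rng, GENE_LENGTHS["accessory:peptidase"])
        shared_prot[fa] = prot
        shared_prot[fb] = prot

    genomes: list[GenomeRecord] = []
    for f in range(n_families):
        fam = f"fam{f}"
        gc = float(rng.uniform(*gc_range))
        genes = list(CORE_ORDER)
        for name, p in OPTIONAL_PROB.items():
            if f in shared_prot and name == "accessory:peptidase":
                continue  # planted separately below
            if rng.random() < p:
                genes.append(name)
        if f in shared_prot:
            genes.append("accessory:peptidase")
        # family ancestors
        fam_prot: dict[str, str] = {}
        for name in genes:
            length = max(40, int(rng.normal(GENE_LENGTHS[name], GENE_LENGTHS[name] * 0.05)))
            if name == "accessory:peptidase" and f in shared_prot:
                # branch rates chosen so cross-family pairwise identity of the
                # shared peptidase lands near the ~74% AAI of the reported
                # cross-family connection while the capsids stay unrelated
                fam_prot[name] = _mutate_protein(shared_prot[f], 0.08, rng)
            else:
                fam_prot[name] = _random_protein(rng, length)
            truth.ancestral_proteins[f"{fam}:{name}"] = fam_prot[name]
        for j in range(genera_per_family):
            genus = f"{fam}g{j}"
            genus_prot = {
                name: _mutate_protein(
                    fam_prot[name],
                    0.04 if (name == "accessory:peptidase" and f in shared_prot)
                    else div["within_family"],
                    rng,
                )
                for name in genes
            }
            for name in genes:
                truth.ancestral_proteins[f"{genus}:{name}"] = genus_prot[name]
            genus_nt = {name: _back_translate(genus_prot[name], gc, rng) for name in genes}
            core = tuple((order_permutations or {}).get(genus, CORE_ORDER))
            if sorted(core) != sorted(CORE_ORDER):
                raise ValueError(f"invalid core order for {genus}: {core}")
            layout = list(core) + [g_ for g_ in genes if g_ not in CORE_ORDER]
            truth.gene_order[genus] = core
            # the genus carries one nucleotide template (genes, spacers,
            # filler, total length); member genomes are low-rate mutants of
            # it, so within-genus nucleotide identity stays high as in real
            # genus-level clusters
            spacers = [_spacer(rng, gc) for _ in layout]
            coding = sum(3 * len(genus_prot[name]) + 6 for name in layout) + sum(
                len(s) for s in spacers
            )
            target = int(rng.uniform(*length_range))
            if target < coding + len(STOP_BLOCK):
                if length_range[1] < coding + len(STOP_BLOCK):
                    raise ValueError("infeasible packing: genes exceed genome length")
                target = coding + len(STOP_BLOCK)
            genus_filler = _filler(rng, target - coding, gc)
            # intergenic nucleotide divergence mirrors the protein branch rate
            nc_rate = div["within_genus"]
            for k in range(genomes_per_genus):
                gid = f"{genus}n{k}"
                seq_parts: list[str] = []
                feats: list[GeneFeature] = []
                gene_truth = []
                pos = 0
                for gi, name in enumerate(layout):
                    d_gene = (
                        0.03
                        if (name == "accessory:peptidase" and f in shared_prot)
                        else div["within_genus"]
                    )
                    prot = _mutate_protein(genus_prot[name], d_gene, rng)
                    codons = list(genus_nt[name])
                    for i, (a, b) in enumerate(zip(genus_prot[name], prot)):
                        if a != b:
                            opts = CODONS[b]
                            codons[i] = opts[int(rng.choice(len(opts), p=_codon_weights(opts, gc)))]
                    nt = "ATG" + "".join(codons) + "TAA"
                    feats.append(
                        GeneFeature(
                            gene_id=f"g{gi:02d}", start=pos, end=pos + len(nt),
                            strand="+", translation_table=11,
                            protein="M" + prot, label=name,
                        )
                    )
                    gene_truth.append(
                        {"gene_id": f"g{gi:02d}", "label": name, "start": pos,
                         "end": pos + len(nt), "ancestor": f"{genus}:{name}",
                         "divergence": div["within_genus"]}
                    )
                    seq_parts.append(nt)
                    pos += len(nt)
                    sp = _mutate_dna(spacers[gi], nc_rate, rng)
                    seq_parts.append(sp)
                    pos += len(sp)
                seq_parts.append(_mutate_dna(genus_filler, nc_rate, rng))
                genomes.append(
                    GenomeRecord(
                        genome_id=gid, sequence="".join(seq_parts),
                        is_circular=True, source_label="synthetic", genes=feats,
                    )
                )
                truth.family[gid] = fam
                truth.genus[gid] = genus
                truth.genes[gid] = gene_truth
    return genomes, truth


def strip_annotations(genomes: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """Sequence-only copies (what a raw assembly looks like before the
    pipeline annotates it)."""
    return [
        GenomeRecord(
            genome_id=g.genome_id, sequence=g.sequence,
            is_circular=g.is_circular, source_label=g.source_label,
        )
        for g in genomes
    ]


def make_seed_msas(truth: SyntheticTruth) -> list[tuple[str, str, dict[str, str]]]:
    """Per-family, per-hallmark seed alignments from the genus-ancestor
    proteins (equal-length, gapless rows). Returns (profile name, hallmark
    label, rows keyed by lineage id)."""
    groups: dict[tuple[str, str], dict[str, str]] = {}
    for lineage, prot in truth.ancestral_proteins.items():
        head, name = lineage.split(":", 1)
        if "g" not in head:
            continue  # family ancestors are not part of the seed set
        fam = head.split("g")[0]
        groups.setdefault((name, fam), {})[lineage] = prot
    out = []
    for (name, fam) in sorted(groups):
        rows = groups[(name, fam)]
        label = name.split(":")[0] if not name.startswith("accessory") else "accessory"
        out.append((f"{name}|{fam}", label if not name.startswith("accessory") else "accessory", rows))
    return out


def plant_recombination(
    genomes: Sequence[GenomeRecord],
    truth: SyntheticTruth,
    donor_family: str,
    acceptor_family: str,
    tract_len: int = 700,
    tract_identity: float = 0.72,
    backbone_identity: float = 0.38,
    seed: int = 0,
    n_tracts: int = 1,
    min_separation: int = 500,
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Plant a recombinant tract between two distantly related genomes.

    Fig-S2-style scenario: the acceptor is rebuilt as a positionally
    homologous ("syntenic") mutant of the donor, diverged everywhere at the
    backbone rate except for one tract diverged at the tract rate, so the
    donor-vs-acceptor identity plot shows a flat backbone near
    ``backbone_identity`` with one elevated island near ``tract_identity``
    (72% versus 38% by default). The acceptor keeps the donor's gene
    coordinates and labels (proteins are dropped; only the VP1 anchor is
    needed downstream). ``tract_identity == backbone_identity`` yields no
    detectable tract. Returns updated copies; the input list is not
    modified."""
    if donor_family == acceptor_family:
        raise ValueError("donor and acceptor families must differ")
    rng = np.random.default_rng(seed)
    by_fam: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        by_fam.setdefault(truth.family.get(g.genome_id, ""), []).append(g)
    donor = sorted(by_fam[donor_family], key=lambda g: g.genome_id)[0]
    acceptor = sorted(by_fam[acceptor_family], key=lambda g: g.genome_id)[0]
    if n_tracts * (tract_len + min_separation) >= len(donor) - 200:
        raise ValueError("tracts longer than a genome")
    starts: list[int] = []
    while len(starts) < n_tracts:
        cand = int(rng.integers(100, len(donor) - tract_len - 100))
        if all(abs(cand - s) >= tract_len + min_separation for s in starts):
            starts.append(cand)
    starts.sort()
    backbone = _mutate_dna(donor.sequence, 1 - backbone_identity, rng)
    new_seq = backbone
    for d_start in starts:
        tract = _mutate_dna(
            donor.sequence[d_start : d_start + tract_len], 1 - tract_identity, rng
        )
        new_seq = new_seq[:d_start] + tract + new_seq[d_start + tract_len :]
    kept = [
        GeneFeature(
            gene_id=gn.gene_id, start=gn.start, end=gn.end, strand=gn.strand,
            translation_table=gn.translation_table, protein="", label=gn.label,
        )
        for gn in donor.genes
    ]
    out = []
    for g in genomes:
        if g.genome_id == acceptor.genome_id:
            out.append(
                GenomeRecord(
                    genome_id=g.genome_id, sequence=new_seq, is_circular=g.is_circular,
                    source_label=g.source_label, genes=kept,
                )
            )
        else:
            out.append(g)
    for d_start in starts:
        truth.recombination.append(
            {
                "donor": donor.genome_id, "acceptor": acceptor.genome_id,
                "donor_start": d_start, "donor_end": d_start + tract_len,
                "acceptor_start": d_start, "acceptor_end": d_start + tract_len,
                "tract_identity": tract_identity, "backbone_identity": backbone_identity,
            }
        )
    return out, truth


def _mutate_dna(seq: str, fraction: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i, b in enumerate(out):
        if b in "ACGT" and rng.random() < fraction:
            choices = [c for c in "ACGT" if c != b]
            out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def simulate_reads(
    genomes: Sequence[GenomeRecord],
    weights: Mapping[str, float],
    n_reads: int,
    read_len: int = 150,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Simulate single-end reads.

    Genomes are sampled proportional to weight x length, start positions are
    uniform (wrapping the origin on circular genomes), and per-base
    substitution errors applied at ``error_rate``. Returns (reads as
    (id, sequence) pairs, read_id -> source genome truth).
    """
    ids = sorted(weights)
    w = np.array([weights[i] for i in ids], dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    by_id = {g.genome_id: g for g in genomes}
    lengths = np.array([len(by_id[i]) for i in ids], dtype=float)
    if read_len > lengths.min():
        raise ValueError("read length exceeds the shortest genome")
    p = w * lengths
    p /= p.sum()
    rng = np.random.default_rng(seed)
    sources = rng.choice(len(ids), size=n_reads, p=p)
    reads, truth = [], {}
    for r, src in enumerate(sources):
        g = by_id[ids[src]]
        n = len(g)
        if g.is_circular:
            start = int(rng.integers(0, n))
            seq = (g.sequence + g.sequence[:read_len])[start : start + read_len]
        else:
            start = int(rng.integers(0, n - read_len + 1))
            seq = g.sequence[start : start + read_len]
        if error_rate > 0:
            seq = _mutate_dna_at_rate(seq, error_rate, rng)
        rid = f"r{r:06d}"
        reads.append((rid, seq))
        truth[rid] = g.genome_id
    return reads, truth


def _mutate_dna_at_rate(seq: str, rate: float, rng: np.random.Generator) -> str:
    return _mutate_dna(seq, rate, rng)


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def measured_divergence_bands(genomes: Sequence[GenomeRecord], truth: SyntheticTruth) -> dict:
    """Post-hoc VP1 identity bands (within genus / within family / between
    families), measured with the AAI engine on coverage-passing alignments."""
    from . import aai

    vp1 = {}
    for g in genomes:
        gene = g.find_gene("VP1")
        if gene is not None:
            vp1[g.genome_id] = gene.protein
    ids = sorted(vp1)
    bands = {"within_genus": [], "within_family": [], "between_family": []}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            hit = aai.align_pair(vp1[a], vp1[b], a, b)
            ident = hit.identity if hit is not None and hit.coverage >= 0.8 else 0.0
            if truth.genus[a] == truth.genus[b]:
                bands["within_genus"].append(ident)
            elif truth.family[a] == truth.family[b]:
                bands["within_family"].append(ident)
            else:
                bands["between_family"].append(ident)
    return {k: (float(np.mean(v)) if v else 0.0) for k, v in bands.items()}
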