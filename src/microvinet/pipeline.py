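"""End-to-end wiring: raw contigs -> ORFs -> hallmark labels -> curation ->
canonical (VP1-anchored, single-strand) genomes -> network taxonomy.

Each stage logs genome counts in and out so curation attrition is auditable;
`run_pipeline` drives the whole flow from a config and writes a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from . import genome_io
from .annotate import (
    call_orfs, call_orfs_auto, curate_genome, orfs_to_genes,
    prune_overlapping_unknowns,
)
from .config import PipelineConfig
from .genome_io import linearize_at_vp1
from .profiles import ProfileHMM, build_profile, label_hallmarks
from .records import GenomeRecord
from .taxonomy import MicrovirusTaxonomy

log = logging.getLogger(__name__)


def build_hallmark_profiles(
    seed_msas: Sequence[tuple[str, str, dict[str, str]]],
    n_decoys: int = 300,
    seed: int = 0,
) -> list[ProfileHMM]:
    """Fit and calibrate one profile per (name, label, aligned rows) seed
    set."""
    profiles = []
    for i, (name, label, rows) in enumerate(seed_msas):
        p = build_profile(list(rows.values()), name=name, label=label)
        p.calibrate(n_decoys=n_decoys, seed=seed + i)
        profiles.append(p)
    return profiles


@dataclass
class AnnotationReport:
    curated: list[GenomeRecord] = field(default_factory=list)
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (genome, reason)
    n_input: int = 0
    n_length_filtered: int = 0


def annotate_and_curate(
    genomes: Sequence[GenomeRecord],
    profiles: Sequence[ProfileHMM],
    cfg: Optional[PipelineConfig] = None,
    apply_length_filter: bool = False,
) -> AnnotationReport:
    """Full per-genome path: concatemer dedup, (optional) contig length
    floor, ORF calling, hallmark labeling, overlap pruning, curation, strand
    normalization and VP1-anchored linearization."""
    cfg = (cfg or PipelineConfig()).validate()
    rep = AnnotationReport(n_input=len(genomes))
    for g in genomes:
        g = genome_io.dedup_concatemers(g)
        if apply_length_filter and len(g) < cfg.min_contig_length:
            rep.n_length_filtered += 1
            continue
        if not g.genes:
            if cfg.translation_table == "auto":
                orfs, _ = call_orfs_auto(g, min_aa=cfg.min_orf_aa)
            else:
                orfs = call_orfs(g, table=int(cfg.translation_table), min_aa=cfg.min_orf_aa)
            g = replace(g, genes=orfs_to_genes(orfs))
            g.sort_genes()
        if profiles:  # pre-labeled inputs (e.g. trusted annotations) skip this
            g = label_hallmarks(g, profiles, e_max=cfg.hallmark_e_max)
        g = prune_overlapping_unknowns(g)
        result = curate_genome(g, require_vp2=cfg.require_vp2)
        if result.rejected:
            rep.rejected.append((g.genome_id, result.reason))
            continue
        rep.curated.append(linearize_at_vp1(result.genome))
    log.info(
        "annotation: %d in, %d curated, %d rejected, %d under length floor",
        rep.n_input, len(rep.curated), len(rep.rejected), rep.n_length_filtered,
    )
    return rep


def classify_genomes(
    curated: Sequence[GenomeRecord],
    cfg: Optional[PipelineConfig] = None,
) -> MicrovirusTaxonomy:
    cfg = (cfg or PipelineConfig()).validate()
    return MicrovirusTaxonomy.from_config(cfg).fit(curated)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: Path,
    cfg: PipelineConfig,
    seed: int,
    inputs: Sequence[Path],
    outputs: Sequence[Path],
    stages: dict,
    status: str = "ok",
) -> None:
    manifest = {
        "status": status,
        "config": cfg.to_dict(),
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
        "stages": stages,
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
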