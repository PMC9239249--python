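"""Protein clustering, bipartite genome-protein networks, and family/genus
assignment.

Families anchor on VP1, the major capsid protein and hallmark phylogenetic
marker: every tier-30 (30% AAI) protein cluster whose majority label is VP1
and which holds at least two proteins defines a family, and a genome belongs
to the family whose VP1 cluster contains its own VP1. Cohesive VP1-less
map-equation modules of more than five genomes become provisional families;
everything else is a singleton. Genera are tier-50 (50% AAI) map-equation
modules whose members share hallmark gene order (synteny) and >= 50% average
pairwise nucleotide identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from . import aai
from .annotate import classify_gene_order
from .config import PipelineConfig
from .partition import partition_genomes
from .records import AlignmentHit, GenomeRecord, TaxonAssignment

log = logging.getLogger(__name__)

SINGLETON = "SINGLETON"
CORE_HALLMARKS = ("VP1", "VP2", "VP4")


def protein_key(genome_id: str, gene_id: str) -> str:
    return f"{genome_id}|{gene_id}"


def collect_proteins(genomes: Iterable[GenomeRecord]) -> dict[str, str]:
    """All labeled gene products keyed by 'genome|gene'."""
    out = {}
    for g in genomes:
        for gene in g.genes:
            if gene.protein:
                out[protein_key(g.genome_id, gene.gene_id)] = gene.protein
    return out


@dataclass(frozen=True)
class ProteinCluster:
    """Single-linkage protein cluster at one AAI tier."""

    cluster_id: str
    tier: int
    members: frozenset[str]  # protein keys 'genome|gene'
    hallmark_label: str = "unknown"
    is_family_defining: bool = False

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(k.split("|", 1)[0] for k in self.members)


def cluster_proteins(
    all_keys: Iterable[str],
    hits: Sequence[AlignmentHit],
    tier: int,
    labels: Optional[Mapping[str, str]] = None,
) -> list[ProteinCluster]:
    """Connected components of the filtered hit graph; proteins without hits
    become singleton clusters. Cluster ids are deterministic (tier plus the
    lexicographic minimum member)."""
    G = nx.Graph()
    G.add_nodes_from(all_keys)
    for h in hits:
        G.add_edge(h.query_id, h.subject_id)
    clusters = []
    for comp in nx.connected_components(G):
        members = frozenset(comp)
        label = "unknown"
        if labels:
            tally: dict[str, int] = {}
            for k in members:
                tally[labels.get(k, "unknown")] = tally.get(labels.get(k, "unknown"), 0) + 1
            label = min(tally, key=lambda lb: (-tally[lb], lb))
        clusters.append(
            ProteinCluster(
                cluster_id=f"t{tier}:{min(members)}",
                tier=tier,
                members=members,
                hallmark_label=label,
            )
        )
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def clusters_nest(fine: Sequence[ProteinCluster], coarse: Sequence[ProteinCluster]) -> bool:
    """True iff every fine (tier-50) cluster lies inside one coarse (tier-30)
    cluster."""
    where = {}
    for c in coarse:
        for k in c.members:
            where[k] = c.cluster_id
    for c in fine:
        parents = {where.get(k) for k in c.members}
        if len(parents) != 1 or None in parents:
            return False
    return True


@dataclass
class BipartiteNetwork:
    """Genome-group nodes connected to the protein clusters their members
    carry. Group nodes are frozensets of genome ids (size one before any
    genus-level collapsing)."""

    tier: int
    groups: list[frozenset[str]]
    clusters: list[ProteinCluster]
    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def build(
        cls,
        genomes: Sequence[GenomeRecord],
        clusters: Sequence[ProteinCluster],
        tier: int,
        grouping: Optional[Mapping[str, str]] = None,
    ) -> "BipartiteNetwork":
        if grouping is None:
            groups = {g.genome_id: frozenset([g.genome_id]) for g in genomes}
        else:
            by_label: dict[str, set[str]] = {}
            for g in genomes:
                by_label.setdefault(grouping[g.genome_id], set()).add(g.genome_id)
            groups = {}
            for members in by_label.values():
                fs = frozenset(members)
                for m in members:
                    groups[m] = fs
        G = nx.Graph()
        uniq = sorted(set(groups.values()), key=lambda fs: min(fs))
        for fs in uniq:
            G.add_node(_group_node(fs), kind="genome_group", size=len(fs))
        for c in clusters:
            G.add_node(c.cluster_id, kind="protein_cluster", label=c.hallmark_label)
            for genome_id in c.genomes:
                G.add_edge(_group_node(groups[genome_id]), c.cluster_id)
        return cls(tier=tier, groups=uniq, clusters=list(clusters), graph=G)

    @property
    def group_nodes(self) -> list[str]:
        return [_group_node(fs) for fs in self.groups]


def _group_node(members: frozenset[str]) -> str:
    return "grp:" + "+".join(sorted(members))


# ---------------------------------------------------------------------------
# genus and family assignment


def assign_genera(
    modules: Mapping[str, int],
    genomes: Sequence[GenomeRecord],
    nt_identity_min: float = 50.0,
) -> dict[str, str]:
    """Turn tier-50 modules into genera.

    A module becomes one genus iff all members share the hallmark gene-order
    label (synteny) and hold together at >= the nucleotide-identity floor.
    Members violating either condition are split off (logged): the module is
    first grouped by gene-order label, then each group is partitioned into
    the connected components of its pairwise nt-identity >= floor graph.
    (Component linkage rather than a per-member average: when two cohesive
    subgroups are bridged by spurious protein-level edges, every member's
    average identity is dominated by its own subgroup and an average-based
    rule cannot separate them.) Returns genome_id -> genus_id.
    """
    by_id = {g.genome_id: g for g in genomes}
    members_of: dict[int, list[str]] = {}
    for gid, m in modules.items():
        members_of.setdefault(m, []).append(gid)
    genus_of: dict[str, str] = {}
    for m in sorted(members_of, key=lambda m: min(members_of[m])):
        ids = sorted(members_of[m])
        by_order: dict[str, list[str]] = {}
        for gid in ids:
            # core (VP1/VP2/VP4) order only: optional-hallmark detection on
            # short proteins is not reliable enough to define synteny
            by_order.setdefault(
                classify_gene_order(by_id[gid], include_optional=False), []
            ).append(gid)
        if len(by_order) > 1:
            log.info(
                "tier-50 module %s split by gene order into %d groups", min(ids), len(by_order)
            )
        for order_label in sorted(by_order):
            group = by_order[order_label]
            G = nx.Graph()
            G.add_nodes_from(group)
            for a, b in combinations(group, 2):
                if aai.nt_identity(by_id[a], by_id[b]) >= nt_identity_min:
                    G.add_edge(a, b)
            comps = sorted(nx.connected_components(G), key=min)
            if len(comps) > 1:
                log.info(
                    "genus candidate %s split into %d genera (nt identity < %.0f%%)",
                    min(group), len(comps), nt_identity_min,
                )
            for comp in comps:
                gname = f"g:{min(comp)}"
                for gid in comp:
                    genus_of[gid] = gname
    return genus_of


def assign_families(
    modules: Mapping[str, int],
    clusters: Sequence[ProteinCluster],
    genomes: Sequence[GenomeRecord],
    min_family_size: int = 6,
    min_vp1_cluster_size: int = 2,
) -> tuple[dict[str, str], list[ProteinCluster]]:
    """VP1-anchored family assignment at the 30% AAI tier.

    Every VP1-majority cluster with >= min_vp1_cluster_size members defines a
    family; a genome joins the family whose VP1 cluster contains its VP1
    gene. Genomes without such a connection fall back to their map-equation
    module: modules with more than (min_family_size - 1) such genomes become
    provisional (VP1-less) families, everything else is SINGLETON.
    Returns (genome_id -> family_id, family-defining clusters).
    """
    vp1_clusters = [
        c for c in clusters
        if c.hallmark_label == "VP1" and len(c.members) >= min_vp1_cluster_size
    ]
    vp1_clusters.sort(key=lambda c: (-len(c.members), c.cluster_id))
    family_of_cluster = {c.cluster_id: f"F{i + 1}" for i, c in enumerate(vp1_clusters)}
    defining = [replace_family_flag(c) for c in vp1_clusters]

    cluster_of_protein = {}
    for c in clusters:
        for k in c.members:
            cluster_of_protein[k] = c

    family_of: dict[str, str] = {}
    unplaced: list[str] = []
    for g in sorted(genomes, key=lambda g: g.genome_id):
        vp1 = g.find_gene("VP1")
        fam = None
        if vp1 is not None:
            c = cluster_of_protein.get(protein_key(g.genome_id, vp1.gene_id))
            if c is not None and c.cluster_id in family_of_cluster:
                fam = family_of_cluster[c.cluster_id]
        if fam is None:
            unplaced.append(g.genome_id)
        else:
            family_of[g.genome_id] = fam

    by_module: dict[int, list[str]] = {}
    for gid in unplaced:
        by_module.setdefault(modules[gid], []).append(gid)
    for m in sorted(by_module, key=lambda m: min(by_module[m])):
        ids = sorted(by_module[m])
        if len(ids) > min_family_size - 1:
            fam = f"PF:{min(ids)}"
            log.info("provisional VP1-less family %s (%d genomes)", fam, len(ids))
            for gid in ids:
                family_of[gid] = fam
        else:
            for gid in ids:
                family_of[gid] = SINGLETON
    return family_of, defining


def replace_family_flag(c: ProteinCluster) -> ProteinCluster:
    return ProteinCluster(
        cluster_id=c.cluster_id, tier=c.tier, members=c.members,
        hallmark_label=c.hallmark_label, is_family_defining=True,
    )


def reconcile_ranks(
    family_of: Mapping[str, str], genus_of: Mapping[str, str]
) -> dict[str, str]:
    """Enforce that the genus partition refines the family partition: a genus
    spanning several families (or mixing placed and singleton genomes) is
    split per family."""
    members: dict[str, list[str]] = {}
    for gid, genus in genus_of.items():
        members.setdefault(genus, []).append(gid)
    out = dict(genus_of)
    for genus, ids in sorted(members.items()):
        fams = {family_of[g] for g in ids}
        if len(fams) > 1:
            log.warning("genus %s spans families %s; splitting by family", genus, sorted(fams))
            for fam in sorted(fams):
                sub = sorted(g for g in ids if family_of[g] == fam)
                for g in sub:
                    out[g] = f"g:{min(sub)}"
    return out


def detect_shared_accessory(
    assignments: Sequence[TaxonAssignment],
    clusters: Sequence[ProteinCluster],
    proteins: Mapping[str, str],
) -> pd.DataFrame:
    """Tier-30 protein clusters whose members span two or more families
    (candidate horizontally shared proteins, the cross-family connections of
    the protein-sharing network)."""
    family_of = {a.genome_id: a.family_id for a in assignments}
    rows = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        fams = sorted(
            {family_of.get(g) for g in c.genomes} - {None, SINGLETON}
        )
        if len(fams) < 2:
            continue
        lengths = [len(proteins[k]) for k in c.members if k in proteins]
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "n_families": len(fams),
                "families": ",".join(fams),
                "n_members": len(c.members),
                "mean_length": round(sum(lengths) / len(lengths), 1) if lengths else 0.0,
                "label": c.hallmark_label,
                "members": ",".join(sorted(c.members)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_families", "families", "n_members",
            "mean_length", "label", "members",
        ],
    )


def export_network(
    net: BipartiteNetwork,
    assignments: Sequence[TaxonAssignment],
    graphml_path,
    edges_path=None,
) -> None:
    """GraphML plus a flat TSV edge list with node attributes (type, family,
    hallmark label), loadable by standard graph viewers."""
    family_of = {a.genome_id: a.family_id for a in assignments}
    G = nx.Graph()
    for fs in net.groups:
        fams = sorted({family_of.get(g, "") for g in fs})
        G.add_node(
            _group_node(fs), kind="genome_group", size=len(fs), family=";".join(fams)
        )
    for c in net.clusters:
        G.add_node(
            c.cluster_id, kind="protein_cluster", label=c.hallmark_label,
            family_defining=str(c.is_family_defining),
        )
    G.add_edges_from(net.graph.edges)
    nx.write_graphml(G, graphml_path)
    if edges_path is not None:
        with open(edges_path, "w") as fh:
            fh.write("source\ttarget\tsource_kind\ttarget_kind\n")
            for u, v in sorted(G.edges):
                fh.write(f"{u}\t{v}\t{G.nodes[u]['kind']}\t{G.nodes[v]['kind']}\n")


# ---------------------------------------------------------------------------
# the end-to-end estimator


class MicrovirusTaxonomy:
    """Protein-sharing-network classifier for microvirus genomes.

    sklearn-style estimator: ``fit`` learns protein clusters, bipartite
    networks and family/genus assignments from curated, hallmark-labeled
    genomes; ``predict`` classifies new contigs against the fitted reference
    by pooling their proteins and rebuilding the tiers.
    """

    def __init__(
        self,
        family_identity: float = 30.0,
        genus_identity: float = 50.0,
        min_coverage: float = 0.80,
        hit_e_max: float = 0.001,
        min_family_size: int = 6,
        nt_identity_min: float = 50.0,
        seed: int = 42,
    ):
        self.family_identity = family_identity
        self.genus_identity = genus_identity
        self.min_coverage = min_coverage
        self.hit_e_max = hit_e_max
        self.min_family_size = min_family_size
        self.nt_identity_min = nt_identity_min
        self.seed = seed

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "MicrovirusTaxonomy":
        return cls(
            family_identity=cfg.family_identity,
            genus_identity=cfg.genus_identity,
            min_coverage=cfg.min_coverage,
            hit_e_max=cfg.hit_e_max,
            min_family_size=cfg.min_family_size,
            nt_identity_min=cfg.nt_identity_min,
            seed=cfg.map_seed,
        )

    def get_params(self, deep: bool = True) -> dict:
        return {
            "family_identity": self.family_identity,
            "genus_identity": self.genus_identity,
            "min_coverage": self.min_coverage,
            "hit_e_max": self.hit_e_max,
            "min_family_size": self.min_family_size,
            "nt_identity_min": self.nt_identity_min,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "MicrovirusTaxonomy":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, genomes: Sequence[GenomeRecord]) -> "MicrovirusTaxonomy":
        """Learn the two-tier protein-sharing network and taxon assignments.

        ``genomes`` must be curated (single-strand, hallmark-labeled,
        VP1-anchored); see :mod:`microvinet.pipeline` for the raw-contig
        path."""
        genomes = sorted(genomes, key=lambda g: g.genome_id)
        self.genomes_ = genomes
        self.proteins_ = collect_proteins(genomes)
        self.protein_labels_ = {
            protein_key(g.genome_id, gene.gene_id): gene.label
            for g in genomes
            for gene in g.genes
            if gene.protein
        }
        self.hits_ = aai.all_vs_all(self.proteins_, e_max=self.hit_e_max, seed=self.seed)
        self.hits30_ = aai.filter_hits(self.hits_, self.family_identity, self.min_coverage)
        # the genus tier rests on the sharing of *conserved* proteins: the
        # universally present core triad (major capsid, DNA pilot,
        # replication initiator). Accessory peptides and the short optional
        # hallmarks carry too much identity variance to be informative at
        # this rank
        hallmark_keys = {
            k for k, lb in self.protein_labels_.items() if lb in CORE_HALLMARKS
        }
        self.hits50_ = [
            h
            for h in aai.filter_hits(self.hits_, self.genus_identity, self.min_coverage)
            if h.query_id in hallmark_keys and h.subject_id in hallmark_keys
        ]
        keys = sorted(self.proteins_)
        self.clusters30_ = cluster_proteins(keys, self.hits30_, 30, self.protein_labels_)
        self.clusters50_ = cluster_proteins(keys, self.hits50_, 50, self.protein_labels_)
        # the flow networks connect genomes through *shared* protein groups;
        # singleton clusters carry no sharing information and only dilute
        # the random-walk modules
        shared30 = [c for c in self.clusters30_ if len(c.members) >= 2]
        shared50 = [c for c in self.clusters50_ if len(c.members) >= 2]
        self.net30_ = BipartiteNetwork.build(genomes, shared30, 30)
        self.net50_ = BipartiteNetwork.build(genomes, shared50, 50)
        id_of_group = {_group_node(frozenset([g.genome_id])): g.genome_id for g in genomes}
        mod30 = partition_genomes(self.net30_.graph, self.net30_.group_nodes, seed=self.seed)
        mod50 = partition_genomes(self.net50_.graph, self.net50_.group_nodes, seed=self.seed)
        self.modules30_ = {id_of_group[k]: v for k, v in mod30.items()}
        self.modules50_ = {id_of_group[k]: v for k, v in mod50.items()}
        genus_of = assign_genera(self.modules50_, genomes, self.nt_identity_min)
        family_of, defining = assign_families(
            self.modules30_, self.clusters30_, genomes, self.min_family_size
        )
        genus_of = reconcile_ranks(family_of, genus_of)
        self.family_clusters_ = defining
        self.assignments_ = [
            TaxonAssignment(
                genome_id=g.genome_id,
                family_id=family_of[g.genome_id],
                genus_id=genus_of[g.genome_id],
            )
            for g in genomes
        ]
        self.shared_accessory_ = detect_shared_accessory(
            self.assignments_, self.clusters30_, self.proteins_
        )
        return self

    def fit_predict(self, genomes: Sequence[GenomeRecord]) -> list[TaxonAssignment]:
        return self.fit(genomes).assignments_

    # ------------------------------------------------------------------
    def predict(self, contigs: Sequence[GenomeRecord]) -> list[TaxonAssignment]:
        """Classify new (annotated, hallmark-labeled) contigs against the
        fitted reference: contigs inherit the family/genus of the reference
        clusters they join; reference-free tier-50 modules become novel
        genera; fully unconnected contigs are singletons."""
        self._check_fitted()
        ref_ids = {g.genome_id for g in self.genomes_}
        clash = ref_ids & {c.genome_id for c in contigs}
        if clash:
            raise ValueError(f"contig ids collide with reference: {sorted(clash)[:3]}")
        combined = MicrovirusTaxonomy(**self.get_params())
        combined.fit(list(self.genomes_) + list(contigs))
        ref_family = {a.genome_id: a.family_id for a in self.assignments_}
        ref_genus = {a.genome_id: a.genus_id for a in self.assignments_}
        new_family = {a.genome_id: a.family_id for a in combined.assignments_}
        new_genus = {a.genome_id: a.genus_id for a in combined.assignments_}

        def majority(values: list[str]) -> str:
            tally: dict[str, int] = {}
            for v in values:
                tally[v] = tally.get(v, 0) + 1
            return min(tally, key=lambda v: (-tally[v], v))

        fam_members: dict[str, list[str]] = {}
        genus_members: dict[str, list[str]] = {}
        for gid in new_family:
            fam_members.setdefault(new_family[gid], []).append(gid)
            genus_members.setdefault(new_genus[gid], []).append(gid)

        out = []
        for c in sorted(contigs, key=lambda g: g.genome_id):
            gid = c.genome_id
            notes = []
            fam = new_family[gid]
            ref_in_fam = [x for x in fam_members[fam] if x in ref_ids]
            if fam == SINGLETON:
                family = SINGLETON
            elif ref_in_fam:
                family = majority([ref_family[x] for x in ref_in_fam])
            else:
                family = fam
                notes.append("novel-family-candidate")
            ref_in_genus = [x for x in genus_members[new_genus[gid]] if x in ref_ids]
            if ref_in_genus:
                genus = majority([ref_genus[x] for x in ref_in_genus])
                novel = False
            else:
                genus = new_genus[gid]
                novel = True
            out.append(
                TaxonAssignment(
                    genome_id=gid, family_id=family, genus_id=genus,
                    novel_flag=novel, notes=";".join(notes),
                )
            )
        self.prediction_detail_ = combined
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "assignments_"):
            raise ValueError("estimator is not fitted")

    # ------------------------------------------------------------------
    def assignments_frame(self) -> pd.DataFrame:
        self._check_fitted()
        return pd.DataFrame(
            [
                {
                    "genome_id": a.genome_id,
                    "family": a.family_id,
                    "genus": a.genus_id,
                    "singleton": a.is_singleton,
                    "novel": a.novel_flag,
                    "notes": a.notes,
                }
                for a in self.assignments_
            ]
        )
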