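"""ORF calling (incl. circular wraparound and the Mycoplasma code), curation
rules, and hallmark gene-order classification."""

from __future__ import annotations

import numpy as np
import pytest

from microvinet.annotate import (
    call_orfs, call_orfs_auto, classify_gene_order, curate_genome,
)
from microvinet.genome_io import rotate_genome
from microvinet.records import GeneFeature, GenomeRecord, reverse_complement
from microvinet.simulate import simulate_taxonomy


class TestCallOrfs:
    def test_constructed_single_orf(self):
        seq = "ATG" + "AAA" * 50 + "TAA"
        g = GenomeRecord("g", seq + "T" * 20, is_circular=False)
        orfs = call_orfs(g, table=11, min_aa=33)
        assert len(orfs) == 1
        assert orfs[0].protein == "M" + "K" * 50
        assert (orfs[0].start, orfs[0].end) == (0, len(seq))

    def test_internal_tga_absent_table11_tryptophan_table4(self):
        # ORF with an internal TGA: split under the standard code, read
        # through as Trp under the Mycoplasma code
        seq = "ATG" + "AAA" * 20 + "TGA" + "AAA" * 20 + "TAA" + "T" * 20
        g = GenomeRecord("g", seq, is_circular=False)
        t11 = call_orfs(g, table=11, min_aa=33)
        t4 = call_orfs(g, table=4, min_aa=33)
        assert not any(o.start == 0 and o.end == 129 for o in t11)
        full = [o for o in t4 if o.start == 0 and o.end == 129]
        assert len(full) == 1
        assert full[0].protein == "M" + "K" * 20 + "W" + "K" * 20

    def test_circular_orf_spanning_origin_found_once(self):
        core = "ATG" + "CCA" * 40 + "TAA"  # 126 nt
        filler = "TTAATTAATTAA" * 10
        seq = core + filler
        # rotate so the ORF wraps the origin
        g = GenomeRecord("g", seq[60:] + seq[:60], is_circular=True)
        orfs = [o for o in call_orfs(g, min_aa=33) if o.strand == "+"]
        wrapped = [o for o in orfs if o.end > len(seq)]
        assert len(wrapped) == 1
        o = wrapped[0]
        assert o.start == len(seq) - 60
        assert o.end - o.start == len(core)
        assert o.protein == "M" + "P" * 40

    def test_circular_matches_doubled_linear_oracle(self, rng):
        # ORFs on a circular genome == ORFs of the doubled linear sequence
        # (start < n, length <= n), deduplicated modulo n
        genomes, _ = simulate_taxonomy(
            n_families=1, genera_per_family=1, genomes_per_genus=1, seed=5
        )
        g = rotate_genome(genomes[0], 1234)
        n = len(g)
        circ = {(o.start % n, o.length, o.strand) for o in call_orfs(g)}
        doubled = GenomeRecord("d", g.sequence * 2, is_circular=False)
        lin = {
            (o.start % n, o.length, o.strand if o.strand == "+" else o.strand)
            for o in call_orfs(doubled)
            if o.length <= n
        }
        # every circular ORF appears in the doubled-linear scan at some copy
        for start, length, strand in circ:
            if strand == "+":
                assert (start, length, "+") in lin or ((start + n) % n, length, "+") in lin

    def test_table11_orfs_stop_anchor_preserved_under_table4(self):
        # table 4 only removes TGA stops, so every TAA/TAG-anchored table-11
        # ORF persists under table 4 (possibly extended upstream). The stop
        # codon sits at `end` on '+' and at `start` (forward coords) on '-'.
        genomes, _ = simulate_taxonomy(
            n_families=1, genera_per_family=1, genomes_per_genus=1, seed=8
        )
        g = genomes[0]

        def stop_anchor(o):
            return (o.end % len(g) if o.strand == "+" else o.start, o.strand)

        anchors11 = {
            stop_anchor(o)
            for o in call_orfs(g, table=11)
            if g.gene_sequence(GeneFeature("t", o.start, o.end, o.strand))[-3:] != "TGA"
        }
        anchors4 = {stop_anchor(o) for o in call_orfs(g, table=4)}
        assert anchors11 <= anchors4

    def test_auto_retries_mycoplasma_code(self):
        # TGA-riddled genome: almost no ORFs under table 11
        seq = ("ATG" + ("AAATGA" * 12 + "AAA") * 3 + "TAA") + "TTAATTAATTAA" * 5
        g = GenomeRecord("g", seq, is_circular=False)
        orfs, table = call_orfs_auto(g, min_aa=33)
        assert table == 4
        assert len(orfs) >= 1

    def test_min_aa_precondition(self):
        g = GenomeRecord("g", "ATGAAATAA")
        with pytest.raises(ValueError):
            call_orfs(g, min_aa=5)


def _toy_genome(strand_of_unknown="-"):
    genes = [
        GeneFeature("a", 0, 93, "+", 11, "M" * 30, "VP1"),
        GeneFeature("b", 100, 193, "+", 11, "M" * 30, "VP2"),
        GeneFeature("c", 200, 293, "+", 11, "M" * 30, "VP4"),
        GeneFeature("d", 300, 393, strand_of_unknown, 11, "M" * 30, "unknown"),
    ]
    return GenomeRecord("g", "ACGT" * 100, is_circular=True, genes=genes)


class TestCurateGenome:
    def test_antisense_gene_removed_genome_retained(self):
        res = curate_genome(_toy_genome("-"))
        assert not res.rejected
        assert res.removed_genes == ["d"]
        assert [x.gene_id for x in res.genome.genes] == ["a", "b", "c"]

    def test_missing_vp4_rejected_with_reason(self):
        g = _toy_genome("+")
        g.genes = [x for x in g.genes if x.label != "VP4"]
        res = curate_genome(g)
        assert res.rejected and res.reason == "missing:VP4"

    def test_missing_vp1_rejected(self):
        g = _toy_genome("+")
        g.genes = [x for x in g.genes if x.label != "VP1"]
        assert curate_genome(g).reason == "missing:VP1"

    def test_vp2_absent_warns_by_default_rejects_when_required(self):
        g = _toy_genome("+")
        g.genes = [x for x in g.genes if x.label != "VP2"]
        res = curate_genome(g)
        assert not res.rejected
        assert any("Suborder II" in w for w in res.warnings)
        strict = curate_genome(_toy_genome("+").copy(), require_vp2=True)
        assert not strict.rejected  # VP2 present here
        g2 = _toy_genome("+")
        g2.genes = [x for x in g2.genes if x.label != "VP2"]
        assert curate_genome(g2, require_vp2=True).reason == "missing:VP2"

    def test_complete_forward_genome_unchanged(self):
        g = _toy_genome("+")
        res = curate_genome(g)
        assert not res.rejected
        assert res.genome.sequence == g.sequence
        assert len(res.genome.genes) == 4

    def test_all_genes_one_strand_after_curation(self):
        # VP1 on '-': genome gets reverse-complemented to put everything on +
        genes = [
            GeneFeature("a", 0, 93, "-", 11, "M" * 30, "VP1"),
            GeneFeature("b", 100, 193, "-", 11, "M" * 30, "VP2"),
            GeneFeature("c", 200, 293, "-", 11, "M" * 30, "VP4"),
        ]
        g = GenomeRecord("g", "ACGT" * 100, is_circular=True, genes=genes)
        res = curate_genome(g)
        assert not res.rejected
        assert all(x.strand == "+" for x in res.genome.genes)
        assert res.genome.sequence == reverse_complement(g.sequence)


class TestClassifyGeneOrder:
    def test_canonical_label(self):
        assert classify_gene_order(_toy_genome("+")) == "VP1-VP2-VP4"

    def test_rotation_invariant(self):
        g = _toy_genome("+")
        for off in (13, 150, 399):
            assert classify_gene_order(rotate_genome(g, off)) == "VP1-VP2-VP4"

    def test_reverse_complement_invariant(self):
        from microvinet.genome_io import normalize_strand

        g = _toy_genome("+")
        n = len(g.sequence)
        rc_genes = []
        for x in g.genes:
            start = (n - x.end) % n
            rc_genes.append(
                GeneFeature(x.gene_id, start, start + x.length, "-", 11, x.protein, x.label)
            )
        rc = GenomeRecord("g", reverse_complement(g.sequence), True, genes=rc_genes)
        assert classify_gene_order(rc) == classify_gene_order(g)

    def test_partial_label_when_core_missing(self):
        g = _toy_genome("+")
        g.genes = [x for x in g.genes if x.label != "VP2"]
        assert classify_gene_order(g) == "partial:VP1+VP4"

    def test_circular_core_orders_collapse_to_two_classes(self):
        """All 3! positional arrangements of the core genes yield exactly the
        two circular equivalence classes when read from VP1."""
        import itertools

        labels = set()
        for perm in itertools.permutations(("VP1", "VP2", "VP4")):
            genes = [
                GeneFeature(f"g{i}", 100 * i, 100 * i + 93, "+", 11, "M" * 30, lab)
                for i, lab in enumerate(perm)
            ]
            g = GenomeRecord("g", "ACGT" * 100, True, genes=genes)
            labels.add(classify_gene_order(g))
        assert labels == {"VP1-VP2-VP4", "VP1-VP4-VP2"}

    def test_generator_permutation_changes_class(self):
        genomes, truth = simulate_taxonomy(
            n_families=1, genera_per_family=2, genomes_per_genus=1, seed=11,
            order_permutations={"fam0g1": ("VP1", "VP4", "VP2")},
        )
        by_genus = {truth.genus[g.genome_id]: g for g in genomes}
        assert classify_gene_order(by_genus["fam0g0"], include_optional=False) == "VP1-VP2-VP4"
        assert classify_gene_order(by_genus["fam0g1"], include_optional=False) == "VP1-VP4-VP2"
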