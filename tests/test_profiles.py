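"""Profile HMM construction, forward scoring, calibration, iterative search
and hallmark labeling."""

from __future__ import annotations

import numpy as np
import pytest

from microvinet.profiles import ProfileHMM, build_profile, iterative_search, label_hallmarks
from microvinet.records import GeneFeature, GenomeRecord

from .oracles import forward_oracle_bits

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestBuildProfile:
    def test_identical_gapless_rows_peak_emissions(self):
        p = build_profile(["ACDEF"] * 3)
        assert p.n_match_ == 5
        # column 1 observes three A: (3 + 1) / (3 + 20)
        assert p.match_emissions_[1][AA.index("A")] == pytest.approx(4 / 23)
        assert np.argmax(p.match_emissions_[3]) == AA.index("D")

    def test_majority_gap_column_not_match(self):
        p = build_profile(["A-C", "A-C", "AGC"])  # middle column 2/3 gaps
        assert p.n_match_ == 2
        assert p.match_columns_ == [0, 2]

    def test_laplace_smoothing_hand_computed(self):
        # single column {A, A, C}: P(A) = (2+1)/(3+20), P(C) = (1+1)/23
        p = build_profile(["A", "A", "C"])
        assert p.match_emissions_[1][AA.index("A")] == pytest.approx(3 / 23)
        assert p.match_emissions_[1][AA.index("C")] == pytest.approx(2 / 23)
        assert p.match_emissions_[1][AA.index("W")] == pytest.approx(1 / 23)

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["ACD", "AC"])

    def test_transitions_normalize(self):
        p = build_profile(["AC-DE", "A-CDE", "ACCDE"])
        K = p.n_match_
        for j in range(K + 1):
            for src in "MID":
                tot = sum(p.transitions_[src + t][j] for t in "MID")
                if src == "D" and j == 0:
                    continue  # no D_0 state
                assert tot == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_for_fixed_input(self):
        a = build_profile(["ACDEF", "ACDFF", "ACD-F"])
        b = build_profile(["ACDEF", "ACDFF", "ACD-F"])
        assert np.array_equal(a.match_emissions_, b.match_emissions_)
        for t in a.transitions_:
            assert np.array_equal(a.transitions_[t], b.transitions_[t])


class TestForwardScore:
    @pytest.mark.parametrize("msa,seqs", [
        (["AC", "AC"], ["AC", "A", "ACC", "W"]),
        (["ACD", "A-D", "AGD"], ["ACD", "AD", "GGG", "ACDEF"]),
        (["ACDE", "ACDE", "AC-E"], ["ACDE", "ACE", "WACDEW"]),
        (["A", "C"], ["A", "C", "W"]),
    ])
    def test_forward_equals_exhaustive_path_sum(self, msa, seqs):
        p = build_profile(msa)
        assert p.n_match_ <= 4
        for s in seqs:
            assert len(s) <= 6
            assert p.score(s) == pytest.approx(forward_oracle_bits(p, s), abs=1e-9)

    def test_consensus_beats_shuffles(self, rng):
        rows = ["MKLVNERTWQACDFGH" * 2] * 4
        p = build_profile(rows)
        cons = rows[0]
        s_cons = p.score(cons)
        shuffled_scores = []
        letters = list(cons)
        for _ in range(100):
            rng.shuffle(letters)
            shuffled_scores.append(p.score("".join(letters)))
        assert s_cons > float(np.median(shuffled_scores))

    def test_single_column_closed_form(self):
        # 1 match state vs 1-residue protein: the only valid state path is
        # Begin -> M1 -> End (flank/delete routes either emit too much or are
        # disallowed), so the score is a single closed-form term.
        p = build_profile(["A", "A"])
        t = p.transitions_
        e_odds = p.match_emissions_[1][0] / p.background[0]
        expected = np.log2(t["MM"][0] * e_odds * t["MM"][1])
        assert p.score("A") == pytest.approx(expected, abs=1e-9)

    def test_unknown_residue_scores_as_background(self):
        p = build_profile(["ACDEF"] * 3)
        assert p.score("XXXXX") == pytest.approx(p.score("XXXXX"))
        # replacing one consensus residue by X removes its (positive) odds
        assert p.score("ACDEF") > p.score("ACDEX")


class TestCalibration:
    def test_self_consistency_mean_evalue(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list(AA), size=40)) for _ in range(4)]
        p = build_profile(rows)
        hits_at_e1 = []
        for seed in range(5):
            p.calibrate(n_decoys=300, seed=seed)
            rng2 = np.random.default_rng(100 + seed)
            n = 300
            count = 0
            for _ in range(n):
                s = p.score("".join(rng2.choice(list(AA), size=40)))
                if p.evalue(s, n) <= 1.0:
                    count += 1
            hits_at_e1.append(count)
        mean = np.mean(hits_at_e1)
        assert 0.5 <= mean <= 1.5  # ~1 expected, +-50%

    def test_doubling_n_doubles_evalue(self):
        p = build_profile(["ACDEFGHIKL"] * 3).calibrate(n_decoys=200, seed=0)
        s = p.score("ACDEFGHIKL") - 30  # a score in the unclamped regime
        assert p.evalue(s, 200) == pytest.approx(2 * p.evalue(s, 100))

    def test_fixed_seed_reproducible(self):
        p1 = build_profile(["ACDEFGHIKL"] * 3).calibrate(n_decoys=200, seed=5)
        p2 = build_profile(["ACDEFGHIKL"] * 3).calibrate(n_decoys=200, seed=5)
        assert p1.calibration_ == p2.calibration_

    def test_too_few_decoys_rejected(self):
        p = build_profile(["ACDEFGHIKL"] * 3)
        with pytest.raises(ValueError):
            p.calibrate(n_decoys=100, seed=0)


def _family(rng, n, length=90, divergence=0.45):
    ancestor = "".join(rng.choice(list(AA), size=length))
    out = {}
    for i in range(n):
        seq = list(ancestor)
        for pos in rng.choice(length, size=int(divergence * length), replace=False):
            seq[pos] = AA[int(rng.integers(20))]
        out[f"hom{i:02d}"] = "".join(seq)
    return ancestor, out


class TestIterativeSearch:
    def test_db_containing_only_seed_is_fixpoint(self):
        seeds = {"s": "MKLVNERTWQACDFGH"}
        hits, prof, converged = iterative_search(seeds, {"p1": "MKLVNERTWQACDFGH"}, seed=0)
        assert converged
        assert [h.protein_id for h in hits] == ["p1"]

    def test_planted_homologs_recovered_no_decoys(self, rng):
        ancestor, homs = _family(rng, 10, divergence=0.45)
        decoys = {f"dec{i:02d}": "".join(rng.choice(list(AA), size=90)) for i in range(50)}
        db = {**homs, **decoys}
        hits, prof, _ = iterative_search({"seed": ancestor}, db, e_max=0.05, seed=0)
        found = {h.protein_id for h in hits}
        assert set(homs) <= found
        assert not (found & set(decoys))

    def test_emax_zero_yields_nothing(self, rng):
        ancestor, homs = _family(rng, 4)
        hits, _, _ = iterative_search({"seed": ancestor}, homs, e_max=0.0, seed=0)
        assert hits == []

    def test_hit_set_monotone_across_rounds(self, rng):
        ancestor, homs = _family(rng, 8, divergence=0.5)
        seen: list[set] = []
        for it in range(1, 4):
            hits, _, _ = iterative_search({"seed": ancestor}, homs, max_iter=it, seed=0)
            seen.append({h.protein_id for h in hits})
        assert seen[0] <= seen[1] <= seen[2]


class TestLabelHallmarks:
    def _profiles(self):
        vp1 = build_profile(["MKLVNERTWQACDFGHMKLVNERTWQACDFGH"] * 3, name="vp1", label="VP1")
        vp2 = build_profile(["ACDEFACDEFACDEFACDEF"] * 3, name="vp2", label="VP2")
        for p in (vp1, vp2):
            p.calibrate(n_decoys=200, seed=0)
        return [vp1, vp2]

    def _genome(self, proteins):
        genes = [
            GeneFeature(f"g{i}", 100 * i, 100 * i + 3 * (len(p) + 1), "+", 11, p)
            for i, p in enumerate(proteins)
        ]
        return GenomeRecord("g", "ACGT" * 1000, True, genes=genes)

    def test_consensus_genes_labeled(self):
        profs = self._profiles()
        g = self._genome(["MKLVNERTWQACDFGHMKLVNERTWQACDFGH", "ACDEFACDEFACDEFACDEF", "WWWWWWWWWW"])
        g = label_hallmarks(g, profs)
        assert [x.label for x in g.genes] == ["VP1", "VP2", "unknown"]

    def test_duplicate_vp1_tie_broken_by_coordinate(self):
        profs = self._profiles()
        vp1_seq = "MKLVNERTWQACDFGHMKLVNERTWQACDFGH"
        g = self._genome([vp1_seq, vp1_seq])
        g = label_hallmarks(g, profs)
        assert g.genes[0].label == "VP1"
        assert g.genes[1].label == "VP1-duplicate"

    def test_uncalibrated_profile_rejected(self):
        p = build_profile(["ACDEF"] * 2)
        g = self._genome(["ACDEF"])
        with pytest.raises(ValueError, match="calibrated"):
            label_hallmarks(g, [p])

    def test_labeling_invariant_under_profile_order(self):
        profs = self._profiles()
        g1 = label_hallmarks(self._genome(["ACDEFACDEFACDEFACDEF"]), profs)
        g2 = label_hallmarks(self._genome(["ACDEFACDEFACDEFACDEF"]), profs[::-1])
        assert [x.label for x in g1.genes] == [x.label for x in g2.genes]


class TestSerialization:
    def test_json_round_trip_preserves_scores(self):
        p = build_profile(["ACDEFGHIKL", "ACDEFGHIKL", "ACWEFGHIKL"], name="t", label="VP3")
        p.calibrate(n_decoys=200, seed=2)
        q = ProfileHMM.from_json(p.to_json())
        for seq in ("ACDEFGHIKL", "WWWWW", "ACW"):
            assert q.score(seq) == pytest.approx(p.score(seq), abs=1e-12)
        assert q.calibration_ == pytest.approx(p.calibration_)
        assert q.label == "VP3"
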