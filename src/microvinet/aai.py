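"""Pairwise protein alignment, amino-acid identity (AAI) and coverage, decoy-
calibrated all-vs-all hit tables, and pairwise nucleotide identity.

AAI hits feed the protein-sharing networks: a pair of proteins is connected
at a tier when it aligns with >= 80% coverage of the shorter protein and
identity above the tier threshold (30% for families, 50% for genera).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
from Bio.Align import substitution_matrices
from scipy import stats

from ._kernels import sw_align, sw_score_affine
from .records import AlignmentHit, GenomeRecord

log = logging.getLogger(__name__)

GAP_OPEN = 11.0
GAP_EXT = 1.0

# 20 canonical residues first; anything else (X, B, Z, *, unknown) maps to
# index 20 and scores like BLOSUM62's X column.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}


def _build_submatrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    sub = np.zeros((21, 21), dtype=np.float64)
    letters = AA_ORDER + "X"
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            sub[i, j] = blosum[a][b]
    return sub


BLOSUM62 = _build_submatrix()


def encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.int64)


def align_pair(
    a: str,
    b: str,
    query_id: str = "query",
    subject_id: str = "subject",
) -> Optional[AlignmentHit]:
    """Optimal Smith-Waterman local alignment of two proteins.

    BLOSUM62 scoring with affine gaps (open 11, extend 1); identity is the
    percentage of identical residues over all alignment columns (gap columns
    included) and coverage the aligned fraction of the shorter protein.
    Returns None when no positive-scoring alignment exists. Identity and
    coverage are symmetric in the two inputs: the pair is canonically ordered
    internally before aligning, so hit(a, b) and hit(b, a) agree exactly.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    swapped = (b, subject_id) < (a, query_id)
    s1, s2 = (b, a) if swapped else (a, b)
    res = sw_align(encode_protein(s1), encode_protein(s2), BLOSUM62, GAP_OPEN, GAP_EXT)
    score, qs, qe, ss, se, matches, mismatches, gaps_q, gaps_s = res
    if score <= 0.0:
        return None
    columns = matches + mismatches + gaps_q + gaps_s
    shorter = min(len(a), len(b))
    # residues of the shorter protein inside the alignment
    span1, span2 = qe - qs, se - ss
    covered = span1 if len(s1) <= len(s2) else span2
    if swapped:
        qs, qe, ss, se = ss, se, qs, qe
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=100.0 * matches / columns,
        coverage=covered / shorter,
        score=float(score),
        aln_len=columns,
        mismatches=mismatches,
        gaps=gaps_q + gaps_s,
        qstart=qs,
        qend=qe,
        sstart=ss,
        send=se,
    )


def _pair_score(a_enc: np.ndarray, b_enc: np.ndarray) -> float:
    return sw_score_affine(a_enc, b_enc, BLOSUM62, GAP_OPEN, GAP_EXT)


def calibrate_scores(
    proteins: Sequence[np.ndarray],
    n_decoys: int = 300,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit an extreme-value (Gumbel) null to Smith-Waterman scores of
    shuffled-protein decoy pairs. Returns (location, scale in bits-like raw
    score units); scale is floored to avoid degenerate fits on
    zero-variance decoy sets."""
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys, dtype=np.float64)
    k = len(proteins)
    for t in range(n_decoys):
        i = int(rng.integers(k))
        j = int(rng.integers(k))
        da = proteins[i][rng.permutation(len(proteins[i]))]
        db = proteins[j][rng.permutation(len(proteins[j]))]
        scores[t] = _pair_score(da, db)
    loc, scale = stats.gumbel_r.fit(scores)
    if scale < 1e-9:
        log.warning("degenerate decoy score distribution; scale floored")
        scale = 1e-9
    return float(loc), float(scale)


def evalue_from_score(score: float, loc: float, scale: float, n: int) -> float:
    """E-value under the fitted extreme-value null: N * exp(-(s - mu)/beta)."""
    z = min((score - loc) / scale, 700.0)
    if z < -500.0:  # hopeless scores: clamp instead of overflowing exp
        return float(n)
    return float(min(n, n * np.exp(-z)))


def all_vs_all(
    proteins: Mapping[str, str],
    e_max: float = 0.001,
    seed: int = 0,
    n_decoys: int = 300,
) -> list[AlignmentHit]:
    """All unordered protein pairs whose decoy-calibrated significance is
    <= e_max. Self-hits are excluded; output is ordered lexicographically by
    (query_id, subject_id) with query_id < subject_id, so it is invariant
    under input-order permutation."""
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValueError("all_vs_all needs at least two proteins")
    enc = {pid: encode_protein(proteins[pid]) for pid in ids}
    loc, scale = calibrate_scores([enc[pid] for pid in ids], n_decoys=n_decoys, seed=seed)
    n_pairs = len(ids) * (len(ids) - 1) // 2
    hits: list[AlignmentHit] = []
    for xi in range(len(ids)):
        for yi in range(xi + 1, len(ids)):
            qid, sid = ids[xi], ids[yi]
            score = _pair_score(enc[qid], enc[sid])
            if score <= 0.0:
                continue
            ev = evalue_from_score(score, loc, scale, n_pairs)
            if ev > e_max:
                continue
            hit = align_pair(proteins[qid], proteins[sid], qid, sid)
            if hit is None:
                continue
            hit.significance = ev
            hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float,
    min_coverage: float = 0.80,
) -> list[AlignmentHit]:
    """Tier gate: identity >= min_identity AND coverage >= min_coverage.
    The 50%-tier output is by construction a subset of the 30%-tier output."""
    return [h for h in hits if h.identity >= min_identity and h.coverage >= min_coverage]


def hits_to_table(hits: Iterable[AlignmentHit]):
    """BLAST outfmt-6-style rows plus a 13th coverage column."""
    import pandas as pd

    rows = [
        (
            h.query_id,
            h.subject_id,
            round(h.identity, 3),
            h.aln_len,
            h.mismatches,
            h.gaps,
            h.qstart + 1,
            h.qend,
            h.sstart + 1,
            h.send,
            h.significance,
            round(h.score, 1),
            round(h.coverage, 4),
        )
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query", "subject", "identity", "aln_len", "mismatches", "gaps",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore", "coverage",
        ],
    )


# ---------------------------------------------------------------------------
# nucleotide identity


def _cigar_walk(cigar: str):
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            yield int(num), c
            num = ""


def identity_from_cigar(cigar: str) -> tuple[int, int]:
    """(matches, columns) over an extended CIGAR with terminal gaps trimmed."""
    ops = list(_cigar_walk(cigar))
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    matches = sum(n for n, op in ops if op == "=")
    columns = sum(n for n, op in ops)
    return matches, columns


def nt_identity(a: GenomeRecord, b: GenomeRecord) -> float:
    """Global (edit-distance-optimal) nucleotide identity between two genomes,
    each rotated to its VP1 anchor first when possible. Identity is
    matches / alignment columns with terminal gaps excluded, in percent."""
    from .genome_io import linearize_at_vp1

    sa, sb = a, b
    for rec in (a, b):
        if len(rec.sequence) < 100:
            raise ValueError(f"{rec.genome_id}: sequence shorter than 100 nt")
    if a.is_circular and a.find_gene("VP1"):
        sa = linearize_at_vp1(a)
    if b.is_circular and b.find_gene("VP1"):
        sb = linearize_at_vp1(b)
    if sa.sequence == sb.sequence:
        return 100.0
    res = edlib.align(sa.sequence, sb.sequence, mode="NW", task="path")
    matches, columns = identity_from_cigar(res["cigar"])
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns
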