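"""Position-specific profile HMMs for hallmark-protein detection.

A profile is estimated from a seed alignment (match columns = columns with
<= 50% gaps, Laplace pseudocount 1), scored against candidate proteins by the
full forward algorithm in log space, and calibrated against shuffled-
background decoys so scores convert to E-values. Iterative search rebuilds
the profile from its hit set until a fixpoint, mirroring jackhmmer-style
discovery of diverged homologs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._kernels import forward_bits, viterbi_match_columns
from .aai import AA_ORDER, encode_protein
from .records import GenomeRecord

log = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
NEGLOG = -1.0e30

# transition source/target slots; index j runs over columns 0..K where
# M_0 is Begin and transitions out of column K lead to End in the M slot.
_TRANS_NAMES = ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DD", "DI")


@dataclass
class ProfileHMM:
    """A fitted profile hidden Markov model.

    Estimator-style: construct with hyperparameters, call :meth:`fit` with an
    alignment, then :meth:`score`. Fitted attributes carry a trailing
    underscore. ``label`` names the hallmark the profile detects (VP1..VP8 or
    an accessory category); ``name`` identifies the seed set.
    """

    name: str = "profile"
    label: str = "unknown"
    gap_threshold: float = 0.5
    pseudocount: float = 1.0
    background: Optional[np.ndarray] = None  # length 20; default uniform

    # fitted state
    n_match_: int = 0
    match_emissions_: Optional[np.ndarray] = None  # (K+1, 20) probabilities
    transitions_: Optional[dict] = None  # name -> (K+1,) probabilities
    calibration_: Optional[tuple[float, float]] = None  # Gumbel (loc, scale)
    match_columns_: Optional[list[int]] = None

    # log-space caches for the kernels
    _lo_match: Optional[np.ndarray] = field(default=None, repr=False)
    _log_trans: Optional[dict] = field(default=None, repr=False)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "name": self.name,
            "label": self.label,
            "gap_threshold": self.gap_threshold,
            "pseudocount": self.pseudocount,
            "background": self.background,
        }

    def set_params(self, **params) -> "ProfileHMM":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, aligned: Sequence[str]) -> "ProfileHMM":
        """Estimate the profile from an alignment (>= 2 rows of equal length,
        or a single unaligned sequence which forms a trivial profile)."""
        if not aligned:
            raise ValueError("empty alignment")
        width = len(aligned[0])
        if any(len(s) != width for s in aligned):
            raise ValueError("ragged alignment: sequences differ in length")
        if width == 0:
            raise ValueError("zero-width alignment")
        rows = [s.upper() for s in aligned]
        n_seq = len(rows)
        bg = self.background if self.background is not None else np.full(20, 0.05)
        bg = np.asarray(bg, dtype=np.float64)

        is_match = []
        for c in range(width):
            gaps = sum(1 for r in rows if r[c] in GAP_CHARS)
            is_match.append(gaps / n_seq <= self.gap_threshold)
        match_cols = [c for c, m in enumerate(is_match) if m]
        K = len(match_cols)
        if K == 0:
            raise ValueError("no match columns under the gap threshold")

        pc = self.pseudocount
        emis = np.full((K + 1, 20), np.nan)
        emis[0] = bg  # unused row for Begin
        for k, c in enumerate(match_cols, start=1):
            counts = np.full(20, pc, dtype=np.float64)
            for r in rows:
                ch = r[c]
                if ch in GAP_CHARS:
                    continue
                idx = AA_ORDER.find(ch)
                if idx >= 0:
                    counts[idx] += 1.0
            emis[k] = counts / counts.sum()

        # transition counts from each sequence's path through the columns
        counts = {t: np.full(K + 1, pc, dtype=np.float64) for t in _TRANS_NAMES}
        col_of = {c: k for k, c in enumerate(match_cols, start=1)}
        for r in rows:
            state, j = "M", 0  # Begin
            for c in range(width):
                if is_match[c]:
                    nxt = "M" if r[c] not in GAP_CHARS else "D"
                    counts[state + nxt][j] += 1.0
                    state, j = nxt, col_of[c]
                elif r[c] not in GAP_CHARS:
                    counts[state + "I"][j] += 1.0
                    state = "I"
            counts[state + "M"][j] += 1.0  # -> End
        trans = self._normalize_transitions(counts, K)
        self.n_match_ = K
        self.match_columns_ = match_cols
        self.match_emissions_ = emis
        self.transitions_ = trans
        self.background = bg
        self._build_log_caches()
        self.calibration_ = None
        return self

    # self-loop probability of the terminal flank insert states: flanking
    # sequence around the matched domain is near-free (glocal semantics), as
    # in standard profile-search tools; without this a called ORF whose
    # boundaries overshoot the domain would be heavily penalized
    FLANK_LOOP = 0.99

    @classmethod
    def _normalize_transitions(cls, counts: dict, K: int) -> dict:
        """Normalize per source state and column over the allowed targets.
        At column K the D slot is unavailable (no column K+1 deletions), and
        D_K moves to End with probability 1. The N-/C-terminal flank insert
        states (I_0, I_K) are overridden with a fixed high self-loop."""
        trans = {t: np.zeros(K + 1) for t in _TRANS_NAMES}
        for src in ("M", "I", "D"):
            for j in range(K + 1):
                opts = ["M", "I", "D"] if j < K else ["M", "I"]
                if src == "D" and j == K:
                    opts = ["M"]
                total = sum(counts[src + t][j] for t in opts)
                for t in ("M", "I", "D"):
                    key = src + t
                    trans[key][j] = counts[key][j] / total if t in opts else 0.0
        for j in (0, K):
            trans["II"][j] = cls.FLANK_LOOP
            trans["IM"][j] = 1.0 - cls.FLANK_LOOP
            trans["ID"][j] = 0.0
        return trans

    def _build_log_caches(self) -> None:
        K = self.n_match_
        lo = np.zeros((K + 1, 21))
        with np.errstate(divide="ignore"):
            lo[:, :20] = np.log(self.match_emissions_) - np.log(self.background)
        lo[0, :] = 0.0
        lo[:, 20] = 0.0  # out-of-alphabet residues score as background
        self._lo_match = lo
        logt = {}
        with np.errstate(divide="ignore"):
            for t in _TRANS_NAMES:
                logt[t] = np.where(
                    self.transitions_[t] > 0.0, np.log(self.transitions_[t]), NEGLOG
                )
        self._log_trans = logt

    # ------------------------------------------------------------------
    def score(self, protein: str) -> float:
        """Log-odds forward score in bits versus an i.i.d. background null."""
        self._check_fitted()
        if len(protein) < 1:
            raise ValueError("empty protein")
        t = self._log_trans
        return float(
            forward_bits(
                encode_protein(protein), self._lo_match,
                t["MM"], t["MI"], t["MD"], t["IM"], t["II"], t["ID"],
                t["DM"], t["DD"], t["DI"],
            )
        )

    def viterbi_columns(self, protein: str) -> tuple[np.ndarray, int, int]:
        """Best-path assignment of residues to match columns (realignment)."""
        self._check_fitted()
        t = self._log_trans
        return viterbi_match_columns(
            encode_protein(protein), self._lo_match,
            t["MM"], t["MI"], t["MD"], t["IM"], t["II"], t["ID"],
            t["DM"], t["DD"], t["DI"],
        )

    def realign(self, protein: str) -> str:
        """Project a protein onto the profile's match columns, giving one row
        of a fixed-width alignment (inserts dropped, deletions as gaps)."""
        cols, _, _ = self.viterbi_columns(protein)
        return "".join(protein[i] if i >= 0 else "-" for i in cols)

    def calibrate(self, n_decoys: int = 300, seed: int = 0) -> "ProfileHMM":
        """Fit an extreme-value null to scores of random background-composition
        decoy sequences; E-value(score, N) = N * exp(-(score - mu)/beta).

        The exponential tail is fitted by peaks-over-threshold (exceedances
        over the 90th percentile): forward scores sum over paths rather than
        maximize, so their null is lighter-tailed than the Gumbel of optimal-
        alignment scores and a full-distribution fit would miscalibrate the
        tail that E-values live in."""
        self._check_fitted()
        if n_decoys < 200:
            raise ValueError("n_decoys must be >= 200")
        rng = np.random.default_rng(seed)
        length = max(30, self.n_match_)
        letters = np.array(list(AA_ORDER))
        scores = np.empty(n_decoys)
        for i in range(n_decoys):
            seq = "".join(rng.choice(letters, size=length, p=self.background / self.background.sum()))
            scores[i] = self.score(seq)
        if np.std(scores) < 1e-9:
            raise ValueError("degenerate decoy score distribution (zero variance)")
        u = float(np.quantile(scores, 0.90))
        exceed = scores[scores > u] - u
        if len(exceed) < 10 or float(np.mean(exceed)) < 1e-9:
            raise ValueError("degenerate decoy score distribution (no tail)")
        scale = float(np.mean(exceed))  # exponential-tail MLE
        frac = len(exceed) / n_decoys
        # P(S >= s) ~ frac * exp(-(s-u)/scale) = exp(-(s-mu)/scale)
        loc = u + scale * float(np.log(frac))
        self.calibration_ = (loc, scale)
        return self

    def evalue(self, score: float, n: int) -> float:
        if self.calibration_ is None:
            raise ValueError("profile is not calibrated")
        loc, scale = self.calibration_
        z = min((score - loc) / scale, 700.0)
        if z < -500.0:  # hopeless scores: clamp instead of overflowing exp
            return float(n)
        return float(min(n, n * np.exp(-z)))

    def _check_fitted(self) -> None:
        if self.match_emissions_ is None:
            raise ValueError("profile is not fitted")

    # ------------------------------------------------------------------
    def to_json(self) -> str:
        self._check_fitted()
        payload = {
            "name": self.name,
            "label": self.label,
            "gap_threshold": self.gap_threshold,
            "pseudocount": self.pseudocount,
            "background": self.background.tolist(),
            "n_match": self.n_match_,
            "match_columns": self.match_columns_,
            "match_emissions": self.match_emissions_.tolist(),
            "transitions": {t: v.tolist() for t, v in self.transitions_.items()},
            "calibration": self.calibration_,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        d = json.loads(text)
        p = cls(
            name=d["name"], label=d["label"], gap_threshold=d["gap_threshold"],
            pseudocount=d["pseudocount"], background=np.array(d["background"]),
        )
        p.n_match_ = d["n_match"]
        p.match_columns_ = d["match_columns"]
        p.match_emissions_ = np.array(d["match_emissions"])
        p.transitions_ = {t: np.array(v) for t, v in d["transitions"].items()}
        p.calibration_ = tuple(d["calibration"]) if d["calibration"] else None
        p._build_log_caches()
        return p


def build_profile(
    msa: Sequence[str], name: str = "profile", label: str = "unknown", **kw
) -> ProfileHMM:
    """Thin functional wrapper: fit a ProfileHMM on an alignment."""
    return ProfileHMM(name=name, label=label, **kw).fit(msa)


@dataclass(frozen=True)
class ProfileHit:
    protein_id: str
    profile: str
    bitscore: float
    evalue: float
    span: tuple[int, int]


def iterative_search(
    seeds: Mapping[str, str],
    db: Mapping[str, str],
    e_max: float = 0.05,
    max_iter: int = 10,
    name: str = "search",
    label: str = "unknown",
    seed: int = 0,
    n_decoys: int = 300,
) -> tuple[list[ProfileHit], ProfileHMM, bool]:
    """Iterative profile search: build from seeds, absorb db hits with
    E <= e_max, rebuild from the Viterbi-realigned hit set, repeat until the
    hit set stops growing (the set is monotone non-decreasing by
    construction). Returns (hits, final profile, converged)."""
    if not seeds or not db:
        raise ValueError("seeds and db must be non-empty")
    seed_rows = list(seeds.values())
    width = len(seed_rows[0])
    if any(len(s) != width for s in seed_rows):
        raise ValueError("seed alignment is ragged")
    profile = build_profile(seed_rows, name=name, label=label)
    member_rows: dict[str, str] = {f"seed:{k}": v for k, v in seeds.items()}
    accepted: dict[str, ProfileHit] = {}
    converged = False
    for it in range(max_iter):
        profile.calibrate(n_decoys=n_decoys, seed=seed + it)
        new = 0
        for pid in sorted(db):
            if pid in accepted:
                continue
            s = profile.score(db[pid])
            ev = profile.evalue(s, len(db))
            if ev <= e_max:
                _, a0, a1 = profile.viterbi_columns(db[pid])
                accepted[pid] = ProfileHit(pid, name, s, ev, (a0, a1))
                member_rows[pid] = profile.realign(db[pid])
                new += 1
        if new == 0:
            converged = True
            break
        profile = build_profile(
            list(member_rows.values()), name=name, label=label,
            gap_threshold=profile.gap_threshold, pseudocount=profile.pseudocount,
        )
    if not converged:
        profile.calibrate(n_decoys=n_decoys, seed=seed + max_iter)
        log.warning("%s: iterative search did not converge in %d rounds", name, max_iter)
    hits = [accepted[pid] for pid in sorted(accepted)]
    return hits, profile, converged


def label_hallmarks(
    g: GenomeRecord,
    profiles: Iterable[ProfileHMM],
    e_max: float = 0.05,
) -> GenomeRecord:
    """Assign each gene the label of its best-scoring profile at E <= e_max,
    else "unknown". At most one gene per genome carries VP1: ties go to the
    best bit score, then the lowest start coordinate; demoted copies are
    relabeled "VP1-duplicate"."""
    profs = list(profiles)
    for p in profs:
        if p.calibration_ is None:
            raise ValueError(f"profile {p.name} must be calibrated before labeling")
    n_db = max(1, len(g.genes))
    scored: list[tuple[float, float, str]] = []  # (evalue, -score, label) per gene
    for gene in g.genes:
        best_label, best_ev, best_score = "unknown", np.inf, -np.inf
        if gene.protein:
            for p in profs:
                s = p.score(gene.protein)
                ev = p.evalue(s, n_db)
                if ev <= e_max and (s > best_score or (s == best_score and p.label < best_label)):
                    best_label, best_ev, best_score = p.label, ev, s
        gene.label = best_label
        scored.append((best_ev, -best_score, best_label))
    vp1s = [(sc[1], g.genes[i].start, i) for i, sc in enumerate(scored) if g.genes[i].label == "VP1"]
    if len(vp1s) > 1:
        vp1s.sort()
        keep = vp1s[0][2]
        for _, _, i in vp1s[1:]:
            g.genes[i].label = "VP1-duplicate"
        log.warning(
            "%s: %d genes scored as VP1; kept %s", g.genome_id, len(vp1s), g.genes[keep].gene_id
        )
    return g
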