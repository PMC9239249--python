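"""Read recruitment at a nucleotide-identity floor and per-taxon relative
abundance profiles.

The recruiter is a seed-and-extend mapper: exact k-mer seeds (k = 13 by
default) vote for candidate genomes, reads with at least two seeds on one
diagonal band are extended by infix alignment, and a read counts for the
single best genome whose alignment identity clears the floor (50% by
default, mirroring permissive virome read recruitment). Ties are split
fractionally so counts conserve the mapped-read total exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import pandas as pd

from .records import GenomeRecord, TaxonAssignment

log = logging.getLogger(__name__)


def read_fastq(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]


class ReadRecruiter:
    """Seed-and-extend read mapper (sklearn-style estimator).

    Parameters
    ----------
    k : int
        Seed k-mer size.
    min_identity : float
        Percent identity floor over the read for a placement to count.
    min_read_fraction : float
        Minimum fraction of the read that must be aligned (infix alignment
        aligns the full read, so this gates degenerate cases only).
    band_slack : int
        Diagonal tolerance when grouping seeds into bands.
    min_band_seeds : int
        Seeds required on one band before extension is attempted. Reads at
        the identity floor carry ~100 exact seeds; a random decoy read needs
        a >= 17 nt exact match (probability ~1e-4) to show five, so the gate
        keeps chance matches away from the permissive aligner.
    tie_policy : {"split", "drop"}
        Fractional equal shares versus discarding ambiguous reads.
    max_kmer_hits : int
        Seeds occurring more often than this across the database are masked
        (standard repeat masking: low-complexity or repetitive k-mers seed
        promiscuously and let random reads through the band gate).
    """

    def __init__(
        self,
        k: int = 13,
        min_identity: float = 50.0,
        min_read_fraction: float = 0.90,
        band_slack: int = 15,
        min_band_seeds: int = 5,
        tie_policy: str = "split",
        wrap: int = 300,
        max_kmer_hits: int = 10,
    ):
        self.k = k
        self.min_identity = min_identity
        self.min_read_fraction = min_read_fraction
        self.band_slack = band_slack
        self.min_band_seeds = min_band_seeds
        self.tie_policy = tie_policy
        self.wrap = wrap
        self.max_kmer_hits = max_kmer_hits

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k": self.k, "min_identity": self.min_identity,
            "min_read_fraction": self.min_read_fraction,
            "band_slack": self.band_slack, "min_band_seeds": self.min_band_seeds,
            "tie_policy": self.tie_policy, "wrap": self.wrap,
            "max_kmer_hits": self.max_kmer_hits,
        }

    def set_params(self, **params) -> "ReadRecruiter":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, genomes: Sequence[GenomeRecord]) -> "ReadRecruiter":
        """Index the genome database (circular genomes are extended by
        ``wrap`` nt so reads spanning the origin still seed)."""
        if not genomes:
            raise ValueError("empty genome database")
        self.targets_ = {}
        self.index_: dict[str, list[tuple[str, int]]] = {}
        for g in sorted(genomes, key=lambda g: g.genome_id):
            ext = g.sequence + (g.sequence[: self.wrap] if g.is_circular else "")
            self.targets_[g.genome_id] = ext
            for p in range(len(ext) - self.k + 1):
                kmer = ext[p : p + self.k]
                if "N" in kmer:
                    continue
                self.index_.setdefault(kmer, []).append((g.genome_id, p))
        masked = [k for k, v in self.index_.items() if len(v) > self.max_kmer_hits]
        for k in masked:
            del self.index_[k]
        if masked:
            log.debug("masked %d over-represented %d-mers", len(masked), self.k)
        return self

    def _candidates(self, read: str) -> dict[str, tuple[int, int, int]]:
        """Best diagonal band per genome: genome -> (n_seeds, diag_lo, diag_hi)."""
        votes: dict[str, list[int]] = {}
        for off in range(len(read) - self.k + 1):
            kmer = read[off : off + self.k]
            for gid, pos in self.index_.get(kmer, ()):  # diagonal = pos - off
                votes.setdefault(gid, []).append(pos - off)
        out = {}
        for gid, diags in votes.items():
            diags.sort()
            best_n, best_lo, best_hi = 0, 0, 0
            left = 0
            for right in range(len(diags)):
                while diags[right] - diags[left] > 2 * self.band_slack:
                    left += 1
                n = right - left + 1
                if n > best_n:
                    best_n, best_lo, best_hi = n, diags[left], diags[right]
            if best_n >= self.min_band_seeds:
                out[gid] = (best_n, best_lo, best_hi)
        return out

    def _extend(self, read: str, gid: str, diag_lo: int, diag_hi: int) -> float:
        """Percent identity of the read against the banded target window."""
        target = self.targets_[gid]
        lo = max(0, diag_lo - self.band_slack - 5)
        hi = min(len(target), diag_hi + len(read) + self.band_slack + 5)
        res = edlib.align(read, target[lo:hi], mode="HW", task="distance")
        dist = res["editDistance"]
        if dist < 0:
            return 0.0
        return 100.0 * max(0.0, 1.0 - dist / len(read))

    def predict_counts(
        self, reads: Iterable[tuple[str, str]]
    ) -> tuple[dict[str, float], pd.DataFrame]:
        """Map reads; returns (per-genome fractional counts, per-read detail).

        A read counts for the single best genome with identity >=
        min_identity; exact ties split fractionally in equal shares (or drop,
        per ``tie_policy``). The sum of counts equals the mapped-read total
        exactly.
        """
        self._check_fitted()
        counts = {gid: 0.0 for gid in self.targets_}
        rows = []
        n_total = 0
        for rid, seq in reads:
            n_total += 1
            seq = seq.upper()
            best_ids: list[str] = []
            best_ident = 0.0
            for gid, (_, lo, hi) in sorted(self._candidates(seq).items()):
                ident = self._extend(seq, gid, lo, hi)
                if ident < self.min_identity:
                    continue
                if ident > best_ident + 1e-9:
                    best_ids, best_ident = [gid], ident
                elif abs(ident - best_ident) <= 1e-9:
                    best_ids.append(gid)
            if not best_ids:
                rows.append((rid, "", 0.0, 0.0))
                continue
            if len(best_ids) > 1 and self.tie_policy == "drop":
                rows.append((rid, "", best_ident, 0.0))
                continue
            share = 1.0 / len(best_ids)
            for gid in best_ids:
                counts[gid] += share
                rows.append((rid, gid, best_ident, share))
        detail = pd.DataFrame(rows, columns=["read_id", "genome_id", "identity", "share"])
        self.n_reads_ = n_total
        return counts, detail

    def _check_fitted(self) -> None:
        if not hasattr(self, "targets_"):
            raise ValueError("recruiter is not fitted")


def recruit_reads(
    reads: Iterable[tuple[str, str]],
    genomes: Sequence[GenomeRecord],
    min_identity: float = 50.0,
    **kw,
) -> dict[str, float]:
    """Functional wrapper: per-genome fractional read counts."""
    reads = list(reads)
    rec = ReadRecruiter(min_identity=min_identity, **kw).fit(genomes)
    if not reads:
        log.warning("empty read set: zero-count profile")
        return {g.genome_id: 0.0 for g in genomes}
    counts, _ = rec.predict_counts(reads)
    return counts


@dataclass
class AbundanceProfile:
    sample_id: str
    counts: dict[str, float]          # taxon -> mapped reads (fractional)
    relative: dict[str, float]        # taxon -> counts / total mapped
    total_reads: int
    mapped_reads: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": self.sample_id,
                    "taxon": t,
                    "count": self.counts[t],
                    "rel_abundance": self.relative.get(t, 0.0),
                }
                for t in sorted(self.counts)
            ]
        )


def aggregate(
    counts: Mapping[str, float],
    assignments: Sequence[TaxonAssignment],
    sample_id: str = "sample",
    total_reads: Optional[int] = None,
) -> AbundanceProfile:
    """Sum per-genome counts into per-family counts and relative abundances.

    Genomes without an assignment fall into an "unassigned" bucket with a
    warning. Relative abundance = taxon count / total mapped reads.
    """
    family_of = {a.genome_id: a.family_id for a in assignments}
    taxa: dict[str, float] = {}
    for gid, c in counts.items():
        if c == 0.0:
            continue
        fam = family_of.get(gid)
        if fam is None:
            log.warning("genome %s has no taxon assignment; bucketed as unassigned", gid)
            fam = "unassigned"
        taxa[fam] = taxa.get(fam, 0.0) + c
    mapped = sum(taxa.values())
    rel = {t: v / mapped for t, v in taxa.items()} if mapped > 0 else {}
    return AbundanceProfile(
        sample_id=sample_id,
        counts=taxa,
        relative=rel,
        total_reads=total_reads if total_reads is not None else int(round(sum(counts.values()))),
        mapped_reads=mapped,
    )
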