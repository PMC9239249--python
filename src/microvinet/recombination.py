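"""Sliding-window nucleotide-identity tracks between genome pairs and
detection of elevated-identity tracts (recombination candidates).

Windows slide over columns of a single global alignment (gaps count as
mismatches), so coordinates stay synchronized between the two genomes. A
tract is a maximal run of windows whose identity exceeds the backbone median
by a robust (MAD-scaled) z threshold; boundaries are refined to single-column
resolution by a change-point scan on the match indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import numpy as np

from .aai import _cigar_walk
from .genome_io import linearize_at_vp1
from .records import GenomeRecord

log = logging.getLogger(__name__)


@dataclass
class WindowIdentityTrack:
    genome_a: str
    genome_b: str
    window: int
    step: int
    identities: np.ndarray  # percent per window
    backbone_identity: float  # median of the track
    # per-column internals used for coordinate mapping and refinement
    match_cols: np.ndarray = field(repr=False, default=None)
    a_pos: np.ndarray = field(repr=False, default=None)  # genome-A coordinate per column

    def __len__(self) -> int:
        return len(self.identities)

    def window_start_col(self, i: int) -> int:
        return i * self.step


@dataclass(frozen=True)
class Tract:
    start: int            # genome-A coordinates, 0-based half-open
    end: int
    mean_identity: float  # percent over the tract's windows
    n_windows: int
    col_start: int
    col_end: int


def _aligned_columns(a_seq: str, b_seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-column match flags and genome-A coordinates of a global alignment,
    terminal gaps trimmed."""
    res = edlib.align(a_seq, b_seq, mode="NW", task="path")
    ops = list(_cigar_walk(res["cigar"]))
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    match, apos = [], []
    # edlib cigar is relative to the query (genome A): I consumes A, D consumes B
    ai = 0
    for n, op in ops:
        for _ in range(n):
            match.append(1 if op == "=" else 0)
            apos.append(ai)
            if op in "=XI":
                ai += 1
    return np.array(match, dtype=np.int8), np.array(apos, dtype=np.int64)


def window_identity(
    a: GenomeRecord,
    b: GenomeRecord,
    window: int = 99,
    step: int = 33,
) -> WindowIdentityTrack:
    """Percent identity per sliding window of alignment columns.

    Both genomes are rotated to their VP1 anchor when possible, a single
    global alignment is computed, and identity is evaluated over windows of
    ``window`` columns every ``step`` columns:
    track length = floor((columns - window)/step) + 1.
    """
    ga = linearize_at_vp1(a) if a.is_circular and a.find_gene("VP1") else a
    gb = linearize_at_vp1(b) if b.is_circular and b.find_gene("VP1") else b
    match, apos = _aligned_columns(ga.sequence, gb.sequence)
    n_cols = len(match)
    if window > n_cols:
        raise ValueError(f"window {window} exceeds alignment length {n_cols}")
    n_win = (n_cols - window) // step + 1
    csum = np.concatenate([[0], np.cumsum(match)])
    starts = np.arange(n_win) * step
    idents = 100.0 * (csum[starts + window] - csum[starts]) / window
    return WindowIdentityTrack(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        window=window,
        step=step,
        identities=idents,
        backbone_identity=float(np.median(idents)),
        match_cols=match,
        a_pos=apos,
    )


def _refine_boundary(
    match: np.ndarray, lo: int, hi: int, anchor_lo: int, anchor_hi: int, thresh: float, side: str
) -> int:
    """Change-point refinement: choose the column c in [lo, hi] maximizing the
    above-threshold excess of the tract side."""
    lo = max(0, lo)
    hi = min(len(match), hi)
    best_c, best_v = lo, -np.inf
    if side == "start":
        # score(c) = sum_{k in [c, anchor_hi)} (m_k - thresh); prefer smallest c on ties
        run = 0.0
        vals = []
        for k in range(anchor_hi - 1, lo - 1, -1):
            run += match[k] - thresh
            vals.append((k, run))
        for k, v in vals:
            if lo <= k <= hi and (v > best_v + 1e-12 or (abs(v - best_v) <= 1e-12 and k < best_c)):
                best_c, best_v = k, v
    else:
        run = 0.0
        vals = []
        for k in range(anchor_lo, hi):
            run += match[k] - thresh
            vals.append((k + 1, run))
        best_c = anchor_lo
        for c, v in vals:
            if lo <= c <= hi and (v > best_v + 1e-12 or (abs(v - best_v) <= 1e-12 and c > best_c)):
                best_c, best_v = c, v
    return best_c


def detect_elevated(track: WindowIdentityTrack, z_min: float = 4.0) -> list[Tract]:
    """Maximal runs of windows exceeding the backbone median by >= z_min
    robust z-units (MAD-scaled, scale floored at one identity point so a
    near-constant backbone cannot inflate trivially small fluctuations).
    A fully constant track yields no tracts."""
    ids = track.identities
    if len(ids) < 10:
        raise ValueError("track must contain at least 10 windows")
    med = float(np.median(ids))
    mad = float(np.median(np.abs(ids - med)))
    scale = max(1.4826 * mad, 1.0)
    z = (ids - med) / scale
    # hysteresis: seed runs where z >= z_min, extend while z >= z_min/2, then
    # merge touching runs -- a long tract whose interior windows fluctuate
    # around the hard threshold stays one tract
    runs: list[list[int]] = []
    i = 0
    while i < len(ids):
        if z[i] < z_min:
            i += 1
            continue
        lo = i
        while lo > 0 and z[lo - 1] >= z_min / 2:
            lo -= 1
        hi = i
        while hi + 1 < len(ids) and (z[hi + 1] >= z_min / 2 or z[hi + 1] >= z_min):
            hi += 1
        if runs and lo <= runs[-1][1] + 1:
            runs[-1][1] = max(runs[-1][1], hi)
        else:
            runs.append([lo, hi])
        i = hi + 1
    tracts: list[Tract] = []
    for i, j in runs:
        col_lo = track.window_start_col(i)
        col_hi = track.window_start_col(j) + track.window
        mean_id = float(np.mean(ids[i : j + 1]))
        thresh = (med + mean_id) / 200.0  # midpoint, as a per-column fraction
        start_col = _refine_boundary(
            track.match_cols, col_lo - track.window, col_lo + track.window,
            col_lo, col_hi, thresh, "start",
        )
        end_col = _refine_boundary(
            track.match_cols, col_hi - track.window, col_hi + track.window,
            col_lo, col_hi, thresh, "end",
        )
        if end_col <= start_col:
            start_col, end_col = col_lo, col_hi
        a_start = int(track.a_pos[start_col])
        a_end = int(track.a_pos[end_col - 1]) + 1
        tracts.append(
            Tract(
                start=a_start, end=a_end, mean_identity=mean_id,
                n_windows=j - i + 1, col_start=start_col, col_end=end_col,
            )
        )
    return tracts


def track_frame(track: WindowIdentityTrack):
    """Track as a DataFrame (window start column and genome-A coordinate)."""
    import pandas as pd

    starts = np.arange(len(track)) * track.step
    return pd.DataFrame(
        {
            "window_start_col": starts,
            "window_start_a": track.a_pos[starts],
            "identity": track.identities,
        }
    )


def tracts_to_bed(tracts: list[Tract], genome_id: str, path) -> None:
    """0-based half-open BED on genome-A coordinates."""
    with open(path, "w") as fh:
        for i, t in enumerate(tracts):
            fh.write(
                f"{genome_id}\t{t.start}\t{t.end}\ttract{i + 1}\t{t.mean_identity:.1f}\t+\n"
            )
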