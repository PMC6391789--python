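"""Motif matching at a controlled false-positive rate.

Position frequency matrices (JASPAR flat files) are converted to
log-odds PWMs in bits against a background base distribution; a score
cutoff is derived by dynamic programming over the discretised score
distribution so that a random background sequence passes with
probability at most the requested FPR.  Both strands are scanned, and
matches are labelled true/false binding sites by distance to ChIP-seq
peak summits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._sequence import BASES, encode

UNIFORM_BG = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_FPR = 1e-4
SCORE_STEP = 0.01          # bits
SUMMIT_RADIUS = 100


@dataclass
class MPBS:
    """Motif-predicted binding site (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str
    label: str = "unlabeled"     # {true_site, false_site, unlabeled}

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def to_bed_line(self) -> str:
        return (f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}\t"
                f"{self.score:.4f}\t{self.strand}")


def load_jaspar_pfms(path: str) -> dict[str, np.ndarray]:
    """Read JASPAR-format PFMs into name -> (L, 4) count matrices."""
    from Bio import motifs

    out: dict[str, np.ndarray] = {}
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float).T
            out[m.name or m.matrix_id] = counts
    return out


def pfm_to_pwm(pfm: np.ndarray, background: np.ndarray = UNIFORM_BG,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Log-odds matrix in bits from a (L, 4) position frequency matrix.

    Counts are pseudocounted proportionally to the background
    (``counts + pc * bg``), normalised per column, and divided by the
    background:  pwm[j, b] = log2(p_jb / bg_b).
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[1] != 4:
        raise ValueError("PFM must have shape (length, 4)")
    if np.any(pfm < 0):
        raise ValueError("PFM counts must be non-negative")
    totals = pfm.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("PFM has an all-zero column")
    probs = (pfm + pseudocount * background) / (totals + pseudocount)[:, None]
    return np.log2(probs / background)


def threshold_at_fpr(pwm: np.ndarray, background: np.ndarray = UNIFORM_BG,
                     fpr: float = DEFAULT_FPR, step: float = SCORE_STEP) -> float:
    """Smallest bit-score t with P(score >= t | background) <= fpr.

    The score distribution under i.i.d. background bases is computed
    exactly by dynamic programming on scores discretised to ``step``
    bits.  ``fpr=1`` returns the minimum achievable score; an FPR
    below the probability of the single best word clamps the cutoff to
    the maximum achievable score.
    """
    if not 0 < fpr <= 1:
        raise ValueError("fpr must be in (0, 1]")
    q = np.rint(np.asarray(pwm, dtype=float) / step).astype(np.int64)
    running = np.ones(1)
    run_lo = 0
    for j in range(q.shape[0]):
        new_lo = run_lo + int(q[j].min())
        new_hi = run_lo + len(running) - 1 + int(q[j].max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            s = run_lo + q[j, b] - new_lo
            new[s:s + len(running)] += background[b] * running
        running, run_lo = new, new_lo
    tail = np.cumsum(running[::-1])[::-1]
    achievable = np.flatnonzero(running > 0)
    ok = achievable[tail[achievable] <= fpr]
    # smallest achievable (discretised) score whose tail probability is
    # within the FPR; clamp to the maximum achievable score when the FPR
    # is unattainable.  Exact scan scores can differ from the grid by up
    # to half a step per position, so words within that band of the
    # cutoff may be classified either way.
    idx = int(ok[0]) if ok.size else int(achievable[-1])
    return (run_lo + idx) * step


def _window_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score of the PWM at every window start; -inf where invalid bases."""
    length = pwm.shape[0]
    n = len(codes) - length + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, -np.inf)
    safe = np.clip(windows, 0, None)
    scores[valid] = pwm[np.arange(length), safe].sum(axis=1)[valid]
    return scores


def scan(sequence: str, pwm: np.ndarray, cutoff: float, name: str = "motif",
         chrom: str = "chr", offset: int = 0) -> list[MPBS]:
    """All windows on either strand scoring >= cutoff, one MPBS per strand.

    Reverse-strand matches are scored on the reverse complement of the
    window but reported in forward coordinates.
    """
    codes = encode(sequence)
    length = pwm.shape[0]
    rc_pwm = pwm[::-1, ::-1]                  # reverse complement of the motif
    hits: list[MPBS] = []
    for strand, mat in (("+", pwm), ("-", rc_pwm)):
        scores = _window_scores(codes, mat)
        for i in np.flatnonzero(scores >= cutoff):
            hits.append(MPBS(chrom, offset + int(i), offset + int(i) + length,
                             name, float(scores[i]), strand))
    hits.sort(key=lambda m: (m.start, m.strand))
    return hits


def label_with_chipseq(mpbs: Iterable[MPBS], summits: Sequence[int],
                       radius: int = SUMMIT_RADIUS) -> list[MPBS]:
    """Label sites true/false by distance from centre to the nearest summit.

    The boundary is inclusive: a centre exactly ``radius`` bp from a
    summit is a true site.
    """
    summit_arr = np.asarray(sorted(summits))
    out = []
    for m in mpbs:
        if summit_arr.size:
            pos = np.searchsorted(summit_arr, m.center)
            dists = [abs(m.center - summit_arr[i])
                     for i in (pos - 1, pos) if 0 <= i < summit_arr.size]
            is_true = min(dists) <= radius
        else:
            is_true = False
        m.label = "true_site" if is_true else "false_site"
        out.append(m)
    return out


def write_mpbs_bed(mpbs: Sequence[MPBS], path: str) -> None:
    with open(path, "w") as fh:
        for m in mpbs:
            fh.write(m.to_bed_line() + "\n")
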