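"""Per-TF activity scores and differential activity between conditions.

The activity score of a TF combines a protection score (flanking minus
footprint cleavage signal) with an openness score (total signal within
±100 bp of the binding site), averaged over the TF's
footprint-supported binding sites.  For sites (f_l, f_r) with motif
width e and corrected signal x, the per-site contribution is

    1/2 Σ_{j=f_l-e-1}^{f_l-1} x_j + 1/2 Σ_{j=f_r+1}^{f_r+e+1} x_j
    - Σ_{j=f_l}^{f_r} x_j  +  Σ_{j=f_l-100}^{f_r+100} x_j .

Differences between two conditions are normalised by DESeq-style
median-of-ratios size factors computed on the per-TF activity scores:
ΔACT = ACT₂/ω₂ − ACT₁/ω₁.  Significance is a Welch t-test on per-site
contributions, Benjamini-Hochberg corrected across TFs, with an
external gene-expression fold-change filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fragments import GenomicRegion

logger = logging.getLogger(__name__)

OPENNESS_FLANK = 100


@dataclass
class BindingSiteSet:
    """Footprint-supported binding sites of one TF (half-open intervals)."""

    tf: str
    sites: list[tuple[int, int]] = field(default_factory=list)
    motif_width: int = 0

    def __post_init__(self) -> None:
        for s, e in self.sites:
            if e <= s:
                raise ValueError("site start must be < end")


def footprint_supported_sites(tf: str, mpbs: Sequence, footprints_cond1: Sequence,
                              footprints_cond2: Sequence) -> BindingSiteSet:
    """Sites overlapping (>= 1 bp) a footprint in at least one condition."""
    fps = [(f.start, f.end) for f in list(footprints_cond1) + list(footprints_cond2)]
    sites = []
    width = 0
    for m in mpbs:
        if any(fs < m.end and m.start < fe for fs, fe in fps):
            sites.append((m.start, m.end))
            width = m.end - m.start
    return BindingSiteSet(tf, sites, width)


def per_site_activity(sites: Sequence[tuple[int, int]], signal: np.ndarray,
                      region: GenomicRegion, motif_width: int | None = None) -> np.ndarray:
    """Per-site activity contributions (protection + openness).

    Sites whose flanks fall outside the signal region are skipped with
    a log message.
    """
    x = np.asarray(signal, dtype=float)
    out = []
    for start, end in sites:
        e = motif_width if motif_width is not None else end - start
        f_l, f_r = start, end - 1                       # inclusive endpoints
        margin = max(e + 1, OPENNESS_FLANK)
        if f_l - margin < region.start or f_r + margin >= region.end:
            logger.info("site %d-%d too close to the region edge; skipped", start, end)
            continue
        o = region.start

        def seg(a: int, b: int) -> float:               # inclusive genomic [a, b]
            return float(x[a - o:b - o + 1].sum())

        protection = (0.5 * seg(f_l - e - 1, f_l - 1)
                      + 0.5 * seg(f_r + 1, f_r + e + 1)
                      - seg(f_l, f_r))
        openness = seg(f_l - OPENNESS_FLANK, f_r + OPENNESS_FLANK)
        out.append(protection + openness)
    return np.asarray(out)


def activity_score(site_set: BindingSiteSet, signal: np.ndarray,
                   region: GenomicRegion) -> float:
    """ACT: mean per-site contribution over the TF's supported sites."""
    contrib = per_site_activity(site_set.sites, signal, region,
                                site_set.motif_width or None)
    if contrib.size == 0:
        raise ValueError(f"no usable sites for {site_set.tf}")
    return float(contrib.mean())


def size_factors(act1: Sequence[float], act2: Sequence[float]) -> tuple[float, float]:
    """Median-of-ratios size factors over per-TF activity scores.

    Per TF, the geometric mean of the two conditions' ACT values is the
    reference; each condition's factor is the median of ACT/reference
    over TFs with positive ACT in both conditions.
    """
    a1 = np.asarray(act1, dtype=float)
    a2 = np.asarray(act2, dtype=float)
    ok = (a1 > 0) & (a2 > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 TFs with positive activity in both conditions")
    geo = np.sqrt(a1[ok] * a2[ok])
    return float(np.median(a1[ok] / geo)), float(np.median(a2[ok] / geo))


def delta_act(act1: float, act2: float, w1: float, w2: float) -> float:
    """ΔACT = ACT₂/ω₂ − ACT₁/ω₁ (positive favours condition 2)."""
    if w1 <= 0 or w2 <= 0:
        raise ValueError("size factors must be positive")
    return act2 / w2 - act1 / w1


def average_cleavage_profile(signal: np.ndarray, region: GenomicRegion,
                             centers: Sequence[int], flank: int = 100) -> np.ndarray:
    """Mean corrected cleavage signal around site centres (±flank).

    The returned vector has length 2*flank + 1; sites too close to the
    region edge are skipped.  Plot it to inspect footprint shape and
    flanking enrichment per TF.
    """
    x = np.asarray(signal, dtype=float)
    rows = []
    for c in centers:
        lo, hi = c - flank - region.start, c + flank + 1 - region.start
        if lo < 0 or hi > len(x):
            continue
        rows.append(x[lo:hi])
    if not rows:
        raise ValueError("no site fits inside the signal region")
    return np.mean(rows, axis=0)


def differential_test(per_site: Mapping[str, tuple[np.ndarray, np.ndarray]],
                      expression_log2fc: Mapping[str, float] | None = None,
                      alpha: float = 0.05, min_abs_log2fc: float = 0.5) -> pd.DataFrame:
    """Differential TF activity between two conditions.

    ``per_site`` maps TF name to the per-site activity contributions in
    condition 1 and condition 2.  Size factors are computed from the
    per-TF mean contributions, per-site values are normalised by them,
    and a Welch t-test per TF is Benjamini-Hochberg corrected across
    TFs.  A TF is flagged when the adjusted p-value is below ``alpha``
    and its expression |log2FC| exceeds ``min_abs_log2fc``; TFs absent
    from the expression table are retained with note
    'expression-unfiltered' and flagged on the p-value alone.
    """
    tfs = sorted(per_site)
    act1 = np.array([np.mean(per_site[tf][0]) for tf in tfs])
    act2 = np.array([np.mean(per_site[tf][1]) for tf in tfs])
    w1, w2 = size_factors(act1, act2)
    rows = []
    pvals = []
    for tf, a1, a2 in zip(tfs, act1, act2):
        c1, c2 = per_site[tf]
        if len(c1) < 2 or len(c2) < 2:
            raise ValueError(f"need >= 2 sites per condition for {tf}")
        t, p = stats.ttest_ind(np.asarray(c2) / w2, np.asarray(c1) / w1,
                               equal_var=False)
        pvals.append(p if np.isfinite(p) else 1.0)
        rows.append({"tf": tf, "act1": a1, "act2": a2, "omega1": w1, "omega2": w2,
                     "delta_act": delta_act(a1, a2, w1, w2), "t_stat": t})
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(rows)
    table["p_value"] = pvals
    table["adj_p_value"] = adj
    log2fc = []
    notes = []
    flagged = []
    for tf, ap in zip(tfs, adj):
        if expression_log2fc is not None and tf in expression_log2fc:
            fc = float(expression_log2fc[tf])
            log2fc.append(fc)
            notes.append("")
            flagged.append(ap < alpha and abs(fc) > min_abs_log2fc)
        else:
            log2fc.append(np.nan)
            notes.append("expression-unfiltered")
            flagged.append(ap < alpha)
    table["expression_log2fc"] = log2fc
    table["flagged"] = flagged
    table["note"] = notes
    return table
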