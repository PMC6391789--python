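"""End-to-end footprinting workflows over one chromosome region.

These functions tie the modules together in the fixed order: cleavage
counting (per fragment class and strand) -> bias correction ->
within/between normalisation + slope channels -> semi-supervised HMM
training or Viterbi decoding restricted to peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .bias import (KmerBiasTable, collect_words, correct_track, estimate_kmer,
                   estimate_pwm, estimate_slim)
from .fragments import (AlignedFragment, CleavageTrack, FragmentClassScheme,
                        GenomicRegion, build_signal)
from .hmm import (Footprint, FootprintHMM, extract_footprints,
                  make_training_windows, tag_count_score, train_semi_supervised,
                  viterbi_decode)
from .transform import DecompositionStrategy, ObservationMatrix, assemble

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one footprinting run."""

    protocol: str = "atac"
    bias_method: str = "slim"          # {kmer, pwm, slim, none}
    k: int = 8
    d: int = 5
    strategy: str = "All"
    strand_specific: bool = True
    n_states: int = 5
    seed: int = 0
    min_footprint: int = 5
    max_footprint: int = 50
    bin_size: int = 10_000
    savgol_window: int = 9
    expected_counts_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.protocol not in ("atac", "dnase"):
            raise ValueError("protocol must be atac or dnase")
        if self.bias_method not in ("kmer", "pwm", "slim", "none"):
            raise ValueError("unknown bias method")
        DecompositionStrategy(self.strategy, self.strand_specific)  # validates

    @property
    def decomposition(self) -> DecompositionStrategy:
        return DecompositionStrategy(self.strategy, self.strand_specific)

    def to_dict(self) -> dict:
        return asdict(self)


class _UniformBias:
    """Neutral bias model (b(w) = 1 for every word)."""

    def __init__(self, k: int = 1):
        self.k = k

    def bias_table(self) -> np.ndarray:
        return np.ones(4 ** self.k)

    def bias_of(self, word: str) -> float:
        return 1.0


def estimate_bias(fragments: Sequence[AlignedFragment], peaks: Sequence[GenomicRegion],
                  genome: Mapping[str, str], config: RunConfig):
    """Fit the configured bias model from cleavage events inside peaks."""
    if config.bias_method == "none":
        return _UniformBias()
    tracks = []
    for chrom, seq in genome.items():
        region = GenomicRegion(chrom, 0, len(seq))
        for strand in "+-":
            tracks.append(build_signal(fragments, region, strand, "All",
                                       config.protocol, chrom_length=len(seq)))
    w_obs, w_exp = collect_words(tracks, peaks, genome, config.k)
    if config.bias_method == "kmer":
        return estimate_kmer(w_obs, w_exp)
    if config.bias_method == "pwm":
        return estimate_pwm(w_obs, w_exp)
    return estimate_slim(w_obs, w_exp, d=config.d, seed=config.seed)


def corrected_class_tracks(fragments: Sequence[AlignedFragment], region: GenomicRegion,
                           genome_seq: str, bias_model, config: RunConfig,
                           scheme: FragmentClassScheme | None = None
                           ) -> dict[tuple[str, str], np.ndarray]:
    """Bias-corrected signal per (fragment class, strand) over a region."""
    strategy = config.decomposition
    scheme = scheme or FragmentClassScheme()
    out: dict[tuple[str, str], np.ndarray] = {}
    for cls in strategy.classes:
        if strategy.strand_specific:
            for strand in "+-":
                track = build_signal(fragments, region, strand, cls, config.protocol,
                                     scheme, chrom_length=len(genome_seq))
                out[(cls, strand)] = correct_track(
                    track, bias_model, genome_seq,
                    expected_counts_mode=config.expected_counts_mode)
        else:
            plus = build_signal(fragments, region, "+", cls, config.protocol,
                                scheme, chrom_length=len(genome_seq))
            minus = build_signal(fragments, region, "-", cls, config.protocol,
                                 scheme, chrom_length=len(genome_seq))
            merged = CleavageTrack(region, "+", cls, plus.counts + minus.counts)
            out[(cls, "*")] = correct_track(
                merged, bias_model, genome_seq,
                expected_counts_mode=config.expected_counts_mode)
    return out


def observations_for_region(fragments: Sequence[AlignedFragment], region: GenomicRegion,
                            genome_seq: str, bias_model, config: RunConfig,
                            scheme: FragmentClassScheme | None = None) -> ObservationMatrix:
    corrected = corrected_class_tracks(fragments, region, genome_seq, bias_model,
                                       config, scheme)
    return assemble(corrected, region, config.decomposition,
                    config.bin_size, config.savgol_window)


def scoring_signal(corrected: Mapping[tuple[str, str], np.ndarray]) -> np.ndarray:
    """Corrected cleavage signal used for tag counts (both strands, All class)."""
    keys = [k for k in corrected if k[0] == "All"] or list(corrected)
    return np.sum([corrected[k] for k in keys], axis=0)


def train_model(observations: ObservationMatrix, chip_peaks: Sequence[tuple[int, int]],
                mpbs: Sequence[tuple[int, int]], config: RunConfig,
                flank: int = 500, n_restarts: int = 3) -> FootprintHMM:
    """Semi-supervised training with EM restarts.

    EM from random-posterior initialisations can settle in a local
    optimum; the model with the best final training log-likelihood
    across ``n_restarts`` seeded initialisations is kept.
    Deterministic for a fixed config seed.
    """
    windows = make_training_windows(chip_peaks, mpbs, observations, flank)
    logger.info("training on %d labelled windows", len(windows))
    best = None
    for r in range(n_restarts):
        model = train_semi_supervised(windows, config.n_states,
                                      config.seed + 1000 * r)
        if best is None or model.training_history[-1] > best.training_history[-1]:
            best = model
    return best


def detect_footprints(model: FootprintHMM, observations: ObservationMatrix,
                      peaks: Sequence[GenomicRegion], config: RunConfig,
                      score_signal: np.ndarray | None = None) -> list[Footprint]:
    """Viterbi-decode each peak and extract scored FOOTPRINT runs."""
    region = observations.region
    footprints: list[Footprint] = []
    for peak in peaks:
        lo = max(peak.start, region.start)
        hi = min(peak.end, region.end)
        if hi <= lo:
            continue
        obs = observations.data[lo - region.start:hi - region.start]
        path = viterbi_decode(model, obs)
        found = extract_footprints(path, GenomicRegion(region.chrom, lo, hi),
                                   model.footprint_state, config.min_footprint,
                                   config.max_footprint)
        if score_signal is not None:
            for fp in found:
                fp.score = tag_count_score(fp, score_signal, region)
        footprints.extend(found)
    return footprints
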