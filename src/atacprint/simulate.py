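"""Synthetic ATAC-seq libraries with planted footprints and cleavage bias.

The generator emulates the features the footprinting pipeline relies
on: an i.i.d. genome with planted motif occurrences, a sequence-driven
cleavage bias (log-bias additive over word positions, optionally with
a planted pairwise dependency), a multi-modal fragment-length mixture
(nucleosome-free / mono- / poly-nucleosome modes), and footprint
protection that suppresses cleavage events inside bound motif sites.
Because forward reads report the left cut and reverse reads the right
cut of each fragment, nucleosome-free fragments spanning a bound site
produce the characteristic strand geometry (forward 5' ends left of
the site, reverse right) without further modelling.

Outputs use the same formats the real pipeline consumes: FASTA (+fai),
coordinate-sorted BAM (+bai) and BED truth files, all written at run
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bias import word_index_track
from .fragments import AlignedFragment, GenomicRegion

# fragment geometry: forward event = start + 4, reverse event = end - 6,
# so a fragment of length l spans events (e_f, e_f + l - 10)
_EVENT_SPAN_OFFSET = 10
MIN_FRAGMENT_LENGTH = 20

#: default fragment-length mixture (bp): Nfr / 1N / 2N modes
DEFAULT_FRAG_MEANS = (60.0, 200.0, 400.0)
DEFAULT_FRAG_SDS = (20.0, 30.0, 40.0)
DEFAULT_FRAG_WEIGHTS = (0.6, 0.3, 0.1)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic library."""

    genome_length: int = 100_000
    gc: float = 0.5
    seed: int = 0
    motif: str = "GTGACTCATGC"
    n_sites: int = 20
    protection: float = 0.9
    bias_k: int = 6
    bias_strength: float = 0.8       # SD of per-position log-bias weights
    bias_dependency: bool = False    # plant a first-order pairwise term
    motif_bias_boost: float = 1.0    # extra cleavage preference for motif words
    n_fragments: int = 50_000
    peak_halfwidth: int = 600
    background_weight: float = 0.02  # cleavage weight outside peaks
    frag_means: tuple = DEFAULT_FRAG_MEANS
    frag_sds: tuple = DEFAULT_FRAG_SDS
    frag_weights: tuple = DEFAULT_FRAG_WEIGHTS
    protection_multiplier: float = 1.0   # condition-specific scaling

    def __post_init__(self) -> None:
        if not 0 <= self.protection <= 1:
            raise ValueError("protection must lie in [0, 1]")
        if abs(sum(self.frag_weights) - 1) > 1e-9:
            raise ValueError("fragment mixture weights must sum to 1")
        if self.n_fragments <= 0:
            raise ValueError("read depth must be positive")


@dataclass
class Fixture:
    """A generated library plus its ground truth."""

    spec: FixtureSpec
    genome: str
    fragments: list[AlignedFragment] = field(repr=False)
    footprints: list[tuple[int, int]]        # planted (start, end)
    peaks: list[GenomicRegion]
    bias_table: np.ndarray = field(repr=False)

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion("chr1", 0, len(self.genome))


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """i.i.d. genome with the requested GC content."""
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=probs)])


def generate_bias_table(k: int, strength: float = 0.8, dependency: bool = False,
                        seed: int = 0) -> np.ndarray:
    """A planted bias table b(w) over all 4^k words.

    log b(w) is a sum of per-position base weights (zero-mean normal
    with SD ``strength``), plus, when ``dependency`` is set, a pairwise
    term coupling the two central positions.  The low-dimensional
    structure mirrors enzyme bias well enough for the position-aware
    estimators to capture it.
    """
    rng = np.random.default_rng(seed)
    from .bias import word_digits

    digits = word_digits(k)
    weights = rng.normal(0.0, strength, size=(k, 4))
    weights -= weights.mean(axis=1, keepdims=True)
    logb = np.zeros(4 ** k)
    for j in range(k):
        logb += weights[j, digits[:, j]]
    if dependency:
        pair = rng.normal(0.0, strength, size=(4, 4))
        pair -= pair.mean()
        j = k // 2
        logb += pair[digits[:, j - 1], digits[:, j]]
    return np.exp(logb)


def boost_motif_words(bias_table: np.ndarray, motif: str, k: int,
                      boost: float) -> np.ndarray:
    """Multiply the bias of every k-word occurring in the motif by ``boost``.

    Emulates an enzyme whose sequence preference overlaps the TF motif:
    cleavage hotspots then sit inside bound sites (on both strands, via
    the reverse complement) and mask the footprint unless the bias is
    corrected.
    """
    from ._sequence import encode, revcomp

    table = bias_table.copy()
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    boosted = set()
    for seq in (motif, revcomp(motif)):
        codes = encode(seq).astype(np.int64)
        for s in range(len(seq) - k + 1):
            boosted.add(int(codes[s:s + k] @ powers))
    for idx in boosted:
        table[idx] *= boost
    return table


def plant_sites(genome: str, motif: str, positions: Sequence[int]) -> tuple[str, list[tuple[int, int]]]:
    """Write the motif into the genome at the given start positions."""
    seq = list(genome)
    truth = []
    for pos in positions:
        if pos < 0 or pos + len(motif) > len(genome):
            raise ValueError("planted site outside the genome")
        seq[pos:pos + len(motif)] = motif
        truth.append((pos, pos + len(motif)))
    return "".join(seq), truth


def _event_weights(genome: str, spec: FixtureSpec, bias_table: np.ndarray,
                   footprints: Sequence[tuple[int, int]],
                   peaks: Sequence[GenomicRegion]) -> tuple[np.ndarray, np.ndarray]:
    """Per-position cleavage weights for forward and reverse events.

    Reverse-strand events follow the bias of the reverse complement of
    the forward-genome word, mirroring how the enzyme reads the
    opposite strand.
    """
    from .bias import revcomp_index_permutation

    idx = word_index_track(genome, spec.bias_k)
    rc = revcomp_index_permutation(spec.bias_k)
    mean_bias = float(bias_table.mean())
    b_fwd = np.where(idx >= 0, bias_table[np.clip(idx, 0, None)], mean_bias)
    b_rev = np.where(idx >= 0, bias_table[rc[np.clip(idx, 0, None)]], mean_bias)
    base = np.full(len(genome), spec.background_weight)
    for p in peaks:
        base[p.start:p.end] = 1.0
    depth = min(1.0, spec.protection * spec.protection_multiplier)
    for s, e in footprints:
        base[s:e] *= (1.0 - depth)
    return b_fwd * base, b_rev * base


def _sample_lengths(rng: np.random.Generator, n: int, spec: FixtureSpec) -> np.ndarray:
    comp = rng.choice(len(spec.frag_weights), size=n, p=spec.frag_weights)
    lengths = rng.normal(np.asarray(spec.frag_means)[comp],
                         np.asarray(spec.frag_sds)[comp])
    lengths = np.rint(lengths).astype(int)
    bad = lengths < MIN_FRAGMENT_LENGTH
    while bad.any():
        lengths[bad] = np.rint(rng.normal(
            np.asarray(spec.frag_means)[comp[bad]],
            np.asarray(spec.frag_sds)[comp[bad]])).astype(int)
        bad = lengths < MIN_FRAGMENT_LENGTH
    return lengths


def simulate_library(genome: str, spec: FixtureSpec,
                     footprints: Sequence[tuple[int, int]] = (),
                     peaks: Sequence[GenomicRegion] | None = None,
                     bias_table: np.ndarray | None = None) -> Fixture:
    """Draw paired-end fragments whose cut sites follow bias and protection.

    The left cleavage event is drawn from the per-position weight
    (bias x openness x protection); the fragment length comes from the
    nucleosome mixture; the implied right event is accepted by
    rejection against the same weights, so both fragment ends respect
    bias and protection.
    """
    rng = np.random.default_rng(spec.seed)
    if peaks is None:
        peaks = [GenomicRegion("chr1", 0, len(genome))]
    if bias_table is None:
        bias_table = generate_bias_table(spec.bias_k, spec.bias_strength,
                                         spec.bias_dependency, spec.seed + 7)
        if spec.motif_bias_boost != 1.0:
            bias_table = boost_motif_words(bias_table, spec.motif, spec.bias_k,
                                           spec.motif_bias_boost)
    w_fwd, w_rev = _event_weights(genome, spec, bias_table, footprints, peaks)
    probs = w_fwd / w_fwd.sum()
    wmax = w_rev.max()
    n_target = spec.n_fragments
    starts_out = np.empty(0, dtype=int)
    lengths_out = np.empty(0, dtype=int)
    guard = 0
    while len(starts_out) < n_target and guard < 60:
        guard += 1
        batch = int((n_target - len(starts_out)) * 1.8) + 64
        e_f = rng.choice(len(genome), size=batch, p=probs)
        lens = _sample_lengths(rng, batch, spec)
        e_r = e_f + lens - _EVENT_SPAN_OFFSET
        ok = e_r < len(genome) - 6
        accept = rng.random(batch) * wmax < np.where(
            ok, w_rev[np.clip(e_r, 0, len(genome) - 1)], 0)
        keep = ok & accept & (e_f >= 4)
        starts_out = np.concatenate([starts_out, e_f[keep]])
        lengths_out = np.concatenate([lengths_out, lens[keep]])
    starts_out = starts_out[:n_target]
    lengths_out = lengths_out[:n_target]
    fragments = [AlignedFragment("chr1", int(e - 4), int(e - 4 + l))
                 for e, l in zip(starts_out, lengths_out)]
    return Fixture(spec, genome, fragments, list(footprints), list(peaks), bias_table)


def simulate_fixture(spec: FixtureSpec) -> Fixture:
    """Full fixture: genome, planted sites in peak centres, biased library."""
    rng = np.random.default_rng(spec.seed + 1)
    genome = simulate_genome(spec.genome_length, spec.gc, spec.seed)
    width = 2 * spec.peak_halfwidth
    spacing = spec.genome_length // max(spec.n_sites, 1)
    if spacing < width + 200:
        raise ValueError("genome too short for the requested number of peaks")
    peaks = []
    positions = []
    for i in range(spec.n_sites):
        center = i * spacing + spacing // 2
        peaks.append(GenomicRegion("chr1", center - spec.peak_halfwidth,
                                   center + spec.peak_halfwidth))
        jitter = int(rng.integers(-20, 21))
        positions.append(center + jitter - len(spec.motif) // 2)
    genome, truth = plant_sites(genome, spec.motif, positions)
    return simulate_library(genome, spec, truth, peaks)


def simulate_chipseq(truth: Sequence[tuple[int, int]], jitter_sd: float = 0.0,
                     seed: int = 0) -> list[int]:
    """ChIP-seq-like summit positions: site centres plus Gaussian jitter."""
    rng = np.random.default_rng(seed)
    summits = []
    for s, e in truth:
        center = (s + e) // 2
        if jitter_sd > 0:
            center += int(round(rng.normal(0, jitter_sd)))
        summits.append(center)
    return summits


# ---------------------------------------------------------------------------
# file emission (same formats the real pipeline consumes)


def write_fasta(genome: str, path: str, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 60):
            fh.write(genome[i:i + 60] + "\n")
    import pysam
    pysam.faidx(path)


def write_bam(fragments: Sequence[AlignedFragment], genome_length: int, path: str,
              chrom: str = "chr1", read_length: int = 36) -> None:
    """Write fragments as proper read pairs to a sorted, indexed BAM."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": genome_length}]}
    frags = sorted(fragments, key=lambda f: f.start)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, frag in enumerate(frags):
            rlen = min(read_length, frag.length)
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"frag{i}"
            a.reference_id = 0
            a.reference_start = frag.start
            a.mapping_quality = 60
            a.cigarstring = f"{rlen}M"
            a.flag = 0x1 | 0x2 | 0x40        # paired, proper, first in pair
            a.next_reference_id = 0
            a.next_reference_start = frag.end - rlen
            a.template_length = frag.length
            a.query_sequence = "A" * rlen

            b = pysam.AlignedSegment(bam.header)
            b.query_name = f"frag{i}"
            b.reference_id = 0
            b.reference_start = frag.end - rlen
            b.mapping_quality = 60
            b.cigarstring = f"{rlen}M"
            b.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
            b.next_reference_id = 0
            b.next_reference_start = frag.start
            b.template_length = -frag.length
            b.query_sequence = "A" * rlen
            bam.write(a)
            bam.write(b)
    sorted_path = path + ".sorted"
    pysam.sort("-o", sorted_path, path)
    import os
    os.replace(sorted_path, path)
    pysam.index(path)


def write_bed(intervals: Sequence[tuple[int, int]], path: str, chrom: str = "chr1",
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(intervals):
            name = names[i] if names else f"site{i}"
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_summits_bed(summits: Sequence[int], path: str, chrom: str = "chr1") -> None:
    write_bed([(s, s + 1) for s in summits], path, chrom)
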