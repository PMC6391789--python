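"""Cleavage-event counting from paired-end fragments.

ATAC-seq reads report transposition (cleavage) events of the Tn5 dimer.
The centre of the cleavage event sits at the fifth base of the read, so
the 5' alignment coordinate is shifted by +4 on the forward strand and
-5 on the reverse strand before counting.  DNase-seq reads are counted
at the 5' position itself.

Paired-end fragment lengths carry nucleosome information: the fragment
size distribution is multi-modal, with modes for nucleosome-free (Nfr),
mono-nucleosome (1N) and poly-nucleosome fragments.  Cleavage signals
can be decomposed by these classes before footprint decoding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

#: default +strand / -strand shifts for ATAC-seq (centre of Tn5 event)
ATAC_SHIFTS = (4, -5)
DNASE_SHIFTS = (0, 0)

#: default fragment-class boundaries (bp) for standard ATAC-seq
DEFAULT_NFR_UPPER = 145
DEFAULT_MONO_UPPER = 307

FRAGMENT_CLASSES = ("All", "Nfr", "1N", "+1N", "+2N")


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedFragment:
    """A sequenced fragment inferred from a properly paired read pair.

    ``start``/``end`` are the 0-based leftmost and exclusive rightmost
    aligned positions of the pair; ``length = end - start``.
    """

    chrom: str
    start: int
    end: int
    first_read_strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentClassScheme:
    """Fragment-size intervals, half-open on the left.

    Nfr = (0, nfr_upper], 1N = (nfr_upper, mono_upper],
    +1N = (nfr_upper, inf), +2N = (mono_upper, inf); All covers everything.
    """

    nfr_upper: int = DEFAULT_NFR_UPPER
    mono_upper: int = DEFAULT_MONO_UPPER

    def __post_init__(self) -> None:
        if not 0 < self.nfr_upper < self.mono_upper:
            raise ValueError("require 0 < nfr_upper < mono_upper")

    def classify(self, length: int) -> str:
        """Partition class (Nfr / 1N / +2N) of a fragment length."""
        if length < 1:
            raise ValueError("fragment length must be >= 1")
        if length <= self.nfr_upper:
            return "Nfr"
        if length <= self.mono_upper:
            return "1N"
        return "+2N"

    def contains(self, cls: str, length: int) -> bool:
        """Whether ``length`` belongs to (possibly overlapping) class ``cls``."""
        if cls == "All":
            return length >= 1
        if cls == "+1N":
            return length > self.nfr_upper
        return self.classify(length) == cls


@dataclass
class CleavageTrack:
    """Per-base cleavage-event counts for one region / strand / class."""

    region: GenomicRegion
    strand: str
    fragment_class: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.region):
            raise ValueError("counts length must equal region length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def cleavage_position(position: int, strand: str, protocol: str = "atac",
                      shifts: tuple[int, int] = ATAC_SHIFTS) -> int:
    """Map a read's 5' alignment coordinate to its cleavage-event position.

    For ATAC-seq the centre of the Tn5 event is the fifth base of the
    read: ``position + 4`` for forward reads, ``position - 5`` for
    reverse reads (the 5' end of a reverse read being its rightmost
    aligned base).  DNase-seq events are the 5' position unchanged.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if protocol == "dnase":
        return position
    if protocol != "atac":
        raise ValueError(f"unknown protocol {protocol!r}")
    return position + shifts[0] if strand == "+" else position + shifts[1]


def classify_fragment(length: int, scheme: FragmentClassScheme | None = None) -> str:
    """Partition class label for a fragment length (boundaries right-inclusive)."""
    return (scheme or FragmentClassScheme()).classify(length)


def fragment_events(fragment: AlignedFragment, protocol: str = "atac",
                    shifts: tuple[int, int] = ATAC_SHIFTS) -> tuple[tuple[int, str], tuple[int, str]]:
    """The two cleavage events of a fragment as ``(position, strand)`` pairs.

    The forward mate's 5' end is the fragment start; the reverse mate's
    5' end is the rightmost aligned base ``end - 1``.
    """
    fwd = cleavage_position(fragment.start, "+", protocol, shifts)
    rev = cleavage_position(fragment.end - 1, "-", protocol, shifts)
    return (fwd, "+"), (rev, "-")


def build_signal(fragments: Iterable[AlignedFragment], region: GenomicRegion,
                 strand: str, fragment_class: str = "All", protocol: str = "atac",
                 scheme: FragmentClassScheme | None = None,
                 shifts: tuple[int, int] = ATAC_SHIFTS,
                 chrom_length: int | None = None) -> CleavageTrack:
    """Count cleavage events per position of ``region`` for one strand/class.

    Events shifted off the chromosome are dropped (counted in the log);
    events outside the region are simply not counted.
    """
    if strand not in "+-":
        raise ValueError("strand must be '+' or '-'")
    scheme = scheme or FragmentClassScheme()
    counts = np.zeros(len(region), dtype=np.int64)
    dropped = 0
    for frag in fragments:
        if frag.chrom != region.chrom:
            continue
        if not scheme.contains(fragment_class, frag.length):
            continue
        for pos, s in fragment_events(frag, protocol, shifts):
            if s != strand:
                continue
            if pos < 0 or (chrom_length is not None and pos >= chrom_length):
                dropped += 1
                continue
            if region.start <= pos < region.end:
                counts[pos - region.start] += 1
    if dropped:
        logger.info("dropped %d cleavage events shifted off-chromosome", dropped)
    return CleavageTrack(region, strand, fragment_class, counts)


def fragments_from_bam(bam_path: str, region: GenomicRegion | None = None,
                       min_mapq: int = 30) -> Iterator[AlignedFragment]:
    """Yield fragments from a coordinate-sorted, indexed BAM.

    Each properly paired fragment is yielded once (from its forward
    mate).  Secondary/supplementary/duplicate reads and pairs below the
    MAPQ floor are skipped; duplicate marking itself is assumed done
    upstream.
    """
    import pysam

    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if region is not None:
            # pad so fragments whose events fall inside the region are seen
            start = max(0, region.start - 2000)
            reads = bam.fetch(region.chrom, start, region.end + 2000)
        else:
            reads = bam.fetch()
        for read in reads:
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.is_reverse):
                continue
            if not read.is_proper_pair or read.mapping_quality < min_mapq:
                continue
            tlen = read.template_length
            if tlen <= 0:
                continue
            yield AlignedFragment(read.reference_name, read.reference_start,
                                  read.reference_start + tlen, "+")


def fragment_length_histogram(fragments: Iterable[AlignedFragment],
                              max_length: int = 1000) -> np.ndarray:
    """Histogram of fragment lengths over 1..max_length (index 0 = length 1)."""
    hist = np.zeros(max_length, dtype=np.int64)
    for frag in fragments:
        if 1 <= frag.length <= max_length:
            hist[frag.length - 1] += 1
    return hist


def estimate_boundaries(histogram: Sequence[float], smooth_window: int = 11,
                        min_prominence_frac: float = 0.01) -> FragmentClassScheme:
    """Estimate Nfr/1N/+2N boundaries from a fragment-length histogram.

    The histogram (index 0 = length 1) is smoothed with a moving average
    and the local minima between the first three modes become the class
    boundaries.  With fewer than three detectable modes the standard
    defaults (145, 307) are returned with a warning.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.size == 0 or hist.sum() <= 0:
        raise ValueError("empty fragment-length histogram")
    smooth = uniform_filter1d(hist, size=smooth_window, mode="nearest")
    prominence = min_prominence_frac * smooth.max()
    peaks, _ = find_peaks(smooth, prominence=prominence)
    if len(peaks) < 3:
        warnings.warn("fewer than three fragment-size modes detected; "
                      "using default boundaries (145, 307)")
        return FragmentClassScheme()
    p0, p1, p2 = peaks[:3]
    nfr_upper = int(np.argmin(smooth[p0:p1 + 1]) + p0) + 1   # index -> length
    mono_upper = int(np.argmin(smooth[p1:p2 + 1]) + p1) + 1
    return FragmentClassScheme(nfr_upper=nfr_upper, mono_upper=mono_upper)
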