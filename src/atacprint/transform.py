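"""Normalisation and slope channels feeding the footprint HMM.

Bias-corrected tracks are first normalised within a signal (each value
divided by the mean of the non-zero values in its enclosing genomic
bin), squashed between signals with a logistic function, and paired
with a Savitzky-Golay first-derivative channel.  A decomposition
strategy selects which fragment classes and strands contribute
channels; dimensions range from 2 (one class, no strand split) to 12
(three classes, strand-specific).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.special import expit

from .fragments import GenomicRegion

#: fragment classes per named decomposition strategy
STRATEGY_CLASSES: dict[str, tuple[str, ...]] = {
    "All": ("All",),
    "Nfr": ("Nfr",),
    "Nfr&+1N": ("Nfr", "+1N"),
    "Nfr&1N&+2N": ("Nfr", "1N", "+2N"),
}

DEFAULT_BIN_SIZE = 10_000
DEFAULT_SAVGOL_WINDOW = 9


@dataclass(frozen=True)
class DecompositionStrategy:
    """Which fragment-class/strand signals enter the observation matrix."""

    name: str = "All"
    strand_specific: bool = True

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_CLASSES:
            raise ValueError(f"unknown strategy {self.name!r}; "
                             f"choose from {sorted(STRATEGY_CLASSES)}")

    @property
    def classes(self) -> tuple[str, ...]:
        return STRATEGY_CLASSES[self.name]

    @property
    def strands(self) -> tuple[str, ...]:
        return ("+", "-") if self.strand_specific else ("*",)

    @property
    def channels(self) -> list[tuple[str, str, str]]:
        """Ordered (fragment_class, strand, {norm, slope}) channel labels."""
        return [(cls, strand, kind)
                for cls in self.classes
                for strand in self.strands
                for kind in ("norm", "slope")]

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class ObservationMatrix:
    """Per-position channel values decoded by the HMM."""

    region: GenomicRegion
    strategy: DecompositionStrategy
    data: np.ndarray = field(repr=False)    # (positions, channels)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.region), self.strategy.n_channels):
            raise ValueError("data shape must be (region length, n_channels)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("observation matrix must be finite")


def within_normalize(x: np.ndarray, bin_size: int = DEFAULT_BIN_SIZE) -> np.ndarray:
    """Divide each value by the mean of non-zero values in its bin.

    Bins with no non-zero value pass through unchanged, so all-zero
    stretches stay zero.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    x = np.asarray(x, dtype=float)
    out = x.copy()
    for start in range(0, len(x), bin_size):
        chunk = x[start:start + bin_size]
        nz = chunk[chunk != 0]
        if nz.size:
            out[start:start + bin_size] = chunk / nz.mean()
    return out


def between_normalize(x: np.ndarray) -> np.ndarray:
    """Logistic squashing into (0, 1): f(v) = 1 / (1 + e^{-v})."""
    return expit(np.asarray(x, dtype=float))


def savgol_slope(x: np.ndarray, window: int = DEFAULT_SAVGOL_WINDOW,
                 order: int = 2) -> np.ndarray:
    """Savitzky-Golay first derivative (unit spacing).

    Exact for polynomials up to ``order`` at interior positions.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 5:
        raise ValueError("window must be odd and >= 5")
    if window > len(x):
        raise ValueError("window larger than signal")
    return savgol_filter(x, window_length=window, polyorder=order, deriv=1, delta=1.0)


def assemble(corrected: Mapping[tuple[str, str], np.ndarray], region: GenomicRegion,
             strategy: DecompositionStrategy, bin_size: int = DEFAULT_BIN_SIZE,
             savgol_window: int = DEFAULT_SAVGOL_WINDOW) -> ObservationMatrix:
    """Build the observation matrix from bias-corrected tracks.

    ``corrected`` maps ``(fragment_class, strand)`` to the corrected
    signal over ``region`` ('*' strand for non-strand-specific input).
    For each channel pair the pipeline is fixed: within-signal
    normalisation, then the logistic squashing for the ``norm`` channel
    and the Savitzky-Golay derivative of the pre-logistic signal for
    the ``slope`` channel.
    """
    cols = []
    for cls in strategy.classes:
        for strand in strategy.strands:
            key = (cls, strand)
            if key not in corrected:
                raise KeyError(f"missing corrected track for {key}")
            x = np.asarray(corrected[key], dtype=float)
            if len(x) != len(region):
                raise ValueError(f"track {key} does not cover the region")
            wn = within_normalize(x, bin_size)
            cols.append(between_normalize(wn))
            cols.append(savgol_slope(wn, savgol_window))
    return ObservationMatrix(region, strategy, np.stack(cols, axis=1))
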