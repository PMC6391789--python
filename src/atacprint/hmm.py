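"""Semi-supervised hidden Markov model for footprint decoding.

A fully connected S-state HMM with multivariate-normal emissions (full
covariance) segments the normalised cleavage channels.  One state is
designated FOOTPRINT.  Training is semi-supervised: windows centred on
ChIP-supported motif sites carry FOOTPRINT labels over the motif
interval; the FOOTPRINT emission is estimated from the labelled
positions and held fixed, while Baum-Welch re-estimates the remaining
states and all transitions, with the labels clamped during the E-step
(non-FOOTPRINT states are forbidden at labelled positions).

Decoding restricts Viterbi paths to open-chromatin peaks; maximal runs
of the FOOTPRINT state within length bounds become footprint calls.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .fragments import GenomicRegion
from .transform import ObservationMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_STATES = 9
DEFAULT_MIN_LEN = 5
DEFAULT_MAX_LEN = 50
COV_RIDGE = 1e-4
COV_MIN_EIG = 1e-6
TRAIN_FLANK = 500


@dataclass
class Footprint:
    """A decoded footprint interval with a tag-count score."""

    chrom: str
    start: int
    end: int
    name: str = "footprint"
    score: float = 0.0
    strand: str = "."

    def to_bed_line(self) -> str:
        return (f"{self.chrom}\t{self.start}\t{self.end}\t{self.name}\t"
                f"{self.score:.4g}\t{self.strand}")


@dataclass
class TrainingWindow:
    """Observations around one supported motif site, with per-position labels."""

    observations: np.ndarray = field(repr=False)   # (T, D)
    labels: np.ndarray = field(repr=False)         # (T,) bool, True = FOOTPRINT

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.shape[0] != self.observations.shape[0]:
            raise ValueError("labels and observations must align")


def _regularize_cov(cov: np.ndarray) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    if np.linalg.eigvalsh(cov).min() < COV_MIN_EIG:
        logger.debug("applying ridge regularisation to a degenerate covariance")
        cov = cov + COV_RIDGE * np.eye(cov.shape[0])
    return cov


def _log_mvn(obs: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Multivariate-normal log density of obs (..., D)."""
    d = mean.shape[0]
    chol = np.linalg.cholesky(cov)
    diff = obs - mean
    sol = np.linalg.solve(chol, diff[..., None])[..., 0] if diff.ndim > 1 else \
        np.linalg.solve(chol, diff)
    maha = np.sum(sol ** 2, axis=-1)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


@dataclass
class FootprintHMM:
    """Fully connected Gaussian HMM with a designated FOOTPRINT state."""

    startprob: np.ndarray = field(repr=False)
    transmat: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)          # (S, D)
    covars: np.ndarray = field(repr=False)         # (S, D, D)
    footprint_state: int = 0

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def validate(self, atol: float = 1e-9) -> None:
        np.testing.assert_allclose(self.startprob.sum(), 1, atol=atol)
        np.testing.assert_allclose(self.transmat.sum(axis=1), 1, atol=atol)
        for cov in self.covars:
            assert np.linalg.eigvalsh(0.5 * (cov + cov.T)).min() > 0

    def log_emission(self, obs: np.ndarray) -> np.ndarray:
        """(T, S) emission log densities (supports (..., T, D) batches)."""
        cols = [_log_mvn(obs, self.means[s], self.covars[s])
                for s in range(self.n_states)]
        out = np.stack(cols, axis=-1)
        if not np.all(np.isfinite(out)):
            raise ValueError("non-finite emission density")
        return out

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({
                "startprob": self.startprob.tolist(),
                "transmat": self.transmat.tolist(),
                "means": self.means.tolist(),
                "covars": self.covars.tolist(),
                "footprint_state": self.footprint_state,
            }, fh)

    @classmethod
    def from_json(cls, path: str) -> "FootprintHMM":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["startprob"]), np.array(d["transmat"]),
                   np.array(d["means"]), np.array(d["covars"]),
                   d["footprint_state"])


def make_training_windows(chip_peaks: Sequence[tuple[int, int]],
                          mpbs: Sequence[tuple[int, int]],
                          observations: ObservationMatrix,
                          flank: int = TRAIN_FLANK) -> list[TrainingWindow]:
    """One labelled window per ChIP-supported motif site.

    ``chip_peaks`` and ``mpbs`` are (start, end) genomic intervals on
    the chromosome of ``observations``.  A motif site is supported when
    it overlaps any ChIP peak; its window spans the motif centre ±
    ``flank`` and the FOOTPRINT label covers exactly the motif
    interval.  Windows not fully inside the observation region are
    dropped so all windows share one length (2*flank + 1).
    """
    region = observations.region
    windows: list[TrainingWindow] = []
    for (ms, me) in mpbs:
        if not any(ms < pe and ps < me for (ps, pe) in chip_peaks):
            continue
        center = (ms + me) // 2
        lo, hi = center - flank, center + flank + 1
        if lo < region.start or hi > region.end:
            continue
        obs = observations.data[lo - region.start:hi - region.start]
        labels = np.zeros(hi - lo, dtype=bool)
        labels[max(ms, lo) - lo:min(me, hi) - lo] = True
        windows.append(TrainingWindow(obs, labels))
    if not windows:
        raise ValueError("no ChIP-supported motif sites available for training")
    return windows


def _mstep_emissions(obs_flat: np.ndarray, gamma_flat: np.ndarray,
                     update: Sequence[int], means: np.ndarray,
                     covars: np.ndarray) -> None:
    """Gaussian M-step with an inverse-Wishart-style ridge prior.

    The prior (scale COV_RIDGE·I, strength 1) keeps covariances
    positive-definite when a state collapses onto near-constant
    observations, while preserving EM monotonicity (it is a MAP
    update with a parameter-independent prior).
    """
    d = obs_flat.shape[1]
    for s in update:
        w = gamma_flat[:, s]
        tot = w.sum()
        if tot <= 1e-12:
            continue
        mu = (w @ obs_flat) / tot
        diff = obs_flat - mu
        scatter = (diff * w[:, None]).T @ diff
        means[s] = mu
        covars[s] = (scatter + COV_RIDGE * np.eye(d)) / (tot + 1.0)


def train_semi_supervised(windows: Sequence[TrainingWindow], n_states: int = DEFAULT_N_STATES,
                          seed: int = 0, footprint_state: int = 0,
                          max_iter: int = 100, tol: float = 1e-6) -> FootprintHMM:
    """Baum-Welch with the FOOTPRINT state supervised by labels.

    The FOOTPRINT emission is fit once on labelled positions and held
    fixed; labelled positions are clamped to the FOOTPRINT state during
    the E-step, which makes each iteration an exact EM step on the
    joint likelihood of observations and labels (monotone up to
    numerical tolerance).  Initial parameters come from an M-step over
    random posteriors (labels excepted).  Deterministic for a fixed
    seed.

    Convergence is declared when the log-likelihood gain per iteration
    drops below ``tol`` nats per observation.  The threshold is
    per-observation rather than relative to the total likelihood: a
    total-likelihood-relative threshold grows with the corpus and can
    halt EM while it is still traversing the symmetric saddle where
    several states share one emission.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    windows = list(windows)
    lengths = {w.observations.shape[0] for w in windows}
    if len(lengths) != 1:
        raise ValueError("training windows must share one length")
    obs = np.stack([w.observations for w in windows])        # (N, T, D)
    labels = np.stack([w.labels for w in windows])           # (N, T)
    n_win, t_len, n_dim = obs.shape
    rng = np.random.default_rng(seed)

    labelled = obs[labels]
    if labelled.shape[0] < n_dim + 1:
        raise ValueError("too few labelled positions to fit the FOOTPRINT emission")
    fp_mean = labelled.mean(axis=0)
    fp_cov = _regularize_cov(np.cov(labelled.T, bias=True).reshape(n_dim, n_dim))

    # init: M-step over random posteriors, labels clamped.  A sparse
    # Dirichlet makes the posteriors near-one-hot so the free states start
    # from distinct random partitions of the data (uniform posteriors would
    # initialise every state at the global mean and EM would often stall
    # in a symmetric local optimum).
    gamma = rng.dirichlet(np.full(n_states, 0.1), size=(n_win, t_len))
    gamma[labels] = np.eye(n_states)[footprint_state]
    means = np.zeros((n_states, n_dim))
    covars = np.zeros((n_states, n_dim, n_dim))
    free_states = [s for s in range(n_states) if s != footprint_state]
    gflat = gamma.reshape(-1, n_states)
    oflat = obs.reshape(-1, n_dim)
    _mstep_emissions(oflat, gflat, free_states, means, covars)
    means[footprint_state] = fp_mean
    covars[footprint_state] = fp_cov
    startprob = gamma[:, 0].mean(axis=0)
    pseudo_xi = np.einsum("nti,ntj->ij", gamma[:, :-1], gamma[:, 1:])
    transmat = pseudo_xi / pseudo_xi.sum(axis=1, keepdims=True)

    model = FootprintHMM(startprob, transmat, means, covars, footprint_state)
    prev_ll = -np.inf
    history: list[float] = []
    label_mask = np.zeros((n_win, t_len, n_states))
    label_mask[labels] = -np.inf
    label_mask[labels, footprint_state] = 0.0

    for it in range(max_iter):
        logb = model.log_emission(obs) + label_mask          # (N, T, S)
        log_a = np.log(np.clip(model.transmat, 1e-300, None))
        log_pi = np.log(np.clip(model.startprob, 1e-300, None))

        alpha = np.empty_like(logb)
        alpha[:, 0] = log_pi + logb[:, 0]
        for t in range(1, t_len):
            alpha[:, t] = logb[:, t] + logsumexp(alpha[:, t - 1][:, :, None] + log_a, axis=1)
        beta = np.zeros_like(logb)
        for t in range(t_len - 2, -1, -1):
            beta[:, t] = logsumexp(log_a[None] + (logb[:, t + 1] + beta[:, t + 1])[:, None, :],
                                   axis=2)
        ll = float(logsumexp(alpha[:, -1], axis=1).sum())
        history.append(ll)

        log_gamma = alpha + beta
        log_gamma -= logsumexp(log_gamma, axis=2, keepdims=True)
        gamma = np.exp(log_gamma)

        # xi summed over t, per window batch
        xi_sum = np.zeros((n_states, n_states))
        norm = logsumexp(alpha[:, -1], axis=1)               # (N,)
        for t in range(t_len - 1):
            m = (alpha[:, t][:, :, None] + log_a[None]
                 + (logb[:, t + 1] + beta[:, t + 1])[:, None, :]
                 - norm[:, None, None])
            xi_sum += np.exp(m).sum(axis=0)

        startprob = gamma[:, 0].sum(axis=0)
        startprob /= startprob.sum()
        transmat = xi_sum / np.clip(xi_sum.sum(axis=1, keepdims=True), 1e-300, None)
        gflat = gamma.reshape(-1, n_states)
        _mstep_emissions(oflat, gflat, free_states, means, covars)
        model = FootprintHMM(startprob, transmat, means, covars, footprint_state)

        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            logger.warning("training objective decreased at iteration %d", it)
        if prev_ll > -np.inf and abs(ll - prev_ll) < tol * n_win * t_len:
            break
        prev_ll = ll
    else:
        warnings.warn("semi-supervised training reached max_iter without converging")
    model.validate(atol=1e-6)
    model.training_history = history   # per-iteration joint log-likelihood
    return model


def viterbi_decode(model: FootprintHMM, obs: np.ndarray) -> np.ndarray:
    """Most probable state path (log-space; ties broken to the lowest index)."""
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != model.n_dims:
        raise ValueError("observation dimension does not match the model")
    logb = model.log_emission(obs)
    log_a = np.log(np.clip(model.transmat, 1e-300, None))
    log_pi = np.log(np.clip(model.startprob, 1e-300, None))
    t_len, s = logb.shape
    delta = log_pi + logb[0]
    psi = np.zeros((t_len, s), dtype=int)
    for t in range(1, t_len):
        cand = delta[:, None] + log_a
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(s)] + logb[t]
    path = np.empty(t_len, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(t_len - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def extract_footprints(path: np.ndarray, region: GenomicRegion,
                       footprint_state: int = 0, min_len: int = DEFAULT_MIN_LEN,
                       max_len: int = DEFAULT_MAX_LEN, name: str = "footprint") -> list[Footprint]:
    """Maximal FOOTPRINT-state runs as intervals, filtered by length."""
    hits = np.asarray(path) == footprint_state
    footprints = []
    boundaries = np.flatnonzero(np.diff(np.concatenate(([0], hits.view(np.int8), [0]))))
    for start, end in boundaries.reshape(-1, 2):
        if min_len <= end - start <= max_len:
            footprints.append(Footprint(region.chrom, region.start + int(start),
                                        region.start + int(end), name=name))
    return footprints


def tag_count_score(footprint: Footprint, signal: np.ndarray, region: GenomicRegion,
                    mpbs: tuple[int, int] | None = None) -> float:
    """Sum of corrected cleavage signal over the footprint (plus its motif window)."""
    lo, hi = footprint.start, footprint.end
    if mpbs is not None:
        lo, hi = min(lo, mpbs[0]), max(hi, mpbs[1])
    lo = max(lo, region.start)
    hi = min(hi, region.end)
    if hi <= lo:
        return 0.0
    return float(np.sum(signal[lo - region.start:hi - region.start]))


def write_footprints_bed(footprints: Sequence[Footprint], path: str) -> None:
    with open(path, "w") as fh:
        for fp in footprints:
            fh.write(fp.to_bed_line() + "\n")
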