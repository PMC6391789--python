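"""Sequence-specific cleavage-bias estimation and signal correction.

Cleavage enzymes (Tn5, DNase-I) prefer particular DNA words, so raw
cut-site counts confound protein occupancy with sequence composition.
The bias of a word ``w`` is the ratio

    b(w) = p(w | obs) / p(w | exp),

where ``obs`` is the distribution of k-words centred on observed
cleavage events and ``exp`` the distribution over all positions of the
accessible (peak) regions.  Three estimators of p(w) are provided:

* k-mer: a full multinomial over 4^k words (flexible, overfits for
  large k);
* PWM: independent per-position base frequencies;
* SLIM: a sparse local inhomogeneous mixture — per position j, a
  mixture of the marginal p(w_j) and pairwise conditionals p(w_j|w_l)
  for l < j within distance d, with mixture priors learned
  discriminatively against uniform random words.  The PWM is the
  special case p(C_j = 0) = 1 at every position.

Corrected signals divide observed counts by locally normalised expected
counts:  x_i = (y_i + 1) / (ŷ_i · b̂(w[i]) + 1)  with ŷ the windowed
mean count and b̂ the bias normalised over the same window.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, softmax

from ._sequence import BASES, encode, revcomp
from .fragments import CleavageTrack, GenomicRegion

logger = logging.getLogger(__name__)

MAX_SLIM_K = 12


# ---------------------------------------------------------------------------
# word extraction and counting


def extract_word(genome: str, i: int, k: int) -> str | None:
    """Word of length k centred on position i: G[i - k//2 .. i + ceil(k/2) - 1].

    Returns None (skipped) when the word overlaps a chromosome end or
    contains a non-ACGT character.
    """
    lo = i - k // 2
    hi = lo + k
    if lo < 0 or hi > len(genome):
        return None
    word = genome[lo:hi].upper()
    if any(c not in BASES for c in word):
        return None
    return word


def word_index_track(seq: str, k: int) -> np.ndarray:
    """Packed base-4 word index centred at every position of ``seq``.

    Entry i is the index of ``extract_word(seq, i, k)``, or -1 where the
    word is invalid (boundary overhang or non-ACGT).
    """
    codes = encode(seq)
    n = len(codes)
    out = np.full(n, -1, dtype=np.int64)
    if n < k:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)  # (n-k+1, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    packed = windows.astype(np.int64) @ powers
    centers = np.arange(n - k + 1) + k // 2
    out[centers[valid]] = packed[valid]
    return out


def revcomp_index_permutation(k: int) -> np.ndarray:
    """Permutation p such that p[idx(w)] = idx(revcomp(w)) for packed words."""
    idx = np.arange(4 ** k, dtype=np.int64)
    digits = (idx[:, None] // 4 ** np.arange(k - 1, -1, -1)) % 4
    rc = 3 - digits[:, ::-1]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return rc @ powers


def word_digits(k: int) -> np.ndarray:
    """(4^k, k) array of base codes for every word, lexicographic order."""
    idx = np.arange(4 ** k, dtype=np.int64)
    return ((idx[:, None] // 4 ** np.arange(k - 1, -1, -1)) % 4).astype(np.int8)


class WordCounts:
    """Multiset of DNA words of fixed length k, stored as a 4^k count vector."""

    def __init__(self, k: int, counts: np.ndarray | None = None):
        if k > MAX_SLIM_K:
            raise ValueError(f"k={k} too large for dense word counting")
        self.k = k
        self.counts = (np.zeros(4 ** k, dtype=np.float64) if counts is None
                       else np.asarray(counts, dtype=np.float64))
        if self.counts.shape != (4 ** k,):
            raise ValueError("counts must have length 4^k")

    @classmethod
    def from_words(cls, words: Iterable[str] | Mapping[str, float], k: int) -> "WordCounts":
        wc = cls(k)
        items = words.items() if isinstance(words, Mapping) else ((w, 1) for w in words)
        for w, n in items:
            wc.add(w, n)
        return wc

    def add(self, word: str, count: float = 1) -> None:
        codes = encode(word)
        if len(codes) != self.k or (codes < 0).any():
            raise ValueError(f"invalid word {word!r} for k={self.k}")
        powers = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        self.counts[int(codes.astype(np.int64) @ powers)] += count

    def add_indices(self, indices: np.ndarray, weights: np.ndarray | None = None) -> None:
        """Accumulate packed word indices (entries < 0 are skipped)."""
        ok = indices >= 0
        w = None if weights is None else np.asarray(weights, dtype=float)[ok]
        self.counts += np.bincount(indices[ok], weights=w, minlength=4 ** self.k)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __getitem__(self, word: str) -> float:
        codes = encode(word).astype(np.int64)
        powers = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        return float(self.counts[int(codes @ powers)])


def collect_words(tracks: Iterable[CleavageTrack], peaks: Sequence[GenomicRegion],
                  genome: Mapping[str, str], k: int,
                  whole_genome_background: bool = False) -> tuple[WordCounts, WordCounts]:
    """Build the observed and expected word multisets for bias estimation.

    ``W_obs`` holds the word around every cleavage event inside a peak,
    with multiplicity equal to the event count; reverse-strand events
    contribute the reverse complement of the forward-genome word.
    ``W_exp`` holds the word at every position of every peak (or of the
    whole genome for naked-DNA libraries).
    """
    peaks = list(peaks)
    if not peaks and not whole_genome_background:
        raise ValueError("peaks required unless whole_genome_background=True")
    w_obs = WordCounts(k)
    w_exp = WordCounts(k)
    rc_perm = revcomp_index_permutation(k)
    idx_cache: dict[str, np.ndarray] = {}

    def chrom_index(chrom: str) -> np.ndarray:
        if chrom not in idx_cache:
            idx_cache[chrom] = word_index_track(str(genome[chrom]), k)
        return idx_cache[chrom]

    peak_mask: dict[str, np.ndarray] = {}
    for p in peaks:
        mask = peak_mask.setdefault(p.chrom, np.zeros(len(str(genome[p.chrom])), dtype=bool))
        mask[p.start:p.end] = True

    for track in tracks:
        idx = chrom_index(track.region.chrom)[track.region.start:track.region.end]
        if track.strand == "-":
            valid = idx >= 0
            idx = np.where(valid, rc_perm[np.clip(idx, 0, None)], -1)
        weights = np.asarray(track.counts, dtype=float)
        if not whole_genome_background:
            mask = peak_mask.get(track.region.chrom)
            inpeak = (mask[track.region.start:track.region.end]
                      if mask is not None else np.zeros(len(idx), dtype=bool))
            weights = weights * inpeak
        w_obs.add_indices(idx, weights)

    if whole_genome_background:
        for chrom in genome:
            w_exp.add_indices(chrom_index(chrom))
    else:
        for p in peaks:
            w_exp.add_indices(chrom_index(p.chrom)[p.start:p.end])

    if w_obs.total <= 0:
        raise ValueError("no observed cleavage events inside peaks")
    return w_obs, w_exp


# ---------------------------------------------------------------------------
# estimators


@dataclass
class KmerBiasTable:
    """Multinomial k-mer bias: b(w) = p(w|obs) / p(w|exp)."""

    k: int
    obs_prob: np.ndarray = field(repr=False)
    exp_prob: np.ndarray = field(repr=False)

    @property
    def bias(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            b = self.obs_prob / self.exp_prob
        return np.nan_to_num(b, nan=0.0, posinf=np.inf)

    def bias_table(self) -> np.ndarray:
        return self.bias

    def bias_of(self, word: str) -> float:
        wc = WordCounts(self.k)
        wc.add(word)
        return float(self.bias[np.argmax(wc.counts)])

    def to_tsv(self, path: str) -> None:
        from ._sequence import all_words
        bias = self.bias
        with open(path, "w") as fh:
            fh.write("word\tobs_prob\texp_prob\tbias\n")
            for i, w in enumerate(all_words(self.k)):
                fh.write(f"{w}\t{self.obs_prob[i]:.6g}\t{self.exp_prob[i]:.6g}\t{bias[i]:.6g}\n")


def estimate_kmer(w_obs: WordCounts, w_exp: WordCounts, pseudocount: float = 1.0) -> KmerBiasTable:
    """k-mer bias table from observed/background word multisets.

    A pseudocount is added to every word count before normalising so
    unseen background words cannot zero the denominator.
    """
    if w_obs.k != w_exp.k:
        raise ValueError("word lengths differ")
    if w_obs.total <= 0 or w_exp.total <= 0:
        raise ValueError("empty word multiset")
    obs = w_obs.counts + pseudocount
    exp = w_exp.counts + pseudocount
    return KmerBiasTable(w_obs.k, obs / obs.sum(), exp / exp.sum())


@dataclass
class PwmBiasModel:
    """Position-independent bias: p(w) = prod_j p(w_j)."""

    k: int
    obs: np.ndarray = field(repr=False)   # (k, 4) per-position base probs
    exp: np.ndarray = field(repr=False)

    def log_prob(self, which: str = "obs") -> np.ndarray:
        """log p(w) for all 4^k words in lexicographic order."""
        mat = self.obs if which == "obs" else self.exp
        digits = word_digits(self.k)
        out = np.zeros(4 ** self.k)
        for j in range(self.k):
            out += np.log(mat[j, digits[:, j]])
        return out

    def bias_table(self) -> np.ndarray:
        return np.exp(self.log_prob("obs") - self.log_prob("exp"))

    def bias_of(self, word: str) -> float:
        codes = encode(word)
        num = np.prod(self.obs[np.arange(self.k), codes])
        den = np.prod(self.exp[np.arange(self.k), codes])
        return float(num / den)


def _position_base_freqs(wc: WordCounts, pseudocount: float) -> np.ndarray:
    digits = word_digits(wc.k)
    freqs = np.empty((wc.k, 4))
    for j in range(wc.k):
        freqs[j] = np.bincount(digits[:, j], weights=wc.counts, minlength=4)
    freqs += pseudocount
    return freqs / freqs.sum(axis=1, keepdims=True)


def estimate_pwm(w_obs: WordCounts, w_exp: WordCounts, pseudocount: float = 1.0) -> PwmBiasModel:
    """Per-position independent bias model from word multisets."""
    if w_obs.k != w_exp.k:
        raise ValueError("word lengths differ")
    return PwmBiasModel(w_obs.k,
                        _position_base_freqs(w_obs, pseudocount),
                        _position_base_freqs(w_exp, pseudocount))


# ---------------------------------------------------------------------------
# SLIM position-dependency model


@dataclass
class SlimModel:
    """Sparse local inhomogeneous mixture over words of length k.

    Per position j (0-based):  m_j(w) = p(C_j=0) p(w_j)
        + p(C_j=1) sum_l p(R_lj) p(w_j | w_l),  l < j, j - l <= d,
    and p(w) = prod_j m_j(w).  Position 0 has no admissible l, so
    p(C_0 = 1) = 0 by construction.
    """

    k: int
    d: int
    marginal: np.ndarray = field(repr=False)            # (k, 4)
    conditional: dict = field(repr=False)               # (l, j) -> (4, 4) rows l
    prior_c: np.ndarray = field(repr=False)             # (k,) = p(C_j = 1)
    prior_r: dict = field(repr=False)                   # j -> weights over admissible l
    converged: bool = True

    def admissible(self, j: int) -> list[int]:
        return [l for l in range(max(0, j - self.d), j)]

    def validate(self, atol: float = 1e-9) -> None:
        assert np.all((self.prior_c >= -atol) & (self.prior_c <= 1 + atol))
        assert self.prior_c[0] <= atol
        np.testing.assert_allclose(self.marginal.sum(axis=1), 1, atol=atol)
        for j in range(1, self.k):
            ls = self.admissible(j)
            if ls:
                np.testing.assert_allclose(self.prior_r[j].sum(), 1, atol=atol)
            for l in ls:
                np.testing.assert_allclose(self.conditional[(l, j)].sum(axis=1), 1, atol=atol)

    def _mixture_factors(self, digits: np.ndarray) -> np.ndarray:
        """(n_words, k) matrix of per-position mixture factors m_j."""
        n = digits.shape[0]
        m = np.empty((n, self.k))
        for j in range(self.k):
            pj = self.marginal[j, digits[:, j]]
            ls = self.admissible(j)
            if not ls or self.prior_c[j] == 0:
                m[:, j] = pj
                continue
            cond = np.zeros(n)
            for li, l in enumerate(ls):
                cond += self.prior_r[j][li] * self.conditional[(l, j)][digits[:, l], digits[:, j]]
            m[:, j] = (1 - self.prior_c[j]) * pj + self.prior_c[j] * cond
        return m

    def log_prob_all(self) -> np.ndarray:
        """log p(w) for every word of length k, lexicographic order."""
        return np.log(self._mixture_factors(word_digits(self.k))).sum(axis=1)

    def probability(self, word: str) -> float:
        codes = encode(word)
        if len(codes) != self.k or (codes < 0).any():
            raise ValueError(f"invalid word {word!r}")
        return float(np.prod(self._mixture_factors(codes[None, :].astype(np.int8))))

    def to_dict(self) -> dict:
        return {
            "k": self.k, "d": self.d,
            "marginal": self.marginal.tolist(),
            "prior_c": self.prior_c.tolist(),
            "prior_r": {str(j): w.tolist() for j, w in self.prior_r.items()},
            "conditional": {f"{l},{j}": c.tolist() for (l, j), c in self.conditional.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SlimModel":
        return cls(
            k=data["k"], d=data["d"],
            marginal=np.array(data["marginal"]),
            prior_c=np.array(data["prior_c"]),
            prior_r={int(j): np.array(w) for j, w in data["prior_r"].items()},
            conditional={tuple(map(int, key.split(","))): np.array(c)
                         for key, c in data["conditional"].items()},
        )


def slim_probability(model: SlimModel, word: str) -> float:
    """Probability of a word under a SLIM model (see :class:`SlimModel`)."""
    return model.probability(word)


def _slim_sufficient_stats(wc: WordCounts, d: int, pseudocount: float):
    """Marginals and pairwise conditionals from corpus frequencies."""
    k = wc.k
    digits = word_digits(k)
    marginal = np.empty((k, 4))
    for j in range(k):
        row = np.bincount(digits[:, j], weights=wc.counts, minlength=4) + pseudocount
        marginal[j] = row / row.sum()
    conditional = {}
    for j in range(1, k):
        for l in range(max(0, j - d), j):
            joint = np.zeros((4, 4))
            np.add.at(joint, (digits[:, l], digits[:, j]), wc.counts)
            joint += pseudocount
            conditional[(l, j)] = joint / joint.sum(axis=1, keepdims=True)
    return marginal, conditional


def fit_slim(corpus: WordCounts, d: int = 5, seed: int = 0, pseudocount: float = 1.0,
             sparsity_beta: float = 10.0, max_iter: int = 500,
             tol: float = 1e-6) -> SlimModel:
    """Fit a SLIM model to a word corpus.

    Marginals and pairwise conditionals are plain (pseudocounted)
    corpus frequencies.  The mixture priors p(C_j), p(R_lj) are learned
    by maximising a supervised posterior: the corpus words are
    discriminated from an equal number of uniform random words, with a
    Beta(1, ``sparsity_beta``) prior on each p(C_j = 1) that favours the
    independent (PWM) component unless dependencies genuinely improve
    discrimination.  Optimisation is quasi-Newton (L-BFGS) on the
    logit/softmax transform of the priors.
    """
    if d > 5:
        raise ValueError("dependency distance d must be <= 5")
    if corpus.total <= 0:
        raise ValueError("empty corpus")
    k = corpus.k
    marginal, conditional = _slim_sufficient_stats(corpus, d, pseudocount)
    digits = word_digits(k)
    n_words = 4 ** k

    rng = np.random.default_rng(seed)
    n_neg = int(round(corpus.total))
    neg_counts = rng.multinomial(n_neg, np.full(n_words, 1.0 / n_words)).astype(float)

    # per-position precomputations over all 4^k words
    pj_all = np.stack([marginal[j, digits[:, j]] for j in range(k)], axis=1)
    cond_all: dict[int, np.ndarray] = {}   # j -> (n_words, n_admissible)
    admissible = {j: list(range(max(0, j - d), j)) for j in range(k)}
    for j in range(1, k):
        cols = [conditional[(l, j)][digits[:, l], digits[:, j]] for l in admissible[j]]
        cond_all[j] = np.stack(cols, axis=1)

    free_j = [j for j in range(1, k)]
    n_r = {j: len(admissible[j]) for j in free_j}
    sizes = [1 + n_r[j] for j in free_j]          # a_j plus softmax logits
    offsets = np.cumsum([0] + sizes)
    log_bg = -k * np.log(4.0)

    def unpack(theta):
        cs = np.zeros(k)
        rs: dict[int, np.ndarray] = {}
        for idx, j in enumerate(free_j):
            seg = theta[offsets[idx]:offsets[idx + 1]]
            cs[j] = expit(seg[0])
            rs[j] = softmax(seg[1:])
        return cs, rs

    pos_counts = corpus.counts

    def negobj(theta):
        cs, rs = unpack(theta)
        logp = np.log(pj_all[:, 0])
        grads = []
        per_j = []
        for idx, j in enumerate(free_j):
            q = cond_all[j] @ rs[j]
            m = (1 - cs[j]) * pj_all[:, j] + cs[j] * q
            per_j.append((q, m))
            logp = logp + np.log(m)
        s = logp - log_bg
        sig = expit(s)
        # F = sum_pos log sigma(s) + sum_neg log sigma(-s) + log prior
        with np.errstate(divide="ignore"):
            f = float(pos_counts @ np.log(np.clip(sig, 1e-300, None))
                      + neg_counts @ np.log(np.clip(1 - sig, 1e-300, None)))
        coeff = pos_counts * (1 - sig) - neg_counts * sig       # dF/ds per word
        grad = np.empty_like(theta)
        for idx, j in enumerate(free_j):
            q, m = per_j[idx]
            dlogp_dc = (q - pj_all[:, j]) / m
            da = cs[j] * (1 - cs[j]) * float(coeff @ dlogp_dc)
            # prior: (beta-1) * log(1 - c_j); d/da = -(beta-1)*c_j
            f += (sparsity_beta - 1) * np.log1p(-min(cs[j], 1 - 1e-12))
            da += -(sparsity_beta - 1) * cs[j]
            qbar = q
            # d log p / d b_m = (c r_m / m)(q_m - sum_l r_l q_l)
            diff = cond_all[j] - qbar[:, None]
            db = rs[j] * (cs[j] * (coeff / m) @ diff)
            grad[offsets[idx]] = da
            grad[offsets[idx] + 1:offsets[idx + 1]] = db
        return -f, -grad

    if offsets[-1] == 0:                      # k == 1: no mixture priors to fit
        model = SlimModel(k=k, d=d, marginal=marginal, conditional=conditional,
                          prior_c=np.zeros(k), prior_r={}, converged=True)
        return model
    theta0 = np.zeros(offsets[-1])
    for idx, j in enumerate(free_j):
        theta0[offsets[idx]] = -2.0           # start near the PWM special case
    res = minimize(negobj, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": tol})
    if not res.success:
        warnings.warn(f"SLIM prior optimisation did not converge: {res.message}")
    cs, rs = unpack(res.x)
    prior_r = {j: rs.get(j, np.ones(max(len(admissible[j]), 1)) / max(len(admissible[j]), 1))
               for j in range(1, k)}
    model = SlimModel(k=k, d=d, marginal=marginal, conditional=conditional,
                      prior_c=cs, prior_r=prior_r, converged=bool(res.success))
    return model


@dataclass
class SlimBiasModel:
    """Paired obs/exp SLIM models giving b(w) = p(w|obs)/p(w|exp)."""

    obs: SlimModel
    exp: SlimModel

    @property
    def k(self) -> int:
        return self.obs.k

    def bias_table(self) -> np.ndarray:
        return np.exp(self.obs.log_prob_all() - self.exp.log_prob_all())

    def bias_of(self, word: str) -> float:
        return self.obs.probability(word) / self.exp.probability(word)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"obs": self.obs.to_dict(), "exp": self.exp.to_dict()}, fh)

    @classmethod
    def from_json(cls, path: str) -> "SlimBiasModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(SlimModel.from_dict(data["obs"]), SlimModel.from_dict(data["exp"]))


def estimate_slim(w_obs: WordCounts, w_exp: WordCounts, d: int = 5, seed: int = 0,
                  **kwargs) -> SlimBiasModel:
    """Fit SLIM models to both corpora and pair them as a bias model."""
    return SlimBiasModel(fit_slim(w_obs, d=d, seed=seed, **kwargs),
                         fit_slim(w_exp, d=d, seed=seed + 1, **kwargs))


def bias_ratio(model, word: str) -> float:
    """b(w) under any fitted bias model (k-mer, PWM or SLIM pair)."""
    return model.bias_of(word)


# ---------------------------------------------------------------------------
# track correction


def correct_track(track: CleavageTrack, model, genome: str, window: int = 50,
                  expected_counts_mode: str = "mean") -> np.ndarray:
    """Bias-corrected cleavage signal  x_i = (y_i + 1) / (ŷ_i · b̂(w[i]) + 1).

    ``ŷ_i`` is the average count over the window [i-25, i+24] (or the
    windowed sum with ``expected_counts_mode='sum'``) and
    ``b̂(w[i]) = b(w[i]) / Σ_{j∈window} b(w[j])``.  Reverse-strand
    tracks look the bias up on the reverse complement of the forward
    word.  Positions with an undeterminable word (boundary overhang or
    non-ACGT) take neutral bias 1.  Windows truncated at chromosome
    ends are renormalised over the positions available.
    """
    if expected_counts_mode not in ("mean", "sum"):
        raise ValueError("expected_counts_mode must be 'mean' or 'sum'")
    region = track.region
    k = model.k
    half = window // 2
    table = model.bias_table()

    lo = max(0, region.start - half)
    hi = min(len(genome), region.end + half)
    ctx_lo = max(0, lo - k)                  # keep genome context at slice edges
    ctx_hi = min(len(genome), hi + k)
    idx = word_index_track(genome[ctx_lo:ctx_hi], k)[lo - ctx_lo:lo - ctx_lo + (hi - lo)]
    if track.strand == "-":
        rc_perm = revcomp_index_permutation(k)
        idx = np.where(idx >= 0, rc_perm[np.clip(idx, 0, None)], -1)
    b = np.where(idx >= 0, table[np.clip(idx, 0, None)], 1.0)

    y = np.zeros(hi - lo)
    y[region.start - lo:region.start - lo + len(region)] = track.counts

    kernel = np.ones(window)
    # window [i-25, i+24]: correlate with origin shifted one left of centre
    pad_left, pad_right = half, half - 1
    ypad = np.pad(y, (pad_left, pad_right))
    bpad = np.pad(b, (pad_left, pad_right))
    npad = np.pad(np.ones_like(y), (pad_left, pad_right))
    ysum = np.convolve(ypad, kernel, mode="valid")
    bsum = np.convolve(bpad, kernel, mode="valid")
    nsum = np.convolve(npad, kernel, mode="valid")

    # truncate at true chromosome ends only (zero-padded positions beyond
    # [0, len(genome)) never exist); within the genome the padding added
    # above is real margin, so nsum counts actual positions
    bhat = np.where(bsum > 0, b / bsum, 0.0)
    if expected_counts_mode == "mean":
        yhat = ysum / nsum
    else:
        yhat = ysum
    x = (y + 1) / (yhat * bhat + 1)
    sl = slice(region.start - lo, region.start - lo + len(region))
    return x[sl]
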