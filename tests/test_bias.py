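"""Bias estimators (k-mer, PWM, SLIM) and cleavage-signal correction."""

import numpy as np
import pytest

import atacprint as ap
from atacprint._sequence import all_words, revcomp
from atacprint.bias import (SlimModel, WordCounts, word_digits, _slim_sufficient_stats,
                            collect_words, word_index_track)
from atacprint.fragments import CleavageTrack, GenomicRegion


# ---------------------------------------------------------------------------
# word extraction


def test_extract_word_centre_convention():
    # w[i] = G[i - k//2 .. i + ceil(k/2) - 1]; even k puts G[i] at index k//2
    assert ap.extract_word("AACGTT", 2, 4) == "AACG"
    assert ap.extract_word("AACGTT", 2, 3) == "ACG"
    assert ap.extract_word("AACGTT", 2, 1) == "C"
    assert ap.extract_word("AACGTT", 0, 2) is None       # left overhang
    assert ap.extract_word("AANGTT", 2, 3) is None       # non-ACGT


def test_word_index_track_matches_extract_word(rng):
    seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.24] * 4 + [0.04]))
    for k in (1, 2, 5):
        idx = word_index_track(seq, k)
        words = all_words(k)
        for i in range(len(seq)):
            w = ap.extract_word(seq, i, k)
            assert (idx[i] == -1) == (w is None)
            if w is not None:
                assert words[idx[i]] == w


def test_collect_words_multiplicity_and_brute_force(rng):
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 400))}
    peaks = [GenomicRegion("chr1", 50, 150), GenomicRegion("chr1", 200, 300)]
    counts = np.zeros(400, dtype=int)
    counts[60] = 3
    counts[210] = 1
    counts[350] = 5        # outside peaks: ignored
    track = CleavageTrack(GenomicRegion("chr1", 0, 400), "+", "All", counts)
    k = 3
    w_obs, w_exp = collect_words([track], peaks, genome, k)
    assert w_obs[ap.extract_word(genome["chr1"], 60, k)] == 3
    assert w_obs.total == 4
    assert w_exp.total == 200          # every peak position, no boundary skips here
    # brute force the expected multiset
    brute = {}
    for p in peaks:
        for i in range(p.start, p.end):
            w = ap.extract_word(genome["chr1"], i, k)
            if w:
                brute[w] = brute.get(w, 0) + 1
    for w, n in brute.items():
        assert w_exp[w] == n


def test_collect_words_reverse_strand_uses_reverse_complement(rng):
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 200))}
    peaks = [GenomicRegion("chr1", 0, 200)]
    counts = np.zeros(200, dtype=int)
    counts[100] = 2
    track = CleavageTrack(GenomicRegion("chr1", 0, 200), "-", "All", counts)
    w_obs, _ = collect_words([track], peaks, genome, 4)
    assert w_obs[revcomp(ap.extract_word(genome["chr1"], 100, 4))] == 2


# ---------------------------------------------------------------------------
# k-mer and PWM estimators


def test_kmer_identical_multisets_give_unit_bias():
    wc = WordCounts.from_words({"AA": 3, "CT": 2, "GG": 4}, 2)
    table = ap.estimate_kmer(wc, wc)
    for w in ("AA", "CT", "GG"):
        assert table.bias_of(w) == pytest.approx(1.0)


def test_kmer_hand_example():
    w_obs = WordCounts.from_words({"AA": 2, "AC": 2}, 2)
    w_exp = WordCounts.from_words({"AA": 1, "AC": 3}, 2)
    t = ap.estimate_kmer(w_obs, w_exp, pseudocount=0)
    assert t.bias_of("AA") == pytest.approx(2.0)
    assert t.bias_of("AC") == pytest.approx(2 / 3)


def test_kmer_uniform_monte_carlo(rng):
    """Uniform events on a uniform genome give bias ~ 1 for every word."""
    n = 200_000
    k = 2
    counts = rng.multinomial(n, np.full(16, 1 / 16)).astype(float)
    bg = rng.multinomial(4 * n, np.full(16, 1 / 16)).astype(float)
    t = ap.estimate_kmer(WordCounts(k, counts), WordCounts(k, bg))
    assert np.all(np.abs(t.bias - 1) < 0.05)


def test_pwm_hand_count_and_k1_equivalence():
    w_obs = WordCounts.from_words(["AC", "AG"], 2)
    w_exp = WordCounts.from_words(all_words(2), 2)
    m = ap.estimate_pwm(w_obs, w_exp, pseudocount=0)
    assert m.obs[0, 0] == pytest.approx(1.0)          # p(w_1 = A | obs)
    assert m.obs[1, 1] == pytest.approx(0.5)          # C
    assert m.obs[1, 2] == pytest.approx(0.5)          # G
    # k = 1: PWM bias equals k-mer bias exactly
    w1o = WordCounts.from_words({"A": 5, "C": 3, "G": 1, "T": 1}, 1)
    w1e = WordCounts.from_words({"A": 2, "C": 2, "G": 2, "T": 4}, 1)
    pw = ap.estimate_pwm(w1o, w1e)
    km = ap.estimate_kmer(w1o, w1e)
    np.testing.assert_allclose(pw.bias_table(), km.bias_table(), rtol=1e-12)


# ---------------------------------------------------------------------------
# SLIM


def _random_valid_slim(k, d, rng):
    marginal = rng.dirichlet(np.ones(4), size=k)
    conditional = {(l, j): rng.dirichlet(np.ones(4), size=4)
                   for j in range(1, k) for l in range(max(0, j - d), j)}
    prior_c = rng.uniform(0, 1, k)
    prior_c[0] = 0.0
    prior_r = {j: rng.dirichlet(np.ones(min(j, d))) for j in range(1, k)}
    return SlimModel(k=k, d=d, marginal=marginal, conditional=conditional,
                     prior_c=prior_c, prior_r=prior_r)


@pytest.mark.parametrize("k", [2, 4, 6])
def test_slim_probabilities_sum_to_one_by_enumeration(k, rng):
    model = _random_valid_slim(k, min(k - 1, 3), rng)
    model.validate(1e-9)
    assert np.exp(model.log_prob_all()).sum() == pytest.approx(1.0, abs=1e-9)


def test_slim_hand_expansion_k2():
    marginal = np.array([[0.1, 0.2, 0.3, 0.4], [0.25, 0.25, 0.25, 0.25]])
    cond = {(0, 1): np.array([[0.7, 0.1, 0.1, 0.1]] * 4)}
    model = SlimModel(k=2, d=1, marginal=marginal, conditional=cond,
                      prior_c=np.array([0.0, 0.6]), prior_r={1: np.array([1.0])})
    # p("CA") = p(w0=C) * [0.4 * p(w1=A) + 0.6 * p(A | C)]
    want = 0.2 * (0.4 * 0.25 + 0.6 * 0.7)
    assert ap.slim_probability(model, "CA") == pytest.approx(want)


def test_slim_degenerate_case_is_product_of_marginals(rng):
    model = _random_valid_slim(4, 2, rng)
    model.prior_c[:] = 0.0
    probs = np.exp(model.log_prob_all())
    digits = word_digits(4)
    expected = np.ones(256)
    for j in range(4):
        expected *= model.marginal[j, digits[:, j]]
    np.testing.assert_allclose(probs, expected, rtol=1e-12)


def test_fit_slim_recovers_planted_dependency(rng):
    """Position 1 copying position 0 yields p(C_1=1) > 0.9 and p(R_01) ~ 1."""
    n = 5000
    b0 = rng.choice(4, n, p=[0.4, 0.3, 0.2, 0.1])
    words = np.stack([b0, b0, rng.choice(4, n)], axis=1)
    wc = WordCounts(3)
    wc.add_indices((words @ (4 ** np.arange(2, -1, -1))).astype(np.int64))
    m = ap.fit_slim(wc, d=2, seed=0)
    m.validate(1e-6)
    assert m.prior_c[1] > 0.9
    assert m.prior_r[1][0] == pytest.approx(1.0, abs=0.05)


def test_fit_slim_independent_corpus_approaches_pwm(rng):
    """A dependency-free corpus gives p(C_j=1) ~ 0 and KL(SLIM || PWM) < 0.01."""
    k = 4
    pwm_probs = rng.dirichlet(np.ones(4), size=k)
    digits = word_digits(k)
    p = np.ones(4 ** k)
    for j in range(k):
        p *= pwm_probs[j, digits[:, j]]
    wc = WordCounts(k, rng.multinomial(30_000, p).astype(float))
    m = ap.fit_slim(wc, d=3, seed=0)
    assert np.all(m.prior_c < 0.1)
    logslim = m.log_prob_all()
    logpwm = ap.estimate_pwm(wc, wc).log_prob("obs")
    kl = float(np.sum(np.exp(logslim) * (logslim - logpwm)))
    assert kl < 0.01


def test_slim_nesting_is_exact(rng):
    """Forcing p(C_j=0)=1 reproduces the PWM probabilities bit for bit."""
    wc = WordCounts(3, rng.integers(0, 50, 64).astype(float))
    m = ap.fit_slim(wc, d=2, seed=0)
    m.prior_c[:] = 0.0
    pwm = ap.estimate_pwm(wc, wc)
    np.testing.assert_array_equal(np.exp(m.log_prob_all()), np.exp(pwm.log_prob("obs")))


def test_identical_obs_exp_slim_bias_is_one(rng):
    wc = WordCounts(3, rng.integers(1, 30, 64).astype(float))
    model = ap.SlimBiasModel(ap.fit_slim(wc, d=2, seed=3), ap.fit_slim(wc, d=2, seed=3))
    np.testing.assert_allclose(model.bias_table(), 1.0, atol=1e-12)
    assert ap.bias_ratio(model, "ACG") == pytest.approx(1.0)


def test_slim_json_round_trip(tmp_path, rng):
    wc = WordCounts(3, rng.integers(1, 30, 64).astype(float))
    model = ap.estimate_slim(wc, wc, d=2, seed=0)
    path = str(tmp_path / "slim.json")
    model.to_json(path)
    back = ap.SlimBiasModel.from_json(path)
    np.testing.assert_allclose(back.bias_table(), model.bias_table(), rtol=1e-12)


# ---------------------------------------------------------------------------
# track correction


def _brute_force_correct(track, model, genome, mode="mean"):
    region = track.region
    k = model.k
    lo = max(0, region.start - 25)
    hi = min(len(genome), region.end + 25)
    yext = np.zeros(len(genome))
    yext[region.start:region.end] = track.counts

    def b_at(j):
        w = ap.extract_word(genome, j, k)
        if w is None:
            return 1.0
        if track.strand == "-":
            w = revcomp(w)
        return model.bias_of(w)

    out = np.empty(len(region))
    for n, i in enumerate(range(region.start, region.end)):
        js = [j for j in range(i - 25, i + 25) if lo <= j < hi]
        bsum = sum(b_at(j) for j in js)
        ysum = sum(yext[j] for j in js)
        yhat = ysum / len(js) if mode == "mean" else ysum
        bhat = b_at(i) / bsum
        out[n] = (yext[i] + 1) / (yhat * bhat + 1)
    return out


def test_correct_track_zero_signal_gives_ones(rng):
    genome = "".join(rng.choice(list("ACGT"), 300))
    region = GenomicRegion("chr1", 100, 150)
    model = ap.estimate_kmer(WordCounts(2, rng.integers(1, 9, 16).astype(float)),
                             WordCounts(2, rng.integers(1, 9, 16).astype(float)))
    track = CleavageTrack(region, "+", "All", np.zeros(50, int))
    np.testing.assert_allclose(ap.correct_track(track, model, genome), 1.0)


@pytest.mark.parametrize("strand", ["+", "-"])
@pytest.mark.parametrize("mode", ["mean", "sum"])
def test_correct_track_matches_brute_force(strand, mode, rng):
    genome = "".join(rng.choice(list("ACGT"), 300))
    region = GenomicRegion("chr1", 100, 150)
    y = rng.poisson(3, 50)
    track = CleavageTrack(region, strand, "All", y)
    model = ap.estimate_kmer(WordCounts(2, rng.integers(1, 20, 16).astype(float)),
                             WordCounts(2, rng.integers(1, 20, 16).astype(float)))
    x = ap.correct_track(track, model, genome, expected_counts_mode=mode)
    np.testing.assert_allclose(x, _brute_force_correct(track, model, genome, mode),
                               rtol=1e-10)


def test_correct_track_scale_invariant_in_bias(rng):
    genome = "".join(rng.choice(list("ACGT"), 400))
    region = GenomicRegion("chr1", 100, 300)
    y = rng.poisson(5, 200)
    track = CleavageTrack(region, "+", "All", y)
    t = ap.estimate_kmer(WordCounts(2, rng.integers(1, 20, 16).astype(float)),
                         WordCounts(2, rng.integers(1, 20, 16).astype(float)))
    x1 = ap.correct_track(track, t, genome)
    scaled = ap.KmerBiasTable(t.k, t.obs_prob * 7.0, t.exp_prob)
    x2 = ap.correct_track(track, scaled, genome)
    np.testing.assert_allclose(x1, x2, rtol=1e-10)


def test_correction_reduces_variation_on_biased_footprint_free_library():
    """With planted bias and no footprints, correction lowers the CV of the track."""
    spec = ap.FixtureSpec(genome_length=30_000, n_sites=0, n_fragments=60_000,
                          protection=0.0, bias_k=4, bias_strength=0.8, seed=5)
    genome = ap.simulate_genome(spec.genome_length, 0.5, spec.seed)
    fx = ap.simulate_library(genome, spec)
    region = fx.region
    track = ap.build_signal(fx.fragments, region, "+")
    w_obs, w_exp = collect_words([track], [region], {"chr1": genome}, spec.bias_k)
    model = ap.estimate_kmer(w_obs, w_exp)
    x = ap.correct_track(track, model, genome)
    inner = slice(1000, 29_000)
    cv_raw = track.counts[inner].std() / track.counts[inner].mean()
    cv_corrected = x[inner].std() / x[inner].mean()
    assert cv_corrected < cv_raw
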