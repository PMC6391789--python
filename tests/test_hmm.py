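"""Semi-supervised HMM training, Viterbi decoding and footprint extraction."""

from itertools import product

import numpy as np
import pytest

import atacprint as ap
from atacprint.fragments import GenomicRegion
from atacprint.hmm import (Footprint, FootprintHMM, TrainingWindow, extract_footprints,
                           make_training_windows, tag_count_score,
                           train_semi_supervised, viterbi_decode)
from atacprint.transform import DecompositionStrategy, ObservationMatrix


def _random_model(rng, n_states, n_dims):
    start = rng.dirichlet(np.ones(n_states))
    trans = rng.dirichlet(np.ones(n_states), n_states)
    means = rng.normal(0, 1.5, (n_states, n_dims))
    covs = np.array([np.eye(n_dims) * rng.uniform(0.5, 2.0) for _ in range(n_states)])
    return FootprintHMM(start, trans, means, covs, 0)


def _brute_force_path(model, obs):
    logb = model.log_emission(obs)
    t_len, s = logb.shape
    best, best_lp = None, -np.inf
    for p in product(range(s), repeat=t_len):
        lp = np.log(model.startprob[p[0]]) + logb[0, p[0]]
        for t in range(1, t_len):
            lp += np.log(model.transmat[p[t - 1], p[t]]) + logb[t, p[t]]
        if lp > best_lp:                       # strict: first (lowest-index) max kept
            best_lp, best = lp, p
    return np.array(best)


def test_viterbi_equals_exhaustive_enumeration():
    rng = np.random.default_rng(100)
    for _ in range(100):
        s = int(rng.integers(2, 4))
        t = int(rng.integers(2, 9))
        model = _random_model(rng, s, 2)
        obs = rng.normal(0, 1, (t, 2))
        np.testing.assert_array_equal(viterbi_decode(model, obs),
                                      _brute_force_path(model, obs))


def test_viterbi_tie_break_and_degenerate_models():
    # identical emissions + uniform transitions: lowest state index wins
    s, d = 3, 2
    model = FootprintHMM(np.full(s, 1 / s), np.full((s, s), 1 / s),
                         np.zeros((s, d)), np.array([np.eye(d)] * s), 0)
    path = viterbi_decode(model, np.zeros((6, d)))
    np.testing.assert_array_equal(path, 0)
    single = FootprintHMM(np.ones(1), np.ones((1, 1)), np.zeros((1, d)),
                          np.array([np.eye(d)]), 0)
    np.testing.assert_array_equal(viterbi_decode(single, np.zeros((5, d))), 0)
    with pytest.raises(ValueError):
        viterbi_decode(model, np.zeros((5, d + 1)))


def test_viterbi_agrees_with_hmmlearn(rng):
    """Independent cross-check against hmmlearn's Viterbi implementation."""
    from hmmlearn.hmm import GaussianHMM

    model = _random_model(rng, 3, 2)
    obs = rng.normal(0, 1, (50, 2))
    ref = GaussianHMM(n_components=3, covariance_type="full", init_params="")
    ref.startprob_ = model.startprob
    ref.transmat_ = model.transmat
    ref.means_ = model.means
    ref.covars_ = model.covars
    _, ref_path = ref.decode(obs)
    np.testing.assert_array_equal(viterbi_decode(model, obs), ref_path)


def _simulate_windows(rng, A, pi, means, covs, n_windows, t_len):
    windows = []
    s_count = len(pi)
    for _ in range(n_windows):
        states = np.empty(t_len, dtype=int)
        states[0] = rng.choice(s_count, p=pi)
        for t in range(1, t_len):
            states[t] = rng.choice(s_count, p=A[states[t - 1]])
        obs = np.array([rng.multivariate_normal(means[s], covs[s]) for s in states])
        windows.append(TrainingWindow(obs, states == 0))
    return windows


def test_training_recovers_known_three_state_generator():
    rng = np.random.default_rng(5)
    A = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.25, 0.7]])
    pi = np.array([0.5, 0.3, 0.2])
    means = np.array([[0.0, 0.0], [2.0, 1.0], [-1.0, 2.0]])
    covs = np.array([np.diag([0.3, 0.2]), [[0.4, 0.1], [0.1, 0.3]], np.diag([0.2, 0.4])])
    windows = _simulate_windows(rng, A, pi, means, covs, 50, 200)
    model = train_semi_supervised(windows, n_states=3, seed=0)
    from conftest import recovery_errors
    a_err, m_err = recovery_errors(model, A, means)
    assert a_err < 0.1
    assert m_err < 0.1


def test_training_objective_is_monotone():
    rng = np.random.default_rng(6)
    A = np.array([[0.9, 0.1], [0.2, 0.8]])
    windows = _simulate_windows(rng, A, np.array([0.6, 0.4]),
                                np.array([[0.0, 0.0], [3.0, 3.0]]),
                                np.array([np.eye(2) * 0.5] * 2), 10, 100)
    model = train_semi_supervised(windows, n_states=2, seed=0)
    lls = np.array(model.training_history)
    assert np.all(np.diff(lls) >= -1e-8 * np.maximum(1.0, np.abs(lls[:-1])))


def test_training_is_deterministic_and_separable_limit():
    rng = np.random.default_rng(7)
    # two well-separated clusters; labelled positions are cluster 0
    windows = []
    for _ in range(8):
        states = rng.integers(0, 2, 60)
        obs = np.where(states[:, None] == 0,
                       rng.normal(0, 0.1, (60, 2)),
                       rng.normal(5, 0.1, (60, 2)))
        windows.append(TrainingWindow(obs, states == 0))
    m1 = train_semi_supervised(windows, n_states=2, seed=3)
    m2 = train_semi_supervised(windows, n_states=2, seed=3)
    np.testing.assert_array_equal(m1.transmat, m2.transmat)
    np.testing.assert_array_equal(m1.means, m2.means)
    path = viterbi_decode(m1, windows[0].observations)
    truth = windows[0].labels
    assert np.mean((path == 0) == truth) > 0.95


def test_make_training_windows_geometry():
    region = GenomicRegion("chr1", 0, 5000)
    strategy = DecompositionStrategy("Nfr", False)
    obs = ObservationMatrix(region, strategy, np.zeros((5000, 2)))
    mpbs = [(2495, 2506), (4000, 4011), (100, 111)]
    chip = [(2400, 2600), (90, 200)]          # supports sites 1 and 3
    windows = make_training_windows(chip, mpbs, obs, flank=500)
    # site at 100 is supported but its window would leave the region
    assert len(windows) == 1
    w = windows[0]
    assert w.labels.sum() == 11
    assert w.observations.shape == (1001, 2)
    center = 1001 // 2
    assert w.labels[center - 5:center + 6].all()
    with pytest.raises(ValueError):
        make_training_windows([(9000, 9100)], mpbs, obs)


def test_extract_footprints_runs_and_filters():
    region = GenomicRegion("chr1", 1000, 1100)
    path = np.ones(100, dtype=int)
    path[10:22] = 0                    # 12-run: kept
    path[40:43] = 0                    # 3-run: below min length
    path[60:80] = 0                    # 20-run: kept
    fps = extract_footprints(path, region, footprint_state=0, min_len=5, max_len=50)
    assert [(f.start, f.end) for f in fps] == [(1010, 1022), (1060, 1080)]
    fps2 = extract_footprints(path, region, footprint_state=0, min_len=5, max_len=15)
    assert [(f.start, f.end) for f in fps2] == [(1010, 1022)]


def test_tag_count_score_arithmetic_and_monotonicity():
    region = GenomicRegion("chr1", 0, 100)
    signal = np.arange(100, dtype=float)
    fp = Footprint("chr1", 10, 20)
    assert tag_count_score(fp, np.zeros(100), region) == 0.0
    assert tag_count_score(fp, signal, region) == pytest.approx(sum(range(10, 20)))
    with_motif = tag_count_score(fp, signal, region, mpbs=(5, 25))
    assert with_motif == pytest.approx(sum(range(5, 25)))
    assert with_motif >= tag_count_score(fp, signal, region)


def test_model_json_round_trip(tmp_path, rng):
    model = _random_model(rng, 3, 2)
    path = str(tmp_path / "model.json")
    model.to_json(path)
    back = FootprintHMM.from_json(path)
    np.testing.assert_allclose(back.transmat, model.transmat)
    np.testing.assert_allclose(back.covars, model.covars)
    assert back.footprint_state == model.footprint_state


def test_model_transfers_between_synthetic_tfs(clean_run):
    """A model trained on one TF decodes another TF's library without retraining."""
    spec = ap.FixtureSpec(genome_length=40_000, n_sites=8, n_fragments=80_000,
                          protection=0.95, bias_k=6, bias_strength=0.4, seed=33,
                          motif="CCATTAGGTCC")
    fx = ap.simulate_fixture(spec)
    config = clean_run["config"]
    genome = {"chr1": fx.genome}
    bias_model = ap.estimate_bias(fx.fragments, fx.peaks, genome, config)
    obs = ap.observations_for_region(fx.fragments, fx.region, fx.genome,
                                     bias_model, config)
    fps = ap.detect_footprints(clean_run["model"], obs, fx.peaks, config)
    from conftest import footprint_recall
    assert footprint_recall(fps, fx.footprints) >= 0.5
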