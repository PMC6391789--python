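"""Shared fixtures: synthetic libraries and full pipeline runs.

The heavier end-to-end runs are session-scoped so several tests can
reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import atacprint as ap


def footprint_recall(footprints, truth, min_overlap: float = 0.5) -> float:
    """Fraction of planted sites recovered at reciprocal overlap >= min_overlap."""
    hit = 0
    for (s, e) in truth:
        for f in footprints:
            ov = min(e, f.end) - max(s, f.start)
            if ov > 0 and ov >= min_overlap * (e - s) and ov >= min_overlap * (f.end - f.start):
                hit += 1
                break
    return hit / len(truth)


def run_pipeline(fixture, bias_method: str = "kmer", k: int = 6, n_states: int = 5,
                 seed: int = 0):
    """Bias estimation, observation assembly, training and decoding on a fixture."""
    config = ap.RunConfig(bias_method=bias_method, k=k, n_states=n_states,
                          seed=seed, strategy="All")
    genome = {"chr1": fixture.genome}
    bias_model = ap.estimate_bias(fixture.fragments, fixture.peaks, genome, config)
    obs = ap.observations_for_region(fixture.fragments, fixture.region,
                                     fixture.genome, bias_model, config)
    chip = [(c - 100, c + 100)
            for c in ap.simulate_chipseq(fixture.footprints, 10, 1)]
    model = ap.train_model(obs, chip, fixture.footprints, config)
    footprints = ap.detect_footprints(model, obs, fixture.peaks, config)
    return {"config": config, "bias_model": bias_model, "obs": obs,
            "model": model, "footprints": footprints,
            "recall": footprint_recall(footprints, fixture.footprints)}


@pytest.fixture(scope="session")
def clean_fixture():
    """Deeply sequenced library with mild bias and strongly protected sites."""
    spec = ap.FixtureSpec(genome_length=100_000, n_sites=20, n_fragments=200_000,
                          protection=0.95, bias_k=6, bias_strength=0.4, seed=11,
                          motif="GTGACTCATGC")
    return ap.simulate_fixture(spec)


@pytest.fixture(scope="session")
def clean_run(clean_fixture):
    return run_pipeline(clean_fixture, bias_method="kmer")


@pytest.fixture(scope="session")
def confounded_fixture():
    """Library with a strongly dispersed enzyme sequence preference.

    Per-position log-bias SD 0.9 over 6-bp words makes the raw track a
    sequence-driven comb of hotspots and deep false dips that drowns
    the occupancy footprints; only the bias-corrected signal exposes
    them.
    """
    spec = ap.FixtureSpec(genome_length=100_000, n_sites=20, n_fragments=200_000,
                          protection=0.9, bias_k=6, bias_strength=0.9,
                          seed=21, motif="GTGACTCATGC")
    return ap.simulate_fixture(spec)


@pytest.fixture(scope="session")
def small_fixture():
    """Small, fast library for I/O and CLI tests."""
    spec = ap.FixtureSpec(genome_length=30_000, n_sites=6, n_fragments=40_000,
                          protection=0.95, bias_k=4, bias_strength=0.3, seed=7,
                          motif="GTGACTCATGC", peak_halfwidth=600)
    return ap.simulate_fixture(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def recovery_errors(model, true_transmat, true_means):
    """L-inf errors of recovered parameters, minimised over relabellings
    of the free (non-FOOTPRINT) states."""
    from itertools import permutations

    s = len(true_means)
    free = [i for i in range(s) if i != model.footprint_state]
    best = (np.inf, np.inf)
    for perm_free in permutations(free):
        perm = list(range(s))
        for src, dst in zip(free, perm_free):
            perm[src] = dst
        a_err = np.abs(model.transmat[np.ix_(perm, perm)] - true_transmat).max()
        m_err = np.abs(model.means[perm] - true_means).max()
        if a_err + m_err < sum(best):
            best = (a_err, m_err)
    return best
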