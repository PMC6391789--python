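"""Estimate Tn5 cleavage bias from a synthetic library and correct the signal.

Builds a footprint-free open-chromatin library whose cut sites follow a
planted sequence bias, estimates the bias back from the reads with the
k-mer and SLIM models, and shows that correction flattens the track.
"""

import numpy as np
from scipy.stats import spearmanr

import atacprint as ap
from atacprint.bias import collect_words

spec = ap.FixtureSpec(genome_length=60_000, n_sites=0, n_fragments=150_000,
                      protection=0.0, bias_k=4, bias_strength=0.6, seed=13)
genome = ap.simulate_genome(spec.genome_length, gc=0.5, seed=spec.seed)
fx = ap.simulate_library(genome, spec)
print(f"library: {len(fx.fragments):,} fragments over {len(genome):,} bp")

track = ap.build_signal(fx.fragments, fx.region, "+")
w_obs, w_exp = collect_words([track], [fx.region], {"chr1": genome}, spec.bias_k)
kmer = ap.estimate_kmer(w_obs, w_exp)
slim = ap.estimate_slim(w_obs, w_exp, d=3, seed=0)

for name, model in [("k-mer", kmer), ("SLIM", slim)]:
    rho = spearmanr(model.bias_table(), fx.bias_table).statistic
    print(f"{name:6s} bias vs planted bias: Spearman rho = {rho:.3f}")

x = ap.correct_track(track, kmer, genome)
inner = slice(1000, 59_000)
cv_raw = track.counts[inner].std() / track.counts[inner].mean()
cv_corr = x[inner].std() / x[inner].mean()
print(f"coefficient of variation: raw {cv_raw:.3f} -> corrected {cv_corr:.3f}")
print("A rho near 1 means the estimator recovered the enzyme preference;")
print("the lower corrected CV shows sequence-driven structure was removed.")
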