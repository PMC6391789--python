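# atacprint

Transcription-factor footprinting for ATAC-seq (and DNase-seq), built
around three ideas: correct the cleavage enzyme's sequence bias with a
position-dependency model, decompose cleavage signals by strand and by
the nucleosome content of the sequenced fragment, and decode the
resulting multichannel signal with a semi-supervised hidden Markov
model. The package also scores differential TF activity between two
conditions and ships the evaluation harness (motif matching at a fixed
FPR, ChIP-summit labelling, partial AUC/AUPR, combined ranking score).

It is written for computational-genomics researchers who work from
Python: the importable API is the primary interface (see `examples/`),
with a thin `atacprint` command-line wrapper for file-to-file runs.

## The model

**Cleavage counting.** Paired-end alignments are reduced to cleavage
events: the centre of the Tn5 transposition event sits at the fifth
base of the read, so the 5' coordinate is shifted by +4 (forward) or
−5 (reverse); DNase-seq cuts are counted at the 5' base itself.
Strand-specific count vectors y⁺, y⁻ are optionally restricted to a
fragment-size class — nucleosome-free (0, 145], mono-nucleosome
(145, 307], or more — with boundaries re-estimated per library from the
local minima of the fragment-size distribution.

**Bias correction.** The bias of a k-bp word w is
b(w) = p(w | obs) / p(w | exp), where *obs* is the distribution of
words centred on cut sites and *exp* the distribution over all peak
positions. p(w) can be a full multinomial over 4^k words (k-mer), a
per-position independent model (PWM), or a sparse local inhomogeneous
mixture (SLIM): per position j a mixture of the marginal p(w_j) and
pairwise conditionals p(w_j | w_l) for l < j within distance d,

    p(w) = Π_j [ p(C_j=0) p(w_j) + p(C_j=1) Σ_l p(R_lj) p(w_j|w_l) ],

with mixture priors learned discriminatively against uniform random
words. The PWM is the special case p(C_j=0) = 1. The corrected signal
is x_i = (y_i + 1) / (ŷ_i · b̂(w[i]) + 1) with ŷ the 50-bp windowed mean
count and b̂ the window-normalised bias.

**Footprint decoding.** Corrected tracks are normalised within bins,
squashed with a logistic, and paired with Savitzky–Golay slope
channels (2–12 dimensions depending on the decomposition strategy).
A fully connected S-state Gaussian HMM with full covariances is
trained semi-supervised: windows of ±500 bp around ChIP-supported
motif sites carry FOOTPRINT labels over the motif; that state's
emission is fit on labelled positions and held fixed while Baum–Welch
re-estimates the rest. Viterbi paths inside peaks yield footprints
(maximal FOOTPRINT runs of 5–50 bp), ranked by tag count.

**Differential activity.** Per TF, the activity score ACT averages a
per-site combination of protection (flanking minus footprint signal)
and openness (total signal within ±100 bp). Conditions are compared
as ΔACT = ACT₂/ω₂ − ACT₁/ω₁ with median-of-ratios size factors ω, a
Welch t-test on per-site contributions, Benjamini–Hochberg correction
across TFs, and an expression |log2FC| > 0.5 filter.

## Worked example

`examples/02_footprint_calling.py` simulates a 50 kb library with ten
protected motif sites and runs the full pipeline:

```
planted 10 bound motif sites in 10 peaks
called 10 footprints; 10/10 planted sites recovered at >= 50% reciprocal overlap
```

Every planted site is recovered as a maximal FOOTPRINT-state run
overlapping the protected interval. `examples/01_bias_correction.py`
shows the bias estimators recovering a planted enzyme preference from
reads alone:

```
k-mer  bias vs planted bias: Spearman rho = 0.997
SLIM   bias vs planted bias: Spearman rho = 0.999
coefficient of variation: raw 0.961 -> corrected 0.645
```

and `examples/04_differential_activity.py` flags exactly the TF whose
sites gain occupancy in condition 2 (ΔACT = 866, adjusted
p = 1.1e-85) while leaving the unchanged TFs unflagged. The other
example covers motif matching at FPR 10⁻⁴ (182 matches on a random
1 Mb genome, expected ≈ 200).

The same workflows are available from the shell:

```sh
atacprint footprint library.bam peaks.bed genome.fa -o run/ \
    --train-chip chip.bed --motif motifs.jaspar --bias-method slim -k 8
atacprint evaluate run/footprints.bed mpbs.bed summits.bed -o metrics.tsv
```

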