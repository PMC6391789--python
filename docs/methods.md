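# Methods

## Cleavage events and fragment classes

A properly paired fragment contributes two cleavage events, one per
end. The 5' coordinate of the forward mate is the fragment start; the
5' coordinate of the reverse mate is the rightmost aligned base. For
ATAC-seq the event is placed at the centre of the Tn5 transposition
site — +4 from the forward 5' end, −5 from the reverse 5' end — and
the shift pair is configurable (`shifts=(4, -5)`), since protocol
variants differ; DNase-seq uses the 5' base unshifted. Events shifted
off the chromosome are dropped and counted in the log. Coordinates are
0-based half-open everywhere; BED output follows the same convention.

Fragment-size classes are half-open on the left and closed on the
right: Nfr = (0, 145], 1N = (145, 307], +1N = (145, ∞), +2N =
(307, ∞). The defaults correspond to a standard library; per-library
boundaries are re-estimated as the local minima of the fragment-size
histogram after an 11-bp moving-average smoothing, with a peak
prominence floor of 1% of the histogram maximum. Fewer than three
detectable modes triggers a fall-back to the defaults with a warning.

## Bias models

All three estimators are fit on two word multisets: W_obs (the k-word
centred on every cleavage event inside a peak, with event
multiplicity; reverse-strand events contribute the reverse complement
of the forward-genome word) and W_exp (the word at every peak
position; the whole genome in naked-DNA mode). The word at position i
is G[i − ⌊k/2⌋ .. i + ⌈k/2⌉ − 1]; words crossing a chromosome end or
containing a non-ACGT base are skipped. Default k is 8 for ATAC-seq
and 6 for DNase-seq comparisons.

A pseudocount of 1 is added to every word count (k-mer), per-position
base count (PWM), and conditional cell (SLIM) before normalising, so
unseen background words cannot produce divisions by zero at k = 8–12.

**SLIM.** Marginals and pairwise conditionals (l < j, j − l ≤ d,
d ≤ 5) are pseudocounted corpus frequencies. The mixture priors
p(C_j), p(R_lj) are learned by maximising a supervised posterior: the
corpus words (weighted by multiplicity) are discriminated from an
equal number of uniform random words under a logistic link on
log p_SLIM(w) − log p_uniform(w). The priors are parameterised on the
logit/softmax scale and optimised with L-BFGS (analytic gradients,
at most 500 iterations, objective tolerance 1e-6). A Beta(1, 10)
prior on each p(C_j = 1) makes the mixture sparse: for a
dependency-free corpus the discriminative objective is flat in the
mixing priors, and without the prior they would stay at their
initialisation instead of collapsing to the PWM special case. The
prior costs a few nats — negligible against a genuine dependency,
whose evidence grows with corpus size. Position 1 has no admissible
conditioning position, so p(C_1 = 1) = 0 structurally.

**Correction.** x_i = (y_i + 1) / (ŷ_i · b̂(w[i]) + 1), with
ŷ_i the mean count over [i − 25, i + 24] and
b̂(w[i]) = b(w[i]) / Σ_{j ∈ window} b(w[j]). This is the literal form;
`expected_counts_mode="sum"` substitutes the windowed sum for the
mean, since the two readings differ only by the constant factor 50
absorbed into b̂'s normalisation in one direction but not the other.
Windows truncated at chromosome ends renormalise over the positions
available. Positions with an undeterminable word take neutral bias 1.
The corrected signal is invariant to rescaling the whole bias table
(b̂ is scale-free), and y ≡ 0 gives x ≡ 1.

A property worth knowing: at positions where the local expected count
ŷ·b̂ is small (cold words), x is pinned near 1 regardless of
occupancy — the information that a protected site is *not* being cut
lives at positions whose expected cut rate is high.

## Signal transform

Per channel the pipeline order is fixed: bias-correct →
within-signal normalisation (divide by the mean of non-zero values in
the enclosing bin; all-zero bins pass through) → logistic squashing
for the `norm` channel, and a Savitzky–Golay first derivative
(window 9, order 2) of the *pre-logistic* signal for the `slope`
channel, so slopes keep magnitude information. Defaults: bin size
10,000 bp, plain logistic 1/(1 + e^{−v}). Channels are ordered
deterministically (class, then strand, then norm/slope), giving 2–12
dimensions depending on the decomposition strategy.

## Semi-supervised HMM

Fully connected S states (default 9 for production-scale signals; the
test and example configurations use 4–5 states, which is sufficient
for the synthetic libraries' simpler background structure), Gaussian
emissions with full covariance. The FOOTPRINT state's emission is
estimated once from the labelled positions of the training windows
and held fixed; labels are enforced during the E-step by masking
non-FOOTPRINT states at labelled positions, which makes each
iteration an exact EM step on the joint likelihood of observations
and labels. Transitions, the initial distribution, and the other
S − 1 emissions are re-estimated each iteration; transition rows
touching FOOTPRINT stay free, which is the minimal reading of
supervising only that state's emission.

Numerical choices:

* Initialisation is an M-step over random posteriors (labels
  clamped), drawn from a sparse Dirichlet (α = 0.1) so the free
  states start from near-disjoint random partitions — with uniform
  posteriors every state would initialise at the global mean and EM
  frequently stalls in the symmetric optimum where two states share
  one emission.
* Covariance M-steps use an inverse-Wishart-style ridge
  (scale 1e-4·I, strength 1). This keeps covariances positive
  definite when a state collapses onto near-constant stretches (for
  example signal outside peaks) while preserving EM monotonicity,
  unlike post-hoc ridge injection, which oscillates.
* Convergence: log-likelihood gain below 1e-6 nats per observation,
  or 100 iterations. The threshold is per-observation rather than
  relative to the total likelihood — a relative threshold grows with
  the corpus and can stop EM while it is still traversing the
  symmetric saddle.
* Viterbi runs in log space; ties break toward the lower state index.
* EM identifies the free states only up to relabelling; comparisons
  against a known generator are made over free-state permutations.

Decoding is restricted to peak intervals; maximal FOOTPRINT runs of
5–50 bp (configurable) become footprint calls, scored by the tag
count (sum of corrected signal over footprint ∪ motif interval).

## Motif matching

PFMs (JASPAR flat files via Bio.motifs) become bit-score PWMs with a
background-proportional pseudocount of 0.8 and a uniform background.
The FPR cutoff is computed by dynamic programming over the score
distribution discretised to 0.01 bits, returning the smallest
*achievable* discretised score whose background tail probability is
at most the FPR (clamped to the maximum achievable score when the FPR
is below the probability of the single best word). Exact scan scores
can differ from the grid by up to half a step per position; words
within that band of the cutoff may fall on either side. Both strands
are scanned; reverse-strand matches are scored on the reverse
complement and reported in forward coordinates. ChIP labelling takes
the motif-interval centre and an inclusive 100 bp summit radius.

## Evaluation

Each labelled motif site receives the tag count of its best
overlapping footprint (0 without one). ROC areas are trapezoidal,
restricted to FPR ≤ {1, 0.1, 0.01} and normalised by the bound;
precision-recall areas use step interpolation restricted to recall ≤
{1, 0.1, 0.01}, likewise normalised. Methods are compared by
Σ −ln(r/(N+1)) over the six measures (natural log; ties get average
ranks).

## Differential activity

The per-site contribution is
½·Σ_left-flank x + ½·Σ_right-flank x − Σ_footprint x (protection,
flanks of e + 1 positions for motif width e) plus Σ_{±100 bp} x
(openness); ACT is the mean over a TF's footprint-supported sites
(union support across the two conditions, ≥ 1 bp overlap). Note that
the footprint-interior sum cancels exactly between the protection
(−1) and openness (+1) terms, so the statistic responds to flanking
accessibility — which is also where occupancy manifests in real
libraries — and not to interior depth in isolation.

Size factors are DESeq-style median-of-ratios over per-TF ACT values
(TFs positive in both conditions); the significance test is a Welch
t-test on per-site contributions normalised by the size factors, BH
corrected across TFs, and a TF is flagged when the adjusted p < 0.05
and its externally supplied expression |log2FC| > 0.5 (TFs missing
from the expression table are retained, marked
`expression-unfiltered`, and flagged on the p-value alone).

## Synthetic libraries

The generator emulates what the pipeline consumes: an i.i.d. genome
with planted motif occurrences at peak centres; a planted bias table
whose log is additive over word positions (SD 0.8 per position by
default) with an optional pairwise term; a tri-modal fragment-length
mixture (means 60/200/400 bp, SDs 20/30/40, weights 0.6/0.3/0.1);
and footprint protection that thins cleavage events inside bound
sites. The left cut is drawn from the per-position weight
(bias × openness × protection, with reverse-strand cuts following the
reverse-complement word bias), the length from the mixture, and the
implied right cut accepted by rejection against the same weights —
so the nucleosome-free type-I strand geometry (forward cuts left of a
bound site, reverse cuts right) emerges from fragment geometry rather
than being painted on. A `motif_bias_boost` option multiplies the
bias of the motif's own k-words (both strands), emulating an enzyme
whose preference overlaps the motif (boost = 1/(1 − protection)
removes the mean depletion at bound sites entirely).

The bias-confounded condition used in the tests raises the
per-position log-bias SD to 0.9: the raw track becomes a
sequence-driven comb of hotspots and deep false dips in which the
occupancy footprints are no longer identifiable, while the corrected
track recovers them. This is a sharper confound than the motif-boost
one — a supervised HMM can learn to exploit residual second-moment
structure at boost-compensated sites, but it cannot separate
sequence-driven dips from occupancy-driven ones without the bias
model.

What the generator does not emulate: PCR duplication, mappability,
chrM contamination, GC-dependent amplification, realistic peak
calling, or TF-specific footprint shapes. Passing tests therefore
demonstrate the correctness and internal consistency of the
algorithms under the stated generative model, not performance on real
libraries.

The boundary-recovery checks use a tri-modal mixture with means
60/200/400, SDs 45/40/50 and weights 0.65/0.25/0.10, whose smoothed
histogram provably has local minima near (145, 307) (verified by
exhaustive scan); the generator's default mixture has its minima
nearer (118, 277).

## Problem sizes

Tests and the acceptance script run at deliberately moderate scale,
chosen to keep the full suite in the minutes range on one CPU while
leaving comfortable statistical margins: 100 kb genomes with 20
peaks and 200,000 fragments for end-to-end footprinting; 200,000
events over 4^8 words for bias-stability comparisons; 50 windows of
200 positions for HMM parameter recovery; 1 Mb for genome-wide motif
match rates; 50 sites per TF for differential activity.

## Known limitations

* The SLIM optimiser fits mixing priors only; marginals and
  conditionals stay at corpus frequencies (no joint refinement).
* Training windows must share one length; sites whose ±500 bp window
  leaves the observation region are dropped from training.
* Bias estimation at k = 8 needs a background of at least ~10^5 peak
  positions before exp-side noise dominates (use smaller k for small
  fixtures).
* The non-strand-specific pipeline corrects the summed track using
  forward-strand words only.
* Decoding assumes the model's channel layout matches the observation
  matrix; models do not transfer across decomposition strategies.
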