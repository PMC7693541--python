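# Methods

## Counting model

All statistics are built on dense occurrence vectors over the 4^k words of
length k in lexicographic A<C<G<T order. Because an assembled contig may
come from either strand, every valid window of the sequence *and* of its
reverse complement is counted; palindromic words receive contributions from
both strands like any other word, and no canonicalization into k-mer
equivalence classes is performed, since all formulas index the full 4^k
vocabulary. Windows containing an N (any non-ACGT input character is mapped
to N on ingest) are skipped whole rather than fractionally distributed. The
`effective_positions` of a vector — the number of windows actually counted,
summed over strands and sequences — serves as the multi-sequence,
two-strand generalization of the single-sequence window count L − k + 1
wherever a length scale is required. Dense arrays cap k at 12; the
classifier itself accepts 3 ≤ k ≤ 12 and defaults to k = 10.

## Markov backgrounds

Two null models produce expected counts E(X_w):

**Order-r product form** (used by d2\*, d2S). Transition probabilities are
estimated from the same sequence set's (r+1)-mer counts. Rows are
normalized by the (r+1)-mer row sum rather than the raw r-mer count: the
two denominators differ only where a context occurs at a sequence end, and
row normalization is what makes each transition row sum to exactly 1 and
Σ_w E(X_w) equal the effective window count. The leading factor is the
r-mer relative frequency (defined as 1 for r = 0, the empty context).
Contexts never observed — possible on 500 bp contigs at higher orders —
fall back to an additively smoothed row (+1 per extended word, +4 on the
denominator, i.e. uniform when nothing was seen); observed contexts always
use raw ratios so the count-ratio definitions are preserved exactly.

**(k−2)-order count-ratio form** (used by CVTree, Teeling, EuF):
E(X_w) = X(w_1..w_{k−1}) · X(w_2..w_k) / X(w_2..w_{k−1}), with variance
var(X_w) = E(X_w)(X(inner) − X(prefix))(X(inner) − X(suffix)) / X(inner)²
for the Teeling z-scores. A zero inner count zeroes that word's
expectation, ratio and variance; such words contribute nothing to any sum.

Each side of a comparison carries its own background: a contig's centered
counts use a model fitted on the contig alone (even at 500 bp), the pooled
training side a model fitted on the pooled class counts. CVTree uses the
ratio form X/E by default; the composition-vector variant (X−E)/E is
available behind a flag.

## Classification rule

Training pools the double-strand counts of all labeled genomes per class at
every word length any measure needs (k, k−1, k−2, r, r+1). A contig is
scored by D_temperate / D_lytic; a ratio below 1 calls it temperate, and an
exact tie is called lytic (the majority class in typical phage collections;
configurable). The Teeling similarity is converted to the same convention
by shifting both similarities by 1 − min(S_t, S_l, 0) and taking
S_lytic / S_temperate, so smaller-than-1 still means temperate-like. The
Euclidean distance is the printed squared form; since the classifier
thresholds a ratio at 1 and ROC only uses ranks, the rooted form (exposed
via a flag) produces identical calls and AUROCs.

Note that d2S is *not* invariant to rescaling one side's counts: its
per-word weight √(X̃² + Ỹ²) mixes the contig's and the pool's scales. d2,
d2\*, CVTree and the frequency measures are scale-invariant; tests assert
invariance only for those.

## Evaluation protocol

Test genomes (always disjoint from training genomes by id) are split into
non-overlapping fragments of fixed length — 500, 1000, 3000, 5000, 10000 bp
by default — discarding the trailing remainder; classes are balanced by
sampling min(|pos|, |neg|) fragments without replacement. AUROC is the
Mann–Whitney rank statistic with mid-ranks for ties (lower ratio = more
temperate-like = positive); hard calls at the ratio-1 threshold give TPR1
(temperate), TPR2 (lytic) and overall accuracy. Every grid cell derives its
own 31-bit seed from a CRC of the global seed and the cell coordinates, so
cells are independently reproducible. The mutation experiment subsamples
fragments per replicate, injects independent per-base substitutions
(substitutions only — the dominant Illumina error mode; a substituted base
becomes one of the three others uniformly; N is never mutated) at rates
0.001, 0.005, 0.01, and compares each rate's AUROC sample against the
clean baseline with Welch's unequal-variance, unpaired t-test (the safer
default when variances differ across rates). Subsampling seeds are shared
across rates, so rate effects are paired by construction even though the
test is unpaired.

## Synthetic genome generator

Labeled corpora are sampled from parameterized Markov sources: the initial
context is drawn from the chain's stationary distribution (power iteration
to an L1 tolerance of 1e-10, error after 10,000 sweeps for non-ergodic
matrices), so fragments are statistically homogeneous along the genome. The
default base source is a mildly AT-rich order-1 chain in the compositional
range of phage genomes; the "divergent" preset moves ε = 0.1 of probability
mass from A/T to C/G in the C- and G-context rows of one class, and the
"null" preset uses the identical law for both classes, differing only in
seed.

Study scale, chosen once: 30 training and 15 testing genomes of 50 kb per
class for divergent experiments (null calibration uses 100 × 15 kb test
genomes so that 500 balanced 3 kb fragments per class come from many
near-independent genomes); grid cells cap at 150–500 balanced fragments per
class; the mutation experiment runs 10 replicates of 100 fragments per
class at 1 kb. The 1 kb choice is deliberate: at 5 kb the divergent-source
AUROC saturates near 1.0 and a 1%/bp substitution rate produces no
measurable drop, while at 1 kb the classifier is strong (~0.8–0.9 AUROC)
but unsaturated, so rate effects are visible. The module default for
replicates is 30.

### What the generator does and does not emulate

An order-1 source reproduces realistic base and dinucleotide composition
and gives full experimental control over class divergence, but its class
signal is *entirely* dinucleotide-determined: two order-1 chains with the
same dinucleotide statistics are the same chain. Two consequences, verified
empirically and worth understanding before interpreting test results:

1. **Background order must stay below the signal order.** Scoring d2S/d2\*
   with an order-1 background on order-1-divergent classes removes exactly
   the signal the classes differ by — AUROC collapses to ~0.5. Signal-
   recovery experiments therefore use an order-0 background (the order is a
   free protocol knob; real analyses sweep 0–3). On real phage genomes,
   which carry structure far beyond any fitted background order, higher
   orders help rather than hurt.
2. **No k-monotonicity.** Because a k=3 vector already captures all of an
   order-1 signal, longer words add dimensions that carry noise but no new
   information: d2S AUROC *decreases* slightly but consistently from k=3 to
   k=6 on this generator (for d2\*, whose per-word 1/√E weighting
   standardizes the added words, the difference is indistinguishable from
   zero). The empirical finding that AUROC grows with k on real phage
   contigs reflects genuine high-order genomic structure that no order-1
   generator can emulate; the corresponding check in the acceptance suite
   documents this limit and fails by design on synthetic data.

Passing tests on this generator therefore demonstrate correctness of the
statistics and calibration of the protocol, not field performance on real
viromes.

## Numerical choices

- Frequencies are undefined (an error, not NaN) on empty count vectors;
  measures raise on degenerate inputs (zero vectors, no informative words)
  with the contig id attached, and batch prediction collects such failures
  in a skipped-list instead of aborting.
- Words degenerate on both sides contribute 0 to every sum, never NaN.
- A distance ratio with D_lytic = 0 is +inf (called lytic) unless
  D_temperate is also 0, which scores 1 and follows the tie rule.
- Models serialize to a single .npz archive (count arrays plus a JSON
  metadata header with k, order, class sizes and tool version); reloading
  reproduces scores bit-for-bit.
- All randomness flows through explicit integer seeds; derived seeds stay
  below 2^31.

## Known limitations

- Dense counting only (k ≤ 12); no streaming or disk-backed mode.
- Two-class lifestyles only; no probability calibration of the ratio score.
- The synthetic generator produces homogeneous Markov sequences — no genome
  mosaicism, repeats, or compositional heterogeneity along the genome.
- Training pools weight genomes by length (counts are pooled raw), matching
  the merged-training-set design rather than per-genome averaging.
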