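# Methods

## Signatures and strand handling

A sample's signature at tuple size `k` is the integer vector of counts of
all `4^k` words over its reads. Because shotgun reads are strand-agnostic,
every read is counted together with its reverse complement; internally this
is done in a single pass by adding the forward counts to themselves under
the reverse-complement index permutation, which makes the strand symmetry
`counts[w] = counts[revcomp(w)]` exact by construction. Words are indexed
lexicographically (A<C<G<T, leftmost base most significant) and the index
convention is recorded in every signature file header so dialect mismatches
fail loudly. Windows containing N are skipped entirely on both strands —
the simplest defensible rule; fractional attribution of ambiguous windows
would change counts by amounts far below the sampling noise of any
realistic read set. "Complement" is implemented as *reverse* complement
(the biological convention for reading the opposite strand); for the
strand-symmetrised count vector the literal unreversed complement would
give the same vector, so no downstream quantity depends on this choice.

Tuple sizes are capped at 12 by default (a `4^12 ≈ 17M`-entry vector per
sample); the practically useful range is 2–10, and the cap can be raised
explicitly.

## Background models and centering

Each sample is centered against a Markov chain of order `r ∈ {0..3}` fitted
to *that sample's own* strand-augmented tuple counts: the per-sample
notation `p_w^X`, `p_w^Y` in the centered statistics implies per-sample
backgrounds, and fitting on strand-augmented counts makes the expectations
inherit the signature's reverse-complement symmetry. The initial
distribution is the `r`-tuple frequency vector; each transition row is the
`(r+1)`-tuple counts divided by their context total. Word probabilities are
evaluated for all `4^k` words at once by dynamic programming on the word
index (the last `r` bases of a word are its low base-4 digits), so the cost
is `O(4^k)` independent of read volume.

The chain factorisation needs `k ≥ r+1`; requesting less raises a typed
`NotApplicableError` that the matrix layer renders as an NA matrix, and the
CVTree expectation analogously needs `k ≥ 3`. NA handling is explicit
everywhere — an invalid combination is bookkept, never silently zeroed.

**Zero-probability floor.** A word with positive observed count can receive
zero model probability when its context was never observed (possible after
aggressive subsampling). Such probabilities are floored at `1/(10·n)`,
`n` the sample's strand-augmented base total, with a logged warning. The
floor only exists to keep `X̃²/E` and `F ln(F/P)` finite; any value well
below `1/n` leaves all reported quantities unchanged to the precision shown
anywhere. Words with zero count and zero probability contribute nothing and
are skipped. Whether the original tools floored or pseudocounted is
unknowable from their descriptions; the floor is this package's choice.

## The measures

All cosine-type statistics are reported as `(1 − cos)/2`: 0 for identical
signatures, 0.5 for orthogonal nonnegative vectors (the maximum for raw
counts, hence `d2 ∈ [0, 0.5]`), 1 for anti-parallel centered vectors (hence
`d2s, d2star, hao ∈ [0, 1]`, the bounds following from Cauchy–Schwarz).
Terms of the form 0/0 (a word centered to zero in both samples, or with
zero expectation in both) are skipped — they contribute nothing to either
the numerator or the norms. Summations run in fixed word-index order over
float64 accumulators, so results are bit-reproducible across runs; final
values are clipped to their analytic range to absorb last-ulp rounding.

`ma`/`eu`/`ch` operate on relative frequencies, not raw counts: library
sizes differ by orders of magnitude between real samples and raw-count
L-distances would predominantly measure sequencing depth.

**S2 pairing.** The relative-entropy measure pairs each sample's observed
frequencies with an order-`r` model. Whose model is genuinely ambiguous in
the published description; the default here is the *cross* form (X's
frequencies against Y's model and vice versa), which makes S2 respond to
differences between the samples rather than to each sample's internal
departure from its own background — the self form is identically the sum
of two within-sample goodness-of-fit terms and is near-blind to the
partner. The self form remains available via `s2(..., form="self")`.
With natural log and `0·ln(0/p) := 0`, Gibbs' inequality gives S2 ≥ 0
whenever the probability vectors sum to at most 1.

## Evaluation

**UPGMA** is implemented directly rather than through a generic linkage
routine because two contract details matter downstream: the merge height is
*distance/2* (leaves sit at height 0, so trees are exactly ultrametric),
and ties are broken deterministically by the lexicographically smallest
pair of cluster representative labels, making output invariant to input
order. scipy's average linkage serves as an independent cross-check in the
tests (identical merge-height multisets on tie-free matrices).

**Symmetric difference** counts the nontrivial rooted clusters (each
internal node denoted by its clustered leaf set; singletons and the full
set excluded) present in exactly one tree — branch lengths ignored. A
splits mode on unrooted bipartitions is provided for compatibility with
Robinson–Foulds-style tools. Note the score between a multifurcating
reference and a fully resolved binary tree has a floor: a binary tree on
`L` leaves carries `L−2` nontrivial clusters, so against a star of `G`
groups the best attainable score is `(L−2) − G`, reached exactly when every
planted group appears in the tree. The robustness protocols therefore test
for attainment of this floor, which is the precise meaning of "perfect
recovery" for that comparison.

**PCoA** is classical scaling: double-center `−½D²`, eigendecompose,
scale eigenvectors of positive eigenvalues by `√λ`. It is implemented
directly (and cross-checked against scikit-bio's implementation in the
tests) so that two reporting contracts are pinned: negative eigenvalues of
non-Euclidean matrices are reported, never corrected, and the first-axis
goodness of fit is `λ₁ / Σ max(λᵢ, 0)` by default with the
`Σ|λᵢ|` denominator behind a flag. Gradient reports use the *absolute*
Spearman correlation of axis 1 with the covariate because a principal
axis has arbitrary orientation. Spearman itself is scipy's, with mid-ranks
for ties; note that with `m` replicates per gradient level the covariate
ranks are tied, so even a perfect ordering yields |SRCC| < 1 (0.9759 for
2 replicates × 4 levels).

## Synthetic communities

The generator plants the two properties that distinguish real
transcriptome-level samples: *sequence composition* divergence and
*expression abundance* differences. Pools share a random base transition
table (order-1 by default — the weakest model that still carries local
composition structure beyond base frequencies); each pool mixes it with an
independent random table at weight δ and generates its own transcripts and
Dirichlet(1) expression weights. Defaults, fixed once:

| parameter | default | rationale |
|---|---|---|
| transcripts per pool | 40 | small expressed gene pool; keeps panels cheap while leaving per-transcript coverage realistic |
| transcript length | 900 nt | typical bacterial CDS scale |
| source chain order | 1 | dinucleotide composition signal |
| divergence δ | 0.3 | clearly separated communities, analogous to geographically distinct sites |
| expression weights | Dirichlet(1) | flat prior over abundance profiles, independent per pool |
| group panel | 4 pools × 5 samples, 2000 reads × 150 bp | the study layout of the robustness protocols, at desk scale |
| gradient panel | 2 replicates × 4 levels, mixture fractions (0, ⅓, ⅔, 1) | emulates a two-sample-per-depth ocean series |
| error rates | 1% indel + 0.1% substitution | pyrosequencing-style error profile |

Read lengths are Normal(mean, sd) truncated to [20, transcript length]
(sd = 0 gives fixed-length Illumina-style reads); a read is a uniform
substring of a transcript chosen by expression weight. The error injector
is a homogeneous per-base model — substitution to a uniformly chosen other
base, insertion/deletion splitting the indel rate evenly (the split is this
package's choice; only the combined rate is conventionally quoted). It does
not model flow-cycle or homopolymer effects, quality values, or paired-end
structure, so robustness results here speak to rate-matched random errors,
not to platform-specific error *patterns*. Likewise the generator draws
iid reads from static pools: no coverage bias, GC bias, contamination or
within-group biological variability beyond resampling noise. Passing the
planted-structure tests therefore demonstrates the statistical machinery is
correct and depth/error-robust under its stated model, not that any measure
will rank real communities correctly.

All generators are seed-deterministic end to end; per-sample and
per-repetition seeds are spawned from the master seed via
`numpy.random.SeedSequence`, so any single repetition can be re-run in
isolation.

## Problem sizes in the shipped protocols

The test-suite protocols run 100 seeds of the 4×5 group panel (2000 reads
× 150 bp per sample) for full-depth, 10%-depth and error-injected
clustering, three seeds of the gradient panel, and a 200-pair range-bound
survey (500 reads × 100 bp per set, k = 5); these sizes make the planted
signal comfortably detectable while keeping the whole suite at a few
minutes on one CPU. The acceptance script reruns only the 200-pair survey.

## Known limitations

* Orders above 3 and smoothed/interpolated chains are out of scope.
* The symmetric-difference score carries no significance test; attaching
  p-values would require a null model over tree space that is not specified
  by any of the conventions this package follows.
* `hao` at large `k` estimates an order-(k−2) chain from finite reads; its
  instability at low depth is inherent to the measure, not mitigated here.
* FASTQ qualities are parsed and ignored; no trimming or filtering.
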