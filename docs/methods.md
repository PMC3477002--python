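# Methods

## The problem

Composition-based taxonomic classification assigns metagenomic sequences
to taxa using only statistics of the nucleotide string itself — here,
frequencies of overlapping words of length *n* (*n*-mers). Before
committing to any particular classifier, one can ask how *separable* the
taxonomic classes are under a given encoding: if sequences of the same
species occupy distinct regions of frequency-vector space, almost any
classifier will do well; if classes overlap, none will. `taxosep`
quantifies that separability as a function of three design choices: the
word length *n*, the dissimilarity measure *s*, and whether
classification is flat or hierarchical.

## Encoding

A sequence is scanned with a window of length *n* and step 1 (overlap
*n* − 1). Each ACGT-only window maps to an integer in [0, 4ⁿ) by
big-endian 2-bit packing (A=0, C=1, G=2, T=3); windows containing any
other character are skipped and counted separately, and a sequence whose
every window is skipped is rejected as un-encodable. Counts are stored
sparsely (at *n* = 10 the implicit dimension is ~1.05 × 10⁶ but a 400 bp
fragment fills at most 391 positions). Two normalizations are available:

* plain: freq(i) = count(i) / total windows;
* add-one smoothed: freq(i) = (count(i) + 1) / (total + 4ⁿ). Every
  implicit coordinate is then strictly positive; all zero-count
  positions share one scalar, so the representation stays sparse.

Smoothing is applied exactly when the Kullback-Leibler measure is in
use (both operands), because the KL divergence is undefined on zeros.
Words are counted literally — no reverse-complement canonicalization.

## Dissimilarity measures

For frequency vectors x, y of dimension 4ⁿ:

* s₁(x,y) = Σᵢ |xᵢ − yᵢ| (1-norm),
* s₂(x,y) = (Σᵢ |xᵢ − yᵢ|²)^½ (Euclidean),
* s∞(x,y) = maxᵢ |xᵢ − yᵢ| (Chebyshev),
* s_kl(x,y) = Σᵢ xᵢ ln(xᵢ/yᵢ) (KL divergence; x is the query, y the
  candidate neighbor — the divergence is asymmetric and the direction
  must be fixed by convention).

All sums run over the implicit dense coordinates but are evaluated as a
single merge over the two sparse supports; the block of coordinates
stored in neither operand contributes `(4ⁿ − |union|) · f(v_x, v_y)` in
closed form, where v are the operands' shared zero-count values. This
keeps *n* = 10 tractable without densification. The pairwise kernels are
compiled with numba; a dense brute-force oracle (independent code path)
pins them down in the test suite to 1 × 10⁻¹².

## Scores

Fix a labeled pool, a taxonomic level *t* ∈ {domain … species}, *n* and
*s*. Both scores are fractions in [0, 1] of nearest-neighbor class
matches, with these shared rules:

* the query is never its own neighbor, but an exact duplicate under a
  different ID is a legitimate neighbor;
* distance ties (bit-equal) are broken toward the lexicographically
  smallest record ID, for reproducibility;
* a sequence that is the sole representative of its class in the pool
  being searched is not scored (its neighbor is necessarily wrong-class,
  which would only bias the score downward);
* if nothing is scorable (m = 0) the score is undefined, and undefined
  propagates rather than aborting a grid.

**Conventional score** — the fraction of (scorable) sequences whose
nearest neighbor in the whole pool shares their taxon at level *t*.
Equivalent to leave-one-out 1-NN accuracy, minus the singleton classes.

**Hierarchical score** — models a tree of per-clade classifiers. At the
domain it equals the conventional score. At a deeper level *t*, each
query's candidate pool is first pruned to the sequences sharing its
class at *t* − 1 (the classifier it would have been routed to); the
pruned pool must have more than one member and the query must not be the
sole representative of its level-*t* class *within that pruned pool*
(the pool actually searched is what forces a wrong-class neighbor). The
level's match fraction then multiplies the hierarchical score one level
above, which accounts for the probability of having been routed
correctly. The recursion is pool-level, so each level's fraction is
computed once per (n, s), not once per query; the per-level fractions
are reported alongside the product.

Class identity at a level compares the single lineage slot at that
level, appropriate for globally unique identifiers (NCBI taxids). A
prefix mode compares the full lineage prefix instead, for labeling
schemes whose names repeat across clades.

A *configuration grid* evaluates every (level, n, s, score-mode) cell on
a dataset; each distance matrix is computed once per (n, s) and shared
across levels and modes, and encodings are dropped after each *n* so
memory stays flat (~32 MB per matrix at 2,000 records).

## Synthetic communities

The generator exists so every scoring path can be exercised, and the
known qualitative behaviors probed, without downloading genomes.

**Planted taxonomy.** A balanced tree given by a children-per-rank
vector; the default (2, 4, 2, 3, 1, 1, 1) yields 48 species in 2
domains × 4 phyla × 2 classes × 3 orders, with the deep ranks
degenerate — mirroring real curated collections, where most genera
contribute a single species. Node identifiers embed the tree path, so
slot-wise comparison behaves like taxid comparison.

**Composition signal.** Each species has an order-2 (dinucleotide)
Markov model; genomes are sampled from their species' model. Order 2 is
the smallest order that plants word-level signal for n ≥ 2 while leaving
mononucleotide frequencies nearly uninformative. Crucially, divergence
between clades is modeled along a *single dominant axis* in
transition-logit space, mimicking the fact that real microbial
composition variation is dominated by G+C content: one unit direction is
drawn per community, and the children of each node are spread along it
at centered, evenly spaced offsets scaled by the rank's divergence
(plus a small Gaussian jitter, all in log space, renormalized by
softmax). The default divergence ladder (2.0, 0.65, 0.4, 0.2, …) makes
each rank's child span exceed its parent's sibling gap, so clades from
different parents *interleave* along the axis: two sequences from
different classes can be compositionally near-identical even though each
is cleanly separated from its own siblings. This convergence is the
empirically documented failure mode of flat composition classification
and is exactly what hierarchical pruning repairs — a full-rank isotropic
jitter model cannot produce it at realistic magnitudes, because
independent random walks in ~50 dimensions essentially never collide.

Setting every divergence to zero removes the signal entirely (all
species share one model), in which case the species-level conventional
score has a known expectation: the class-size chance rate
Σ_k (m_k/m)·((m_k − 1)/(m − 1)). This identity is used as a calibration
check in the test suite and the acceptance script.

**Fragments.** ~400 bp reads are drawn uniformly over genomes (or by a
supplied abundance vector) and positions, lengths Normal(400, 40)
truncated below at 20 bp, with errors applied in the order substitution
→ homopolymer-run extension → indels. Defaults (substitution and indel
rates 5 × 10⁻⁴ each, run-extension probability 0.01 per run) emulate a
low-error pyrosequencer-like profile dominated by homopolymer-length
mistakes. This is an explicit, transparent simplification: no flowgram
simulation, no quality values, no chimeras. The default genome length
(200 kb) is chosen so that at ~20 fragments per genome, two fragments
rarely overlap positionally — overlapping fragments share literal
sequence and act as near-duplicate neighbors, inflating flat scores
through a route that has nothing to do with composition signal.

**What passing tests do and do not show.** The generator plants
stationary Markov composition with a one-axis divergence geometry; real
genomes are non-stationary (horizontally transferred islands, rRNA
operons, strand asymmetries), real divergence has more than one axis,
and real taxonomies are unbalanced. Tests on these communities validate
the *scoring machinery* and reproduce the qualitative regime (concave
score-vs-n with an interior optimum near n = 3–4 for 400 bp fragments;
fragment scores below genome scores; hierarchical at least matching
conventional at the species level when comparing best configurations).
They do not predict absolute scores on real data.

## Numerical choices

* Distance comparisons during NN search are exact (no epsilon); the
  ID tie-break applies only to bit-equal distances.
* The hierarchical score is reported as the product of per-level
  fractions; the product and factors agree to 1 × 10⁻¹² by construction.
* Sequences are uppercased before counting; IUPAC ambiguity codes are
  treated as non-ACGT and skipped per window with a logged warning.
* Seeds: every stochastic component (taxonomy, signal, genome sampling,
  fragment shearing) takes an explicit seed; per-node random streams are
  keyed by the tree path so results are independent of traversal order.

## Problem sizes

The default test and reproduction runs use 96 genomes of 200 kb,
2,000 fragments, word lengths 1–8 for fragments and 1–10 for genomes,
and 20 replicate seeds for the chance-recovery check; the full suite
runs in about five minutes on one CPU and the reproduction script in
about three.

## Known limitations

* O(m²) pairwise distances bound practical pool sizes to a few thousand
  records; no approximate NN index is provided (by design — the score is
  defined by the exact nearest neighbor).
* The KL direction (query ‖ neighbor) is a convention; the reverse
  direction gives different distances, though empirically similar scores.
* Fragment simulation does not reproduce any specific instrument's error
  spectrum; quantitative comparison with scores computed on reads from a
  real simulator is out of scope.
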