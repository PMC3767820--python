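# Methods

## The statistical model

Each sequencing library is treated as N draws from a categorical
distribution over tags; a tag observed x times has an unknown true
proportion θ. With a Beta(a, b) prior, the posterior is

    θ | x ~ Beta(x + a, N − x + b)

and two libraries give independent posteriors θ₁, θ₂ (the libraries are
separate sequencing runs; nothing couples the posteriors beyond their
data). The quantity reported per tag is the posterior probability that
the true proportions differ by at least a fold factor R:

    p_fold = P(θ₂ ≥ R·θ₁) + P(θ₁ ≥ R·θ₂)      (two-sided)

The two events are disjoint up to a null set when R > 1, so the sum is a
probability. A tag is called significant when p_fold exceeds the
threshold *strictly* (p_fold > 0.95).

Defaults: R = 2, a = b = 2, threshold 0.95, two-sided. The symmetric
pseudocounts act as a weak smoothing prior: a tag absent from one library
still has a proper posterior there, and low-count noise is damped. The
prior is interpreted as exact beta pseudocounts rather than any gamma or
normal approximation of the posterior — at the scale this package runs,
the exact computation is cheap and strictly more defensible.

Design choices worth stating explicitly:

- **Two-sided by default.** The single probability must cover both up-
  and down-regulation because significance feeds a Venn partition and a
  pattern classifier that use direction separately (direction is read off
  the posterior means θ̂ᵢ = (xᵢ + a)/(Nᵢ + a + b)).
- **No multiple-testing correction on p_fold.** The 0.95 cut is applied
  per tag per comparison. This is deliberate and prominent: the posterior
  probability is not a frequentist p-value, and the null-calibration
  check below measures what the rule actually does under the null.
- **Library-size awareness.** Because the test is on proportions, equal
  counts at a 10-fold library-size imbalance are strong evidence of
  change, not a null result; this is asserted by test.
- **Ties.** Exactly equal posterior means give direction "flat"; flat
  tags are excluded from Venn membership regardless of p_fold (a
  degenerate case real data essentially never hits, but the rule must be
  total).

### Numerical evaluation

Writing F₁ for the CDF of θ₁ and S₂ for the survival function of θ₂,

    P(θ₂ ≥ R·θ₁) = ∫₀¹ S₂(R · F₁⁻¹(u)) du

after the substitution u = F₁(t). The integrand is smooth, monotone and
bounded on [0, 1] even when both posteriors are sharply concentrated
(where naive quadrature over t would miss the peak), and is integrated
with adaptive Gauss–Kronrod quadrature (`scipy.integrate.quad`,
epsabs = epsrel = 10⁻⁶, up to 200 subintervals). Results are clamped to
[0, 1]. QUADPACK's divergence heuristic can misfire when the integrand is
near-constant outside a narrow transition; that warning is suppressed
locally and accuracy is instead guarded by a Monte-Carlo oracle test
(10⁶ independent beta draws per grid cell, agreement within 0.005;
observed worst-case ≈ 5·10⁻⁴).

In pairwise comparison runs, tags sharing the same (x₁, x₂) pair share
one quadrature via a cache — at depth 2·10⁵ many tags have identical
counts, and the cache cuts runtime several-fold without changing any
value. Output is sorted by descending p_fold, then tag sequence, so runs
are byte-reproducible.

## Virtual tag library

A tag is the NlaIII recognition site `CATG` plus the 18 nt immediately
3' of it — 22 bp total, used as an exact-match key. Extraction rules:

- **All sites** with ≥ 18 clean nt downstream are used by default, not
  only the 3'-most (the classic LongSAGE convention is available as
  `site_policy="three-prime-most"`).
- **Sense strand only**: tags derive from oriented cDNA.
- **0-based offsets**, pointing at the C of `CATG`.
- Windows containing **N** are dropped: a perfect-match mapper could
  never hit them. Whether ambiguous windows should instead be expanded
  is a judgement call; dropping is the conservative choice and is
  flagged here rather than buried.

Tags found in more than one transcript are marked multi-mapped. Gene
aggregation adds a multi-mapped tag's count *in full* to every gene it
maps to and flags those genes ambiguous — fractional splitting would
invent weights the data do not support, while flags preserve the
information. The tag-level table remains the primary object.

## Read filtering and counting

Filtering is structural only: a read is truncated to 22 nt from the 5'
end (sequencers over-read the tag), then rejected as `too_short`
(< 22 nt), `no_anchor` (no leading `CATG`) or `ambiguous_base` (N inside
the window), in that order. FASTQ base qualities are parsed but unused;
a mean-quality floor is left as an extension point because no defensible
default exists for this chemistry. Counting enforces the conservation
ledger `n_reads_in = n_filtered + n_unmapped + N` on every input and is
invariant under read order.

## Pattern classification

Category membership uses only the naive→induced and induced→tolerant
comparisons; naive→tolerant is computed and reported (it completes the
Venn partition) but does not vote, because the four trajectories are
defined by the two consecutive steps. "Further upregulated" is
operationalised as *significant*-up on the second leg, not as a raw
ratio ordering — classification inherits the significance machinery
rather than introducing a second, uncalibrated rule. Both conventions
are isolated in one rule table (`patterns._RULES`) should a user want
the alternative reading.

The four margin identities

    |I| + |II|  = up-after-first-stimulus      |I| + |III| = up-in-tolerant
    |III| + |IV| = down-after-first-stimulus   |II| + |IV| = down-in-tolerant

hold exactly on any input by construction and are re-asserted at
summary time as a guard against rule drift.

## Enrichment

The EASE score is the right-tail hypergeometric probability recomputed
with the study/term overlap reduced by one: P(X ≥ k−1) for
X ~ Hypergeom(N_pop, K, n), with k ≤ 1 mapping to exactly 1. It is
conservative by construction (ease_p ≥ Fisher right-tail p for every
table; property-tested). The background is every gene with at least one
annotation in the supplied map — not every gene in the tag index —
mirroring the standard annotated-background rule; terms with zero study
overlap are not tested, so they cannot dilute the Benjamini–Hochberg
correction, which is applied across all tested terms at a 0.05 cut
(`statsmodels` step-up; the test oracle is an independent hand-rolled
implementation).

## ΔΔCt

ΔCt = Ct_target − Ct_reference within a sample (reference 18S by
convention), ΔΔCt = ΔCt_sample − ΔCt_calibrator, ratio = 2^−ΔΔCt.
Technical replicates are aggregated by mean Ct before ΔΔCt (median
available); log₂(ratio) = −ΔΔCt exactly, which the tests assert to
machine precision. Amplification-efficiency correction is out of scope.

## The synthetic generator

The generator emulates the three-library design, not the sequencing
chemistry. Per experiment:

- **Transcriptome**: each transcript is random sequence scrubbed of
  `CATG`, with a single planted `CATG` + 18 nt tag flush with the 3'
  end, so tag↔transcript is bijective and the planted tag is the only
  extractable one. Planted 22-mers are globally distinct in the default
  collision-free mode; a multimap mode deliberately copies one tag
  across two transcripts to exercise the multi-mapping bookkeeping.
  Transcript lengths default to 200–400 nt, consistent with NlaIII
  sites occurring every few hundred nucleotides in real transcripts.
- **Patterns**: each tag gets a label with default fractions
  (I, II, III, IV, null) = (0.10, 0.20, 0.10, 0.05, 0.55) by
  largest-remainder apportionment. Relative abundance shapes across
  (naive, induced, tolerant) are I: (1, f, f²), II: (1, f, 1),
  III: (f, 1, f), IV: (f², f, 1), null: (1, 1, 1) with fold effect
  f = 4 by default.
- **Column balancing**: proportions are shapes normalised per condition,
  so unequal condition totals would silently shrink every planted fold
  step and make null tags differ between conditions. Per-pattern base
  abundances are therefore solved so the three condition columns carry
  equal total mass; the constraints reduce to m_I = m_IV and
  m_II = m_III + (f−1)·m_I (m_k = pattern k's total mass). Under the
  default fractions this gives patterns II and IV twice the base
  abundance of the others — a harmless artefact — and makes every
  planted step *exactly* f while null tags are *exactly* equal.
  Fraction combinations that cannot satisfy the constraints (e.g.
  pattern I without pattern IV) are rejected with an explicit error;
  ground truth with arbitrary proportion vectors can always be built
  directly when an unbalanced design is wanted.
- **Sampling**: each library is one multinomial draw of fixed depth
  (default 2·10⁵) from its condition's proportion vector — totals are
  fixed, matching the fixed-N conditioning of the statistic. Poisson
  sampling would model random library sizes the analysis never sees.
- **Seeding**: one integer seed drives everything through numpy
  `SeedSequence` spawning (child 0 → transcriptome, child 1 → counts,
  child 2 → read-level noise), so fixtures are byte-reproducible.
  Bit-exact equality across numpy versions or other languages is not a
  contract; the derivation is documented so behaviour can be matched
  qualitatively.

At the default sizes (500 tags, depth 2·10⁵) the smallest per-tag
expected count is ≈ 130, comfortably in the regime where a true 4-fold
step clears the R = 2, p > 0.95 rule; the suite's recovery checks
restrict to tags with expected count ≥ 20 in every condition so that the
claim tested is about the statistic, not about sampling starvation.

**What the generator does not emulate** — and therefore what passing
tests do not show about real data: sequencing error (the optional
uniform substitution noise is a stress input for the filter, not an
error model), base-quality structure, alternative transcripts sharing
tags at realistic rates, the long-tailed abundance distribution of real
transcriptomes, and any batch or pooling effects. Recovery rates on real
libraries will be lower than on the fixture for all of these reasons.

## Problem sizes

The test suite and the acceptance script run the statistic's oracle grid
at 10⁶ Monte-Carlo draws per cell (55 cells), null calibration on 5,000
tags, and the end-to-end fixture at 500 tags × 2·10⁵ depth — sizes
chosen so the full suite completes in well under a minute on one CPU
while keeping every expected count far from the boundary cases the
individual unit tests probe directly.

## Known limitations

- Perfect-match counting discards reads with any sequencing error in the
  22 bp window; at realistic error rates a few percent of reads are lost
  per library, which the fixed-N statistic absorbs but which slightly
  reduces effective depth.
- The beta-posterior model ignores overdispersion between biological
  replicates (the design pools RNA before sequencing, so within-condition
  variance is not estimable); p_fold is a statement about sampling
  uncertainty given pooled proportions, not about population variability.
- Gene-level aggregation double-counts multi-mapped tags by design;
  downstream consumers must respect the ambiguity flags.
- EASE results depend strongly on the supplied annotation map; the
  package ships no annotation database and makes no claim about any
  particular one.
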