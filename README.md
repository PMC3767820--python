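# sagetally

SAGE-Seq tag counting, Bayesian fold-change testing and tolerance-pattern
classification for three-condition stimulation designs.

## The problem

SAGE-Seq measures gene expression digitally: each mRNA is represented by a
short sequence tag cut next to an NlaIII restriction site (recognition
sequence `CATG`), and expression is the count of that tag in a sequenced
library. In models of innate-immune tolerance, cells are profiled in three
states — **naive** (N), **induced** (one stimulus, N+PGN) and **tolerant**
(restimulated, T+PGN) — and the interesting biology lives in each gene's
*trajectory* across the three states: is an induced gene still inducible
after restimulation (non-tolerizeable) or is its induction lost
(tolerizeable)?

`sagetally` implements that analysis end to end:

1. **Virtual tag library** — every 22 bp tag (`CATG` + 18 nt) a
   transcriptome could produce, with multi-mapping tags tracked, never
   silently resolved.
2. **Exact-match counting** — structural read filtering (length / anchor /
   ambiguous bases) and perfect 22 bp matching; the ledger
   `n_reads_in = n_filtered + n_unmapped + N` always balances.
3. **Bayesian fold-change test** — for a tag with counts x₁/N₁ and x₂/N₂,
   the true proportions get independent beta posteriors
   θᵢ ~ Beta(xᵢ + a, Nᵢ − xᵢ + b) with a = b = 2, and the reported statistic
   is the posterior probability of at least an R-fold difference,

   p_fold = P(θ₂ ≥ R·θ₁) + P(θ₁ ≥ R·θ₂),  R = 2 by default,

   computed by deterministic quadrature; a tag is significant when
   p_fold > 0.95. Because the test is on proportions it automatically
   accounts for unequal library sizes.
4. **Venn partition** of the three pairwise comparisons' significant tags.
5. **Pattern classification** — each tag's (naive→induced, induced→tolerant)
   significance/direction pair maps to one of four trajectory categories:
   I non-tolerizeable amplified (up, up), II tolerizeable (up, down),
   III suppressed-then-induced (down, up), IV progressively suppressed
   (down, down); anything else is unclassified.
6. **EASE-score enrichment** — right-tail hypergeometric with the study
   overlap penalised by one, Benjamini–Hochberg corrected at 0.05.
7. **2^-ΔΔCt** relative quantification for qPCR validation panels.

A synthetic-data generator emulates the three-library design with planted
fold-change patterns, so the whole pipeline is testable with a known
answer key and no external downloads.

## Worked example

```python
from sagetally import (SimulationSpec, simulate_experiment, build_index,
                       compare_libraries, classify_all, summarize_patterns,
                       BayesConfig)

spec = SimulationSpec(n_transcripts=100, depth_per_library=50_000, seed=42)
transcripts, truth, tables = simulate_experiment(spec)
index = build_index(transcripts)
print(f"library: {index.n_tags} virtual tags from {len(transcripts)} transcripts")

cfg = BayesConfig()  # R=2, a=b=2, p > 0.95
ni = compare_libraries(tables["naive"], tables["induced"], cfg)
it = compare_libraries(tables["induced"], tables["tolerant"], cfg)
print(f"naive vs induced:    {sum(r.significant for r in ni)} / {len(ni)} tags significant")
print(f"induced vs tolerant: {sum(r.significant for r in it)} / {len(it)} tags significant")

summary = summarize_patterns(classify_all(ni, it))
for category, count in summary.counts.items():
    print(f"{category:35s} {count}")
```

prints

```
library: 100 virtual tags from 100 transcripts
naive vs induced:    45 / 100 tags significant
induced vs tolerant: 45 / 100 tags significant
I_non_tolerizeable_amplified        10
II_tolerizeable                     20
III_suppressed_then_induced         10
IV_progressively_suppressed         5
unclassified                        55
```

The generator planted 10/20/10/5 tags in categories I–IV (and 55 null
tags) with a 4-fold effect per trajectory step; at 50,000 tags per library
every planted tag is recovered in its true category and no null tag is
called. The 45 significant tags on each leg are exactly the 45 planted
non-null tags — every pattern changes 4-fold on both legs.

The same stages are available from the shell:

```sh
sagetally simulate --n-transcripts 100 --depth 50000 --seed 42 --out fixture/
sagetally build-library --fasta fixture/transcripts.fasta --out index.tsv
sagetally run --config run.yaml     # the whole pipeline, checksummed
```

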