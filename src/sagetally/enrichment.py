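"""EASE-score annotation-term enrichment with Benjamini–Hochberg control.

Given a study gene list and a gene→terms annotation map, each term is
tested for over-representation with the EASE score: the right-tail
hypergeometric (Fisher's exact) p-value recomputed after removing one
gene from the study/term overlap.  Penalising the overlap by one makes
the score conservative — a term supported by a single study gene can
never score better than 1 — so ease_p ≥ the exact Fisher right-tail p
for every table.

The background population is, by default, every gene with at least one
annotation in the supplied map; terms with no study overlap are not
tested (they cannot be enriched and would only dilute the correction).
P-values are adjusted across all tested terms by the Benjamini–Hochberg
step-up procedure and a term is called significant when its adjusted
value falls below 0.05.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's 2×2 table, EASE p-value and adjusted call.

    k: study genes carrying the term; n: study size; K: population genes
    carrying the term; Npop: population size.
    """

    term_id: str
    k: int
    n: int
    K: int
    Npop: int
    ease_p: float
    bh_q: float
    significant: bool


def _validate_table(k: int, n: int, K: int, Npop: int) -> None:
    if not (0 <= k <= min(n, K) and n <= Npop and K <= Npop and n >= 0 and K >= 0):
        raise ValueError(
            f"inconsistent 2x2 table: k={k}, n={n}, K={K}, Npop={Npop}"
        )


def ease_score(k: int, n: int, K: int, Npop: int) -> float:
    """EASE p-value: right-tail hypergeometric with the overlap reduced by one.

    Returns P(X ≥ k−1) for X ~ Hypergeom(Npop, K, n); k ≤ 1 gives 1
    exactly (the penalised overlap is empty, so the tail is the whole
    distribution).
    """
    _validate_table(k, n, K, Npop)
    if k <= 1:
        return 1.0
    # sf(k-2) = P(X >= k-1)
    return float(hypergeom.sf(k - 2, Npop, K, n))


def fisher_right_tail(k: int, n: int, K: int, Npop: int) -> float:
    """Unpenalised Fisher right-tail p-value, P(X ≥ k), for reference."""
    _validate_table(k, n, K, Npop)
    return float(hypergeom.sf(k - 1, Npop, K, n))


def benjamini_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Monotone-enforced and capped at 1; invariant to input order (values
    are matched back to their positions).  Raises on values outside
    [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    study_genes: Iterable[str],
    annotation_map: Mapping[str, Iterable[str]],
    population_genes: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in a study list.

    The population is restricted to genes carrying at least one term
    (optionally intersected with an explicit ``population_genes``
    universe), mirroring the default annotated-background rule; the
    study list is restricted the same way.  One result per term with
    k ≥ 1, BH-adjusted across all tested terms, sorted by ascending
    ease_p then term id.
    """
    annotated = {g: set(ts) for g, ts in annotation_map.items() if ts}
    population = set(annotated)
    if population_genes is not None:
        population &= set(population_genes)
    study = set(study_genes) & population
    if not study:
        raise ValueError(
            "no study genes remain after restricting to the annotated background"
        )

    term_K: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene in population:
        in_study = gene in study
        for term in annotated[gene]:
            term_K[term] = term_K.get(term, 0) + 1
            if in_study:
                term_k[term] = term_k.get(term, 0) + 1

    n, Npop = len(study), len(population)
    terms = sorted(term_k)  # k >= 1 only
    pvals = [ease_score(term_k[t], n, term_K[t], Npop) for t in terms]
    qvals = benjamini_adjust(pvals)
    results = [
        EnrichmentResult(
            term_id=t,
            k=term_k[t],
            n=n,
            K=term_K[t],
            Npop=Npop,
            ease_p=p,
            bh_q=float(q),
            significant=bool(q < SIGNIFICANCE_LEVEL),
        )
        for t, p, q in zip(terms, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.ease_p, r.term_id))
    return results


# ---------------------------------------------------------------------------
# I/O


def read_annotation_map(path: str | Path) -> dict[str, set[str]]:
    """Load a gene→terms map from a headerless TSV of (gene, term) rows."""
    mapping: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            gene, term = row[0].strip(), row[1].strip()
            mapping.setdefault(gene, set()).add(term)
    return mapping


def read_gene_list(path: str | Path) -> list[str]:
    """Load a one-gene-per-line list."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["term", "k", "n", "K", "Npop", "ease_p", "bh_q", "significant"])
        for r in results:
            w.writerow(
                [
                    r.term_id,
                    r.k,
                    r.n,
                    r.K,
                    r.Npop,
                    f"{r.ease_p:.8g}",
                    f"{r.bh_q:.8g}",
                    int(r.significant),
                ]
            )
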