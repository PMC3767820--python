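"""Bayesian fold-change testing between two tag-count libraries.

For a tag observed x₁ times out of N₁ mapped tags in one library and x₂
out of N₂ in another, the true per-library tag proportions θ₁, θ₂ are
given independent beta posteriors

    θᵢ | xᵢ ~ Beta(xᵢ + a, Nᵢ − xᵢ + b)

with symmetric prior pseudocounts a = b = 2 by default.  The reported
statistic is the posterior probability that the true proportions differ
by at least a fold factor R,

    p_fold = P(θ₂ ≥ R·θ₁) + P(θ₁ ≥ R·θ₂)        (two-sided, R > 1)

computed by deterministic numerical quadrature.  A tag is called
significant when p_fold exceeds 0.95 (strict).  Because the posterior is
on proportions, the test automatically accounts for unequal library
sizes: identical counts at very different N give very different θ̂ and a
correspondingly high p_fold.

No multiple-testing correction is applied to p_fold: the 0.95 cut is a
per-tag, per-comparison rule.  Direction (up/down/flat) is reported from
the posterior means, separately from the probability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import warnings

from scipy.integrate import IntegrationWarning, quad
from scipy.special import betainc, betaincinv

from .tag_quant import TagCountTable

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_FLAT = "flat"


@dataclass(frozen=True)
class BayesConfig:
    """Parameters of the fold-change test.

    fold_factor
        Minimum true-abundance ratio R whose posterior probability is
        computed; must be ≥ 1 (1 makes the two-sided event trivially
        certain and exists only as a limit check).
    prior_a, prior_b
        Beta prior pseudocounts added to the observed count and to its
        complement, respectively.
    significance_threshold
        Strict cut on p_fold for the significance call.
    two_sided
        Cover both up- and down-regulation in a single probability.
    integration_tolerance
        Absolute/relative tolerance of the quadrature.
    """

    fold_factor: float = 2.0
    prior_a: float = 2.0
    prior_b: float = 2.0
    significance_threshold: float = 0.95
    two_sided: bool = True
    integration_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.fold_factor < 1.0:
            raise ValueError("fold_factor must be >= 1")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("prior pseudocounts must be positive")
        if not 0.0 < self.significance_threshold < 1.0:
            raise ValueError("significance_threshold must be in (0, 1)")


@dataclass(frozen=True)
class ComparisonResult:
    """Per-tag output of one pairwise library comparison.

    Direction is library 2 relative to library 1 on posterior means;
    exactly equal posterior means give "flat", and flat tags never enter
    Venn membership.
    """

    tag_seq: str
    x1: int
    x2: int
    N1: int
    N2: int
    theta1_hat: float
    theta2_hat: float
    direction: str
    p_fold: float
    significant: bool


def _one_sided_fold_probability(
    a1: float, b1: float, a2: float, b2: float, R: float, tol: float
) -> float:
    """P(θ₂ ≥ R·θ₁) for θᵢ ~ Beta(aᵢ, bᵢ), independent.

    Substituting u = F₁(t) turns the integral into
    ∫₀¹ S₂(R·F₁⁻¹(u)) du with S₂ the survival function of θ₂ — a smooth,
    monotone, bounded integrand that adaptive quadrature handles well
    even when both posteriors are sharply concentrated.
    """

    def integrand(u: float) -> float:
        t = R * betaincinv(a1, b1, u)
        if t >= 1.0:
            return 0.0
        return 1.0 - betainc(a2, b2, t)

    with warnings.catch_warnings():
        # the integrand is bounded on [0,1]; QUADPACK's divergence heuristic
        # misfires when it is near-constant outside a narrow transition
        warnings.simplefilter("ignore", IntegrationWarning)
        value, _err = quad(integrand, 0.0, 1.0, epsabs=tol, epsrel=tol, limit=200)
    return min(max(value, 0.0), 1.0)


def fold_probability(
    x1: int, N1: int, x2: int, N2: int, cfg: BayesConfig | None = None
) -> float:
    """Posterior probability of at least a fold-factor difference.

    Returns P(θ₂ ≥ R·θ₁ or θ₁ ≥ R·θ₂) under the independent beta
    posteriors (or the first term only if one-sided), clamped to [0, 1].
    """
    cfg = cfg or BayesConfig()
    for x, N in ((x1, N1), (x2, N2)):
        if N < 1:
            raise ValueError("library total N must be >= 1")
        if not 0 <= x <= N:
            raise ValueError(f"count x={x} outside [0, N={N}]")
    a1, b1 = x1 + cfg.prior_a, N1 - x1 + cfg.prior_b
    a2, b2 = x2 + cfg.prior_a, N2 - x2 + cfg.prior_b
    tol = cfg.integration_tolerance
    p = _one_sided_fold_probability(a1, b1, a2, b2, cfg.fold_factor, tol)
    if cfg.two_sided:
        p += _one_sided_fold_probability(a2, b2, a1, b1, cfg.fold_factor, tol)
    return min(max(p, 0.0), 1.0)


def compare_libraries(
    table1: TagCountTable, table2: TagCountTable, cfg: BayesConfig | None = None
) -> list[ComparisonResult]:
    """Run the fold-change test for every tag in the union of two tables.

    A tag absent from one table contributes a zero count there.  Results
    are sorted by descending p_fold, then tag sequence, so output order
    is deterministic.  Identical (x1, x2) pairs share one quadrature via
    a local cache, which matters for deeply sequenced libraries where
    many tags have equal counts.
    """
    cfg = cfg or BayesConfig()
    N1, N2 = table1.N, table2.N
    if N1 == 0 or N2 == 0:
        raise ValueError("both libraries must contain mapped tags (N >= 1)")
    denom1 = N1 + cfg.prior_a + cfg.prior_b
    denom2 = N2 + cfg.prior_a + cfg.prior_b

    cache: dict[tuple[int, int], float] = {}
    results: list[ComparisonResult] = []
    for tag in set(table1.counts) | set(table2.counts):
        x1 = table1.counts.get(tag, 0)
        x2 = table2.counts.get(tag, 0)
        key = (x1, x2)
        p = cache.get(key)
        if p is None:
            p = fold_probability(x1, N1, x2, N2, cfg)
            cache[key] = p
        t1 = (x1 + cfg.prior_a) / denom1
        t2 = (x2 + cfg.prior_a) / denom2
        if t2 > t1:
            direction = DIRECTION_UP
        elif t2 < t1:
            direction = DIRECTION_DOWN
        else:
            direction = DIRECTION_FLAT
        results.append(
            ComparisonResult(
                tag_seq=tag,
                x1=x1,
                x2=x2,
                N1=N1,
                N2=N2,
                theta1_hat=t1,
                theta2_hat=t2,
                direction=direction,
                p_fold=p,
                significant=p > cfg.significance_threshold,
            )
        )
    results.sort(key=lambda r: (-r.p_fold, r.tag_seq))
    return results


# ---------------------------------------------------------------------------
# Venn partition of the three pairwise comparisons


@dataclass(frozen=True)
class VennSummary:
    """Counts of the 7 exclusive regions of three significance sets.

    ``names`` labels the three pairwise comparisons (A, B, C); region
    keys are '_and_'-joined sorted name combinations with '_only'
    suffixes for singletons.
    """

    names: tuple[str, str, str]
    regions: dict[str, int]
    totals: dict[str, int]
    grand_union: int


def _significant_tags(results: Iterable[ComparisonResult]) -> set[str]:
    # flat tags are excluded from membership regardless of p_fold
    return {
        r.tag_seq for r in results if r.significant and r.direction != DIRECTION_FLAT
    }


def venn_summary(
    results_a: Sequence[ComparisonResult],
    results_b: Sequence[ComparisonResult],
    results_c: Sequence[ComparisonResult],
    names: tuple[str, str, str] = (
        "naive_vs_induced",
        "naive_vs_tolerant",
        "induced_vs_tolerant",
    ),
) -> VennSummary:
    """Partition significant tags of three comparisons into the 7 Venn regions."""
    sets = [_significant_tags(r) for r in (results_a, results_b, results_c)]
    a, b, c = sets
    regions = {
        f"{names[0]}_only": len(a - b - c),
        f"{names[1]}_only": len(b - a - c),
        f"{names[2]}_only": len(c - a - b),
        f"{names[0]}_and_{names[1]}": len((a & b) - c),
        f"{names[0]}_and_{names[2]}": len((a & c) - b),
        f"{names[1]}_and_{names[2]}": len((b & c) - a),
        f"{names[0]}_and_{names[1]}_and_{names[2]}": len(a & b & c),
    }
    totals = {name: len(s) for name, s in zip(names, sets)}
    return VennSummary(
        names=names,
        regions=regions,
        totals=totals,
        grand_union=len(a | b | c),
    )


# ---------------------------------------------------------------------------
# I/O

_RESULT_COLUMNS = [
    "tag",
    "x1",
    "x2",
    "N1",
    "N2",
    "theta1_hat",
    "theta2_hat",
    "direction",
    "p_fold",
    "significant",
]


def write_comparison(results: Sequence[ComparisonResult], path: str | Path) -> None:
    """Write per-tag comparison results as TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_RESULT_COLUMNS)
        for r in results:
            w.writerow(
                [
                    r.tag_seq,
                    r.x1,
                    r.x2,
                    r.N1,
                    r.N2,
                    f"{r.theta1_hat:.10g}",
                    f"{r.theta2_hat:.10g}",
                    r.direction,
                    f"{r.p_fold:.8g}",
                    int(r.significant),
                ]
            )


def read_comparison(path: str | Path) -> list[ComparisonResult]:
    """Load comparison results written by :func:`write_comparison`."""
    results = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            results.append(
                ComparisonResult(
                    tag_seq=row["tag"],
                    x1=int(row["x1"]),
                    x2=int(row["x2"]),
                    N1=int(row["N1"]),
                    N2=int(row["N2"]),
                    theta1_hat=float(row["theta1_hat"]),
                    theta2_hat=float(row["theta2_hat"]),
                    direction=row["direction"],
                    p_fold=float(row["p_fold"]),
                    significant=bool(int(row["significant"])),
                )
            )
    return results


def write_venn(summary: VennSummary, path: str | Path) -> None:
    """Write the Venn partition as TSV (region, count)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["region", "count"])
        for region, count in summary.regions.items():
            w.writerow([region, count])
        for name, total in summary.totals.items():
            w.writerow([f"total_{name}", total])
        w.writerow(["grand_union", summary.grand_union])
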