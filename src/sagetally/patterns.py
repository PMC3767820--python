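"""Tolerance-pattern classification of tag trajectories.

Innate-immune genes respond to a repeated stimulus in characteristic
ways: some are induced and stay inducible on restimulation
(non-tolerizeable), others lose their induction (tolerizeable).  Over
the three-condition design — naive (N), induced (one stimulus, N+PGN)
and tolerant (restimulated, T+PGN) — each tag's trajectory is classified
from two pairwise fold-change comparisons:

  leg 1: naive → induced       leg 2: induced → tolerant

  I    non-tolerizeable, amplified : up on leg 1, up again on leg 2
  II   tolerizeable                : up on leg 1, down on leg 2
  III  suppressed then induced     : down on leg 1, up on leg 2
  IV   progressively suppressed    : down on leg 1, down on leg 2

"Up"/"down" mean a *significant* call in that direction; anything else
leaves the tag unclassified.  The categories are mutually exclusive and,
with "unclassified", exhaustive.  The naive→tolerant comparison is not
used for classification (it is reported alongside, e.g. in the Venn
partition).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .bayes_de import DIRECTION_DOWN, DIRECTION_UP, ComparisonResult

CATEGORY_I = "I_non_tolerizeable_amplified"
CATEGORY_II = "II_tolerizeable"
CATEGORY_III = "III_suppressed_then_induced"
CATEGORY_IV = "IV_progressively_suppressed"
UNCLASSIFIED = "unclassified"

CATEGORIES = (CATEGORY_I, CATEGORY_II, CATEGORY_III, CATEGORY_IV)

# (leg1 significant direction, leg2 significant direction) -> category
_RULES: Mapping[tuple[str, str], str] = {
    (DIRECTION_UP, DIRECTION_UP): CATEGORY_I,
    (DIRECTION_UP, DIRECTION_DOWN): CATEGORY_II,
    (DIRECTION_DOWN, DIRECTION_UP): CATEGORY_III,
    (DIRECTION_DOWN, DIRECTION_DOWN): CATEGORY_IV,
}


@dataclass(frozen=True)
class PatternCall:
    """A tag's category with the two significance facts that produced it."""

    tag_seq: str
    category: str
    supporting: tuple[tuple[str, bool], tuple[str, bool]]


@dataclass(frozen=True)
class PatternSummary:
    """Category histogram with the trajectory-identity margins.

    The margins are exact arithmetic identities of the classification
    rule, asserted on construction:

      up_after_first_stimulus   = |I| + |II|
      down_after_first_stimulus = |III| + |IV|
      up_in_tolerant            = |I| + |III|
      down_in_tolerant          = |II| + |IV|
    """

    counts: dict[str, int]
    up_after_first_stimulus: int
    down_after_first_stimulus: int
    up_in_tolerant: int
    down_in_tolerant: int

    @property
    def n_classified(self) -> int:
        return sum(self.counts[c] for c in CATEGORIES)


def classify_tag(
    r_naive_induced: ComparisonResult,
    r_induced_tolerant: ComparisonResult,
) -> PatternCall:
    """Assign one tag to a tolerance category from its two trajectory legs.

    Both legs must be significant for any category; the (up/down)² table
    above decides which.  Deterministic; mismatched tags are an error.
    """
    if r_naive_induced.tag_seq != r_induced_tolerant.tag_seq:
        raise ValueError(
            f"mismatched tags: {r_naive_induced.tag_seq!r} vs "
            f"{r_induced_tolerant.tag_seq!r}"
        )
    leg1, leg2 = r_naive_induced, r_induced_tolerant
    supporting = (
        (leg1.direction, leg1.significant),
        (leg2.direction, leg2.significant),
    )
    category = UNCLASSIFIED
    if leg1.significant and leg2.significant:
        category = _RULES.get((leg1.direction, leg2.direction), UNCLASSIFIED)
    return PatternCall(
        tag_seq=leg1.tag_seq, category=category, supporting=supporting
    )


def classify_all(
    results_naive_induced: Sequence[ComparisonResult],
    results_induced_tolerant: Sequence[ComparisonResult],
) -> list[PatternCall]:
    """Classify every tag present in both comparisons, sorted by tag."""
    by_tag_1 = {r.tag_seq: r for r in results_naive_induced}
    by_tag_2 = {r.tag_seq: r for r in results_induced_tolerant}
    shared = sorted(set(by_tag_1) & set(by_tag_2))
    return [classify_tag(by_tag_1[t], by_tag_2[t]) for t in shared]


def summarize_patterns(calls: Iterable[PatternCall]) -> PatternSummary:
    """Histogram the calls and derive the trajectory margins.

    The four identities hold exactly on any input because each category
    contributes to exactly one "after first stimulus" margin and one
    "in tolerant" margin; they are re-checked here as a guard against
    rule drift.
    """
    counts = {c: 0 for c in (*CATEGORIES, UNCLASSIFIED)}
    for call in calls:
        counts[call.category] += 1
    summary = PatternSummary(
        counts=counts,
        up_after_first_stimulus=counts[CATEGORY_I] + counts[CATEGORY_II],
        down_after_first_stimulus=counts[CATEGORY_III] + counts[CATEGORY_IV],
        up_in_tolerant=counts[CATEGORY_I] + counts[CATEGORY_III],
        down_in_tolerant=counts[CATEGORY_II] + counts[CATEGORY_IV],
    )
    n_classified = summary.n_classified
    assert (
        summary.up_after_first_stimulus + summary.down_after_first_stimulus
        == n_classified
    )
    assert summary.up_in_tolerant + summary.down_in_tolerant == n_classified
    return summary


# ---------------------------------------------------------------------------
# I/O


def write_calls(calls: Sequence[PatternCall], path: str | Path) -> None:
    """Write pattern calls as TSV (tag, category)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag", "category"])
        for call in calls:
            w.writerow([call.tag_seq, call.category])


def write_summary(summary: PatternSummary, path: str | Path) -> None:
    """Write the category histogram and margins as TSV (metric, count)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["metric", "count"])
        for category, count in summary.counts.items():
            w.writerow([category, count])
        w.writerow(["up_after_first_stimulus", summary.up_after_first_stimulus])
        w.writerow(["down_after_first_stimulus", summary.down_after_first_stimulus])
        w.writerow(["up_in_tolerant", summary.up_in_tolerant])
        w.writerow(["down_in_tolerant", summary.down_in_tolerant])
        w.writerow(["n_classified", summary.n_classified])
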