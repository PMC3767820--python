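"""Observed-tag counting against a virtual tag library.

Reads are filtered structurally (length, CATG anchor, ambiguous bases),
truncated to 22 nt from the 5' end, and matched against the index with no
mismatches allowed — a read either hits exactly one 22 bp key or it is
unmapped.  Per-library results are "key-count distributions": a tag→count
table plus the total mapped count N, which the downstream Bayesian test
conditions on.

Filtering here is structural only.  Base qualities, when present in FASTQ
input, are parsed but unused by default; an optional mean-quality floor is
exposed as an extension point.

Bookkeeping invariant, enforced and property-tested:
``n_reads_in == n_reads_filtered + n_unmapped + N``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .tag_library import ANCHOR, TAG_LENGTH, TagLibraryIndex

REJECT_TOO_SHORT = "too_short"
REJECT_NO_ANCHOR = "no_anchor"
REJECT_AMBIGUOUS = "ambiguous_base"


@dataclass
class TagCountTable:
    """One library's tag→count map with mapping statistics."""

    library_name: str
    counts: dict[str, int] = field(default_factory=dict)
    n_reads_in: int = 0
    n_reads_filtered: int = 0
    n_unmapped: int = 0

    @property
    def N(self) -> int:
        """Total mapped tag count (the library size the statistic uses)."""
        return sum(self.counts.values())

    def validate(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative tag count")
        if self.n_reads_in != self.n_reads_filtered + self.n_unmapped + self.N:
            raise ValueError(
                f"read bookkeeping broken for {self.library_name!r}: "
                f"{self.n_reads_in} != {self.n_reads_filtered} + "
                f"{self.n_unmapped} + {self.N}"
            )


def filter_read(read: str) -> tuple[str | None, str | None]:
    """Structurally filter one read.

    Returns ``(tag, None)`` on acceptance — ``tag`` is the read truncated
    to 22 nt from the 5' end — or ``(None, reason)`` with reason one of
    ``too_short`` (under 22 nt), ``no_anchor`` (does not begin with CATG)
    or ``ambiguous_base`` (an N inside the 22 bp window).  Checks apply in
    that order.
    """
    if len(read) < TAG_LENGTH:
        return None, REJECT_TOO_SHORT
    tag = read[:TAG_LENGTH]
    if not tag.startswith(ANCHOR):
        return None, REJECT_NO_ANCHOR
    if "N" in tag:
        return None, REJECT_AMBIGUOUS
    return tag, None


def count_library(
    reads: Iterable[str],
    index: TagLibraryIndex,
    library_name: str,
) -> TagCountTable:
    """Count exact 22 bp matches of filtered reads against the index.

    Each accepted read increments exactly one tag on exact identity with
    an index key; accepted reads matching no key are tallied as unmapped.
    Counting is invariant under read order.
    """
    if len(index) == 0:
        raise ValueError("cannot count against an empty index")
    table = TagCountTable(library_name=library_name)
    counts = table.counts
    for read in reads:
        table.n_reads_in += 1
        tag, _reason = filter_read(read)
        if tag is None:
            table.n_reads_filtered += 1
        elif tag in index:
            counts[tag] = counts.get(tag, 0) + 1
        else:
            table.n_unmapped += 1
    table.validate()
    return table


def aggregate_by_gene(
    table: TagCountTable, index: TagLibraryIndex
) -> tuple[dict[str, int], set[str]]:
    """Roll tag counts up to genes, flagging ambiguous attribution.

    A multi-mapped tag's count is added in full to every gene it maps to —
    never split fractionally — and each such gene is flagged ambiguous so
    the information survives aggregation.  Returns (gene→count, flagged
    gene ids).  Tables must originate from counting against this index;
    a tag absent from the index is an error.
    """
    gene_counts: dict[str, int] = {}
    ambiguous: set[str] = set()
    for tag_seq, count in table.counts.items():
        if tag_seq not in index:
            raise KeyError(
                f"tag {tag_seq!r} not in index; table was not counted against it"
            )
        vt = index[tag_seq]
        for gene in vt.gene_ids:
            gene_counts[gene] = gene_counts.get(gene, 0) + count
            if vt.is_multimapped:
                ambiguous.add(gene)
    return gene_counts, ambiguous


# ---------------------------------------------------------------------------
# I/O


def read_tag_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from FASTQ (.fastq/.fq) or plain one-per-line text."""
    path = Path(path)
    if path.suffix.lower() in {".fastq", ".fq"}:
        for rec in SeqIO.parse(str(path), "fastq"):
            yield str(rec.seq).upper()
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    yield line.upper()


def write_count_table(table: TagCountTable, path: str | Path) -> None:
    """Write a count table as TSV (tag, count), sorted by tag."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag", "count"])
        for tag, count in sorted(table.counts.items()):
            w.writerow([tag, count])


def write_count_stats(table: TagCountTable, path: str | Path) -> None:
    """Write the mapping-statistics sidecar for one library."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["library", "n_reads_in", "n_reads_filtered", "n_unmapped", "N"])
        w.writerow(
            [
                table.library_name,
                table.n_reads_in,
                table.n_reads_filtered,
                table.n_unmapped,
                table.N,
            ]
        )


def read_count_table(path: str | Path, library_name: str | None = None) -> TagCountTable:
    """Load a (tag, count) TSV as a TagCountTable.

    Tables loaded this way carry no filtering statistics: n_reads_in is
    set to the mapped total so the bookkeeping invariant holds.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            counts[row["tag"]] = int(row["count"])
    name = library_name if library_name is not None else path.stem
    table = TagCountTable(library_name=name, counts=counts)
    table.n_reads_in = table.N
    table.validate()
    return table
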