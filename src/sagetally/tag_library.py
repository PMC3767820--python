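"""Virtual NlaIII tag library construction.

SAGE-Seq represents each transcript by short sequence tags anchored at
NlaIII restriction sites (recognition sequence CATG on the sense strand).
A *virtual tag* is the 4 bp anchor plus the 18 nt immediately 3' of it —
a 22 bp key against which observed reads are matched exactly.  This module
scans a transcriptome, extracts every such 22-mer and builds the lookup
index used for counting, keeping track of tags that map to more than one
transcript ("multi-mapped" tags).

Coordinates are 0-based throughout; a site offset points at the C of CATG.
Only the sense strand is scanned: SAGE tags derive from oriented cDNA.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO

ANCHOR = "CATG"
TAG_DOWNSTREAM = 18
TAG_LENGTH = len(ANCHOR) + TAG_DOWNSTREAM  # 22 bp exact-match key

_VALID_BASES = frozenset("ACGTN")

SitePolicy = Literal["all", "three-prime-most"]


@dataclass(frozen=True)
class Transcript:
    """One mRNA sequence with its identifiers.

    ``sequence`` must be uppercase DNA over {A, C, G, T, N}; anything else
    is rejected at construction time.
    """

    transcript_id: str
    sequence: str
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.transcript_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.transcript_id!r}: invalid bases {sorted(bad)}; "
                "sequences must be uppercase DNA over A/C/G/T/N"
            )


@dataclass
class VirtualTag:
    """A 22 bp CATG-anchored tag and every place it occurs.

    ``sources`` holds (transcript_id, site_offset) pairs; ``gene_ids`` the
    union of source gene ids.  A tag is multi-mapped iff it occurs in more
    than one distinct transcript.
    """

    tag_seq: str
    sources: set[tuple[str, int]] = field(default_factory=set)
    gene_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.tag_seq) != TAG_LENGTH or not self.tag_seq.startswith(ANCHOR):
            raise ValueError(
                f"tag must be {TAG_LENGTH} bp starting with {ANCHOR}: {self.tag_seq!r}"
            )

    @property
    def is_multimapped(self) -> bool:
        return len({tid for tid, _ in self.sources}) > 1


@dataclass
class TagLibraryIndex:
    """Exact-match lookup from 22 bp tag sequence to its VirtualTag record."""

    tags: dict[str, VirtualTag]
    n_fragments: int  # total extracted (tag, site) fragments, pre-merge

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    @property
    def n_multimapped(self) -> int:
        return sum(1 for t in self.tags.values() if t.is_multimapped)

    def __contains__(self, tag_seq: str) -> bool:
        return tag_seq in self.tags

    def __getitem__(self, tag_seq: str) -> VirtualTag:
        return self.tags[tag_seq]

    def __len__(self) -> int:
        return len(self.tags)


def find_nlaiii_sites(sequence: str) -> list[int]:
    """Return the 0-based offsets of every CATG occurrence, in order.

    Overlapping occurrences are all reported (CATG cannot overlap itself,
    but the scan advances one base at a time regardless).  N never matches.
    """
    sites: list[int] = []
    start = 0
    while True:
        i = sequence.find(ANCHOR, start)
        if i < 0:
            return sites
        sites.append(i)
        start = i + 1


def extract_virtual_tags(
    transcript: Transcript, site_policy: SitePolicy = "all"
) -> list[VirtualTag]:
    """Extract the candidate virtual tags of one transcript.

    Every CATG site with at least 18 nt strictly 3' of it yields one
    candidate tag (anchor + 18 nt).  Sites too close to the 3' end, or
    whose 22 bp window contains an N, yield nothing: a perfect-match
    mapper could never hit them.

    With ``site_policy="three-prime-most"`` only the 3'-most usable site
    is kept (classic LongSAGE convention); the default keeps all sites.
    """
    seq = transcript.sequence
    gene_ids = {transcript.gene_id} if transcript.gene_id else set()
    tags: list[VirtualTag] = []
    for offset in find_nlaiii_sites(seq):
        window = seq[offset : offset + TAG_LENGTH]
        if len(window) < TAG_LENGTH or "N" in window:
            continue
        tags.append(
            VirtualTag(
                tag_seq=window,
                sources={(transcript.transcript_id, offset)},
                gene_ids=set(gene_ids),
            )
        )
    if site_policy == "three-prime-most" and tags:
        tags = tags[-1:]
    return tags


def build_index(
    transcripts: Iterable[Transcript], site_policy: SitePolicy = "all"
) -> TagLibraryIndex:
    """Build the tag library index over a transcriptome.

    Fragments sharing a tag sequence are merged: sources are unioned and
    the multi-mapping flag follows from the merged sources.  The result is
    independent of transcript input order.  Duplicate transcript ids with
    differing sequences are ambiguous input and raise; exact duplicate
    records are ignored.
    """
    seen: dict[str, str] = {}
    merged: dict[str, VirtualTag] = {}
    n_fragments = 0
    n_transcripts = 0
    for t in transcripts:
        if t.transcript_id in seen:
            if seen[t.transcript_id] != t.sequence:
                raise ValueError(
                    f"duplicate transcript_id {t.transcript_id!r} with differing sequences"
                )
            continue
        seen[t.transcript_id] = t.sequence
        n_transcripts += 1
        for frag in extract_virtual_tags(t, site_policy=site_policy):
            n_fragments += 1
            entry = merged.get(frag.tag_seq)
            if entry is None:
                merged[frag.tag_seq] = frag
            else:
                entry.sources |= frag.sources
                entry.gene_ids |= frag.gene_ids
    if n_transcripts == 0:
        raise ValueError("build_index requires at least one transcript")
    return TagLibraryIndex(tags=dict(sorted(merged.items())), n_fragments=n_fragments)


# ---------------------------------------------------------------------------
# I/O


def read_transcripts(fasta_path: str | Path) -> list[Transcript]:
    """Load transcripts from FASTA.

    The record id is the transcript id; a ``gene=<id>`` token in the
    description, if present, supplies the gene id.  Sequences are
    uppercased on load; non-DNA characters are rejected.
    """
    transcripts = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id = None
        for token in rec.description.split():
            if token.startswith("gene="):
                gene_id = token[len("gene=") :]
        transcripts.append(
            Transcript(
                transcript_id=rec.id,
                sequence=str(rec.seq).upper(),
                gene_id=gene_id,
            )
        )
    if not transcripts:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return transcripts


def write_index(index: TagLibraryIndex, path: str | Path) -> None:
    """Serialize an index as TSV: tag, n_transcripts, transcript_ids, gene_ids, multimapped."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag", "n_transcripts", "transcript_ids", "gene_ids", "multimapped"])
        for tag_seq, tag in index.tags.items():
            tids = sorted({tid for tid, _ in tag.sources})
            w.writerow(
                [
                    tag_seq,
                    len(tids),
                    ";".join(f"{tid}:{off}" for tid, off in sorted(tag.sources)),
                    ";".join(sorted(tag.gene_ids)),
                    int(tag.is_multimapped),
                ]
            )


def read_index(path: str | Path) -> TagLibraryIndex:
    """Load an index written by :func:`write_index`."""
    tags: dict[str, VirtualTag] = {}
    n_fragments = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sources = set()
            for item in row["transcript_ids"].split(";"):
                tid, _, off = item.rpartition(":")
                sources.add((tid, int(off)))
            gene_ids = set(filter(None, row["gene_ids"].split(";")))
            tags[row["tag"]] = VirtualTag(
                tag_seq=row["tag"], sources=sources, gene_ids=gene_ids
            )
            n_fragments += len(sources)
    return TagLibraryIndex(tags=tags, n_fragments=n_fragments)
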