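"""Synthetic three-condition SAGE-Seq experiments with planted patterns.

Emulates the naive / induced / tolerant three-library design: a toy
transcriptome is generated with exactly one NlaIII tag planted at the
3' end of each transcript, each tag is assigned a trajectory pattern
(I–IV or null), per-condition true tag proportions are constructed with
the planted fold steps, and each library is a multinomial draw of fixed
depth from its condition's proportion vector.  Downstream stages —
library building, counting, the Bayesian test, pattern classification —
can then be exercised end to end with a known answer key.

Pattern shapes (relative abundance across naive, induced, tolerant; f is
the fold effect):

    I    (1,  f, f²)   induced, then amplified
    II   (1,  f, 1)    induced, then lost
    III  (f,  1, f)    suppressed, then restored
    IV   (f², f, 1)    progressively suppressed
    null (1,  1, 1)    unchanged

Per-pattern base abundances are solved so that the three condition
columns have *equal* total mass.  This matters: proportions are masses
divided by the column total, so unequal totals would silently rescale
every planted fold step and make null tags differ between conditions.
The balance constraints are m_I = m_IV and m_II = m_III + (f−1)·m_I,
where m_k is pattern k's total mass; fraction combinations that cannot
satisfy them (e.g. pattern I planted without pattern IV) are rejected
with an explicit error.  Under the balanced construction every planted
step equals the fold effect exactly and null tags are exactly equal
across conditions.

A single integer seed drives everything through derived, independent
streams (numpy SeedSequence spawning: child 0 → transcriptome, child 1 →
library counts, child 2 → read-level noise), so identical seeds give
byte-identical fixtures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tag_library import ANCHOR, TAG_DOWNSTREAM, TAG_LENGTH, Transcript
from .tag_quant import TagCountTable, read_count_table

CONDITIONS = ("naive", "induced", "tolerant")
PATTERN_LABELS = ("I", "II", "III", "IV", "null")

DEFAULT_PATTERN_FRACTIONS = {
    "I": 0.10,
    "II": 0.20,
    "III": 0.10,
    "IV": 0.05,
    "null": 0.55,
}

_BASES = np.array(list("ACGT"))


def _pattern_shapes(f: float) -> dict[str, tuple[float, float, float]]:
    return {
        "I": (1.0, f, f * f),
        "II": (1.0, f, 1.0),
        "III": (f, 1.0, f),
        "IV": (f * f, f, 1.0),
        "null": (1.0, 1.0, 1.0),
    }


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic experiment.

    Defaults are the standard study conditions used throughout the test
    suite: 500 transcripts of 200–400 nt (one planted tag each, matching
    the roughly one-NlaIII-site-per-200–300-nt spacing of real
    transcripts), three libraries of 2·10⁵ tags, a 4-fold planted effect
    per trajectory step, and pattern fractions
    (I, II, III, IV, null) = (0.10, 0.20, 0.10, 0.05, 0.55).
    """

    n_transcripts: int = 500
    transcript_length_range: tuple[int, int] = (200, 400)
    depth_per_library: int = 200_000
    pattern_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_FRACTIONS)
    )
    fold_effect: float = 4.0
    seed: int = 0
    collision_free: bool = True
    multimap: bool = False

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        lo, hi = self.transcript_length_range
        if lo < TAG_LENGTH or hi < lo:
            raise ValueError(
                f"transcript lengths must satisfy {TAG_LENGTH} <= min <= max"
            )
        if self.depth_per_library < 0:
            raise ValueError("depth_per_library must be >= 0")
        if self.fold_effect <= 1.0:
            raise ValueError("fold_effect must be > 1")
        unknown = set(self.pattern_fractions) - set(PATTERN_LABELS)
        if unknown:
            raise ValueError(f"unknown pattern labels: {sorted(unknown)}")
        total = sum(self.pattern_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.pattern_fractions.values()):
            raise ValueError("pattern_fractions must be non-negative")
        if self.multimap and self.n_transcripts < 2:
            raise ValueError("multimap mode needs at least 2 transcripts")

    def seed_sequences(self) -> list[np.random.SeedSequence]:
        """The three derived streams: transcriptome, counts, noise."""
        return np.random.SeedSequence(self.seed).spawn(3)


@dataclass
class GroundTruth:
    """The answer key: per-tag true proportions and planted pattern labels.

    ``table`` columns: tag, transcript_id, pattern, p_naive, p_induced,
    p_tolerant.  Within each condition the proportions sum to 1.
    """

    table: pd.DataFrame
    fold_effect: float

    def validate(self, tol: float = 1e-9, check_patterns: bool = True) -> None:
        cols = [f"p_{c}" for c in CONDITIONS]
        sums = self.table[cols].sum()
        if not np.allclose(sums, 1.0, atol=tol, rtol=0):
            raise ValueError(f"condition proportions must sum to 1, got {dict(sums)}")
        if not check_patterns:
            return
        f = self.fold_effect * (1.0 - 1e-9)
        for _, row in self.table.iterrows():
            pn, pi, pt = (row[c] for c in cols)
            label = row["pattern"]
            ok = {
                "I": pi >= f * pn and pt >= f * pi,
                "II": pi >= f * pn and pt <= pi / f * (1 + 1e-9),
                "III": pi <= pn / f * (1 + 1e-9) and pt >= f * pi,
                "IV": pn >= f * pi and pi >= f * pt,
                "null": np.isclose(pn, pi, rtol=1e-9) and np.isclose(pi, pt, rtol=1e-9),
            }[label]
            if not ok:
                raise ValueError(f"tag {row['tag']}: pattern {label} invariant violated")

    def proportions(self, condition: str) -> np.ndarray:
        return self.table[f"p_{condition}"].to_numpy()

    def expected_counts(self, depth: int) -> pd.DataFrame:
        """Expected tag counts per condition at a given library depth."""
        out = self.table[["tag", "pattern"]].copy()
        for c in CONDITIONS:
            out[c] = self.table[f"p_{c}"] * depth
        return out


# ---------------------------------------------------------------------------
# Transcriptome construction


def _scrub_anchor(seq: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate the C of every CATG occurrence in-place until none remain.

    Replacements are drawn from {A, T}: neither can complete a new CATG
    overlapping the edited window, so the loop terminates quickly.
    """
    s = "".join(seq)
    while True:
        i = s.find(ANCHOR)
        if i < 0:
            return
        seq[i] = rng.choice(["A", "T"])
        s = "".join(seq)


def simulate_transcriptome(spec: SimulationSpec) -> list[Transcript]:
    """Generate the toy transcriptome with one planted 3' tag per transcript.

    Each transcript is random sequence scrubbed of CATG, followed by a
    planted CATG + 18 nt tag flush with the 3' end — so the planted site
    is the only usable NlaIII site and tag↔transcript is bijective.  In
    collision-free mode (default) planted 22-mers are globally distinct;
    multimap mode then copies transcript 1's tag into transcript 2 to
    exercise multi-mapping downstream.  Identical seeds give identical
    output.
    """
    rng = np.random.default_rng(spec.seed_sequences()[0])
    lo, hi = spec.transcript_length_range
    seen: set[str] = set()
    transcripts: list[Transcript] = []
    for i in range(spec.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        for _attempt in range(1000):
            tag18 = "".join(rng.choice(_BASES, size=TAG_DOWNSTREAM))
            tag = ANCHOR + tag18
            if not spec.collision_free or tag not in seen:
                break
        else:
            raise RuntimeError(
                "collision-free construction failed: could not draw "
                f"{spec.n_transcripts} distinct {TAG_LENGTH}-mers at the "
                "requested transcript count"
            )
        seen.add(tag)
        prefix = rng.choice(_BASES, size=length - TAG_LENGTH)
        _scrub_anchor(prefix, rng)
        transcripts.append(
            Transcript(
                transcript_id=f"T{i:05d}",
                gene_id=f"G{i:05d}",
                sequence="".join(prefix) + tag,
            )
        )
    if spec.multimap:
        # duplicate transcript 0's tag into transcript 1 (shared 22-mer)
        t0, t1 = transcripts[0], transcripts[1]
        transcripts[1] = Transcript(
            transcript_id=t1.transcript_id,
            gene_id=t1.gene_id,
            sequence=t1.sequence[:-TAG_LENGTH] + t0.sequence[-TAG_LENGTH:],
        )
    return transcripts


def planted_tag(transcript: Transcript) -> str:
    """The 3'-terminal 22-mer a simulated transcript was built around."""
    return transcript.sequence[-TAG_LENGTH:]


# ---------------------------------------------------------------------------
# Ground truth


def _pattern_counts(spec: SimulationSpec) -> dict[str, int]:
    """Integer tag counts per pattern by largest-remainder apportionment."""
    n = spec.n_transcripts
    raw = {k: spec.pattern_fractions.get(k, 0.0) * n for k in PATTERN_LABELS}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def _base_masses(counts: dict[str, int], f: float) -> dict[str, float]:
    """Per-tag base abundance solving the column-balance constraints."""
    n1, n2, n3, n4 = counts["I"], counts["II"], counts["III"], counts["IV"]
    if (n1 > 0) != (n4 > 0):
        raise ValueError(
            "cannot balance condition totals: patterns I and IV must be "
            "planted together (or both absent)"
        )
    b = {"null": 1.0, "I": 1.0, "III": 1.0, "IV": 0.0, "II": 0.0}
    if n4 > 0:
        b["IV"] = n1 / n4  # m_I = m_IV
    m2 = n3 * b["III"] + (f - 1.0) * n1 * b["I"]  # m_II = m_III + (f-1) m_I
    if n2 > 0:
        if m2 <= 0:
            raise ValueError(
                "cannot balance condition totals: pattern II requires "
                "pattern III or I to be planted as well"
            )
        b["II"] = m2 / n2
    elif m2 > 0:
        raise ValueError(
            "cannot balance condition totals: patterns I/III require a "
            "non-zero pattern II fraction to absorb their induced-phase mass"
        )
    return b


def make_ground_truth(
    spec: SimulationSpec, transcripts: list[Transcript]
) -> GroundTruth:
    """Assign patterns and balanced true proportions to the planted tags."""
    counts = _pattern_counts(spec)
    base = _base_masses(counts, spec.fold_effect)
    shapes = _pattern_shapes(spec.fold_effect)

    labels: list[str] = []
    for k in PATTERN_LABELS:
        labels.extend([k] * counts[k])

    rows = []
    for t, label in zip(transcripts, labels):
        b = base[label]
        shape = shapes[label]
        rows.append(
            {
                "tag": planted_tag(t),
                "transcript_id": t.transcript_id,
                "pattern": label,
                "p_naive": b * shape[0],
                "p_induced": b * shape[1],
                "p_tolerant": b * shape[2],
            }
        )
    table = pd.DataFrame(rows)
    if table["tag"].duplicated().any():
        if not spec.multimap:
            raise ValueError("duplicate planted tags in collision-free mode")
        # multimap mode: the deliberately shared tag is one observable unit;
        # merge its rows (abundance adds, first transcript's pattern kept)
        table = table.groupby("tag", as_index=False, sort=False).agg(
            transcript_id=("transcript_id", ";".join),
            pattern=("pattern", "first"),
            p_naive=("p_naive", "sum"),
            p_induced=("p_induced", "sum"),
            p_tolerant=("p_tolerant", "sum"),
        )[["tag", "transcript_id", "pattern", "p_naive", "p_induced", "p_tolerant"]]
    for c in CONDITIONS:
        col = f"p_{c}"
        table[col] = table[col] / table[col].sum()
    truth = GroundTruth(table=table, fold_effect=spec.fold_effect)
    # a merged multimap tag can mix pattern shapes, so only check sums there
    truth.validate(check_patterns=not spec.multimap)
    return truth


# ---------------------------------------------------------------------------
# Count simulation


def simulate_counts(
    truth: GroundTruth, depth_per_library: int, seed: int | np.random.SeedSequence
) -> dict[str, TagCountTable]:
    """Draw the three libraries as fixed-depth multinomials.

    Sampling is multinomial per library rather than Poisson: library
    totals are fixed, matching the fixed-N conditioning of the
    fold-change statistic.  Per-library totals equal the depth exactly.
    """
    rng = np.random.default_rng(seed)
    tags = truth.table["tag"].to_list()
    tables: dict[str, TagCountTable] = {}
    for condition in CONDITIONS:
        p = truth.proportions(condition)
        total = p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{condition} proportions sum to {total}, expected 1 within 1e-9"
            )
        draw = rng.multinomial(depth_per_library, p / total)
        counts = {tag: int(c) for tag, c in zip(tags, draw) if c > 0}
        table = TagCountTable(library_name=condition, counts=counts)
        table.n_reads_in = table.N
        table.validate()
        tables[condition] = table
    return tables


def simulate_experiment(
    spec: SimulationSpec,
) -> tuple[list[Transcript], GroundTruth, dict[str, TagCountTable]]:
    """Transcriptome + ground truth + three count libraries in one call."""
    transcripts = simulate_transcriptome(spec)
    truth = make_ground_truth(spec, transcripts)
    tables = simulate_counts(truth, spec.depth_per_library, spec.seed_sequences()[1])
    return transcripts, truth, tables


def table_to_reads(
    table: TagCountTable,
    rng: np.random.Generator | None = None,
    noise_rate: float = 0.0,
) -> list[str]:
    """Expand a count table into raw read sequences.

    Each tag is emitted once per count.  With an rng, reads are shuffled
    and, at a positive noise rate, bases are substituted uniformly — a
    stress input for the structural filter and perfect-match mapper, not
    an error-model emulation.
    """
    reads: list[str] = []
    for tag, count in sorted(table.counts.items()):
        reads.extend([tag] * count)
    if rng is not None:
        rng.shuffle(reads)
        if noise_rate > 0.0:
            for i, read in enumerate(reads):
                mask = rng.random(len(read)) < noise_rate
                if mask.any():
                    arr = np.array(list(read))
                    arr[mask] = rng.choice(_BASES, size=int(mask.sum()))
                    reads[i] = "".join(arr)
    return reads


# ---------------------------------------------------------------------------
# Fixture I/O


def write_transcripts_fasta(transcripts: list[Transcript], path: str | Path) -> None:
    """Write transcripts as FASTA with '>{id} gene={gene}' headers."""
    with open(path, "w") as fh:
        for t in transcripts:
            header = t.transcript_id
            if t.gene_id:
                header += f" gene={t.gene_id}"
            fh.write(f">{header}\n{t.sequence}\n")


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tag", "transcript_id", "pattern", "p_naive", "p_induced", "p_tolerant"])
        for _, row in truth.table.iterrows():
            w.writerow(
                [
                    row["tag"],
                    row["transcript_id"],
                    row["pattern"],
                    repr(float(row["p_naive"])),
                    repr(float(row["p_induced"])),
                    repr(float(row["p_tolerant"])),
                ]
            )


def read_truth(path: str | Path, fold_effect: float) -> GroundTruth:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"tag": str, "transcript_id": str, "pattern": str},
        keep_default_na=False,  # the pattern label "null" is a literal string
        float_precision="round_trip",
    )
    return GroundTruth(table=table, fold_effect=fold_effect)


def write_fixture(
    transcripts: list[Transcript],
    tables: dict[str, TagCountTable],
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + three count TSVs + truth TSV; round-trips losslessly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": out / "transcripts.fasta", "truth": out / "truth.tsv"}
    write_transcripts_fasta(transcripts, paths["fasta"])
    write_truth(truth, paths["truth"])
    from .tag_quant import write_count_table

    for condition, table in tables.items():
        p = out / f"counts_{condition}.tsv"
        write_count_table(table, p)
        paths[f"counts_{condition}"] = p
    return paths


def read_fixture(
    out_dir: str | Path, fold_effect: float = 4.0
) -> tuple[list[Transcript], GroundTruth, dict[str, TagCountTable]]:
    """Load a fixture written by :func:`write_fixture`."""
    from .tag_library import read_transcripts

    out = Path(out_dir)
    transcripts = read_transcripts(out / "transcripts.fasta")
    truth = read_truth(out / "truth.tsv", fold_effect=fold_effect)
    tables = {
        c: read_count_table(out / f"counts_{c}.tsv", library_name=c)
        for c in CONDITIONS
    }
    return transcripts, truth, tables
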