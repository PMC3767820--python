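"""End-to-end orchestration of the SAGE-Seq analysis stages.

One run directory holds every stage output — simulated fixture (when a
simulation block is configured), the virtual tag library, per-library
counts and mapping stats, the three pairwise comparisons, the Venn
partition, the pattern calls and, optionally, term enrichment — plus a
manifest of SHA-256 checksums.  Identical config + seed reproduces
identical checksums; a completed run directory is a no-op to re-run
unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import bayes_de, enrichment, patterns, synthetic, tag_library, tag_quant
from .synthetic import CONDITIONS, SimulationSpec

logger = logging.getLogger("sagetally")

MANIFEST_NAME = "manifest.json"

COMPARISON_PAIRS = (
    ("naive", "induced"),
    ("naive", "tolerant"),
    ("induced", "tolerant"),
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Either ``simulation`` is set (the fixture is generated) or ``fasta``
    and per-condition ``reads`` paths are supplied.  ``bayes`` carries the
    fold-change test parameters; ``site_policy`` is forwarded to library
    construction; ``annotations`` (optional) enables the enrichment stage
    on the genes of classified tags.
    """

    out_dir: Path
    seed: int = 0
    site_policy: str = "all"
    simulation: SimulationSpec | None = None
    fasta: Path | None = None
    reads: dict[str, Path] = field(default_factory=dict)
    bayes: bayes_de.BayesConfig = field(default_factory=bayes_de.BayesConfig)
    annotations: Path | None = None
    config_path: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        sim = None
        if "simulation" in raw:
            sim_kwargs = dict(raw["simulation"] or {})
            sim_kwargs.setdefault("seed", raw.get("seed", 0))
            if "transcript_length_range" in sim_kwargs:
                sim_kwargs["transcript_length_range"] = tuple(
                    sim_kwargs["transcript_length_range"]
                )
            sim = SimulationSpec(**sim_kwargs)
        inputs = raw.get("inputs") or {}
        cfg = cls(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            site_policy=raw.get("site_policy", "all"),
            simulation=sim,
            fasta=Path(inputs["fasta"]) if "fasta" in inputs else None,
            reads={k: Path(v) for k, v in (inputs.get("reads") or {}).items()},
            bayes=bayes_de.BayesConfig(**(raw.get("bayes") or {})),
            annotations=Path(raw["annotations"]) if raw.get("annotations") else None,
            config_path=path,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulation is None:
            if self.fasta is None:
                raise PipelineError(
                    "config needs either a 'simulation' block or inputs.fasta"
                )
            missing = [c for c in CONDITIONS if c not in self.reads]
            if missing:
                raise PipelineError(
                    f"config missing inputs.reads for conditions: {missing}"
                )
            for p in [self.fasta, *self.reads.values(), self.annotations]:
                if p is not None and not Path(p).exists():
                    raise PipelineError(f"input file does not exist: {p}")
        elif self.annotations is not None and not Path(self.annotations).exists():
            raise PipelineError(f"input file does not exist: {self.annotations}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, force: bool = False) -> dict[str, Any]:
    """Execute all stages in dependency order; returns the manifest.

    Stage outputs land in ``config.out_dir``; any stage failure raises
    :class:`PipelineError` naming the stage, with partial outputs left in
    place for debugging.  A directory whose manifest already exists is
    returned as-is unless ``force``.
    """
    out = Path(config.out_dir)
    manifest_path = out / MANIFEST_NAME
    if manifest_path.exists() and not force:
        logger.info("run directory %s already complete; skipping (use force)", out)
        with open(manifest_path) as fh:
            return json.load(fh)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        return _StageGuard(name)

    # -- simulate -----------------------------------------------------------
    with stage("simulate"):
        if config.simulation is not None:
            spec = config.simulation
            transcripts, truth, tables = synthetic.simulate_experiment(spec)
            paths = synthetic.write_fixture(transcripts, tables, truth, out)
            artifacts.update(paths)
            noise_rng = np.random.default_rng(spec.seed_sequences()[2])
            reads_paths = {}
            for condition in CONDITIONS:
                reads = synthetic.table_to_reads(tables[condition], rng=noise_rng)
                p = out / f"reads_{condition}.txt"
                p.write_text("\n".join(reads) + ("\n" if reads else ""))
                reads_paths[condition] = p
            fasta_path = paths["fasta"]
            logger.info(
                "simulated %d transcripts, %d tags/library",
                len(transcripts),
                spec.depth_per_library,
            )
        else:
            fasta_path = Path(config.fasta)
            reads_paths = {c: Path(p) for c, p in config.reads.items()}

    # -- build the virtual tag library --------------------------------------
    with stage("build-library"):
        transcripts = tag_library.read_transcripts(fasta_path)
        index = tag_library.build_index(transcripts, site_policy=config.site_policy)
        index_path = out / "tag_library.tsv"
        tag_library.write_index(index, index_path)
        artifacts["tag_library"] = index_path
        logger.info(
            "%d fragments -> %d tags (%d multimapped)",
            index.n_fragments,
            index.n_tags,
            index.n_multimapped,
        )

    # -- count each library --------------------------------------------------
    tables = {}
    with stage("count"):
        for condition in CONDITIONS:
            reads = tag_quant.read_tag_sequences(reads_paths[condition])
            table = tag_quant.count_library(reads, index, condition)
            tables[condition] = table
            cpath = out / f"table_{condition}.tsv"
            spath = out / f"stats_{condition}.tsv"
            tag_quant.write_count_table(table, cpath)
            tag_quant.write_count_stats(table, spath)
            artifacts[f"table_{condition}"] = cpath
            artifacts[f"stats_{condition}"] = spath
            logger.info(
                "%s: in=%d filtered=%d unmapped=%d N=%d",
                condition,
                table.n_reads_in,
                table.n_reads_filtered,
                table.n_unmapped,
                table.N,
            )

    # -- pairwise comparisons and Venn ---------------------------------------
    comparisons = {}
    with stage("compare"):
        for a, b in COMPARISON_PAIRS:
            results = bayes_de.compare_libraries(tables[a], tables[b], config.bayes)
            comparisons[(a, b)] = results
            p = out / f"compare_{a}_vs_{b}.tsv"
            bayes_de.write_comparison(results, p)
            artifacts[f"compare_{a}_vs_{b}"] = p
            n_sig = sum(r.significant for r in results)
            logger.info("%s vs %s: %d tags, %d significant", a, b, len(results), n_sig)

    with stage("venn"):
        summary = bayes_de.venn_summary(
            comparisons[("naive", "induced")],
            comparisons[("naive", "tolerant")],
            comparisons[("induced", "tolerant")],
        )
        p = out / "venn.tsv"
        bayes_de.write_venn(summary, p)
        artifacts["venn"] = p

    # -- tolerance-pattern classification ------------------------------------
    with stage("classify"):
        calls = patterns.classify_all(
            comparisons[("naive", "induced")], comparisons[("induced", "tolerant")]
        )
        pattern_summary = patterns.summarize_patterns(calls)
        calls_path = out / "pattern_calls.tsv"
        summary_path = out / "pattern_summary.tsv"
        patterns.write_calls(calls, calls_path)
        patterns.write_summary(pattern_summary, summary_path)
        artifacts["pattern_calls"] = calls_path
        artifacts["pattern_summary"] = summary_path
        logger.info(
            "classified %d/%d tags", pattern_summary.n_classified, len(calls)
        )

    # -- optional enrichment of classified genes -----------------------------
    with stage("enrich"):
        if config.annotations is not None:
            annotation_map = enrichment.read_annotation_map(config.annotations)
            study = sorted(
                {
                    gene
                    for call in calls
                    if call.category != patterns.UNCLASSIFIED and call.tag_seq in index
                    for gene in index[call.tag_seq].gene_ids
                }
            )
            results = enrichment.enrich(study, annotation_map)
            p = out / "enrichment.tsv"
            enrichment.write_enrichment(results, p)
            artifacts["enrichment"] = p

    # -- manifest -------------------------------------------------------------
    with stage("manifest"):
        if config.config_path is not None:
            echoed = out / "config.yaml"
            if Path(config.config_path).resolve() != echoed.resolve():
                shutil.copyfile(config.config_path, echoed)
            artifacts["config"] = echoed
        manifest = {
            "seed": config.seed,
            "artifacts": {
                name: {"path": path.name, "sha256": _sha256(path)}
                for name, path in sorted(artifacts.items())
            },
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest


class _StageGuard:
    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self) -> "_StageGuard":
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc is not None and not isinstance(exc, PipelineError):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
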