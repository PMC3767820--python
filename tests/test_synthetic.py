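"""The synthetic three-library generator: determinism, planted truth, sampling."""

import math

import numpy as np
import pytest

from sagetally import (
    GroundTruth,
    SimulationSpec,
    build_index,
    extract_virtual_tags,
    make_ground_truth,
    simulate_counts,
    simulate_experiment,
    simulate_transcriptome,
    write_fixture,
)
from sagetally.synthetic import (
    CONDITIONS,
    planted_tag,
    read_fixture,
    write_transcripts_fasta,
)
from sagetally.tag_library import TAG_LENGTH


class TestSpecValidation:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationSpec(pattern_fractions={"I": 0.5, "null": 0.4})

    def test_fold_effect_must_exceed_one(self):
        with pytest.raises(ValueError):
            SimulationSpec(fold_effect=1.0)

    def test_lengths_must_hold_a_tag(self):
        with pytest.raises(ValueError):
            SimulationSpec(transcript_length_range=(10, 40))

    def test_unknown_pattern_label_rejected(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            SimulationSpec(pattern_fractions={"V": 1.0})


class TestSimulateTranscriptome:
    def test_single_short_transcript_construction(self):
        spec = SimulationSpec(
            n_transcripts=1, transcript_length_range=(40, 40), seed=7,
            pattern_fractions={"null": 1.0},
        )
        (t,) = simulate_transcriptome(spec)
        assert len(t.sequence) == 40
        i = t.sequence.find("CATG")
        assert i >= 0 and len(t.sequence) - (i + 4) >= 18

    def test_seeded_determinism_is_byte_identical(self, tmp_path):
        spec = SimulationSpec(n_transcripts=10, seed=7)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_transcripts_fasta(simulate_transcriptome(spec), p1)
        write_transcripts_fasta(simulate_transcriptome(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_fifty_transcripts_all_tags_distinct(self):
        spec = SimulationSpec(
            n_transcripts=50, transcript_length_range=(200, 400), seed=1
        )
        transcripts = simulate_transcriptome(spec)
        assert len(transcripts) == 50
        tags = [
            frag.tag_seq for t in transcripts for frag in extract_virtual_tags(t)
        ]
        assert len(tags) == 50  # exactly one usable site per transcript
        assert len(set(tags)) == len(tags)

    def test_multimap_mode_duplicates_one_tag(self):
        spec = SimulationSpec(n_transcripts=10, seed=2, multimap=True)
        transcripts = simulate_transcriptome(spec)
        index = build_index(transcripts)
        assert index.n_multimapped == 1
        assert planted_tag(transcripts[0]) == planted_tag(transcripts[1])


class TestGroundTruth:
    def test_proportions_sum_to_one_and_invariants_hold(self, default_experiment):
        _, truth, _ = default_experiment
        truth.validate()  # raises on violation
        for c in CONDITIONS:
            assert truth.table[f"p_{c}"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_fold_steps_are_exact(self, default_experiment, default_spec):
        _, truth, _ = default_experiment
        f = default_spec.fold_effect
        t = truth.table
        i_rows = t[t.pattern == "I"]
        assert np.allclose(i_rows.p_induced / i_rows.p_naive, f)
        assert np.allclose(i_rows.p_tolerant / i_rows.p_induced, f)
        iv_rows = t[t.pattern == "IV"]
        assert np.allclose(iv_rows.p_naive / iv_rows.p_induced, f)
        null_rows = t[t.pattern == "null"]
        assert np.allclose(null_rows.p_naive, null_rows.p_induced)
        assert np.allclose(null_rows.p_induced, null_rows.p_tolerant)

    def test_unbalanceable_fractions_rejected(self):
        spec = SimulationSpec(
            n_transcripts=20, seed=0,
            pattern_fractions={"I": 0.5, "null": 0.5},
        )
        transcripts = simulate_transcriptome(spec)
        with pytest.raises(ValueError, match="balance"):
            make_ground_truth(spec, transcripts)

    def test_pattern_counts_follow_fractions(self, default_experiment, default_spec):
        _, truth, _ = default_experiment
        counts = truth.table["pattern"].value_counts()
        n = default_spec.n_transcripts
        for label, frac in default_spec.pattern_fractions.items():
            assert counts.get(label, 0) == round(frac * n)


class TestSimulateCounts:
    def one_tag_truth(self):
        import pandas as pd

        table = pd.DataFrame(
            [{"tag": "CATG" + "A" * 18, "transcript_id": "t1", "pattern": "null",
              "p_naive": 1.0, "p_induced": 1.0, "p_tolerant": 1.0}]
        )
        return GroundTruth(table=table, fold_effect=4.0)

    def test_degenerate_multinomial(self):
        tables = simulate_counts(self.one_tag_truth(), 100, seed=0)
        for t in tables.values():
            assert t.counts == {"CATG" + "A" * 18: 100}
            assert t.N == 100

    def test_zero_depth(self):
        tables = simulate_counts(self.one_tag_truth(), 0, seed=0)
        for t in tables.values():
            assert t.counts == {} and t.N == 0

    def test_totals_equal_depth_exactly(self, default_experiment, default_spec):
        _, _, tables = default_experiment
        for t in tables.values():
            assert t.N == default_spec.depth_per_library

    def test_binomial_moments_at_half_half(self):
        import pandas as pd

        table = pd.DataFrame(
            [
                {"tag": "CATG" + "A" * 18, "transcript_id": "t1", "pattern": "null",
                 "p_naive": 0.5, "p_induced": 0.5, "p_tolerant": 0.5},
                {"tag": "CATG" + "C" * 18, "transcript_id": "t2", "pattern": "null",
                 "p_naive": 0.5, "p_induced": 0.5, "p_tolerant": 0.5},
            ]
        )
        truth = GroundTruth(table=table, fold_effect=4.0)
        depth = 10**5
        sd = math.sqrt(depth * 0.25)
        tables = simulate_counts(truth, depth, seed=42)
        for t in tables.values():
            for count in t.counts.values():
                assert abs(count - depth / 2) <= 5 * sd

    def test_bad_proportions_rejected(self):
        truth = self.one_tag_truth()
        truth.table.loc[0, "p_naive"] = 0.5
        with pytest.raises(ValueError, match="sum"):
            simulate_counts(truth, 10, seed=0)

    def test_seeded_determinism(self, default_experiment, default_spec):
        _, truth, tables = default_experiment
        again = simulate_counts(
            truth, default_spec.depth_per_library, default_spec.seed_sequences()[1]
        )
        for c in CONDITIONS:
            assert again[c].counts == tables[c].counts


class TestFixtureIO:
    def test_round_trip(self, tmp_path):
        spec = SimulationSpec(n_transcripts=30, depth_per_library=2000, seed=5)
        transcripts, truth, tables = simulate_experiment(spec)
        write_fixture(transcripts, tables, truth, tmp_path)
        r_transcripts, r_truth, r_tables = read_fixture(tmp_path, spec.fold_effect)
        assert [(t.transcript_id, t.gene_id, t.sequence) for t in r_transcripts] == [
            (t.transcript_id, t.gene_id, t.sequence) for t in transcripts
        ]
        assert r_truth.table["tag"].tolist() == truth.table["tag"].tolist()
        for c in CONDITIONS:
            assert np.allclose(
                r_truth.table[f"p_{c}"], truth.table[f"p_{c}"], rtol=0, atol=0
            )
            assert r_tables[c].counts == tables[c].counts
        r_truth.validate()

    def test_empty_truth_writes_header_only(self, tmp_path):
        import pandas as pd

        from sagetally.synthetic import write_truth

        empty = GroundTruth(
            table=pd.DataFrame(
                columns=["tag", "transcript_id", "pattern",
                         "p_naive", "p_induced", "p_tolerant"]
            ),
            fold_effect=4.0,
        )
        path = tmp_path / "truth.tsv"
        write_truth(empty, path)
        assert path.read_text() == (
            "tag\ttranscript_id\tpattern\tp_naive\tp_induced\tp_tolerant\n"
        )

    def test_fixture_regeneration_is_identical(self, tmp_path):
        spec = SimulationSpec(n_transcripts=15, depth_per_library=500, seed=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            transcripts, truth, tables = simulate_experiment(spec)
            write_fixture(transcripts, tables, truth, d)
        for name in ("transcripts.fasta", "truth.tsv", "counts_naive.tsv",
                     "counts_induced.tsv", "counts_tolerant.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_planted_tags_have_anchor_and_length(default_experiment):
    transcripts, truth, _ = default_experiment
    for tag in truth.table["tag"]:
        assert len(tag) == TAG_LENGTH and tag.startswith("CATG")
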