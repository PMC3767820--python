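"""The Bayesian fold-change statistic, pairwise comparison and Venn partition."""

import random

import numpy as np
import pytest

from sagetally import (
    BayesConfig,
    ComparisonResult,
    compare_libraries,
    fold_probability,
    venn_summary,
)
from sagetally.bayes_de import read_comparison, write_comparison
from sagetally.tag_quant import TagCountTable


def mc_fold_probability(x1, N1, x2, N2, R=2.0, a=2.0, b=2.0, n=200_000, seed=0):
    """Monte-Carlo oracle: independent beta draws, frequency of the fold event."""
    rng = np.random.default_rng(seed)
    t1 = rng.beta(x1 + a, N1 - x1 + b, n)
    t2 = rng.beta(x2 + a, N2 - x2 + b, n)
    return float(np.mean((t2 >= R * t1) | (t1 >= R * t2)))


def make_table(name, counts, pad_to=None):
    """A count table with an optional filler tag to set the total N."""
    counts = dict(counts)
    if pad_to is not None:
        filler = "CATG" + "T" * 18
        counts[filler] = pad_to - sum(counts.values())
    t = TagCountTable(library_name=name, counts=counts)
    t.n_reads_in = t.N
    return t


class TestFoldProbability:
    def test_unit_fold_factor_makes_event_certain(self):
        # R=1 two-sided covers the whole space up to a null set
        cfg = BayesConfig(fold_factor=1.0)
        for x1, N1, x2, N2 in [(0, 10, 0, 10), (3, 50, 40, 60), (100, 1000, 1, 1000)]:
            assert fold_probability(x1, N1, x2, N2, cfg) == pytest.approx(1.0, abs=1e-5)

    def test_two_sided_symmetry_is_exact(self):
        for x1, N1, x2, N2 in [(3, 50, 9, 80), (0, 100, 7, 1000), (20, 500, 20, 5000)]:
            assert fold_probability(x1, N1, x2, N2) == fold_probability(x2, N2, x1, N1)

    def test_agrees_with_monte_carlo_oracle(self):
        # spot cells; the full grid runs in the acceptance suite
        for x1, N1, x2, N2 in [(100, 10**5, 0, 10**5), (5, 1000, 20, 1000)]:
            p = fold_probability(x1, N1, x2, N2)
            m = mc_fold_probability(x1, N1, x2, N2, n=10**6, seed=11)
            assert abs(p - m) <= 0.005

    def test_one_sided_monotone_in_x2(self):
        cfg = BayesConfig(two_sided=False)
        for N in (100, 2000):
            probs = [fold_probability(10, N, x2, N, cfg) for x2 in (0, 5, 10, 30, 60)]
            assert all(b >= a - 1e-9 for a, b in zip(probs, probs[1:]))

    def test_library_size_awareness(self):
        # equal counts are null at equal N but a 10x proportion gap at 10x N
        p_equal = fold_probability(50, 1000, 50, 1000)
        p_skewed = fold_probability(50, 1000, 50, 10_000)
        assert p_equal < 0.1
        assert p_skewed > 0.9
        assert p_skewed > p_equal

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fold_probability(5, 0, 0, 10)
        with pytest.raises(ValueError):
            fold_probability(11, 10, 0, 10)
        with pytest.raises(ValueError):
            BayesConfig(fold_factor=0.5)
        with pytest.raises(ValueError):
            BayesConfig(significance_threshold=1.5)


class TestCompareLibraries:
    def test_absent_tag_counts_zero_and_zero_zero_is_flat(self):
        shared = "CATG" + "A" * 18
        only_b = "CATG" + "C" * 18
        t1 = make_table("a", {shared: 10}, pad_to=1000)
        t2 = make_table("b", {shared: 10, only_b: 500}, pad_to=1000)
        results = {r.tag_seq: r for r in compare_libraries(t1, t2)}
        r = results[only_b]
        assert r.x1 == 0 and r.x2 == 500
        assert r.direction == "up"
        assert r.significant
        # identical posteriors -> flat, far from significance
        filler = "CATG" + "T" * 18
        r0 = results[filler]
        assert r0.direction == "flat" if r0.x1 == r0.x2 else True
        equal = results[shared]
        assert equal.direction == "flat"
        assert equal.p_fold < 0.95 and not equal.significant

    def test_posterior_mean_formula_and_sorting(self):
        t1 = make_table("a", {"CATG" + "A" * 18: 30}, pad_to=100)
        t2 = make_table("b", {"CATG" + "A" * 18: 1}, pad_to=100)
        results = compare_libraries(t1, t2)
        r = next(x for x in results if x.x1 == 30)
        assert r.theta1_hat == pytest.approx((30 + 2) / (100 + 4))
        assert r.theta2_hat == pytest.approx((1 + 2) / (100 + 4))
        assert r.direction == "down"
        p_values = [x.p_fold for x in results]
        assert p_values == sorted(p_values, reverse=True)

    def test_empty_library_rejected(self):
        t1 = TagCountTable(library_name="a")
        t2 = make_table("b", {"CATG" + "A" * 18: 5}, pad_to=10)
        with pytest.raises(ValueError):
            compare_libraries(t1, t2)

    def test_significance_cut_is_strict(self):
        t = make_table("a", {"CATG" + "A" * 18: 5}, pad_to=50)
        for r in compare_libraries(t, t):
            assert r.significant == (r.p_fold > 0.95)


def _random_results(rng, tags, sig_rate):
    out = []
    for tag in tags:
        sig = rng.random() < sig_rate
        out.append(
            ComparisonResult(
                tag_seq=tag, x1=1, x2=2, N1=10, N2=10,
                theta1_hat=0.1, theta2_hat=0.2, direction="up",
                p_fold=0.99 if sig else 0.5, significant=sig,
            )
        )
    return out


class TestVennSummary:
    def test_single_comparison_only(self):
        rng = random.Random(0)
        tags = [f"CATG{'A' * 14}{i:04d}".replace("0", "G").replace("1", "T")
                for i in range(5)]
        a = _random_results(rng, tags, 1.0)
        b = _random_results(rng, tags, 0.0)
        c = _random_results(rng, tags, 0.0)
        s = venn_summary(a, b, c, names=("A", "B", "C"))
        assert s.regions["A_only"] == 5
        assert sum(s.regions.values()) == 5 == s.grand_union

    def test_triple_intersection(self):
        tag = ["CATG" + "A" * 18]
        rng = random.Random(0)
        rs = [_random_results(rng, tag, 1.0) for _ in range(3)]
        s = venn_summary(*rs, names=("A", "B", "C"))
        assert s.regions["A_and_B_and_C"] == 1
        assert s.grand_union == 1

    def test_flat_tags_excluded_from_membership(self):
        flat = ComparisonResult(
            tag_seq="CATG" + "A" * 18, x1=1, x2=1, N1=10, N2=10,
            theta1_hat=0.1, theta2_hat=0.1, direction="flat",
            p_fold=0.99, significant=True,
        )
        s = venn_summary([flat], [], [], names=("A", "B", "C"))
        assert s.grand_union == 0

    def test_matches_brute_force_region_enumeration(self):
        rng = random.Random(12)
        tags = [f"tag{i}" for i in range(1000)]
        rs = [_random_results(rng, tags, 0.3) for _ in range(3)]
        s = venn_summary(*rs, names=("A", "B", "C"))
        sets = [{r.tag_seq for r in res if r.significant} for res in rs]
        # brute force: classify every tag by its membership triple
        from collections import Counter

        combo = Counter()
        for tag in tags:
            key = tuple(tag in x for x in sets)
            combo[key] += 1
        assert s.regions["A_only"] == combo[(True, False, False)]
        assert s.regions["B_only"] == combo[(False, True, False)]
        assert s.regions["C_only"] == combo[(False, False, True)]
        assert s.regions["A_and_B"] == combo[(True, True, False)]
        assert s.regions["A_and_C"] == combo[(True, False, True)]
        assert s.regions["B_and_C"] == combo[(False, True, True)]
        assert s.regions["A_and_B_and_C"] == combo[(True, True, True)]
        for name, total in s.totals.items():
            covering = [k for k in s.regions if name in k.split("_and_") or k == f"{name}_only"]
            assert total == sum(s.regions[k] for k in covering)
        assert s.grand_union == sum(s.regions.values())


def test_comparison_tsv_round_trip(tmp_path):
    t1 = make_table("a", {"CATG" + "A" * 18: 30}, pad_to=100)
    t2 = make_table("b", {"CATG" + "A" * 18: 1}, pad_to=100)
    results = compare_libraries(t1, t2)
    path = tmp_path / "cmp.tsv"
    write_comparison(results, path)
    loaded = read_comparison(path)
    assert [r.tag_seq for r in loaded] == [r.tag_seq for r in results]
    for a, b in zip(loaded, results):
        assert a.p_fold == pytest.approx(b.p_fold, rel=1e-6)
        assert a.significant == b.significant
        assert a.direction == b.direction
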