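"""Median-of-ratios normalization, category aggregation, Mann-Whitney /
Benjamini-Hochberg comparisons and the log10 display transform."""

import itertools

import numpy as np
import pandas as pd
import pytest

from era3d.errors import (ConfigError, InputError, NormalizationError,
                          TransformError)
from era3d.expression import (ExpressionMatrix, aggregate_by_category,
                              benjamini_hochberg, compare_groups,
                              length_decile_stratify, log10_display,
                              normalize_counts, size_factors)


def matrix(counts, samples, tissues=None, categories=None):
    df = pd.DataFrame(counts, columns=samples,
                      index=[f"g{i}" for i in range(len(counts))])
    tissues = tissues or {s: s for s in samples}
    return ExpressionMatrix(df, tissues, categories or {})


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        # sample2 = 2 x sample1 for every gene => factor ratio exactly 2
        c = pd.DataFrame({"s1": [10.0, 100.0, 7.0], "s2": [20.0, 200.0, 14.0]})
        f = size_factors(c)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)
        # and the closed form: sqrt(1/2), sqrt(2)
        assert f["s1"] == pytest.approx(np.sqrt(0.5))
        assert f["s2"] == pytest.approx(np.sqrt(2.0))

    def test_identical_samples_equal_factors(self):
        c = pd.DataFrame({"a": [5.0, 8.0], "b": [5.0, 8.0], "c": [5.0, 8.0]})
        f = size_factors(c)
        assert f.nunique() == 1

    def test_single_sample_factor_one(self):
        c = pd.DataFrame({"only": [3.0, 9.0, 27.0]})
        assert size_factors(c)["only"] == pytest.approx(1.0)

    def test_zero_containing_genes_excluded(self):
        c = pd.DataFrame({"s1": [10.0, 0.0], "s2": [20.0, 500.0]})
        f = size_factors(c)  # only gene 0 is all-nonzero
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_no_all_nonzero_gene_is_error(self):
        c = pd.DataFrame({"s1": [0.0, 5.0], "s2": [5.0, 0.0]})
        with pytest.raises(NormalizationError):
            size_factors(c)

    def test_scaling_one_sample_scales_factor_ratios(self):
        """Scaling one sample's counts by c multiplies its factor relative
        to every other sample by c, and normalized counts are unchanged up
        to a single global constant (the geometric-mean reference shifts
        by c^(1/m))."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = pd.DataFrame(rng.integers(1, 1000, size=(30, 4)).astype(float),
                             columns=list("abcd"))
            f = size_factors(c)
            scaled = c.copy()
            scaled["b"] *= 7.0
            f2 = size_factors(scaled)
            for s in "acd":
                assert (f2["b"] / f2[s]) / (f["b"] / f[s]) == pytest.approx(7.0)
            norm1 = (c / f).to_numpy()
            norm2 = (scaled / f2).to_numpy()
            alpha = norm2[0, 0] / norm1[0, 0]
            assert np.allclose(norm2, alpha * norm1)


class TestAggregateByCategory:
    def test_single_tissue_category_equals_tissue_mean(self):
        m = matrix([[1.0, 3.0], [10.0, 30.0]], ["s1", "s2"],
                   tissues={"s1": "liver", "s2": "liver"},
                   categories={"endoderm": ["liver"]})
        agg = aggregate_by_category(m)
        assert agg["endoderm"].tolist() == [2.0, 20.0]

    def test_shared_tissues_count_in_both_categories(self):
        m = matrix([[4.0, 8.0, 0.0]], ["c1", "cb1", "h1"],
                   tissues={"c1": "cortex", "cb1": "cerebellum", "h1": "heart"},
                   categories={"ectoderm": ["cortex", "cerebellum"],
                               "brain": ["cortex", "cerebellum"],
                               "mesoderm": ["heart"]})
        agg = aggregate_by_category(m)
        assert agg.loc["g0", "ectoderm"] == pytest.approx(6.0)
        assert agg.loc["g0", "brain"] == pytest.approx(6.0)
        assert agg.loc["g0", "mesoderm"] == 0.0

    def test_all_zero_gene_gives_zero_mean(self):
        m = matrix([[0.0, 0.0]], ["s1", "s2"],
                   tissues={"s1": "a", "s2": "a"}, categories={"cat": ["a"]})
        assert aggregate_by_category(m)["cat"].tolist() == [0.0]

    def test_empty_category_is_config_error(self):
        m = matrix([[1.0]], ["s1"], tissues={"s1": "a"}, categories={"bad": []})
        with pytest.raises(ConfigError):
            aggregate_by_category(m)


def exact_mwu(a, b):
    """Exact-enumeration two-sided Mann-Whitney oracle (no ties assumed)."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    center = n1 * n2 / 2
    u_obs = sum((x > y) for x in a for y in b)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        mask = np.zeros(n1 + n2, bool)
        mask[list(idx)] = True
        u = sum((x > y) for x in pooled[mask] for y in pooled[~mask])
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


class TestCompareGroups:
    def grouping(self, n1, n2):
        return {f"a{i}": "A" for i in range(n1)} | {f"b{i}": "B" for i in range(n2)}

    def values(self, va, vb):
        idx = [f"a{i}" for i in range(len(va))] + [f"b{i}" for i in range(len(vb))]
        return pd.Series(list(va) + list(vb), index=idx, name="cat")

    def test_identical_groups_null(self):
        v = self.values([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        (c,) = compare_groups(v, self.grouping(4, 4))
        assert c.u_statistic == pytest.approx(8.0)  # n1*n2/2
        assert c.p > 0.9

    def test_fully_separated_groups(self):
        v = self.values([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        (c,) = compare_groups(v, self.grouping(3, 3))
        assert c.u_statistic in (0.0, 9.0)
        assert c.p < 0.1
        assert c.summary_b.median == 20.0 and c.summary_a.n == 3

    def test_asymptotic_agrees_with_exact_enumeration(self):
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 15:
            n1, n2 = rng.integers(4, 7, 2)
            va = rng.normal(size=int(n1))
            vb = rng.normal(loc=rng.uniform(0, 1.5), size=int(n2))
            u_exact, p_exact = exact_mwu(va, vb)
            (c,) = compare_groups(self.values(va, vb), self.grouping(int(n1), int(n2)))
            assert c.u_statistic == pytest.approx(u_exact)
            if p_exact >= 0.05:  # where the normal approximation applies
                assert c.p == pytest.approx(p_exact, rel=0.10)
                checked += 1

    def test_empty_group_skipped_with_warning(self, caplog):
        v = self.values([1.0, 2.0], [])
        with caplog.at_level("WARNING"):
            out = compare_groups(v, self.grouping(2, 0), pairs=[("A", "B")])
        assert out == [] and "empty group" in caplog.text

    def test_bh_family_is_the_whole_invocation(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(
            {"c1": rng.normal(size=60), "c2": rng.normal(size=60)},
            index=[f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]
                  + [f"c{i}" for i in range(20)])
        grouping = ({f"a{i}": "A" for i in range(20)}
                    | {f"b{i}": "B" for i in range(20)}
                    | {f"c{i}": "C" for i in range(20)})
        out = compare_groups(values, grouping)
        raw = np.array([c.p for c in out])
        adj = np.array([c.p_adjusted for c in out])
        assert np.allclose(adj, benjamini_hochberg(raw))
        assert (adj >= raw - 1e-15).all()


class TestBenjaminiHochberg:
    def test_step_up_formula_example(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_hand_step_up_on_random_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            running = min(running, p[i] * m / (rank_from_top + 1))
            hand[i] = running
        assert np.allclose(benjamini_hochberg(p), hand)

    def test_monotone_in_rank_and_capped(self):
        p = np.array([0.9, 0.5, 0.0001, 0.99, 0.7])
        adj = benjamini_hochberg(p)
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestLengthDecileStratify:
    def test_distinct_lengths_make_equal_deciles(self):
        lengths = {f"g{i}": 100 + i for i in range(100)}
        values = pd.Series(np.arange(100.0), index=list(lengths))
        grouping = {g: "A" for g in lengths}
        out = length_decile_stratify(lengths, values, grouping)
        assert out["n"].tolist() == [10] * 10
        assert not out["degenerate"].any()

    def test_identical_lengths_flagged_degenerate(self):
        lengths = {f"g{i}": 500 for i in range(20)}
        values = pd.Series(np.arange(20.0), index=list(lengths))
        out = length_decile_stratify(lengths, values, {g: "A" for g in lengths})
        assert out["degenerate"].all()

    def test_gradient_maintained_within_deciles(self):
        rng = np.random.default_rng(3)
        lengths, vals, grouping = {}, {}, {}
        for k, (era, mu) in enumerate([("old", 100.0), ("young", 10.0)]):
            for i in range(300):
                g = f"{era}{i}"
                lengths[g] = int(rng.integers(200, 5000))
                vals[g] = mu * rng.lognormal(0, 0.5)
                grouping[g] = era
        out = length_decile_stratify(pd.Series(lengths),
                                     pd.Series(vals), grouping)
        wide = out.pivot(index="decile", columns="group", values="median")
        assert (wide["old"] > wide["young"]).sum() >= 9

    def test_too_few_genes_rejected(self):
        with pytest.raises(InputError):
            length_decile_stratify({"g0": 1}, pd.Series({"g0": 1.0}), {"g0": "A"})


class TestLog10Display:
    def test_stated_rule_examples(self):
        out = log10_display(np.array([0.0, 1.0, 99.0]))  # m = 1
        assert np.allclose(out, [0.0, np.log10(2.0), 2.0])
        assert log10_display(np.array([5.0]))[0] == pytest.approx(1.0)  # m = 5

    def test_strictly_increasing(self):
        rng = np.random.default_rng(4)
        v = np.sort(rng.random(50)) * 100
        v[0] = 0.0
        out = log10_display(v)
        assert (np.diff(out) > 0).all()

    def test_all_zero_is_error(self):
        with pytest.raises(TransformError):
            log10_display(np.zeros(3))

    def test_negative_is_error(self):
        with pytest.raises(InputError):
            log10_display(np.array([-1.0, 2.0]))
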