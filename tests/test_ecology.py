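"""Diversity, dissimilarity, clustering, rank tests, and IndVal."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import kstest

from b1profiler.ecology import (
    assign_depth_layer, average_linkage, bray_curtis, bray_curtis_matrix,
    drop_chloroplasts, grouped_rank_test, indval, prototroph_share,
    relative_abundance, shannon_index,
)
from b1profiler.errors import ConfigurationError, ConsistencyError


class TestRelativeAbundance:
    def test_simple_proportions(self):
        counts = pd.DataFrame({"s1": [10, 30]}, index=["a", "b"])
        rel = relative_abundance(counts)
        assert list(rel["s1"]) == [0.25, 0.75]

    def test_collapse_at_class(self):
        counts = pd.DataFrame({"s1": [10, 30]}, index=["a", "b"])
        tax = pd.Series({"a": "bacteria;P1;C1;O1", "b": "bacteria;P1;C1;O2"})
        rel = relative_abundance(counts, taxonomy=tax, collapse_rank="class")
        assert rel.shape[0] == 1
        assert rel["s1"].iloc[0] == 1.0

    def test_all_zero_sample_named(self):
        counts = pd.DataFrame({"good": [1], "empty": [0]}, index=["a"])
        with pytest.raises(ConsistencyError, match="empty"):
            relative_abundance(counts)

    def test_chloroplast_filter(self):
        counts = pd.DataFrame({"s1": [5, 5]}, index=["a", "b"])
        tax = pd.Series({"a": "bacteria;Cyanobacteria;Chloroplast", "b": "bacteria;X"})
        assert list(drop_chloroplasts(counts, tax).index) == ["b"]


class TestShannon:
    def test_uniform_four_taxa(self):
        assert shannon_index([0.25] * 4) == pytest.approx(math.log(4))

    def test_single_taxon_zero(self):
        assert shannon_index([1.0]) == 0.0

    def test_mixed_closed_form(self):
        assert shannon_index([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ConsistencyError):
            shannon_index([1.5, -0.5])

    def test_bounds_on_random_compositions(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            s = int(rng.integers(2, 20))
            p = rng.dirichlet(np.ones(s))
            h = shannon_index(p)
            assert -1e-12 <= h <= math.log(s) + 1e-12


class TestBrayCurtis:
    def test_identical_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_one(self):
        assert bray_curtis([1, 0], [0, 2]) == 1.0

    def test_hand_case(self):
        assert bray_curtis([1, 1], [1, 3]) == pytest.approx(1 / 3)

    def test_matches_hand_formula_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            x = rng.integers(0, 50, size=8).astype(float)
            y = rng.integers(0, 50, size=8).astype(float)
            if x.sum() == 0 and y.sum() == 0:
                continue
            expected = 1 - 2 * np.minimum(x, y).sum() / (x.sum() + y.sum())
            got = bray_curtis(x, y)
            assert got == pytest.approx(expected, abs=1e-12)
            assert 0 <= got <= 1
            assert got == pytest.approx(bray_curtis(y, x))

    def test_both_zero_undefined(self):
        with pytest.raises(ConsistencyError):
            bray_curtis([0, 0], [0, 0])


class TestAverageLinkage:
    def test_two_samples_single_merge(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=list("ab"),
                         columns=list("ab"))
        tree = average_linkage(d)
        assert len(tree.merges) == 1
        assert tree.merges[0].height == 0.4

    def test_identical_samples_merge_at_zero(self):
        d = np.array([
            [0.0, 0.0, 0.5],
            [0.0, 0.0, 0.5],
            [0.5, 0.5, 0.0],
        ])
        tree = average_linkage(d, labels=list("abc"))
        assert tree.merges[0].height == 0.0
        assert set(tree.merges[0].left + tree.merges[0].right) == {"a", "b"}

    def test_asymmetry_rejected(self):
        with pytest.raises(ConsistencyError):
            average_linkage(np.array([[0.0, 0.1], [0.2, 0.0]]))

    def test_against_scipy_oracle_on_random_matrices(self):
        """Merge heights must match scipy's average-linkage on 100 random
        (tie-free, continuous) 5x5 dissimilarity matrices."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = 5
            cond = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
            d = squareform(cond)
            ours = average_linkage(d, labels=[f"s{i}" for i in range(n)])
            heights = sorted(m.height for m in ours.merges)
            scipy_heights = sorted(linkage(cond, method="average")[:, 2])
            assert np.allclose(heights, scipy_heights, atol=1e-9)

    def test_newick_is_parseable_and_ultrametric(self):
        rng = np.random.default_rng(3)
        cond = rng.uniform(0.1, 1.0, size=10)
        tree = average_linkage(squareform(cond), labels=list("abcde"))
        import io
        import skbio
        t = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        assert {tip.name for tip in t.tips()} == set("abcde")
        depths = {tip.name: t.distance(tip) for tip in t.tips()}
        root_height = max(m.height for m in tree.merges) / 2
        for depth in depths.values():
            assert depth == pytest.approx(root_height, abs=1e-9)


class TestGroupedRankTest:
    def test_degenerate_identical_values(self):
        stat, p = grouped_rank_test([1, 1, 1, 1], ["a", "a", "b", "b"],
                                    test="kruskal_wallis")
        assert (stat, p) == (0.0, 1.0)

    def test_fully_separated_groups(self):
        values = list(range(10)) + list(range(100, 110))
        groups = ["lo"] * 10 + ["hi"] * 10
        _, p = grouped_rank_test(values, groups, test="wilcoxon_rank_sum")
        assert p < 0.001

    def test_wilcoxon_needs_two_groups(self):
        with pytest.raises(ConfigurationError):
            grouped_rank_test([1, 2, 3], ["a", "b", "c"], test="wilcoxon_rank_sum")

    def test_type_one_error_calibration(self):
        """Three groups drawn from one distribution: rejection rate at the
        0.05 level stays within +-0.02 over 1000 simulations."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            values = rng.normal(size=18)
            groups = np.repeat(["a", "b", "c"], 6)
            _, p = grouped_rank_test(values, groups, test="kruskal_wallis")
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestIndval:
    def test_perfect_indicator(self):
        table = pd.DataFrame(
            {"a1": [5], "a2": [3], "b1": [0], "b2": [0]}, index=["t"])
        res = indval(table, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                     n_permutations=99, seed=1)
        assert res["stat"].iloc[0] == 1.0
        assert res["group"].iloc[0] == "A"

    def test_even_taxon_scores_half(self):
        table = pd.DataFrame(
            {"a1": [2], "a2": [4], "b1": [4], "b2": [2]}, index=["t"])
        res = indval(table, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
                     n_permutations=99, seed=1)
        assert res["stat"].iloc[0] == pytest.approx(0.5)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """With 4 samples in 2 groups the permutation p must agree with the
        exact value over all 4!/(2!2!)... all 24 relabelings within
        permutation-sampling error."""
        table = pd.DataFrame(
            {"a1": [10, 1], "a2": [8, 2], "b1": [1, 3], "b2": [0, 4]},
            index=["t1", "t2"])
        samples = list(table.columns)
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}

        def stat_for(labels):
            out = []
            for _, row in table.iterrows():
                best = 0.0
                for g in ("A", "B"):
                    sel = [s for s, l in zip(samples, labels) if l == g]
                    means = {
                        gg: np.mean([row[s] for s, l in zip(samples, labels) if l == gg])
                        for gg in ("A", "B")
                    }
                    tot = sum(means.values())
                    a = means[g] / tot if tot > 0 else 0.0
                    b = np.mean([row[s] > 0 for s in sel])
                    best = max(best, a * b)
                out.append(best)
            return np.array(out)

        obs = stat_for([groups[s] for s in samples])
        perms = [stat_for(lab) for lab in
                 set(itertools.permutations([groups[s] for s in samples]))]
        exact_p = np.array([
            np.mean([p[i] >= obs[i] for p in perms]) for i in range(len(obs))
        ])
        res = indval(table, groups, n_permutations=999, seed=5)
        se = np.sqrt(exact_p * (1 - exact_p) / 999)
        assert np.all(np.abs(res["p_value"].to_numpy() - exact_p) <= 3 * se + 2 / 999)

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.integers(0, 20, size=(10, 8)),
                             columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        r1 = indval(table, groups, n_permutations=199, seed=42)
        r2 = indval(table, groups, n_permutations=199, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_null_p_values_super_uniform(self):
        """200 taxa with no group structure: permutation p-values must not be
        anti-conservative (one-sided KS against uniform)."""
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.gamma(2.0, 5.0, size=(200, 12)),
                             columns=[f"s{i}" for i in range(12)])
        groups = {f"s{i}": ("A" if i < 6 else "B") for i in range(12)}
        res = indval(table, groups, n_permutations=999, seed=13)
        ks = kstest(res["p_value"], "uniform", alternative="greater")
        assert ks.pvalue > 0.01

    def test_too_few_permutations_rejected(self):
        table = pd.DataFrame({"a": [1], "b": [2]}, index=["t"])
        with pytest.raises(ConfigurationError):
            indval(table, {"a": "A", "b": "B"}, n_permutations=50)


class TestLayersAndShares:
    @pytest.mark.parametrize("depth,layer", [
        (2, "epipelagic"), (200, "epipelagic"), (700, "mesopelagic"),
        (1000, "mesopelagic"), (1250, "bathypelagic"), (2500, "bathypelagic"),
    ])
    def test_depth_layers(self, depth, layer):
        assert assign_depth_layer(depth) == layer

    def test_negative_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_depth_layer(-1)

    def test_prototroph_share(self):
        rel = pd.DataFrame({"s1": [0.20, 0.15, 0.65]}, index=["p1", "p2", "x"])
        gmap = {"p1": "PROTOTROPH", "p2": "PROTOTROPH", "x": "AUX_HMP"}
        assert prototroph_share(rel, gmap)["s1"] == pytest.approx(0.35)

    def test_no_mapped_prototrophs(self):
        rel = pd.DataFrame({"s1": [1.0]}, index=["x"])
        assert prototroph_share(rel, {})["s1"] == 0.0
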