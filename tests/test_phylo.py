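"""Tree parsing, independent contrasts, correlation and FDR."""

import math
import subprocess
import sys

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stramtf.errors import ConsistencyError, ParseError
from stramtf.phylo import (
    bh_fdr,
    contrast_correlation,
    correlate_families,
    parse_newick,
    pic_contrasts,
    read_traits,
    write_traits,
)
from stramtf.rule_engine import FamilySizeMatrix
from stramtf.simulate import SimConfig, sim_bm_traits, sim_tree


def bm_covariance_oracle(newick: str) -> tuple[np.ndarray, list[str]]:
    """BM tip covariance from dendropy path lengths (independent of the
    package's tree arrays): V[i,j] = (depth_i + depth_j - d_ij) / 2."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    depth = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length
            node = node.parent_node
        depth[leaf.taxon] = d
    n = len(taxa)
    V = np.empty((n, n))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            V[i, j] = depth[a] if i == j else 0.5 * (
                depth[a] + depth[b] - pdm.patristic_distance(a, b)
            )
    return V, [t.label for t in taxa]


def contrast_matrix(tree) -> np.ndarray:
    """Recover the linear map x -> contrasts by probing with unit vectors."""
    tips = tree.tip_labels
    cols = []
    for t in tips:
        x = {u: (1.0 if u == t else 0.0) for u in tips}
        cols.append(pic_contrasts(tree, x).contrasts)
    return np.column_stack(cols)


class TestParseNewick:
    def test_counts_nodes(self):
        tree = parse_newick("((A:1,B:1):0.5,C:2);")
        assert tree.n_tips == 3
        assert len(tree.internal_nodes()) == 2

    def test_polytomy_rejected_by_default(self):
        with pytest.raises(ParseError, match="bifurcating"):
            parse_newick("((A:1,B:1,C:1):1,D:1);")

    def test_polytomy_optionally_resolved(self):
        tree = parse_newick("((A:1,B:1,C:1):1,D:1);", resolve_polytomies=True)
        assert tree.n_tips == 4
        assert len(tree.internal_nodes()) == 3

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ParseError, match="duplicate"):
            parse_newick("((A:1,A:1):1,B:1);")

    def test_missing_length_configurable(self):
        with pytest.raises(ParseError, match="branch length"):
            parse_newick("((A:1,B):1,C:1);")
        tree = parse_newick("((A:1,B):1,C:1);", default_length=1.0)
        assert tree.blen[tree.tip_index["B"]] == 1.0

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ParseError):
            parse_newick("((A:1,B:1:0.5,C:2);")

    def test_round_trip_preserves_topology_and_lengths(self):
        for seed in range(20):
            tree = sim_tree(SimConfig(n_tips=10, seed=seed))
            back = parse_newick(tree.to_newick())
            assert back.to_newick() == tree.to_newick()
            V1, t1 = back.bm_covariance()
            V2, t2 = tree.bm_covariance()
            assert t1 == t2
            np.testing.assert_allclose(V1, V2, atol=1e-12)


class TestPicContrasts:
    def test_two_tip_closed_form(self, two_tip_tree):
        cs = pic_contrasts(two_tip_tree, {"A": 3.0, "B": 1.0})
        assert len(cs) == 1
        assert cs.contrasts[0] == pytest.approx((3 - 1) / math.sqrt(2), abs=1e-12)

    def test_three_tip_hand_recursion(self, three_tip_tree):
        cs = pic_contrasts(three_tip_tree, {"A": 1.0, "B": 3.0, "C": 2.0})
        np.testing.assert_allclose(cs.contrasts, [-math.sqrt(2), 0.0], atol=1e-12)
        # working value at the cherry's ancestor and its augmented edge
        assert cs.node_values[0] == pytest.approx(2.0)
        assert cs.working_lengths[0] == pytest.approx(0.5 + 0.5)

    def test_contrast_count_is_tips_minus_one(self):
        for n in (3, 7, 16):
            tree = sim_tree(SimConfig(n_tips=n, seed=n))
            x = dict(zip(tree.tip_labels, np.arange(n, dtype=float)))
            assert len(pic_contrasts(tree, x)) == n - 1

    def test_constant_trait_gives_zero_contrasts(self):
        tree = sim_tree(SimConfig(n_tips=9, seed=3))
        cs = pic_contrasts(tree, {t: 5.0 for t in tree.tip_labels})
        np.testing.assert_allclose(cs.contrasts, 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(-10, 10, allow_nan=False).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-100, 100, allow_nan=False),
           seed=st.integers(0, 50))
    def test_affine_equivariance(self, a, b, seed):
        tree = sim_tree(SimConfig(n_tips=8, seed=seed))
        rng = np.random.default_rng(seed)
        x = dict(zip(tree.tip_labels, rng.normal(size=8)))
        base = pic_contrasts(tree, x).contrasts
        scaled = pic_contrasts(tree, {t: a * v + b for t, v in x.items()}).contrasts
        np.testing.assert_allclose(scaled, a * base, rtol=1e-9, atol=1e-9)

    def test_child_swap_flips_signs_only(self):
        cs1 = pic_contrasts(parse_newick("((A:1,B:1):0.5,C:2);"),
                            {"A": 1.0, "B": 3.0, "C": 2.0})
        cs2 = pic_contrasts(parse_newick("(C:2,(B:1,A:1):0.5);"),
                            {"A": 1.0, "B": 3.0, "C": 2.0})
        np.testing.assert_allclose(np.abs(np.sort(cs1.contrasts)),
                                   np.abs(np.sort(-cs2.contrasts)), atol=1e-12)

    def test_missing_tip_value_rejected(self, two_tip_tree):
        with pytest.raises(ConsistencyError, match="B"):
            pic_contrasts(two_tip_tree, {"A": 1.0})

    def test_whitening_identity_on_small_trees(self):
        """Standardized contrasts whiten the BM covariance: A V A' = I."""
        for seed in range(25):
            tree = sim_tree(SimConfig(n_tips=int(5 + seed % 4), seed=seed))
            A = contrast_matrix(tree)
            V, taxa = bm_covariance_oracle(tree.to_newick())
            order = [taxa.index(t) for t in tree.tip_labels]
            V = V[np.ix_(order, order)]
            np.testing.assert_allclose(A @ V @ A.T, np.eye(len(A)), atol=1e-8)

    def test_sum_of_squares_equals_gls_quadratic_form(self):
        """sum c^2 = (x - mu)' V^-1 (x - mu) with the GLS mean, tips <= 8."""
        rng = np.random.default_rng(0)
        for seed in range(25):
            tree = sim_tree(SimConfig(n_tips=int(4 + seed % 5), seed=seed))
            x = rng.normal(size=tree.n_tips) * 3
            cs = pic_contrasts(tree, dict(zip(tree.tip_labels, x)))
            V, taxa = bm_covariance_oracle(tree.to_newick())
            order = [taxa.index(t) for t in tree.tip_labels]
            V = V[np.ix_(order, order)]
            Vi = np.linalg.inv(V)
            one = np.ones(tree.n_tips)
            mu = (one @ Vi @ x) / (one @ Vi @ one)
            q = (x - mu) @ Vi @ (x - mu)
            assert np.sum(cs.contrasts**2) == pytest.approx(q, abs=1e-8)

    def test_matches_ape_reference_implementation(self, tmp_path):
        """Cross-check contrasts against R's ape::pic on random trees."""
        cases = []
        for seed in range(8):
            tree = sim_tree(SimConfig(n_tips=int(5 + seed), seed=seed))
            rng = np.random.default_rng(100 + seed)
            x = dict(zip(tree.tip_labels, rng.normal(size=tree.n_tips) * 2))
            cases.append((tree, x))
        lines = ["library(ape)"]
        for tree, x in cases:
            vals = ",".join(f"{float(x[t]):.17g}" for t in tree.tip_labels)
            names = ",".join(f"'{t}'" for t in tree.tip_labels)
            lines += [
                f"tr <- read.tree(text='{tree.to_newick()}')",
                f"x <- setNames(c({vals}), c({names}))",
                "cat(sprintf('%.15g', sort(abs(pic(x, tr)))), sep=',')",
                "cat('\\n')",
            ]
        script = tmp_path / "pic_oracle.R"
        script.write_text("\n".join(lines) + "\n", encoding="utf-8")
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        ).stdout.strip().splitlines()
        assert len(out) == len(cases)
        for (tree, x), line in zip(cases, out):
            expected = np.array([float(v) for v in line.split(",")])
            mine = np.sort(np.abs(pic_contrasts(tree, x).contrasts))
            np.testing.assert_allclose(mine, expected, rtol=1e-8, atol=1e-10)


class TestContrastCorrelation:
    def test_proportional_vectors_give_r_one(self):
        r, p = contrast_correlation(np.array([1.0, 2.0]), np.array([2.0, 4.0]))
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_orthogonal_vectors_give_r_zero(self):
        r, p = contrast_correlation(np.array([1.0, -1.0]), np.array([1.0, 1.0]))
        assert r == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_flagged_undefined(self):
        r, p = contrast_correlation(np.zeros(4), np.ones(4))
        assert math.isnan(r) and math.isnan(p)

    def test_centered_mode_matches_scipy_pearson(self, rng):
        from scipy import stats as sps
        a, b = rng.normal(size=20), rng.normal(size=20)
        r, p = contrast_correlation(a, b, mode="centered")
        ref = sps.pearsonr(a, b)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_through_origin_matches_regression_anova(self, rng):
        # r^2/(1-r^2)*(k-1) is the F statistic of no-intercept regression
        a, b = rng.normal(size=15), rng.normal(size=15)
        r, p = contrast_correlation(a, b)
        from scipy import stats as sps
        f = r * r / (1 - r * r) * (len(a) - 1)
        assert p == pytest.approx(sps.f.sf(f, 1, len(a) - 1), abs=1e-12)


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_p(self):
        assert bh_fdr([1.0]) == pytest.approx([1.0])

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            m = len(p)
            brute = np.array([
                min(min(m * pj / (np.sum(p <= pj)) for pj in p if pj >= pi), 1.0)
                for pi in p
            ])
            np.testing.assert_allclose(bh_fdr(p), brute, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=50)
        np.testing.assert_allclose(
            bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_q_at_least_p_and_monotone_in_rank(self, rng):
        p = rng.uniform(size=40)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCorrelateFamilies:
    def make_sizes(self, tree, data):
        counts = pd.DataFrame(data, index=tree.tip_labels)
        return FamilySizeMatrix(counts=counts,
                                categories={f: "TF" for f in counts.columns})

    def test_constant_family_flagged_undefined(self):
        tree = sim_tree(SimConfig(n_tips=6, seed=1))
        cfg = SimConfig(n_tips=6, seed=1)
        traits, _, _ = sim_bm_traits(tree, cfg)
        sizes = self.make_sizes(tree, {"FLAT": [7] * 6, "VAR": range(1, 7)})
        results = correlate_families(tree, traits, sizes)
        for res in results:
            if res.family_id == "FLAT":
                assert not res.defined and not res.significant
            else:
                assert res.defined

    def test_species_mismatch_reported(self):
        tree = sim_tree(SimConfig(n_tips=6, seed=1))
        cfg = SimConfig(n_tips=6, seed=1)
        traits, _, _ = sim_bm_traits(tree, cfg)
        sizes = self.make_sizes(tree, {"F": range(6)})
        with pytest.raises(ConsistencyError, match="sp"):
            correlate_families(tree, traits.drop(index=tree.tip_labels[0]), sizes)

    def test_alpha_one_flags_every_defined_test(self):
        tree = sim_tree(SimConfig(n_tips=6, seed=2))
        cfg = SimConfig(n_tips=6, seed=2)
        traits, _, _ = sim_bm_traits(tree, cfg)
        sizes = self.make_sizes(tree, {"F1": range(6), "F2": [3, 1, 4, 1, 5, 9]})
        results = correlate_families(tree, traits, sizes, alpha_q=1.0)
        assert all(r.significant for r in results if r.defined)


class TestTraitIO:
    def test_round_trip(self, tmp_path, small_bundle):
        path = tmp_path / "traits.tsv"
        write_traits(small_bundle.traits, small_bundle.binary_traits, path)
        cont, binary = read_traits(path)
        pd.testing.assert_frame_equal(cont, small_bundle.traits)
        pd.testing.assert_frame_equal(binary, small_bundle.binary_traits)

    def test_bad_binary_values_rejected(self, tmp_path):
        path = tmp_path / "traits.tsv"
        path.write_text(
            "species\tx\n#type\tbinary\nA\t2.0\nB\t0.0\n", encoding="utf-8"
        )
        with pytest.raises(ParseError, match="binary"):
            read_traits(path)
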