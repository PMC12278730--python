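"""IBS distances, NJ tree, phylogenetic VCV, GLS and exact Spearman test."""

import io

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from Bio import Phylo
from dendropy.calculate import treecompare

from mutload import (
    PopulationPanel,
    choose_representatives,
    ibs_distance,
    nj_tree,
    phylo_gls,
    population_vcv,
    spearman_exact,
    tree_to_vcv,
)
from mutload.core import MISSING


def read_bio(newick):
    tree = Phylo.read(io.StringIO(newick), "newick")
    tree.rooted = True
    return tree


class TestIbsDistance:
    def test_identical_and_opposite(self):
        dos = np.array([[2, 2, 0], [0, 0, 2]], dtype=np.int8)
        d = ibs_distance(dos, ["a", "b", "c"])
        assert d.loc["a", "b"] == 0.0  # identical genotypes
        assert d.loc["a", "c"] == 1.0  # opposite homozygotes at both sites
        assert d.loc["b", "c"] == 1.0

    def test_mean_over_sites(self):
        # diffs |2-2|, |1-0|, |1-2| -> mean(0,1,1)/2 = 1/3
        dos = np.array([[2, 2], [1, 0], [1, 2]], dtype=np.int8)
        d = ibs_distance(dos, ["a", "b"])
        assert d.loc["a", "b"] == pytest.approx(1 / 3)

    def test_missing_sites_excluded(self):
        dos = np.array([[2, MISSING], [0, 2], [MISSING, 1]], dtype=np.int8)
        d = ibs_distance(dos, ["a", "b"])
        assert d.loc["a", "b"] == pytest.approx(1.0)  # only the middle site

    def test_symmetric_with_zero_diagonal(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, (50, 6)).astype(np.int8)
        d = ibs_distance(dos, [f"s{i}" for i in range(6)])
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    def test_no_shared_sites_fails(self):
        dos = np.array([[2, MISSING], [MISSING, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="shared"):
            ibs_distance(dos, ["a", "b"])


def random_newick(names, rng):
    """Random binary topology with branch lengths in (0.1, 1)."""
    nodes = [f"{n}:{rng.uniform(0.1, 1.0):.6f}" for n in names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), 2, replace=False)
        merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 1.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


def patristic_df(newick, names):
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tns}
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                taxa[names[i]], taxa[names[j]]
            )
    return pd.DataFrame(D, index=names, columns=names)


class TestNjTree:
    def test_recovers_additive_four_taxon_distances(self):
        newick = "((A:1.0,B:2.0):1.0,(C:3.0,OUT:4.0):0.5);"
        names = ["A", "B", "C", "OUT"]
        D = patristic_df(newick, names)
        tree = nj_tree(D, outgroup="OUT")
        # NJ is exact on additive distances: every tip-to-tip path matches
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                assert tree.distance(a, b) == pytest.approx(D.loc[a, b], abs=1e-9)

    def test_outgroup_sits_alone_at_root(self):
        D = patristic_df("((A:1.0,B:1.5):0.7,OUT:3.0);", ["A", "B", "OUT"])
        tree = nj_tree(D, outgroup="OUT")
        assert tree.rooted
        children = tree.root.clades
        assert len(children) == 2
        sides = [sorted(t.name for t in c.get_terminals()) for c in children]
        assert ["OUT"] in sides and ["A", "B"] in sides

    def test_asymmetric_matrix_fails(self):
        D = pd.DataFrame(
            [[0.0, 1.0, 2.0], [1.1, 0.0, 1.0], [2.0, 1.0, 0.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, outgroup="C")

    def test_missing_outgroup_fails(self):
        D = pd.DataFrame(np.zeros((2, 2)), index=["A", "B"], columns=["A", "B"])
        with pytest.raises(KeyError, match="OUT"):
            nj_tree(D, outgroup="OUT")

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_topology_matches_truth_on_random_additive_trees(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        names = [f"t{i}" for i in range(n)]
        newick = random_newick(names, rng)
        D = patristic_df(newick, names)
        mine = nj_tree(D, outgroup="t0")
        buf = io.StringIO()
        Phylo.write(mine, buf, "newick")
        tns = dendropy.TaxonNamespace()
        true = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
        recon = dendropy.Tree.get(
            data=buf.getvalue(), schema="newick", taxon_namespace=tns
        )
        for t in (true, recon):
            t.is_rooted = False
            t.encode_bipartitions()
        assert treecompare.symmetric_difference(true, recon) == 0


class TestTreeToVcv:
    def test_star_tree_is_diagonal(self):
        tree = read_bio("(A:1.0,B:2.0,C:3.0);")
        V = tree_to_vcv(tree)
        expected = np.diag([1.0, 2.0, 3.0])
        assert np.allclose(V.loc[["A", "B", "C"], ["A", "B", "C"]], expected)

    def test_cherry_shares_stem_branch(self):
        tree = read_bio("((A:1.0,B:1.0):0.5,C:2.0);")
        V = tree_to_vcv(tree)
        assert V.loc["A", "B"] == pytest.approx(0.5)
        assert V.loc["A", "A"] == pytest.approx(1.5)
        assert V.loc["C", "C"] == pytest.approx(2.0)
        assert V.loc["A", "C"] == 0.0

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_brute_force_mrca_depths(self, seed):
        rng = np.random.default_rng(seed)
        names = [f"t{i}" for i in range(8)]
        tree = read_bio(random_newick(names, rng))
        V = tree_to_vcv(tree, names)
        for a in names:
            for b in names:
                if a == b:
                    want = tree.distance(tree.root, a)
                else:
                    mrca = tree.common_ancestor({"name": a}, {"name": b})
                    want = tree.distance(tree.root, mrca)
                assert V.loc[a, b] == pytest.approx(want, abs=1e-9)

    def test_psd_on_random_trees(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            names = [f"t{i}" for i in range(10)]
            V = tree_to_vcv(read_bio(random_newick(names, rng)), names)
            eig = np.linalg.eigvalsh(V.to_numpy())
            assert eig.min() >= -1e-9

    def test_unrooted_tree_fails(self):
        tree = Phylo.read(io.StringIO("(A:1,B:1,C:1);"), "newick")
        tree.rooted = False
        with pytest.raises(ValueError, match="rooted"):
            tree_to_vcv(tree)


class TestPhyloGls:
    def test_identity_vcv_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        n = 30
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        res = phylo_gls(y, x, np.eye(n), standardize=False)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.slope == pytest.approx(ols.params[1], abs=1e-8)
        assert res.intercept == pytest.approx(ols.params[0], abs=1e-8)
        assert res.slope_se == pytest.approx(ols.bse[1], abs=1e-8)
        assert res.p_value == pytest.approx(ols.pvalues[1], abs=1e-8)

    def test_matches_statsmodels_gls_oracle(self):
        rng = np.random.default_rng(6)
        n = 25
        A = rng.normal(size=(n, n))
        V = A @ A.T + n * np.eye(n)
        x = rng.normal(size=n)
        y = 0.8 * x + rng.multivariate_normal(np.zeros(n), V)
        res = phylo_gls(y, x, V, standardize=False)
        gls = sm.GLS(y, sm.add_constant(x), sigma=V).fit()
        assert res.slope == pytest.approx(gls.params[1], rel=1e-8)
        assert res.slope_se == pytest.approx(gls.bse[1], rel=1e-8)
        assert res.p_value == pytest.approx(gls.pvalues[1], rel=1e-6)

    def test_standardized_slope_scales_by_response_sd(self):
        rng = np.random.default_rng(7)
        n = 20
        x = rng.normal(size=n)
        y = 3.0 * x + rng.normal(size=n)
        raw = phylo_gls(y, x, np.eye(n), standardize=False)
        std = phylo_gls(y, x, np.eye(n), standardize=True)
        assert std.slope == pytest.approx(raw.slope / np.std(y, ddof=1), rel=1e-10)
        assert std.p_value == pytest.approx(raw.p_value, rel=1e-10)

    def test_constant_predictor_fails(self):
        with pytest.raises(ValueError, match="collinear"):
            phylo_gls(np.arange(5.0), np.ones(5), np.eye(5), standardize=False)

    def test_shape_mismatch_fails(self):
        with pytest.raises(ValueError, match="shape"):
            phylo_gls(np.arange(4.0), np.arange(5.0), np.eye(5))


class TestSpearmanExact:
    def test_perfect_concordance(self):
        rho, p = spearman_exact([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 120)

    def test_one_swap_gives_point_nine(self):
        rho, p = spearman_exact([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
        assert rho == pytest.approx(0.9)
        assert p == pytest.approx(5 / 120)

    def test_anticoncordance_has_full_upper_tail(self):
        rho, p = spearman_exact([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)
        assert p == 1.0

    def test_ties_fail(self):
        with pytest.raises(ValueError, match="ties"):
            spearman_exact([1, 1, 2, 3, 4], [1, 2, 3, 4, 5])

    @pytest.mark.parametrize("n", [2, 9])
    def test_size_bounds(self, n):
        with pytest.raises(ValueError, match="3 <= n <= 8"):
            spearman_exact(np.arange(n), np.arange(n))


class TestRepresentatives:
    def panel(self):
        rows = []
        for p in ("P1", "P2"):
            for k in range(4):
                rows.append((f"{p}_i{k}", p, "pond", 100.0, 50.0))
        rows.append(("og", "OG", "outgroup", 1e6, 1e6))
        return PopulationPanel(
            pd.DataFrame(
                rows,
                columns=["individual", "population", "habitat", "ne_hist", "ne_now"],
            )
        )

    def test_one_member_per_population_and_deterministic(self):
        panel = self.panel()
        reps = choose_representatives(panel, seed=3)
        assert set(reps) == {"P1", "P2"}  # outgroup excluded
        for pop, ind in reps.items():
            assert ind in panel.members(pop)
        assert reps == choose_representatives(panel, seed=3)

    def test_population_vcv_relabels(self):
        panel = self.panel()
        inds = [i for p in ("P1", "P2") for i in panel.members(p)]
        rng = np.random.default_rng(0)
        A = rng.normal(size=(8, 8))
        V = pd.DataFrame(A @ A.T, index=inds, columns=inds)
        sub, reps = population_vcv(V, panel, seed=3)
        assert list(sub.index) == ["P1", "P2"]
        assert sub.loc["P1", "P2"] == V.loc[reps["P1"], reps["P2"]]
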