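"""Pruning likelihood, Gamma quadrature, GTR comparison model, AICc."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.special import logsumexp

from selon.core import (
    PopulationConfig,
    SelectionProfile,
    build_mutation_matrix,
    site_rate_matrix,
)
from selon.io import UCEAlignment
from selon.likelihood import (
    EigSystem,
    aicc,
    gtr_gamma_log_likelihood,
    gtr_rate_matrix,
    laguerre_gamma_rates,
    site_log_likelihood,
    transition_probabilities,
    uce_log_likelihood,
)
from selon.tree import RootedTree

from .conftest import make_alignment, random_rate_matrix, random_rooted_tree
from .oracles import enumerate_loglik


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, rng=np.random.default_rng(0)):
        q = random_rate_matrix(rng)
        assert np.allclose(transition_probabilities(q, 0.0), np.eye(4), atol=1e-14)

    def test_short_time_first_order_series(self):
        rng = np.random.default_rng(1)
        q = random_rate_matrix(rng)
        t = 1e-6
        p = transition_probabilities(q, t)
        assert np.allclose(p, np.eye(4) + q * t, atol=1e-9)

    def test_long_time_reaches_stationarity(self, unrest_unit):
        from selon.core import equilibrium_frequencies

        q = unrest_unit.matrix
        pi = equilibrium_frequencies(q)
        p = transition_probabilities(q, 1e4)
        assert np.allclose(p, np.tile(pi, (4, 1)), atol=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(np.zeros((4, 4)), -0.1)

    def test_batched_eig_matches_expm(self):
        rng = np.random.default_rng(2)
        q = np.stack([random_rate_matrix(rng) for _ in range(30)])
        eig = EigSystem(q)
        for t in (0.01, 0.3, 2.5):
            p = eig.transition(t)
            ref = np.stack([expm(qk * t) for qk in q])
            assert np.allclose(p, ref, atol=1e-10)


class TestPruning:
    def test_two_taxon_root_sum(self, unrest_unit, pop, profile):
        tree = RootedTree.from_newick("(a:0.15,b:0.3);")
        site = site_rate_matrix(25, 1, unrest_unit, profile, pop)
        p1 = expm(site.q_raw * 0.15)
        p2 = expm(site.q_raw * 0.3)
        expected = np.log(sum(site.pi[r] * p1[r, 0] * p2[r, 2] for r in range(4)))
        got = site_log_likelihood(tree, np.array([0, 2]), site)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_four_taxon_matches_enumeration(self, four_taxon_tree, unrest_unit, pop, profile):
        site = site_rate_matrix(10, 3, unrest_unit, profile, pop)
        pattern = np.array([0, 1, 2, 1])
        expected = enumerate_loglik(four_taxon_tree, pattern, site.q_raw, site.pi)
        got = site_log_likelihood(four_taxon_tree, pattern, site)
        assert got == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("n_taxa", [3, 4, 5])
    def test_random_trees_match_enumeration(self, n_taxa):
        """Pruning equals exhaustive internal-state enumeration on random
        trees, matrices and patterns (including missing data)."""
        rng = np.random.default_rng(100 + n_taxa)
        from selon.core import SiteModel, equilibrium_frequencies

        for _ in range(12):
            tree = random_rooted_tree(rng, n_taxa)
            q = random_rate_matrix(rng)
            pi = equilibrium_frequencies(q)
            pattern = rng.integers(0, 5, size=n_taxa)
            site = SiteModel(position=1, sensitivity=0.0, q_raw=q, pi=pi)
            got = site_log_likelihood(tree, pattern, site)
            expected = enumerate_loglik(tree, pattern, q, pi)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_all_missing_column_contributes_zero(self, four_taxon_tree, unrest_unit, pop, profile):
        site = site_rate_matrix(5, 0, unrest_unit, profile, pop)
        got = site_log_likelihood(four_taxon_tree, np.array([4, 4, 4, 4]), site)
        assert got == pytest.approx(0.0, abs=1e-12)

    def test_uce_likelihood_is_additive(self, four_taxon_tree, unrest_unit, pop, profile):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, size=(4, 20)).astype(np.int8)
        sites = [
            site_rate_matrix(k + 1, int(codes[0, k]), unrest_unit, profile, pop)
            for k in range(20)
        ]
        full = make_alignment(codes, taxa=four_taxon_tree.taxa)
        left = make_alignment(codes[:, :8], taxa=four_taxon_tree.taxa)
        right = make_alignment(codes[:, 8:], taxa=four_taxon_tree.taxa)
        total = uce_log_likelihood(four_taxon_tree, full, sites)
        assert total == pytest.approx(
            uce_log_likelihood(four_taxon_tree, left, sites[:8])
            + uce_log_likelihood(four_taxon_tree, right, sites[8:]),
            abs=1e-8,
        )

    def test_leaf_permutation_invariance(self, unrest_unit, pop, profile):
        treeA = RootedTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07);")
        treeB = RootedTree.from_newick("((b:0.2,a:0.1):0.05,(d:0.1,c:0.3):0.07);")
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 4, size=(4, 15)).astype(np.int8)
        sites = [
            site_rate_matrix(k + 1, 0, unrest_unit, profile, pop) for k in range(15)
        ]
        alnA = make_alignment(codes, taxa=("a", "b", "c", "d"))
        assert uce_log_likelihood(treeA, alnA, sites) == pytest.approx(
            uce_log_likelihood(treeB, alnA, sites), abs=1e-9
        )

    def test_missing_taxon_equals_pruned_tree(self, unrest_unit, pop, profile):
        """A leaf whose data are entirely missing leaves every site
        log-likelihood unchanged relative to dropping it from the tree."""
        tree5 = RootedTree.from_newick(
            "(((a:0.1,b:0.2):0.05,e:0.4):0.03,(c:0.3,d:0.1):0.07);"
        )
        tree4 = tree5.drop_leaf("e")
        rng = np.random.default_rng(11)
        codes5 = rng.integers(0, 4, size=(5, 10)).astype(np.int8)
        codes5[tree5.taxa.index("e")] = 4  # all missing
        sites = [
            site_rate_matrix(k + 1, 1, unrest_unit, profile, pop) for k in range(10)
        ]
        aln5 = make_alignment(codes5, taxa=tree5.taxa)
        keep = [t for t in tree5.taxa if t != "e"]
        codes4 = codes5[[tree5.taxa.index(t) for t in keep]]
        aln4 = make_alignment(codes4, taxa=keep)
        assert uce_log_likelihood(tree5, aln5, sites) == pytest.approx(
            uce_log_likelihood(tree4, aln4, sites), abs=1e-9
        )


class TestLaguerreGamma:
    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 3.7, 100.0])
    @pytest.mark.parametrize("ncat", [4, 8])
    def test_normalization(self, alpha, ncat):
        g = laguerre_gamma_rates(alpha, ncat)
        assert g.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert g.weights @ g.rates == pytest.approx(1.0, abs=1e-8)
        assert np.all(g.rates > 0) and np.all(g.weights > 0)

    def test_large_alpha_concentrates_near_one(self):
        # the unit-mean Gamma(alpha, alpha) has sd 1/sqrt(alpha); the four
        # scaled nodes sit within ~2.8 sd of 1 (outermost node at alpha=100
        # is 1.2749, directly verified against scipy's quadrature nodes)
        g = laguerre_gamma_rates(100.0, 4)
        assert np.all((g.rates > 0.75) & (g.rates < 1.30))
        g = laguerre_gamma_rates(1000.0, 4)
        assert np.all((g.rates > 0.9) & (g.rates < 1.1))

    def test_second_moment_matches_gamma(self):
        g = laguerre_gamma_rates(0.5, 4)
        # E[r^2] = 1 + 1/alpha for the unit-mean Gamma density
        assert g.weights @ (g.rates**2) == pytest.approx(3.0, rel=0.05)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            laguerre_gamma_rates(0.0, 4)


class TestGtrGamma:
    exch = np.array([1.2, 3.5, 0.8, 1.1, 4.2])
    freqs = np.array([0.3, 0.2, 0.25, 0.25])

    def test_single_category_equals_plain_gtr(self, four_taxon_tree):
        rng = np.random.default_rng(21)
        aln = make_alignment(
            rng.integers(0, 4, size=(4, 30)), taxa=four_taxon_tree.taxa
        )
        plain = gtr_gamma_log_likelihood(
            four_taxon_tree, aln, self.exch, self.freqs, gamma=None
        )
        one_cat = gtr_gamma_log_likelihood(
            four_taxon_tree, aln, self.exch, self.freqs, laguerre_gamma_rates(5.0, 1)
        )
        assert one_cat == pytest.approx(plain, abs=1e-9)

    def test_three_taxon_brute_force_with_categories(self):
        tree = RootedTree.from_newick("((a:0.2,b:0.1):0.05,c:0.3);")
        rng = np.random.default_rng(22)
        aln = make_alignment(rng.integers(0, 4, size=(3, 12)), taxa=tree.taxa)
        gamma = laguerre_gamma_rates(0.7, 4)
        got = gtr_gamma_log_likelihood(tree, aln, self.exch, self.freqs, gamma)
        q = gtr_rate_matrix(self.exch, self.freqs)
        expected = 0.0
        for k in range(12):
            per_cat = [
                enumerate_loglik(tree, aln.codes[:, k], q * r, self.freqs)
                for r in gamma.rates
            ]
            expected += logsumexp(np.log(gamma.weights) + np.array(per_cat))
        assert got == pytest.approx(expected, abs=1e-8)

    def test_huge_alpha_approaches_plain_gtr(self, four_taxon_tree):
        rng = np.random.default_rng(23)
        aln = make_alignment(
            rng.integers(0, 4, size=(4, 50)), taxa=four_taxon_tree.taxa
        )
        g = laguerre_gamma_rates(1000.0, 4)
        with_g = gtr_gamma_log_likelihood(four_taxon_tree, aln, self.exch, self.freqs, g)
        plain = gtr_gamma_log_likelihood(
            four_taxon_tree, aln, self.exch, self.freqs, None
        )
        assert abs(with_g - plain) / 50 < 1e-3

    def test_rerooting_invariance(self):
        """The reversible comparison model is invariant to root placement;
        the selection model is not, and the engine never reroots."""
        treeA = RootedTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07);")
        # same unrooted tree rooted inside the (c,d) clade edge
        treeB = RootedTree.from_newick("(((a:0.1,b:0.2):0.12,c:0.3):0.02,d:0.08);")
        rng = np.random.default_rng(24)
        aln = make_alignment(rng.integers(0, 4, size=(4, 40)), taxa=("a", "b", "c", "d"))
        g = laguerre_gamma_rates(1.3, 4)
        la = gtr_gamma_log_likelihood(treeA, aln, self.exch, self.freqs, g)
        lb = gtr_gamma_log_likelihood(treeB, aln, self.exch, self.freqs, g)
        assert la == pytest.approx(lb, abs=1e-8)


class TestAicc:
    def test_zero_parameters(self):
        assert aicc(-100.0, 0, 10, 100) == pytest.approx(200.0)

    def test_small_sample_correction(self):
        assert aicc(-100.0, 5, 10, 100) == pytest.approx(210.0 + 60.0 / 994.0)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 5, 1000, 10000) == pytest.approx(210.0, abs=1e-2)

    def test_degenerate_sample_size_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 1, 6)


class TestScalingAndRooting:
    def _selected_site(self):
        from selon.core import (
            PopulationConfig,
            scale_sites,
        )

        mut = build_mutation_matrix("UNREST", np.linspace(0.5, 2.5, 11))
        site = site_rate_matrix(
            10, 2, mut, SelectionProfile(3.0, 10.0, 4.0), PopulationConfig()
        )
        scale_sites([site])
        return site

    def test_scaling_invariance(self):
        """Multiplying all branch lengths by c and dividing the scaled rate
        matrix by c leaves the site likelihood unchanged."""
        from selon.core import SiteModel

        site = self._selected_site()
        tree = RootedTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07);")
        pattern = np.array([0, 1, 2, 1])
        base = site_log_likelihood(tree, pattern, site)
        for c in (0.2, 3.7):
            rescaled = SiteModel(
                position=site.position,
                sensitivity=site.sensitivity,
                q_raw=site.q_raw,
                pi=site.pi,
                q_scaled=site.q_scaled / c,
            )
            stretched = tree.copy()
            stretched.lengths = tree.lengths * c
            assert site_log_likelihood(stretched, pattern, rescaled) == pytest.approx(
                base, abs=1e-8
            )

    def test_selection_model_is_not_rerooting_invariant(self):
        """With selection the process is non-reversible: rerooting the same
        unrooted tree changes the likelihood (the engine therefore never
        applies pulley-principle rerooting)."""
        site = self._selected_site()
        tree_a = RootedTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.07);")
        tree_b = RootedTree.from_newick("(((a:0.1,b:0.2):0.12,c:0.3):0.02,d:0.08);")
        pattern = np.array([0, 1, 2, 1])
        la = site_log_likelihood(tree_a, pattern, site)
        lb = site_log_likelihood(tree_b, pattern, site)
        # the shift is small (root placement has limited leverage) but real,
        # far above the pruning accuracy of ~1e-12
        assert abs(la - lb) > 1e-8
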