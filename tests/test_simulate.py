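"""Random graphs, DE patterns, covariance construction, and sampling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from cone import (
    BoundarySet,
    DEPatternConfig,
    GraphConfig,
    Relationship,
    SignedLink,
    SignedNetwork,
    Subnetwork,
    assign_link_signs,
    baseline_means,
    boundary,
    build_covariance,
    coherent_de,
    generate_graph,
    grow_module,
    is_coherent,
    modular_de,
    sample_dataset,
    scattered_de,
    simulate_dataset,
    simulate_truth,
)

from conftest import make_link


class TestGenerateGraph:
    def test_er_counts(self):
        net = generate_graph(GraphConfig(family="exponential_er", v=500, e=2000), seed=1)
        assert net.n_genes == 500
        assert net.n_links == 2000

    def test_er_links_are_unique_unordered_pairs(self):
        net = generate_graph(GraphConfig(family="exponential_er", v=40, e=300), seed=2)
        keys = {tuple(sorted(k)) for k in net.link_keys}
        assert len(keys) == 300

    def test_ba_exact_link_count(self):
        """Preferential attachment adds min(m, t) links for node t, so a
        (v, m=2) graph has 1 + 2(v-2) links."""
        for v in (10, 100, 500):
            net = generate_graph(GraphConfig(family="scale_free_ba", v=v, power=1, m=2), seed=3)
            assert net.n_genes == v
            assert net.n_links == 1 + 2 * (v - 2)

    def test_er_degrees_approximately_poisson(self, rng):
        """Pooled degree distribution over 100 small ER draws matches a
        Poisson with mean 2e/v at coarse tolerance."""
        v, e = 500, 1000
        degrees = []
        for i in range(100):
            net = generate_graph(GraphConfig(family="exponential_er", v=v, e=e), seed=1000 + i)
            degrees.extend(net.degree(g) for g in net.genes)
        degrees = np.array(degrees)
        lam = 2 * e / v
        assert degrees.mean() == pytest.approx(lam, rel=0.02)
        assert degrees.var() == pytest.approx(lam, rel=0.05)  # Poisson: var = mean
        # coarse goodness of fit on the pooled counts
        kmax = 10
        observed = np.bincount(np.minimum(degrees, kmax), minlength=kmax + 1)
        pmf = sp_stats.poisson.pmf(np.arange(kmax), lam)
        expected = np.append(pmf, 1 - pmf.sum()) * degrees.size
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < sp_stats.chi2.ppf(0.999, df=kmax)

    def test_infeasible_er_errors(self):
        with pytest.raises(ValueError, match="e must be"):
            GraphConfig(family="exponential_er", v=5, e=100)

    def test_ba_degree_distribution_is_heavy_tailed(self):
        net = generate_graph(GraphConfig(family="scale_free_ba", v=500, power=1, m=2), seed=4)
        degrees = sorted((net.degree(g) for g in net.genes), reverse=True)
        # a hub far above the mean degree (~4) is the scale-free signature
        assert degrees[0] > 20


class TestAssignLinkSigns:
    def _graph(self, seed=0):
        return generate_graph(GraphConfig(family="exponential_er", v=50, e=150), seed=seed)

    def test_forced_all_non_inhibiting(self):
        net, p = assign_link_signs(self._graph(), seed=1, p=1.0)
        assert p == 1.0
        assert all(l.relationship is Relationship.NON_INHIBITING for l in net.links)

    def test_forced_all_inhibiting(self):
        net, p = assign_link_signs(self._graph(), seed=1, p=0.0)
        assert all(l.relationship is Relationship.INHIBITING for l in net.links)

    def test_mean_inducing_fraction_matches_uniform_mixture(self, rng):
        """Over 200 graphs the realized inducing fraction averages ~0.785,
        the mean of U(0.72, 0.85)."""
        fractions = []
        for i in range(200):
            net, _ = assign_link_signs(self._graph(seed=i), seed=5000 + i)
            inducing = sum(1 for l in net.links if l.weight == 1)
            fractions.append(inducing / net.n_links)
        mean = float(np.mean(fractions))
        assert 0.72 < mean < 0.85
        assert mean == pytest.approx(0.785, abs=0.01)


class TestBaselineMeans:
    def test_support(self):
        mu = baseline_means(1000, 4.0, seed=1)
        assert (np.abs(mu) <= 4.0).all()

    def test_mean_near_zero(self):
        mu = baseline_means(100_000, 4.0, seed=2)
        assert abs(mu.mean()) < 0.05

    def test_mean_absolute_value_is_half_d(self):
        # E|U(-4, 4)| = 2 by direct integration
        mu = baseline_means(100_000, 4.0, seed=3)
        assert np.abs(mu).mean() == pytest.approx(2.0, abs=0.02)


class TestScatteredDE:
    def _mu0(self, v=500):
        return pd.Series(np.zeros(v), index=[f"g{i:04d}" for i in range(v)])

    def test_exact_de_count(self):
        mu1, genes = scattered_de(self._mu0(), 0.01, 4.0, seed=1)
        assert len(genes) == 5  # round(0.01 * 500)

    def test_non_selected_genes_unchanged(self):
        mu0 = self._mu0()
        mu1, genes = scattered_de(mu0, 0.1, 4.0, seed=2)
        untouched = mu0.index.difference(list(genes))
        assert (mu1.loc[untouched] == mu0.loc[untouched]).all()

    def test_mean_absolute_offset_half_d(self):
        """d=4 corresponds to mean |dE| = 2 across simulations."""
        offsets = []
        mu0 = self._mu0(2000)
        for i in range(50):
            mu1, genes = scattered_de(mu0, 0.5, 4.0, seed=100 + i)
            offsets.extend(np.abs(mu1 - mu0)[list(genes)])
        assert np.mean(offsets) == pytest.approx(2.0, abs=0.03)

    def test_zero_genes_warns(self):
        with pytest.warns(UserWarning, match="zero DE genes"):
            mu1, genes = scattered_de(self._mu0(10), 0.01, 4.0, seed=1)
        assert genes == set()


class TestGrowModule:
    def _net(self, seed=0):
        return generate_graph(GraphConfig(family="scale_free_ba", v=200, m=2), seed=seed)

    def test_singleton(self):
        assert len(grow_module(self._net(), 1, seed=1)) == 1

    def test_induced_subgraph_connected_and_exact_size(self):
        import networkx as nx

        net = self._net()
        for seed in range(10):
            module = grow_module(net, 25, seed=seed)
            assert len(module) == 25
            g = nx.Graph()
            g.add_nodes_from(module)
            members = set(module)
            for gene in module:
                for nb in net.neighbors(gene):
                    if nb in members:
                        g.add_edge(gene, nb)
            assert nx.is_connected(g)

    def test_addition_order_has_earlier_neighbour(self):
        net = self._net()
        module = grow_module(net, 30, seed=7)
        for idx in range(1, len(module)):
            assert any(g in net.neighbors(module[idx]) for g in module[:idx])

    def test_excluded_genes_never_selected(self):
        net = self._net()
        excluded = set(list(net.genes)[:50])
        module = grow_module(net, 20, excluded_genes=excluded, seed=3)
        assert not set(module) & excluded

    def test_stalled_growth_errors(self):
        # two linked pairs cannot host a connected 3-gene module
        net = SignedNetwork([make_link("A", "B"), make_link("C", "D")])
        with pytest.raises(RuntimeError, match="could not grow"):
            grow_module(net, 3, seed=1, max_restarts=5)


class TestCoherentDE:
    def test_sign_propagation_along_chain(self, chain3):
        """A-(induce)-B-(inhibit)-C gives psi = (+1, +1, -1)."""
        mu0 = pd.Series(0.0, index=["A", "B", "C"])
        mu1, psi, truth = coherent_de(chain3, ["A", "B", "C"], mu0, 4.0, seed=1)
        assert psi == {"A": 1, "B": 1, "C": -1}
        assert truth.link_keys == chain3.link_keys  # both spanning links coherent

    def test_every_truth_link_coherent_under_delta(self):
        net = generate_graph(GraphConfig(family="scale_free_ba", v=200, m=2), seed=2)
        net, _ = assign_link_signs(net, seed=3)
        mu0 = pd.Series(baseline_means(200, 8.0, seed=4), index=sorted(map(str, net.genes)))
        module = grow_module(net, 40, seed=5)
        mu1, psi, truth = coherent_de(net, module, mu0, 8.0, seed=6)
        delta = mu1 - mu0
        for link in truth.links:
            assert is_coherent(delta[link.source], delta[link.target], link.weight)
        # spanning structure: the truth subnetwork is connected
        from cone import connected_components

        assert len(connected_components(truth)) == 1

    def test_all_inducing_module_all_signs_equal(self):
        net = SignedNetwork([make_link("A", "B"), make_link("B", "C"), make_link("C", "D")])
        mu0 = pd.Series(0.0, index=list("ABCD"))
        _, psi, _ = coherent_de(net, ["A", "B", "C", "D"], mu0, 4.0, seed=1)
        assert set(psi.values()) == {1}

    def test_disconnected_order_errors(self):
        net = SignedNetwork([make_link("A", "B"), make_link("C", "D")])
        mu0 = pd.Series(0.0, index=list("ABCD"))
        with pytest.raises(ValueError, match="no earlier linked neighbour"):
            coherent_de(net, ["A", "C"], mu0, 4.0, seed=1)

    def test_three_modules_average_size_five(self):
        """Three-module low-density pattern on v=500: 3% DE split across
        three modules gives average module size 5."""
        net = generate_graph(GraphConfig(family="scale_free_ba", v=500, m=2), seed=9)
        net, _ = assign_link_signs(net, seed=10)
        mu0 = pd.Series(baseline_means(500, 8.0, seed=11), index=sorted(map(str, net.genes)))
        mu1, psi, truth, modules = modular_de(net, mu0, 0.03, 3, 8.0, seed=12)
        assert len(modules) == 3
        assert np.mean([len(m) for m in modules]) == pytest.approx(5.0)
        assert truth.n_genes == 15
        # modules are disjoint
        assert len(set().union(*map(set, modules))) == 15


class TestBuildCovariance:
    def _signed(self, v=80, e=240, seed=0):
        net = generate_graph(GraphConfig(family="exponential_er", v=v, e=e), seed=seed)
        net, _ = assign_link_signs(net, seed=seed + 1)
        return net

    def test_condition_number_equals_gene_count(self):
        net = self._signed()
        cov = build_covariance(net, seed=1)
        w = np.linalg.eigvalsh(cov.precision)
        assert w[-1] / w[0] == pytest.approx(80, rel=1e-6)
        assert cov.condition_number == pytest.approx(80, rel=1e-9)

    def test_inverse_covariance_zero_pattern_matches_non_links(self):
        """(Sigma^-1)_jk = 0 exactly for unlinked gene pairs."""
        net = self._signed(v=60, e=150, seed=3)
        cov = build_covariance(net, seed=4)
        prec = np.linalg.inv(cov.covariance)
        genes = cov.genes
        idx = {g: i for i, g in enumerate(genes)}
        linked = {frozenset(k) for k in net.link_keys}
        scale = np.abs(prec).max()
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                entry = prec[i, j]
                if frozenset((genes[i], genes[j])) in linked:
                    continue
                assert abs(entry) < 1e-8 * scale

    def test_partial_correlation_sign_opposite_relationship(self):
        """Inhibiting links yield negative partial correlation: the
        precision off-diagonal is +|u| for inhibiting, -|u| for inducing."""
        net = self._signed(v=50, e=120, seed=5)
        cov = build_covariance(net, seed=6)
        idx = {g: i for i, g in enumerate(cov.genes)}
        for link in net.links:
            entry = cov.precision[idx[str(link.source)], idx[str(link.target)]]
            # rho_jk = -p_jk / sqrt(p_jj p_kk): inhibiting => rho < 0 => p_jk > 0
            assert np.sign(entry) == -link.weight

    def test_lambda_shift_three_gene_closed_form(self):
        """Fixed weights on a 3-gene toy: lambda2 = (lam_max + lambda1)/(v-1)
        against direct eigenvalue computation."""
        net = SignedNetwork([make_link("A", "B"), make_link("B", "C", "inhibit")])
        weights = {("A", "B"): 0.6, ("B", "C"): 0.9}
        cov = build_covariance(net, bnd=BoundarySet.empty(), seed=1, link_weights=weights)
        a = np.zeros((3, 3))
        # +1 non-boundary boost, then sign -w
        a[0, 1] = a[1, 0] = -1.0 * 1.6
        a[1, 2] = a[2, 1] = +1.0 * 1.9
        w = np.linalg.eigvalsh(a)
        lam1 = -w[0]
        lam2 = (w[-1] + lam1) / 2
        assert cov.lambda1 == pytest.approx(lam1)
        assert cov.lambda2 == pytest.approx(lam2)
        assert np.allclose(cov.precision, a + (lam1 + lam2) * np.eye(3))

    def test_lambda1_makes_psd_and_lambda2_positive(self):
        net = self._signed(seed=7)
        cov = build_covariance(net, seed=8)
        assert cov.lambda2 > 0
        step3 = cov.precision - (cov.lambda1 + cov.lambda2) * np.eye(len(cov.genes))
        w = np.linalg.eigvalsh(step3 + cov.lambda1 * np.eye(len(cov.genes)))
        assert w.min() >= -1e-10

    def test_boundary_links_not_boosted(self):
        """Boundary links keep U(0.5, 1) magnitudes; non-boundary links get
        +1, so module-internal coupling is strictly stronger."""
        net = self._signed(seed=9)
        some_links = sorted(net.link_keys)[:40]
        bnd = BoundarySet(frozenset(), frozenset(some_links))
        cov = build_covariance(net, bnd=bnd, seed=10)
        idx = {g: i for i, g in enumerate(cov.genes)}
        for link in net.links:
            mag = abs(cov.precision[idx[str(link.source)], idx[str(link.target)]])
            if link.key in bnd.boundary:
                assert 0.5 <= mag <= 1.0
            else:
                assert 1.5 <= mag <= 2.0


class TestSampleDataset:
    def _truth_cov(self, v=40, seed=0):
        return simulate_truth(
            GraphConfig(family="exponential_er", v=v, e=3 * v),
            DEPatternConfig(pattern="modular", fraction=0.2, n_modules=1, d=8),
            seed=seed,
        )

    def test_half_samples_per_class(self):
        truth, cov = self._truth_cov()
        ds = sample_dataset(truth, cov, 8, seed=1)
        assert (ds.class_labels == 0).sum() == 4
        assert (ds.class_labels == 1).sum() == 4

    def test_odd_n_errors(self):
        truth, cov = self._truth_cov()
        with pytest.raises(ValueError, match="even"):
            sample_dataset(truth, cov, 7, seed=1)

    def test_sample_means_converge_to_mu(self):
        truth, cov = self._truth_cov()
        ds = sample_dataset(truth, cov, 2000, seed=2)
        x = ds.expression.values
        mean0 = x.loc[:, ds.class_labels == 0].mean(axis=1)
        mean1 = x.loc[:, ds.class_labels == 1].mean(axis=1)
        sd = np.sqrt(np.diag(cov.covariance))
        tol = 5 * sd.max() / math.sqrt(1000)
        assert np.abs(mean0 - truth.mu0.loc[x.index]).max() < tol
        assert np.abs(mean1 - truth.mu1.loc[x.index]).max() < tol

    def test_sample_covariance_converges_in_frobenius_norm(self):
        truth, cov = self._truth_cov(v=25, seed=3)
        ds = sample_dataset(truth, cov, 4000, seed=4)
        x = ds.expression.values.loc[cov.genes]
        x0 = x.loc[:, ds.class_labels == 0].to_numpy()
        emp = np.cov(x0)
        rel = np.linalg.norm(emp - cov.covariance) / np.linalg.norm(cov.covariance)
        assert rel < 0.15


class TestEndToEnd:
    def test_truth_fully_coherent_and_modules_connected(self):
        import networkx as nx

        truth, _ = simulate_truth(
            GraphConfig(family="scale_free_ba", v=300, m=2),
            DEPatternConfig(pattern="modular", fraction=0.1, n_modules=3, d=8),
            seed=11,
        )
        delta = truth.deltas
        for link in truth.truth_subnetwork.links:
            assert is_coherent(delta[link.source], delta[link.target], link.weight)
        for module in truth.module_genes:
            g = nx.Graph()
            g.add_nodes_from(module)
            members = set(module)
            for gene in module:
                for nb in truth.network.neighbors(gene):
                    if nb in members:
                        g.add_edge(gene, nb)
            assert nx.is_connected(g)

    def test_null_pattern_mu_equal_and_truth_empty(self):
        truth, _ = simulate_truth(
            GraphConfig(family="exponential_er", v=60, e=150),
            DEPatternConfig(pattern="null", fraction=0.0, d=8),
            seed=12,
        )
        assert (truth.mu0 == truth.mu1).all()
        assert truth.truth_subnetwork.is_empty()
        assert truth.boundary.boundary == frozenset()

    def test_identical_seeds_bit_identical(self):
        cfgs = (
            GraphConfig(family="scale_free_ba", v=100, m=2),
            DEPatternConfig(pattern="modular", fraction=0.1, n_modules=1, d=8),
        )
        a = simulate_dataset(*cfgs, 16, seed=99)
        b = simulate_dataset(*cfgs, 16, seed=99)
        assert a.expression.values.equals(b.expression.values)
        assert a.truth.truth_subnetwork.link_keys == b.truth.truth_subnetwork.link_keys
        assert a.truth.inducing_proportion == b.truth.inducing_proportion

    def test_serialization_round_trip(self, tmp_path):
        import json

        from cone.simulate import write_simulation

        ds = simulate_dataset(
            GraphConfig(family="exponential_er", v=50, e=120),
            DEPatternConfig(pattern="modular", fraction=0.1, n_modules=1, d=8),
            8,
            seed=5,
        )
        write_simulation(ds, tmp_path, seed=5)
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert payload["n"] == 8
        assert set(payload["truth_genes"]) == set(map(str, ds.truth.truth_subnetwork.genes))
        expr = pd.read_csv(tmp_path / "expression.tsv", sep="\t", index_col=0)
        assert expr.shape == (50, 8)
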