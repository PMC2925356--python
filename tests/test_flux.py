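import numpy as np
import pandas as pd
import pytest

import pinentropy as pe
from pinentropy.flux import UndefinedEntropyError

from conftest import hub_flux_from_corr, star_net


class TestEdgeCorrelations:
    def test_identical_rows_give_one(self):
        pin = pe.PIN.from_edges([("A", "B")])
        expr = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 3, 4]],
                            index=["A", "B"], columns=list("wxyz"))
        net = pe.integrate(pin, expr)
        cf = pe.edge_correlations(net, list("wxyz"))
        assert cf.corr("A", "B") == pytest.approx(1.0)

    def test_negated_row_gives_minus_one(self):
        pin = pe.PIN.from_edges([("A", "B")])
        expr = pd.DataFrame([[1.0, 2, 3], [-1.0, -2, -3]],
                            index=["A", "B"], columns=list("xyz"))
        net = pe.integrate(pin, expr)
        assert pe.edge_correlations(net, list("xyz")).corr("A", "B") == \
            pytest.approx(-1.0)

    def test_matches_direct_formula(self, small_net):
        samples = small_net.samples[:5]
        cf = pe.edge_correlations(small_net, samples)
        x = small_net.expr[samples].to_numpy()
        for eid in range(0, small_net.n_edges, 37):
            i, j = small_net.edges_i[eid], small_net.edges_j[eid]
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            expected = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
            assert cf.values[eid] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_gene_gives_zero(self):
        pin = pe.PIN.from_edges([("A", "B")])
        expr = pd.DataFrame([[5.0, 5, 5], [1.0, 2, 3]],
                            index=["A", "B"], columns=list("xyz"))
        net = pe.integrate(pin, expr)
        assert pe.edge_correlations(net, list("xyz")).corr("A", "B") == 0.0

    def test_too_few_samples_error(self, chain_net):
        with pytest.raises(ValueError, match="at least 3"):
            pe.edge_correlations(chain_net, chain_net.samples[:2])


class TestWeightsAndFlux:
    def test_weight_transform_endpoints(self, chain_net):
        cf = pe.CorrelationField(chain_net, np.array([1.0, -1.0]))
        w = pe.weights_from_correlations(cf)
        assert list(w) == [1.0, 0.0]

    def test_zero_correlation_weight_half(self, chain_net):
        cf = pe.CorrelationField(chain_net, np.zeros(2))
        assert set(pe.weights_from_correlations(cf)) == {0.5}

    def test_worked_flux_vector(self):
        # six C=+1 and four C=-1 neighbours -> p = 1/6(1,1,1,1,1,1,0,0,0,0)
        net = star_net(10)
        flux, _ = hub_flux_from_corr(net, [1] * 6 + [-1] * 4)
        row = flux.row("HUB").to_numpy()
        assert np.allclose(sorted(row), [0] * 4 + [1 / 6] * 6)

    def test_zero_correlations_give_uniform_flux(self):
        net = star_net(10)
        flux, _ = hub_flux_from_corr(net, [0.0] * 10)
        assert np.allclose(flux.row("HUB").to_numpy(), 0.1)

    def test_row_sums_are_one(self, small_net):
        cf = pe.edge_correlations(small_net, small_net.samples[:30])
        flux = pe.stochastic_flux(pe.weights_from_correlations(cf), small_net)
        assert np.allclose(flux.row_sums(), 1.0, atol=1e-12)

    def test_not_doubly_stochastic(self, small_net):
        cf = pe.edge_correlations(small_net, small_net.samples[:30])
        flux = pe.stochastic_flux(pe.weights_from_correlations(cf), small_net)
        import scipy.sparse as sp
        mat = sp.csr_array(
            (flux.p, small_net.indices, small_net.indptr),
            shape=(small_net.n_nodes,) * 2,
        )
        col_sums = np.asarray(mat.sum(axis=0)).ravel()
        assert not np.allclose(col_sums, 1.0)

    def test_all_anticorrelated_falls_back_to_uniform(self):
        net = star_net(3)
        cf = pe.CorrelationField(net, np.array([-1.0, -1.0, -1.0]))
        with pytest.warns(UserWarning, match="uniform"):
            flux = pe.stochastic_flux(pe.weights_from_correlations(cf), net)
        assert np.allclose(flux.row("HUB").to_numpy(), 1 / 3)


class TestLocalEntropy:
    def test_worked_example_078(self):
        net = star_net(10)
        flux, _ = hub_flux_from_corr(net, [1] * 6 + [-1] * 4)
        assert pe.local_entropy(flux, "HUB") == pytest.approx(
            np.log(6) / np.log(10)
        )
        assert round(pe.local_entropy(flux, "HUB"), 2) == 0.78

    @pytest.mark.parametrize("k,half", [(10, 5), (100, 50)])
    def test_half_support_degree_examples(self, k, half):
        # half the neighbours at p = 1/half, rest 0 -> S = log(half)/log(k)
        net = star_net(k)
        flux, _ = hub_flux_from_corr(net, [1] * half + [-1] * (k - half))
        assert pe.local_entropy(flux, "HUB") == pytest.approx(
            np.log(half) / np.log(k), abs=1e-12
        )

    def test_uniform_flux_is_maximal(self):
        net = star_net(7)
        flux, _ = hub_flux_from_corr(net, [0.0] * 7)
        assert pe.local_entropy(flux, "HUB") == pytest.approx(1.0)

    def test_point_mass_is_zero(self):
        net = star_net(4)
        flux, _ = hub_flux_from_corr(net, [1.0, -1.0, -1.0, -1.0])
        assert pe.local_entropy(flux, "HUB") == 0.0

    def test_degree_one_undefined(self):
        net = star_net(4)
        flux, _ = hub_flux_from_corr(net, [0.5, 0.1, -0.2, 0.3])
        with pytest.raises(UndefinedEntropyError):
            pe.local_entropy(flux, "L000")

    def test_bounds_on_random_fields(self, small_net):
        rng = np.random.default_rng(5)
        for _ in range(3):
            cf = pe.CorrelationField(
                small_net, rng.uniform(-1, 1, small_net.n_edges)
            )
            flux = pe.stochastic_flux(pe.weights_from_correlations(cf), small_net)
            prof = pe.entropy_profile(flux)
            assert ((prof.S >= 0) & (prof.S <= 1)).all()

    def test_base_invariance(self, small_net):
        cf = pe.edge_correlations(small_net, small_net.samples[:20])
        flux = pe.stochastic_flux(pe.weights_from_correlations(cf), small_net)
        prof = pe.entropy_profile(flux)
        p, net = flux.p, small_net
        plogp = np.where(p > 0, p * np.log10(np.where(p > 0, p, 1.0)), 0.0)
        raw = -np.add.reduceat(plogp, net.indptr[:-1])
        s10 = raw / np.log10(net.degrees.astype(float))
        s10 = pd.Series(s10, index=net.nodes).loc[prof.S.index]
        assert np.allclose(prof.S, s10, atol=1e-12)

    def test_neighbour_relabelling_invariance(self):
        net = star_net(6)
        corr = [0.9, -0.3, 0.1, 0.5, -0.8, 0.2]
        flux_a, _ = hub_flux_from_corr(net, corr)
        flux_b, _ = hub_flux_from_corr(net, corr[::-1])
        assert pe.local_entropy(flux_a, "HUB") == pytest.approx(
            pe.local_entropy(flux_b, "HUB"), abs=1e-15
        )

    def test_profile_matches_per_node_brute_force(self, small_net):
        cf = pe.edge_correlations(small_net, small_net.samples[:15])
        flux = pe.stochastic_flux(pe.weights_from_correlations(cf), small_net)
        prof = pe.entropy_profile(flux)
        for node in list(prof.S.index)[::29]:
            assert prof.S[node] == pytest.approx(
                pe.local_entropy(flux, node), abs=1e-14
            )
        # nodes of degree < 2 are absent
        deg = small_net.degree_series()
        assert (deg.loc[prof.S.index] >= 2).all()


class TestDifferentials:
    def test_fig1_differential(self, fig1):
        net = fig1.integrated()
        fl_case, _ = hub_flux_from_corr_net(net, fig1, "case")
        fl_ctrl, _ = hub_flux_from_corr_net(net, fig1, "control")
        s_case = pe.entropy_profile(fl_case)
        s_ctrl = pe.entropy_profile(fl_ctrl)
        ds = pe.differential_entropy(s_case, s_ctrl)
        assert round(float(ds["HUB"]), 2) == 0.22

    def test_identical_profiles_zero(self, small_net):
        cf = pe.edge_correlations(small_net, small_net.samples[:10])
        flux = pe.stochastic_flux(pe.weights_from_correlations(cf), small_net)
        prof = pe.entropy_profile(flux)
        assert (pe.differential_entropy(prof, prof) == 0).all()

    def test_antisymmetry(self, small_net):
        cf1 = pe.edge_correlations(small_net, small_net.samples[:20])
        cf2 = pe.edge_correlations(small_net, small_net.samples[20:40])
        fl1 = pe.stochastic_flux(pe.weights_from_correlations(cf1), small_net)
        fl2 = pe.stochastic_flux(pe.weights_from_correlations(cf2), small_net)
        p1, p2 = pe.entropy_profile(fl1), pe.entropy_profile(fl2)
        assert np.allclose(
            pe.differential_entropy(p1, p2), -pe.differential_entropy(p2, p1)
        )

    def test_mismatched_node_sets_error(self, small_net):
        cf = pe.edge_correlations(small_net, small_net.samples[:10])
        flux = pe.stochastic_flux(pe.weights_from_correlations(cf), small_net)
        prof = pe.entropy_profile(flux)
        truncated = pe.EntropyProfile(prof.S.iloc[:-1])
        with pytest.raises(ValueError, match="node sets"):
            pe.differential_entropy(prof, truncated)

    def test_mean_local_correlation_worked(self):
        net = star_net(4)
        _, cf = hub_flux_from_corr(net, [1.0, 1.0, -1.0, -1.0])
        d = pe.mean_local_correlation(cf)
        h = pe.mean_local_abs_correlation(cf)
        assert d["HUB"] == pytest.approx(0.0)
        assert h["HUB"] == pytest.approx(1.0)

    def test_all_zero_correlations(self):
        net = star_net(5)
        _, cf = hub_flux_from_corr(net, [0.0] * 5)
        assert pe.mean_local_correlation(cf)["HUB"] == 0.0
        assert pe.mean_local_abs_correlation(cf)["HUB"] == 0.0

    def test_mean_local_matches_brute_force(self, small_net):
        cf = pe.edge_correlations(small_net, small_net.samples[:12])
        d = pe.mean_local_correlation(cf)
        g = small_net.graph
        for node in list(small_net.nodes)[::43]:
            vals = [cf.corr(node, nb) for nb in g.neighbors(node)]
            assert d[node] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_differential_metric_sign_convention(self):
        a = pd.Series([0.2], index=["g"])
        b = pd.Series([0.5], index=["g"])
        h = pd.Series([0.0], index=["g"])
        dd, dh = pe.differential_metrics(a, b, h, h)
        assert dd["g"] == pytest.approx(0.3)  # correlation dropped -> positive
        assert dh["g"] == 0.0

    def test_planted_nodes_lose_absolute_correlation(self, small_cohort, small_net):
        labels = small_cohort.labels
        cf_case = pe.edge_correlations(small_net, labels.samples("case"))
        cf_ctrl = pe.edge_correlations(small_net, labels.samples("control"))
        h_case = pe.mean_local_abs_correlation(cf_case)
        h_ctrl = pe.mean_local_abs_correlation(cf_ctrl)
        dh = -(h_case - h_ctrl)
        assert dh.loc[small_cohort.planted].median() > 0


def hub_flux_from_corr_net(net, fx, phenotype):
    samples = fx.labels.samples(phenotype)
    cf = pe.edge_correlations(net, samples)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        flux = pe.stochastic_flux(pe.weights_from_correlations(cf), net)
    return flux, cf
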