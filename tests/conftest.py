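import numpy as np
import pandas as pd
import pytest

import pinentropy as pe


@pytest.fixture
def chain_net():
    """Integrated 3-node chain A-B-C with a tiny expression matrix."""
    pin = pe.PIN.from_edges([("A", "B"), ("B", "C")])
    rng = np.random.default_rng(42)
    expr = pd.DataFrame(
        rng.standard_normal((3, 6)),
        index=["A", "B", "C"],
        columns=[f"s{i}" for i in range(6)],
    )
    return pe.integrate(pin, expr)


@pytest.fixture
def fig1():
    return pe.worked_star_example()


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted-decorrelation cohort shared by read-only tests."""
    spec = pe.SyntheticCohortSpec(
        n_nodes=300, n_samples=60, f_disrupted=0.03, seed=11
    )
    return pe.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_net(small_cohort):
    return small_cohort.integrated()


def star_net(k: int, n_samples: int = 6, seed: int = 0):
    """Integrated star: hub with k leaves and random expression."""
    hub = "HUB"
    leaves = [f"L{i:03d}" for i in range(k)]
    pin = pe.PIN.from_edges([(hub, leaf) for leaf in leaves])
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.standard_normal((k + 1, n_samples)),
        index=[hub] + leaves,
        columns=[f"s{i}" for i in range(n_samples)],
    )
    return pe.integrate(pin, expr)


def hub_flux_from_corr(net, corr):
    """Flux matrix of a star network from explicit hub-leaf correlations."""
    hub_idx = net.index_of("HUB")
    values = np.asarray(corr, dtype=float)
    # edges are sorted by (lo, hi); map each edge to its leaf position
    order = np.argsort(
        [net.nodes[j if i == hub_idx else i]
         for i, j in zip(net.edges_i, net.edges_j)]
    )
    edge_vals = np.empty(net.n_edges)
    edge_vals[order] = values
    cf = pe.CorrelationField(net, edge_vals)
    import warnings

    with warnings.catch_warnings():
        # leaves with a single C = -1 edge trigger the uniform-flux fallback
        warnings.simplefilter("ignore")
        flux = pe.stochastic_flux(pe.weights_from_correlations(cf), net)
    return flux, cf
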