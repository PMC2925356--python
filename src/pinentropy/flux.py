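"""Stochastic information-flux matrix and local network entropy.

Per phenotype, each PIN edge {i, j} carries the Pearson correlation C_ij of
the two genes' expression across that phenotype's samples.  The monotone
transform w_ij = (1 + C_ij)/2 maps correlations into [0, 1] flux weights
(strong positive correlation -> ~1, absent correlation -> 0.5, strong
anti-correlation -> ~0).  Row normalisation over each node's neighbourhood,

    p_ij = w_ij / sum_{j' in N(i)} w_ij',

yields a row-stochastic matrix interpreted as the relative probability of
signal transmission from i to each neighbour.  The local entropy

    S_i = -(1 / log k_i) * sum_{j in N(i)} p_ij log p_ij

measures the randomness of that local flux distribution, normalised by the
maximum attainable at degree k_i so that S_i is in [0, 1] (and is independent
of the logarithm base).  S_i is undefined for k_i < 2.

The differential entropy dS_i = S_i(case) - S_i(control) and the competing
mean local (absolute) correlation metrics, sign-flipped so that larger values
always mean *more disorder in the case phenotype*, are also computed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import IntegratedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationField",
    "FluxMatrix",
    "EntropyProfile",
    "DifferentialProfile",
    "edge_correlations",
    "weights_from_correlations",
    "stochastic_flux",
    "local_entropy",
    "entropy_profile",
    "differential_entropy",
    "mean_local_correlation",
    "mean_local_abs_correlation",
    "differential_metrics",
]


class UndefinedEntropyError(ValueError):
    """Local entropy requested for a node of degree < 2."""


@dataclass
class CorrelationField:
    """Per-edge Pearson correlations for one phenotype.

    ``values[eid]`` is C_ij for the undirected edge ``eid`` of ``net``
    (supported only on PIN edges; C is symmetric by construction).
    """

    net: IntegratedNetwork
    values: np.ndarray  # shape (n_edges,), in [-1, 1]
    phenotype: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.net.n_edges,):
            raise ValueError(
                f"expected {self.net.n_edges} edge correlations, "
                f"got shape {self.values.shape}"
            )
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("edge correlations must lie in [-1, 1]")

    def csr_data(self) -> np.ndarray:
        """Correlations expanded to CSR slot order (both directions)."""
        return self.values[self.net.edge_id]

    def corr(self, u: str, v: str) -> float:
        i, j = self.net.index_of(u), self.net.index_of(v)
        lo, hi = min(i, j), max(i, j)
        eid = np.flatnonzero((self.net.edges_i == lo) & (self.net.edges_j == hi))
        if len(eid) == 0:
            raise KeyError(f"{u!r}-{v!r} is not a PIN edge")
        return float(self.values[eid[0]])

    @classmethod
    def from_edge_values(
        cls, net: IntegratedNetwork, mapping: dict, phenotype: str | None = None
    ) -> "CorrelationField":
        """Build a field from an explicit {(u, v): C} edge dictionary."""
        values = np.zeros(net.n_edges)
        seen = np.zeros(net.n_edges, dtype=bool)
        for (u, v), c in mapping.items():
            i, j = net.index_of(u), net.index_of(v)
            lo, hi = min(i, j), max(i, j)
            eid = np.flatnonzero((net.edges_i == lo) & (net.edges_j == hi))
            if len(eid) == 0:
                raise KeyError(f"{u!r}-{v!r} is not a PIN edge")
            values[eid[0]] = c
            seen[eid[0]] = True
        if not seen.all():
            raise ValueError("correlation missing for some PIN edges")
        return cls(net, values, phenotype)


def edge_correlations(
    net: IntegratedNetwork,
    samples,
    expr: pd.DataFrame | None = None,
    phenotype: str | None = None,
) -> CorrelationField:
    """Pearson correlation per PIN edge across the given samples.

    ``expr`` optionally overrides the network's expression matrix (same gene
    alignment); used for randomisation replicates.  Genes with zero variance
    across the samples yield C = 0 on all their edges (the "no correlation"
    convention, equivalent to flux weight 0.5).
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError(f"need at least 3 samples, got {len(samples)}")
    source = net.expr if expr is None else expr.loc[net.nodes]
    x = source[samples].to_numpy(dtype=float)
    z = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((z**2).sum(axis=1))
    zero_var = norm == 0
    norm[zero_var] = 1.0
    z /= norm[:, None]
    z[zero_var] = 0.0
    c = np.einsum("ij,ij->i", z[net.edges_i], z[net.edges_j])
    np.clip(c, -1.0, 1.0, out=c)
    return CorrelationField(net, c, phenotype)


def weights_from_correlations(cf: CorrelationField) -> np.ndarray:
    """Flux weights w = (1 + C)/2 per undirected edge, in [0, 1]."""
    return (1.0 + cf.values) / 2.0


@dataclass
class FluxMatrix:
    """Row-stochastic flux matrix supported on the PIN edges.

    ``p`` and ``weights`` are stored in CSR slot order: slot s of node i's
    block holds p_ij for j = net.indices[s].  Rows sum to 1 (it is not doubly
    stochastic: in general p_ij != p_ji).
    """

    net: IntegratedNetwork
    p: np.ndarray
    weights: np.ndarray
    phenotype: str | None = None

    def row(self, node: str) -> pd.Series:
        i = self.net.index_of(node)
        sl = slice(self.net.indptr[i], self.net.indptr[i + 1])
        return pd.Series(self.p[sl], index=self.net.nodes[self.net.indices[sl]])

    def row_sums(self) -> np.ndarray:
        return np.add.reduceat(self.p, self.net.indptr[:-1])


def stochastic_flux(
    weights: np.ndarray,
    net: IntegratedNetwork,
    phenotype: str | None = None,
) -> FluxMatrix:
    """Normalise per-edge weights into the row-stochastic flux matrix.

    A node whose neighbour weights sum to exactly zero (every neighbour
    correlation exactly -1) gets the uniform distribution 1/k_i, with a
    warning: the flux direction is then completely uninformative.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (net.n_edges,):
        raise ValueError("one weight per undirected PIN edge required")
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValueError("flux weights must lie in [0, 1]")
    w = weights[net.edge_id]
    row_sums = np.add.reduceat(w, net.indptr[:-1])
    zero_rows = row_sums == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} node(s) with all-zero flux weights; "
            "assigning uniform flux",
            stacklevel=2,
        )
        uniform = np.repeat(zero_rows, net.degrees)
        w = np.where(uniform, 1.0, w)
        row_sums = np.where(zero_rows, net.degrees.astype(float), row_sums)
    p = w / np.repeat(row_sums, net.degrees)
    return FluxMatrix(net, p, weights[net.edge_id], phenotype)


def _entropies(flux: FluxMatrix) -> np.ndarray:
    p = flux.p
    plogp = np.zeros_like(p)
    nz = p > 0
    plogp[nz] = p[nz] * np.log(p[nz])
    raw = -np.add.reduceat(plogp, flux.net.indptr[:-1])
    k = flux.net.degrees
    s = np.full(len(k), np.nan)
    eligible = k >= 2
    s[eligible] = raw[eligible] / np.log(k[eligible])
    # guard against round-off pushing S a hair outside [0, 1]
    return np.clip(s, 0.0, 1.0, out=s)


def local_entropy(flux: FluxMatrix, node: str) -> float:
    """Degree-normalised Shannon entropy of one node's flux distribution."""
    i = flux.net.index_of(node)
    k = int(flux.net.degrees[i])
    if k < 2:
        raise UndefinedEntropyError(
            f"entropy undefined for node {node!r} of degree {k}"
        )
    sl = slice(flux.net.indptr[i], flux.net.indptr[i + 1])
    p = flux.p[sl]
    nz = p > 0
    return float(np.clip(-(p[nz] * np.log(p[nz])).sum() / np.log(k), 0.0, 1.0))


@dataclass
class EntropyProfile:
    """Local entropies S_i over the eligible (degree >= 2) nodes."""

    S: pd.Series
    phenotype: str | None = None

    def __post_init__(self) -> None:
        if ((self.S < 0) | (self.S > 1)).any():
            raise ValueError("local entropies must lie in [0, 1]")


def entropy_profile(flux: FluxMatrix, nodes=None) -> EntropyProfile:
    """Local entropy for every eligible node (optionally a subset)."""
    s = _entropies(flux)
    ser = pd.Series(s, index=flux.net.nodes).dropna()
    if nodes is not None:
        ser = ser.loc[[n for n in nodes if n in ser.index]]
    return EntropyProfile(ser, flux.phenotype)


def _check_aligned(a: pd.Series, b: pd.Series) -> None:
    if len(a) != len(b) or not (a.index == b.index).all():
        raise ValueError("profiles are defined on different node sets")


def differential_entropy(sA: EntropyProfile, sB: EntropyProfile) -> pd.Series:
    """dS_i = S_i(A) - S_i(B); A is the case (e.g. metastatic-like) group."""
    _check_aligned(sA.S, sB.S)
    ds = sA.S - sB.S
    ds.name = "dS"
    return ds


def mean_local_correlation(cf: CorrelationField) -> pd.Series:
    """Mean correlation of each node with its PIN neighbours (k_i >= 1)."""
    sums = np.add.reduceat(cf.csr_data(), cf.net.indptr[:-1])
    return pd.Series(sums / cf.net.degrees, index=cf.net.nodes, name="D")


def mean_local_abs_correlation(cf: CorrelationField) -> pd.Series:
    """Mean |correlation| of each node with its PIN neighbours."""
    sums = np.add.reduceat(np.abs(cf.csr_data()), cf.net.indptr[:-1])
    return pd.Series(sums / cf.net.degrees, index=cf.net.nodes, name="H")


def differential_metrics(
    dA: pd.Series, dB: pd.Series, hA: pd.Series, hB: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Sign-flipped changes in mean local (absolute) correlation.

    dD_i = -(D_i(A) - D_i(B)) and dH_i = -(H_i(A) - H_i(B)), so that, like
    dS, positive values indicate more disorder (weaker local correlation) in
    the case phenotype.
    """
    _check_aligned(dA, dB)
    _check_aligned(hA, hB)
    dd = -(dA - dB)
    dh = -(hA - hB)
    dd.name, dh.name = "dD", "dH"
    return dd, dh


@dataclass
class DifferentialProfile:
    """Per-node differential statistics between two phenotypes."""

    dS: pd.Series
    dD: pd.Series | None = None
    dH: pd.Series | None = None

    def to_frame(
        self,
        net: IntegratedNetwork,
        sA: EntropyProfile | None = None,
        sB: EntropyProfile | None = None,
    ) -> pd.DataFrame:
        out = pd.DataFrame(index=self.dS.index)
        out.index.name = "gene"
        out["degree"] = net.degree_series().loc[out.index]
        if sA is not None:
            out["S_A"] = sA.S.reindex(out.index)
        if sB is not None:
            out["S_B"] = sB.S.reindex(out.index)
        out["dS"] = self.dS
        if self.dD is not None:
            out["dD"] = self.dD.reindex(out.index)
        if self.dH is not None:
            out["dH"] = self.dH.reindex(out.index)
        return out

    def to_tsv(self, path, net: IntegratedNetwork, sA=None, sB=None) -> None:
        self.to_frame(net, sA, sB).to_csv(path, sep="\t")
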