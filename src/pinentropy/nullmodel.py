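"""Degree-dependent permutation null for differential entropy.

The sampling variance of dS_i shrinks with node degree, so ranking genes by
|dS| alone is biased toward low-degree nodes.  The empirical null:

1. permute the gene values within every sample (column), destroying all
   gene-gene correlation while preserving each sample's value distribution;
2. recompute the two phenotype flux matrices and dS on the permuted data;
3. within each replicate, estimate the spread of null dS across nodes of the
   same degree (degrees above 50 are pooled into the bins (50,75], (75,100],
   (100,150], (150,max], where the spread is approximately constant);
4. average the per-replicate standard deviations over R replicates
   (default R = 100);
5. smooth the degree-indexed spread with a power law sigma(k) = a / k^b
   fitted by non-linear least squares;
6. convert each observed dS_i into a P-value against N(0, sigma(k_i)^2) and
   apply Benjamini-Hochberg FDR.

The resulting ranking is approximately degree-unbiased.  Note the null
destroys *all* correlation structure: for data whose edge correlations are
strong even without a phenotype difference, the observed dS fluctuations
exceed sigma(k) and per-gene P-values become anti-conservative (see the
methods notes).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .flux import (
    differential_entropy,
    edge_correlations,
    entropy_profile,
    stochastic_flux,
    weights_from_correlations,
)
from .network import IntegratedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeVarianceTable",
    "PowerLawNull",
    "randomize_expression",
    "null_differential_entropies",
    "estimate_degree_variance",
    "fit_sigma_power_law",
    "node_pvalues",
    "bh_fdr",
    "rank_genes",
]

#: pooled high-degree bins (lo, hi], per-degree estimation below POOL_START
POOL_START = 50
POOL_EDGES = (50, 75, 100, 150)


def randomize_expression(expr: pd.DataFrame, seed) -> pd.DataFrame:
    """Permute gene values independently within each sample (column).

    Preserves every column's value multiset (and hence each sample's
    marginal distribution) while destroying gene-gene correlations.
    ``seed`` is an int or a numpy Generator.
    """
    rng = np.random.default_rng(seed)
    values = expr.to_numpy(dtype=float, copy=True)
    order = np.argsort(rng.random(values.shape), axis=0)
    return pd.DataFrame(
        np.take_along_axis(values, order, axis=0),
        index=expr.index,
        columns=expr.columns,
    )


def null_differential_entropies(
    net: IntegratedNetwork,
    samples_case,
    samples_control,
    seed,
) -> pd.Series:
    """One null replicate of dS per eligible node.

    Expression is fully randomised, then the two phenotype flux matrices are
    rebuilt from the given (equal-size) sample subsets and dS recomputed.
    """
    if len(samples_case) != len(samples_control):
        raise ValueError("null replicates require equal-size groups")
    shuffled = randomize_expression(net.expr, seed)
    profiles = []
    for samples in (samples_case, samples_control):
        cf = edge_correlations(net, samples, expr=shuffled)
        flux = stochastic_flux(weights_from_correlations(cf), net)
        profiles.append(entropy_profile(flux))
    return differential_entropy(profiles[0], profiles[1])


@dataclass
class _Bin:
    lo: float  # half-open (lo, hi]
    hi: float
    rep_degree: float
    node_idx: np.ndarray
    sigma: float = np.nan

    @property
    def n_nodes(self) -> int:
        return len(self.node_idx)


@dataclass
class DegreeVarianceTable:
    """Degree-indexed null-dS spread estimates.

    One bin per exact degree up to 50, pooled bins above; ``sigma`` is the
    across-node sample SD within a replicate, averaged over R replicates.
    """

    bins: list[_Bin]
    R: int
    degenerate: bool = False  # all-zero null spread

    @classmethod
    def from_points(cls, degrees, sigmas, R: int = 1) -> "DegreeVarianceTable":
        """Build a table directly from (degree, sigma) points (no node data)."""
        bins = [
            _Bin(k - 0.5, k + 0.5, float(k), np.empty(0, dtype=int), float(s))
            for k, s in zip(degrees, sigmas)
        ]
        return cls(bins, R=R, degenerate=all(s == 0 for s in sigmas))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lo": [b.lo for b in self.bins],
                "hi": [b.hi for b in self.bins],
                "degree": [b.rep_degree for b in self.bins],
                "sigma": [b.sigma for b in self.bins],
                "n_nodes": [b.n_nodes for b in self.bins],
            }
        )


def _make_bins(degrees: np.ndarray) -> list[_Bin]:
    kmax = int(degrees.max())
    bins: list[_Bin] = []
    for k in sorted(set(degrees[degrees <= POOL_START])):
        idx = np.flatnonzero(degrees == k)
        bins.append(_Bin(k - 0.5, k + 0.5, float(k), idx))
    edges = [*POOL_EDGES, max(kmax, POOL_EDGES[-1] + 1)]
    for lo, hi in zip(edges[:-1], edges[1:]):
        idx = np.flatnonzero((degrees > lo) & (degrees <= hi))
        if len(idx):
            bins.append(_Bin(float(lo), float(hi), (lo + hi) / 2.0, idx))
    # merge bins too small for an SD estimate into the nearest neighbour
    merged = True
    while merged and len(bins) > 1:
        merged = False
        for i, b in enumerate(bins):
            if b.n_nodes < 2:
                others = [j for j in range(len(bins)) if j != i]
                j = min(others, key=lambda j: abs(bins[j].rep_degree - b.rep_degree))
                tgt = bins[j]
                warnings.warn(
                    f"degree bin {b.rep_degree:g} has {b.n_nodes} node(s); "
                    f"merging into bin {tgt.rep_degree:g}",
                    stacklevel=3,
                )
                all_idx = np.concatenate([tgt.node_idx, b.node_idx])
                lo, hi = min(tgt.lo, b.lo), max(tgt.hi, b.hi)
                w = tgt.n_nodes / len(all_idx)
                rep = w * tgt.rep_degree + (1 - w) * b.rep_degree
                bins[j] = _Bin(lo, hi, rep, all_idx)
                bins.pop(i)
                merged = True
                break
    return bins


def estimate_degree_variance(
    null_reps: list[pd.Series], degrees: pd.Series
) -> DegreeVarianceTable:
    """Average within-replicate, across-same-degree-node SDs of null dS."""
    if len(null_reps) < 2:
        raise ValueError("need at least 2 null replicates")
    index = null_reps[0].index
    for rep in null_reps[1:]:
        if len(rep) != len(index) or not (rep.index == index).all():
            raise ValueError("null replicates cover different node sets")
    k = degrees.loc[index].to_numpy()
    mat = np.column_stack([rep.to_numpy() for rep in null_reps])  # nodes x R
    bins = _make_bins(k)
    for b in bins:
        sds = mat[b.node_idx].std(axis=0, ddof=1)  # one SD per replicate
        b.sigma = float(sds.mean())
    degenerate = all(b.sigma == 0 for b in bins)
    if degenerate:
        warnings.warn("degenerate null: all dS replicates identical", stacklevel=2)
    return DegreeVarianceTable(bins, R=len(null_reps), degenerate=degenerate)


@dataclass
class PowerLawNull:
    """Fitted sigma(k) = a / k^b null spread with fit diagnostics."""

    a: float
    b: float
    rss: float
    R: int = 0
    bins: list[dict] = field(default_factory=list)
    seed: int | None = None

    def sigma(self, k) -> np.ndarray:
        return self.a / np.asarray(k, dtype=float) ** self.b

    def to_dict(self) -> dict:
        return {
            "a": float(self.a),
            "b": float(self.b),
            "rss": float(self.rss),
            "R": int(self.R),
            "bins": self.bins,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PowerLawNull":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def fit_sigma_power_law(table: DegreeVarianceTable, seed=None) -> PowerLawNull:
    """Non-linear least squares fit of sigma(k) = a / k^b.

    Pooled bins enter at their representative (midpoint) degree.  The fit is
    initialised from the log-log linear regression and constrained to a > 0,
    b >= 0 so sigma is positive and non-increasing in degree.
    """
    if table.degenerate:
        raise ValueError("cannot fit a power law to a degenerate (all-zero) null")
    k = np.array([b.rep_degree for b in table.bins], dtype=float)
    s = np.array([b.sigma for b in table.bins], dtype=float)
    keep = s > 0
    k, s = k[keep], s[keep]
    if len(k) < 3:
        raise ValueError("need at least 3 positive (degree, sigma) points")
    slope, intercept = np.polyfit(np.log(k), np.log(s), 1)
    p0 = (float(np.exp(intercept)), float(max(-slope, 0.0)))
    try:
        popt, _ = optimize.curve_fit(
            lambda kk, a, b: a / kk**b,
            k,
            s,
            p0=p0,
            bounds=([np.finfo(float).tiny, 0.0], [np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"power-law fit failed to converge (start {p0}): {err}"
        ) from err
    a, b = float(popt[0]), float(popt[1])
    rss = float(((s - a / k**b) ** 2).sum())
    bins = [
        {
            "lo": float(b_.lo),
            "hi": float(b_.hi),
            "degree": float(b_.rep_degree),
            "sigma": float(b_.sigma),
            "n_nodes": int(b_.n_nodes),
        }
        for b_ in table.bins
    ]
    return PowerLawNull(a=a, b=b, rss=rss, R=table.R, bins=bins)


def node_pvalues(
    dS: pd.Series,
    null: PowerLawNull,
    degrees: pd.Series,
    sided: str = "two",
) -> pd.Series:
    """Gaussian P-values of observed dS against the N(0, sigma(k)^2) null.

    ``sided="two"`` (default) gives P = 2*Phi(-|dS|/sigma(k)); ``"greater"``
    tests for entropy increase only.
    """
    sigma = null.sigma(degrees.loc[dS.index].to_numpy())
    if np.any(sigma <= 0):
        raise ValueError("null sigma(k) must be positive for all tested nodes")
    z = dS.to_numpy() / sigma
    if sided == "two":
        p = 2.0 * stats.norm.sf(np.abs(z))
    elif sided == "greater":
        p = stats.norm.sf(z)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return pd.Series(np.minimum(p, 1.0), index=dS.index, name="pvalue")


def bh_fdr(pvalues) -> pd.Series:
    """Benjamini-Hochberg step-up q-values."""
    p = pd.Series(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or p.isna().any():
        raise ValueError("P-values must lie in [0, 1]")
    q = multipletests(p.to_numpy(), method="fdr_bh")[1]
    return pd.Series(q, index=p.index, name="fdr")


def rank_genes(
    dS: pd.Series, degrees: pd.Series, pvalues: pd.Series, qvalues: pd.Series
) -> pd.DataFrame:
    """Ranked gene table: sorted by P, ties by |dS| (desc) then gene id."""
    for other in (degrees.loc[dS.index], pvalues, qvalues):
        if len(other) != len(dS) or not (other.index == dS.index).all():
            raise ValueError("inputs cover different node sets")
    table = pd.DataFrame(
        {
            "gene": dS.index,
            "dS": dS.to_numpy(),
            "degree": degrees.loc[dS.index].to_numpy(),
            "pvalue": pvalues.to_numpy(),
            "fdr": qvalues.to_numpy(),
        }
    )
    order = np.lexsort(
        (table["gene"].to_numpy(), -np.abs(table["dS"].to_numpy()),
         table["pvalue"].to_numpy())
    )
    return table.iloc[order].reset_index(drop=True)
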