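"""Synthetic cohorts with the statistical structure the method assumes.

The generator emulates the qualitative features of a curated human PIN
integrated with a two-phenotype expression cohort: a sparse scale-free
network (preferential attachment; long-tailed degree distribution, majority
of nodes with degree <= 5), two phenotype groups of equal analysed size, and
expression in which PIN-adjacent genes are correlated with a mix of signs.

Expression model (per group): one latent activity factor f per sample and a
Bernoulli(1/2) sign s_i per node, shared between the two groups, give

    x_i = s_i * sqrt(rho) * f + sqrt(1 - rho) * eps_i,

so every PIN edge has population correlation s_i * s_j * rho — magnitude rho
with a random sign, which keeps the sign-sensitive entropy metric and the
sign-blind absolute-correlation metric distinguishable.  In the disrupted
("case") group a planted subset of hub nodes is perturbed:

- ``decorrelate``   — the node's expression is replaced by independent noise
                      (all its edge correlations drop to ~0; entropy -> 1);
- ``sign-flip``     — the node's sign is inverted (correlation magnitudes,
                      and hence entropy, are unchanged: only D moves);
- ``uniform-weaken``— the node's factor loading is quartered (correlations
                      shrink uniformly without vanishing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .network import PIN, IntegratedNetwork, PhenotypeLabels, integrate

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_pin",
    "generate_expression",
    "generate_cohort",
    "worked_star_example",
    "WorkedStarExample",
]

MECHANISMS = ("decorrelate", "sign-flip", "uniform-weaken")


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic two-phenotype cohort.

    Defaults define the reference conditions used throughout the test-bench:
    a 1000-node preferential-attachment network (m = 3: edge density ~0.6%,
    roughly 70% of nodes with degree <= 5 and a long degree tail), 100
    samples per group, base edge-correlation strength rho = 0.5, and 5% of
    nodes — drawn among hubs of degree >= 10 — decorrelated in the case
    group.
    """

    n_nodes: int = 1000
    attachment: int = 3
    n_samples: int = 100
    rho: float = 0.5
    f_disrupted: float = 0.05
    mechanism: str = "decorrelate"
    noise_sd: float = 0.0
    seed: int = 0
    hub_min_degree: int = 10

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if not (0 < self.attachment < self.n_nodes):
            raise ValueError("attachment must be in (0, n_nodes)")
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples per group")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not (0.0 <= self.f_disrupted <= 1.0):
            raise ValueError("f_disrupted must lie in [0, 1]")
        if 0 < self.f_disrupted * self.n_nodes < 1:
            raise ValueError(
                "f_disrupted * n_nodes < 1: no node would be planted"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    """Generated PIN + expression + labels with ground truth."""

    pin: PIN
    expr: pd.DataFrame
    labels: PhenotypeLabels
    planted: list[str]
    spec: SyntheticCohortSpec

    def integrated(self) -> IntegratedNetwork:
        return integrate(self.pin, self.expr)


def _node_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_pin(spec: SyntheticCohortSpec) -> PIN:
    """Scale-free PIN via preferential attachment, deterministic under seed."""
    g = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=spec.seed)
    width = len(str(spec.n_nodes - 1))
    g = nx.relabel_nodes(g, {i: _node_name(i, width) for i in g.nodes})
    return PIN(g)


def _group_matrix(
    rng: np.random.Generator,
    signs: np.ndarray,
    loading: np.ndarray,
    n_samples: int,
    noise_sd: float,
) -> np.ndarray:
    n_genes = len(signs)
    f = rng.standard_normal(n_samples)
    eps = rng.standard_normal((n_genes, n_samples))
    x = (signs * loading)[:, None] * f[None, :] \
        + np.sqrt(1.0 - loading**2)[:, None] * eps
    if noise_sd > 0:
        x = (x + noise_sd * rng.standard_normal((n_genes, n_samples))) \
            / np.sqrt(1.0 + noise_sd**2)
    return x


def generate_expression(pin: PIN, spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Two-group expression for a PIN, with planted disruption in the case group."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    nodes = pin.nodes
    n = len(nodes)
    degrees = pin.degrees

    n_planted = int(round(spec.f_disrupted * n))
    if n_planted > 0:
        hubs = sorted(g for g in nodes if degrees[g] >= spec.hub_min_degree)
        if len(hubs) < n_planted:
            raise ValueError(
                f"cannot plant {n_planted} nodes: only {len(hubs)} hubs with "
                f"degree >= {spec.hub_min_degree}"
            )
        planted = sorted(str(g) for g in
                         rng.choice(hubs, size=n_planted, replace=False))
    else:
        planted = []
    planted_idx = np.array([nodes.index(g) for g in planted], dtype=int)

    signs = rng.choice([-1.0, 1.0], size=n)
    loading = np.full(n, np.sqrt(spec.rho))

    # control group: shared structure, no disruption
    x_control = _group_matrix(rng, signs, loading, spec.n_samples, spec.noise_sd)

    # case group: same structure except for the planted nodes
    case_signs = signs.copy()
    case_loading = loading.copy()
    if len(planted_idx):
        if spec.mechanism == "sign-flip":
            case_signs[planted_idx] *= -1.0
        elif spec.mechanism == "uniform-weaken":
            case_loading[planted_idx] = np.sqrt(spec.rho / 4.0)
        elif spec.mechanism == "decorrelate":
            case_loading[planted_idx] = 0.0
    x_case = _group_matrix(rng, case_signs, case_loading, spec.n_samples,
                           spec.noise_sd)

    case_cols = [f"case_{i:03d}" for i in range(spec.n_samples)]
    ctrl_cols = [f"control_{i:03d}" for i in range(spec.n_samples)]
    expr = pd.DataFrame(
        np.hstack([x_case, x_control]),
        index=pd.Index(nodes, name="gene"),
        columns=case_cols + ctrl_cols,
    )
    labels = PhenotypeLabels(
        pd.Series(
            ["case"] * spec.n_samples + ["control"] * spec.n_samples,
            index=case_cols + ctrl_cols,
        ),
        case="case",
        control="control",
    )
    return SyntheticCohort(pin, expr, labels, list(planted), spec)


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Convenience: generate_pin + generate_expression."""
    return generate_expression(generate_pin(spec), spec)


@dataclass
class WorkedStarExample:
    """The worked 10-neighbour star example.

    In the control phenotype the hub is perfectly correlated (C = +1) with
    six neighbours and perfectly anti-correlated (C = -1) with the remaining
    four, giving the flux vector p = 1/6*(1,1,1,1,1,1,0,0,0,0) and local
    entropy log 6 / log 10 ~= 0.78.  In the case phenotype the hub's
    correlations all vanish: uniform flux and maximal entropy 1.  The
    expression matrices are small integer designs that reproduce those
    correlations *exactly*.
    """

    pin: PIN
    expr: pd.DataFrame
    labels: PhenotypeLabels
    hub: str
    corr_case: np.ndarray  # all zeros
    corr_control: np.ndarray  # six +1, four -1

    def integrated(self) -> IntegratedNetwork:
        return integrate(self.pin, self.expr)


def worked_star_example() -> WorkedStarExample:
    """Build the exact 10-neighbour star worked example."""
    hub = "HUB"
    neighbours = [f"NB{i:02d}" for i in range(1, 11)]
    pin = PIN.from_edges([(hub, nb) for nb in neighbours])

    base = np.array([1.0, 1.0, -1.0, -1.0])  # hub pattern, both phenotypes
    orth = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal, zero-mean pattern
    # control: six neighbours follow the hub, four oppose it
    ctrl_rows = [base] + [base] * 6 + [-base] * 4
    # case: every neighbour is orthogonal to the hub (C = 0 exactly)
    case_rows = [base] + [orth] * 10
    case_cols = [f"case_{i}" for i in range(4)]
    ctrl_cols = [f"control_{i}" for i in range(4)]
    expr = pd.DataFrame(
        np.hstack([np.array(case_rows).reshape(11, 4),
                   np.array(ctrl_rows).reshape(11, 4)]),
        index=pd.Index([hub] + neighbours, name="gene"),
        columns=case_cols + ctrl_cols,
    )
    labels = PhenotypeLabels(
        pd.Series(["case"] * 4 + ["control"] * 4, index=case_cols + ctrl_cols),
        case="case",
        control="control",
    )
    return WorkedStarExample(
        pin=pin,
        expr=expr,
        labels=labels,
        hub=hub,
        corr_case=np.zeros(10),
        corr_control=np.array([1.0] * 6 + [-1.0] * 4),
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Serialise a cohort to the TSV formats the loaders read.

    Writes ``pin.tsv`` (2-column edge list), ``expr.tsv``, ``labels.tsv`` and
    returns a manifest dict (spec + planted nodes + file names).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    pin_path = os.path.join(outdir, "pin.tsv")
    with open(pin_path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in cohort.pin.graph.edges):
            fh.write(f"{u}\t{v}\n")
    expr_path = os.path.join(outdir, "expr.tsv")
    cohort.expr.to_csv(expr_path, sep="\t")
    labels_path = os.path.join(outdir, "labels.tsv")
    with open(labels_path, "w") as fh:
        for sample, group in cohort.labels.assignment.items():
            fh.write(f"{sample}\t{group}\n")
    return {
        "spec": cohort.spec.to_dict(),
        "planted": cohort.planted,
        "files": {
            "pin": "pin.tsv",
            "expression": "expr.tsv",
            "labels": "labels.tsv",
        },
    }
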