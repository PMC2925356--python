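"""Protein-interaction network and expression-matrix handling.

The analysis operates on an *integrated* network: the protein-interaction
network (PIN) restricted to genes that have expression profiles, with a 1-1
correspondence between network nodes and expression rows.  Nodes that become
isolated after the restriction carry no local-correlation information and are
removed.  All gene-identifier matching is exact, case-sensitive string
equality; identifier translation is a preprocessing concern for the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "PIN",
    "PhenotypeLabels",
    "IntegratedNetwork",
    "load_edge_list",
    "load_expression",
    "load_labels",
    "integrate",
    "filter_by_degree",
]


class NetworkError(ValueError):
    """Raised for malformed or inconsistent network inputs."""


@dataclass
class PIN:
    """Undirected, unweighted, self-loop-free protein interaction network."""

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @classmethod
    def from_edges(cls, edges, nodes=()) -> "PIN":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        g.remove_edges_from(nx.selfloop_edges(g))
        return cls(g)


def load_edge_list(path, format: str | None = None) -> PIN:
    """Read a PIN from a two-column TSV edge list or a SIF file.

    ``format`` is ``"tsv2col"`` or ``"sif"``; when *None* it is inferred from
    the filename extension (``.sif`` -> SIF, anything else -> two-column TSV).
    Duplicate edges, reversed duplicates and self-loops are discarded.
    Identifiers are preserved verbatim (case-sensitive).
    """
    path = str(path)
    if format is None:
        format = "sif" if path.lower().endswith(".sif") else "tsv2col"
    if format not in ("tsv2col", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")

    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            n_lines += 1
            if format == "tsv2col":
                parts = line.split("\t")
                if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                    raise NetworkError(
                        f"{path}:{lineno}: expected two tab-separated node "
                        f"identifiers, got {line!r}"
                    )
                edges.append((parts[0].strip(), parts[1].strip()))
            else:  # SIF: "source relation target [target ...]"
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) == 1:
                    nodes.append(parts[0])  # isolated-node line, legal SIF
                elif len(parts) == 2:
                    raise NetworkError(
                        f"{path}:{lineno}: SIF line has a relation but no "
                        f"target node: {line!r}"
                    )
                else:
                    src = parts[0]
                    edges.extend((src, tgt) for tgt in parts[2:])
    if n_lines == 0:
        raise NetworkError(f"{path}: empty edge-list file")
    return PIN.from_edges(edges, nodes)


def load_expression(path, collapse: str = "mean") -> pd.DataFrame:
    """Read a genes x samples expression TSV (header = sample IDs).

    Duplicate gene rows are collapsed with the ``collapse`` rule: ``"mean"``
    (row-wise average) or ``"maxvar"`` (keep the highest-variance row).
    Returns a DataFrame with unique gene index and float values.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if not samples:
        raise NetworkError(f"{path}: no sample columns found")
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise NetworkError(f"{path}: duplicate sample identifiers: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        missing = df[col].isna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise NetworkError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at "
                f"gene {gene!r}, sample {col!r}"
            )
        if missing.any():
            gene = df.index[missing.to_numpy()][0]
            raise NetworkError(
                f"{path}: missing value at gene {gene!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns)
    if out.index.duplicated().any():
        if collapse == "mean":
            out = out.groupby(level=0, sort=False).mean()
        elif collapse == "maxvar":
            variances = out.var(axis=1)
            order = np.argsort(-variances.to_numpy(), kind="stable")
            out = out.iloc[order]
            out = out[~out.index.duplicated(keep="first")]
            out = out.loc[sorted(out.index)]
        else:
            raise ValueError(f"unknown collapse rule: {collapse!r}")
    return out


@dataclass
class PhenotypeLabels:
    """Binary phenotype assignment sample -> group label."""

    assignment: pd.Series  # index = sample id, values = group label
    case: str  # the phenotype treated as "case" (e.g. metastatic)
    control: str

    def __post_init__(self) -> None:
        groups = set(self.assignment.unique())
        if groups != {self.case, self.control}:
            raise NetworkError(
                f"labels contain groups {sorted(groups)}, expected exactly "
                f"{{{self.case!r}, {self.control!r}}}"
            )
        if self.assignment.index.duplicated().any():
            raise NetworkError("duplicate sample identifiers in labels")

    def samples(self, group: str) -> list[str]:
        return list(self.assignment.index[self.assignment == group])

    @property
    def n_case(self) -> int:
        return int((self.assignment == self.case).sum())

    @property
    def n_control(self) -> int:
        return int((self.assignment == self.control).sum())


def load_labels(path, case: str | None = None) -> PhenotypeLabels:
    """Read a two-column TSV ``sample_id<TAB>group`` (no header).

    When ``case`` is not given, the minority group is taken as the case
    phenotype (ties broken lexicographically), matching the convention that
    the smaller (e.g. metastatic) group is the one of interest.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise NetworkError(
                    f"{path}:{lineno}: expected 'sample<TAB>group', got {line!r}"
                )
            rows.append(parts)
    if not rows:
        raise NetworkError(f"{path}: empty labels file")
    ser = pd.Series({s: g for s, g in rows})
    if len(ser) != len(rows):
        raise NetworkError(f"{path}: duplicate sample identifiers")
    groups = sorted(ser.unique())
    if len(groups) != 2:
        raise NetworkError(f"{path}: expected exactly two groups, got {groups}")
    if case is None:
        counts = ser.value_counts()
        case = sorted(groups, key=lambda g: (counts[g], g))[0]
    control = next(g for g in groups if g != case)
    return PhenotypeLabels(ser, case=case, control=control)


@dataclass
class IntegratedNetwork:
    """PIN restricted to the expression gene universe (isolated nodes removed).

    Nodes are held in sorted order; ``expr`` rows are aligned 1-1 with
    ``nodes``.  The adjacency structure is cached in CSR form together with an
    undirected-edge indexing used by the flux computations: ``edge_id[s]`` maps
    CSR slot ``s`` (an ordered pair i->j) to the id of the undirected edge
    {i, j}, whose endpoints are ``edges_i[eid] < edges_j[eid]``.
    """

    graph: nx.Graph
    expr: pd.DataFrame
    n_isolated_removed: int = 0
    # derived fields
    nodes: np.ndarray = field(init=False)
    degrees: np.ndarray = field(init=False)
    indptr: np.ndarray = field(init=False)
    indices: np.ndarray = field(init=False)
    edge_id: np.ndarray = field(init=False)
    edges_i: np.ndarray = field(init=False)
    edges_j: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(sorted(self.graph.nodes), dtype=object)
        if set(self.nodes) != set(self.expr.index):
            raise NetworkError("node set and expression gene set differ")
        if (np.asarray([self.graph.degree[n] for n in self.nodes]) == 0).any():
            raise NetworkError("integrated network contains isolated nodes")
        self.expr = self.expr.loc[self.nodes]
        adj = nx.to_scipy_sparse_array(
            self.graph, nodelist=list(self.nodes), format="csr", dtype=np.int8
        )
        adj = sparse.csr_array(adj)
        self.indptr = adj.indptr
        self.indices = adj.indices
        self.degrees = np.diff(self.indptr).astype(np.int64)
        n = len(self.nodes)
        rows = np.repeat(np.arange(n), self.degrees)
        cols = self.indices
        lo = np.minimum(rows, cols).astype(np.int64)
        hi = np.maximum(rows, cols).astype(np.int64)
        key = lo * n + hi
        uniq, inv = np.unique(key, return_inverse=True)
        self.edge_id = inv
        self.edges_i = (uniq // n).astype(np.int64)
        self.edges_j = (uniq % n).astype(np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges_i)

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    def index_of(self, node: str) -> int:
        idx = np.searchsorted(self.nodes, node)
        if idx >= len(self.nodes) or self.nodes[idx] != node:
            raise KeyError(node)
        return int(idx)

    def degree_series(self) -> pd.Series:
        return pd.Series(self.degrees, index=self.nodes, name="degree")

    def component_summary(self) -> dict:
        comps = [len(c) for c in nx.connected_components(self.graph)]
        return {
            "n_components": len(comps),
            "largest_component": max(comps) if comps else 0,
        }


def integrate(pin: PIN, expr: pd.DataFrame) -> IntegratedNetwork:
    """Intersect a PIN with an expression matrix into an integrated network.

    Restricts both objects to the common gene universe, drops nodes that end
    up with no interaction partner, and logs the counts the analysis reports
    (common genes, isolated removed, component structure).
    """
    common = sorted(set(pin.graph.nodes) & set(expr.index))
    if not common:
        raise NetworkError("no genes shared between PIN and expression matrix")
    sub = pin.graph.subgraph(common).copy()
    isolated = [n for n in sub.nodes if sub.degree[n] == 0]
    sub.remove_nodes_from(isolated)
    if sub.number_of_nodes() == 0:
        raise NetworkError("all common genes are isolated in the restricted PIN")
    net = IntegratedNetwork(
        graph=sub,
        expr=expr.loc[list(sub.nodes)],
        n_isolated_removed=len(isolated),
    )
    comp = net.component_summary()
    logger.info(
        "integrated network: %d common genes, %d isolated nodes removed, "
        "%d nodes / %d edges retained, %d components (largest %d)",
        len(common), len(isolated), net.n_nodes, net.n_edges,
        comp["n_components"], comp["largest_component"],
    )
    return net


def filter_by_degree(net: IntegratedNetwork, min_degree: int) -> np.ndarray:
    """Nodes with degree >= ``min_degree`` (degrees from the full network)."""
    return net.nodes[net.degrees >= min_degree]
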