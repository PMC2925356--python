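"""Fisher-test over-representation of entropy-shifted gene lists.

"Enrichment" here is the classical one-tailed Fisher exact test of the 2x2
overlap table between a hit list and a named gene set, with the analysed
network genes as the background universe.  Gene sets are read from GMT files
(tab-separated: name, description, genes...).
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

__all__ = ["read_gmt", "fisher_enrichment", "split_by_direction"]


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection into {set name: genes}."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def fisher_enrichment(
    hits,
    background,
    sets: dict[str, set[str]],
    two_sided: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Over-representation P per gene set on the 2x2 overlap table.

    Each set is first intersected with the background; the one-tailed
    (over-representation) P equals the hypergeometric upper-tail probability
    of drawing at least the observed overlap.  ``two_sided`` switches to the
    two-tailed Fisher exact test; ``bh`` appends a Benjamini-Hochberg column
    (the default reports raw P only).
    """
    hits = set(hits)
    background = set(background)
    stray = hits - background
    if stray:
        raise ValueError(
            f"hit genes missing from the background: {sorted(stray)[:5]}"
        )
    n_bg = len(background)
    n_hits = len(hits)
    rows = []
    for name, genes in sets.items():
        in_bg = genes & background
        if not in_bg:
            continue
        overlap = sorted(in_bg & hits)
        k, K = len(overlap), len(in_bg)
        if two_sided:
            table = [[k, n_hits - k], [K - k, n_bg - n_hits - (K - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(stats.hypergeom.sf(k - 1, n_bg, K, n_hits))
        rows.append(
            {
                "set": name,
                "pvalue": min(p, 1.0),
                "overlap": len(overlap),
                "set_size": K,
                "overlap_genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows, columns=["set", "pvalue", "overlap", "set_size",
                                      "overlap_genes"])
    if bh and len(out):
        from .nullmodel import bh_fdr

        out["fdr"] = bh_fdr(out["pvalue"]).to_numpy()
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)


def split_by_direction(
    table: pd.DataFrame, fdr_cut: float, top_k: int | None = None
) -> tuple[list[str], list[str]]:
    """Partition significant ranked genes by the sign of dS.

    Genes with FDR < ``fdr_cut`` (optionally capped at the ``top_k`` best
    ranked) are split into an increase (dS > 0) and a decrease (dS < 0)
    list; exact-zero dS genes belong to neither.
    """
    if "fdr" not in table.columns:
        raise ValueError("ranked table lacks an 'fdr' column")
    sel = table[table["fdr"] < fdr_cut]
    if top_k is not None:
        sel = sel.head(top_k)
    increase = sel.loc[sel["dS"] > 0, "gene"].tolist()
    decrease = sel.loc[sel["dS"] < 0, "gene"].tolist()
    return increase, decrease
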