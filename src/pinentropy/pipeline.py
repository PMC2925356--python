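"""End-to-end orchestration: flux -> entropy -> null -> ranking -> enrichment.

A single master seed determines every source of randomness: the
``numpy.random.SeedSequence`` of the master seed is spawned into independent
streams for (1) the bootstrap plan, (2) the null randomisation replicates and
(3) any synthetic generation, so one config reruns to byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import comparison as cmp
from . import enrichment as enr
from . import nullmodel as nm
from .network import (
    IntegratedNetwork,
    PhenotypeLabels,
    filter_by_degree,
    integrate,
    load_edge_list,
    load_expression,
    load_labels,
)
from .synthetic import SyntheticCohortSpec, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_synthetic"]


@dataclass
class RunConfig:
    """Pipeline parameters; defaults follow the reference analysis protocol
    (degree >= 10 node set, 10 bootstraps, 100 null replicates, FDR < 0.001)."""

    pin: str | None = None
    expression: str | None = None
    labels: str | None = None
    gene_sets: str | None = None
    outdir: str = "pinentropy_out"
    min_degree: int = 10
    bootstraps: int = 10
    null_reps: int = 100
    fdr_cut: float = 0.001
    sided: str = "two"
    case_label: str | None = None
    collapse: str = "mean"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    net: IntegratedNetwork
    report: cmp.ComparisonReport
    null: nm.PowerLawNull
    ranked: pd.DataFrame
    enrichment_increase: pd.DataFrame | None = None
    enrichment_decrease: pd.DataFrame | None = None
    paths: dict = field(default_factory=dict)


def _seed_streams(master_seed: int):
    ss = np.random.SeedSequence(master_seed)
    return ss.spawn(3)  # bootstrap, null, misc


def run_pipeline(
    config: RunConfig,
    net: IntegratedNetwork | None = None,
    labels: PhenotypeLabels | None = None,
) -> PipelineResult:
    """Run the full two-phenotype analysis and write the output directory.

    Inputs are read from the config paths unless pre-built ``net``/``labels``
    objects are supplied.  Outputs: ``ranked_genes.tsv``, ``comparison.json``
    (+ a human-readable ``comparison.txt``), ``null_model.yaml``, optionally
    ``enrichment_increase.tsv``/``enrichment_decrease.tsv``, and ``run.log``.
    """
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("pinentropy")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        return _run(config, net, labels)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()


def _run(config, net, labels) -> PipelineResult:
    boot_ss, null_ss, _ = _seed_streams(config.seed)
    if net is None:
        if not (config.pin and config.expression):
            raise ValueError("config must provide pin and expression paths")
        pin = load_edge_list(config.pin)
        expr = load_expression(config.expression, collapse=config.collapse)
        logger.info("PIN: %d nodes, %d edges", len(pin.nodes), pin.edge_count)
        net = integrate(pin, expr)
    if labels is None:
        if not config.labels:
            raise ValueError("config must provide a labels path")
        labels = load_labels(config.labels, case=config.case_label)
    missing = set(labels.assignment.index) - set(net.samples)
    if missing:
        raise ValueError(f"labelled samples missing from expression: "
                         f"{sorted(missing)[:5]}")
    logger.info(
        "phenotypes: %d %s (case) vs %d %s (control); master seed %d",
        labels.n_case, labels.case, labels.n_control, labels.control,
        config.seed,
    )
    analysed = filter_by_degree(net, config.min_degree)
    logger.info("%d nodes with degree >= %d analysed", len(analysed),
                config.min_degree)

    # --- phenotype comparison on the analysed node set -------------------
    plan = cmp.make_bootstraps(
        labels, B=config.bootstraps, seed=np.random.default_rng(boot_ss)
    )
    report = cmp.compare_metrics(net, labels, plan, min_degree=config.min_degree)
    logger.info(
        "S: Wilcoxon P=%.3g, %d up / %d down (binomial P=%.3g); "
        "bootstrap consistency %.3f",
        report.metrics["S"].wilcoxon_p, report.metrics["S"].n_up,
        report.metrics["S"].n_down, report.metrics["S"].binomial_p,
        report.bootstrap_consistency,
    )

    # --- degree-dependent null and gene ranking --------------------------
    case_samples = labels.samples(plan.minority)
    control_subset = plan.subsets[0]
    rep_seeds = null_ss.spawn(config.null_reps)
    null_reps = [
        nm.null_differential_entropies(net, case_samples, control_subset, s)
        for s in rep_seeds
    ]
    var_table = nm.estimate_degree_variance(null_reps, net.degree_series())
    null = nm.fit_sigma_power_law(var_table)
    null.seed = config.seed
    logger.info("null model: sigma(k) = %.4g / k^%.4g (R=%d)", null.a, null.b,
                null.R)

    ds_analysed = report.differentials["dS"]
    degrees = net.degree_series()
    pvals = nm.node_pvalues(ds_analysed, null, degrees, sided=config.sided)
    qvals = nm.bh_fdr(pvals)
    ranked = nm.rank_genes(ds_analysed, degrees, pvals, qvals)

    # --- enrichment -------------------------------------------------------
    enrich_inc = enrich_dec = None
    if config.gene_sets:
        sets = enr.read_gmt(config.gene_sets)
        increase, decrease = enr.split_by_direction(ranked, config.fdr_cut)
        background = list(ranked["gene"])
        logger.info("enrichment: %d increase / %d decrease genes at FDR < %g",
                    len(increase), len(decrease), config.fdr_cut)
        if increase:
            enrich_inc = enr.fisher_enrichment(increase, background, sets)
        if decrease:
            enrich_dec = enr.fisher_enrichment(decrease, background, sets)

    # --- outputs ----------------------------------------------------------
    paths = {}
    paths["ranked_genes"] = os.path.join(config.outdir, "ranked_genes.tsv")
    ranked.to_csv(paths["ranked_genes"], sep="\t", index=False,
                  float_format="%.10g")
    paths["comparison_json"] = os.path.join(config.outdir, "comparison.json")
    report.to_json(paths["comparison_json"])
    paths["comparison_txt"] = os.path.join(config.outdir, "comparison.txt")
    with open(paths["comparison_txt"], "w") as fh:
        fh.write(report.to_text() + "\n")
    paths["null_model"] = os.path.join(config.outdir, "null_model.yaml")
    null.save(paths["null_model"])
    for name, table in (("enrichment_increase", enrich_inc),
                        ("enrichment_decrease", enrich_dec)):
        if table is not None:
            paths[name] = os.path.join(config.outdir, f"{name}.tsv")
            table.to_csv(paths[name], sep="\t", index=False)
    return PipelineResult(
        net=net,
        report=report,
        null=null,
        ranked=ranked,
        enrichment_increase=enrich_inc,
        enrichment_decrease=enrich_dec,
        paths=paths,
    )


def run_synthetic(spec_path, outdir) -> dict:
    """Generate a synthetic cohort from a YAML spec and write it to disk."""
    with open(spec_path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SyntheticCohortSpec)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown synthetic-spec keys: {sorted(unknown)}")
    spec = SyntheticCohortSpec(**data)
    cohort = generate_cohort(spec)
    manifest = write_cohort(cohort, outdir)
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
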