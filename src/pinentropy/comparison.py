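"""Two-phenotype comparison: bootstraps, global tests and metric head-to-head.

The majority phenotype is subsampled (without replacement) to the minority
group's size B times ("bootstraps" in the sense used here), so that the two
flux matrices are always built from the same number of samples and entropy
differences cannot be a sample-size artefact.  Global differences per metric
(entropy S; sign-flipped mean local correlation D and mean local absolute
correlation H) are assessed with a one-tailed paired Wilcoxon signed-rank
test on the per-node differences, plus a sign-skew count with an exact
one-tailed binomial test.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .flux import (
    differential_metrics,
    edge_correlations,
    entropy_profile,
    mean_local_abs_correlation,
    mean_local_correlation,
    stochastic_flux,
    weights_from_correlations,
)
from .network import IntegratedNetwork, PhenotypeLabels, filter_by_degree

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapPlan",
    "ComparisonReport",
    "make_bootstraps",
    "paired_wilcoxon",
    "skew_counts",
    "compare_metrics",
    "bootstrap_consistency",
    "cross_cohort_validation",
]


@dataclass
class BootstrapPlan:
    """Equal-size subsampling plan for the majority phenotype."""

    B: int
    size: int
    seed: int | None
    subsets: list[list[str]]
    majority: str
    minority: str

    def __post_init__(self) -> None:
        for sub in self.subsets:
            if len(sub) != self.size or len(set(sub)) != len(sub):
                raise ValueError("bootstrap subsets must be distinct samples "
                                 "of the planned size")


def make_bootstraps(labels: PhenotypeLabels, B: int = 10, seed=None) -> BootstrapPlan:
    """Draw B without-replacement subsets of the majority group.

    Each subset has the minority group's size.  If the groups are already of
    equal size there is nothing to subsample: the plan holds the single
    trivial "bootstrap" equal to the full majority group.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    case, ctrl = labels.samples(labels.case), labels.samples(labels.control)
    if len(case) <= len(ctrl):
        minority, majority = labels.case, labels.control
        pool, size = ctrl, len(case)
    else:
        minority, majority = labels.control, labels.case
        pool, size = case, len(ctrl)
    rng = np.random.default_rng(seed)
    if len(pool) == size:
        subsets = [list(pool)]
    else:
        subsets = [
            sorted(rng.choice(pool, size=size, replace=False)) for _ in range(B)
        ]
    return BootstrapPlan(
        B=len(subsets),
        size=size,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        subsets=subsets,
        majority=majority,
        minority=minority,
    )


def paired_wilcoxon(x, y, alternative: str = "two-sided") -> float:
    """Paired Wilcoxon (signed-rank) P-value on per-node differences.

    Zero differences are dropped.  The exact distribution is enumerated for
    n <= 25 untied differences; otherwise the normal approximation with tie
    correction is used.  If every difference is zero the test is undefined
    and P = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; returning P = 1",
                      stacklevel=2)
        return 1.0
    exact = len(d) <= 25
    res = stats.wilcoxon(
        d,
        alternative=alternative,
        method="exact" if exact else "approx",
        correction=False,
    )
    return float(res.pvalue)


@dataclass
class SkewCounts:
    n_up: int
    n_down: int
    binomial_p: float


def skew_counts(d) -> SkewCounts:
    """Counts of positive/negative differentials and one-tailed binomial P.

    Exact zeros are excluded (standard sign-test practice).  The binomial
    test is one-tailed in the majority direction against proportion 1/2.
    """
    d = np.asarray(d, dtype=float)
    if len(d) == 0:
        raise ValueError("empty differential vector")
    n_up = int((d > 0).sum())
    n_down = int((d < 0).sum())
    n = n_up + n_down
    if n == 0:
        return SkewCounts(0, 0, 1.0)
    p = stats.binomtest(max(n_up, n_down), n, 0.5, alternative="greater").pvalue
    return SkewCounts(n_up, n_down, float(p))


def bootstrap_consistency(ds_vectors: list[pd.Series]):
    """Mean pairwise Pearson correlation of dS across bootstraps.

    Returns ``(consistency, mean_vector)``; with a single bootstrap the
    consistency is undefined (NaN) and the mean is that vector.
    """
    if len(ds_vectors) == 0:
        raise ValueError("no bootstrap dS vectors given")
    index = ds_vectors[0].index
    mat = np.column_stack([v.loc[index].to_numpy() for v in ds_vectors])
    mean_vec = pd.Series(mat.mean(axis=1), index=index, name="dS")
    if len(ds_vectors) < 2:
        return float("nan"), mean_vec
    corr = np.corrcoef(mat.T)
    iu = np.triu_indices(len(ds_vectors), k=1)
    return float(corr[iu].mean()), mean_vec


@dataclass
class MetricComparison:
    wilcoxon_p: float
    per_bootstrap_p: list[float]
    n_up: int
    n_down: int
    n_tie: int
    binomial_p: float


@dataclass
class ComparisonReport:
    """Head-to-head comparison of S, D and H on one identical node set."""

    n_nodes: int
    min_degree: int
    metrics: dict[str, MetricComparison]
    bootstrap_consistency: float
    B: int
    differentials: pd.DataFrame = field(repr=False)  # per-node dS, dD, dH

    def to_dict(self) -> dict:
        consistency = self.bootstrap_consistency
        return {
            "n_nodes": self.n_nodes,
            "min_degree": self.min_degree,
            "B": self.B,
            "bootstrap_consistency": None if np.isnan(consistency)
            else consistency,
            "metrics": {
                name: {
                    "wilcoxon_p": m.wilcoxon_p,
                    "per_bootstrap_p": m.per_bootstrap_p,
                    "n_up": m.n_up,
                    "n_down": m.n_down,
                    "n_tie": m.n_tie,
                    "binomial_p": m.binomial_p,
                }
                for name, m in self.metrics.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        lines = [
            f"Phenotype comparison on {self.n_nodes} nodes "
            f"(degree >= {self.min_degree}), {self.B} bootstrap(s)",
            f"bootstrap consistency (mean pairwise Pearson r of dS): "
            f"{self.bootstrap_consistency:.3g}",
            f"{'metric':<8}{'Wilcoxon P':>12}{'up':>7}{'down':>7}{'tie':>6}"
            f"{'binomial P':>13}",
        ]
        for name, m in self.metrics.items():
            lines.append(
                f"{name:<8}{m.wilcoxon_p:>12.3g}{m.n_up:>7}{m.n_down:>7}"
                f"{m.n_tie:>6}{m.binomial_p:>13.3g}"
            )
        return "\n".join(lines)


def _phenotype_profiles(net: IntegratedNetwork, samples, keep: np.ndarray):
    """S, D, H profiles (restricted to ``keep`` nodes) for one sample set."""
    cf = edge_correlations(net, samples)
    flux = stochastic_flux(weights_from_correlations(cf), net)
    s = entropy_profile(flux).S.loc[keep]
    d = mean_local_correlation(cf).loc[keep]
    h = mean_local_abs_correlation(cf).loc[keep]
    return s, d, h


def compare_metrics(
    net: IntegratedNetwork,
    labels: PhenotypeLabels,
    plan: BootstrapPlan,
    min_degree: int = 10,
) -> ComparisonReport:
    """Compare case vs control with S, D and H on one identical node set.

    The case phenotype is the minority group (all of its samples are used);
    the control side is averaged over the plan's bootstrap subsets.  Each
    one-tailed paired Wilcoxon tests the alternative "case more disordered"
    (S greater; D and H smaller, i.e. their sign-flipped differentials
    positive), so the three P-values are directly comparable.
    """
    keep = filter_by_degree(net, max(2, min_degree))
    if len(keep) == 0:
        raise ValueError(f"no nodes with degree >= {max(2, min_degree)}")
    case_samples = labels.samples(plan.minority)
    s_case, d_case, h_case = _phenotype_profiles(net, case_samples, keep)

    s_boot, d_boot, h_boot, ds_vectors = [], [], [], []
    for subset in plan.subsets:
        s_b, d_b, h_b = _phenotype_profiles(net, subset, keep)
        s_boot.append(s_b)
        d_boot.append(d_b)
        h_boot.append(h_b)
        ds_vectors.append(s_case - s_b)
    consistency, ds_mean = bootstrap_consistency(ds_vectors)
    s_ctrl = pd.concat(s_boot, axis=1).mean(axis=1)
    d_ctrl = pd.concat(d_boot, axis=1).mean(axis=1)
    h_ctrl = pd.concat(h_boot, axis=1).mean(axis=1)
    dd, dh = differential_metrics(d_case, d_ctrl, h_case, h_ctrl)

    metrics: dict[str, MetricComparison] = {}
    for name, case_v, ctrl_v, diff, boots in (
        ("S", s_case, s_ctrl, ds_mean, s_boot),
        ("D", -d_case, -d_ctrl, dd, [-b for b in d_boot]),
        ("H", -h_case, -h_ctrl, dh, [-b for b in h_boot]),
    ):
        sk = skew_counts(diff.to_numpy())
        metrics[name] = MetricComparison(
            wilcoxon_p=paired_wilcoxon(case_v, ctrl_v, alternative="greater"),
            per_bootstrap_p=[
                paired_wilcoxon(case_v, b, alternative="greater") for b in boots
            ],
            n_up=sk.n_up,
            n_down=sk.n_down,
            n_tie=len(diff) - sk.n_up - sk.n_down,
            binomial_p=sk.binomial_p,
        )
    differentials = pd.DataFrame({"dS": ds_mean, "dD": dd, "dH": dh})
    differentials.index.name = "gene"
    return ComparisonReport(
        n_nodes=len(keep),
        min_degree=min_degree,
        metrics=metrics,
        bootstrap_consistency=consistency,
        B=plan.B,
        differentials=differentials,
    )


@dataclass
class ValidationResult:
    p: float
    n_increase: int
    n_decrease: int
    n_increase_mapped: int
    n_decrease_mapped: int


def cross_cohort_validation(
    discovery: pd.DataFrame,
    validation_stats: pd.Series,
    top_k: int = 200,
    fdr_cut: float = 0.001,
) -> ValidationResult:
    """Test gene-wise replication of entropy shifts in a second cohort.

    Takes the discovery cohort's ``top_k`` ranked genes passing ``fdr_cut``,
    splits them by the sign of dS, and compares the validation cohort's
    z-statistics (dS_i / sigma(k_i)) between the increase and decrease groups
    with a one-tailed rank-sum test (alternative: increase group larger).
    Genes absent from the validation cohort are dropped but counted.
    """
    sel = discovery[discovery["fdr"] < fdr_cut].head(top_k)
    inc = sel.loc[sel["dS"] > 0, "gene"].tolist()
    dec = sel.loc[sel["dS"] < 0, "gene"].tolist()
    inc_mapped = [g for g in inc if g in validation_stats.index]
    dec_mapped = [g for g in dec if g in validation_stats.index]
    if not inc_mapped or not dec_mapped:
        raise ValueError(
            "one direction group is empty after mapping to the validation set"
        )
    res = stats.mannwhitneyu(
        validation_stats.loc[inc_mapped],
        validation_stats.loc[dec_mapped],
        alternative="greater",
    )
    return ValidationResult(
        p=float(res.pvalue),
        n_increase=len(inc),
        n_decrease=len(dec),
        n_increase_mapped=len(inc_mapped),
        n_decrease_mapped=len(dec_mapped),
    )
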