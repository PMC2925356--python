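# pinentropy

Local network entropy of information flux in integrated protein-interaction /
mRNA-expression networks.

## The problem

Aggressive cancer phenotypes accumulate genomic and epigenomic alterations
that disrupt signalling. On an integrated network — a protein-interaction
network (PIN) whose edges are weighted by the co-expression of the two
interacting genes in a given phenotype — such disruption shows up not
necessarily as a *shift* in correlation, but as an increase in the
*randomness* of the local correlation pattern around a gene. `pinentropy`
quantifies that randomness, compares it between two phenotypes (e.g.
metastatic vs non-metastatic tumours), ranks genes against a degree-aware
permutation null, and tests the resulting gene lists for pathway
over-representation. It is aimed at computational biologists working with a
PIN edge list and a normalised expression matrix with binary sample labels.

## The statistic

For each phenotype, every PIN edge {i, j} carries the Pearson correlation
C_ij of the two genes across that phenotype's samples. The monotone map
w_ij = (1 + C_ij)/2 turns correlations into positive flux weights, and row
normalisation over the neighbourhood N(i)

```
p_ij = w_ij / Σ_{j'∈N(i)} w_ij'
```

defines a row-stochastic matrix: the relative probability of signal
transmission from protein i to each interaction partner. The **local
entropy** of node i with degree k_i,

```
S_i = − (1 / log k_i) Σ_{j∈N(i)} p_ij log p_ij   ∈ [0, 1],
```

is 0 when all flux runs through one edge and 1 when flux is uniform —
i.e. when the local expression pattern carries no directional information.
The **differential entropy** dS_i = S_i(case) − S_i(control) is compared
against an empirical null: expression is permuted within each sample,
dS recomputed R times, the per-degree standard deviation smoothed with a
power law σ(k) = a/k^b, and each observed dS_i converted to a Gaussian
P-value with Benjamini–Hochberg FDR. Because σ(k) falls with degree, this
ranking does not favour low-degree nodes the way raw |dS| does.

## Worked example

Generate a synthetic cohort (1000-node scale-free PIN, 100 samples per
phenotype, 5% of hub genes decorrelated in the case group) and analyse it:

```sh
pinentropy synth demo_spec.yaml --out demo_cohort
# -> cohort written to demo_cohort (50 planted nodes)

pinentropy run --pin demo_cohort/pin.tsv --expr demo_cohort/expr.tsv \
  --labels demo_cohort/labels.tsv --case-label case \
  --null-reps 10 --seed 42 --out demo_out
```

with `demo_spec.yaml` containing the generator defaults
(`n_nodes: 1000`, `attachment: 3`, `n_samples: 100`, `rho: 0.5`,
`f_disrupted: 0.05`, `mechanism: decorrelate`, `seed: 42`). Output:

```
Phenotype comparison on 115 nodes (degree >= 10), 1 bootstrap(s)
metric    Wilcoxon P     up   down   tie   binomial P
S           1.12e-12     90     25     0     4.18e-10
D              0.178     58     57     0          0.5
H            6.3e-17     97     18     0      1.4e-14
```

Reading this: of the 115 analysed hub genes, 90 gained entropy in the case
phenotype (paired Wilcoxon P ≈ 1e-12; binomial skew P ≈ 4e-10) — the
disruption is detected. The mean local *signed* correlation D barely moves
(P = 0.18) because the planted decorrelation destroys positive and negative
correlations alike; the sign-blind absolute-correlation metric H responds,
as expected of a close surrogate of entropy. The head of
`demo_out/ranked_genes.tsv`:

```
gene    dS            degree  pvalue  fdr
G132    0.07330859317 10      0       0
G213    0.07227524366 13      0       0
G094    0.05903860012 14      0       0
```

(P-values underflow to 0 here because the planted effect is ~4 standard
deviations above the null σ(k) ≈ 0.017/k.) 48 of the 50 planted genes land
in the top 50 of this ranking. The fitted null is written to
`demo_out/null_model.yaml`, the metric comparison to `comparison.json`, and
a run log with all node/edge/isolated counts to `run.log`. With unequal
group sizes the majority phenotype is subsampled (default 10 "bootstraps")
and dS is averaged across subsamples; `comparison.json` then also reports
the mean pairwise Pearson correlation of dS across bootstraps.

Gene-set over-representation of the significant genes (one-tailed Fisher
test with the analysed genes as background) is available via
`pinentropy enrich`, and `pinentropy validate` tests whether the entropy
shifts of a discovery cohort's top genes replicate in a second cohort.

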