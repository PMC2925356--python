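# Methods notes

## Model

`pinentropy` analyses an *integrated* network: an undirected, unweighted
protein-interaction network (PIN) restricted to the genes present in an
expression matrix, with isolated nodes removed (they carry no local
correlation information). All components are retained — the entropy
statistic is purely local, so a multi-component network poses no problem.
Gene matching is exact, case-sensitive string equality; identifier mapping
is deliberately out of scope.

Per phenotype, each PIN edge {i, j} carries the Pearson correlation C_ij of
the two genes' expression across that phenotype's samples only. The
transform w = (1 + C)/2 maps correlations to [0, 1]: strong positive
correlation → ~1, absent correlation → 0.5, strong anti-correlation → ~0.
Row normalisation over each node's neighbourhood gives a row-stochastic
flux matrix p_ij (it is not doubly stochastic), and the local entropy

    S_i = −(1/log k_i) Σ_j p_ij log p_ij

is the degree-normalised Shannon entropy of the outgoing flux, in [0, 1]
and independent of logarithm base. S_i is undefined for degree < 2 (one
neighbour forces p = 1, entropy identically 0 with a degenerate
normaliser); degree-1 nodes remain in the network — they still contribute
correlations to their neighbours' entropies — but are excluded from every
entropy profile.

The case-vs-control statistics are the differential entropy
dS_i = S_i(case) − S_i(control) and, for head-to-head comparison, the
changes in mean local correlation (D) and mean local absolute correlation
(H), both sign-flipped so that positive values always mean "more disorder
in the case phenotype".

## Procedure

1. **Equal-size groups.** The majority phenotype is subsampled without
   replacement to the minority's size, B = 10 times by default
   ("bootstraps"), so no entropy difference can be a sample-size effect.
   dS is averaged across bootstraps; the mean pairwise Pearson correlation
   of the per-bootstrap dS vectors is reported as a robustness statistic.
   When the groups are already equal there is a single trivial bootstrap
   and the consistency statistic is undefined (reported as null).
2. **Global tests.** Per metric, a one-tailed paired Wilcoxon signed-rank
   test on the per-node differences ("case more disordered"), plus counts
   of increases/decreases with an exact one-tailed binomial test against
   1/2. The paired test compares the same node under the two conditions
   and therefore sidesteps the degree dependence of S. All three metrics
   are evaluated on the identical node set (degree ≥ 10 by default), so
   their P-values are directly comparable.
3. **Degree-dependent null.** Expression values are permuted within each
   sample (column), preserving every sample's value distribution while
   destroying gene-gene correlation; dS is recomputed per replicate
   (R = 100 by default; desk-scale studies in this repository use R = 10).
   Within each replicate the spread of null dS is estimated as the sample
   SD across nodes of equal degree — exact degrees up to 50, pooled bins
   (50,75], (75,100], (100,150], (150,max] above, where the spread is
   approximately constant — then averaged over replicates. Degrees with a
   single node are merged into the nearest bin with a warning. A power law
   σ(k) = a/k^b is fitted by non-linear least squares (pooled bins at their
   midpoint degree; initialised from the log-log regression; bounds a > 0,
   b ≥ 0 so σ is positive and non-increasing).
4. **Ranking.** Each observed dS_i (bootstrap-averaged) is converted to a
   P-value against N(0, σ(k_i)²) — two-sided by default, with direction
   recoverable from sign(dS); a one-sided mode is a flag — followed by
   Benjamini–Hochberg FDR. Ties in P are broken by |dS| descending, then
   gene id.
5. **Enrichment.** Genes at FDR < 0.001 (default) are split by sign of dS
   and each list is tested per gene set with the one-tailed Fisher exact
   test (hypergeometric upper tail) against the analysed-gene background.
   Raw P-values are reported by default; BH across sets is a flag.
6. **Cross-cohort validation.** The discovery cohort's top genes, split by
   direction, are compared on their validation-cohort z-statistics
   (dS/σ(k)) with a one-tailed rank-sum test.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_degree` | 10 | node set for ranking/enrichment; hubs are the disruption-prone, best-estimated nodes |
| `bootstraps` (B) | 10 | majority-group subsamples |
| `null_reps` (R) | 100 | permutation replicates behind σ(k) |
| `fdr_cut` | 0.001 | stringent cut for the direction-split gene lists |
| `sided` | two | sidedness of the per-gene Gaussian P |
| `collapse` | mean | duplicate expression rows per gene: `mean` or `maxvar` (the choice is a convention, not derived from data) |

Degenerate inputs: an all-zero weight row (every neighbour correlation
exactly −1) receives uniform flux with a warning rather than a division by
zero; zero-variance genes get C = 0 (weight 0.5, the "no correlation"
value) on all their edges; 0·log 0 = 0 throughout; an all-zero null
(constant expression) is flagged as degenerate and refuses a power-law fit.
Natural logarithms are used internally; base invariance is exercised in the
tests to 1e-12.

## Synthetic cohorts

The generator emulates the qualitative structure of a curated human PIN
integrated with a two-group tumour cohort, at desk scale:

- **Network**: preferential attachment (Barabási–Albert), n = 1000 nodes,
  m = 3 edges per new node. This gives ~3000 edges (density ~0.6%), ~70%
  of nodes with degree ≤ 5, a long degree tail (max degree ~100) and
  ~120 hubs of degree ≥ 10 — the same qualitative shape (sparse,
  scale-free, low-degree-dominated) as literature-curated interactomes,
  though smaller and denser than the real thing. Degree-sequence matching
  is a non-goal.
- **Expression**: per group, one latent activity factor f per sample and a
  node sign s_i = ±1 (Bernoulli 1/2, shared between groups) give
  x_i = s_i√ρ·f + √(1−ρ)·ε. Every PIN edge then has population
  correlation s_i s_j ρ: magnitude ρ with a random sign, which keeps the
  sign-sensitive entropy and the sign-blind absolute-correlation metric
  distinguishable. Defaults: ρ = 0.5, 100 samples per group. ρ = 0.5 was
  chosen once as a clearly-structured regime in which decorrelation is
  detectable at n = 100; real tumour co-expression across PIN edges is
  typically weaker and more heterogeneous (see limitations).
- **Planted disruption** (case group only): a fraction f = 0.05 of nodes,
  drawn among hubs (degree ≥ 10), is perturbed by one mechanism:
  `decorrelate` (expression replaced by independent noise — entropy rises
  toward 1), `sign-flip` (s_i inverted — correlation magnitudes and entropy
  unchanged, only the signed mean correlation D moves; useful for
  separating the metrics), or `uniform-weaken` (factor loading quartered).

What the generator does *not* emulate: probe-level noise structure,
heavy-tailed expression marginals, co-expression that varies by complex
membership, inter-edge correlation heterogeneity, or any real pathway
topology. Passing the recovery tests therefore shows the machinery is
correct and well-calibrated under its own assumptions, not that effect
sizes on real cohorts will match.

## Calibration of the permutation null — a known limitation

The permutation null destroys *all* gene-gene correlation. Under data that
are themselves uncorrelated (ρ = 0), the pipeline is well calibrated: on a
no-effect cohort the per-gene P-values are uniform within every degree
stratum and ~5% of genes fall under q < 0.05 (asserted in the acceptance
suite). But when the baseline co-expression is strong, the sampling
fluctuation of dS between two *exchangeable* groups exceeds the
permutation σ(k) — our own measurement on the single-factor cohort at
n = 100/group, degree-10 nodes: null σ ≈ 0.0014 versus exchangeable-group
dS SD ≈ 0.006–0.022 for ρ = 0.2–0.7 — so per-gene P-values become
anti-conservative (at ρ = 0.5, ~80% of genes of a no-effect cohort pass
q < 0.05). The entropy statistic sits at its maximum under the permutation
null (uniform flux), where its gradient vanishes; structured data sit on
the slope. Per-gene P-values from this null should therefore be read as a
degree-corrected *ranking* device — which is how they are used here — and
the global paired Wilcoxon, which needs no null model, as the inferential
test. The test-bench exercises calibration claims in the regime where the
null's assumption holds (ρ = 0) and documents the inflation otherwise.

## Numerical choices and problem sizes

- Row-stochasticity is maintained to 1e-12; entropies are clipped to
  [0, 1] against round-off at the boundaries.
- The power-law fit uses `scipy.optimize.curve_fit` with xtol = ftol =
  1e-12; noiseless inputs are recovered to ~1e-15 relative error.
- Paired Wilcoxon: exact distribution for ≤ 25 non-zero differences,
  normal approximation with tie correction above; zero differences are
  dropped, and an all-zero vector returns P = 1 with a warning.
- Wilcoxon exactness, Fisher tails (all 2×2 tables with total ≤ 60) and
  BH q-values are verified against independent enumeration oracles in the
  test suite.
- Simulation studies in the tests use 1000-node networks, 100 samples per
  group and R = 10 permutation replicates over 10 seeds — sizes chosen so
  the whole suite runs in seconds while each study retains ~100 analysed
  hubs per cohort. The reference protocol defaults (R = 100, B = 10)
  remain the package defaults.
- All randomness derives from one master seed via
  `numpy.random.SeedSequence` spawning (bootstrap plan, permutation
  replicates, synthetic generation), so a fixed config reproduces outputs
  byte-identically.

## Design choices where the design was open

- **Duplicate expression rows** are averaged by default (`maxvar`
  alternative); any collapsing rule is defensible and this one is
  deterministic and smooth.
- **Sidedness** of the per-gene P: two-sided by default so both entropy
  increases and decreases can be reported, with the direction split done
  on sign(dS); a one-sided mode exists for increase-only screens.
- **"Paired Wilcoxon rank sum"** is implemented as the Wilcoxon
  signed-rank test on per-node differences — the standard paired Wilcoxon;
  the rank-sum (Mann-Whitney) test is unpaired and would ignore the
  node-wise pairing that motivates the design.
- **Within-replicate spread**: the per-degree SD is computed across
  same-degree nodes within each replicate and then averaged over
  replicates (matching "smoothed standard error estimates by averaging").
  The alternative — per-node SD across replicates, then averaged within
  degree — converges to the same σ(k) under the null's exchangeability but
  needs many more replicates for stable per-node estimates.
- **Pooled-bin representative degree** is the bin midpoint; bin edges are
  half-open (lo, hi].
- **Exact zeros** in skew counts are excluded from the binomial test
  (standard sign-test practice).

## Known limitations

- mRNA correlation is a crude proxy for protein-level signalling flux;
  edges with low mRNA co-expression may be fully active at the protein
  level.
- The per-gene null is anti-conservative under strong baseline
  co-expression (see above).
- The entropy statistic cannot see disruptions that preserve the *shape*
  of the flux distribution — e.g. a uniform switch from positive to
  negative correlations (the sign-flip mechanism) leaves S unchanged; the
  D metric is complementary there.
- No partial-correlation/graphical-model treatment of indirect
  correlations; the PIN scaffold is the only guard against them.
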