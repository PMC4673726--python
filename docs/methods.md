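# Methods

This note documents the statistical procedures implemented in femnet, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical/design choices made where more than one reasonable
option existed.

## Gene-level statistics

**Probe-to-gene collapse.** 450K-style probes are collapsed to one methylation
value per gene using the promoter-region hierarchy: the mean of TSS200 probes
if any exist, else the mean of 1st-exon probes, else the mean of probes within
1500 bp of the TSS. Gene-body probes never contribute (promoter methylation is
the most predictive of expression and body methylation often moves the
opposite way), and genes covered only by body probes are absent from the
output. Statistics are computed on beta values directly; no M-value transform
is applied.

**Missingness and imputation.** Probes missing in strictly more than
`max_missing_frac` (default 0.5) of samples are dropped; remaining gaps are
filled by k-nearest-probe averaging (default k = 5) with Euclidean distance
over shared non-missing samples, scaled by the number of shared samples so
probes with different missingness patterns are comparable. A probe with no
usable neighbour at a sample falls back to its own row mean.

**Expression preprocessing.** Non-negative expression values have zeros
replaced by the global minimum positive value, are log2-transformed, and are
quantile-normalised column-wise (reference = row means of the column-sorted
matrix; ties receive the mean of the reference values at the tied positions).

**Moderated t.** Two-group (tumour − normal) t-statistics with empirical-Bayes
variance moderation: per-gene pooled variances are modelled as scaled-F draws
around a prior variance s₀² with prior degrees of freedom d₀, both estimated
by the method of moments on the log sample variances (trigamma inversion by
Newton iteration). When the log-variances show no excess spread, d₀ = ∞ and
every gene is shrunk fully to the mean sample variance. The total degrees of
freedom are capped at the pooled residual df across genes. Setting
`prior_df=0` recovers the ordinary pooled t-test exactly. Zero-variance genes
are floored to the smallest positive pooled variance and flagged. P-values are
two-sided throughout. The implementation agrees with the reference
empirical-Bayes implementation in the limma package to ~1e-15 on fixed
fixtures (frozen in the test suite).

**Statistic scaling.** Expression t-statistics are multiplied by
sd(t_D)/sd(t_R) over all genes present in both statistic vectors (not only
network genes), so both data types contribute with equal spread to the edge
weights. Scaling precedes restriction to the network.

## Hotspot discovery

**Weights.** t_I(g) = [H(t_D)H(−t_R) + H(−t_D)H(t_R)]·|t_D − t_R| with
H(0) = 0: a zero statistic carries no anti-correlation evidence. Edge weight
w_gh = (t_I(g)+t_I(h))/2; concordant-sign genes therefore contribute zero to
every incident edge. Search runs on the largest connected component of the
statistic-covered network (ties between equal-sized components broken by the
lexicographically smallest gene).

**Growth objective.** Seeds are the `n_seeds` (default 10) genes with the
largest t_I (ties lexicographic). Growth is greedy and local: at each step the
adjacent node whose addition most increases the *local spin-glass density* —
the induced edge-weight sum divided by the module size — is added, stopping at
the first non-improvement or at `max_size` (default 100). The density is the
objective because a greedy rule on the mean induced edge weight itself is
degenerate for node-additive weights: any module's mean edge weight is a
weighted average of its node statistics and is maximised by the single
heaviest pair, so such a rule can never grow past two nodes and cannot recover
a planted clique. The **reported modularity remains the mean induced edge
weight** (the average-edge-weight score that is also re-computed under
permutation and in validation).

**Significance.** Node statistic pairs are shuffled over all network nodes
(`n_perm` default 1000), edge weights implied by each shuffle are re-scored on
the fixed member set, and p = (1 + #{permuted modularity ≥ observed})/(1 +
n_perm). Ties count as exceedances and the pseudo-count keeps p > 0, making
the test conservative; under a continuous exchangeable null it is calibrated
(type-I error ≈ nominal, verified by simulation in the acceptance suite).
Because the weights are node-additive, a module's modularity under any
assignment is Σ_g indeg(g)·t_I(g)/(2·|E|), which makes permutation re-scoring
a dot product. Only this statistic-randomisation test is implemented; a
topology-preserving second test is left as a hook.

**Pruning and validation.** Modules are ranked by modularity (ties by seed
symbol) and dropped when their overlap coefficient |A∩B|/min(|A|,|B|) with any
retained module exceeds 0.5. Validation re-weights the network with
independent-cohort statistics (processed by the same pipeline), drops member
genes absent there (counted), and recomputes modularity and permutation p;
modules with fewer than two surviving members are flagged not validated.
Cross-cohort consistency is the Pearson correlation of discovery vs validation
t-statistics over module genes, per data type. Gene-set annotation is an
upper-tail hypergeometric overlap test against GMT collections with
Benjamini–Hochberg adjustment across sets.

## Deviation scores and coordination

The normal reference (per-gene mean and sd per data type) is estimated from at
least 3 normal samples; zero sds are floored to the smallest positive sd and
flagged. Z_gs = (X_gs − μ_g)/σ_g. The scaling factor α is the ratio of the
standard deviations of *all* Z entries (all genes, all tumour samples), not
just module genes. The module score FEM_s = (1/m)Σ|Z^D − α·Z^R| runs over
eligible genes only: significant at both levels (`alpha_sig`, default 0.05)
with anti-correlated t-statistics. Because Z-standardisation absorbs affine
changes of the raw data, the score is invariant to rescaling when the
reference is refit.

Binary deviation matrices use two-sided Gaussian p-values from |Z| (the
per-sample deviation is a location shift relative to a Gaussian normal
reference; two-sided is the neutral choice since the cohort-level direction is
enforced separately): an entry is 1 iff both p < `p_threshold` (default 0.1, a
deliberately relaxed level so patterns are assessable in more genes) and the
sample's deviation directions match the gene's cohort-level anti-correlative
pattern (sign(Z) = sign(t) for both data types).

The coordination test permutes samples independently within each row (row
sums exactly preserved) and compares the observed mean Manhattan distance
between gene rows to the null, lower tail by default ("more extreme" =
smaller distance = more coordinated); the mutually-exclusive alternative is
available as an upper-tail mode. Constant matrices have a degenerate null and
report p = 1 with a flag.

## Subtyping

The joint latent-variable clustering used on real cohorts is **not**
reimplemented; `joint_cluster_standin` row-standardises both matrices, stacks
them feature-wise and runs k-means (k = 2 default, 20 restarts, fixed seed),
and every downstream step accepts any externally produced partition, so a
faithful integrative-clustering fit can be plugged in. Centroids are built per
data type by centring each gene to mean zero across training samples and
averaging per cluster; this makes centroids exactly invariant to per-gene
constant offsets in the training data.

Classification of independent samples is a two-step procedure: genes of the
new set are centred with that set's own means (`center_genes`, default-on) —
this removes per-gene baselines such as promoter methylation levels, which
otherwise dominate the correlation — and each sample is then assigned to the
centroid with the largest Spearman rank correlation (average ranks for ties;
assignment ties broken by cluster order and flagged; constant profiles
flagged unclassifiable). The classifier core sees only within-sample ranks,
so given its input representation it is exactly invariant under strictly
monotone per-sample transformations; the centring step is kept separate
precisely because own-mean per-gene centring and exact rank invariance of the
raw input cannot hold simultaneously. The adjusted Rand index (permutation
model) quantifies partition agreement.

## Network distances

Top-n gene lists (by |statistic|, lexicographic ties, n = 100/200 typical) are
compared by all-pairs unweighted shortest paths (hop counts — the edge weights
are statistics, not costs, so hop count is the only defensible reading of path
length). Pairs in different components are excluded from the mean and counted
separately rather than assigned an arbitrary large value. Distance multisets
are compared by mean difference and a two-sided Wilcoxon rank-sum test
(asymptotic, tie-corrected, no continuity correction so identical inputs give
p = 1 exactly; fully tied inputs short-circuit to p = 1).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

- **Methylation**: logit-normal betas around region-specific baselines
  (promoter ≈ 0.15, body ≈ 0.7 on the beta scale; gene-level logit spread 0.5,
  probe offset 0.2, observation noise 0.5), guaranteeing values strictly
  inside (0, 1). Each gene gets `probes_per_gene` (default 4) probes: the
  first always promoter-mapped (TSS200 60% / 1st exon 25% / TSS1500 15%), the
  rest drawn from all four regions, so decoy body probes and the region
  fallback are both exercised.
- **Expression**: Gaussian on the log2 scale (baseline mean 8, sd 2, noise
  sd 1); optionally emitted on the raw scale with a small zero fraction to
  exercise the preprocessing path.
- **Network**: connected small-world (or scale-free) background with each
  planted module wired as a dense connected subgraph (internal density 0.8
  plus a spanning path).
- **Planted signal**: module genes shift methylation by +δ_D on the logit
  scale and expression by δ_R (opposite sign enforced) in affected tumours;
  luminal-B tumours get `lumB_multiplier` (default 2) times the shift,
  producing the normal < luminal-A < luminal-B deviation gradient. The
  coordination mode controls *which* tumours deviate per gene: one shared set
  (coordinated), disjoint sets (exclusive), or i.i.d. (independent). Default
  deltas are ±1 with affected fraction 1 — large enough for near-complete
  per-gene power at n = 50 + 25 + 25, the default cohort size chosen as a
  realistic small matched study.
- **Copy number**: a gene-level score, N(0,1) background with ~15 spiked genes
  placed uniformly at random — deliberately network-dispersed, to contrast
  with the network-clustered methylation planting.
- A truth record (planted members, per-gene affected samples, spiked CNV
  genes) makes recovery exactly scorable, and the whole generation is
  deterministic under the spec seed.

What the generator does **not** emulate: realistic probe identifiers and
genomic coordinates, batch/array effects, cell-type composition, copy-number
segmentation, count noise in RNA-seq, or correlated background structure
between genes. Passing tests therefore demonstrate correctness and power of
the algorithms under the assumed generative structure, not performance on
real tumour data.

## Problem sizes and determinism

Simulation-based checks run at desk scale chosen for tight feedback loops:
500-gene networks with one 15-gene planted module for hotspot recovery (50
replicates), 100 cohorts of 120 genes × 50 samples for the score gradient,
500 null replicates at 200 permutations for calibration, and 100 replicates
of 10 × 100 binary matrices at 500 permutations for coordination
discrimination. Every stochastic operation takes an explicit seed or
generator; pipeline runs derive all sub-seeds from one configured seed and
write them to the manifest, so a run is reproducible bit-for-bit from the
manifest plus inputs.

## Known limitations

- The greedy local search has no backtracking; modules interlocking through a
  shared heavy node may be merged or shadowed before pruning.
- The permutation test conditions on the module's member set; it does not
  correct for the selection step (the same statistics grew the module), so
  discovery p-values are optimistic in the usual post-selection sense —
  independent-cohort validation is the honest check.
- α is a single global factor; data types with strongly gene-dependent scale
  differences are only partially harmonised.
- k-NN probe imputation is O(n²) in probes and intended for desk-scale or
  pre-filtered matrices.
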