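# femnet

Integrative discovery of **functional epigenetic modules (FEMs)** — interactome
hotspots where promoter DNA methylation and gene expression change together, in
opposite directions — with per-sample deviation scoring, molecular subtyping
and coordination analysis. The package targets matched tumour/normal cohorts of
the kind produced by Illumina 450K methylation arrays plus RNA-seq (e.g. ER+
breast cancer, where such hotspots separate the luminal-A and luminal-B
subtypes by their *level* of epigenetic deregulation), and ships a synthetic
matched-cohort simulator so the whole pipeline is testable without any data
download.

## The method

For every gene *g* the package computes moderated t-statistics of differential
promoter methylation, t<sub>g</sub><sup>(D)</sup>, and differential expression,
t<sub>g</sub><sup>(R)</sup> (empirical-Bayes variance shrinkage; probe-level
betas are collapsed to gene level with the promoter priority
TSS200 → 1st exon → TSS1500, gene-body probes excluded; expression statistics
are rescaled to the methylation-statistic spread). Each gene's integrated,
anti-correlation-gated statistic is

    t_I(g) = [H(t_D) H(−t_R) + H(−t_D) H(t_R)] · |t_D − t_R|,        H(0) = 0,

and a protein–protein interaction edge between genes *g*, *h* carries weight
w<sub>gh</sub> = (t<sub>I</sub>(g) + t<sub>I</sub>(h)) / 2. Modules are grown
greedily around the top-statistic seed genes (a local spin-glass-style search
on the weighted network), scored by their **modularity** — the mean weight of
the induced edges — and tested by permuting node statistics over the network.
Overlapping modules are pruned; surviving modules can be re-scored with
statistics from an independent cohort.

Per-sample deviation from the normal state uses Z-statistics against the
normal-reference mean and standard deviation of each gene, with a data-type
scaling factor α = σ<sub>Z</sub>(D)/σ<sub>Z</sub>(R) computed over all genes
and tumour samples. The module deviation score of sample *s* is

    FEM_s = (1/m) Σ_g |Z_gs^(D) − α · Z_gs^(R)|

over the module's *m* eligible genes (significant at both levels and
anti-correlated). Binary deviation matrices (per-sample Gaussian p < 0.1 in
both data types, directions matching the cohort-level pattern) feed a
within-row permutation test of the mean Manhattan distance between genes:
small distances mean *coordinated* deregulation (the same tumours deviate for
every gene), large distances mean *mutual exclusivity*. Finally, two-cluster
integrative subtyping builds gene-centred centroids per data type and
classifies independent samples by Spearman nearest centroid, and the
shortest-path module compares the interactome clustering of top-ranked
differentially methylated genes against top-ranked copy-number-altered genes.

## Worked example

```python
import numpy as np
from femnet import (CohortSpec, PlantedModule, generate_cohort,
                    summarize_gene_methylation, moderated_t, scale_statistics,
                    combine_stats, FEMDetector, DeviationScorer)

spec = CohortSpec(n_genes=300, n_normal=40, n_lumA=25, n_lumB=25,
                  planted_modules=[PlantedModule(size=15, delta_D=1.2, delta_R=-1.2)],
                  lumB_multiplier=2.0, seed=1)
cohort = generate_cohort(spec)

meth = summarize_gene_methylation(cohort.beta, cohort.annotation)
stats_D = moderated_t(meth, cohort.phenotype)
stats_R = scale_statistics(stats_D, moderated_t(cohort.expression, cohort.phenotype))
stats = combine_stats(stats_D, stats_R)

detector = FEMDetector(n_seeds=10, n_perm=1000, random_state=1).fit(stats, cohort.network)
print(detector.module_table()[["size", "modularity", "p_value"]].round(3))

scorer = DeviationScorer().fit(meth, cohort.expression, cohort.phenotype)
scores = scorer.score_modules(detector.modules_, stats)
phen = cohort.phenotype
for grp in ("lumA", "lumB"):
    cols = [s for s in scores.columns if phen.at[s, "subtype"] == grp]
    print(f"median FEM score {grp}: {scores[cols].iloc[0].median():.2f}")
print(f"alpha = {scorer.alpha_:.3f}")
res = scorer.coordination(detector.modules_[0], stats, n_perm=1000,
                          rng=np.random.default_rng(1))
print(f"coordination: observed MHD {res['observed_mhd']:.2f} "
      f"(null mean {res['null_mean']:.2f}), p = {res['p_value']:.3f}")
```

Output:

```
       size  modularity  p_value
seed
G0041    15      27.151    0.001
median FEM score lumA: 7.15
median FEM score lumB: 15.61
alpha = 1.979
coordination: observed MHD 18.48 (null mean 24.85), p = 0.001
```

The detector recovered a single 15-gene module around seed `G0041` — exactly
the planted hotspot — with modularity 27.2 (mean induced edge weight on the
t-statistic scale) and permutation p = 0.001 at 1000 permutations (the floor,
(1 + 0)/(1 + 1000)). The module deviation score is roughly twice as large in
the simulated luminal-B tumours as in luminal-A (the generator doubles the
planted shift for luminal-B), α ≈ 2 reflects the wider spread of methylation
Z-statistics relative to expression, and the observed mean Manhattan distance
of 18.5 falls far below the permutation-null mean of 24.9: deviations are
coordinated across the module's genes, not mutually exclusive.

The same analysis is available from a shell via the `femnet` CLI
(`femnet simulate`, `diffstats`, `fem`, `validate`, `score`, `coordinate`,
`classify`, `pathdist`, `enrich`, `run-all`); `femnet run-all` writes every
table plus a manifest that makes the run reproducible.

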