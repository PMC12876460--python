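# vertescreen

A pipeline for large-scale mouse knockout vertebral-phenotype screens.

Single-gene knockout lines phenotyped by standardized pipelines (X-ray,
dysmorphology/SHIRPA, body composition, embryo gross morphology) yield, for
every gene × parameter × zygosity, per-sex knockout-effect p-values, a
genotype main-effect p-value, a sex × genotype interaction p-value, and a
significance flag, plus per-animal categorical calls (abnormal/normal).
`vertescreen` turns these exports into the downstream analyses a vertebral
screen needs:

- **Significance classification** (`vertescreen.significance`): a gene is
  significant in a sex when any row has that sex's knockout-effect
  p < α (default α = 10⁻⁴, strict `<`); genes are partitioned into
  male-only / female-only / both sexes / not considered / considered but
  not significant, screened for sexual dimorphism (interaction p < α) and a
  stricter main-effect-only rule (main p < α with no significant
  interaction), and tallied by zygosity and life stage (embryo vs adult by
  procedure).
- **Penetrance** (`vertescreen.penetrance`): for each gene × parameter ×
  life stage × zygosity stratum (optionally split by sex), penetrance
  p̂ = x/n over mutant animals with a definitive call, with exact 95%
  binomial (Clopper–Pearson) intervals from Beta quantiles
  `Beta(x, n−x+1)` / `Beta(x+1, n−x)` and a minimum-N rule (n ≥ 3).
- **Genomic clustering** (`vertescreen.clustering`): the statistic S(w) is
  the number of target genes with ≥ 1 other target on the same chromosome
  within w bp (start-to-start, boundary inclusive).  The null is S(w)
  recomputed over random same-size gene sets drawn without replacement from
  the annotation; reported are the permutation mean µ and SD σ,
  z = (S − µ)/σ, and the +1-smoothed right-tail Monte-Carlo p-value
  (r + 1)/(n_perm + 1), with a Bonferroni-adjusted α across windows
  (defaults 1/2/5/10 Mb, 5,000 permutations).
- **Vertebral categories** (`vertescreen.categories`): parameter → category
  roll-up over the six general vertebral categories (somitogenesis, spine
  shape, tail morphology, vertebral form, vertebral number, vertebral
  processes), exclusive intersection cells (UpSet counts), and per-gene
  vertebral pleiotropy (fraction of a gene's phenotypes that are vertebral,
  with vertebral-only / majority-vertebral / lethality-only-other flags).
- **Somite expression** (`vertescreen.expression`): expressed calls against
  a somite RNA-seq matrix (levels SI/SII/SIII at the 8/18/21/25/27/35-somite
  stages), placement relative to the genome-wide median, cross-referencing
  against maturation-DE and stage-DE gene lists, and hierarchical clustering
  (correlation distance, average linkage) of standardized stage profiles
  into k groups (k = 8 stage clusters, 3 maturation patterns by default).
- **Synthetic data** (`vertescreen.synthetic`): a generator that emulates
  all four inputs on a mouse-scale genome (~2.7 Gb, 19 autosomes + X + Y)
  with planted ground truth — significant genes with known categories,
  per-stratum penetrance, spatial gene clusters, and expression-cluster
  profiles — so the whole pipeline runs and validates offline.

## Worked example

Simulate a mouse-scale annotation, plant 10 clusters of 5 target genes
within 100 kb, and run the permutation test:

```python
from vertescreen.synthetic import SimConfig, simulate_annotation, plant_clustered_targets
from vertescreen.clustering import run_test, results_frame

cfg = SimConfig(seed=1, n_genes=2000, n_target_genes=204,
                n_planted_spatial_clusters=10, genes_per_cluster=5,
                cluster_span_bp=100_000)
loci = simulate_annotation(cfg)
loci, targets, truth = plant_clustered_targets(loci, cfg)
results, meta = run_test(loci, targets, [1_000_000, 2_000_000, 5_000_000, 10_000_000],
                         n_perm=1000, seed=1)
print(results_frame(results).to_string(index=False))
```

```
 window_bp  observed  perm_mean  perm_sd    z     p_mc  n_perm
   1000000        71     28.925 6.838724 6.15 0.000999    1000
   2000000        94     53.737 8.073972 4.99 0.000999    1000
   5000000       131    105.927 8.218955 3.05 0.002997    1000
  10000000       167    154.494 6.108459 2.05 0.017982    1000
```

71 of the 204 targets have a target neighbour within 1 Mb versus 28.9 ± 6.8
expected under the uniform null (z = 6.15); the Monte-Carlo p-value hits its
smoothing floor 1/1001, far below the Bonferroni-adjusted α = 0.0125 for
four windows — the planted short-range clustering is detected, and the
signal attenuates with window size exactly as a local-clustering signature
should.

Penetrance with an exact interval, for a stratum of 50 pooled mutants with
planted penetrance 0.4:

```python
from vertescreen.synthetic import simulate_observations
from vertescreen.penetrance import estimate

obs, _ = simulate_observations(SimConfig(seed=1, penetrance_truth={"Nog": 0.4},
                                         n_animals_per_stratum=25))
est, _ = estimate(obs, "pooled")
```

```
gene_symbol  n_abnormal  n_normal  penetrance  pen_low95  pen_high95
        Nog          19        31        0.38      0.247       0.528
```

19/50 animals scored abnormal: p̂ = 0.38 with exact 95% CI (0.247, 0.528),
covering the planted 0.4.

The same stages are available from the shell:

```bash
vertescreen simulate --seed 1 --outdir sim/
vertescreen filter --stats sim/stat_results.tsv
vertescreen penetrance --obs sim/observations.tsv --min-n 3
vertescreen clustertest --annotation sim/annotation.tsv --targets sim/targets.txt \
    --windows 1e6,2e6,5e6,1e7 --nperm 5000 --seed 17
vertescreen run --config pipeline.yaml --outdir out/
```

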