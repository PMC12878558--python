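# popg

Population-genomics analysis pipeline for all-sites (variant + invariant)
diploid data, with a built-in two-deme structured-coalescent simulator:

* **simulate** — isolation-with-migration coalescent datasets (all-sites
  VCF with DP/AD/QUAL sequencing artifacts), sample coordinates and
  latitude-driven environment variables, optional adaptive-locus clines;
* **filter** — the QUAL / allele-balance / all-heterozygous / per-sample
  depth / site-missingness cascade with a per-rule report;
* **diversity** — missing-data-aware windowed π, Watterson's θ, Tajima's D,
  D_xy, Hudson F_ST (ratio-of-sums), per-sample heterozygosity and F_IS,
  runs of homozygosity and F_ROH, LD decay and LD pruning;
* **structure** — PCA (mean-imputed, centred), 1−IBS distances, haversine
  geography, isolation-by-distance via matrix regression with permutation
  tests (MRM), neighbour-joining trees over all sites, and NMF ancestry
  with masked cross-entropy K selection;
* **demography** — folded joint SFS with hypergeometric projection
  (monomorphic cell included), simulation-based expected SFS, composite
  log10 likelihood, cyclic conditional-maximization fits of three nested
  scenarios (single population / split without / split with migration),
  AIC and ΔAIC comparison;
* **gea** — redundancy analysis of dosages on environment predictors,
  Spearman collinearity pre-filter, 3-SD outlier loci, marginal
  permutation tests.

## CLI

Every stage reads one YAML config; stages can run together or one at a
time (later stages consume the files written by earlier ones via
`inputs:`):

```sh
popg all --config config.yaml --out results/ --seed 1
popg simulate --config config.yaml --out results/
popg diversity --config config.yaml --out results/
```

Minimal config:

```yaml
seed: 1
stages: [simulate, filter, diversity, structure, demography, gea]
simulate:
  n_samples_per_pop: 10
  Ne_anc: 5000
  Ne_1: 5000
  Ne_2: 5000
  T_div: 2000
  m_12: 0.001
  m_21: 0.001
  mu: 1.0e-7
  seq_length: 10000
  n_loci: 200
  artifacts: {mean_depth: 20, genotype_missing_rate: 0.02}
  environment: {n_env_vars: 4, noise_sd: 2.0}
demography: {projection: [10, 10], n_sims: 20000, n_cycles: 15, mu: 1.0e-7}
gea: {n_perm: 100}
```

To analyse existing data instead of simulating, drop the `simulate` stage
and provide:

```yaml
inputs:
  vcf: allsites.vcf        # VCF v4.2, bi-allelic + invariant records
  popmap: popmap.tsv       # sample, population[, lat, lon]
  env: environment.tsv     # sample + one column per environment variable
```

Outputs are plain TSV/JSON (windowed stats, ROH intervals, PCA scores,
Q matrices, Newick tree, per-scenario fit JSONs, ΔAIC comparison table,
RDA outliers) plus `run_log.json` with versions, seeds and site counts at
every filter step.

## Layout

```
src/popg/
  coalescent.py    two-deme structured-coalescent engine (numba kernels)
  artifacts.py     DP/AD/QUAL/missingness simulation
  environment.py   coordinates, gradients, adaptive-locus clines
  variants.py      VariantTable / GenotypeMatrix containers
  vcfio.py         all-sites VCF + metadata TSV I/O
  filtering.py     filter cascade + report
  diversity.py     windowed pi/theta/D/D_xy/F_ST, het, F_IS
  roh.py           runs of homozygosity, F_ROH
  ld.py            LD decay and pruning
  structure.py     PCA, IBS, haversine, MRM, NJ
  admixture.py     masked-CV NMF ancestry, K selection
  demography.py    joint SFS, expected SFS, composite likelihood, AIC
  gea.py           RDA, collinearity filter, outliers, permutation tests
  pipeline.py      stage orchestration
  cli.py           click CLI (`popg`)
```
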