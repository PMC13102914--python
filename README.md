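# repgea

Replicated genotype–environment association (GEA) scans and
repeated-adaptation statistics for landscape genomics.

`repgea` is for population geneticists asking whether two independently
evolving populations — e.g. two human-modified landscapes sampled as
replicates — use the **same genes** to respond to **similar environmental
pressures**. It implements, as one tested pipeline:

* **genotype QC**: biallelic SNP filtering (genotype depth/quality masking,
  per-locus missingness ≤ 20%, MAF ≥ 0.05, exact Hardy–Weinberg test at
  α = 10⁻⁴) and environment-variable pruning (greedy removal of any pair
  with |Pearson r| ≥ 0.8);
* **three outlier scans** per landscape: redundancy analysis (RDA) with a
  sequential permutation test of the canonical axes and 3-SD loading
  outliers; a ridge latent factor mixed model (LFMM) with K latent factors
  and per-variable z-tests; and a PCA–Mahalanobis scan — the latter two
  recalibrated by the genomic inflation factor (GIF) and thresholded at
  FDR q < 0.01;
* **consensus candidates**: SNPs flagged by ≥ 2 of the 3 methods, each
  assigned the environmental variable with the highest |Pearson r|;
* **the 14-test repeatability design**: RDAs of candidate, neutral and
  size-matched random SNP sets against each landscape's environment,
  including crossed tests of one landscape's loci on the other's data;
* **hypergeometric repeatability statistics**: per-variable overlap tests
  and the repeated-adaptation score

  C_hyper = (a_s − a_x·a_y/g₀) / sd,  sd = √((a_x·a_y/g₀)(1 − a_x/g₀)((g₀ − a_y)/(g₀ − 1))),

  where g₀ is the gene universe, a_x/a_y the genes contributing to selection
  in each landscape and a_s their observed overlap;
* **gene-set over-representation** of the shared genes (hypergeometric
  upper tail, fold enrichment (k/n)/(K/N), FDR), and a site-level
  allele-frequency RDA linking the SNPs of the shared enriched genes back
  to the environment;
* a **synthetic-data generator** producing two-landscape studies with
  correlated climatic/water-chemistry variables, Balding–Nichols neutral
  structure, logit-linear environment-driven adaptive SNPs and a configurable
  fraction of adaptive genes shared between landscapes — with full ground
  truth for power and calibration experiments.

The scan engines are scikit-learn-style estimators (`RDA`, `LFMMRidge`,
`PCAdaptScan` with `fit` and trailing-underscore attributes); module-level
functions wrap them.

## Worked example

```python
from repgea import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(sim=SimConfig(seed=3000), n_perm=999, seed=3000)
bundle = run_pipeline(cfg)
```

On this simulated study (two landscapes, 8 and 7 sites, 120 and 63
individuals, ~3000 SNPs with 50 planted adaptive loci each, half of the
adaptive genes shared) the run prints, per landscape, the filtered locus
count, the per-method outlier sets and the ≥2-of-3 consensus:

```
L1 filtered loci: 2945 | method sets: {'rda': 66, 'lfmm': 24, 'pcadapt': 0} | consensus: 22
L2 filtered loci: 2940 | method sets: {'rda': 59, 'lfmm': 33, 'pcadapt': 7} | consensus: 34
gene counts: {'n_L1': 18, 'n_L2': 26, 'n_shared': 6}
repeatability: {'g0': 38, 'a_x': 6, 'a_s': 5, 'expected': 0.947, 'sd': 0.831,
                'c_hyper': 4.879, 'p': 7e-05}
```

The candidate genes recovered independently in the two landscapes overlap
far more than the hypergeometric null expects (0.95 genes expected, 5
observed, C_hyper ≈ 4.9) — the repeated-selection signal planted by the
generator. The 14-test table shows the complementary variance-explained
pattern: candidate sets explain ~48–51% (adjusted R²) of their own
landscape's environmental structure while neutral and size-matched random
sets explain ~9–15%:

```
test      snp_set env_landscape  adjusted_R2  p_global
   a    Set-22-L1            L1        0.482     0.001
   b    Set-34-L2            L2        0.511     0.001
   e SetN-2877-L1            L1        0.113     0.001
   g  SetRN-22-L1            L1        0.107     0.001
   ...
```

A command-line interface mirrors the library
(`repgea simulate`, `repgea run-all --config cfg.yaml --out outdir`);
`run-all` writes per-landscape scan TSVs, the candidate/neutral sets, the
14-test table, the enrichment table and a `repeatability.json` report.

## Documentation

`docs/methods.md` describes the statistical models, the synthetic-data
generator and its limitations, numerical conventions and the design
decisions behind the defaults.
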