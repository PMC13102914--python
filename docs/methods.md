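# Methods

## The question and the design

Two landscapes are treated as independent evolutionary replicates: each is
sampled at a handful of sites (8 and 7 by default), individuals are
genotyped at shared biallelic SNPs, and each site carries a vector of
climatic and water-physicochemistry measurements. The analysis asks, per
landscape, which SNPs covary with the environment beyond what population
structure explains, and, across landscapes, whether the genes those SNPs
map to overlap more than chance — repeated adaptation at the functional
level.

## Genotype and environment preprocessing

Genotype calls below a depth of 10 or genotype quality of 20 are masked
(when those FORMAT fields are present); loci are then removed if their
missing fraction exceeds 20% (strict >), their minor-allele frequency is
below 0.05 (strict <), or the exact conditional Hardy–Weinberg test —
computed per landscape over all its individuals — gives p < 10⁻⁴. Removing
*deviating* loci is the scientifically standard direction; the inverse is
exposed as a switch (`FilterThresholds.hwe_remove_deviating`) for strict
replication of alternative protocols. Remaining missing dosages are imputed
with the per-locus modal dosage (default; preserves the {0,1,2} domain the
ordinations expect) or the mean.

An important, deliberate consequence of per-landscape HWE filtering: pooling
sites that are strongly differentiated at a locus produces a
homozygote excess (the Wahlund effect), so *very* strongly
environment-differentiated adaptive loci can be removed by QC before any
scan sees them. Power statements below are therefore about the post-QC
locus universe.

Environmental variables are pruned before association testing: while any
pair has |Pearson r| ≥ 0.8, the member of the strongest pair with the
larger mean absolute correlation to all remaining variables (the hub) is
dropped; ties break lexicographically, and zero-variance variables are
dropped first. This is deterministic and removes the fewest variables in
hub topologies. A PCA of the standardized site × variable table (both
landscapes pooled) summarizes environmental similarity between landscapes.

## The three scans

**RDA.** Response Y (centered dosages, individuals × loci) is regressed on
standardized predictors X (site environment broadcast to individuals);
collinear predictor columns are dropped by pivoted QR (site-level
predictors are rank-limited by the number of sites). The canonical axes are
the SVD of the fitted values scaled by 1/√(n−1); axis orientation is fixed
by forcing the largest-|loading| locus positive. Axis significance uses a
sequential permutation test: axis i is tested with axes 1..i−1 partialled
out of both response and predictor basis, comparing its pseudo-F
(λ_i / (residual inertia / (n − 1 − rank))) to row permutations of the
residualized response, p = (exceedances + 1)/(B + 1), B = 999 by default.
Outliers are loci whose loading on **any** axis with p ≤ 0.05 lies more
than 3 SD from the mean loading (two-sided, union over axes; a zero-SD
loading distribution yields no outliers).

**LFMM (ridge).** minimize ‖Y − XBᵀ − UVᵀ‖² + λ‖B‖² by block coordinate
descent — (U, V) from the rank-K truncated SVD of Y − XBᵀ, B from the ridge
normal equations (λ = 10⁻⁵, the conventional default) — with a
monotonically non-increasing objective. Association tests condition on the
estimated factors: each locus is refit by OLS on [x_k, U] for each variable
k separately. Testing per variable (rather than on the joint [X, U]) keeps
the design full-rank when site-level predictors are collinear and yields a
z-score for every variable. Squared z-scores are divided by the per-variable
genomic inflation factor (GIF = median(z²)/median of χ²₁) and referred to
χ²₁; q-values are Benjamini–Hochberg per variable, and the method-level
candidate set is the union of per-variable selections at q < 0.01.
BH is the default because it is deterministic; Storey's π₀-weighted
q-values (cubic-polynomial smoother of π₀(λ), evaluated at λ = 0.9) are
available as an option.

**PCA–Mahalanobis.** Each locus is scaled to unit binomial variance
((g − 2p̂)/√(2p̂(1−p̂))), individuals are projected onto the K leading
principal components, and each locus's K-vector of regression z-scores is
scored by a Mahalanobis distance under a robust covariance
(minimum covariance determinant, support fraction 0.75; sample covariance
as fallback if MCD fails). Distances are divided by the GIF (df = K) and
referred to χ²_K, with BH selection at q < 0.01.

K is supplied per landscape from prior knowledge of the genetic structure
(defaults: the simulated cluster counts, 3 and 2).

## Consensus, neutral and random sets

Candidates are loci flagged by ≥ 2 of the 3 methods; each is assigned the
environmental variable with the largest |Pearson r| against its dosages
(signed r stored; ties < 10⁻¹² break lexicographically and are flagged).
The neutral set removes the **union** of all three methods' outliers from
the filtered loci — stricter than removing only the consensus — and random
comparison sets are drawn from it without replacement, size-matched to the
candidate sets.

## The 14-test repeatability design

Fourteen RDAs, labelled a–n, quantify how much environmental variance each
SNP set explains: candidates on their own landscape (a, b) and crossed to
the other landscape's individuals and environment (c, d; loci missing
after the other landscape's filtering are dropped and counted); full
neutral sets on their own landscape (e, f); size-matched random-neutral
sets on their own landscape (g–j, both candidate sizes × both landscapes)
and crossed (k–n). Each test reports R², adjusted R²
(1 − (1 − R²)(n − 1)/(n − q − 1)) and a global permutation p of the joint
pseudo-F. The expected signature of genuine, repeated selection is rows
a–b far above every random/neutral row, with crossed candidate rows
intermediate.

## Overlap statistics

Per environmental variable, the number of candidate SNPs assigned to that
variable in both landscapes is tested against a hypergeometric null over
the universe of loci filtered in **both** landscapes; a pooled row applies
the same construction to the full candidate sets with same-variable
overlap. At the gene level, candidates map to genes through the annotation
table (one gene per locus at most; unmapped loci counted), the landscape
gene sets are intersected, and the C-score standardizes the observed
overlap by its hypergeometric moments:

    E = a_x a_y / g0
    sd = sqrt(E (1 − a_x/g0) (g0 − a_y)/(g0 − 1))
    C_hyper = (a_s − E) / sd,  p = P(X ≥ a_s), X ~ Hypergeom(g0, a_x, a_y)

The gene universe is g0 = |genes(L1) ∪ genes(L2)|
(= a_total_x + a_total_y − shared), the only convention consistent with the
worked example the statistic is validated against (g0 = 599, a_x = a_y = 34,
a_s = 7 → E = 1.93, sd = 1.311, C_hyper = 3.866); it is an explicit input so
other conventions can be forced. The "contributing" sets a_x = a_y are the
shared genes, and a_s is the union of genes appearing in any significant
over-represented term (q ≤ 0.05) among the shared genes. Note the exact
upper tail at the worked example's counts is 1.8 × 10⁻³.

Over-representation uses the hypergeometric upper tail with fold enrichment
(k/n)/(K/N) against a background of all genes in the annotation map (no
external database), BH-adjusted across terms.

## The synthetic-data generator

The generator emulates the replicated design: per landscape,
sites × variables environments from a Gaussian copy of ten field variables
(ambient/water temperature, relative humidity, solar radiation,
evapotranspiration, oxygen availability, pH, potassium, nitrates, sodium)
correlated through two latent factors — heat and runoff chemistry — so that
at least one pair (pH–NO) exceeds the 0.8 pruning threshold in expectation.
Neutral SNPs follow a Balding–Nichols model: ancestral frequency
~ U(0.1, 0.9), cluster frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = 0.1, sites assigned round-robin to 3 (landscape 1) or 2 (landscape 2)
clusters, genotypes Binomial(2, cluster frequency). Adaptive SNPs replace
the cluster frequency by expit(logit(p₀) + β·z) where z is the site's
standardized driving variable and β = 2 log-odds per SD by default
(frequencies clamped to [0.01, 0.99] and the clamps counted). Each adaptive
gene — one contig of two SNPs — responds to a single driving variable,
drawn from the variables not requested to correlate ≥ 0.8 with any other
(so the true driver is identifiable after pruning); pleiotropy is out of
scope. A fraction f of adaptive genes (default 0.5) carries adaptive SNPs
in both landscapes (one per landscape, same gene), giving
s = round(f·n_adaptive/(2 − f)) shared genes. Genes are assigned 1–2
background terms; shared adaptive genes join one of three designated
enriched terms with probability 0.9, other genes with probability 0.02.
Entries are masked missing at rate 0.05. All randomness descends from one
integer seed via `SeedSequence` spawning (layout, two environments, two
genotype draws, terms), so studies are bitwise reproducible.

Default sample sizes emulate the field design this package targets: 8 and
7 sites with 15 and 9 individuals per site (120 and 63 individuals) and
~3000 SNPs (2950 neutral + 50 adaptive per landscape) — enough for
desk-speed experiments while preserving the asymmetric two-landscape
layout. Calibration experiments in the test suite use a smaller 40 × 3000
null configuration (5 individuals per site, no adaptive loci).

What the generator does **not** emulate: linkage disequilibrium beyond
within-contig gene assignment, isolation-by-distance or admixture
gradients, genotyping error, read-level noise, or multi-allelic sites.
Passing tests therefore show the statistics behave correctly under the
stated model, not that the pipeline is robust to every artifact of real
RADseq data.

## Power and calibration, as measured by the test suite

* With no adaptive loci, each scan selects ≤ 2% of loci at q < 0.01 and
  both GIFs average within [0.8, 1.2] (20 seeds).
* With the default planted signal, the ≥2-of-3 consensus recovers ≥ 70% of
  the adaptive loci present after QC, ≥ 50% of recovered loci are assigned
  their true driving variable, and the consensus false-discovery proportion
  stays ≤ 0.2 (20 seeds).
* In the 14-test table, candidate sets out-explain every size-matched
  random-neutral set on their own landscape in ≥ 95% of comparisons.
* The full annotation → enrichment → C_hyper chain is noticeably harder:
  a shared gene only contributes to a_s if its SNP is detected in *both*
  landscapes and the recovered shared set reaches enrichment significance,
  so at the default conditions the end-to-end C_hyper is significantly
  positive in roughly half the replicates. This attenuation — QC attrition
  of strongly differentiated loci compounded across two landscapes and a
  small-list enrichment test — is a genuine property of the design, worth
  keeping in mind when interpreting negative repeatability results on real
  data.

## Numerical conventions

Inertia is variance-scaled (divisor n − 1); canonical axes below a relative
singular-value tolerance of 10⁻⁹ are discarded; permutation p-values are
(exceedances + 1)/(B + 1) with a 10⁻¹² slack on the ≥ comparison; the exact
HWE test works in log-space with a (1 + 10⁻¹²) multiplicative slack when
summing configurations no more probable than the observed one; modal
imputation breaks ties toward the smaller dosage; the site-level GEA table
drops predictors beyond n_sites − 2 to keep the ordination estimable.
Locus ids are `contig:position` (1-based, VCF convention) throughout.
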