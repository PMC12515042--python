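# Methods

`cwpsoil` implements a multi-kingdom analysis of soil communities sampled
at wild populations of crop wild progenitors (CWPs): ecoregion delineation
from edaphoclimatic tables, core-community selection, probabilistic
co-occurrence networks with module detection, module biogeography, and
mixed-model driver analysis. This note records the models, the defaults and
why they hold, the numerical choices, and what the synthetic validation
does and does not establish.

## Pipeline model

The unit of observation is a wild population (site). Inputs are one
phylotype (zOTU) count table per kingdom (bacteria, fungi, protists,
invertebrates; taxa x sites, integer reads), a site table (CWP species,
coordinates), and a per-site table of edaphoclimatic variables with
occasional missing cells. Stages run in a fixed order — impute, rarefy,
ecoregions, core, network, module ecology, drivers — with all randomness
drawn from per-stage seeds derived from a single root seed by hashing, so
any stage can be re-run in isolation and reproduce a full-pipeline run bit
for bit.

### Imputation (predictive mean matching)

Missing environmental cells (~4% in the survey this pipeline targets) are
filled by chained-equation PMM: each incomplete variable is regressed (OLS,
all other variables as predictors) on the cases where it is observed; every
missing cell receives the observed value of one of the `n_donors = 5`
candidate donors whose predicted mean is nearest, chosen uniformly at
random. The sweep repeats for `imputation_cycles` (default 999) and a
single completed dataset feeds all downstream stages — no multiple-
imputation pooling. We match donors on the OLS predicted mean without a
Bayesian parameter draw: with a single completed dataset there is no
between-imputation variance to propagate, and the donor mechanism is what
guarantees the key invariant (every imputed value is an observed value of
its column). 999 cycles is far beyond convergence for tables of this size;
tests use 10 cycles, which gives indistinguishable marginals
(Kolmogorov–Smirnov distance < 0.2 per variable under MCAR holes).
Missingness is treated as MCAR.

### Rarefaction

Each sample is subsampled without replacement (multivariate hypergeometric
draw) to a fixed per-kingdom depth — 12000 (bacteria), 8000 (fungi), 5000
(protists), 250 (invertebrates) reads. Samples below depth are dropped and
logged. One draw per sample with a recorded seed; we do not average over
repeated rarefactions. "Present" everywhere downstream means count > 0
after rarefaction.

A utility converts Walkley–Black soil organic carbon to the dry-combustion
scale (x 1.15) for batches measured by wet oxidation; it is applied only
when a column is flagged as Walkley–Black.

### Ecoregions

Variables are centred and scaled (denominator n−1) and decomposed by SVD
(equivalently, PCA of the correlation matrix). Scores carry variance equal
to the eigenvalue; the sign convention makes the largest-magnitude loading
of each component positive, so output is independent of the BLAS backend.
Squared cosines (squared correlation of variable with component) identify
the variables that interpret each axis.

Clustering uses the first `n_pca_axes = 5` components. Each score column is
standardized to unit variance and multiplied by the square root of its
eigenvalue, so squared Euclidean distances in the reduced space are
eigenvalue-weighted. Raw PC scores already have variance equal to the
eigenvalue, so this weighting coincides with using raw scores up to
numerical scale — both conventions give identical K-means partitions; we
implement the standardize-then-weight form explicitly and test the
variance identity.

K-means (Lloyd, greedy k-means++ initialization, 25 restarts) runs for
k = 2..10 and the Calinski–Harabasz index CH(k) = [B/(k−1)]/[W/(n−k)]
selects k; ties break toward smaller k; labels are renumbered by
descending cluster size for determinism. Per-CWP positions on the leading
axes are tested against zero with Wilcoxon signed-rank tests (exact null
for n ≤ 25 without ties or zeros, otherwise normal approximation with
continuity correction) and across CWPs with a one-way linear model,
Bonferroni-adjusted pairwise mean comparisons and a compact letter display
(insert-and-absorb; ties at exactly alpha are non-significant).

### Core community

Per kingdom, on the pooled rarefied table: step 1 keeps the
ceil(0.10 x S) taxa of highest mean relative abundance, the mean taken over
all samples with zeros included (dominance semantics); ties at the boundary
value are all kept so the result is order-free. Step 2 keeps taxa present
in at least 4 distinct CWP species. The report carries the core's share of
richness and of total reads, plus Upset-style intersection counts of
CWP-presence signatures.

### Co-occurrence networks

For two taxa present in n_a and n_b of N sites, the number of shared sites
under random independent placement is hypergeometric; the co-presence
p-value is the exact upper tail P(J ≥ j_obs), computed via the survival
function in log space (stable for N well beyond 10^4) and checked against
rational-arithmetic tails to 10 significant digits. The tail is inclusive
of the observed value — the conservative convention of the probabilistic
co-occurrence literature — with a switch for the strict tail. Pairs with
p < 0.05 become edges; only positive associations enter the network, while
significant segregation (lower tail) goes to a side table. Taxa with zero
or full prevalence are uninformative (p = 1 by construction), skipped from
testing but retained as isolated nodes. No multiple-testing correction is
applied by default (an FDR switch exists), and no expected-co-occurrence
pre-filter (also switchable, off by default).

Modules come from walktrap (4-step random walks) run per connected
component with the dendrogram cut at maximum modularity; isolated nodes are
singleton modules; module ids are ordered by descending size; modularity is
reported on the full graph (0 for an empty edge set). Modules with ≥ 5
nodes are flagged "main".

### Module biogeography

Reads of core taxa are standardized within each population: z_ij =
(x_ij − mean_i)/sd_i over taxa j in population i (sample sd, n−1), so
each phylotype contributes on a common scale; rows with zero spread yield
all-zero z with a warning. This within-population standardization is the
default; a `per_taxon` flag standardizes each taxon across populations
instead (an alternative reading of "balanced contribution"), and both are
tested. Module abundance is the mean z per module and population. Module
completeness is the fraction of a module's nodes present in a population,
averaged per ecoregion; it is computed on main modules by default
(switchable). Group differences use the same one-way-model /
Bonferroni / compact-letter machinery as the axis tests.

### Environmental drivers

Predictors fall into four groups: climate (MAT, MDR, PSEA, AI), soil
properties (pH, conductivity, sand), soil nutrients (NH4, NO3, PO4, Ca, B,
K, Mg, Zn, Fe, Mn, Mo — whichever are present in the input table; none is
hard-coded), and carbon sink (NDVI, SOC). Predictors are standardized and
screened by variance inflation factor: iteratively drop the largest-VIF
variable until all VIF ≤ 5, with infinite VIFs (perfect collinearity)
dropped first and the order logged.

The response (module mean z per site) is modelled as a Gaussian linear
mixed model with a CWP-species random intercept. The fitter profiles the
variance ratio lambda = sigma2_u/sigma2_e: for fixed lambda the GLS
coefficients and profiled variances are closed-form through per-group
rank-one corrections of the OLS cross-products, leaving a 1-D optimization
in log(lambda) (coarse grid, bounded refinement, explicit check of the
lambda → 0 boundary, which returns a flagged boundary fit rather than an
error). This closed-form route makes the thousands of refits required by
the bootstrap and partitioning experiments cheap; it is validated against
an established general mixed-model implementation (coefficients, variance
components and ML log-likelihood agree to ≥ 6 digits in the tests).

Backward selection drops, at each step, the single fixed term whose removal
most decreases the Akaike criterion, stopping when no removal improves it;
ML fits are used during selection because REML criteria are not comparable
across fixed structures, and the final model is refit by REML. Confidence
intervals are percentile intervals from a parametric bootstrap (default
1000 replicates): responses are simulated from the fitted model with fresh
group intercepts and residuals, refit, and the coefficient draws collected;
failed replicates are dropped and counted, with > 20% failures aborting.
Case (group) resampling is available behind a flag.

R2m = var(Xb)/(var(Xb) + sigma2_u + sigma2_e) and R2c adds sigma2_u to the
numerator (variance-components definitions). The marginal R2 is decomposed
over predictor groups by hierarchical partitioning: each group's total
contribution is its Shapley value over group orderings (2^g subset refits
with the same random structure); unique = R2m(all) − R2m(all minus g);
shared = total − unique. Totals sum to the full model's R2m exactly by the
averaging algebra (asserted to 1e−6). Residual normality is checked by the
Anderson–Darling test with estimated parameters (small-sample modification
and the standard piecewise exponential p-value approximation; agrees with
the reference R implementation to 7 digits).

Selection drops whole variables, not groups; groups matter only for the
partitioning. One model is fit per module per kingdom. In two-module
networks the module abundances are complementary by construction (the
size-weighted module means of row-standardized z sum to zero), so the two
fits mirror each other — the reports keep both for completeness.

## Synthetic survey generator

The generator emulates the survey design: 125 sites partitioned over 10
CWP species (10–15 each), four latent ecoregions, each CWP concentrated in
a primary ecoregion with 30% spillover into a secondary one. Eighteen
environmental variables are affine maps of linear combinations of two
latent gradients whose levels are well-separated ecoregion centroids, plus
Gaussian noise (default sd 0.5 on the latent scale); 4% of cells are
blanked completely at random.

Count tables are Dirichlet-multinomial: a planted core (top `core_fraction`
of taxa) receives a base read mass of 0.2, with per-sample proportions
perturbed by a Dirichlet draw (concentration 200) and counts drawn
multinomially at lognormal depths. Core taxa are split into two modules,
each tied to one ecoregion: presence probability 0.97 and an 8-fold
abundance boost inside it, presence 0.25 elsewhere — signal is planted on
presence, not only abundance, so the presence–absence co-occurrence test
has true positives. Non-core taxa are confined to the sites of 1–3 CWP
species, so they can never satisfy the prevalence criterion; with the
boosts, the realized core read share lands near 65–70% of reads while the
core is < 10% of taxa, matching the dominance structure such surveys
report. The generator verifies at build time that every planted core taxon
is present in ≥ 4 CWP species.

Two presets share this structure: `paper` at survey-scale richness
(2000/1500/800/300 taxa; placeholders — per-kingdom richness of the real
survey is not published — and fully configurable) and `desk` at reduced
richness (500/400/300/150) used by the tests and the acceptance script so
end-to-end runs finish in seconds. A separate response simulator
(`simulate_module_response`) generates y = sum beta_g x_g + u_cwp + eps
directly for mixed-model parameter-recovery and coverage experiments,
independent of the count model.

What passing the synthetic recovery tests shows: the pipeline's stages are
wired correctly and recover planted structure when signal is strong
(multipliers ≫ 1, noise sd ≤ 0.5) — selected k equals the planted 4, core
Jaccard ≥ 0.8, walktrap ARI ≥ 0.7, module completeness strictly highest in
the home ecoregion. What it does not show: performance on real amplicon
data, where cores are fuzzier, modules overlap, missingness need not be
MCAR, taxa abundances have heavier tails and spatial/phylogenetic
structure, and effect sizes are smaller. The generator makes no attempt to
simulate sequences, chimeras, taxonomy, or spatial autocorrelation.

## Numerical choices and degenerate inputs

- Exact test: survival-function evaluation, relative agreement with
  rational tails < 1e−10 over every feasible (N ≤ 30, n_a, n_b, j).
- K-means ties in CH break toward smaller k; labels renumbered by size.
- PCA on a table with a constant variable raises, naming the variable.
- Zero-eigenvalue axes weight to identically zero columns.
- Constant z rows (a population whose core reads are uniform) standardize
  to zero with a warning; single-taxon tables raise.
- Boundary mixed-model fits (sigma2_u → 0) return with a warning, never
  raise; bootstrap replicates that fail are dropped and counted.
- Empty fixed sets are legal endpoints of backward selection (intercept-
  only model, R2m = 0).
- Rank ties at the core-selection boundary are all included and logged.

## Known limitations

- The LMM supports a single categorical random intercept — exactly the
  design analysed here; nested or crossed random effects are out of scope.
- Hierarchical partitioning is limited to ≤ 6 groups (2^g refits).
- The co-occurrence model conditions on observed prevalences and assumes
  independent placement across sites; spatial autocorrelation among nearby
  populations is not modelled.
- Imputation assumes MCAR and linear conditional means.
- Wilcoxon exact p-values switch to the normal approximation in the
  presence of ties or zeros regardless of n.
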