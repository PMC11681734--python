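# Methods

## Study design and data model

The pipeline models an ex vivo whole-blood stimulation study: 10 species —
4 resilient to LPS (mouse, rat, rhesus, baboon) and 6 sensitive (rabbit,
pig, cow, sheep, chimpanzee, human) — with 4–5 individuals each, blood
incubated with 0, 10, 100 or 1000 ng/mL E. coli LPS for 2, 6 or 24 h.
Dose 0 at a given time is the paired control for every stimulated sample of
the same individual at that time; "baseline" means dose-0 samples at the
earliest time point (2 h), the closest available estimate of the resting
leukocyte state (configurable via `DEConfig.baseline_time`). All tables are
plain TSV with `NA` as the missing token.

Expression is carried as TPM or log2(TPM + pseudocount), genes × samples,
with an explicit missing mask. Missing means *unmeasured* — typically a gene
with no annotated ortholog in a species — and is propagated, never imputed,
except in the PCA overview (gene-mean imputation, display only).

## Ortholog-space translation

Orthology between a species and human is many-to-many. The translation
groups the relation into connected components of the bipartite graph; within
a component with m species genes (total TPM S) and n human genes, every
human gene receives S/n. Components are the only partition under which
"the m genes" and "the n orthologs" are simultaneously well defined; the
per-human-gene alternative would double-count species genes shared between
human paralogs. Translation runs on the TPM scale (the rule is stated on
abundances) before any log transform, and conserves per-sample mass exactly
(S/n × n = S). A mapped species gene absent from the quantification counts
as abundance 0 (annotation and quantification sets rarely coincide); a human
gene in no component for a species is missing there for all of that species'
samples.

## Quantile normalization

Columns are forced onto the common distribution defined as the mean of the
per-rank sorted columns. Missing cells are excluded from each column's rank
pool; with unequal depths the reference is built on the deepest column's
quantile grid and shallower columns are mapped through linear interpolation
of their quantiles, which reduces to the classic exact algorithm when depths
are equal. Ties receive the mean of their target quantiles. The operation is
exactly idempotent at equal depths. Columns with fewer than two observed
values are refused.

## Baseline group test: blocked GLS with empirical-Bayes moderation

Gene-wise model: log2 expression = group mean (sensitive vs resilient, fixed)
+ block intercept (random) + noise. The blocking unit defaults to species —
the group contrast is between sets of species, so species-level variation is
the relevant exchangeable unit — with `block_on="individual"` exposed for
designs with repeated samples per individual.

1. **Consensus correlation.** For each gene, residuals after removing group
   means are decomposed into between- and within-block mean squares (MSB,
   MSW) with the unbalanced-design effective block size n₀. A single
   consensus ρ is formed from the trimmed means (15% per tail) of the
   per-gene MSB and MSW. Because a trimmed mean of chi-square-distributed
   mean squares is biased low, each trimmed mean is rescaled by the exact
   expected trimmed mean of a χ²(df)/df variable at the design's median
   degrees of freedom, making the consensus Fisher-consistent under a shared
   ρ while trimming retains robustness to outlying genes. Averaging mean
   squares rather than per-gene correlation ratios avoids the Jensen bias
   that makes ratio averages systematically small.
2. **GLS fit.** Each gene is fit by generalized least squares under
   compound symmetry with the consensus ρ: block means enter with weights
   n_b / (1 + (n_b − 1)ρ), and the whitened residual sum of squares has
   N − 2 degrees of freedom. With ρ known this gives an exactly
   t-distributed statistic; in simulation the estimated consensus leaves the
   null fraction of p < 0.05 within Monte-Carlo tolerance of 0.05.
3. **Moderation.** Residual variances are shrunk toward a pooled prior:
   s̃² = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²) estimated by matching the
   mean and variance of log s² under the scaled-F model (digamma/trigamma
   identities, Newton inversion of trigamma). The moderated t is referred to
   a t distribution on d₀ + d degrees of freedom. `moderate=False` gives the
   d₀ → 0 limit (plain GLS), used by the tests as an algebraic anchor.
4. **Multiplicity.** Benjamini–Hochberg step-up across all genes with a fit;
   significance requires fold ≥ `fold_cutoff` (default 2) and FDR ≤ 0.05.

Genes missing in an entire group, or with fewer than two blocks per group,
are excluded with a recorded reason rather than silently dropped. The log2
transform uses pseudocount 1 TPM (bounded at 0, standard for TPM-scale
data; configurable).

## LPS response analyses

Fold changes are computed on TPM + pseudocount within individuals —
log2(TPM_dose + pc) − log2(TPM_0 + pc) at the same time point — not on
normalized values: the response is defined as a fold change in TPM, and the
within-pair design already cancels individual- and sample-level offsets.
The default dose is 10 ng/mL (dose escalation adds little) and the default
time 6 h (the peak of the response in both the emulated design and the
generator's time profile).

*Per species*: moderated one-sample t of the mean response across ≥ 3 paired
individuals, fold ≥ 2, FDR ≤ 0.05. *Between groups*: per-individual
responses feed the blocked moderated machinery above (species as blocks);
the difference-in-fold-changes threshold is multiplicative,
|Δ mean log2FC| ≥ log2(1.5), consistent with the fold-style cutoffs used
elsewhere.

## Complete-divergence screens

A gene separates the groups when every measured value of the higher class
strictly exceeds every measured value of the lower class. The higher class
is decided by the group mean of non-missing values before tolerance is
applied (the simplest consistent decision statistic; recorded in output for
audit). One missing annotation is tolerated in the higher class only — a
missing measurement in the lower class could conceal an overlap, so it
always breaks separation. Ties break separation (conservative reading of
"no overlap"). Missingness from absent orthologs hits whole species, so
tolerance is counted in annotation units (species) rather than columns; the
unit map defaults to the identity for per-individual tables. Ranking uses
the signed difference of group means; ties in rank break lexicographically
by gene ID. For response-mode top-k lists the ranking is restricted to genes
significant in the group-difference test (FDR ≤ 0.05); the baseline screen
applies no DE filter. Both orders are available.

## Proteome discrimination cascade

Three mutually exclusive captures in strict order, on log2 LFQ with species
as replicates: (1) two-group one-way ANOVA where both groups have ≥ 2
detected values — p < 0.05 captures, and any protein with a p-value exits
the cascade; (2) among proteins without a p-value but detected in both
groups and ≥ 4 species total, |difference of group means| ≥ 3 log2 units
captures ("occurrences" read as species with a detected value — the only
replicate unit in species-pooled plasma); (3) proteins detected in exactly
one group capture when seen in ≥ 3 species. Zero within-group variance with
unequal means is treated as maximally significant (p → 0); with equal means
as p = 1. No multiple-testing correction is applied in tier 1 — the raw
p < 0.05 threshold is the capture rule. The same cascade serves whole-plasma
and HDL tables.

## Synthetic-data generator

The generator emulates the study in human-ortholog space on the log2 scale:

| component | default | role |
|---|---|---|
| gene mean μ_g | Uniform(2, 10) log2 TPM | expression landscape |
| noise σ | 0.5 log2 | i.i.d. measurement/biological noise |
| individual intercept | N(0, 0.3), shared across an individual's samples | makes pairing informative |
| species shift | N(0, 0.3) per (gene, species) | real species differ beyond their group; makes species blocking informative |
| baseline effect | ±1.5 log2 to one group, 10% of genes, 50% sensitive-up | planted group difference |
| response effect | 2.0 log2 × dose factor {10: 0.8, 100: 0.9, 1000: 1.0} × time factor {2 h: 0.7, 6 h: 1.0, 24 h: 0.5} | planted LPS induction, 10% of genes |
| group response delta | 1.5 log2 on top of a 0.5 base response, 5% of genes, 80% resilient-stronger | planted response divergence |
| orthology | 1:1 0.80, 2:1 0.06, 1:2 0.06, 2:3 0.03; dropout 0.05 | m:n structure and annotation gaps |

The dose factors encode the observed weak effect of dose escalation; the
time profile peaks at 6 h. TPM = max(2^value − pseudocount, 0), so the log2
transform inverts the generation exactly above 1 TPM.

Orthology component classes are sampled once per human gene for the whole
study; what varies per species is annotation *dropout* (a component absent
from a species' map, feeding the one-missing tolerance) and how a
component's mass is split across its species genes (Dirichlet shares).
Per-species topology classes were rejected: they would give almost every
gene a heavy-tailed species-level distortion from merging with different
partners in different species, which no single-consensus-correlation model
can represent, and they would conflate annotation artifacts with the
group-level biology the planted effects define. Planted genes are placed in
n = 1 components so their effects survive the S/n translation undiluted.
Merged (n ≥ 2) components are reported as the component mean in every
non-reference species — the same cross-species distortion real
ortholog-space translation produces — while the reference species (human)
maps to itself 1:1 and is never missing.

The proteome generator plants, per tier: a 3-log2 group shift with full
detection (ANOVA-detectable); a 5.5-log2 shift detected in 4 species of one
group and exactly 1 of the other, which denies the ANOVA tier a p-value
while clearing the ±3 threshold with high probability; and detection in 4
species of exactly one group. Background proteins have 95% per-cell
detection. Same seed, same bytes, for every output file.

**What the generator does not emulate** — and what passing tests therefore
do not establish about real data: library-size and composition effects
(columns share one TPM scale, so quantile normalization is exercised as an
invariance, not as a correction), count-level (Poisson/NB) noise at low
expression, correlated gene modules and cell-type composition shifts,
phylogenetic correlation among the species (each species' shift is
independent), and effect-size heterogeneity (planted effects are
single-valued, real ones have heavy tails). In particular, complete
divergence across ~50 animals is essentially unreachable at the default
planted effect sizes — the per-individual noise overlaps the groups — so
divergence-screen counts on default synthetic studies are near zero;
screens are validated against an exhaustive oracle and, for illustration,
on configurations with stronger planted divergence (examples/04).

## Numerical and scale choices

Problem sizes in the test-suite and acceptance runs — 2000 orthologs,
10 species × 5 individuals, 20 replicate seeds for calibration and recovery,
500 proteins — were chosen to estimate every reported proportion to ~1%
Monte-Carlo precision while a full run stays in the minutes range.
Tolerances: translation mass conservation and quantile-normalization
properties at 1e-9 (pure floating-point accumulation); algebraic
equivalences (GLS limit, label-swap antisymmetry) at 1e-9; results tables
round-trip through text at 1e-12 (13 significant digits written). The
trigamma inversion uses Newton iteration to 1e-10 relative steps. BH FDR is
delegated to statsmodels, PCA to scikit-learn; limma (R) serves as an
independent oracle for the empirical-Bayes moderation in one test and is
never on the analysis path.

## Known limitations

The consensus-correlation GLS is exactly calibrated only when the
compound-symmetry assumption with a shared ρ holds; heterogeneous per-gene
block correlations (e.g. from species-specific annotation artifacts) push
it anticonservative, which is why the generator models such artifacts as
dropout rather than per-species merging. The moderated t's d₀ + d degrees
of freedom slightly overstate the information in the block-level contrast
when ρ is large and blocks are few. Tier-1 ANOVA treats species as
exchangeable replicates and ignores phylogeny. The screens' group-mean
decision rule for the higher class can, at tolerance ≥ 1, differ from a
rule based on the surviving extremes in contrived near-tie cases; the
decision statistic is recorded per gene so audits can catch this.
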