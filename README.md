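# xlps — cross-species analysis of blood responses to LPS

Species differ over 100,000-fold in their in vivo sensitivity to bacterial
lipopolysaccharide (LPS, endotoxin). Rodents and several non-human primates
survive doses above 1 mg/kg ("resilient": mouse, rat, rhesus, baboon), while
rabbits, pigs, cows, sheep, chimpanzees and humans react to nanogram-scale
doses ("sensitive"). `xlps` is a Python library and command-line pipeline for
asking where that division shows up in blood: it compares whole-blood
leukocyte transcriptomes (ex vivo LPS stimulation at 0/10/100/1000 ng/mL for
2/6/24 h) and plasma proteomes between the two groups, across a shared
human-ortholog gene space. It is aimed at comparative immunologists and
computational biologists who need the full analysis chain — ortholog-space
translation, blocked differential expression, paired response analysis,
complete-divergence screens and proteome discrimination tiers — as tested,
reusable components with a synthetic-data generator for validation.

## What it computes

**Ortholog translation.** When *m* genes of a species share *n* human
orthologs (a connected component of the bipartite orthology relation,
m ≥ 0, n ≥ 1), each human ortholog receives the summed abundance of the *m*
genes divided by *n*. This conserves TPM mass per sample exactly and puts
all species on one gene axis; human genes without an ortholog in a species
are *missing* there, not zero.

**Baseline differential expression.** On quantile-normalized log2(TPM + 1)
from unstimulated 2 h samples, each gene is fit with group (sensitive vs
resilient) as fixed effect and the species as a random-intercept block:
a consensus intra-block correlation ρ is estimated across genes from trimmed
per-gene variance components, each gene is fit by GLS under compound
symmetry with that ρ, and residual variances are moderated by empirical
Bayes — s̃² = (d₀s₀² + d·s²)/(d₀ + d) with (d₀, s₀²) from moment-matching
the scaled-F model — giving a moderated t on d₀ + d degrees of freedom.
Significance: fold difference ≥ 2 and Benjamini–Hochberg FDR ≤ 0.05.

**LPS response.** Per individual, the response is
log2(TPM_dose + 1) − log2(TPM_0 + 1) against the paired same-time control.
Per species, a moderated one-sample t tests mean response ≠ 0 (fold ≥ 2,
FDR ≤ 0.05); between groups, the per-individual responses feed the same
blocked machinery with a difference-in-fold-changes threshold of 1.5.

**Complete-divergence screens.** A gene separates the groups when every
measured animal of the higher class (by group mean) strictly exceeds every
measured animal of the lower class; one missing species annotation is
tolerated in the higher class only. Separated genes are ranked by |group
mean difference| for top-k lists and direction censuses.

**Proteome tiers.** Plasma/HDL LFQ tables pass through three mutually
exclusive captures: two-group ANOVA p < 0.05 (≥ 2 detected values per
group); else |Δ mean log2 LFQ| ≥ 3 with ≥ 4 occurrences across both groups;
else presence in ≥ 3 species of exactly one group.

**Synthetic studies.** `xlps.simulate` generates the whole design — m:n
ortholog maps with per-species annotation dropout, log-normal TPM noise,
individual-level intercepts, species-level expression shifts, and planted
baseline effects, response effects and group-response differences, plus LFQ
tables with planted proteins for each tier — deterministically from a seed,
with ground truth returned alongside the data.

## Worked example

```python
from xlps import DEConfig, SimulationConfig, simulate_transcriptome
from xlps.de import fit_blocked_moderated_test, quantile_normalize

sim = simulate_transcriptome(SimulationConfig(seed=7, doses=(0.0,), times=(2.0,)))
base = sim.sheet.baseline(time=2.0)
logged = quantile_normalize(sim.to_human_space().subset_samples(base.sample_ids).to_log2())
results = fit_blocked_moderated_test(logged, base, DEConfig())
sig = [r for r in results if r.significant]
```

Running `python examples/02_baseline_differential_expression.py` (the same
computation, plus a PCA overview) prints:

```
PCA overview: PC1-3 explain 25.8% of sample variance
194 of 2000 orthologs differ >= 2-fold at FDR <= 0.05 (99 higher in sensitive, 95 higher in resilient)
planted group effects: 200; recovered: 194; false discoveries: 0
  HG00014: log2FC=+2.07, moderated t=+9.2, FDR=2.15e-12
```

194 of the 200 planted group effects are recovered with no false discovery:
the moderated blocked test finds essentially everything the generator hid at
a 1.5-log2 effect, while Benjamini–Hochberg keeps the discovery list clean.
The other examples walk through translation (`01`), the paired response
analysis (`03`), divergence screens (`04`) and the proteome cascade (`05`).

The same stages are available as a CLI for file-based pipelines:

```bash
xlps simulate --seed 13 --out study/
xlps translate --expr study/mouse_expression.tsv --map study/mouse_orthologs.tsv \
               --universe study/human_universe.txt --out mouse_human.tsv
xlps baseline-de --expr human.tsv --sheet study/sample_sheet.tsv --out baseline_de.tsv
xlps proteome-screen --lfq study/protein_lfq.tsv --groups study/protein_groups.tsv --out tiers.tsv
```

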