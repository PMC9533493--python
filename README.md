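# microbreed

Microbiome-driven breeding-value prediction for meat-quality traits in
ruminants.

Rumen microbial gene abundances are heritable in part, and some of them are
genetically correlated with hard-to-measure product-quality traits such as
the beneficial omega-3 and conjugated-linoleic-acid content of meat. That
opens a selection route: instead of waiting for slaughterhouse fatty-acid
profiles, rank candidate animals on breeding values predicted from their
rumen microbiome. `microbreed` implements the full analysis chain for this
strategy:

1. **Compositional preprocessing** (`microbreed.coda`) — core-feature
   filtering by occupancy and mean relative abundance, Bayesian-multiplicative
   (geometric-Bayesian-multiplicative) zero replacement, additive and centred
   log-ratio transforms, and data-driven choice of the alr reference part by a
   Procrustes-correlation / log-variance trade-off. Fatty-acid index traits
   (N3, CLA) as log ratios of nutritionally relevant acid groups.
2. **Genomics** (`microbreed.genomics`) — SNP quality control (call rate,
   Hardy–Weinberg, minor-allele frequency), VanRaden method-2 genomic
   relationship matrix, dosage-TSV and VCF input/output.
3. **Bayesian GBLUP** (`microbreed.gblup`) — uni- and multivariate animal
   models fitted by Gibbs sampling with bounded flat priors; heritabilities,
   genomic correlations, DIC, Bayes factors, HPD intervals and convergence
   diagnostics. An eigendecomposition-rotated sampler is the default; a
   direct mixed-model-equation sampler is kept as a cross-check.
4. **Screening** (`microbreed.screening`) — the host-genomically influenced
   functional core: features whose genomic model beats the non-genomic one by
   DIC and an FDR-controlled Bayes-factor threshold, then features whose
   genomic correlations with the goal traits are jointly significant and
   sign-consistent.
5. **Network reduction** (`microbreed.network`) — co-abundance graph,
   Markov clustering, abundance filtering and redundancy-analysis pruning of
   the selected features.
6. **Breeding** (`microbreed.breeding`) — assembly of the multi-trait
   covariance matrix from pairwise bivariate fits, bending to positive
   definiteness, microbiome-driven EBV prediction with the goal traits set
   missing, per-animal accuracies, truncation-selection intensities and
   posterior response to selection (including correlated responses, e.g.
   methane yield).
7. **Pipeline** (`microbreed.pipeline`, CLI `microbreed`) — the eight stages
   wired together through on-disk artifacts with deterministic per-stage
   seeding and a hash manifest, so reruns are byte-identical.

A calibrated synthetic-data generator (`microbreed.simulate`) produces
genotypes with half-sib family structure, goal traits with chosen
heritabilities and genomic correlations, and a compositional microbiome with
host-genomic structure and realistic sparsity. All documentation examples
and tests run on it.

## Quick start

```python
import numpy as np
from microbreed import coda
from microbreed.simulate import SimulationSpec, simulate_population
from microbreed.gblup import GBLUP, McmcConfig

pop = simulate_population(
    SimulationSpec(n_animals=150, n_snps=800, n_features=60, seed=11)
)

# compositional preprocessing of the microbiome
core, report = coda.filter_core(pop.microbiome)
print(f"core features: {report['n_retained']} of {report['n_in']}")
table = coda.replace_zeros_gbm(core)
ref = coda.select_alr_reference(table)
print(f"alr reference: {ref.best} "
      f"(Procrustes r = {ref.table.loc[ref.best, 'procrustes_correlation']:.4f})")
alr = coda.alr_transform(table, ref.best).to_frame()

# bivariate animal model for the two fatty-acid goal traits
model = GBLUP(pop.traits[["N3", "CLA"]], pop.grm, pop.traits["fixed_level"])
res = model.fit(McmcConfig(n_iter=20_000, burn_in=4_000, thin=4, seed=1))
for t in ("N3", "CLA"):
    d = res.heritability_draws(t)
    print(f"h2[{t}] = {d.mean():.2f} (posterior sd {d.std(ddof=1):.2f})")
rg = res.genomic_correlation_draws("N3", "CLA")
print(f"rg[N3,CLA] = {rg.mean():.2f} (posterior sd {rg.std(ddof=1):.2f})")
```

Output:

```text
core features: 58 of 60
alr reference: KO00039 (Procrustes r = 0.8751)
h2[N3] = 0.69 (posterior sd 0.16)
h2[CLA] = 0.63 (posterior sd 0.17)
rg[N3,CLA] = 0.59 (posterior sd 0.19)
```

(The generating values were h² = 0.76/0.57 and rg = 0.39; at n = 150 the
posteriors are wide, as the reported standard deviations show.)

## Running the full pipeline

```bash
microbreed init-config my_run.yaml   # write a template with all defaults
microbreed run -c my_run.yaml        # simulate -> ... -> report
microbreed run -c my_run.yaml --stages screen,select,predict,report
```

Each stage reads its inputs from and writes its outputs to the configured
output directory; a `manifest.json` records the configuration hash and the
SHA-256 of every artifact. Real data can be supplied through
`genotype_path` (dosage TSV or VCF), `microbiome_path` (counts TSV,
features × samples) and `phenotype_path` (CSV with the goal traits and a
`fixed_level` column); otherwise the simulate stage generates a study.

Chain lengths default to desk-scale settings (20 000 iterations, 4 000
burn-in, thinning 4). Set `paper_scale: true` for publication-scale chains
(1 000 000 / 200 000 / 100); everything else is unchanged.

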