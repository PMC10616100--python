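# eqtlshare

A tested pipeline for **spatiotemporal cis-eQTL analysis** across fetal-like
and adult pancreatic tissues: it maps expression and isoform-usage QTLs with a
kinship-aware linear mixed model, fine-maps each signal with single-causal
Bayes factors, colocalizes signals across tissues under the five-hypothesis
Bayesian model, groups colocalized signals into validated network modules,
classifies every signal and module by tissue-sharing category and
eGene-overlap plasticity, and integrates GWAS traits with 99% credible sets.
It ships with a synthetic-data generator that plants every sharing pattern
with known ground truth, so the whole pipeline is testable end to end without
any external data.

It is written for statistical geneticists who want a desk-scale, fully
reproducible re-implementation of this analysis style — e.g. to study how the
sharing categories behave under controlled LD, power and relatedness.

## The models

**Association.** For feature *i* and variant *j* (dosages 0/0.5/1):

```
y_i = beta_ji g_j + C b + u + eps,     cov(u) = sg^2 K,  eps ~ N(0, se^2 I)
```

fitted EMMAX-style (kinship eigendecomposed once; variance ratio per feature
from the null model; GLS per variant). Multiple testing is two-step:
gene-level correction by the effective number of tests M_eff (eigenvalues of
the windowed variant correlation matrix), then genome-wide Benjamini-Hochberg
over feature leads at q <= 0.01, with up to five stepwise conditional rounds.

**Fine-mapping.** Wakefield approximate Bayes factors from (p, MAF, N):
`log ABF = 0.5 [log(V/(V+W)) + z^2 W/(V+W)]` with `V = 1/(2 N f (1-f))`,
`W = 0.15^2`; causal posteriors are the softmax of the log-ABFs, credible
sets the shortest posterior-descending prefix reaching 99%.

**Colocalization.** For two signals over >= 500 shared variants, the five
hypotheses H0 (neither), H1/H2 (one trait only), H3 (both, distinct causal
variants), H4 (both, same causal variant) get posteriors from log-space sums
of the per-variant ABFs with priors p1 = p2 = 1e-4, p12 = 1e-5; pairs are
*shared* at PP.H4 >= 0.8 and *distinct* at PP.H3 >= 0.8.

**Modules.** Shared pairs form a graph per chromosome and phenotype class;
Leiden communities (modularity, resolution 0.3, 500 iterations) become
modules if >= 30% of all member pairs are H4 and #H4 >= 2 x #H3. Modules are
then categorized by member tissues (seven categories, from iPSC-PPC-unique
through fetal-adult) with per-category LD exclusions (r^2 >= 0.2 within
500 kb, distance fallback), and fetal-sharing modules get eGene-overlap
labels (zero/same/partial/different) per adult tissue.

**GWAS.** An eQTL-trait colocalization is accepted when it shares >= 500
variants and its lead shared variant is genome-wide significant (p <= 5e-8);
modules require >= 30% of members colocalized and H4 >= 2 x H3. Each
(eQTL unit, trait) combination is one locus, reported with the smallest
99% credible set over its members.

## Worked example

The numbered drivers under `analysis/` run the benchmark study (three tissues
of 150 samples, 90 genes — ten per sharing category, ten tissue-unique
singletons, ten nulls — 600 variants per gene at within-block r^2 ~ 0.9):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_map_eqtls.py
python analysis/03_finemap_and_colocalize.py
python analysis/04_modules_and_sharing.py
python analysis/05_integrate_gwas.py
```

which prints (seed 1):

```
iPSC-PPC: 46 significant signals over 46 features
adult-islet: 42 significant signals over 42 features
adult-whole-pancreas: 43 significant signals over 43 features
fine-mapped 131 signals; median 99% credible-set size 22
colocalized 61 candidate pairs: {'shared': 60, 'underpowered': 1}
40 validated modules; categories: {'fetal-adult': 10, 'fetal-islet': 10,
  'adult-shared': 10, 'fetal-whole-pancreas': 10}
planted-category recovery: 100.0% of 80 non-null genes
10 GWAS traits tested; 10 loci called (10 attributed to the fetal tissue)
credible-set size buckets: {'1': 2, '2-10': 2, '>10': 6}
```

Reading this: the scan recovers the 130 planted gene-tissue effects (plus an
FDR-level remainder); every multi-tissue gene's signals colocalize (PP.H4 >=
0.8) and form a validated module of the planted category; single-tissue genes
surface as tissue-unique singletons after the LD exclusion checks; and every
synthetic GWAS trait sharing a causal variant with a fetal-unique eQTL is
attributed to the fetal tissue with both eligibility filters holding. All
tables land under `results/` with the configuration hash and seed in their
headers.

The same pipeline is scriptable via the CLI
(`eqtlshare all --config cfg.yaml --seed 1 --out out/`) or the library
(`eqtlshare.pipeline.simulate_study` / `run_pipeline` / `integrate_gwas`).

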