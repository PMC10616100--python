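# Methods

This package re-implements, end to end, a spatiotemporal cis-eQTL analysis
across three pancreatic tissues — fetal-like iPSC-derived pancreatic
progenitors (iPSC-PPC), adult islets, and adult whole pancreas — and exercises
it on synthetic multi-tissue data with known ground truth. This note records
the models, the defaults that matter, what the generator does and does not
emulate, and the numerical choices.

## Association model

For feature *i* (gene expression or isoform usage, quantile-normalized to
N(0,1)) and variant *j* (dosage coded 0/0.5/1):

    y_i = beta_ji * g_j + C b + u + eps,   cov(u) = sg^2 K,   eps ~ N(0, se^2 I)

with K the standardized-dosage kinship (plink `--make-rel` convention:
dosages centred by allele frequency, scaled by sqrt(f(1-f)/2), averaged over
variants; self-kinship ~ 1). The model is fitted EMMAX-style: K is
eigendecomposed once per cohort, the variance ratio delta = se^2/sg^2 is
estimated per feature by maximum likelihood on the covariate-only null model
(1-D bounded optimization over log delta in [-10, 10]), and every cis variant
is then scored by generalized least squares in the rotated space with a
t-test on n - k - 1 degrees of freedom. With K = I this is exactly OLS, which
the tests assert to 1e-6. Whether conditional rounds re-estimate delta:
yes — the covariate set changed, so the null model is re-fitted each round.

Because the synthetic panel contains only the cis windows of the simulated
genes (the real study built K from 439k genome-wide common variants), the
scan uses leave-one-chromosome-out kinship: the tested chromosome's variants
are excluded from K, otherwise the random effect absorbs the cis signal
(proximal contamination). When no off-chromosome variants exist the cohort
kinship is used as given.

Variant filters before the scan: MAF > 5%, Hardy-Weinberg exact-test
p > 1e-6 (Wigginton-style exact test, written here because no installed
package provides one; validated against an exact-fraction enumeration),
call rate > 99%, position within 500 kb of the gene body. Expressed features:
genes with TPM >= 1 in >= 10% of samples; isoforms additionally need usage
>= 10% in >= 10% of samples and a parent gene with >= 2 expressed isoforms.

## Multiple testing

Two-step: (1) gene-level, p_corrected = min(1, p x M_eff) with M_eff the
effective number of tests from the eigenvalues of the variant correlation
matrix in windows of 200 variants (per window, the smallest k whose top
eigenvalues explain >= 99% of the trace; summed over windows). Window size
and variance threshold follow the standard tool's defaults and are
config-exposed. (2) Genome-wide Benjamini-Hochberg across per-feature leads;
significance at q <= 0.01. The lead is the minimum corrected p, ties broken
by largest |beta|, residual ties by smallest position (the positional rule is
ours — the source procedure is silent past |beta| — and guarantees
determinism). Conditional signals: up to five rounds, each adding all prior
lead genotypes as covariates; rounds are run across features so BH is applied
per round genome-wide (the single-feature entry point gates on the corrected
p directly, i.e. BH with m = 1).

At the benchmark LD (within-block r^2 ~ 0.9, 24 blocks x 25 variants) the
windowed M_eff measures ~190 of 600 variants — conservative relative to the
~24 truly independent blocks. Note the consequence: BH at q <= 0.01 still
admits ~1% false discoveries, so across hundreds of null feature scans an
occasional null gene becomes a significant "eQTL" and is then annotated like
any other signal. This is inherent to the FDR layer, not a calibration
defect: the null-study check (500 null genes) finds no feature at q <= 0.01
and KS-uniform pooled p-values, while the 5-seed benchmark, with its 450
null gene-tissue scans, can surface a borderline false discovery.

## Fine-mapping

Single-causal Wakefield approximate Bayes factors from (p, MAF, N):
z from the two-sided normal inverse of p (signed by beta when available —
the sign does not enter the ABF), V = 1/(2 N f (1-f)) for a unit-variance
quantitative trait, W = w_sd^2, log ABF = 0.5[log(V/(V+W)) + z^2 W/(V+W)],
all in log space. Priors: w_sd = 0.15 (quantitative), 0.2 (case-control) —
the referenced tool's published defaults, config-exposed; traits are assumed
quantitative unless declared case-control. Posteriors are the softmax of the
log-ABFs; 99% credible sets are the shortest pp-descending prefix reaching
the level, pp ties ordered by position. Candidate causal variants: pp >= 1%
(eligibility) and pp >= 5% (enrichment). Annotation enrichment is a 2x2
Fisher exact test of candidates vs a background variant set, BH-corrected;
by default candidates are excluded from the background (the source is silent;
both modes are supported). Interval inputs are accepted 1-based closed
(VCF-like) or BED half-open and normalized internally to 0-based half-open.

## Colocalization

Five-hypothesis Bayesian colocalization on the inner join (strict
chrom/pos/ref/alt identity; no strand flips or allele swaps — conservative)
of two association tables. With S1 = logsumexp(labf1), S2 = logsumexp(labf2),
S4 = logsumexp(labf1 + labf2):

    L0 = 0;  L1 = log p1 + S1;  L2 = log p2 + S2;
    L3 = log p1 + log p2 + logdiff(S1 + S2, S4);  L4 = log p12 + S4

and the posteriors are the softmax of (L0..L4). Priors p1 = p2 = 1e-4,
p12 = 1e-5 (the tool defaults; config-exposed). Pairs sharing < 500 variants
are `insufficient_overlap` and skipped. Classification: shared if
PP.H4 >= 0.8, distinct if PP.H3 >= 0.8, else underpowered. The log-space
sums are tested against a brute-force enumeration over all (variant-for-
trait-1, variant-for-trait-2) configurations to 1e-8. Signals of the
gene-expression and splicing classes are colocalized separately, and only
pairs whose gene bodies lie within 3 Mb are tested. Per-signal log-ABFs are
computed once and shared between fine-mapping and colocalization.

## Modules

Per (chromosome, phenotype class): nodes are all signals in eligible pairs,
edges the shared pairs; Leiden community detection with the modularity
objective, resolution 0.3, 500 iterations, and a fixed seed (default 1 —
the source reports no seed; partition stability across seeds is observable,
not asserted). Communities of size 1 are not modules. Validation over all
C(k,2) member pairs: H4 fraction >= 30% and #H4 >= 2 x #H3. "All pairs"
counts untested pairs in the denominator (the stricter reading, supported by
the worked four-member example of six pairs; a config switch restricts to
tested pairs); underpowered pairs count toward neither H4 nor H3. Validated
modules get ids `<GE|AS>_<chrom>_<int>`, numbered by ascending minimum
member lead position.

## Tissue-sharing annotation

LD between two signals uses their representative candidate causal variants:
the highest-pp variant genotyped in the reference panel, walking down the
pp order over variants with pp >= 1%; a signal with no such variant is
ineligible for annotation entirely. Two signals are in LD iff their
representatives are within 500 kb and r^2 >= 0.2, or r^2 is unavailable
(panel-absent variant) — the distance fallback; beyond 500 kb they are never
in LD. Distances are absolute differences of 1-based positions.

Singletons (no shared classification with any signal) are checked against
every other signal of the same phenotype class in any tissue, conditional
leads included; an LD hit makes them ambiguous, otherwise they are
tissue-unique singletons of their own tissue. Validated modules take a
seven-way category from their member tissue set; single- and two-tissue
categories then require every member to show no LD with any signal of the
excluded tissue(s) (e.g. fetal-islet excludes whole pancreas; adult-shared
excludes fetal only, as stated — whether islet-vs-whole-pancreas LD was also
meant is unstated and not applied); fetal-adult has no LD check. Violations
make the whole module ambiguous.

Fetal-sharing modules get per-adult-tissue eGene-overlap labels (zero /
same / partial / different, comparing gene sets with splicing signals mapped
to their parent gene) and an A-E plasticity category: A same with one adult
tissue, B same with both, C partial (any partial label, or mixed
same/different — the mixed case is not enumerated by the source scheme and
is folded into the partial class), D different with one, E different with
both.

## GWAS integration

Each eQTL-trait colocalization must share >= 500 variants and have a
top shared candidate causal variant (argmax of labf_eqtl + labf_gwas) with
GWAS p <= 5e-8 — the significance filter applies to the lead shared variant,
as stated, not to the whole credible set. A module colocalizes with a trait
when >= 30% of its members individually colocalize (PP.H4 >= 0.8) and member
H4 >= 2 x H3; members rejected on overlap stay in the denominator. Each
accepted (unit, trait) combination is one locus, id `trait|unit`. The locus
99% credible set comes from the member colocalization yielding the fewest
variants, ties broken by highest PP.H4; sizes are bucketed 1 / 2-10 / >10.

## Synthetic data

Genotypes: each gene owns a ~1 Mb window of 24 LD blocks x 25 variants
(600 — the colocalization overlap filter of >= 500 variants makes smaller
windows pointless). Per sample a block draws two latent haplotype bits at
the block allele frequency (uniform in the configured MAF range); each
variant copies the block haplotype per haploid genome except with
probability `within_block_flip_prob` it is re-drawn from the block
frequency. The re-draw preserves the marginal MAF exactly and gives pairwise
within-block r^2 = (1 - flip)^4 (helper `flip_prob_for_r2`); across blocks
variants are independent. Dosages are 0/0.5/1 end to end. Gene regions are
striped across the 22 autosomes, 10 Mb apart, so colocalization candidates
arise only within a gene's own window. Tissue cohorts are independent sample
draws over the same variant map; a further independent draw serves as the LD
reference panel (emulating an external reference). Optional sibling pairs
share one parental haplotype; kinship is then computed, never assumed.

Phenotypes: y = effect x standardized causal dosage + polygenic background
(covariance polygenic_sd^2 K, default 0.3 — a modest heritable background)
+ iid noise (sd 1). The effect multiplies the *standardized* dosage, i.e. it
is in phenotype-SD-per-genotype-SD units, so power is MAF-independent;
benchmark |effect| = 0.8 gives per-variant z ~ 7-8 at n = 150. Summary
statistics (colocalization-only tests, GWAS traits) come from the standard
RSS/LD approximation: marginal standardized effect = LD correlation with the
causal variant x true effect, plus noise with per-variant standard error
1/sqrt(N) correlated across variants by the panel LD matrix (a small 1e-6
jitter stabilizes the Cholesky). The LD-correlated noise matters: with
independent noise a large-N GWAS concentrates its posterior on an arbitrary
block variant and colocalization collapses. GWAS traits use N = 50,000 and a
standardized effect of 0.05 (z ~ 11, comfortably genome-wide significant, as
a well-powered biobank trait would be).

Sharing categories are planted per gene: multi-tissue categories share one
identical causal variant across their active tissues; single-tissue
categories and "singleton-unique" plant one causal tissue (so they surface
as tissue-unique singletons — the module path is exercised by the
multi-tissue categories); null genes have no effect anywhere.

What the generator does not emulate: realistic recombination maps or LD
decay with distance (r^2 is flat within a block, zero between), population
structure, allele-frequency spectra, missing genotypes, expression count
noise or library-size effects, trans effects, and real covariates (PEER
factors are out of scope; covariates enter as an opaque matrix). Passing
tests therefore show the machinery is correct under the stated statistical
assumptions, not that the thresholds are optimal for real data.

## Problem sizes and determinism

The benchmark study is 90 genes (10 per 7 sharing categories + 10 singleton
+ 10 null) x 3 tissues x 150 samples x 600 variants per gene, run over five
seeds — chosen so the whole suite and the acceptance script each run in
minutes on one CPU while still exercising every category ten times per seed.
Every generator is a pure function of (config, seed); rng streams are split
per artefact (panel draw, truth, phenotypes, summary noise), so each stage
is reproducible in isolation. All reports carry the configuration hash and
seed; reruns are byte-identical.

## Known limitations

- Single-causal fine-mapping only (no SuSiE-style multi-causal sets); the
  conditional scan mitigates but credible sets of multi-causal signals are
  not decomposed.
- The colocalization network uses binary H4 edges; PP.H4 magnitudes are not
  used as weights.
- An occasional null gene passes the q <= 0.01 FDR layer (~1% of
  discoveries by construction) and is then annotated as a tissue-unique
  singleton like any significant signal; downstream consumers should treat
  singleton categories with the usual FDR caveat.
- The A-E plasticity mapping folds mixed same/different label pairs into the
  partial class (C); the source scheme does not enumerate that case.
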