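# Methods

`locuslens` implements a functional-genomics workflow for interpreting
GWAS loci: which gene(s) does each association actually implicate, is the
marker variant tied to cis-regulatory activity, and how many independent
functional variants does a locus harbour? This note records the models,
the defaults and the design decisions, and what the synthetic-data tests
do and do not establish about real data.

## Tier classification of loci

A locus carries one or more marker variants and a set G of GWAS-annotated
genes. Evidence genes Q are collected by three routes, unioned over the
locus's markers:

1. **eQTL / sQTL exact match** — a marker variant appears verbatim
   (normalized `chrom:pos:ref:alt` identity, rsIDs resolved through an
   alias table) in a table of significant tissue-level cis-eQTLs or
   sQTLs. Exact identity is deliberate: no colocalization model is fitted
   and no LD relaxation is applied at this stage, which avoids the
   single-causal-variant assumptions such models impose at the cost of
   missing overlap when GWAS and QTL analyses chose different markers for
   the same haplotype.
2. **Position** — any transcript whose genomic span (introns included)
   covers the marker position contributes its gene, regardless of strand.
   Span rather than exon union is used because intronic hits count as
   positional evidence.
3. For loci with no evidence at all, **proxy expansion** searches a
   haplotype reference panel for variants with r² > 0.8 (strict) within a
   1 Mb window, interpreted as ±500 kb around the query, and the QTL
   lookup is repeated on the expanded set.

The tier rule: Q = ∅ → Tier 3; Q ⊆ G (non-empty) → Tier 1; otherwise new
genes exist and G ⊆ Q → 2A, G ∩ Q ≠ ∅ → 2B, G ∩ Q = ∅ → 2C. Two
boundary cases are fixed by convention: a locus whose evidence supports
only a subset of G while introducing nothing new is still Tier 1 (the
annotation is supported, nothing is added), and the degenerate G = ∅
with evidence present classifies 2C (every evidence gene is new). In the
per-source bookkeeping a new gene implicated by more than one route
counts under "combination", including when the routes come from
different markers of the same locus.

Gene coding status follows fixed transcript-biotype vocabularies
(Ensembl/BioMart dialect, normalised for case and space/underscore/hyphen
variation): a gene is non-coding only if every transcript classifies
non-coding, and an unrecognised biotype is an error rather than a silent
default. Both `transcript_biotype` and `transcript_type` GTF attribute
keys are accepted.

## Linkage disequilibrium

For phased haplotypes, D = p_AB − p_A·p_B, r² = D²/(p_A q_A p_B q_B) and
D′ = |D|/D_max with the usual sign-dependent D_max. For unphased dosages
the default is maximum-likelihood haplotype frequencies via EM over the
double-heterozygote phase ambiguity (the genetics convention), with
squared Pearson correlation of dosages ("composite") retained as a
robustness check; the EM estimate equals the phased computation exactly
when no double heterozygotes exist, and an all-double-heterozygote input
is flagged as non-identifiable. Missing dosages are pairwise-deleted with
a floor of 20 informative samples. Threshold comparisons used elsewhere
(r² > 0.8, > 0.9, < 0.1; D′ > 0.9) are strict inequalities; boundary
equality is excluded. LD clustering is average-linkage hierarchical
clustering on 1 − r², returning leaf order (heatmap rendering) and labels
at a configurable cut (default 0.5).

## Allelic expression imbalance

At a heterozygous transcribed site, REF_RATIO = REF/(REF+ALT) is
compared to NULL_RATIO, the expected reference fraction under allelic
balance. NULL_RATIO absorbs mapping/reference bias, so bias alone gives
zero deviation. The per-sample call — the published analyses this
follows plot deviations without stating a call rule, so the rule here is
a parameterised choice — is a two-sided exact binomial test of REF_COUNT
against NULL_RATIO at α = 0.05, gated at a minimum of 8 reads (low-count
sites remain usable but very shallow ones are uninformative). No
multiple-testing correction is applied across samples within one
variant-tissue cell (raw per-sample calls are what gets counted);
Bonferroni across variants is available where a family is defined.
Summaries per variant-tissue require ≥ 5 samples and report the number
called, direction consistency (the larger directional share among calls)
and the median deviation. "Every informative sample imbalanced" is
reported as a marker-quality annotation — a marker in imperfect LD with
the functional variant should leave some carriers balanced — never as a
filter.

The LD-stratified control separates cis effects from locus-wide
artefacts (e.g. preferential amplification): partners in strong LD
(r² > 0.9) with the target should share true imbalance, partners in weak
LD (r² < 0.1) should not, while a systematic artefact reaches both. A
site is "enriched" when ≥ θ (default 0.5) of its informative samples are
called imbalanced; majority-enriched strong partners with
majority-unenriched weak partners → `true_aei`, majority-enriched weak
partners → `suspected_bias`, anything else (including an empty partner
stratum) → `inconclusive`.

Detection power of the binomial call depends steeply on depth: against
an allelic fold-change of 2 (reference share 2/3) the exact power is
0.43 at 30 reads, 0.82 at 80 and 0.90 at 100. Tests of the ≥ 0.9
detection property therefore evaluate at depth 100 and assert the exact
enumerated power, with the simulator's Monte-Carlo rate checked for
consistency against that exact value.

## Independent eQTL signals

The cis scan fits expression ~ dosage (+ covariates) per variant by
least squares, with dosages standardized so slopes are comparable across
allele frequencies; significance is Bonferroni over tested pairs by
default. Under a single functional variant the population slope at a
proxy equals r × (causal slope) for standardized dosages, so observed
|beta| plotted against r² with the lead eQTL should track
√r²·|beta_lead|. The lead is the minimum-p variant, ties broken by
larger |slope| then smaller position.

Signal enumeration formalises "more significant than LD predicts":
starting from the lead's tight-LD cluster (graph components under
r² > 0.9 AND D′ > 0.9), any unassigned variant with r² < 0.5 to every
current lead whose |beta| exceeds √(max r² to a lead)·|that lead's beta|
by more than τ·|first lead's beta| (τ = 0.25) flags a further signal;
the most significant such variant seeds it, and the iteration continues
until no excess remains. The independence cut-off 0.5 reflects the
r² ≈ 0.5 regime in which secondary clusters were observed; τ and the
cut-off are exposed parameters calibrated on simulations, not fitted to
any reference cohort. Conditional-regression confirmation of each added
signal is available through the nested-model module but off by default,
keeping the diagnostic self-contained. The report is invariant to input
row order.

## Nested association models

Expression responses use a Gaussian GLM, disease a logit GLM with
additive minor-allele dosage coding. Covariate defaults in the synthetic
phenotype mirror common practice (sex and age for expression; richer
clinical covariates belong to the caller's data). Nested fits on the
same rows are compared by likelihood ratio: 2·ΔlogLik ~ χ² on the
parameter difference, with Bonferroni over the emitted comparison family
(the family size is the number of rows in the emitted table, logged
explicitly) and AIC = 2k − 2·logLik per model; for Gaussian fits k
includes the MLE variance parameter. A marker perfectly collinear with
included terms is dropped as aliased and its comparison reported
uninformative (df = 0, p = 1) rather than failing — this is exactly the
behaviour expected when a perfect LD proxy is added, and it is reported,
not hidden. The sequential table emits each marker alone against the
covariate base and each marker "in context of" the previously
accumulated markers. Exact p-values are reported throughout; no
numerical flooring is emulated. The genotype-stratified comparison runs
a two-sided Wilcoxon rank-sum test of expression by disease status
within each dosage group, exact for small untied groups, with
empty-class groups flagged untestable.

## eQTL power

One-way ANOVA across genotype classes under HWE weights
((1−p)², 2p(1−p), p²) with class means μ(1−δ), μ, μ(1+δ) — δ = 0.2
encodes a "40% effect" (homozygote means 40% apart around the median
expression μ). Noncentrality λ = n·Σw(μ_g−μ̄)²/σ²; power is the upper
tail of noncentral F(2, n−3) at the Bonferroni per-test α (default
0.05/5×10⁶). σ is a free parameter defaulting to a coefficient of
variation of 0.3 times μ — reference implementations derive variance
from a CV internally and published analyses do not print it, so the
default is a documented choice, configurable. At λ = 0 the central F
tail is used directly (the noncentral survival function is numerically
unreliable at zero noncentrality), making size exactly the per-test α.

## Synthetic data: what it emulates and what it does not

The generator produces every input format the pipeline reads, with
planted truth.

**Haplotypes** follow a founder-mosaic model, not a coalescent: each
block descends from k derived founder haplotypes segregating against an
implicit ancestral all-reference background; every variant's alternate
allele sits on a non-empty subset of the founders, consecutive variants
reuse the previous variant's subset with probability `ld_tightness`
(default 0.8, giving runs of perfect LD as in real blocks), and founder
choice is independent across blocks. k = 1 places the whole block on one
derived haplotype — perfect within-block coupling — which is the
degenerate case used wherever tests need an exact r² = 1 regime.
Empirical MAFs are constrained to `maf_range` (default 0.1–0.5) with
bounded resampling; an unsatisfiable constraint (e.g. a tight low-MAF
band with few founders, whose achievable frequencies are coarse) raises
an error naming the variant. Genotypes pair independent chromosomes, so
Hardy–Weinberg holds by construction. The model reproduces the LD
regimes the pipeline consumes (r² > 0.9, ≈ 0.5, < 0.1) but not
realistic recombination-driven LD decay with distance.

**Expression**: E[y | g] = μ·(1 + Σ_v δ_v (g_v − 1)) plus Gaussian noise
(default sd 1.0 against μ = 10, i.e. strong planted effects are ~2 noise
sd between homozygotes); non-target genes are noise-only.

**Allelic counts**: depth ~ negative binomial (default mean 50,
dispersion 5 — overdispersed as RNA-seq site depths are; mean 50 sits
above the ~30-read floor below which ratio estimates are unstable);
REF_COUNT ~ Binomial(depth, p) with p = ρx/(ρx+(1−ρ)(1−x)), x = a/(1+a)
for allelic fold-change a and reference bias ρ. The emitted NULL_RATIO
is p at a = 1 (= ρ), matching the semantics in which bias alone yields
zero deviation; passing a different `null_ratio` plants exactly the
unabsorbed-bias artefact the LD-stratified control is meant to catch.

**Catalog**: one locus per requested tier, each in its own genomic
region with a strong-LD marker block and a weak-LD control block, gene
models mixing coding and non-coding biotypes, a two-SNP Tier-1 locus, a
Tier-3 locus with no QTL and no overlapping transcript, GTEx-dialect QTL
tables, a GWAS hit table, an rsID alias table and truth JSON. Outputs
are byte-identical for a fixed seed.

Deliberate simplifications: tissues are independent sample sets (no
donor sharing across tissues), no read-level RNA-seq simulation, no
coalescent LD decay. Consequently, passing tests establish that the
methods recover what they are designed to recover under their stated
models — they do not establish robustness to cross-tissue correlation,
alignment artefacts beyond a multiplicative reference bias, or fine-scale
LD structure.

## Problem sizes and numerical choices

Simulation-based tests use n = 500 samples per replicate with 100–200
replicates for rate assertions (≥ 95% single-signal, ≥ 80% two-signal,
≥ 90% AEI-control labelling), 500 simulations for null-uniformity KS
checks, 1000 sites for calibration envelopes, and n = 5000 for the HWE
chi-square — sizes at which the asserted rates are stable across seeds.
Monte-Carlo power checks run at a relaxed per-test α = 10⁻³ (the same
noncentrality machinery) because rejection events at 10⁻⁸ are not
observable in feasible replicate counts. Ties in lead selection are
broken deterministically (p, then |slope|, then position); hierarchical
clustering distances are symmetrised and clipped to [0, 1] before
linkage; EM runs to a 10⁻¹⁰ tolerance with a 1000-iteration cap and
reports non-convergence as an error.

## Known limitations

- Exact-identity QTL matching misses loci where GWAS and QTL analyses
  tagged the same signal with different markers; proxy expansion
  recovers some of this only for otherwise-empty loci, as specified.
- The AEI call rule is one defensible formalisation of "exhibits
  imbalance"; published counts based on an unstated criterion are not
  reproduced, only the qualitative strong/weak-LD pattern.
- The signal-enumeration margin τ and independence cut-off are
  simulation-calibrated defaults; on real cohorts they should be
  sensitivity-checked, and conditional regression used as confirmation.
- Power results depend on the unprinted residual-variance convention;
  comparisons across tissues are meaningful, absolute values depend on
  the chosen CV.
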